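"""End-to-end MR orchestration: select -> clump -> harmonize -> outlier scan
-> estimate -> diagnostics, with tidy TSV/JSON reports.

The run configuration is a plain dataclass loadable from YAML or JSON; every
report embeds the resolved configuration and seed, so two runs with the same
manifest are identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .clump import LDTable, clump
from .estimators import (
    cochrans_q,
    estimates_frame,
    ivw,
    leave_one_out_sweep,
    mr_egger,
    per_doubling,
    weighted_median,
)
from .harmonize import HarmonizedSet, harmonize_pair
from .presso import presso
from .strength import f_statistic, mr_power_binary, variance_explained
from .sumstats import SummaryStatsTable, read_sumstats, select_instruments

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failure, labelled with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Resolved configuration for one MR run."""

    exposure_path: str
    outcome_path: str
    exposure_trait: str = "exposure"
    outcome_trait: str = "outcome"
    exposure_type: str = "continuous"
    exposure_columns: str | dict = "default"
    outcome_columns: str | dict = "default"
    ld_path: str | None = None
    p_index: float = 5e-8
    r2_max: float = 0.001
    window_kb: float = 10_000
    palindromic_band: float = 0.08
    estimators: list[str] = field(
        default_factory=lambda: ["ivw", "egger", "weighted_median"]
    )
    run_presso: bool = True
    presso_n_sim: int = 1000
    presso_alpha: float = 0.05
    exclude_presso_outliers: bool = True
    power_or: float = 0.8
    power_alpha: float = 0.05
    outcome_n_case: int | None = None
    outcome_n_control: int | None = None
    out_dir: str = "mr_run"
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class MRReport:
    """Bundle of per-run outputs; ``write`` emits TSV/JSON under out_dir."""

    config: RunConfig
    harmonized: HarmonizedSet
    estimates: list
    heterogeneity: object | None
    presso_result: object | None
    loo: dict
    strength: dict

    def write(self, out_dir: str | Path | None = None) -> Path:
        out = Path(out_dir if out_dir is not None else self.config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        estimates_frame(self.estimates).to_csv(out / "estimates.tsv", sep="\t", index=False)
        self.harmonized.write_tsv(out / "harmonized.tsv")
        if self.heterogeneity is not None:
            pd.DataFrame(
                [
                    {
                        "Q": self.heterogeneity.Q,
                        "df": self.heterogeneity.df,
                        "I2": self.heterogeneity.I2,
                        "pvalue": self.heterogeneity.pvalue,
                    }
                ]
            ).to_csv(out / "heterogeneity.tsv", sep="\t", index=False)
        if self.presso_result is not None:
            self.presso_result.to_json(out / "presso.json")
        if self.loo:
            rows = [
                {"excluded_rsid": r, "beta": e.beta, "se": e.se, "pvalue": e.pvalue}
                for r, e in self.loo.items()
            ]
            pd.DataFrame(rows).to_csv(out / "leave_one_out.tsv", sep="\t", index=False)
        scatter_frame(self.harmonized, self.estimates).to_csv(
            out / "scatter_data.tsv", sep="\t", index=False
        )
        manifest = {
            "package_version": __version__,
            "config": self.config.to_dict(),
            "n_instruments": len(self.harmonized.variants),
            "dropped": self.harmonized.dropped,
            "strength": self.strength,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        return out


def scatter_frame(s: HarmonizedSet, estimates) -> pd.DataFrame:
    """Per-SNP effects plus fitted slopes/intercepts — the data behind
    scatter, forest and funnel plots."""
    rows = [
        {
            "rsid": v.rsid,
            "beta_exp": v.beta_exp,
            "se_exp": v.se_exp,
            "beta_out": v.beta_out,
            "se_out": v.se_out,
            "wald_ratio": v.beta_out / v.beta_exp,
            "wald_se": v.se_out / abs(v.beta_exp),
            "precision": abs(v.beta_exp) / v.se_out,
        }
        for v in s.variants
    ]
    df = pd.DataFrame(rows)
    for e in estimates:
        label = e.method.split(" (")[0].lower().replace(" ", "_").replace("-", "_")
        df[f"fit_slope_{label}"] = e.beta
        df[f"fit_intercept_{label}"] = e.intercept if e.intercept is not None else 0.0
    return df


def _load_tables(cfg: RunConfig) -> tuple[SummaryStatsTable, SummaryStatsTable]:
    exposure = read_sumstats(
        cfg.exposure_path,
        column_map=cfg.exposure_columns,
        trait_name=cfg.exposure_trait,
        trait_type=cfg.exposure_type,
    )
    outcome = read_sumstats(
        cfg.outcome_path,
        column_map=cfg.outcome_columns,
        trait_name=cfg.outcome_trait,
        trait_type="binary",
    )
    return exposure, outcome


def analyze_harmonized(s: HarmonizedSet, cfg: RunConfig) -> MRReport:
    """Estimation stages shared by file-driven and in-memory runs."""
    presso_result = None
    working = s
    if cfg.run_presso and len(s.variants) >= 4:
        try:
            presso_result = presso(
                s, n_sim=cfg.presso_n_sim, alpha_outlier=cfg.presso_alpha, seed=cfg.seed
            )
        except Exception as exc:  # noqa: BLE001
            raise StageError("presso", exc) from exc
        if cfg.exclude_presso_outliers and presso_result.outliers:
            working = s.without(*presso_result.outliers)
            logger.info("excluded %d PRESSO outliers", len(presso_result.outliers))

    estimates = []
    try:
        est_ivw = ivw(working)
        if "ivw" in cfg.estimators:
            estimates.append(est_ivw)
        if "egger" in cfg.estimators and len(working.variants) >= 3:
            estimates.append(mr_egger(working))
        if "weighted_median" in cfg.estimators and len(working.variants) >= 3:
            estimates.append(weighted_median(working, seed=cfg.seed))
    except Exception as exc:  # noqa: BLE001
        raise StageError("estimators", exc) from exc
    if working.exposure_type == "binary":
        estimates.extend(per_doubling(e) for e in list(estimates))

    heterogeneity = (
        cochrans_q(working, est_ivw.beta) if len(working.variants) >= 2 else None
    )
    loo = leave_one_out_sweep(working) if len(working.variants) >= 2 else {}

    strength: dict = {}
    return MRReport(
        config=cfg,
        harmonized=working,
        estimates=estimates,
        heterogeneity=heterogeneity,
        presso_result=presso_result,
        loo=loo,
        strength=strength,
    )


def run_mr(cfg: RunConfig) -> MRReport:
    """Full file-driven pipeline; writes the report bundle under out_dir."""
    try:
        exposure, outcome = _load_tables(cfg)
    except Exception as exc:  # noqa: BLE001
        raise StageError("read", exc) from exc
    try:
        instruments = select_instruments(exposure, cfg.p_index)
        ld = LDTable.read_tsv(cfg.ld_path) if cfg.ld_path else None
        instruments = clump(
            instruments, ld, p_index=cfg.p_index, r2_max=cfg.r2_max, window_kb=cfg.window_kb
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("clump", exc) from exc
    try:
        harmonized = harmonize_pair(instruments, outcome, cfg.palindromic_band)
    except Exception as exc:  # noqa: BLE001
        raise StageError("harmonize", exc) from exc

    report = analyze_harmonized(harmonized, cfg)

    n_instruments = len(report.harmonized.variants)
    r2 = variance_explained(instruments.subset([v.rsid for v in report.harmonized.variants]))
    strength = {"r2": r2, "k": n_instruments}
    n_exp = instruments.records[0].n if instruments.records else 0
    if n_exp > n_instruments + 1 and 0 < r2 < 1:
        strength["f_stat"] = f_statistic(r2, int(n_exp), n_instruments)
    if cfg.outcome_n_case and cfg.outcome_n_control and 0 < r2 < 1:
        strength["power"] = mr_power_binary(
            r2, cfg.outcome_n_case, cfg.outcome_n_control, cfg.power_or, cfg.power_alpha
        )
    report.strength = strength
    report.write()
    return report


def run_bidirectional(forward_cfg: RunConfig, reverse_cfg: RunConfig) -> tuple[MRReport, MRReport]:
    """Forward and reverse runs; the reverse config swaps the study roles and
    re-selects instruments from the (former) outcome study."""
    forward = run_mr(forward_cfg)
    reverse = run_mr(reverse_cfg)
    return forward, reverse
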