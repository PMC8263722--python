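"""Synthetic two-sample GWAS summary statistics with known ground truth.

Emulates paired exposure/outcome summary-statistics tables at configurable
study sizes, with a configurable true causal effect, balanced or directional
pleiotropy, planted outliers, and optional participant overlap inducing
correlated sampling errors.  Defaults mirror a large substance-use exposure
GWAS (~9.4e5 participants, 33 instruments jointly explaining ~0.5% of
exposure variance) feeding a case-control neurodegenerative-disease outcome
study (~5.6e4 cases, 1.4e6 controls).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .sumstats import SummaryStatsTable, VariantAssociation

# Non-palindromic allele pairs only, so harmonization keeps every variant
# under the default ambiguity band.
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "T")]

PleiotropyMode = Literal["none", "balanced", "directional"]


@dataclass
class SyntheticConfig:
    """Generative parameters for a paired exposure/outcome experiment."""

    n_snps: int = 33
    theta: float = 0.0  # true causal log-OR per exposure unit
    eaf_range: tuple[float, float] = (0.05, 0.95)
    exposure_beta_mean: float = 0.015  # per-SNP effect distribution (SD units)
    exposure_beta_sd: float = 0.013  # wide spread, as in real instrument panels
    n_exposure: int = 941_280
    n_case: int = 56_306
    n_control: int = 1_400_000
    pleiotropy_mode: PleiotropyMode = "none"
    pleiotropy_magnitude: float = 0.0
    n_outliers: int = 0
    outlier_offset: float = 0.0  # added to the true outcome beta (log-odds)
    overlap_fraction: float = 0.0  # shared participants -> correlated errors
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must lie in [0, 1]")
        if self.n_outliers > self.n_snps:
            raise ValueError("cannot plant more outliers than SNPs")


@dataclass
class TruthRecord:
    """Ground truth behind one generated pair, for recovery checks."""

    theta: float
    beta_exp_true: list[float]
    beta_out_true: list[float]
    pleiotropy: list[float]
    outlier_rsids: list[str]

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def generate_pair(
    cfg: SyntheticConfig,
) -> tuple[SummaryStatsTable, SummaryStatsTable, TruthRecord]:
    """Draw one paired exposure/outcome summary-statistics experiment.

    Per SNP: eaf ~ Uniform(eaf_range); true exposure beta ~ Normal(mean, sd)
    in phenotype SD units; exposure SE is the standard per-allele regression
    SE ``1/sqrt(2 p (1-p) n)``; the true outcome (log-odds) beta is
    ``theta * beta_exp`` plus any pleiotropy term and planted outlier
    offset; the outcome SE uses the case-control score-test variance
    ``1/sqrt(2 p (1-p) N K (1-K))``.  Observed betas are drawn normal about
    their truths, with correlation ``overlap_fraction`` between the two
    studies' errors when participants are shared.  About a third of outcome
    records are re-coded on the opposite allele to exercise harmonization.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_snps
    eaf = rng.uniform(*cfg.eaf_range, size=n)
    beta_exp_true = rng.normal(cfg.exposure_beta_mean, cfg.exposure_beta_sd, size=n)

    se_exp = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * cfg.n_exposure)
    n_out_total = cfg.n_case + cfg.n_control
    k_frac = cfg.n_case / n_out_total
    se_out = 1.0 / np.sqrt(
        2.0 * eaf * (1.0 - eaf) * n_out_total * k_frac * (1.0 - k_frac)
    )

    pleio = np.zeros(n)
    if cfg.pleiotropy_mode == "balanced":
        pleio = rng.normal(0.0, cfg.pleiotropy_magnitude, size=n)
    elif cfg.pleiotropy_mode == "directional":
        # aligned with the exposure-increasing allele, so the offset keeps a
        # consistent direction after positive orientation
        sign = np.where(beta_exp_true >= 0, 1.0, -1.0)
        pleio = sign * cfg.pleiotropy_magnitude

    outlier_idx = (
        rng.choice(n, size=cfg.n_outliers, replace=False)
        if cfg.n_outliers
        else np.array([], dtype=int)
    )
    offset = np.zeros(n)
    offset[outlier_idx] = cfg.outlier_offset

    beta_out_true = cfg.theta * beta_exp_true + pleio + offset

    # Correlated sampling errors from participant overlap.
    rho = cfg.overlap_fraction
    z1 = rng.standard_normal(n)
    z_shared = rng.standard_normal(n)
    z2 = rho * z1 + math.sqrt(1.0 - rho**2) * z_shared
    beta_exp_obs = beta_exp_true + se_exp * z1
    beta_out_obs = beta_out_true + se_out * z2

    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=n)
    swap_outcome = rng.random(n) < (1.0 / 3.0)

    exp_records, out_records = [], []
    rsids = [f"rs{1000 + i}" for i in range(n)]
    for i in range(n):
        ea, oa = _ALLELE_PAIRS[pair_idx[i]]
        chrom = str(1 + i % 22)
        pos = 1_000_000 * (1 + i)
        exp_records.append(
            VariantAssociation(
                rsid=rsids[i],
                chrom=chrom,
                pos=pos,
                effect_allele=ea,
                other_allele=oa,
                eaf=float(eaf[i]),
                beta=float(beta_exp_obs[i]),
                se=float(se_exp[i]),
                pvalue=_p_from(beta_exp_obs[i], se_exp[i]),
                n=float(cfg.n_exposure),
            )
        )
        if swap_outcome[i]:
            out_ea, out_oa = oa, ea
            b_out, eaf_out = -beta_out_obs[i], 1.0 - eaf[i]
        else:
            out_ea, out_oa = ea, oa
            b_out, eaf_out = beta_out_obs[i], eaf[i]
        out_records.append(
            VariantAssociation(
                rsid=rsids[i],
                chrom=chrom,
                pos=pos,
                effect_allele=out_ea,
                other_allele=out_oa,
                eaf=float(eaf_out),
                beta=float(b_out),
                se=float(se_out[i]),
                pvalue=_p_from(b_out, se_out[i]),
                n=float(n_out_total),
            )
        )

    exposure = SummaryStatsTable(
        trait_name="synthetic_exposure",
        trait_type="continuous",
        records=exp_records,
        provenance=f"synthetic seed={cfg.seed}",
    )
    outcome = SummaryStatsTable(
        trait_name="synthetic_outcome",
        trait_type="binary",
        records=out_records,
        provenance=f"synthetic seed={cfg.seed}",
    )
    truth = TruthRecord(
        theta=cfg.theta,
        beta_exp_true=[float(b) for b in beta_exp_true],
        beta_out_true=[float(b) for b in beta_out_true],
        pleiotropy=[float(p) for p in pleio],
        outlier_rsids=[rsids[i] for i in sorted(outlier_idx.tolist())],
    )
    return exposure, outcome, truth


def _p_from(beta: float, se: float) -> float:
    from scipy import stats

    p = float(2.0 * stats.norm.sf(abs(beta) / se))
    return max(p, 5e-324)


# --- published-study metadata fixture -------------------------------------

_TABLE1_ROWS = [
    # trait, k (SNPs), n (exposure GWAS), R2, printed F, printed power %
    ("age_at_smoking_initiation", 7, 341_427, 0.00102, 49.74375, 33.0),
    ("smoking_initiation", 87, 1_232_091, 0.00441, 62.74564, 89.0),
    ("drinks_per_week", 33, 941_280, 0.00513, 147.00378, 93.0),
    ("smoking_continuation", 8, 547_219, 0.00105, 72.13881, 34.0),
    ("smoking_heaviness", 25, 337_334, 0.00983, 113.90956, 100.0),
]

_SPECIAL_VARIANTS = [
    ("rs1229984", "ADH1B", "strongest drinks-per-week instrument; alcohol dehydrogenase 1B"),
    ("rs29001570", "ADH5", "alcohol dehydrogenase 5 locus instrument"),
    ("rs1260326", "GCKR", "pleiotropic outlier (triglyceride/serum urate associations)"),
    ("rs34121753", "", "pleiotropic outlier (hematocrit association)"),
    ("rs9607805", "", "smoking-continuation pleiotropic outlier (neuroticism)"),
]


def paper_fixture() -> dict[str, pd.DataFrame]:
    """Published-study metadata used in tests and docs.

    Returns the per-trait instrument-strength table (trait, k, n, R²,
    F statistic and power as printed by the source study) and an annotation
    table for the individually discussed variants.  Deterministic:
    re-emitting the fixture is byte-identical.
    """
    strength = pd.DataFrame(
        _TABLE1_ROWS, columns=["trait", "k", "n", "r2", "f_stat", "power_pct"]
    )
    variants = pd.DataFrame(_SPECIAL_VARIANTS, columns=["rsid", "locus", "note"])
    return {"strength": strength, "variants": variants}
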