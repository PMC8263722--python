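"""Allele harmonization between exposure and outcome summary statistics.

Exposure effects are first oriented positive (flipping the allele coding and
frequency when beta < 0).  Outcome records are then aligned to the exposure's
effect allele: same-order pairs pass through, swapped pairs flip the outcome
beta and frequency, strand-complement pairs are matched after complementing,
and anything else is dropped.  Palindromic variants (A/T or C/G) whose allele
frequency is too close to 0.5 on either side cannot be strand-resolved and
are dropped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

from .sumstats import SummaryStatsTable, VariantAssociation

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

FLIPPED_EXPOSURE = "flipped_exposure"
FLIPPED_OUTCOME = "flipped_outcome"
COMPLEMENT_MATCHED = "complement_matched"
MISSING_EAF = "missing_eaf"


@dataclass(frozen=True)
class HarmonizedVariant:
    """Exposure and outcome effects for one variant on a shared effect allele."""

    rsid: str
    effect_allele: str
    other_allele: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: float
    eaf_out: float
    flags: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.beta_exp < 0:
            raise ValueError(f"{self.rsid}: exposure beta must be oriented non-negative")
        if not self.se_exp > 0 or not self.se_out > 0:
            raise ValueError(f"{self.rsid}: standard errors must be positive")


@dataclass
class HarmonizedSet:
    """The aligned exposure/outcome instrument set every estimator consumes."""

    exposure_name: str
    outcome_name: str
    variants: list[HarmonizedVariant] = field(default_factory=list)
    dropped: list[tuple[str, str]] = field(default_factory=list)
    exposure_type: str = "continuous"  # binary | continuous; drives OR rescaling

    def __post_init__(self) -> None:
        rsids = [v.rsid for v in self.variants] + [r for r, _ in self.dropped]
        if len(rsids) != len(set(rsids)):
            raise ValueError("rsids not unique across variants and dropped")

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)

    def without(self, *rsids: str) -> "HarmonizedSet":
        """A copy excluding the named variants (they are simply omitted)."""
        excluded = set(rsids)
        missing = excluded - {v.rsid for v in self.variants}
        if missing:
            raise KeyError(f"rsids not in set: {sorted(missing)}")
        return HarmonizedSet(
            exposure_name=self.exposure_name,
            outcome_name=self.outcome_name,
            variants=[v for v in self.variants if v.rsid not in excluded],
            dropped=list(self.dropped),
            exposure_type=self.exposure_type,
        )

    def write_tsv(self, path: str | Path) -> None:
        cols = (
            "rsid\teffect_allele\tother_allele\tbeta_exp\tse_exp\tbeta_out\t"
            "se_out\teaf_exp\teaf_out\tflags\n"
        )
        with open(path, "w") as fh:
            fh.write(cols)
            for v in self.variants:
                fh.write(
                    f"{v.rsid}\t{v.effect_allele}\t{v.other_allele}\t"
                    f"{v.beta_exp!r}\t{v.se_exp!r}\t{v.beta_out!r}\t{v.se_out!r}\t"
                    f"{v.eaf_exp!r}\t{v.eaf_out!r}\t{';'.join(sorted(v.flags))}\n"
                )


def orient_positive(v: VariantAssociation) -> VariantAssociation:
    """Return the record coded so that beta >= 0.

    A negative effect is recoded on the opposite allele: beta is negated,
    effect/other alleles swap, and the effect-allele frequency becomes its
    complement.  Idempotent.
    """
    if v.beta >= 0:
        return v
    return replace(
        v,
        beta=-v.beta,
        effect_allele=v.other_allele,
        other_allele=v.effect_allele,
        eaf=1.0 - v.eaf if not math.isnan(v.eaf) else v.eaf,
    )


def is_palindromic(a1: str, a2: str) -> bool:
    return COMPLEMENT[a1] == a2


def _allele_match(exp_ea: str, exp_oa: str, out_ea: str, out_oa: str) -> str | None:
    """Classify the outcome allele pair relative to the exposure pair.

    Returns "same", "swapped", "comp_same", "comp_swapped", or None for an
    incompatible pair.
    """
    if (out_ea, out_oa) == (exp_ea, exp_oa):
        return "same"
    if (out_ea, out_oa) == (exp_oa, exp_ea):
        return "swapped"
    c_ea, c_oa = COMPLEMENT[out_ea], COMPLEMENT[out_oa]
    if (c_ea, c_oa) == (exp_ea, exp_oa):
        return "comp_same"
    if (c_ea, c_oa) == (exp_oa, exp_ea):
        return "comp_swapped"
    return None


def harmonize_pair(
    exposure: SummaryStatsTable,
    outcome: SummaryStatsTable,
    palindromic_eaf_band: float = 0.08,
    complement_match: bool = True,
) -> HarmonizedSet:
    """Align outcome records to the exposure's (positive-oriented) effect alleles.

    Parameters
    ----------
    exposure
        Instrument-selected exposure table; records are oriented positive
        here regardless of input orientation.
    outcome
        Outcome summary statistics (need not be pre-filtered).
    palindromic_eaf_band
        A/T and C/G variants with either study's EAF inside
        ``[0.5 - band, 0.5 + band]`` are dropped as strand-ambiguous.
        ``0`` keeps all palindromic variants.
    complement_match
        Treat strand-complement allele pairs (e.g. G/A vs C/T) as the same
        variant, flagging records so matched.

    Every exposure instrument lands in ``variants`` or ``dropped`` exactly once.
    """
    out_by_rsid = {r.rsid: r for r in outcome.records}
    variants: list[HarmonizedVariant] = []
    dropped: list[tuple[str, str]] = []

    for exp_raw in exposure.records:
        exp = orient_positive(exp_raw)
        flags: set[str] = set()
        if exp is not exp_raw:
            flags.add(FLIPPED_EXPOSURE)

        out = out_by_rsid.get(exp.rsid)
        if out is None:
            dropped.append((exp.rsid, "missing_in_outcome"))
            continue

        match = _allele_match(
            exp.effect_allele, exp.other_allele, out.effect_allele, out.other_allele
        )
        if match is None or (not complement_match and match.startswith("comp_")):
            dropped.append((exp.rsid, "allele_mismatch"))
            continue
        if match.startswith("comp_"):
            flags.add(COMPLEMENT_MATCHED)

        if is_palindromic(exp.effect_allele, exp.other_allele):
            ambiguous = False
            for eaf in (exp.eaf, out.eaf):
                if math.isnan(eaf):
                    flags.add(MISSING_EAF)
                    ambiguous = True  # cannot run the frequency check
                elif abs(eaf - 0.5) <= palindromic_eaf_band:
                    ambiguous = True
            if palindromic_eaf_band > 0 and ambiguous:
                dropped.append((exp.rsid, "palindromic_ambiguous"))
                continue

        if match in ("swapped", "comp_swapped"):
            beta_out = -out.beta
            eaf_out = 1.0 - out.eaf if not math.isnan(out.eaf) else out.eaf
            flags.add(FLIPPED_OUTCOME)
        else:
            beta_out = out.beta
            eaf_out = out.eaf

        variants.append(
            HarmonizedVariant(
                rsid=exp.rsid,
                effect_allele=exp.effect_allele,
                other_allele=exp.other_allele,
                beta_exp=exp.beta,
                se_exp=exp.se,
                beta_out=beta_out,
                se_out=out.se,
                eaf_exp=exp.eaf,
                eaf_out=eaf_out,
                flags=frozenset(flags),
            )
        )

    if not variants and not dropped:
        raise ValueError("no exposure instruments supplied")
    if not variants and all(reason == "missing_in_outcome" for _, reason in dropped):
        raise ValueError(
            f"no shared variants between {exposure.trait_name!r} "
            f"and {outcome.trait_name!r}"
        )
    logger.info(
        "harmonized %d variants (%d dropped) for %s on %s",
        len(variants),
        len(dropped),
        exposure.trait_name,
        outcome.trait_name,
    )
    return HarmonizedSet(
        exposure_name=exposure.trait_name,
        outcome_name=outcome.trait_name,
        variants=variants,
        dropped=dropped,
        exposure_type=exposure.trait_type,
    )
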