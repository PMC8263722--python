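"""Multivariable MR: direct effects of an exposure conditional on competing traits.

A single zero-intercept weighted regression of outcome betas on the K
exposure-beta columns (weights 1/se_out²) yields one conditional causal
estimate per exposure.  Instruments are the primary exposure's instruments;
competing-trait effects at those SNPs are looked up from their summary
tables, with absent lookups imputed as zero and flagged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .estimators import InsufficientInstrumentsError, MREstimate
from .harmonize import COMPLEMENT, HarmonizedSet
from .sumstats import SummaryStatsTable

logger = logging.getLogger(__name__)


class CollinearityError(np.linalg.LinAlgError):
    """Raised when the exposure-beta matrix is rank deficient."""


@dataclass
class MultiExposureRecord:
    rsid: str
    beta_exp: np.ndarray  # K-vector
    se_exp: np.ndarray  # K-vector
    beta_out: float
    se_out: float
    imputed: list[str] = field(default_factory=list)  # exposures imputed as 0


@dataclass
class MultiExposureSet:
    """Instrument set carrying K exposure-effect columns per variant."""

    outcome_name: str
    exposure_names: list[str]
    variants: list[MultiExposureRecord]

    def __post_init__(self) -> None:
        k = len(self.exposure_names)
        if k < 1:
            raise ValueError("at least one exposure required")
        if len(self.variants) <= k:
            raise ValueError(
                f"{len(self.variants)} variants cannot identify {k} exposures"
            )


def build_multi_exposure_set(
    primary: HarmonizedSet,
    covariate_tables: list[SummaryStatsTable],
) -> MultiExposureSet:
    """Attach competing-trait betas (aligned to each instrument's effect
    allele) to a harmonized primary set.

    A covariate record coded on the opposite allele (directly or as a strand
    complement) has its beta negated; a missing or allele-incompatible
    lookup is imputed as beta 0 and flagged on the record.
    """
    names = [primary.exposure_name] + [t.trait_name for t in covariate_tables]
    lookups = [{r.rsid: r for r in t.records} for t in covariate_tables]
    variants = []
    for v in primary.variants:
        betas = [v.beta_exp]
        ses = [v.se_exp]
        imputed: list[str] = []
        for table, lut in zip(covariate_tables, lookups):
            rec = lut.get(v.rsid)
            aligned = None
            if rec is not None:
                pairs = {
                    (rec.effect_allele, rec.other_allele): rec.beta,
                    (rec.other_allele, rec.effect_allele): -rec.beta,
                    (COMPLEMENT[rec.effect_allele], COMPLEMENT[rec.other_allele]): rec.beta,
                    (COMPLEMENT[rec.other_allele], COMPLEMENT[rec.effect_allele]): -rec.beta,
                }
                aligned = pairs.get((v.effect_allele, v.other_allele))
            if aligned is None:
                imputed.append(table.trait_name)
                betas.append(0.0)
                ses.append(math.nan)
            else:
                betas.append(aligned)
                ses.append(rec.se)
        variants.append(
            MultiExposureRecord(
                rsid=v.rsid,
                beta_exp=np.array(betas),
                se_exp=np.array(ses),
                beta_out=v.beta_out,
                se_out=v.se_out,
                imputed=imputed,
            )
        )
    n_imputed = sum(len(v.imputed) for v in variants)
    if n_imputed:
        logger.warning("imputed %d missing covariate lookups as zero", n_imputed)
    return MultiExposureSet(
        outcome_name=primary.outcome_name, exposure_names=names, variants=variants
    )


def mvmr_ivw(s: MultiExposureSet) -> list[MREstimate]:
    """Zero-intercept weighted multiple regression of outcome betas on the K
    exposure-beta columns; one conditional (direct-effect) estimate per
    exposure.

    Weights are 1/se_out²; SEs carry multiplicative residual scaling and
    inference is on the t distribution with n - K df.  With K = 1 this is
    exactly the univariable IVW regression formulation.
    """
    n = len(s.variants)
    k = len(s.exposure_names)
    if n <= k + 1:
        raise InsufficientInstrumentsError(
            f"multivariable IVW needs more than K+1={k + 1} variants, got {n}"
        )
    X = np.vstack([v.beta_exp for v in s.variants])
    y = np.array([v.beta_out for v in s.variants])
    w = np.array([1.0 / v.se_out**2 for v in s.variants])

    rank = np.linalg.matrix_rank(X * np.sqrt(w)[:, None])
    if rank < k:
        raise CollinearityError(
            f"exposure-beta matrix rank {rank} < K={k}; columns {s.exposure_names} "
            "are collinear"
        )
    WX = X * w[:, None]
    xtwx = X.T @ WX
    coef = np.linalg.solve(xtwx, WX.T @ y)
    resid = y - X @ coef
    df = n - k
    sigma2 = float(np.sum(w * resid**2) / df)
    cov = np.linalg.inv(xtwx) * sigma2
    tq = float(stats.t.ppf(0.975, df))

    estimates = []
    for j, name in enumerate(s.exposure_names):
        b = float(coef[j])
        se = float(math.sqrt(cov[j, j]))
        estimates.append(
            MREstimate(
                method=f"MVMR-IVW ({name})",
                beta=b,
                se=se,
                ci_low=b - tq * se,
                ci_high=b + tq * se,
                pvalue=float(2.0 * stats.t.sf(abs(b) / se, df)),
                n_snps=n,
            )
        )
    return estimates
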