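"""Instrument-strength metrics (variance explained, F statistic) and
statistical power for MR with a binary outcome.

``mr_power_binary`` follows the mRnd approximation for case-control
outcomes: the causal log-odds effect implied by the alternative OR is
converted to a linear-probability slope, its sampling variance under the
instrument's R² is derived, and power is read from a non-central chi-square
with one degree of freedom.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .sumstats import SummaryStatsTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class InstrumentStrength:
    """Variance explained, F statistic and power for one instrument set."""

    trait: str
    r2: float
    f_stat: float
    n: int
    k: int
    power: float  # at or_alt / alpha below
    or_alt: float
    alpha: float


def variance_explained(instruments: SummaryStatsTable, var_y: float = 1.0) -> float:
    """Phenotypic variance explained by the instruments.

    ``R² = Σ 2 m_i (1 - m_i) β_i² / Var(Y)`` with ``m_i`` the minor-allele
    frequency.  Variants without an allele frequency are excluded with a
    warning.  ``Var(Y) = 1`` is exact for standardized continuous traits;
    for binary traits the sum is only an approximation on the observed
    scale (warned).
    """
    if not var_y > 0:
        raise ValueError("var_y must be positive")
    if instruments.trait_type == "binary":
        logger.warning(
            "%s: R² formula is an approximation for binary traits",
            instruments.trait_name,
        )
    total = 0.0
    skipped = 0
    for rec in instruments.records:
        if math.isnan(rec.eaf):
            skipped += 1
            continue
        m = rec.minor_allele_freq
        total += 2.0 * m * (1.0 - m) * rec.beta**2
    if skipped:
        logger.warning(
            "%s: %d variants lack eaf, excluded from R²",
            instruments.trait_name,
            skipped,
        )
    return total / var_y


def f_statistic(r2: float, n: int, k: int) -> float:
    """Joint instrument F statistic: ``F = R² (n - 1 - k) / ((1 - R²) k)``."""
    if not (0.0 <= r2 < 1.0):
        raise ValueError(f"r2 must lie in [0, 1), got {r2}")
    if not (n > k + 1 >= 2):
        raise ValueError(f"need n > k + 1 >= 2, got n={n}, k={k}")
    return r2 * (n - 1 - k) / ((1.0 - r2) * k)


def mr_power_binary(
    r2: float,
    n_case: int,
    n_control: int,
    or_alt: float,
    alpha: float = 0.05,
) -> float:
    """Two-sided power of an MR test for a binary outcome (mRnd approximation).

    With ``N = n_case + n_control`` and case fraction ``K``, the alternative
    OR maps to a linear-probability effect
    ``b = K (OR / (1 + K (OR - 1)) - 1)`` whose variance is
    ``(K (1 - K) - b²) / (N R²)``; power is the tail mass of the
    non-central chi-square(1, b²/var) beyond the central alpha critical
    value.  At OR = 1 this returns exactly alpha.
    """
    if not or_alt > 0:
        raise ValueError("or_alt must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if not (0 < r2 < 1):
        raise ValueError("r2 must lie in (0, 1)")
    n_total = n_case + n_control
    frac_case = n_case / n_total
    b = frac_case * (or_alt / (1.0 + frac_case * (or_alt - 1.0)) - 1.0)
    v = (frac_case * (1.0 - frac_case) - b * b) / (n_total * r2)
    ncp = b * b / v
    crit = stats.chi2.ppf(1.0 - alpha, 1)
    return float(stats.ncx2.sf(crit, 1, ncp)) if ncp > 0 else alpha


def strength_report(
    entries: list[tuple[str, float, int, int]],
    n_case: int,
    n_control: int,
    or_alt: float = 0.8,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-trait strength/power table (trait, k, n, R², F, power %).

    ``entries`` rows are (trait, r2, n, k); power is evaluated against the
    stated binary-outcome study at ``or_alt`` and ``alpha``.
    """
    rows = []
    for trait, r2, n, k in entries:
        rows.append(
            {
                "trait": trait,
                "k": k,
                "n": n,
                "r2": r2,
                "f_stat": f_statistic(r2, n, k),
                "power_pct": 100.0 * mr_power_binary(r2, n_case, n_control, or_alt, alpha),
            }
        )
    return pd.DataFrame(rows)
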