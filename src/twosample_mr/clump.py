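"""Greedy clumping of associated variants into approximately independent index SNPs.

Variants are ranked by p-value; the best unclaimed variant below the index
threshold becomes an index SNP and claims every unclaimed variant either in
high LD with it (``r2 > r2_max``) or within ``window_kb`` on the same
chromosome.  This mirrors the behaviour of PLINK's ``--clump`` given a
pairwise LD table instead of a genotype panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .sumstats import SummaryStatsTable, VariantAssociation, replace_records

logger = logging.getLogger(__name__)


@dataclass
class LDTable:
    """Symmetric pairwise LD lookup; unlisted pairs are treated as r² = 0."""

    pairs: dict[frozenset, float] = field(default_factory=dict)

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str, float]]) -> "LDTable":
        pairs: dict[frozenset, float] = {}
        for a, b, r2 in records:
            if not (0.0 <= r2 <= 1.0):
                raise ValueError(f"r2 out of [0,1] for ({a},{b}): {r2}")
            pairs[frozenset((a, b))] = float(r2)
        return cls(pairs)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "LDTable":
        """Read a 3-column (rsid_a, rsid_b, r2) TSV with header."""
        records = []
        with open(path) as fh:
            header = fh.readline()
            if not header:
                raise ValueError(f"{path}: empty LD table")
            for line in fh:
                a, b, r2 = line.rstrip("\n").split("\t")[:3]
                records.append((a, b, float(r2)))
        return cls.from_records(records)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self.pairs.get(frozenset((a, b)), 0.0)


def _rank_key(v: VariantAssociation) -> tuple:
    # p-value ties broken by smaller se, then lexicographic rsid, for determinism
    return (v.pvalue, v.se, v.rsid)


def clump(
    table: SummaryStatsTable,
    ld: LDTable | None = None,
    p_index: float = 5e-8,
    r2_max: float = 0.001,
    window_kb: float = 10_000,
) -> SummaryStatsTable:
    """Greedy p-value-ranked clumping; returns index SNPs in selection order.

    A variant is claimed by an index SNP if ``r2 > r2_max`` against it or if
    it lies on the same chromosome within ``window_kb`` kilobases (|pos
    difference| <= window_kb * 1000, positions 1-based).  With no LD table
    only the distance rule applies (logged as a warning).
    """
    if ld is None:
        logger.warning("no LD table supplied; clumping by distance only")
    window_bp = window_kb * 1000.0

    unclaimed = list(table.records)
    index_snps: list[VariantAssociation] = []
    while True:
        candidates = [v for v in unclaimed if v.pvalue < p_index]
        if not candidates:
            break
        index = min(candidates, key=_rank_key)
        index_snps.append(index)
        kept = []
        for v in unclaimed:
            if v.rsid == index.rsid:
                continue
            in_window = (
                v.chrom == index.chrom and abs(v.pos - index.pos) <= window_bp
            )
            in_ld = ld is not None and ld.r2(v.rsid, index.rsid) > r2_max
            if not (in_window or in_ld):
                kept.append(v)
        unclaimed = kept
    return replace_records(table, index_snps)
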