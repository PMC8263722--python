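"""GWAS summary-statistics data model, TSV readers/writers and instrument selection.

The unit record is a single variant association (:class:`VariantAssociation`);
a study is an ordered collection of them (:class:`SummaryStatsTable`).  Files
are tab-separated text with a header row; gzip is handled transparently.
Column names are resolved through a configurable mapping so that different
consortium header dialects can be read without editing the files.
"""

from __future__ import annotations

import gzip
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")

#: Logical column names every summary-statistics table must resolve.
REQUIRED_COLUMNS = (
    "rsid",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
)

#: Named header presets.  ``default`` is the dialect this package writes;
#: ``gwas_ssf`` covers the GWAS-SSF-like layout used by several consortia.
COLUMN_PRESETS: dict[str, dict[str, str]] = {
    "default": {c: c for c in REQUIRED_COLUMNS},
    "gwas_ssf": {
        "rsid": "rsid",
        "chrom": "chromosome",
        "pos": "base_pair_location",
        "effect_allele": "effect_allele",
        "other_allele": "other_allele",
        "eaf": "effect_allele_frequency",
        "beta": "beta",
        "se": "standard_error",
        "pvalue": "p_value",
        "n": "n",
    },
}


class SumstatsError(ValueError):
    """Raised for unreadable or structurally invalid summary-statistics input."""


@dataclass(frozen=True)
class VariantAssociation:
    """One GWAS association record.

    ``beta`` is the per-allele effect of ``effect_allele``: log-odds for a
    binary trait, phenotype SD units for a continuous one.  ``eaf`` may be
    NaN when the source file does not report allele frequencies; such
    variants are excluded from frequency-based checks downstream.
    """

    rsid: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pvalue: float
    n: float

    def validate(self) -> None:
        """Raise ``ValueError`` on any hard invariant violation."""
        if self.effect_allele not in VALID_ALLELES:
            raise ValueError(f"{self.rsid}: invalid effect allele {self.effect_allele!r}")
        if self.other_allele not in VALID_ALLELES:
            raise ValueError(f"{self.rsid}: invalid other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.rsid}: effect and other allele identical")
        if not self.se > 0 or not math.isfinite(self.se):
            raise ValueError(f"{self.rsid}: se must be finite and > 0, got {self.se}")
        if not math.isfinite(self.beta):
            raise ValueError(f"{self.rsid}: beta must be finite")
        if not (0 < self.pvalue <= 1):
            raise ValueError(f"{self.rsid}: pvalue must lie in (0, 1], got {self.pvalue}")
        if not math.isnan(self.eaf) and not (0.0 <= self.eaf <= 1.0):
            raise ValueError(f"{self.rsid}: eaf out of [0, 1], got {self.eaf}")
        if self.pos < 1:
            raise ValueError(f"{self.rsid}: position must be 1-based positive")
        if self.n < 1:
            raise ValueError(f"{self.rsid}: sample size must be >= 1")
        self._warn_p_inconsistent()

    def _warn_p_inconsistent(self, rtol: float = 0.10) -> None:
        # Soft check: p should agree with the two-sided normal p of beta/se.
        expected = 2.0 * stats.norm.sf(abs(self.beta) / self.se)
        if expected <= 0:
            return
        if abs(self.pvalue - expected) > rtol * max(expected, self.pvalue):
            logger.warning(
                "%s: reported p=%.3g disagrees with |beta/se| normal p=%.3g",
                self.rsid,
                self.pvalue,
                expected,
            )

    @property
    def minor_allele_freq(self) -> float:
        return min(self.eaf, 1.0 - self.eaf)


@dataclass
class SummaryStatsTable:
    """An ordered, rsid-unique collection of variant associations for one trait."""

    trait_name: str
    trait_type: str  # "binary" | "continuous"
    records: list[VariantAssociation] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "continuous"):
            raise ValueError(f"trait_type must be binary|continuous, got {self.trait_type!r}")
        seen: set[str] = set()
        for rec in self.records:
            if rec.rsid in seen:
                raise ValueError(f"duplicate rsid {rec.rsid} in table {self.trait_name!r}")
            seen.add(rec.rsid)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, rsid: str) -> VariantAssociation | None:
        for rec in self.records:
            if rec.rsid == rsid:
                return rec
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records], columns=list(REQUIRED_COLUMNS))

    def subset(self, rsids: Iterable[str]) -> "SummaryStatsTable":
        wanted = set(rsids)
        return replace_records(self, [r for r in self.records if r.rsid in wanted])


def replace_records(
    table: SummaryStatsTable, records: Sequence[VariantAssociation]
) -> SummaryStatsTable:
    return SummaryStatsTable(
        trait_name=table.trait_name,
        trait_type=table.trait_type,
        records=list(records),
        provenance=table.provenance,
    )


def _open_text(path: Path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | str = "default",
    trait_name: str = "",
    trait_type: str = "continuous",
    provenance: str | None = None,
) -> SummaryStatsTable:
    """Read a delimited summary-statistics file into a validated table.

    Parameters
    ----------
    path
        Tab-separated text file with a header row; ``.gz`` accepted.
    column_map
        Mapping of logical column name -> file column name, or the name of a
        preset in :data:`COLUMN_PRESETS`.
    trait_name, trait_type
        Trait metadata attached to the table.
    provenance
        Free-text source label; defaults to the file path.

    Rows failing per-record invariants are dropped with a logged count.
    A missing required column raises :class:`SumstatsError`.
    """
    path = Path(path)
    if isinstance(column_map, str):
        try:
            column_map = COLUMN_PRESETS[column_map]
        except KeyError:
            raise SumstatsError(f"unknown column preset {column_map!r}") from None
    missing_logical = [c for c in REQUIRED_COLUMNS if c not in column_map]
    if missing_logical:
        raise SumstatsError(f"column_map missing logical columns: {missing_logical}")

    with _open_text(path) as fh:
        try:
            df = pd.read_csv(fh, sep="\t", dtype=str)
        except pd.errors.EmptyDataError:
            raise SumstatsError(f"{path}: empty summary-statistics file") from None
    if df.empty:
        raise SumstatsError(f"{path}: summary-statistics file has no data rows")

    missing_cols = [column_map[c] for c in REQUIRED_COLUMNS if column_map[c] not in df.columns]
    if missing_cols:
        raise SumstatsError(f"{path}: required columns absent: {missing_cols}")

    records: list[VariantAssociation] = []
    n_dropped = 0
    for _, row in df.iterrows():
        try:
            rec = VariantAssociation(
                rsid=str(row[column_map["rsid"]]),
                chrom=str(row[column_map["chrom"]]),
                pos=int(row[column_map["pos"]]),
                effect_allele=str(row[column_map["effect_allele"]]).upper(),
                other_allele=str(row[column_map["other_allele"]]).upper(),
                eaf=_parse_float(row[column_map["eaf"]]),
                beta=float(row[column_map["beta"]]),
                se=float(row[column_map["se"]]),
                pvalue=float(row[column_map["pvalue"]]),
                n=float(row[column_map["n"]]),
            )
            rec.validate()
        except (ValueError, TypeError) as exc:
            logger.debug("dropping row: %s", exc)
            n_dropped += 1
            continue
        records.append(rec)
    if n_dropped:
        logger.info("%s: dropped %d invalid rows of %d", path, n_dropped, len(df))

    return SummaryStatsTable(
        trait_name=trait_name or path.stem,
        trait_type=trait_type,
        records=records,
        provenance=provenance if provenance is not None else str(path),
    )


def _parse_float(value) -> float:
    if value is None or (isinstance(value, str) and value.strip() in ("", "NA", "nan", ".")):
        return math.nan
    return float(value)


def write_sumstats(table: SummaryStatsTable, path: str | Path) -> None:
    """Write a table as TSV (gzip if the path ends in .gz), full float precision."""
    path = Path(path)
    with _open_text(path, "wt") as fh:
        fh.write("\t".join(REQUIRED_COLUMNS) + "\n")
        for r in table.records:
            fh.write(
                "\t".join(
                    [
                        r.rsid,
                        r.chrom,
                        str(r.pos),
                        r.effect_allele,
                        r.other_allele,
                        repr(r.eaf),
                        repr(r.beta),
                        repr(r.se),
                        repr(r.pvalue),
                        repr(r.n),
                    ]
                )
                + "\n"
            )


def select_instruments(
    table: SummaryStatsTable, p_threshold: float = 5e-8
) -> SummaryStatsTable:
    """Keep records with ``pvalue < p_threshold``, preserving input order.

    An empty result is allowed (and logged); it is not an error.
    """
    if not (0 < p_threshold < 1):
        raise ValueError(f"p_threshold must lie in (0, 1), got {p_threshold}")
    selected = [r for r in table.records if r.pvalue < p_threshold]
    if not selected:
        logger.info(
            "%s: no instruments pass p < %g (of %d records)",
            table.trait_name,
            p_threshold,
            len(table.records),
        )
    return replace_records(table, selected)


# re-export for convenience
replace_variant = replace
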