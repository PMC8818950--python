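"""Read, validate, filter, and write delimited GWAS summary-statistic tables.

The canonical dialect is a TSV/CSV with header columns
``SNP, chr, pos, effect_allele, other_allele, eaf, beta, se, pval, n``.
Other dialects (GWAS Catalog exports, COVID-19 HGI releases, ...) are
supported through a :class:`ColumnMap` that renames their headers onto the
canonical field names.
"""

from __future__ import annotations

import io
import json
import math
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .exceptions import ColumnMapError, EmptyInputError

__all__ = [
    "SummaryStatRecord",
    "ColumnMap",
    "ParseResult",
    "CANONICAL_COLUMNS",
    "VALID_ALLELES",
    "read_summary_stats",
    "write_summary_stats",
    "records_to_frame",
    "filter_genome_wide_significant",
]

CANONICAL_COLUMNS = (
    "SNP",
    "chr",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
)

#: canonical header -> record attribute
_FIELD_OF_COLUMN = {
    "SNP": "snp_id",
    "chr": "chrom",
    "pos": "pos",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pval": "pval",
    "n": "n",
}

VALID_ALLELES = frozenset("ACGT")

#: columns that may be absent or blank without dropping the row
_OPTIONAL_COLUMNS = ("eaf", "n")


@dataclass(frozen=True)
class SummaryStatRecord:
    """One SNP's association with one trait.

    ``beta`` is the per-allele effect of ``effect_allele`` on the trait
    (log-odds for binary traits). ``eaf`` is the effect-allele frequency and
    may be ``None`` at parse time; palindromic SNPs without a frequency are
    discarded later in harmonization.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: Optional[float]
    beta: float
    se: float
    pval: float
    n: Optional[int] = None

    def is_palindromic(self) -> bool:
        pair = {self.effect_allele, self.other_allele}
        return pair == {"A", "T"} or pair == {"G", "C"}


@dataclass(frozen=True)
class ColumnMap:
    """Maps canonical column names to the header names of a file dialect."""

    mapping: Mapping[str, str] = field(
        default_factory=lambda: {c: c for c in CANONICAL_COLUMNS}
    )

    def __post_init__(self) -> None:
        unknown = set(self.mapping) - set(CANONICAL_COLUMNS)
        if unknown:
            raise ColumnMapError(f"unknown canonical fields in column map: {sorted(unknown)}")
        required = set(CANONICAL_COLUMNS) - set(_OPTIONAL_COLUMNS)
        missing = required - set(self.mapping)
        if missing:
            raise ColumnMapError(f"column map lacks required fields: {sorted(missing)}")
        targets = list(self.mapping.values())
        if len(targets) != len(set(targets)):
            raise ColumnMapError("column map assigns one header to several fields")

    @classmethod
    def from_json(cls, path: str | Path) -> "ColumnMap":
        with open(path) as fh:
            return cls(json.load(fh))

    def header_for(self, canonical: str) -> Optional[str]:
        return self.mapping.get(canonical)


@dataclass
class ParseResult:
    """Parsed records plus a per-reason tally of rejected rows."""

    records: list[SummaryStatRecord]
    rejections: Counter
    flagged_missing_eaf: int = 0

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _sniff_delimiter(header_line: str) -> str:
    # tab wins when both occur: canonical files are TSV, and embedded commas
    # inside tab-separated fields are more plausible than the reverse
    return "\t" if "\t" in header_line else ","


def _parse_float(value) -> Optional[float]:
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    try:
        out = float(value)
    except (TypeError, ValueError):
        return None
    return None if math.isnan(out) else out


def _parse_int(value) -> Optional[int]:
    x = _parse_float(value)
    if x is None or x != int(x):
        return None
    return int(x)


def _validate_row(row: dict) -> tuple[Optional[SummaryStatRecord], Optional[str], bool]:
    """Returns (record, rejection reason, missing-eaf flag)."""
    snp_id = row.get("SNP")
    chrom = row.get("chr")
    if snp_id is None or (isinstance(snp_id, float) and math.isnan(snp_id)) or str(snp_id) == "":
        return None, "missing snp id", False
    if chrom is None or (isinstance(chrom, float) and math.isnan(chrom)):
        return None, "missing chromosome", False

    pos = _parse_int(row.get("pos"))
    if pos is None or pos < 1:
        return None, "invalid position", False

    ea = str(row.get("effect_allele", "")).strip().upper()
    oa = str(row.get("other_allele", "")).strip().upper()
    if len(ea) != 1 or len(oa) != 1 or ea not in VALID_ALLELES or oa not in VALID_ALLELES:
        return None, "non-SNP allele", False
    if ea == oa:
        return None, "identical alleles", False

    beta = _parse_float(row.get("beta"))
    if beta is None:
        return None, "missing beta", False
    se = _parse_float(row.get("se"))
    if se is None:
        return None, "missing se", False
    if se <= 0:
        return None, "nonpositive se", False
    pval = _parse_float(row.get("pval"))
    if pval is None or not 0.0 <= pval <= 1.0:
        return None, "invalid pval", False

    eaf = _parse_float(row.get("eaf"))
    flagged = eaf is None
    if eaf is not None and not 0.0 < eaf < 1.0:
        return None, "invalid eaf", False

    n = _parse_int(row.get("n"))
    if n is not None and n <= 0:
        return None, "invalid n", False

    # chromosome kept as a plain string ("1".."22", "X"); strip a "chr" prefix
    chrom_s = str(chrom).strip()
    if chrom_s.lower().startswith("chr"):
        chrom_s = chrom_s[3:]

    rec = SummaryStatRecord(
        snp_id=str(snp_id).strip(),
        chrom=chrom_s,
        pos=pos,
        effect_allele=ea,
        other_allele=oa,
        eaf=eaf,
        beta=beta,
        se=se,
        pval=pval,
        n=n,
    )
    return rec, None, flagged


def read_summary_stats(
    path: str | Path, column_map: Optional[ColumnMap] = None
) -> ParseResult:
    """Parse a delimited summary-statistic table into validated records.

    Rows violating the record invariants are dropped and tallied per reason.
    Duplicate rsIDs are rejected outright (all copies dropped) rather than
    silently resolved.

    Raises
    ------
    ColumnMapError
        If a mapped column is absent from the header.
    EmptyInputError
        If no row survives validation.
    """
    column_map = column_map or ColumnMap()
    path = Path(path)
    with open(path) as fh:
        header_line = fh.readline()
    sep = _sniff_delimiter(header_line)

    df = pd.read_csv(
        path, sep=sep, na_values=["", "NA", "."], float_precision="round_trip"
    )
    missing = [
        h
        for canonical, h in column_map.mapping.items()
        if h not in df.columns and canonical not in _OPTIONAL_COLUMNS
    ]
    if missing:
        raise ColumnMapError(f"mapped columns absent from {path.name} header: {missing}")

    rename = {h: c for c, h in column_map.mapping.items() if h in df.columns}
    df = df.rename(columns=rename)

    records: list[SummaryStatRecord] = []
    rejections: Counter = Counter()
    flagged = 0
    for row in df.to_dict(orient="records"):
        rec, reason, miss_eaf = _validate_row(row)
        if rec is None:
            rejections[reason] += 1
        else:
            records.append(rec)
            flagged += miss_eaf

    # duplicate rsIDs: drop every copy (source-data ambiguity, not resolvable)
    counts = Counter(r.snp_id for r in records)
    dupes = {s for s, c in counts.items() if c > 1}
    if dupes:
        n_before = len(records)
        records = [r for r in records if r.snp_id not in dupes]
        rejections["duplicate snp_id"] += n_before - len(records)

    if not records:
        raise EmptyInputError(f"no valid summary-statistic rows in {path}")
    return ParseResult(records=records, rejections=rejections, flagged_missing_eaf=flagged)


def records_to_frame(records: Iterable[SummaryStatRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "SNP": r.snp_id,
                "chr": r.chrom,
                "pos": r.pos,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "eaf": r.eaf,
                "beta": r.beta,
                "se": r.se,
                "pval": r.pval,
                "n": r.n,
            }
        )
    return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))


def write_summary_stats(records: Sequence[SummaryStatRecord], path: str | Path) -> None:
    """Write records as canonical TSV; round-trips through read_summary_stats."""
    df = records_to_frame(records)
    # format via repr so floats survive a write/read cycle bit-exactly
    buf = io.StringIO()
    buf.write("\t".join(CANONICAL_COLUMNS) + "\n")
    for row in df.itertuples(index=False):
        cells = []
        for value in row:
            if value is None or (isinstance(value, float) and math.isnan(value)):
                cells.append("")
            elif isinstance(value, float):
                cells.append(repr(value))
            else:
                cells.append(str(value))
        buf.write("\t".join(cells) + "\n")
    Path(path).write_text(buf.getvalue())


def filter_genome_wide_significant(
    records: Sequence[SummaryStatRecord], threshold: float = 5e-8
) -> list[SummaryStatRecord]:
    """Keep records with ``pval`` strictly below ``threshold``, in order."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    return [r for r in records if r.pval < threshold]
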