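"""Instrument selection: LD clumping, proxy lookup, and F-statistics.

LD is always an input here (pairwise r-squared values); nothing is computed
from a genotype reference panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .exceptions import (
    ContractViolationError,
    DomainError,
    LDInformationRequiredError,
)
from .gwas_io import SummaryStatRecord

__all__ = ["LDMatrix", "ClumpConfig", "ld_clump", "find_proxy", "f_statistic"]


@dataclass
class LDMatrix:
    """Sparse symmetric store of pairwise squared correlations.

    A pair absent from the store is *unknown*, which is distinct from r² = 0:
    clumping refuses to assume independence for co-located SNPs whose r² is
    unknown, while SNPs not present in ``snp_ids`` at all are treated as
    unlinked to everything.
    """

    snp_ids: list[str] = field(default_factory=list)
    _pairs: dict[frozenset, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.snp_ids) != len(set(self.snp_ids)):
            raise ValueError("LD matrix snp_ids must be unique")
        self._idset = set(self.snp_ids)
        for key, r2 in self._pairs.items():
            if not 0.0 <= r2 <= 1.0:
                raise ValueError(f"r2 out of [0,1] for pair {sorted(key)}: {r2}")

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._idset

    def set_r2(self, a: str, b: str, r2: float) -> None:
        if not 0.0 <= r2 <= 1.0:
            raise ValueError(f"r2 out of [0,1]: {r2}")
        for s in (a, b):
            if s not in self._idset:
                self._idset.add(s)
                self.snp_ids.append(s)
        if a != b:
            self._pairs[frozenset((a, b))] = r2

    def r2(self, a: str, b: str) -> Optional[float]:
        """r² between two SNPs; None when unknown (see class docstring)."""
        if a == b:
            return 1.0 if a in self._idset else None
        if a not in self._idset or b not in self._idset:
            return None
        return self._pairs.get(frozenset((a, b)))

    @classmethod
    def from_pairs_tsv(cls, path: str | Path) -> "LDMatrix":
        """Load a three-column (snp_a, snp_b, r2) TSV; symmetrized on load."""
        df = pd.read_csv(path, sep="\t")
        expected = {"snp_a", "snp_b", "r2"}
        if not expected.issubset(df.columns):
            raise ValueError(f"LD pairs file needs columns {sorted(expected)}")
        ld = cls()
        for row in df.itertuples(index=False):
            ld.set_r2(str(row.snp_a), str(row.snp_b), float(row.r2))
        return ld

    @classmethod
    def from_square_tsv(cls, path: str | Path) -> "LDMatrix":
        """Load a square matrix TSV with rsID header row and index column."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        ids = [str(c) for c in df.columns]
        if [str(i) for i in df.index] != ids:
            raise ValueError("square LD matrix must have identical row/column ids")
        ld = cls(snp_ids=list(ids))
        vals = df.to_numpy(dtype=float)
        n = len(ids)
        for i in range(n):
            if abs(vals[i, i] - 1.0) > 1e-9:
                raise ValueError(f"diagonal entry for {ids[i]} is {vals[i, i]}, expected 1")
            for j in range(i + 1, n):
                if abs(vals[i, j] - vals[j, i]) > 1e-9:
                    raise ValueError(f"LD matrix asymmetric at ({ids[i]}, {ids[j]})")
                ld.set_r2(ids[i], ids[j], vals[i, j])
        return ld

    def to_pairs_frame(self) -> pd.DataFrame:
        rows = [
            {"snp_a": a, "snp_b": b, "r2": r2}
            for (a, b), r2 in sorted(
                (tuple(sorted(k)), v) for k, v in self._pairs.items()
            )
        ]
        return pd.DataFrame(rows, columns=["snp_a", "snp_b", "r2"])


@dataclass(frozen=True)
class ClumpConfig:
    r2_threshold: float = 0.01
    window_kb: float = 10_000.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2_threshold <= 1.0:
            raise ValueError(f"r2_threshold must be in [0,1], got {self.r2_threshold}")
        if self.window_kb <= 0:
            raise ValueError(f"window_kb must be > 0, got {self.window_kb}")


def _within_window(a: SummaryStatRecord, b: SummaryStatRecord, window_kb: float) -> bool:
    return a.chrom == b.chrom and abs(a.pos - b.pos) <= window_kb * 1000


def ld_clump(
    records: Sequence[SummaryStatRecord],
    ld: LDMatrix,
    config: ClumpConfig = ClumpConfig(),
) -> list[SummaryStatRecord]:
    """Greedy lowest-p-first clumping.

    Repeatedly takes the remaining SNP with the lowest p-value as an index
    and removes every remaining SNP on the same chromosome within the window
    whose r² with it exceeds the threshold. Ties in p broken by rsID.

    Raises
    ------
    LDInformationRequiredError
        If two co-located input SNPs are both present in the LD store yet
        their pairwise r² is unknown: independence is never assumed silently.
    """
    pool = sorted(records, key=lambda r: (r.pval, r.snp_id))
    kept: list[SummaryStatRecord] = []
    while pool:
        index = pool.pop(0)
        kept.append(index)
        survivors = []
        for cand in pool:
            if not _within_window(index, cand, config.window_kb):
                survivors.append(cand)
                continue
            r2 = ld.r2(index.snp_id, cand.snp_id)
            if r2 is None:
                if index.snp_id in ld and cand.snp_id in ld:
                    raise LDInformationRequiredError(
                        f"LD information required for co-located pair "
                        f"{index.snp_id}/{cand.snp_id} on chr{index.chrom}"
                    )
                r2 = 0.0  # at least one SNP unknown to the panel: unlinked
            if r2 <= config.r2_threshold:
                survivors.append(cand)
        pool = survivors
    return kept


def find_proxy(
    target: str,
    available: Sequence[SummaryStatRecord],
    ld: LDMatrix,
    min_r2: float = 0.8,
) -> Optional[SummaryStatRecord]:
    """Best LD proxy for ``target`` among ``available`` records.

    Returns the candidate with maximal r² to the target subject to
    r² >= ``min_r2``; ties broken by lowest p-value then rsID. ``None`` when
    nothing qualifies.
    """
    if not 0.0 < min_r2 <= 1.0:
        raise DomainError(f"min_r2 must be in (0,1], got {min_r2}")
    if any(rec.snp_id == target for rec in available):
        raise ContractViolationError(f"proxy target {target} is present in available records")

    best: Optional[tuple[float, float, str, SummaryStatRecord]] = None
    for rec in available:
        r2 = ld.r2(target, rec.snp_id)
        if r2 is None or r2 < min_r2:
            continue
        key = (-r2, rec.pval, rec.snp_id)
        if best is None or key < best[:3]:
            best = (*key, rec)
    return None if best is None else best[3]


def f_statistic(beta: float, se: float) -> float:
    """Single-SNP instrument-strength approximation (beta/se)²."""
    if se <= 0:
        raise DomainError(f"se must be > 0, got {se}")
    return (beta / se) ** 2
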