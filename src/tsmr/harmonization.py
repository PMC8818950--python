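"""Express exposure and outcome effects on the same effect allele.

Non-palindromic mismatches are fixed by allele swapping and/or strand
complementation. Palindromic SNPs (A/T, G/C) carry no strand information in
their alleles, so orientation is inferred from allele frequency: frequencies
on the same side of 0.5 mean the reported effect alleles refer to the same
physical allele. SNPs whose minor allele frequency exceeds ``maf_limit`` on
either side are too close to 0.5 to infer and are discarded.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .exceptions import ContractViolationError, NoSharedInstrumentsError
from .gwas_io import SummaryStatRecord

__all__ = [
    "HarmonizedInstrument",
    "HarmonizationResult",
    "harmonize",
    "harmonize_all",
    "COMPLEMENT",
]

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

STATUSES = (
    "aligned",
    "flipped",
    "strand_corrected",
    "frequency_inferred",
    "frequency_inferred_flipped",
)


@dataclass(frozen=True)
class HarmonizedInstrument:
    """A SNP with exposure and outcome effects on the shared effect allele.

    ``sign_flipped`` records whether the raw outcome beta was negated; it is
    implied by status for "flipped"/"frequency_inferred_flipped" but is also
    set when a strand correction uncovered a swapped orientation.
    """

    snp_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: Optional[float]
    eaf_out: Optional[float]
    status: Optional[str]
    kept: bool
    reason: Optional[str] = None
    sign_flipped: bool = False


def _is_palindromic_pair(a: str, b: str) -> bool:
    return {a, b} in ({"A", "T"}, {"G", "C"})


def _maf(eaf: float) -> float:
    return min(eaf, 1.0 - eaf)


def _discard(exposure: SummaryStatRecord, outcome: SummaryStatRecord, reason: str) -> HarmonizedInstrument:
    return HarmonizedInstrument(
        snp_id=exposure.snp_id,
        beta_exp=exposure.beta,
        se_exp=exposure.se,
        beta_out=outcome.beta,
        se_out=outcome.se,
        eaf_exp=exposure.eaf,
        eaf_out=outcome.eaf,
        status=None,
        kept=False,
        reason=reason,
    )


def harmonize(
    exposure: SummaryStatRecord,
    outcome: SummaryStatRecord,
    maf_limit: float = 0.42,
) -> HarmonizedInstrument:
    """Harmonize one exposure/outcome record pair onto the exposure's effect allele.

    Cases: identical allele pair in the same orientation (aligned) or swapped
    (flipped: negate outcome beta, complement its frequency); alleles matching
    only after strand complementation (strand_corrected); palindromic pairs
    resolved by allele frequency (frequency_inferred / ..._flipped) or
    discarded when MAF > ``maf_limit`` on either side; anything else is
    discarded as incompatible.
    """
    if exposure.snp_id != outcome.snp_id:
        raise ContractViolationError(
            f"snp_id mismatch: {exposure.snp_id} vs {outcome.snp_id}"
        )

    ea_e, oa_e = exposure.effect_allele, exposure.other_allele
    ea_o, oa_o = outcome.effect_allele, outcome.other_allele
    exp_set = {ea_e, oa_e}

    def _result(status, beta_out, eaf_out, sign_flipped):
        return HarmonizedInstrument(
            snp_id=exposure.snp_id,
            beta_exp=exposure.beta,
            se_exp=exposure.se,
            beta_out=beta_out,
            se_out=outcome.se,
            eaf_exp=exposure.eaf,
            eaf_out=eaf_out,
            status=status,
            kept=True,
            sign_flipped=sign_flipped,
        )

    if _is_palindromic_pair(ea_e, oa_e):
        if {ea_o, oa_o} != exp_set:
            return _discard(exposure, outcome, "incompatible alleles")
        if exposure.eaf is None or outcome.eaf is None:
            return _discard(exposure, outcome, "missing frequency")
        if _maf(exposure.eaf) > maf_limit or _maf(outcome.eaf) > maf_limit:
            return _discard(exposure, outcome, "non-inferable palindromic")
        # same side of 0.5: the reported frequencies describe the same
        # physical allele, whatever strand or orientation was used
        same_side = (exposure.eaf < 0.5) == (outcome.eaf < 0.5)
        if same_side:
            return _result("frequency_inferred", outcome.beta, outcome.eaf, False)
        return _result(
            "frequency_inferred_flipped", -outcome.beta, 1.0 - outcome.eaf, True
        )

    eaf_o = outcome.eaf

    if {ea_o, oa_o} == exp_set:
        strand = False
    elif {COMPLEMENT[ea_o], COMPLEMENT[oa_o]} == exp_set:
        strand = True
        ea_o, oa_o = COMPLEMENT[ea_o], COMPLEMENT[oa_o]
    else:
        return _discard(exposure, outcome, "incompatible alleles")

    if ea_o == ea_e:
        status = "strand_corrected" if strand else "aligned"
        return _result(status, outcome.beta, eaf_o, False)
    status = "strand_corrected" if strand else "flipped"
    return _result(
        status,
        -outcome.beta,
        None if eaf_o is None else 1.0 - eaf_o,
        True,
    )


@dataclass
class HarmonizationResult:
    kept: list[HarmonizedInstrument]
    discarded: list[HarmonizedInstrument]
    tally: Counter
    missing_from_outcome: list[str]

    @property
    def all_rows(self) -> list[HarmonizedInstrument]:
        return self.kept + self.discarded

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "snp_id": h.snp_id,
                "beta_exp": h.beta_exp,
                "se_exp": h.se_exp,
                "beta_out": h.beta_out,
                "se_out": h.se_out,
                "eaf_exp": h.eaf_exp,
                "eaf_out": h.eaf_out,
                "status": h.status,
                "kept": h.kept,
                "reason": h.reason,
            }
            for h in self.all_rows
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "snp_id",
                "beta_exp",
                "se_exp",
                "beta_out",
                "se_out",
                "eaf_exp",
                "eaf_out",
                "status",
                "kept",
                "reason",
            ],
        )


def harmonize_all(
    exposures: Sequence[SummaryStatRecord],
    outcomes: Sequence[SummaryStatRecord],
    maf_limit: float = 0.42,
) -> HarmonizationResult:
    """Inner-join on snp_id and harmonize each pair.

    Exposure SNPs absent from the outcome table are listed in
    ``missing_from_outcome`` (eligible for proxy search upstream).

    Raises
    ------
    NoSharedInstrumentsError
        If no snp_id is shared between the two tables.
    """
    by_id = {o.snp_id: o for o in outcomes}
    kept: list[HarmonizedInstrument] = []
    discarded: list[HarmonizedInstrument] = []
    missing: list[str] = []
    tally: Counter = Counter()
    shared = 0
    for exp in exposures:
        out = by_id.get(exp.snp_id)
        if out is None:
            missing.append(exp.snp_id)
            continue
        shared += 1
        h = harmonize(exp, out, maf_limit=maf_limit)
        if h.kept:
            kept.append(h)
            tally[h.status] += 1
        else:
            discarded.append(h)
            tally[h.reason] += 1
    if shared == 0:
        raise NoSharedInstrumentsError(
            "no shared instruments between exposure and outcome tables"
        )
    return HarmonizationResult(
        kept=kept, discarded=discarded, tally=tally, missing_from_outcome=missing
    )
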