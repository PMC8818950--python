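"""E-value: minimum confounder strength needed to explain away a risk ratio."""

from __future__ import annotations

import math
from dataclasses import dataclass

from .exceptions import DomainError

__all__ = ["EValueResult", "evalue_from_rr"]


@dataclass(frozen=True)
class EValueResult:
    rr_input: float
    rr_effective: float
    evalue: float


def evalue_from_rr(rr: float) -> EValueResult:
    """E-value for an observed risk ratio.

    Risk ratios below 1 are inverted first; then
    E = RR + sqrt(RR·(RR − 1)). E = 1 exactly when RR = 1 (no association),
    and E(rr) = E(1/rr) by construction.
    """
    if not rr > 0:
        raise DomainError(f"risk ratio must be > 0, got {rr}")
    eff = rr if rr >= 1.0 else 1.0 / rr
    ev = eff + math.sqrt(eff * (eff - 1.0))
    return EValueResult(rr_input=rr, rr_effective=eff, evalue=ev)
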