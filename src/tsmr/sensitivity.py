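"""Heterogeneity, pleiotropy, leave-one-out, funnel, and multiple-testing diagnostics."""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientInstrumentsError, TsmrError
from .estimators import (
    MREstimate,
    _egger_fit,
    egger,
    ivw,
    mode_estimate,
    ratio_estimates,
    weighted_median,
)
from .harmonization import HarmonizedInstrument
from .instruments import f_statistic

__all__ = [
    "SensitivityReport",
    "cochran_q",
    "rucker_q",
    "egger_intercept_test",
    "leave_one_out",
    "funnel_data",
    "bonferroni_threshold",
    "build_sensitivity_report",
]


def cochran_q(
    instruments: Sequence[HarmonizedInstrument], theta: float
) -> tuple[float, int, float]:
    """Cochran's Q about a pooled estimate.

    Q = sum over SNPs of w_j·(ratio_j − theta)² with first-order
    inverse-variance weights; df = nsnp − 1; p from the upper chi-square tail.
    """
    n = len(instruments)
    if n < 2:
        raise InsufficientInstrumentsError("cochran_q requires >= 2 instruments")
    re = ratio_estimates(instruments)
    q = float(np.sum(re.weights * (re.ratios - theta) ** 2))
    df = n - 1
    return q, df, float(stats.chi2.sf(q, df))


def rucker_q(instruments: Sequence[HarmonizedInstrument]) -> tuple[float, int, float]:
    """Heterogeneity about the Egger fit (weighted residual sum of squares), df = nsnp − 2."""
    n = len(instruments)
    _, _, _, _, df, rss, _ = _egger_fit(instruments)
    return rss, df, float(stats.chi2.sf(rss, df))


def egger_intercept_test(
    instruments: Sequence[HarmonizedInstrument],
) -> tuple[float, float, float]:
    """Egger intercept, its standard error, and a two-sided t test (df = nsnp − 2)."""
    est = egger(instruments)
    return est.extra["intercept"], est.extra["intercept_se"], est.extra["intercept_pval"]


def _dispatch(method: str, instruments, n_boot: int = 1000, seed: int = 0,
              ivw_variant: str = "fixed") -> MREstimate:
    if method == "ivw":
        return ivw(instruments, variant=ivw_variant)
    if method == "egger":
        return egger(instruments)
    if method == "weighted_median":
        return weighted_median(instruments, n_boot=n_boot, seed=seed)
    if method == "weighted_mode":
        return mode_estimate(instruments, weighted=True, n_boot=n_boot, seed=seed)
    if method == "simple_mode":
        return mode_estimate(instruments, weighted=False, n_boot=n_boot, seed=seed)
    raise ValueError(f"unknown method: {method}")


@dataclass
class LooRow:
    dropped: str
    estimate: Optional[MREstimate]
    failed: Optional[str] = None
    sign_change: bool = False
    significance_change: bool = False


def leave_one_out(
    instruments: Sequence[HarmonizedInstrument],
    method: str = "ivw",
    alpha: float = 0.05,
    n_boot: int = 1000,
    seed: int = 0,
    ivw_variant: str = "fixed",
) -> list[LooRow]:
    """Refit after dropping each instrument in turn.

    Each row is flagged when the reduced fit changes sign or crosses nominal
    significance relative to the full fit. A method that is not estimable
    after a drop yields a failed row, not a fatal error.
    """
    n = len(instruments)
    if n < 3:
        raise InsufficientInstrumentsError("leave_one_out requires >= 3 instruments")
    full = _dispatch(method, instruments, n_boot=n_boot, seed=seed, ivw_variant=ivw_variant)
    rows: list[LooRow] = []
    for i, dropped in enumerate(instruments):
        subset = list(instruments[:i]) + list(instruments[i + 1 :])
        try:
            est = _dispatch(method, subset, n_boot=n_boot, seed=seed, ivw_variant=ivw_variant)
        except TsmrError as exc:
            rows.append(LooRow(dropped=dropped.snp_id, estimate=None, failed=str(exc)))
            continue
        rows.append(
            LooRow(
                dropped=dropped.snp_id,
                estimate=est,
                sign_change=(est.beta > 0) != (full.beta > 0) and est.beta != full.beta,
                significance_change=(est.pval < alpha) != (full.pval < alpha),
            )
        )
    return rows


def loo_to_frame(rows: Sequence[LooRow]) -> pd.DataFrame:
    out = []
    for r in rows:
        out.append(
            {
                "dropped": r.dropped,
                "beta": r.estimate.beta if r.estimate else None,
                "se": r.estimate.se if r.estimate else None,
                "pval": r.estimate.pval if r.estimate else None,
                "sign_change": r.sign_change,
                "significance_change": r.significance_change,
                "failed": r.failed,
            }
        )
    return pd.DataFrame(out)


def funnel_data(
    instruments: Sequence[HarmonizedInstrument],
) -> tuple[pd.DataFrame, Optional[float]]:
    """Plot-ready funnel coordinates: per-SNP Wald ratio vs inverse ratio-se.

    Also returns a weighted Pearson correlation between ratio and precision as
    a crude asymmetry statistic (None for a single SNP, where it is undefined).
    """
    if len(instruments) < 1:
        raise InsufficientInstrumentsError("funnel_data requires >= 1 instrument")
    re = ratio_estimates(instruments)
    precision = 1.0 / np.sqrt(re.variances)
    df = pd.DataFrame(
        {
            "snp_id": [h.snp_id for h in instruments],
            "ratio": re.ratios,
            "precision": precision,
        }
    )
    if len(instruments) < 2 or np.ptp(re.ratios) == 0 or np.ptp(precision) == 0:
        return df, None
    w = re.weights / re.weights.sum()
    mx = float(np.sum(w * re.ratios))
    my = float(np.sum(w * precision))
    cov = float(np.sum(w * (re.ratios - mx) * (precision - my)))
    vx = float(np.sum(w * (re.ratios - mx) ** 2))
    vy = float(np.sum(w * (precision - my) ** 2))
    return df, cov / math.sqrt(vx * vy)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test threshold alpha/m."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    return alpha / m


@dataclass
class SensitivityReport:
    q_ivw: Optional[tuple[float, int, float]]
    q_egger: Optional[tuple[float, int, float]]
    egger_intercept: Optional[tuple[float, float, float]]
    loo: list[LooRow]
    funnel: pd.DataFrame
    funnel_asymmetry: Optional[float]
    f_stats: dict[str, float]
    bonferroni_alpha: float
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "q_ivw": None
            if self.q_ivw is None
            else dict(zip(("Q", "df", "p"), self.q_ivw)),
            "q_egger": None
            if self.q_egger is None
            else dict(zip(("Q", "df", "p"), self.q_egger)),
            "egger_intercept": None
            if self.egger_intercept is None
            else dict(zip(("estimate", "se", "p"), self.egger_intercept)),
            "leave_one_out": loo_to_frame(self.loo).to_dict(orient="records"),
            "funnel": self.funnel.to_dict(orient="records"),
            "funnel_asymmetry": self.funnel_asymmetry,
            "f_statistics": self.f_stats,
            "bonferroni_alpha": self.bonferroni_alpha,
            "notes": self.notes,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def build_sensitivity_report(
    instruments: Sequence[HarmonizedInstrument],
    loo_method: str = "ivw",
    alpha: float = 0.05,
    m_tests: int = 5,
    n_boot: int = 1000,
    seed: int = 0,
    ivw_variant: str = "fixed",
) -> SensitivityReport:
    """Run the full diagnostic battery, degrading gracefully below method minimums."""
    notes: list[str] = []
    n = len(instruments)

    q_ivw = None
    if n >= 2:
        theta = ivw(instruments, variant=ivw_variant).beta
        q_ivw = cochran_q(instruments, theta)
    else:
        notes.append("q_ivw skipped: fewer than 2 instruments")

    q_egg = intercept = None
    if n >= 3:
        q_egg = rucker_q(instruments)
        intercept = egger_intercept_test(instruments)
    else:
        notes.append("egger diagnostics skipped: fewer than 3 instruments")

    loo: list[LooRow] = []
    if n >= 3:
        loo = leave_one_out(
            instruments, method=loo_method, alpha=alpha, n_boot=n_boot, seed=seed,
            ivw_variant=ivw_variant,
        )
    else:
        notes.append("leave-one-out skipped: fewer than 3 instruments")

    funnel, asymmetry = funnel_data(instruments)
    f_stats = {h.snp_id: f_statistic(h.beta_exp, h.se_exp) for h in instruments}
    return SensitivityReport(
        q_ivw=q_ivw,
        q_egger=q_egg,
        egger_intercept=intercept,
        loo=loo,
        funnel=funnel,
        funnel_asymmetry=asymmetry,
        f_stats=f_stats,
        bonferroni_alpha=bonferroni_threshold(alpha, m_tests),
        notes=notes,
    )
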