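"""The five causal-effect estimators plus the single-SNP Wald ratio.

All estimators consume :class:`~tsmr.harmonization.HarmonizedInstrument`
sequences and return :class:`MREstimate`. Per-SNP causal effects are Wald
ratios (outcome beta over exposure beta) with first-order delta-method
variances; a second-order correction that includes exposure uncertainty is
available behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .exceptions import (
    CollinearityError,
    DegenerateInstrumentError,
    InsufficientInstrumentsError,
)
from .harmonization import HarmonizedInstrument

__all__ = [
    "MREstimate",
    "RatioEstimates",
    "ratio_estimates",
    "wald_ratio",
    "ivw",
    "egger",
    "weighted_median",
    "mode_estimate",
    "or_from_beta",
    "METHOD_NAMES",
]

METHOD_NAMES = ("ivw", "egger", "weighted_median", "simple_mode", "weighted_mode")

_Z975 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class MREstimate:
    """One method's causal estimate on the log-odds scale."""

    method: str
    beta: float
    se: float
    pval: float
    or_value: float
    ci_low: float
    ci_high: float
    nsnp: int
    extra: dict = field(default_factory=dict)


def _as_arrays(instruments: Sequence[HarmonizedInstrument]):
    bx = np.array([h.beta_exp for h in instruments], dtype=float)
    sx = np.array([h.se_exp for h in instruments], dtype=float)
    by = np.array([h.beta_out for h in instruments], dtype=float)
    sy = np.array([h.se_out for h in instruments], dtype=float)
    return bx, sx, by, sy


def _check_nonzero_bx(instruments, bx) -> None:
    zeros = [h.snp_id for h, b in zip(instruments, bx) if b == 0.0]
    if zeros:
        raise DegenerateInstrumentError(
            f"zero exposure effect for instrument(s): {', '.join(zeros)}"
        )


@dataclass(frozen=True)
class RatioEstimates:
    """Per-SNP Wald ratios, delta-method variances, and inverse-variance weights."""

    ratios: np.ndarray
    variances: np.ndarray

    @property
    def weights(self) -> np.ndarray:
        return 1.0 / self.variances


def ratio_estimates(
    instruments: Sequence[HarmonizedInstrument], second_order: bool = False
) -> RatioEstimates:
    """Wald ratios beta_out/beta_exp with delta-method variances.

    First order: se_out²/beta_exp². Second order adds the exposure-noise term
    beta_out²·se_exp²/beta_exp⁴.
    """
    bx, sx, by, sy = _as_arrays(instruments)
    _check_nonzero_bx(instruments, bx)
    ratios = by / bx
    var = sy**2 / bx**2
    if second_order:
        var = var + (by**2 * sx**2) / bx**4
    return RatioEstimates(ratios=ratios, variances=var)


def _estimate(method, beta, se, nsnp, dist="norm", df=None, extra=None) -> MREstimate:
    if dist == "norm":
        pval = 2.0 * stats.norm.sf(abs(beta) / se) if se > 0 else float(beta != 0.0)
        q = _Z975
    else:
        pval = 2.0 * stats.t.sf(abs(beta) / se, df) if se > 0 else float(beta != 0.0)
        q = stats.t.ppf(0.975, df)
    return MREstimate(
        method=method,
        beta=float(beta),
        se=float(se),
        pval=float(min(pval, 1.0)),
        or_value=float(math.exp(beta)),
        ci_low=float(beta - q * se),
        ci_high=float(beta + q * se),
        nsnp=nsnp,
        extra=extra or {},
    )


def wald_ratio(instrument: HarmonizedInstrument) -> MREstimate:
    """Single-SNP causal estimate: beta_out/beta_exp with se = se_out/|beta_exp|."""
    if instrument.beta_exp == 0.0:
        raise DegenerateInstrumentError(
            f"zero exposure effect for instrument: {instrument.snp_id}"
        )
    beta = instrument.beta_out / instrument.beta_exp
    se = instrument.se_out / abs(instrument.beta_exp)
    return _estimate("wald_ratio", beta, se, 1)


def ivw(
    instruments: Sequence[HarmonizedInstrument], variant: str = "fixed"
) -> MREstimate:
    """Inverse-variance-weighted pooled estimate.

    Fixed-effect form: theta = sum(by·bx·wy) / sum(bx²·wy) with wy = se_out⁻²,
    se = [sum(bx²·wy)]^(-1/2) — identical to weighted least squares of by on
    bx through the origin. ``variant="multiplicative"`` inflates the standard
    error by the residual standard deviation floored at 1.
    """
    if variant not in ("fixed", "multiplicative"):
        raise ValueError(f"unknown IVW variant: {variant}")
    if len(instruments) == 0:
        raise InsufficientInstrumentsError("ivw requires at least 1 instrument")
    if len(instruments) == 1:
        est = wald_ratio(instruments[0])
        return MREstimate(**{**est.__dict__, "method": "ivw", "extra": {"variant": "wald_ratio"}})

    bx, _, by, sy = _as_arrays(instruments)
    _check_nonzero_bx(instruments, bx)
    wy = sy**-2
    denom = float(np.sum(bx**2 * wy))
    theta = float(np.sum(by * bx * wy)) / denom
    se = denom**-0.5
    n = len(instruments)
    scale = 1.0
    if variant == "multiplicative":
        resid = by - theta * bx
        sigma2 = float(np.sum(wy * resid**2)) / (n - 1)
        scale = max(1.0, math.sqrt(sigma2))
    return _estimate(
        "ivw", theta, se * scale, n, extra={"variant": variant, "se_scale": scale}
    )


def _egger_fit(instruments: Sequence[HarmonizedInstrument]):
    """Weighted least squares of oriented by on bx with free intercept.

    Orientation: each SNP sign-flipped so its exposure effect is nonnegative.
    Returns (intercept, slope, se_int, se_slope, df, rss_weighted, scale).
    """
    n = len(instruments)
    if n < 3:
        raise InsufficientInstrumentsError(f"egger requires >= 3 instruments, got {n}")
    bx, _, by, sy = _as_arrays(instruments)
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    if np.ptp(bx) == 0.0:
        raise CollinearityError("no variation in oriented exposure effects")
    w = sy**-2
    X = np.column_stack([np.ones(n), bx])
    A = (X.T * w) @ X
    coef = np.linalg.solve(A, (X.T * w) @ by)
    resid = by - X @ coef
    rss = float(np.sum(w * resid**2))
    df = n - 2
    sigma = math.sqrt(rss / df)
    scale = max(1.0, sigma)  # multiplicative over-dispersion floor
    cov_unscaled = np.linalg.inv(A)
    ses = np.sqrt(np.diag(cov_unscaled)) * scale
    return float(coef[0]), float(coef[1]), float(ses[0]), float(ses[1]), df, rss, scale


def egger(instruments: Sequence[HarmonizedInstrument]) -> MREstimate:
    """MR-Egger slope: IVW with a free intercept absorbing directional pleiotropy.

    The intercept estimate/test rides along in ``extra``; p-values use the t
    distribution with nsnp − 2 degrees of freedom.
    """
    intercept, slope, se_int, se_slope, df, rss, scale = _egger_fit(instruments)
    p_int = float(min(2.0 * stats.t.sf(abs(intercept) / se_int, df), 1.0)) if se_int > 0 else 1.0
    extra = {
        "intercept": intercept,
        "intercept_se": se_int,
        "intercept_pval": p_int,
        "q_rucker": rss,
        "se_scale": scale,
    }
    return _estimate(
        "egger", slope, se_slope, len(instruments), dist="t", df=df, extra=extra
    )


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios, kind="stable")
    b = ratios[order]
    w = weights[order]
    total = w.sum()
    if total <= 0:
        raise DegenerateInstrumentError("total weight is zero in weighted median")
    cum = np.cumsum(w)
    p = (cum - w / 2.0) / total
    return float(np.interp(0.5, p, b))


def _bootstrap_se(
    instruments, point_fn, n_boot: int, seed: int, weighted: bool = True
) -> float:
    """Parametric bootstrap: resample betas from N(beta_hat, se), recompute."""
    bx, sx, by, sy = _as_arrays(instruments)
    rng = np.random.default_rng(seed)
    n = len(instruments)
    BX = rng.normal(bx, sx, size=(n_boot, n))
    BY = rng.normal(by, sy, size=(n_boot, n))
    out = np.empty(n_boot)
    for i in range(n_boot):
        r = BY[i] / BX[i]
        var = sy**2 / BX[i] ** 2
        w = 1.0 / var if weighted else np.ones(n)
        out[i] = point_fn(r, w)
    return float(np.std(out, ddof=0))


def weighted_median(
    instruments: Sequence[HarmonizedInstrument],
    n_boot: int = 1000,
    seed: int = 0,
    second_order: bool = False,
) -> MREstimate:
    """Weighted median of per-SNP Wald ratios.

    Ratios are sorted; the cumulative standardized weight of rank j is
    p_j = (S_j − w_j/2)/Σw and the estimate linearly interpolates the ratio at
    p = 0.5. The standard error comes from a seeded parametric bootstrap.
    """
    if len(instruments) < 2:
        raise InsufficientInstrumentsError("weighted_median requires >= 2 instruments")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    re = ratio_estimates(instruments, second_order=second_order)
    point = _weighted_median_point(re.ratios, re.weights)
    se = _bootstrap_se(instruments, _weighted_median_point, n_boot, seed)
    return _estimate("weighted_median", point, se, len(instruments))


def _mode_bandwidth(ratios: np.ndarray, phi: float) -> float:
    # normal-reference rule: 0.9 * min(sd, iqr/1.349) * n^(-1/5), scaled by phi
    s = float(np.std(ratios, ddof=1))
    q75, q25 = np.percentile(ratios, [75, 25])
    iqr_s = (q75 - q25) / 1.349
    candidates = [v for v in (s, iqr_s) if v > 0]
    sigma = min(candidates) if candidates else 0.0
    return phi * 0.9 * sigma * len(ratios) ** (-0.2)


def _kde_mode(ratios: np.ndarray, weights: np.ndarray, h: float, gridsize: int = 512) -> float:
    if h == 0.0 or np.ptp(ratios) == 0.0:
        return float(ratios[0])
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, gridsize)
    z = (grid[:, None] - ratios[None, :]) / h
    dens = (weights[None, :] * np.exp(-0.5 * z * z)).sum(axis=1)
    return float(grid[int(np.argmax(dens))])


def mode_estimate(
    instruments: Sequence[HarmonizedInstrument],
    weighted: bool = True,
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
    second_order: bool = False,
) -> MREstimate:
    """Mode of the per-SNP Wald-ratio density under a normal kernel.

    ``weighted`` uses inverse-variance weights (weighted mode); otherwise all
    SNPs count equally (simple mode). Bandwidth follows the normal-reference
    rule scaled by ``phi``. Identical ratios (bandwidth 0) return the common
    value rather than erroring. Standard error by parametric bootstrap.
    """
    if len(instruments) < 3:
        raise InsufficientInstrumentsError("mode estimators require >= 3 instruments")
    if phi <= 0:
        raise ValueError("phi must be > 0")
    re = ratio_estimates(instruments, second_order=second_order)
    w = re.weights if weighted else np.ones(len(re.ratios))

    def point_fn(ratios, weights):
        h = _mode_bandwidth(ratios, phi)
        return _kde_mode(ratios, weights, h)

    point = point_fn(re.ratios, w)
    se = _bootstrap_se(instruments, point_fn, n_boot, seed, weighted=weighted)
    name = "weighted_mode" if weighted else "simple_mode"
    return _estimate(name, point, se, len(instruments), extra={"phi": phi})


def or_from_beta(beta: float) -> float:
    """Odds ratio from a log-odds effect."""
    if not math.isfinite(beta):
        raise ValueError(f"beta must be finite, got {beta}")
    return math.exp(beta)
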