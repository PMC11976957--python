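"""Growth-curve and permeability kinetics, plus the two-group test helper.

Growth curves are fit to the logistic model
``N(t) = K / (1 + ((K - N0)/N0) * exp(-r t))`` with carrying capacity K
(OD units), initial population N0 and intrinsic growth rate r (1/h); the
time to half-maximal population is the closed form
``Tmid = ln((K - N0)/N0) / r``. Vesicle swelling assays are fit to an
exponential turbidity decay ``A(t) = Ainf + (A0 - Ainf) * exp(-k t)``;
the rate constant k serves as a water-permeability proxy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "GrowthCurve",
    "GrowthFit",
    "TurbidityTrace",
    "TurbidityFit",
    "logistic",
    "fit_logistic",
    "turbidity_rate",
    "two_group_t",
]


@dataclass(frozen=True)
class GrowthCurve:
    time: np.ndarray  # hours
    od: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.time, float)
        od = np.asarray(self.od, float)
        if t.size < 8:
            raise ValueError("growth curve needs >= 8 points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(od < 0):
            raise ValueError("OD readings must be non-negative")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "od", od)


@dataclass
class GrowthFit:
    K: float
    N0: float
    r: float
    tmid: float
    residual_sd: float
    converged: bool


@dataclass(frozen=True)
class TurbidityTrace:
    time: np.ndarray  # seconds
    a550: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.time, float)
        a = np.asarray(self.a550, float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "a550", a)


@dataclass
class TurbidityFit:
    k: float      # 1/s, permeability proxy
    A0: float
    Ainf: float
    residual_sd: float


def logistic(t: np.ndarray, K: float, N0: float, r: float) -> np.ndarray:
    """Logistic population model N(t)."""
    return K / (1.0 + (K - N0) / N0 * np.exp(-r * np.asarray(t, float)))


def fit_logistic(curve: GrowthCurve) -> GrowthFit:
    """Least-squares logistic fit with data-driven initialization.

    Initial K is the max OD, N0 the first positive OD, r the log-slope of
    the early readings. Non-growing curves (last OD <= first) or
    non-converging fits return ``converged=False`` with NaN parameters.
    """
    t, od = curve.time, curve.od
    failed = GrowthFit(math.nan, math.nan, math.nan, math.nan, math.nan,
                       False)
    if od[-1] <= od[0]:
        return failed
    K0 = float(od.max())
    positive = od[od > 0]
    if positive.size == 0:
        return failed
    N00 = float(positive[0])
    # log-slope of the early growth phase
    early = slice(0, max(3, od.size // 4))
    with np.errstate(divide="ignore"):
        logod = np.log(np.clip(od[early], 1e-12, None))
    r0 = float(np.polyfit(t[early], logod, 1)[0])
    r0 = max(r0, 1e-3)
    try:
        popt, _ = optimize.curve_fit(
            logistic, t, od, p0=[K0, N00, r0],
            bounds=([1e-12, 1e-12, 1e-12], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
    except (RuntimeError, ValueError):
        return failed
    K, N0, r = (float(v) for v in popt)
    if not (K > N0 > 0) or r <= 0:
        return failed
    tmid = math.log((K - N0) / N0) / r
    resid = od - logistic(t, K, N0, r)
    dof = max(od.size - 3, 1)
    return GrowthFit(K, N0, r, tmid,
                     float(np.sqrt((resid**2).sum() / dof)), True)


def _exp_decay(t, Ainf, A0, k):
    return Ainf + (A0 - Ainf) * np.exp(-k * t)


def turbidity_rate(trace: TurbidityTrace) -> TurbidityFit:
    """Exponential-decay fit of a turbidity trace; k is the permeability
    proxy.

    Raises on traces with no overall decrease (nothing to fit).
    """
    t, a = trace.time, trace.a550
    if a[-1] >= a[0]:
        raise ValueError("trace is not decreasing; no decay to fit")
    A0_0 = float(a[0])
    Ainf_0 = float(a.min())
    drop = a - Ainf_0
    # crude initial rate from the time to lose half the amplitude
    half = Ainf_0 + 0.5 * (A0_0 - Ainf_0)
    below = np.nonzero(a <= half)[0]
    t_half = t[below[0]] if below.size else t[-1]
    k0 = math.log(2) / max(t_half - t[0], (t[1] - t[0]))
    popt, _ = optimize.curve_fit(
        _exp_decay, t, a, p0=[Ainf_0, A0_0, k0], maxfev=10000
    )
    Ainf, A0, k = (float(v) for v in popt)
    resid = a - _exp_decay(t, Ainf, A0, k)
    dof = max(a.size - 3, 1)
    return TurbidityFit(k, A0, Ainf, float(np.sqrt((resid**2).sum() / dof)))


def two_group_t(
    group_a: np.ndarray,
    group_b: np.ndarray,
    equal_var: bool = False,
) -> tuple[float, float]:
    """Two-tailed unpaired t-test (Welch by default).

    Returns ``(t, p)``. Identical groups give t = 0, p = 1. Groups need
    n >= 2 and finite, nonzero pooled variance.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("groups must be finite")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("degenerate groups with zero variance")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)
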