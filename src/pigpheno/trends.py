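"""Caption-level statistics: Pearson correlation, unpaired t-test, simple
linear regression and a four-parameter Gaussian curve fit.

The first three are written out from their closed forms (the test suite
cross-checks them against scipy/statsmodels); only tail probabilities come
from the t distribution.  The Gaussian fit is a nonlinear least-squares fit
of ``baseline + amplitude * exp(-(x - mean)^2 / (2 sd^2))`` with multi-start
initialization and an explicit convergence flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats


@dataclass
class TrendResult:
    """One fitted trend: estimates, effect size, two-tailed p and n."""

    kind: str
    n: int
    estimates: dict = field(default_factory=dict)
    r: float = np.nan
    r_squared: float = np.nan
    p: float = np.nan
    flags: list = field(default_factory=list)


def pearson(x, y) -> TrendResult:
    """Pearson correlation with two-tailed p from the t distribution.

    r = cov(x, y) / (sd_x sd_y);  t = r sqrt((n-2)/(1-r^2)) with n-2 df.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n != len(y):
        raise ValueError("x and y must have equal length")
    if n < 3:
        raise ValueError("pearson needs n >= 3")
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    if sxx == 0.0 or syy == 0.0:
        return TrendResult(kind="pearson", n=n, flags=["zero-variance"])
    r = float(dx @ dy) / np.sqrt(sxx * syy)
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 2
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = 2.0 * float(stats.t.sf(abs(t), df))
    return TrendResult(kind="pearson", n=n, r=r, r_squared=r * r, p=p)


def unpaired_t(a, b, welch: bool = False) -> TrendResult:
    """Unpaired two-sample t-test (pooled variance by default, Welch by flag).

    Reports eta^2 = t^2 / (t^2 + df) as the explained-variance companion,
    labeled in ``estimates``.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each group needs >= 2 observations")
    va = float(a.var(ddof=1))
    vb = float(b.var(ddof=1))
    diff = float(a.mean() - b.mean())
    if welch:
        se2 = va / na + vb / nb
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    else:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se2 = sp2 * (1.0 / na + 1.0 / nb)
        df = na + nb - 2
    flags = []
    if se2 == 0.0:
        if diff == 0.0:
            t, p, eta2 = 0.0, 1.0, 0.0
            flags.append("zero-variance")
        else:
            t, p, eta2 = np.inf, 0.0, 1.0
            flags.append("zero-variance")
    else:
        t = diff / np.sqrt(se2)
        p = 2.0 * float(stats.t.sf(abs(t), df))
        eta2 = t * t / (t * t + df)
    return TrendResult(
        kind="welch_t" if welch else "pooled_t",
        n=na + nb,
        estimates={"mean_diff": diff, "t": float(t), "df": float(df), "eta_squared": float(eta2)},
        r_squared=float(eta2),
        p=p,
        flags=flags,
    )


def linreg(x, y) -> TrendResult:
    """Simple linear regression by the normal equations.

    slope = Sxy/Sxx, intercept = ybar - slope*xbar; the slope's two-tailed p
    comes from t = slope/SE(slope) with n-2 df.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n != len(y):
        raise ValueError("x and y must have equal length")
    if n < 3:
        raise ValueError("linreg needs n >= 3")
    dx = x - x.mean()
    sxx = float(dx @ dx)
    if sxx == 0.0:
        return TrendResult(kind="linreg", n=n, flags=["zero-variance"])
    slope = float(dx @ (y - y.mean())) / sxx
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    ss_res = float(resid @ resid)
    ss_tot = float((y - y.mean()) @ (y - y.mean()))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    df = n - 2
    if ss_res <= 0.0:
        p = 0.0
        se = 0.0
    else:
        se = np.sqrt(ss_res / df / sxx)
        t = slope / se
        p = 2.0 * float(stats.t.sf(abs(t), df))
    return TrendResult(
        kind="linreg",
        n=n,
        estimates={"slope": slope, "intercept": intercept, "slope_se": float(se)},
        r=float(np.sign(slope) * np.sqrt(max(r2, 0.0))),
        r_squared=float(r2),
        p=p,
    )


def _gaussian(x, amplitude, mean, sd, baseline):
    return baseline + amplitude * np.exp(-((x - mean) ** 2) / (2.0 * sd**2))


def gaussian_fit(x, y, with_baseline: bool = True, n_starts: int = 8, seed: int = 0) -> TrendResult:
    """Least-squares Gaussian peak fit with multi-start initialization.

    Starts are spread over the x range (plus the moment-based guess); the
    best converged start wins.  Non-convergence is flagged, never silent.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n < 5:
        raise ValueError("gaussian_fit needs >= 5 points")
    span = float(np.ptp(x)) or 1.0
    base0 = float(np.min(y)) if with_baseline else 0.0
    amp0 = float(np.max(y) - base0)
    rng = np.random.default_rng(seed)
    starts = [(amp0 or 1.0, float(x[np.argmax(y)]), span / 4.0, base0)]
    for _ in range(n_starts - 1):
        starts.append(
            (
                (amp0 or 1.0) * rng.uniform(0.3, 2.0),
                float(rng.uniform(x.min(), x.max())),
                span * rng.uniform(0.05, 0.6),
                base0 + (amp0 or 1.0) * rng.uniform(-0.2, 0.2),
            )
        )
    best = None
    for p0 in starts:
        if not with_baseline:
            p0 = p0[:3]
        try:
            with warnings.catch_warnings():
                # poor multi-start seeds routinely yield singular covariances
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                if with_baseline:
                    popt, _ = optimize.curve_fit(_gaussian, x, y, p0=p0, maxfev=20000)
                else:
                    popt, _ = optimize.curve_fit(
                        lambda xx, a, m, s: _gaussian(xx, a, m, s, 0.0), x, y, p0=p0, maxfev=20000
                    )
                    popt = np.append(popt, 0.0)
        except (RuntimeError, ValueError):
            continue
        resid = y - _gaussian(x, *popt)
        ss = float(resid @ resid)
        if best is None or ss < best[1]:
            best = (popt, ss)
    if best is None:
        return TrendResult(kind="gaussian", n=n, flags=["non-convergence"])
    popt, ss_res = best
    amplitude, mean, sd, baseline = (float(v) for v in popt)
    sd = abs(sd)  # sign of sd is unidentifiable
    ss_tot = float((y - y.mean()) @ (y - y.mean()))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return TrendResult(
        kind="gaussian",
        n=n,
        estimates={"amplitude": amplitude, "mean": mean, "sd": sd, "baseline": baseline},
        r_squared=float(r2),
        flags=[],
    )
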