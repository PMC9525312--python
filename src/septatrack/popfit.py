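"""Population fits of segment speeds.

Processive speeds are fitted with a single or double log-normal mixture
on the empirical cumulative distribution,

    CDF(v) = P1 * Phi((ln v - u1) / s1) + (1 - P1) * Phi((ln v - u2) / s2),

where Phi is the standard normal CDF (erf form) and u, sigma are the
log-space mean and standard deviation; the mean speed of a component is
exp(u + sigma^2 / 2). Standard errors come from a 200x bootstrap over
the speed sample. Apparent speeds of the stationary population are
fitted with a single exponential decay f(x) = A exp(-lambda x) on
histogram counts, with mean apparent speed u = 1/lambda.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import ks_2samp, norm

__all__ = ["SpeedFit", "StationaryFit", "fit_speed_cdf", "bootstrap_fit",
           "fit_stationary_exponential", "ks_two_sample", "mixture_cdf"]


def mixture_cdf(v, p1, u1, s1, u2=0.0, s2=1.0):
    """Log-normal mixture CDF evaluated at speeds v (nm/s)."""
    v = np.asarray(v, dtype=float)
    c1 = norm.cdf((np.log(v) - u1) / max(s1, 1e-9))
    c2 = norm.cdf((np.log(v) - u2) / max(s2, 1e-9))
    return p1 * c1 + (1.0 - p1) * c2


@dataclass
class SpeedFit:
    """Fitted log-normal mixture of processive speeds."""

    n_components: int
    p1: float
    u1: float
    sigma1: float
    u2: float | None = None
    sigma2: float | None = None
    n: int = 0
    rss: float = np.nan
    bic: float = np.nan
    se: dict = field(default_factory=dict)   # filled by bootstrap_fit
    B: int | None = None
    seed: int | None = None

    @property
    def mean_speeds(self) -> list[float]:
        out = [float(np.exp(self.u1 + self.sigma1**2 / 2))]
        if self.n_components == 2:
            out.append(float(np.exp(self.u2 + self.sigma2**2 / 2)))
        return out

    def cdf(self, v):
        if self.n_components == 1:
            return mixture_cdf(v, 1.0, self.u1, self.sigma1)
        return mixture_cdf(v, self.p1, self.u1, self.sigma1, self.u2,
                           self.sigma2)


@dataclass
class StationaryFit:
    """Exponential decay fit of the stationary apparent-speed histogram."""

    A: float
    lam: float            # per (nm/s)
    bin_edges: np.ndarray

    @property
    def u(self) -> float:
        """Mean apparent speed, u = 1/lambda (nm/s)."""
        return 1.0 / self.lam


def _ecdf(speeds):
    x = np.sort(speeds)
    y = (np.arange(1, x.size + 1) - 0.5) / x.size
    return x, y


def _mixture_loglik(v, p1, u1, s1, u2=None, s2=None):
    """Sample log-likelihood under the fitted log-normal mixture."""
    logv = np.log(v)
    s1 = max(s1, 1e-6)

    def comp(u, s):
        return np.exp(-0.5 * ((logv - u) / s) ** 2) / (s * v * np.sqrt(2 * np.pi))

    if u2 is None:
        dens = comp(u1, s1)
    else:
        dens = p1 * comp(u1, s1) + (1.0 - p1) * comp(u2, max(s2, 1e-6))
    return float(np.sum(np.log(np.clip(dens, 1e-300, None))))


def _fit_once(x, y, n_components, x0):
    logx = np.log(x)
    lo, hi = logx.min() - 2.0, logx.max() + 2.0
    if n_components == 1:
        def resid(p):
            return mixture_cdf(x, 1.0, p[0], p[1]) - y
        bounds = ([lo, 1e-3], [hi, 3.0])
    else:
        def resid(p):
            return mixture_cdf(x, p[0], p[1], p[2], p[3], p[4]) - y
        bounds = ([0.0, lo, 1e-3, lo, 1e-3], [1.0, hi, 3.0, hi, 3.0])
    sol = least_squares(resid, x0, bounds=bounds, xtol=1e-12, ftol=1e-12)
    return sol.x, float((sol.fun**2).sum())


def fit_speed_cdf(speeds, n_components=1, _x0=None) -> SpeedFit:
    """Least-squares log-normal mixture fit of the empirical speed CDF.

    Parameters
    ----------
    speeds : positive speeds (nm/s), at least 20 values.
    n_components : 1, 2, or "auto". With "auto" both models are fitted
        and the two-component fit is kept only if it improves the BIC by
        at least 6 (strong evidence).

    Components are ordered so u1 <= u2 (slow population first); for a
    single component P1 is fixed to 1.

    Parameters are estimated by least squares on the empirical CDF (the
    classic erf-form fit); the BIC used for model selection is computed
    from the sample log-likelihood of the fitted mixture density, since
    squared ECDF residuals are strongly autocorrelated and would make a
    Gaussian-residual BIC systematically favor the larger model.
    """
    v = np.asarray(speeds, dtype=float)
    if v.size < 20:
        raise ValueError("need at least 20 speeds")
    if np.any(v <= 0) or not np.all(np.isfinite(v)):
        raise ValueError("speeds must be positive and finite")
    x, y = _ecdf(v)
    logx = np.log(x)

    def bic(loglik, k):
        return -2.0 * loglik + k * np.log(x.size)

    if n_components == "auto":
        f1 = fit_speed_cdf(v, 1)
        f2 = fit_speed_cdf(v, 2)
        return f2 if f2.bic < f1.bic - 6.0 else f1

    if n_components == 1:
        x0 = _x0 if _x0 is not None else [logx.mean(), max(logx.std(), 0.05)]
        starts = [x0, [np.median(logx), 0.3]]
        best = None
        for s0 in starts:
            try:
                p, rss = _fit_once(x, y, 1, s0)
            except Exception:
                continue
            if best is None or rss < best[1]:
                best = (p, rss)
        if best is None:
            raise RuntimeError("single log-normal CDF fit did not converge")
        p, rss = best
        ll = _mixture_loglik(x, 1.0, p[0], p[1])
        return SpeedFit(1, 1.0, float(p[0]), float(p[1]), n=x.size, rss=rss,
                        bic=bic(ll, 2))

    if _x0 is not None:
        starts = [_x0]
    else:
        med = np.median(logx)
        lowm = logx[logx <= med].mean()
        highm = logx[logx > med].mean()
        sd = float(np.clip(logx.std() / 2, 0.05, 2.9))
        starts = [[0.5, lowm, sd, highm, sd],
                  [0.3, np.quantile(logx, 0.15), sd, np.quantile(logx, 0.7), sd],
                  [0.7, np.quantile(logx, 0.3), sd, np.quantile(logx, 0.85), sd]]
    best = None
    for s0 in starts:
        try:
            p, rss = _fit_once(x, y, 2, s0)
        except Exception:
            continue
        if best is None or rss < best[1]:
            best = (p, rss)
    if best is None:
        raise RuntimeError("double log-normal CDF fit did not converge")
    p, rss = best
    p1, u1, s1, u2, s2 = p
    if u1 > u2:  # order components slow-first
        p1, u1, s1, u2, s2 = 1.0 - p1, u2, s2, u1, s1
    ll = _mixture_loglik(x, p1, u1, s1, u2, s2)
    return SpeedFit(2, float(p1), float(u1), float(s1), float(u2), float(s2),
                    n=x.size, rss=rss, bic=bic(ll, 5))


def bootstrap_fit(speeds, n_components=1, B: int = 200, seed: int = 0,
                  max_dropped_frac: float = 0.2) -> SpeedFit:
    """Fit plus bootstrap standard errors.

    Resamples the speeds with replacement B times, refits each replicate
    (initialized at the full-sample solution), and reports the standard
    deviation across replicates for every parameter and derived mean.
    Replicates that fail to converge are dropped and counted; more than
    20% dropped raises.
    """
    fit = fit_speed_cdf(speeds, n_components)
    v = np.asarray(speeds, dtype=float)
    rng = np.random.default_rng(seed)
    if fit.n_components == 1:
        x0 = [fit.u1, fit.sigma1]
    else:
        x0 = [fit.p1, fit.u1, fit.sigma1, fit.u2, fit.sigma2]
    rows = []
    dropped = 0
    for _ in range(B):
        sample = rng.choice(v, size=v.size, replace=True)
        try:
            f = fit_speed_cdf(sample, fit.n_components, _x0=x0)
        except Exception:
            dropped += 1
            continue
        if fit.n_components == 1:
            row = [f.p1, f.u1, f.sigma1, f.mean_speeds[0]]
        else:
            row = [f.p1, f.u1, f.sigma1, f.u2, f.sigma2] + f.mean_speeds
        rows.append(row)
    if dropped > max_dropped_frac * B:
        raise RuntimeError(f"{dropped}/{B} bootstrap replicates failed")
    arr = np.asarray(rows, dtype=float)
    names = (["p1", "u1", "sigma1", "mean1"] if fit.n_components == 1 else
             ["p1", "u1", "sigma1", "u2", "sigma2", "mean1", "mean2"])
    fit.se = {k: float(np.std(arr[:, i], ddof=1))
              for i, k in enumerate(names)}
    fit.B = B
    fit.seed = seed
    fit.se["n_dropped"] = dropped
    return fit


def fit_stationary_exponential(apparent_speeds, bin_width: float = 2.0
                               ) -> StationaryFit:
    """Exponential decay fit of the stationary apparent-speed histogram.

    Histograms |v| from 0 with fixed `bin_width` (nm/s) and fits
    A exp(-lambda x) to (bin center, count) by least squares. The mean
    apparent speed is u = 1/lambda.
    """
    v = np.abs(np.asarray(apparent_speeds, dtype=float))
    if v.size < 20:
        raise ValueError("need at least 20 apparent speeds")
    hi = bin_width * np.ceil(v.max() / bin_width + 0.5)
    edges = np.arange(0.0, hi + bin_width / 2, bin_width)
    counts, _ = np.histogram(v, bins=edges)
    if np.count_nonzero(counts) < 3:
        raise ValueError("fewer than 3 nonempty histogram bins")
    centers = 0.5 * (edges[:-1] + edges[1:])

    def resid(p):
        return p[0] * np.exp(-p[1] * centers) - counts

    x0 = [float(counts.max()), 1.0 / max(v.mean(), 1e-6)]
    sol = least_squares(resid, x0, bounds=([1e-9, 1e-9], [np.inf, np.inf]))
    A, lam = sol.x
    return StationaryFit(A=float(A), lam=float(lam), bin_edges=edges)


def ks_two_sample(a, b):
    """Two-sample Kolmogorov-Smirnov test: returns (D, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    res = ks_2samp(a, b, method="asymp" if min(a.size, b.size) > 50 else "auto")
    return float(res.statistic), float(res.pvalue)
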