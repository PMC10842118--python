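"""Heavy-tail fitting, model comparison, log binning and spectral summaries.

Power-law exponents are estimated by maximum likelihood on truncated
supports; the power-law/exponential decision uses the normalized
log-likelihood-ratio test, with p = erfc(|R| / sqrt(2 n sigma^2)) where
sigma^2 is the variance of the per-point log-likelihood ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal, special

from .io_core import MultichannelRecording


@dataclass
class ScalingFit:
    """Result of a scaling-law fit."""

    family: str  # powerlaw | exponential | stretched_exp
    params: dict = field(default_factory=dict)
    xmin: float = np.nan
    xmax: float = np.nan
    n: int = 0
    loglik: float = np.nan
    R: float = np.nan
    p_value: float = np.nan

    @property
    def exponent(self) -> float:
        return self.params.get("alpha", self.params.get("beta", np.nan))

    @property
    def stderr(self) -> float:
        return self.params.get("se", np.nan)


@dataclass
class SpectralSummary:
    freqs: np.ndarray
    psd: np.ndarray
    f_alpha_max: float
    alpha_band: tuple[float, float] = (8.0, 13.0)


# ---------------------------------------------------------------------------
# truncated power law


def _pl_logpdf(x: np.ndarray, alpha: float, xmin: float, xmax: float) -> np.ndarray:
    """log density of x^-alpha normalized on [xmin, xmax] (xmax may be inf)."""
    if np.isinf(xmax):
        if alpha <= 1:
            raise ValueError("alpha must exceed 1 for unbounded support")
        logz = math.log(alpha - 1) + (alpha - 1) * math.log(xmin)
    else:
        if abs(alpha - 1) < 1e-12:
            z = math.log(xmax / xmin)
        else:
            z = (xmax ** (1 - alpha) - xmin ** (1 - alpha)) / (1 - alpha)
        logz = -math.log(z)
    return logz - alpha * np.log(x)


def fit_powerlaw_mle(x: np.ndarray, xmin: float, xmax: float = np.inf) -> ScalingFit:
    """MLE of the exponent of p(x) ∝ x^-alpha on [xmin, xmax].

    Unbounded support uses the closed form alpha = 1 + n / Σ ln(x/xmin);
    a finite xmax is handled by 1-D likelihood maximization and admits any
    alpha > 0 (including alpha < 1).  The standard error comes from the
    observed Fisher information.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 observations")
    if np.any(x < xmin) or np.any(x > xmax):
        raise ValueError("data outside [xmin, xmax]")
    n = x.size
    slog = float(np.log(x / xmin).sum())
    if np.isinf(xmax):
        if slog == 0:
            raise ValueError("degenerate sample: all values at xmin")
        alpha = 1.0 + n / slog
        se = (alpha - 1.0) / math.sqrt(n)
    else:
        if np.allclose(x, x[0]):
            raise ValueError("degenerate sample: all values equal")
        def nll(a: float) -> float:
            return -float(_pl_logpdf(x, a, xmin, xmax).sum())

        res = optimize.minimize_scalar(nll, bounds=(1e-6, 50.0), method="bounded",
                                       options={"xatol": 1e-10})
        alpha = float(res.x)
        h = 1e-4 * max(alpha, 1.0)
        d2 = (nll(alpha + h) - 2 * nll(alpha) + nll(alpha - h)) / h**2
        se = 1.0 / math.sqrt(d2) if d2 > 0 else np.nan
    ll = float(_pl_logpdf(x, alpha, xmin, xmax).sum())
    return ScalingFit("powerlaw", {"alpha": alpha, "se": se},
                      xmin=xmin, xmax=xmax, n=n, loglik=ll)


def compare_powerlaw_exponential(x: np.ndarray, xmin: float) -> tuple[float, float]:
    """Log-likelihood ratio R (power law vs exponential) and its p-value.

    Both families are MLE-fitted above ``xmin``; R > 0 favors the power
    law.  p = erfc(|R| / sqrt(2 n sigma^2)) with sigma^2 the variance of
    the per-point log ratios (Vuong normalization).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 observations")
    if np.any(x < xmin):
        raise ValueError("data below xmin")
    mean_excess = float(np.mean(x - xmin))
    if mean_excess <= 0 or np.allclose(x, x[0]):
        raise ValueError("degenerate sample")
    pl = fit_powerlaw_mle(x, xmin)
    lam = 1.0 / mean_excess  # exponential MLE on [xmin, inf)
    li_pl = _pl_logpdf(x, pl.params["alpha"], xmin, np.inf)
    li_ex = math.log(lam) - lam * (x - xmin)
    li = li_pl - li_ex
    R = float(li.sum())
    n = x.size
    sigma2 = float(np.var(li))
    if sigma2 == 0:
        return R, 1.0
    p = float(special.erfc(abs(R) / math.sqrt(2.0 * n * sigma2)))
    return R, p


def fit_double_powerlaw(dt: np.ndarray, crossover: float | None = None,
                        dt_cut: float | None = None,
                        n_grid: int = 30) -> tuple[ScalingFit, ScalingFit, float]:
    """Fit two truncated power laws below/above a crossover quiet time.

    When the crossover is not given it is selected on a log-spaced grid by
    minimizing the summed Kolmogorov-Smirnov distances of the two truncated
    fits.  ``dt_cut`` defaults to the 99th percentile to exclude the
    exponential cutoff region.
    """
    dt = np.asarray(dt, dtype=float)
    if dt.size < 200:
        raise ValueError("need at least 200 quiet times")
    dt_min = float(dt.min())
    if dt_cut is None:
        dt_cut = float(np.quantile(dt, 0.99))
    core = dt[(dt >= dt_min) & (dt <= dt_cut)]

    def two_fits(xc: float) -> tuple[ScalingFit, ScalingFit]:
        lo = core[core <= xc]
        hi = core[core >= xc]
        if lo.size < 50 or hi.size < 50:
            raise ValueError(
                f"fewer than 50 points in a segment at crossover {xc:g}")
        return (fit_powerlaw_mle(lo, dt_min, xc), fit_powerlaw_mle(hi, xc, dt_cut))

    def ks(seg: np.ndarray, f: ScalingFit) -> float:
        a, lo, hi = f.params["alpha"], f.xmin, f.xmax
        xs = np.sort(seg)
        if abs(a - 1) < 1e-12:
            cdf = np.log(xs / lo) / math.log(hi / lo)
        else:
            cdf = (xs ** (1 - a) - lo ** (1 - a)) / (hi ** (1 - a) - lo ** (1 - a))
        emp = np.arange(1, xs.size + 1) / xs.size
        return float(np.max(np.abs(emp - cdf)))

    if crossover is None:
        lo_q, hi_q = np.quantile(core, [0.05, 0.95])
        grid = np.geomspace(lo_q, hi_q, n_grid)
        best, crossover = np.inf, grid[0]
        for xc in grid:
            try:
                flo, fhi = two_fits(xc)
            except ValueError:
                continue
            d = ks(core[core <= xc], flo) + ks(core[core >= xc], fhi)
            if d < best:
                best, crossover = d, float(xc)
    fit_lo, fit_hi = two_fits(float(crossover))
    return fit_lo, fit_hi, float(crossover)


# ---------------------------------------------------------------------------
# stretched exponential


def fit_stretched_exponential(t_centers: np.ndarray, N_values: np.ndarray,
                              weights: np.ndarray | None = None) -> ScalingFit:
    """Weighted least squares of ln N = ln A - (t/tau)^beta on positive bins."""
    t = np.asarray(t_centers, dtype=float)
    N = np.asarray(N_values, dtype=float)
    pos = (N > 0) & (t > 0)
    if pos.sum() < 6:
        raise ValueError("need at least 6 positive (t, N) points")
    t, N = t[pos], N[pos]
    w = np.ones_like(N) if weights is None else np.asarray(weights, dtype=float)[pos]
    lnN = np.log(N)

    def model(p: np.ndarray) -> np.ndarray:
        lnA, beta, ltau = p
        return lnA - (t / math.exp(ltau)) ** beta

    def cost(p: np.ndarray) -> float:
        if not (0 < p[1] <= 1.5):
            return 1e30
        return float(np.sum(w * (lnN - model(p)) ** 2))

    t_scale = float(np.median(t))
    best = None
    for b0 in (0.25, 0.5, 1.0):
        res = optimize.minimize(cost, x0=[lnN.max(), b0, math.log(t_scale)],
                                method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12,
                                         "maxiter": 20000, "maxfev": 20000})
        if best is None or res.fun < best.fun:
            best = res
    lnA, beta, ltau = best.x
    return ScalingFit("stretched_exp",
                      {"beta": float(beta), "tau_se": float(math.exp(ltau)),
                       "A": float(math.exp(lnA))},
                      xmin=float(t.min()), xmax=float(t.max()), n=int(pos.sum()),
                      loglik=-float(best.fun))


# ---------------------------------------------------------------------------
# binning, correlation, spectra


def log_bins(w1: float, c: float, t_max: float) -> np.ndarray:
    """Boundaries w_k = w1 * 10^(c (k-1)) up to the first boundary >= t_max."""
    if w1 <= 0 or c <= 0:
        raise ValueError("w1 and c must be positive")
    k = max(1, int(np.ceil(np.log10(t_max / w1) / c - 1e-9)))
    return w1 * 10.0 ** (c * np.arange(k + 1))


def log_binned_density(x: np.ndarray, w1: float | None = None,
                       c: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin-width normalized density on logarithmic bins (for heavy tails)."""
    x = np.asarray(x, dtype=float)
    if w1 is None:
        w1 = float(x.min())
    edges = log_bins(w1, c, float(x.max()) * 1.0000001)
    counts, _ = np.histogram(x, bins=edges)
    widths = np.diff(edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    dens = counts / (widths * x.size)
    return centers, dens


def autocorrelation(series: np.ndarray, max_lag_bins: int | None = None) -> np.ndarray:
    """C(lag) = Cov(x_u, x_{u+lag}) / Var(x); global mean removed, C(0)=1."""
    x = np.asarray(series, dtype=float)
    n = x.size
    if max_lag_bins is None:
        max_lag_bins = n // 4
    if n <= 2 * max_lag_bins:
        raise ValueError("series must be longer than twice the maximum lag")
    x = x - x.mean()
    var = float(np.dot(x, x) / n)
    if var == 0:
        raise ValueError("zero-variance series")
    full = signal.fftconvolve(x, x[::-1], mode="full")[n - 1: n + max_lag_bins]
    return full / (n - np.arange(max_lag_bins + 1)) / var


def power_spectrum(rec: MultichannelRecording, channels: np.ndarray | None = None,
                   alpha_band: tuple[float, float] = (8.0, 13.0),
                   seg_seconds: float = 2.0) -> SpectralSummary:
    """Channel-averaged Welch periodogram and the alpha-band peak frequency."""
    if rec.duration < 2.0:
        raise ValueError("record must be at least 2 s long for 0.5 Hz resolution")
    data = rec.data if channels is None else rec.data[np.asarray(channels)]
    nper = min(int(seg_seconds * rec.fs), rec.n_samples)
    freqs, psd = signal.welch(data, fs=rec.fs, nperseg=nper, axis=-1)
    psd = psd.mean(axis=0)
    band = (freqs >= alpha_band[0]) & (freqs <= alpha_band[1])
    if not band.any():
        raise ValueError("no frequency bins inside the alpha band")
    f_alpha = float(freqs[band][np.argmax(psd[band])])
    return SpectralSummary(freqs, psd, f_alpha, alpha_band)
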