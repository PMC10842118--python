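"""The attenuation-amplification statistic δP(s0, t0).

P(Δs<s0 | Δt<t0) is the probability that two consecutive avalanches closer
than t0 have a size increment below s0 (strict inequalities on both sides).
It is compared against the same probability under size-shuffled surrogates
(quiet times fixed): δP = P − P*, significant where |δP| > 2σ*.  A maximum
of δP at negative s0 marks attenuation (the next avalanche tends to be
smaller), at positive s0 amplification; the t0 that minimizes the summed
|δP| over a band of s0 values is the transition point t0_min, with
transition frequency 1/t0_min.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .avalanches import AvalancheSequence, quiet_times

#: marker for conditional probabilities with an empty conditioning set
UNDEFINED = np.nan

ATTENUATION = "attenuation"
AMPLIFICATION = "amplification"
INDETERMINATE = "indeterminate"


@dataclass
class DeltaPSurface:
    """Grid of P, P*, σ* and δP over (s0, t0); the AAD decision object."""

    s0_grid: np.ndarray
    t0_grid: np.ndarray
    P: np.ndarray  # (n_s0, n_t0), NaN where undefined
    P_star: np.ndarray
    sigma_star: np.ndarray
    n_surrogates: int
    seed: int
    n_pairs: np.ndarray = field(default=None)  # conditioning-set size per t0

    @property
    def deltaP(self) -> np.ndarray:
        return self.P - self.P_star

    @property
    def significant(self) -> np.ndarray:
        """Mask of cells with |δP| > 2σ* (NaN-safe, False where undefined)."""
        with np.errstate(invalid="ignore"):
            return np.abs(self.deltaP) > 2.0 * self.sigma_star

    def to_records(self) -> list[dict]:
        """Long-format rows for the TSV export."""
        rows = []
        dP = self.deltaP
        sig = self.significant
        for i, s0 in enumerate(self.s0_grid):
            for j, t0 in enumerate(self.t0_grid):
                rows.append({
                    "s0": float(s0), "t0": float(t0),
                    "P": float(self.P[i, j]), "P_star": float(self.P_star[i, j]),
                    "sigma_star": float(self.sigma_star[i, j]),
                    "deltaP": float(dP[i, j]), "significant": bool(sig[i, j]),
                })
        return rows


@dataclass
class TransitionResult:
    t0_min: float
    f_t0min: float
    objective: np.ndarray  # mean |δP| per t0 column (NaN where masked)
    regimes: list[str]
    low_contrast: bool = False


def spearman_by_sign(ds: np.ndarray, dt: np.ndarray, n_perm: int = 2000,
                     seed: int = 0) -> dict:
    """Spearman ρ(Δs, Δt) separately on the Δs<0 and Δs>0 subsets.

    Mid-ranks for ties; p-values by permutation.  A sign class with fewer
    than 10 pairs is flagged with ρ = NaN.
    """
    ds = np.asarray(ds, dtype=float)
    dt = np.asarray(dt, dtype=float)
    rng = np.random.default_rng(seed)
    out = {}
    for name, mask in (("neg", ds < 0), ("pos", ds > 0)):
        if mask.sum() < 10:
            out[f"rho_{name}"] = np.nan
            out[f"p_{name}"] = np.nan
            out[f"n_{name}"] = int(mask.sum())
            continue
        a, b = ds[mask], dt[mask]
        rho = stats.spearmanr(a, b).statistic
        cnt = 0
        for _ in range(n_perm):
            r = stats.spearmanr(a, rng.permutation(b)).statistic
            if abs(r) >= abs(rho):
                cnt += 1
        out[f"rho_{name}"] = float(rho)
        out[f"p_{name}"] = (cnt + 1) / (n_perm + 1)
        out[f"n_{name}"] = int(mask.sum())
    return out


def shuffle_sizes(seq: AvalancheSequence, seed: int | np.random.Generator = 0) -> AvalancheSequence:
    """Uniform random permutation of sizes; start/end bins (hence Δt) fixed."""
    if len(seq) < 2:
        raise ValueError("need at least 2 avalanches")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(len(seq))
    return AvalancheSequence(seq.start_bin, seq.end_bin,
                             seq.size_count[perm], seq.size_amp[perm],
                             seq.eps_seconds, seq.boundary)


def conditional_probability(ds: np.ndarray, dt: np.ndarray,
                            s0: float, t0: float) -> float:
    """N(Δs<s0, Δt<t0) / N(Δt<t0); NaN when no Δt < t0 (never silently 0)."""
    ds = np.asarray(ds, dtype=float)
    dt = np.asarray(dt, dtype=float)
    m = dt < t0
    n_cond = int(np.count_nonzero(m))
    if n_cond == 0:
        return UNDEFINED
    return float(np.count_nonzero(ds[m] < s0)) / n_cond


def _probs_grid(ds: np.ndarray, masks: list[np.ndarray],
                s0_grid: np.ndarray) -> np.ndarray:
    """P(Δs<s0 | mask) for every (s0, mask); strict '<' via searchsorted."""
    out = np.full((s0_grid.size, len(masks)), np.nan)
    for j, m in enumerate(masks):
        sel = ds[m]
        if sel.size:
            out[:, j] = np.searchsorted(np.sort(sel), s0_grid, side="left") / sel.size
    return out


def delta_p_surface(seq: AvalancheSequence,
                    s0_grid=None, t0_grid=None,
                    n_surrogates: int = 10_000, seed: int = 0,
                    size_measure: str = "count") -> DeltaPSurface:
    """Observed and surrogate-calibrated conditional probabilities.

    Surrogates permute the size sequence (quiet times fixed) and recompute
    the increments on the same pairs; P* and σ* are the mean and SD of the
    surrogate statistic.  Cells with an empty conditioning set stay NaN.
    """
    from .io_core import DEFAULT_S0_GRID, DEFAULT_T0_GRID
    s0_grid = np.asarray(DEFAULT_S0_GRID if s0_grid is None else s0_grid, dtype=float)
    t0_grid = np.asarray(DEFAULT_T0_GRID if t0_grid is None else t0_grid, dtype=float)
    if len(seq) < 100:
        raise ValueError("need at least 100 avalanches")
    if n_surrogates < 100:
        raise ValueError("need at least 100 surrogates")
    rng = np.random.default_rng(seed)
    s = seq.sizes(size_measure)
    dt = quiet_times(seq)
    pair_ok = ~(seq.boundary[:-1] | seq.boundary[1:])
    masks = [(dt < t0) & pair_ok for t0 in t0_grid]
    n_pairs = np.array([int(m.sum()) for m in masks])

    P = _probs_grid(np.diff(s), masks, s0_grid)
    acc = np.zeros_like(P)
    acc2 = np.zeros_like(P)
    for _ in range(n_surrogates):
        ps = _probs_grid(np.diff(s[rng.permutation(s.size)]), masks, s0_grid)
        acc += np.nan_to_num(ps)
        acc2 += np.nan_to_num(ps) ** 2
    with np.errstate(invalid="ignore"):
        P_star = np.where(np.isnan(P), np.nan, acc / n_surrogates)
        var = acc2 / n_surrogates - (acc / n_surrogates) ** 2
        sigma_star = np.where(np.isnan(P), np.nan, np.sqrt(np.maximum(var, 0.0)))
    return DeltaPSurface(s0_grid, t0_grid, P, P_star, sigma_star,
                         n_surrogates, seed, n_pairs)


def classify_regime(surface: DeltaPSurface, t0: float) -> str:
    """Label one t0 column by the sign of the δP maximum (if significant)."""
    j = int(np.argmin(np.abs(surface.t0_grid - t0)))
    if not np.isclose(surface.t0_grid[j], t0):
        raise ValueError(f"t0={t0} not on the grid")
    col = surface.deltaP[:, j]
    if np.all(np.isnan(col)):
        return INDETERMINATE
    i = int(np.nanargmax(col))
    if not (col[i] > 2.0 * surface.sigma_star[i, j]):
        return INDETERMINATE
    s0 = surface.s0_grid[i]
    if s0 < 0:
        return ATTENUATION
    if s0 > 0:
        return AMPLIFICATION
    return INDETERMINATE


def transition_time(surface: DeltaPSurface,
                    s0_sum_range: tuple[float, float] = (-30.0, 30.0)) -> TransitionResult:
    """t0 minimizing the mean |δP| over s0 in ``s0_sum_range``.

    Masked cells are skipped with renormalization by the defined-cell count
    (mean rather than sum, for comparability across t0 columns); ties break
    toward the smaller t0.
    """
    band = (surface.s0_grid >= s0_sum_range[0]) & (surface.s0_grid <= s0_sum_range[1])
    dP = surface.deltaP[band, :]
    obj = np.full(surface.t0_grid.size, np.nan)
    for j in range(surface.t0_grid.size):
        col = dP[:, j]
        ok = ~np.isnan(col)
        if ok.any():
            obj[j] = float(np.mean(np.abs(col[ok])))
    defined = ~np.isnan(obj)
    if defined.sum() < 3:
        raise ValueError("fewer than 3 defined t0 columns")
    jmin = int(np.nanargmin(obj))  # argmin returns the first (smallest t0) on ties
    t0_min = float(surface.t0_grid[jmin])
    regimes = [classify_regime(surface, t0) for t0 in surface.t0_grid]
    # flat objective (relative to the surrogate noise floor) => low contrast
    sig_floor = np.nanmean(surface.sigma_star)
    spread = np.nanmax(obj) - np.nanmin(obj)
    low_contrast = bool(spread < 2.0 * sig_floor)
    return TransitionResult(t0_min, 1.0 / t0_min, obj, regimes, low_contrast)


def alpha_transition_regression(points: np.ndarray) -> tuple[float, float, float]:
    """OLS of the alpha-peak frequency on the transition frequency.

    ``points`` holds rows (f_alpha_max, f_t0min); returns (A, B, r^2) of
    f_alpha_max = A * f_t0min + B.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (f_alpha_max, f_t0min) points")
    y, x = pts[:, 0], pts[:, 1]
    if np.allclose(x, x[0]):
        raise ValueError("degenerate x variance")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)
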