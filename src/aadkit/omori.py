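"""Omori-sequence analysis: avalanche rate after main avalanches.

Avalanches larger than s* are labelled main avalanches (A*).  The rate
N(t) of subsequent avalanches, measured from each main avalanche's end and
truncated at the next main avalanche, is pooled on logarithmic windows
w_{i+1} = w_i * 10^c.  During resting wakefulness N(t) follows the Omori
law N(t) ∝ (t+c)^-p; during NREM sleep it is a stretched exponential, and
curves for different s* collapse when t is rescaled by s*^0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .avalanches import AvalancheSequence
from .scaling_stats import ScalingFit, compare_powerlaw_exponential, log_bins


@dataclass
class OmoriCurve:
    boundaries: np.ndarray  # window edges, seconds, log-spaced
    N_t: np.ndarray  # rate per second per epoch
    counts: np.ndarray  # pooled raw counts per window
    epoch_counts: np.ndarray  # epochs fully covering each window
    s_star: float
    w1: float
    c: float

    @property
    def t_centers(self) -> np.ndarray:
        return np.sqrt(self.boundaries[:-1] * self.boundaries[1:])


def _epochs(seq: AvalancheSequence, main_idx: np.ndarray,
            truncate_at_next_main: bool = True) -> list[tuple[float, float, np.ndarray]]:
    """(origin, horizon, follower-onset-times) per main avalanche."""
    eps = seq.eps_seconds
    starts = seq.start_bin * eps
    ends = (seq.end_bin + 1) * eps  # end of the last occupied bin
    record_end = float(ends[-1])
    main_idx = np.asarray(main_idx, dtype=np.int64)
    out = []
    for k, i in enumerate(main_idx):
        origin = float(ends[i])
        if truncate_at_next_main and k + 1 < main_idx.size:
            horizon = float(starts[main_idx[k + 1]])
        else:
            horizon = record_end
        if horizon <= origin:
            continue
        j0 = i + 1
        j1 = main_idx[k + 1] if (truncate_at_next_main and k + 1 < main_idx.size) else len(seq)
        t = starts[j0:j1] - origin
        out.append((origin, horizon - origin, t[t > 0]))
    return out


def omori_rate_from_times(times: np.ndarray, w1: float = 0.010, c: float = 0.1,
                          horizon: float | None = None,
                          s_star: float = np.nan) -> OmoriCurve:
    """Rate curve for a single epoch of post-main event times on log windows."""
    t = np.sort(np.asarray(times, dtype=float))
    if t.size == 0:
        raise ValueError("no event times")
    if horizon is None:
        horizon = float(t[-1]) * 1.0000001
    edges = log_bins(w1, c, horizon)
    counts, _ = np.histogram(t, bins=edges)
    cover = (edges[1:] <= horizon).astype(np.int64)
    widths = np.diff(edges)
    with np.errstate(divide="ignore", invalid="ignore"):
        N_t = np.where(cover > 0, counts / widths, np.nan)
    return OmoriCurve(edges, N_t, counts.astype(float), cover, s_star, w1, c)


def omori_rate(seq: AvalancheSequence, main_idx: np.ndarray,
               w1: float = 0.010, c: float = 0.1,
               truncate_at_next_main: bool = True,
               s_star: float = np.nan) -> OmoriCurve:
    """Pooled post-main avalanche rate on logarithmic windows.

    N_t[k] = pooled count / (window duration x number of epochs fully
    covering the window); epochs end at the next main avalanche.
    """
    main_idx = np.asarray(main_idx, dtype=np.int64)
    if main_idx.size < 2:
        raise ValueError("need at least 2 main avalanches")
    epochs = _epochs(seq, main_idx, truncate_at_next_main)
    all_t = np.concatenate([t for _, _, t in epochs]) if epochs else np.zeros(0)
    if all_t.size == 0:
        raise ValueError("no avalanches after any main avalanche")
    horizon = max(dur for _, dur, _ in epochs)
    edges = log_bins(w1, c, horizon)
    counts = np.zeros(edges.size - 1)
    cover = np.zeros(edges.size - 1, dtype=np.int64)
    for _, dur, t in epochs:
        covered = edges[1:] <= dur
        cover += covered
        if t.size:
            h, _ = np.histogram(t[t < dur], bins=edges)
            counts += np.where(covered, h, 0)
    widths = np.diff(edges)
    with np.errstate(divide="ignore", invalid="ignore"):
        N_t = np.where(cover > 0, counts / (widths * np.maximum(cover, 1)), np.nan)
    return OmoriCurve(edges, N_t, counts, cover, s_star, w1, c)


def fit_omori(curve: OmoriCurve, t_range: tuple[float, float] | None = None,
              seq_for_comparison: np.ndarray | None = None) -> ScalingFit:
    """Weighted least squares of ln N on ln t over ``t_range``.

    Weights are the pooled counts.  Returns the decay exponent p with its
    standard error; when waiting times are supplied the power-law vs
    exponential likelihood ratio is attached as a diagnostic.
    """
    t = curve.t_centers
    ok = np.isfinite(curve.N_t) & (curve.N_t > 0)
    if t_range is not None:
        ok &= (t >= t_range[0]) & (t <= t_range[1])
    if ok.sum() < 6:
        raise ValueError("fewer than 6 positive windows in the fit range")
    x = np.log(t[ok])
    y = np.log(curve.N_t[ok])
    w = curve.counts[ok].astype(float)
    W = np.diag(w)
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(np.sqrt(W) @ X, np.sqrt(w) * y, rcond=None)
    resid = y - X @ beta
    dof = max(ok.sum() - 2, 1)
    s2 = float(np.sum(w * resid**2) / w.sum()) * ok.sum() / dof
    cov = s2 * np.linalg.inv(X.T @ W @ X) * w.mean()
    p = -float(beta[1])
    se = float(np.sqrt(cov[1, 1]))
    fit = ScalingFit("powerlaw", {"alpha": p, "se": se, "lnA": float(beta[0])},
                     xmin=float(t[ok].min()), xmax=float(t[ok].max()),
                     n=int(curve.counts[ok].sum()))
    if seq_for_comparison is not None and seq_for_comparison.size >= 10:
        xw = np.asarray(seq_for_comparison, dtype=float)
        fit.R, fit.p_value = compare_powerlaw_exponential(xw, float(xw.min()))
    return fit


def collapse_rescale(curves: list[OmoriCurve], rescale_exponent: float = 0.5
                     ) -> tuple[list[tuple[np.ndarray, np.ndarray]], float]:
    """Rescale each curve's t by s*^exponent and score the collapse.

    The score is the RMS log10 distance of each curve to the pointwise mean
    over the overlapping rescaled range (lower is better).
    """
    if len(curves) < 2:
        raise ValueError("need at least 2 curves")
    rescaled = []
    for cu in curves:
        ok = np.isfinite(cu.N_t) & (cu.N_t > 0)
        t = cu.t_centers[ok] / cu.s_star ** rescale_exponent
        rescaled.append((t, cu.N_t[ok]))
    lo = max(t.min() for t, _ in rescaled)
    hi = min(t.max() for t, _ in rescaled)
    if not (hi > lo):
        raise ValueError("no overlapping range after rescaling")
    grid = np.geomspace(lo, hi, 25)
    logs = np.array([
        np.interp(np.log10(grid), np.log10(t), np.log10(N))
        for t, N in rescaled
    ])
    score = float(np.sqrt(np.mean((logs - logs.mean(axis=0)) ** 2)))
    return rescaled, score


def mean_increment_vs_time(seq: AvalancheSequence, main_idx: np.ndarray,
                           windows: np.ndarray,
                           size_measure: str = "count") -> list[dict]:
    """Mean Δs between consecutive avalanches vs time from the last main.

    Each consecutive pair strictly between two main avalanches contributes
    its Δs to the window containing the pair's elapsed time (onset of the
    pair's first avalanche) since the preceding main avalanche's end.
    Empty windows are reported with n=0.
    """
    main_idx = np.asarray(main_idx, dtype=np.int64)
    if main_idx.size < 2:
        raise ValueError("need at least 2 main avalanches")
    eps = seq.eps_seconds
    starts = seq.start_bin * eps
    ends = (seq.end_bin + 1) * eps
    s = seq.sizes(size_measure)
    edges = np.asarray(windows, dtype=float)
    sums = np.zeros(edges.size - 1)
    sq = np.zeros(edges.size - 1)
    n = np.zeros(edges.size - 1, dtype=np.int64)
    for k in range(main_idx.size - 1):
        i0, i1 = main_idx[k], main_idx[k + 1]
        origin = ends[i0]
        for j in range(i0 + 1, i1 - 1):  # pairs strictly between the mains
            t = starts[j] - origin
            b = np.searchsorted(edges, t, side="right") - 1
            if 0 <= b < n.size:
                d = s[j + 1] - s[j]
                sums[b] += d
                sq[b] += d * d
                n[b] += 1
    out = []
    for b in range(n.size):
        c = float(np.sqrt(edges[b] * edges[b + 1]))
        if n[b] > 1:
            m = sums[b] / n[b]
            sem = float(np.sqrt(max(sq[b] / n[b] - m * m, 0.0) / (n[b] - 1)))
        elif n[b] == 1:
            m, sem = sums[b], np.nan
        else:
            m, sem = np.nan, np.nan
        out.append({"t_center": c, "mean_ds": float(m), "sem": sem, "n": int(n[b])})
    return out
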