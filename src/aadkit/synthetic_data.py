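"""Synthetic point processes and recordings with the statistics the
analysis assumes, so every pipeline stage is testable without recordings.

The generators emulate, at the level of the observed statistics rather
than any biophysical mechanism:

* quiet-time sequences with a double power law crossing over near 100 ms;
* avalanche-size sequences whose increments couple to the preceding quiet
  time — attenuation below a switch time, amplification/persistence above;
* Omori-type decaying rates after large avalanches, power-law and
  stretched-exponential;
* multichannel signals carrying an alpha oscillation under a slow
  stochastic envelope ("waxing and waning") plus 1/f^a background noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .avalanches import AvalancheSequence, from_quiet_times
from .io_core import MultichannelRecording


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# elementary samplers


def gen_truncated_powerlaw(alpha: float, xmin: float, xmax: float, n: int,
                           seed=0) -> np.ndarray:
    """I.i.d. draws from p(x) ∝ x^-alpha on [xmin, xmax] by inverse CDF.

    Handles alpha = 1 (log-uniform) and alpha < 1 (finite xmax only);
    alpha <= 1 with unbounded support is non-normalizable.
    """
    if not (0 < xmin < xmax):
        raise ValueError("need 0 < xmin < xmax")
    if np.isinf(xmax) and alpha <= 1:
        raise ValueError("alpha must exceed 1 for unbounded support")
    u = _rng(seed).random(n)
    if np.isinf(xmax):
        return xmin * (1.0 - u) ** (-1.0 / (alpha - 1.0))
    if abs(alpha - 1.0) < 1e-12:
        return xmin * (xmax / xmin) ** u
    a1 = 1.0 - alpha
    return (xmin**a1 + u * (xmax**a1 - xmin**a1)) ** (1.0 / a1)


def gen_double_powerlaw_quiet_times(mu_lt: float, mu_gt: float, dt_cross: float,
                                    dt_min: float, dt_cut: float, n: int,
                                    seed=0) -> np.ndarray:
    """Quiet times from a piecewise power-law density continuous at the crossover.

    Density ∝ Δt^-mu_lt on [dt_min, dt_cross] and ∝ Δt^-mu_gt on
    [dt_cross, dt_cut]; exact piecewise inverse-CDF sampling.
    """
    if not (0 < dt_min < dt_cross < dt_cut):
        raise ValueError("need 0 < dt_min < dt_cross < dt_cut")
    if mu_lt <= 0 or mu_gt <= 0:
        raise ValueError("exponents must be positive")

    def mass(mu: float, a: float, b: float) -> float:
        if abs(mu - 1.0) < 1e-12:
            return math.log(b / a)
        return (b ** (1 - mu) - a ** (1 - mu)) / (1 - mu)

    m1 = mass(mu_lt, dt_min, dt_cross)
    m2 = dt_cross ** (mu_gt - mu_lt) * mass(mu_gt, dt_cross, dt_cut)
    p1 = m1 / (m1 + m2)
    rng = _rng(seed)
    lo = rng.random(n) < p1
    out = np.empty(n)
    out[lo] = gen_truncated_powerlaw(mu_lt, dt_min, dt_cross, int(lo.sum()), rng)
    out[~lo] = gen_truncated_powerlaw(mu_gt, dt_cross, dt_cut, int((~lo).sum()), rng)
    return out


# ---------------------------------------------------------------------------
# decaying-rate point processes

_MAX_EXPECTED_EVENTS = 10**8


def gen_omori_process(p_exp: float, c_offset: float, K: float, T: float,
                      seed=0) -> np.ndarray:
    """Inhomogeneous Poisson events with rate K (t + c)^-p on (0, T].

    Generated by time rescaling with the exact integrated rate (the
    logarithmic case p = 1 included).
    """
    if p_exp < 0 or c_offset < 0 or T <= 0 or K <= 0:
        raise ValueError("need p_exp >= 0, c_offset >= 0, K > 0, T > 0")
    if p_exp > 0 and c_offset == 0:
        raise ValueError("c_offset must be positive for a singular rate")

    def Lam(t: float) -> float:
        if p_exp == 0:
            return K * t
        if abs(p_exp - 1.0) < 1e-12:
            return K * math.log((t + c_offset) / c_offset)
        return K * ((t + c_offset) ** (1 - p_exp) - c_offset ** (1 - p_exp)) / (1 - p_exp)

    def Lam_inv(y: float) -> float:
        if p_exp == 0:
            return y / K
        if abs(p_exp - 1.0) < 1e-12:
            return c_offset * math.exp(y / K) - c_offset
        base = y * (1 - p_exp) / K + c_offset ** (1 - p_exp)
        if base <= 0:
            return math.inf
        return base ** (1.0 / (1 - p_exp)) - c_offset

    total = Lam(T)
    if total > _MAX_EXPECTED_EVENTS:
        raise ValueError(f"expected event count {total:.3g} exceeds the resource guard")
    rng = _rng(seed)
    n = rng.poisson(total)
    y = np.sort(rng.uniform(0.0, total, size=n))
    return np.array([Lam_inv(v) for v in y])


def gen_stretched_exp_process(beta: float, tau: float, K: float, T: float,
                              seed=0) -> np.ndarray:
    """Inhomogeneous Poisson events with rate K exp(-(t/tau)^beta) on (0, T].

    Generated by thinning against the envelope K = λ(0).
    """
    if not (0 < beta <= 1) or tau <= 0 or K <= 0 or T <= 0:
        raise ValueError("need 0 < beta <= 1, tau > 0, K > 0, T > 0")
    if K * T > _MAX_EXPECTED_EVENTS:
        raise ValueError("expected envelope event count exceeds the resource guard")
    rng = _rng(seed)
    n_env = rng.poisson(K * T)
    t = np.sort(rng.uniform(0.0, T, size=n_env))
    accept = rng.random(n_env) < np.exp(-((t / tau) ** beta))
    return t[accept]


# ---------------------------------------------------------------------------
# the AAD avalanche-sequence generator


@dataclass
class AADGenParams:
    """Ground-truth parameters of the synthetic AAD avalanche sequence.

    Quiet times follow the double power law (``mu_lt`` below, ``mu_gt``
    above a crossover near 100 ms).  Sizes follow a coupling switched by
    the quiet time at ``t_switch``: pairs with Δt < t_switch undergo, with
    probability ``q_collapse`` and only when the source avalanche is large
    (s ≥ s_big), a multiplicative collapse ln s → ln s + drift_neg
    (attenuation); otherwise the size refreshes independently of its
    predecessor.  Pairs with Δt ≥ t_switch are persistent:
    ln s_{i+1} = ln s_i + drift_pos + Normal(0, noise_sd) (amplification).
    Sizes live in [s_floor, s_ceil] (clipped) and are rounded to integers.
    """

    mu_lt: float = 0.79
    mu_gt: float = 1.97
    dt_cross: float = 0.1
    dt_min: float = 0.01
    dt_cut: float = 1.0
    t_switch: float = 0.1
    drift_neg: float = -1.1
    drift_pos: float = 0.12
    noise_sd: float = 0.10
    q_collapse: float = 0.30
    s_big: float = 70.0
    collapse_jitter: float = 0.15
    s_floor: float = 10.0
    s_ceil: float = 800.0
    n_avalanches: int = 5000
    seed: int = 0
    eps_seconds: float = 0.001
    n_pass: int = 3

    def __post_init__(self) -> None:
        if not (self.dt_min < self.dt_cross < self.dt_cut):
            raise ValueError("need dt_min < dt_cross < dt_cut")
        if not (self.drift_neg < 0 < self.drift_pos):
            raise ValueError("need drift_neg < 0 < drift_pos")
        if self.mu_lt <= 0 or self.mu_gt <= 0:
            raise ValueError("quiet-time exponents must be positive")
        if not (1 <= self.s_floor < self.s_ceil):
            raise ValueError("need 1 <= s_floor < s_ceil")
        if not (0 <= self.q_collapse <= 1):
            raise ValueError("q_collapse must be a probability")
        if self.n_avalanches < 10:
            raise ValueError("need at least 10 avalanches")


def _aad_sizes(rng: np.random.Generator, dt: np.ndarray, p: AADGenParams,
               refresh_pool: np.ndarray | None) -> np.ndarray:
    """One pass of the coupled log-size sequence; refresh from the pool."""
    n = dt.size + 1
    lf, lc = math.log(p.s_floor), math.log(p.s_ceil)
    lb = math.log(p.s_big)
    U = rng.random(n - 1)
    eta = rng.standard_normal(n - 1)
    if refresh_pool is None:
        def refresh() -> float:
            return lf + rng.random() * (lc - lf)
    else:
        def refresh() -> float:
            return float(refresh_pool[rng.integers(0, refresh_pool.size)])
    ls = np.empty(n)
    ls[0] = refresh()
    for i in range(n - 1):
        if dt[i] < p.t_switch:
            if U[i] < p.q_collapse and ls[i] >= lb:
                x = ls[i] + p.drift_neg + p.collapse_jitter * eta[i]
            else:
                x = refresh()
            ls[i + 1] = min(max(x, lf), lc)
            continue
        x = ls[i] + p.drift_pos + p.noise_sd * eta[i]
        ls[i + 1] = min(max(x, lf), lc)
    return ls


def gen_aad_avalanche_sequence(p: AADGenParams | None = None, **kw) -> AvalancheSequence:
    """Avalanche sequence with an attenuation-amplification transition.

    Quiet times come from the double power law; sizes from the switched
    collapse/refresh/persistence coupling (see :class:`AADGenParams`).
    Refresh draws are made consistent with the realized size marginal by
    iterating the construction ``n_pass`` times, bootstrap-resampling the
    previous pass's sizes; this keeps refreshed pairs statistically
    indistinguishable from size-shuffled surrogate pairs.  Durations are
    one bin — they are not under test here.
    """
    if p is None:
        p = AADGenParams(**kw)
    elif kw:
        raise TypeError("pass either AADGenParams or keyword overrides, not both")
    rng = _rng(p.seed)
    dt = gen_double_powerlaw_quiet_times(p.mu_lt, p.mu_gt, p.dt_cross,
                                         p.dt_min, p.dt_cut,
                                         p.n_avalanches - 1, rng)
    pool = None
    for _ in range(max(1, p.n_pass)):
        ls = _aad_sizes(rng, dt, p, pool)
        pool = ls.copy()
    sizes = np.maximum(np.rint(np.exp(ls)), 1.0)
    return from_quiet_times(dt, sizes, p.eps_seconds)


# ---------------------------------------------------------------------------
# null model


def gen_poisson_cascades(rate: float, size_exponent: float, smin: float,
                         smax: float, n: int, seed=0) -> AvalancheSequence:
    """Memoryless null: exponential i.i.d. quiet times, sizes independent of times."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    if size_exponent <= 0 or not np.isfinite(smax):
        raise ValueError("need a positive exponent and finite size bounds")
    rng = _rng(seed)
    dt = rng.exponential(1.0 / rate, size=n - 1)
    sizes = np.rint(gen_truncated_powerlaw(size_exponent, smin, smax, n, rng))
    return from_quiet_times(dt, np.maximum(sizes, 1.0), eps_seconds=0.001)


# ---------------------------------------------------------------------------
# alpha-modulated multichannel recording


@dataclass
class SignalGenParams:
    """Alpha oscillation under a slow mean-reverting envelope plus 1/f^a noise."""

    n_channels: int = 16
    fs: float = 600.0
    duration: float = 60.0
    f_alpha: float = 10.0
    envelope_tau: float = 2.0
    envelope_sd: float = 0.8
    envelope_mean: float = 0.3
    noise_exponent: float = 0.5
    noise_sd: float = 1.0
    event_gain: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.f_alpha < self.fs / 2):
            raise ValueError("f_alpha must lie below Nyquist")
        if self.duration * self.fs < 2**12:
            raise ValueError("need at least 2^12 samples")


def _one_over_f_noise(rng: np.random.Generator, n: int, fs: float,
                      exponent: float, sd: float) -> np.ndarray:
    freqs = np.fft.rfftfreq(n, 1 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    phases = rng.uniform(0, 2 * np.pi, size=freqs.size)
    spec = amp * np.exp(1j * phases)
    x = np.fft.irfft(spec, n=n)
    s = x.std()
    return x / s * sd if s > 0 else x


def gen_alpha_modulated_recording(p: SignalGenParams | None = None,
                                  **kw) -> MultichannelRecording:
    """Channels = 1/f^a background + A(t) sin(2π f_alpha t + φ_ch).

    A(t) ≥ 0 is a slow mean-reverting (Ornstein-Uhlenbeck, clipped at 0)
    envelope shared across channels up to channel gains, producing the
    waxing and waning of alpha amplitude; threshold-crossing event rates
    track the envelope.
    """
    if p is None:
        p = SignalGenParams(**kw)
    elif kw:
        raise TypeError("pass either SignalGenParams or keyword overrides, not both")
    rng = _rng(p.seed)
    n = int(round(p.duration * p.fs))
    t = np.arange(n) / p.fs
    # OU envelope: dA = -(A - mean)/tau dt + sd sqrt(2 dt / tau) dW, clipped at 0
    a = np.empty(n)
    a[0] = p.envelope_mean
    dtau = 1.0 / (p.fs * p.envelope_tau)
    kick = p.envelope_sd * math.sqrt(2.0 * dtau)
    dw = rng.standard_normal(n - 1)
    for i in range(n - 1):
        a[i + 1] = max(a[i] - (a[i] - p.envelope_mean) * dtau + kick * dw[i], 0.0)
    data = np.empty((p.n_channels, n))
    for ch in range(p.n_channels):
        phase = rng.uniform(0, 2 * np.pi)
        gain = 1.0 + 0.2 * rng.standard_normal()
        osc = p.event_gain * abs(gain) * a * np.sin(2 * np.pi * p.f_alpha * t + phase)
        noise = _one_over_f_noise(rng, n, p.fs, p.noise_exponent, p.noise_sd) \
            if p.noise_sd > 0 else 0.0
        data[ch] = osc + noise
    return MultichannelRecording(data, p.fs, [f"syn{i}" for i in range(p.n_channels)])
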