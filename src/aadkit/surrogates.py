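"""Phase-randomization surrogates for continuous recordings.

The Fourier phases of each channel are replaced by i.i.d. uniform draws
while the amplitude spectrum is preserved, destroying phase synchronization
across channels (and any nonlinear temporal structure) but keeping the
linear properties — power spectral density and two-point correlations — of
the original signals.
"""

from __future__ import annotations

import numpy as np

from .io_core import MultichannelRecording


def phase_randomize(rec: MultichannelRecording, seed: int = 0,
                    shared_phases: bool = False) -> MultichannelRecording:
    """Randomize Fourier phases per channel (independent across channels).

    The DC and (for even lengths) Nyquist components are left untouched so
    the inverse transform is real to rounding error.  With
    ``shared_phases`` one phase draw is applied to every channel,
    preserving cross-spectra — a robustness variant, not the default null.
    """
    n = rec.n_samples
    if n < 16:
        raise ValueError("need at least 16 samples")
    rng = np.random.default_rng(seed)
    spec = np.fft.rfft(rec.data, axis=1)
    n_freq = spec.shape[1]
    hi = n_freq - 1 if n % 2 == 0 else n_freq  # interior (rotatable) bins end here
    shape = (1, hi - 1) if shared_phases else (rec.n_channels, hi - 1)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=shape)
    new_spec = spec.copy()
    new_spec[:, 1:hi] = np.abs(spec[:, 1:hi]) * np.exp(1j * phases)
    out = np.fft.irfft(new_spec, n=n, axis=1)
    return MultichannelRecording(out, rec.fs, rec.channel_ids, rec.units)
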