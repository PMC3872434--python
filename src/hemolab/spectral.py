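"""FFT separation of a measured-style trace into cardiac and respiratory parts.

The breath and the heart beat live at different frequencies (4 beats per
breath by default), so a record covering whole breaths has every component
on an exact DFT bin: the DC bin is the mean, bins at multiples of the heart
fundamental are cardiac, the remaining multiples of the breath fundamental
are respiratory, and everything else is residual (noise).  Inverse
transforms of the disjoint bin sets reconstruct the input exactly, which is
what makes the "with respiration" / "without respiration" boundary-condition
pair internally consistent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .waveforms import Waveform, WaveformError

__all__ = [
    "SpectralDecomposition",
    "estimate_frequencies",
    "separate_components",
    "cardiac_only_waveform",
]


class SpectralError(ValueError):
    """Trace unsuitable for cardiac/respiratory separation."""


@dataclass
class SpectralDecomposition:
    """A trace split into mean + cardiac + respiratory + residual.

    The three component waveforms share the (possibly truncated) time grid
    of the analysed record and each has zero time-mean; their sum plus
    ``mean_level`` reconstructs the input on that grid.
    """

    mean_level: float
    cardiac: Waveform
    respiratory: Waveform
    residual: Waveform
    f_heart: float
    f_breath: float
    beats_per_breath: int
    truncated_to: float | None = None  # seconds actually analysed, if shortened

    def reconstruct(self) -> np.ndarray:
        return (
            self.mean_level
            + self.cardiac.v
            + self.respiratory.v
            + self.residual.v
        )

    def power_balance(self) -> dict:
        """Parseval bookkeeping: mean-square power of input vs parts."""
        total = float(np.mean(self.reconstruct() ** 2))
        return {
            "total": total,
            "mean": self.mean_level**2,
            "cardiac": float(np.mean(self.cardiac.v**2)),
            "respiratory": float(np.mean(self.respiratory.v**2)),
            "residual": float(np.mean(self.residual.v**2)),
        }


def estimate_frequencies(w: Waveform, beats_per_breath: int = 4) -> tuple[float, float]:
    """Locate the breath and heart fundamentals of a periodic trace.

    The dominant non-DC spectral peak is taken as the cardiac fundamental
    candidate; the largest peak strictly below it (the low band) gives the
    respiratory fundamental.  The rigid beats-per-breath ratio is then
    enforced exactly: ``f_heart = beats_per_breath * f_breath``.  Returns
    ``(f_breath, f_heart)`` in Hz.
    """
    n = w.t.size
    spec = np.abs(np.fft.rfft(w.v))
    T = w.duration
    if n < 4 or spec[1:].max() <= 1e-12 * max(spec[0], n * 1e-300) or spec[1:].max() == 0.0:
        raise SpectralError("no detectable periodicity (flat spectrum)")
    k_dom = int(np.argmax(spec[1:]) + 1)
    # low band: everything strictly below the dominant peak (excluding its skirt)
    low = spec[1:k_dom].copy()
    k_breath = None
    if low.size:
        k_low = int(np.argmax(low) + 1)
        if low[k_low - 1] > 1e-9 * spec[k_dom]:
            k_breath = k_low
    if k_breath is None:
        # cardiac-only record: the breath is the (possibly sub-bin) subharmonic
        f_heart = k_dom / T
        return f_heart / beats_per_breath, f_heart
    if k_breath < 2:
        raise SpectralError(
            "record must span at least two breath periods for separation"
        )
    return k_breath / T, beats_per_breath * k_breath / T


def _bin_sets(n: int, T: float, f_heart: float, f_breath: float,
              beats_per_breath: int, half_bandwidth: float | None,
              sidebands: str) -> dict:
    """Partition rfft bins {0..n//2} into mean/cardiac/respiratory/residual."""
    k_b = int(round(f_breath * T))
    k_h = int(round(f_heart * T))
    if k_b < 1 or k_h != beats_per_breath * k_b:
        raise SpectralError(
            f"f_heart must be exactly {beats_per_breath}x f_breath on the DFT grid "
            f"(got bins {k_h} vs {beats_per_breath}*{k_b})"
        )
    hb = 0 if half_bandwidth is None else int(round(half_bandwidth * T))
    nbins = n // 2 + 1
    k = np.arange(nbins)
    cardiac = np.zeros(nbins, bool)
    resp = np.zeros(nbins, bool)
    # cardiac: within hb bins of a positive multiple of the heart fundamental
    kk = k.copy()
    kk[0] = 1  # keep DC out
    near_heart = np.abs(((kk + k_h // 2) % k_h) - k_h // 2) <= hb
    cardiac = near_heart & (k >= k_h - hb) & (k > 0)
    # respiratory: multiples of the breath fundamental that are not cardiac
    near_breath = np.abs(((kk + k_b // 2) % k_b) - k_b // 2) <= hb
    resp = near_breath & (k > 0) & ~cardiac
    if sidebands == "cardiac":
        # reassign modulation sidebands k*f_heart +/- j*f_breath to the
        # cardiac set; only bins closer to a cardiac harmonic than to the
        # midpoint of the spacing qualify, so low breath harmonics (the
        # respiratory fundamental among them) are never captured
        for j in range(1, (beats_per_breath - 1) // 2 + 1):
            for sign in (+1, -1):
                idx = np.arange(k_h, nbins, k_h) + sign * j * k_b
                idx = idx[(idx > 0) & (idx < nbins)]
                cardiac[idx] = True
                resp[idx] = False
    elif sidebands != "respiratory":
        raise SpectralError("sidebands must be 'respiratory' or 'cardiac'")
    residual = ~cardiac & ~resp & (k > 0)
    return {"cardiac": cardiac, "respiratory": resp, "residual": residual,
            "k_b": k_b, "k_h": k_h}


def separate_components(
    w: Waveform,
    f_heart: float | None = None,
    f_breath: float | None = None,
    half_bandwidth: float | None = None,
    beats_per_breath: int = 4,
    sidebands: str = "respiratory",
) -> SpectralDecomposition:
    """Split a trace into mean + cardiac + respiratory + residual by DFT bins.

    If the record is not an integer number of breath periods it is first
    truncated to the largest whole multiple (reported via ``truncated_to``).
    By default the modulation sidebands (k*f_heart +/- j*f_breath) go to the
    respiratory component, since they vanish when respiration is absent;
    ``sidebands='cardiac'`` reassigns them.
    """
    if f_breath is None or f_heart is None:
        f_breath, f_heart = estimate_frequencies(w, beats_per_breath)
    breath_period = 1.0 / f_breath
    n_breaths = int(np.floor(w.duration / breath_period + 1e-9))
    if n_breaths < 1:
        raise SpectralError("record shorter than one breath period")
    truncated_to = None
    n_keep = int(round(n_breaths * breath_period * w.sampling_rate))
    if n_keep < w.t.size:
        truncated_to = n_keep / w.sampling_rate
    t = w.t[:n_keep]
    v = w.v[:n_keep]
    n = n_keep
    T = n / w.sampling_rate
    sets = _bin_sets(n, T, f_heart, f_breath, beats_per_breath,
                     half_bandwidth, sidebands)
    F = np.fft.rfft(v)
    mean_level = float(F[0].real / n)

    def _inv(mask: np.ndarray) -> np.ndarray:
        G = np.where(mask, F, 0.0)
        return np.fft.irfft(G, n=n)

    mk = lambda vals: Waveform(w.port, t.copy(), vals, w.units)
    return SpectralDecomposition(
        mean_level=mean_level,
        cardiac=mk(_inv(sets["cardiac"])),
        respiratory=mk(_inv(sets["respiratory"])),
        residual=mk(_inv(sets["residual"])),
        f_heart=sets["k_h"] / T,
        f_breath=sets["k_b"] / T,
        beats_per_breath=beats_per_breath,
        truncated_to=truncated_to,
    )


def cardiac_only_waveform(d: SpectralDecomposition, method: str = "fold") -> Waveform:
    """One-beat cardiac boundary condition from a decomposition.

    ``method='fold'`` averages the beats of (mean + cardiac + residual) —
    respiration removed, residual noise averaged down.  ``method='harmonic'``
    resynthesises mean + cardiac only and takes its first beat (the cardiac
    harmonics are beat-periodic, so any beat is identical).
    """
    heart_period = 1.0 / d.f_heart
    fs = d.cardiac.sampling_rate
    n = d.cardiac.t.size
    n_beat = int(round(heart_period * fs))
    if n_beat < 2 or n % n_beat != 0:
        raise SpectralError(
            "record length is not an integer number of heart beats at this "
            "sampling rate; cannot fold"
        )
    if method == "fold":
        signal = d.mean_level + d.cardiac.v + d.residual.v
        beat = signal.reshape(n // n_beat, n_beat).mean(axis=0)
    elif method == "harmonic":
        beat = d.mean_level + d.cardiac.v[:n_beat]
    else:
        raise SpectralError("method must be 'fold' or 'harmonic'")
    t = np.arange(n_beat) / fs
    return Waveform(d.cardiac.port, t, beat, d.cardiac.units)
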