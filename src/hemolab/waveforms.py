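"""Synthetic venous-velocity and pulmonary-pressure boundary waveforms.

Generates physiologically structured periodic traces for the venous inlets
(IVC, LIV, RIV and the merged SVC) and the pulmonary-artery outlets (LPA,
RPA) of a cavopulmonary junction.  Each trace is a beat-periodic cardiac
signal carried on a slower respiratory envelope; by construction one breath
spans an integer number of heart beats (four by default), so records that
cover whole breaths are exactly periodic and every tone sits on a DFT bin.

The generating model for a velocity (or pressure) trace is

    v(t) = [m0 + sum_k a_k sin(2 pi k t / T_h + phi_k)]
           * [1 + m sin(2 pi t / T_b + psi)]  + noise        (multiplicative)

or, optionally,

    v(t) = m0 + sum_k a_k sin(2 pi k t / T_h + phi_k)
           + m0 * m sin(2 pi t / T_b + psi)  + noise          (additive)

with heart period T_h, breath period T_b = beats_per_breath * T_h,
respiratory modulation depth m in [0, 1) and seeded Gaussian noise
(disabled by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "PORTS",
    "VELOCITY_PORTS",
    "PRESSURE_PORTS",
    "CycleStructure",
    "WaveformSpec",
    "Waveform",
    "generate_inlet_waveform",
    "generate_outlet_pressure",
    "generate_components",
    "write_waveform",
    "read_waveform",
    "sample_periodic",
]

#: Named measurement/boundary ports of the junction.
PORTS = ("IVC", "LIV", "RIV", "SVC", "LPA", "RPA")
#: Ports carrying velocity traces (m/s): systemic venous inflows.
VELOCITY_PORTS = ("IVC", "LIV", "RIV", "SVC")
#: Ports carrying pressure traces (Pa): pulmonary-artery outflows.
PRESSURE_PORTS = ("LPA", "RPA")


class WaveformError(ValueError):
    """Invalid waveform specification, sampling or file content."""


@dataclass(frozen=True)
class CycleStructure:
    """Cardiac/respiratory timing: one breath spans ``beats_per_breath`` beats.

    Parameters
    ----------
    heart_period : float
        Duration of one heart beat, seconds.
    beats_per_breath : int
        Number of heart beats per respiratory cycle (default 4).
    """

    heart_period: float = 0.6
    beats_per_breath: int = 4

    def __post_init__(self) -> None:
        if self.heart_period <= 0:
            raise WaveformError("heart_period must be positive")
        if int(self.beats_per_breath) != self.beats_per_breath or self.beats_per_breath < 1:
            raise WaveformError("beats_per_breath must be a positive integer")

    @property
    def breath_period(self) -> float:
        """Respiratory period, seconds (exactly beats_per_breath * heart_period)."""
        return self.beats_per_breath * self.heart_period

    @property
    def f_heart(self) -> float:
        return 1.0 / self.heart_period

    @property
    def f_breath(self) -> float:
        return 1.0 / self.breath_period


@dataclass(frozen=True)
class WaveformSpec:
    """Parametric description of one port's boundary trace.

    ``cardiac_harmonics`` is a sequence of (harmonic index k, amplitude,
    phase) triples relative to the heart fundamental.  ``resp_mod_depth``
    is the dimensionless respiratory modulation depth m < 1.
    """

    port: str
    mean_level: float
    cardiac_harmonics: tuple = ()
    resp_mod_depth: float = 0.0
    resp_phase: float = 0.0
    additive_noise_sd: float = 0.0
    allow_reversal: bool = False
    resp_mode: str = "multiplicative"  # or "additive"

    def __post_init__(self) -> None:
        if self.port not in PORTS:
            raise WaveformError(f"unknown port {self.port!r}; expected one of {PORTS}")
        if not (0.0 <= self.resp_mod_depth < 1.0):
            raise WaveformError("resp_mod_depth must lie in [0, 1)")
        if self.resp_mode not in ("multiplicative", "additive"):
            raise WaveformError("resp_mode must be 'multiplicative' or 'additive'")
        for k, a, phi in self.cardiac_harmonics:
            if int(k) != k or k < 1:
                raise WaveformError("harmonic indices must be positive integers")
            if not np.isfinite(a) or not np.isfinite(phi):
                raise WaveformError("harmonic amplitude/phase must be finite")
        if self.additive_noise_sd < 0:
            raise WaveformError("additive_noise_sd must be >= 0")

    @property
    def units(self) -> str:
        return "m/s" if self.port in VELOCITY_PORTS else "Pa"

    @property
    def amplitude_sum(self) -> float:
        return float(sum(abs(a) for _, a, _ in self.cardiac_harmonics))


@dataclass
class Waveform:
    """A uniformly sampled periodic trace at a named port."""

    port: str
    t: np.ndarray
    v: np.ndarray
    units: str

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.v.shape:
            raise WaveformError("t and v must be 1-D arrays of equal length")
        if self.t.size < 2:
            raise WaveformError("waveform needs at least two samples")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise WaveformError("time column must be strictly increasing")
        if np.max(np.abs(dt - dt[0])) > 1e-9:
            raise WaveformError("time column must be uniformly sampled (tol 1e-9 s)")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def sampling_rate(self) -> float:
        return 1.0 / self.dt

    @property
    def duration(self) -> float:
        """Record length including the implied final interval (periodic span)."""
        return float(self.t.size * self.dt)

    def copy_with(self, **kw) -> "Waveform":
        out = Waveform(self.port, self.t.copy(), self.v.copy(), self.units)
        for k, val in kw.items():
            setattr(out, k, val)
        return out


def _time_grid(cycles: CycleStructure, n_breaths: int, sampling_rate: float) -> np.ndarray:
    total = n_breaths * cycles.breath_period
    n = int(round(total * sampling_rate))
    if abs(n - total * sampling_rate) > 1e-9:
        raise WaveformError(
            "sampling_rate must resolve an integer number of samples per breath"
        )
    return np.arange(n) / sampling_rate


def _check_nyquist(spec: WaveformSpec, cycles: CycleStructure, sampling_rate: float,
                   min_harmonics: int = 8) -> None:
    k_max = max([k for k, _, _ in spec.cardiac_harmonics] + [min_harmonics])
    f_required = 2.0 * k_max * cycles.f_heart
    if sampling_rate < f_required:
        raise WaveformError(
            f"sampling rate {sampling_rate:g} Hz violates the Nyquist bound "
            f"{f_required:g} Hz needed to resolve {k_max} cardiac harmonics "
            f"at f_heart={cycles.f_heart:g} Hz"
        )


def generate_components(
    spec: WaveformSpec,
    cycles: CycleStructure,
    n_breaths: int = 2,
    sampling_rate: float = 1000.0,
) -> dict:
    """Noise-free ground-truth parts of the generated trace.

    Returns ``{"t", "mean", "cardiac", "respiratory"}`` such that
    mean + cardiac + respiratory equals the noise-free signal exactly.
    The respiratory part is everything that vanishes when m = 0 (for the
    multiplicative mode this includes the modulation sidebands).
    """
    if n_breaths < 1:
        raise WaveformError("n_breaths must be >= 1")
    _check_nyquist(spec, cycles, sampling_rate)
    t = _time_grid(cycles, n_breaths, sampling_rate)
    cardiac = np.zeros_like(t)
    for k, a, phi in spec.cardiac_harmonics:
        cardiac += a * np.sin(2.0 * np.pi * k * t / cycles.heart_period + phi)
    env = spec.resp_mod_depth * np.sin(
        2.0 * np.pi * t / cycles.breath_period + spec.resp_phase
    )
    if spec.resp_mode == "multiplicative":
        respiratory = (spec.mean_level + cardiac) * env
    else:
        respiratory = spec.mean_level * env
    return {
        "t": t,
        "mean": np.full_like(t, spec.mean_level),
        "cardiac": cardiac,
        "respiratory": respiratory,
    }


def _generate(spec, cycles, n_breaths, seed, sampling_rate) -> Waveform:
    parts = generate_components(spec, cycles, n_breaths, sampling_rate)
    v = parts["mean"] + parts["cardiac"] + parts["respiratory"]
    if not spec.allow_reversal and spec.port in VELOCITY_PORTS:
        if spec.amplitude_sum >= abs(spec.mean_level):
            raise WaveformError(
                "cardiac amplitude sum >= |mean_level|: trace may reverse; "
                "set allow_reversal=True if venous flow reversal is intended"
            )
    if spec.additive_noise_sd > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, spec.additive_noise_sd, size=v.size)
    return Waveform(spec.port, parts["t"], v, spec.units)


def generate_inlet_waveform(
    spec: WaveformSpec,
    cycles: CycleStructure,
    n_breaths: int = 2,
    seed: int = 0,
    sampling_rate: float = 1000.0,
) -> Waveform:
    """Synthesize a venous inlet velocity trace (m/s) over whole breaths."""
    if spec.port not in VELOCITY_PORTS:
        raise WaveformError(f"{spec.port} is not a velocity port")
    return _generate(spec, cycles, n_breaths, seed, sampling_rate)


def generate_outlet_pressure(
    spec: WaveformSpec,
    cycles: CycleStructure,
    n_breaths: int = 2,
    seed: int = 0,
    sampling_rate: float = 1000.0,
) -> Waveform:
    """Synthesize a pulmonary-artery outlet pressure trace (Pa)."""
    if spec.port not in PRESSURE_PORTS:
        raise WaveformError(f"{spec.port} is not a pressure port")
    return _generate(spec, cycles, n_breaths, seed, sampling_rate)


# ---------------------------------------------------------------------------
# ASCII trace-file I/O: two columns (time_s, value) with a one-line header
# `# port=IVC units=m/s rate=1000`.
# ---------------------------------------------------------------------------

def write_waveform(path, w: Waveform) -> None:
    path = Path(path)
    header = f"port={w.port} units={w.units} rate={w.sampling_rate:.12g}"
    np.savetxt(path, np.column_stack([w.t, w.v]), fmt="%.17g", header=header)


def read_waveform(path, expected_units: str | None = None) -> Waveform:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if not first.startswith("#"):
        raise WaveformError(f"{path}: missing header line")
    meta = dict(
        item.split("=", 1) for item in first.lstrip("#").split() if "=" in item
    )
    for key in ("port", "units"):
        if key not in meta:
            raise WaveformError(f"{path}: header lacks '{key}='")
    data = np.loadtxt(path, ndmin=2)
    if data.size == 0:
        raise WaveformError(f"{path}: empty trace file")
    if data.shape[1] != 2:
        raise WaveformError(f"{path}: expected two columns (time, value)")
    if expected_units is not None and meta["units"] != expected_units:
        raise WaveformError(
            f"{path}: units {meta['units']!r} do not match expected {expected_units!r}"
        )
    return Waveform(meta["port"], data[:, 0], data[:, 1], meta["units"])


def sample_periodic(w: Waveform, t) -> np.ndarray:
    """Evaluate the trace at arbitrary times by periodic extension.

    The record is treated as one full period of length ``w.duration``
    (sample i at t_i = t0 + i*dt, wrapping after the last sample).
    Linear interpolation between samples.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    period = w.duration
    tau = np.mod(t - w.t[0], period)
    tp = np.concatenate([w.t - w.t[0], [period]])
    vp = np.concatenate([w.v, [w.v[0]]])
    out = np.interp(tau, tp, vp)
    return out if out.size > 1 else out
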