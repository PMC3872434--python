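"""Generator contracts: periodicity, spectral support, mean, I/O round-trip."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hemolab.waveforms import (CycleStructure, Waveform, WaveformError,
                               WaveformSpec, generate_components,
                               generate_inlet_waveform,
                               generate_outlet_pressure, read_waveform,
                               sample_periodic, write_waveform)


def test_constant_spec_gives_constant_trace(cycles):
    spec = WaveformSpec(port="IVC", mean_level=0.3)
    w = generate_inlet_waveform(spec, cycles, n_breaths=1, seed=0)
    assert np.allclose(w.v, 0.3, atol=0)
    assert w.units == "m/s"


def test_exact_breath_periodicity_without_noise(cycles, ivc_spec):
    w = generate_inlet_waveform(ivc_spec, cycles, n_breaths=3, seed=0)
    n_b = int(round(cycles.breath_period * w.sampling_rate))
    assert np.max(np.abs(w.v[n_b:] - w.v[:-n_b])) < 1e-12


def test_time_average_equals_mean_level(cycles, ivc_spec):
    w = generate_inlet_waveform(ivc_spec, cycles, n_breaths=2, seed=0)
    assert abs(w.v.mean() - ivc_spec.mean_level) < 1e-10


def test_spectral_support_of_modulated_tone(cycles):
    """Energy lives only on {0, f_b, f_h, f_h +/- f_b} bins (brute-force DFT)."""
    spec = WaveformSpec(port="IVC", mean_level=0.3,
                        cardiac_harmonics=((1, 0.1, 0.0),),
                        resp_mod_depth=0.25)
    w = generate_inlet_waveform(spec, cycles, n_breaths=2, seed=0)
    n = w.v.size
    # brute-force DFT (explicit sum, independent of fft implementation)
    k = np.arange(n // 2 + 1)
    ph = -2j * np.pi * np.outer(k, np.arange(n)) / n
    F = (np.exp(ph[:200]) @ w.v)  # low bins suffice: tones sit below bin 200
    T = w.duration
    k_b = int(round(T / cycles.breath_period))
    k_h = cycles.beats_per_breath * k_b
    allowed = {0, k_b, k_h, k_h - k_b, k_h + k_b}
    power = np.abs(F) ** 2
    outside = sum(p for i, p in enumerate(power) if i not in allowed)
    assert outside < 1e-10 * power.sum()


def test_determinism_and_noise_seeding(cycles):
    spec = WaveformSpec(port="LPA", mean_level=1200.0, additive_noise_sd=10.0)
    w1 = generate_outlet_pressure(spec, cycles, n_breaths=1, seed=7)
    w2 = generate_outlet_pressure(spec, cycles, n_breaths=1, seed=7)
    w3 = generate_outlet_pressure(spec, cycles, n_breaths=1, seed=8)
    assert np.array_equal(w1.v, w2.v)
    assert not np.array_equal(w1.v, w3.v)


def test_outlet_pressure_envelope_minimum(cycles):
    """Min over a breath matches the brute-force closed-form minimum."""
    spec = WaveformSpec(port="RPA", mean_level=1000.0, resp_mod_depth=0.1)
    w = generate_outlet_pressure(spec, cycles, n_breaths=1, seed=0)
    t = np.linspace(0, cycles.breath_period, 200001)
    exact = 1000.0 * (1 + 0.1 * np.sin(2 * np.pi * t / cycles.breath_period))
    assert w.v.min() == pytest.approx(exact.min(), rel=1e-6)


def test_nyquist_violation_raises(cycles):
    spec = WaveformSpec(port="IVC", mean_level=0.3,
                        cardiac_harmonics=((12, 0.01, 0.0),))
    with pytest.raises(WaveformError, match="Nyquist"):
        generate_inlet_waveform(spec, cycles, n_breaths=1, seed=0,
                                sampling_rate=20.0)


def test_reversal_guard(cycles):
    spec = WaveformSpec(port="IVC", mean_level=0.1,
                        cardiac_harmonics=((1, 0.2, 0.0),))
    with pytest.raises(WaveformError, match="reversal"):
        generate_inlet_waveform(spec, cycles, n_breaths=1, seed=0)
    ok = WaveformSpec(port="IVC", mean_level=0.1,
                      cardiac_harmonics=((1, 0.2, 0.0),), allow_reversal=True)
    w = generate_inlet_waveform(ok, cycles, n_breaths=1, seed=0)
    assert w.v.min() < 0


def test_components_sum_to_signal(cycles, ivc_spec):
    parts = generate_components(ivc_spec, cycles, n_breaths=2)
    w = generate_inlet_waveform(ivc_spec, cycles, n_breaths=2, seed=0)
    recon = parts["mean"] + parts["cardiac"] + parts["respiratory"]
    assert np.max(np.abs(recon - w.v)) < 1e-14


def test_roundtrip_io(tmp_path, cycles, ivc_spec):
    w = generate_inlet_waveform(ivc_spec, cycles, n_breaths=2, seed=3)
    path = tmp_path / "ivc.txt"
    write_waveform(path, w)
    back = read_waveform(path, expected_units="m/s")
    assert back.port == "IVC"
    assert np.max(np.abs(back.v - w.v)) < 1e-12
    assert np.max(np.abs(back.t - w.t)) < 1e-12


def test_io_error_cases(tmp_path):
    p = tmp_path / "bad.txt"
    p.write_text("# port=IVC units=m/s rate=10\n0.0 1.0\n-0.1 2.0\n")
    with pytest.raises(WaveformError, match="increasing"):
        read_waveform(p)
    p.write_text("# port=IVC units=m/s rate=10\n")
    with pytest.raises(WaveformError):
        read_waveform(p)
    p.write_text("# port=IVC units=Pa rate=10\n0.0 1.0\n0.1 2.0\n")
    with pytest.raises(WaveformError, match="units"):
        read_waveform(p, expected_units="m/s")


def test_sample_periodic_wraps():
    w = Waveform("IVC", np.arange(4) * 0.25, np.array([0.0, 1.0, 0.0, -1.0]),
                 "m/s")
    assert sample_periodic(w, 1.25)[0] == pytest.approx(1.0)
    assert sample_periodic(w, 0.125)[0] == pytest.approx(0.5)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    mean=st.floats(0.1, 0.5),
    amp=st.floats(0.0, 0.08),
    m=st.floats(0.0, 0.4),
    phase=st.floats(0, 6.28),
)
def test_property_mean_and_periodicity(mean, amp, m, phase):
    """Any admissible spec: exact breath periodicity and exact time-mean."""
    cycles = CycleStructure()
    spec = WaveformSpec(port="IVC", mean_level=mean,
                        cardiac_harmonics=((1, amp, phase),),
                        resp_mod_depth=m, resp_phase=phase)
    w = generate_inlet_waveform(spec, cycles, n_breaths=2, seed=0)
    n_b = int(round(cycles.breath_period * w.sampling_rate))
    assert np.max(np.abs(w.v[n_b:] - w.v[:-n_b])) < 1e-12
    assert abs(w.v.mean() - mean) < 1e-10
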