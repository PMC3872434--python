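"""Cardiac/respiratory separation: bin bookkeeping, recovery, folding."""

import numpy as np
import pytest

from hemolab.spectral import (SpectralError, cardiac_only_waveform,
                              estimate_frequencies, separate_components)
from hemolab.waveforms import (CycleStructure, Waveform, WaveformSpec,
                               generate_components, generate_inlet_waveform)


def _two_tone(n_breaths=3, fs=1000.0):
    """x(t) = 2 + sin(2 pi f_h t) + 0.5 sin(2 pi f_b t), f_h = 4 f_b."""
    T_b = 2.4
    t = np.arange(int(n_breaths * T_b * fs)) / fs
    f_b, f_h = 1 / T_b, 4 / T_b
    v = 2.0 + np.sin(2 * np.pi * f_h * t) + 0.5 * np.sin(2 * np.pi * f_b * t)
    return Waveform("IVC", t, v, "m/s"), f_b, f_h


def test_estimate_frequencies_two_tone():
    w, f_b, f_h = _two_tone()
    fb, fh = estimate_frequencies(w, beats_per_breath=4)
    assert fb == pytest.approx(f_b, abs=1 / w.duration)
    assert fh == pytest.approx(f_h, abs=1 / w.duration)
    assert fh == pytest.approx(4 * fb)


def test_estimate_frequencies_flat_raises():
    t = np.arange(1000) / 1000
    w = Waveform("IVC", t, np.full(1000, 0.3), "m/s")
    with pytest.raises(SpectralError, match="periodicity"):
        estimate_frequencies(w)


def test_breath_bin_arithmetic():
    """Over exactly 3 breaths the breath fundamental is bin 3: f_b = 3/T."""
    w, f_b, _ = _two_tone(n_breaths=3)
    fb, _ = estimate_frequencies(w)
    assert fb == pytest.approx(3.0 / w.duration)


def test_two_tone_separation_closed_form():
    w, f_b, f_h = _two_tone()
    d = separate_components(w, f_heart=f_h, f_breath=f_b)
    t = d.cardiac.t
    assert d.mean_level == pytest.approx(2.0, abs=1e-12)
    assert np.max(np.abs(d.cardiac.v - np.sin(2 * np.pi * f_h * t))) < 1e-9
    assert np.max(np.abs(d.respiratory.v - 0.5 * np.sin(2 * np.pi * f_b * t))) < 1e-9
    assert np.linalg.norm(d.residual.v) < 1e-10 * np.linalg.norm(w.v)


def test_reconstruction_and_parseval(cycles, ivc_spec):
    w = generate_inlet_waveform(ivc_spec, cycles, n_breaths=2, seed=0)
    d = separate_components(w)
    rel = np.linalg.norm(d.reconstruct() - w.v) / np.linalg.norm(w.v)
    assert rel < 1e-10
    pb = d.power_balance()
    lhs = pb["total"]
    rhs = pb["mean"] + pb["cardiac"] + pb["respiratory"] + pb["residual"]
    assert abs(lhs - rhs) < 1e-9 * lhs
    # components have zero time-mean
    assert abs(d.cardiac.v.mean()) < 1e-12
    assert abs(d.respiratory.v.mean()) < 1e-12


def test_cardiac_only_input_has_empty_respiratory(cycles):
    spec = WaveformSpec(port="IVC", mean_level=0.3,
                        cardiac_harmonics=((1, 0.1, 0.2), (2, 0.04, 1.0)))
    w = generate_inlet_waveform(spec, cycles, n_breaths=2, seed=0)
    d = separate_components(w, f_heart=cycles.f_heart, f_breath=cycles.f_breath)
    assert np.linalg.norm(d.respiratory.v) < 1e-10 * np.linalg.norm(w.v)


def test_idempotence(cycles, ivc_spec):
    w = generate_inlet_waveform(ivc_spec, cycles, n_breaths=2, seed=0)
    d = separate_components(w)
    cardiac_again = separate_components(
        Waveform(w.port, d.cardiac.t, d.mean_level + d.cardiac.v, w.units),
        f_heart=d.f_heart, f_breath=d.f_breath)
    assert np.linalg.norm(cardiac_again.respiratory.v) < 1e-10 * np.linalg.norm(w.v)


def test_generator_component_recovery(cycles, ivc_spec):
    """Separation returns exactly the generator's cardiac/respiratory parts."""
    parts = generate_components(ivc_spec, cycles, n_breaths=2)
    w = generate_inlet_waveform(ivc_spec, cycles, n_breaths=2, seed=0)
    d = separate_components(w, f_heart=cycles.f_heart, f_breath=cycles.f_breath)
    nrm = np.linalg.norm(w.v)
    assert np.linalg.norm(d.cardiac.v - parts["cardiac"]) < 1e-6 * nrm
    assert np.linalg.norm(d.respiratory.v - parts["respiratory"]) < 1e-6 * nrm


def test_sideband_reassignment(cycles, ivc_spec):
    """With sidebands->cardiac the respiratory part is the pure breath tone."""
    w = generate_inlet_waveform(ivc_spec, cycles, n_breaths=2, seed=0)
    d = separate_components(w, f_heart=cycles.f_heart, f_breath=cycles.f_breath,
                            sidebands="cardiac")
    pure = (ivc_spec.mean_level * ivc_spec.resp_mod_depth
            * np.sin(2 * np.pi * d.respiratory.t / cycles.breath_period))
    assert np.linalg.norm(d.respiratory.v - pure) < 1e-8 * np.linalg.norm(w.v)


def test_truncation_to_whole_breaths(cycles, ivc_spec):
    w = generate_inlet_waveform(ivc_spec, cycles, n_breaths=3, seed=0)
    cut = Waveform(w.port, w.t[:-700], w.v[:-700], w.units)  # 2.3 breaths
    d = separate_components(cut, f_heart=cycles.f_heart,
                            f_breath=cycles.f_breath)
    assert d.truncated_to == pytest.approx(2 * cycles.breath_period)
    rel = np.linalg.norm(d.reconstruct() - cut.v[:d.cardiac.t.size])
    assert rel < 1e-9 * np.linalg.norm(cut.v)


def test_folding_matches_brute_force_beat_average(cycles, ivc_spec):
    """Folded cardiac-only beat == brute-force mean of the four raw beats."""
    w = generate_inlet_waveform(ivc_spec, cycles, n_breaths=1, seed=0)
    d = separate_components(w, f_heart=cycles.f_heart, f_breath=cycles.f_breath)
    beat = cardiac_only_waveform(d, method="fold")
    n_beat = int(round(cycles.heart_period * w.sampling_rate))
    brute = w.v.reshape(-1, n_beat).mean(axis=0)
    assert np.max(np.abs(beat.v - brute)) < 1e-10
    # the multiplicative envelope cancels over the 4 evenly spaced beats,
    # so the folded beat equals the unmodulated cardiac beat
    parts = generate_components(ivc_spec, cycles, n_breaths=1)
    unmod = (parts["mean"] + parts["cardiac"])[:n_beat]
    assert np.max(np.abs(beat.v - unmod)) < 1e-10


def test_fold_and_harmonic_methods_agree_on_clean_signal(cycles, ivc_spec):
    w = generate_inlet_waveform(ivc_spec, cycles, n_breaths=2, seed=0)
    d = separate_components(w)
    f = cardiac_only_waveform(d, method="fold")
    h = cardiac_only_waveform(d, method="harmonic")
    assert np.max(np.abs(f.v - h.v)) < 1e-10
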