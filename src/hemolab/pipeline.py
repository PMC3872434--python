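"""End-to-end experiment orchestration: the two boundary-condition regimes.

Condition II is the full physiological case: respiratory-modulated venous
inflow waveforms at the inlets and measured-style pressure traces at the
pulmonary-artery outlets.  Condition I strips respiration: its inlet
boundary conditions are the spectrally separated cardiac-only beats of the
very same Condition II traces (folded over the beats of one breath), with
zero-pressure outlets.  Comparing the two quantifies what respiration does
to energy loss, flow distribution, pressure and wall shear.

The left and right innominate-vein traces are merged into the single SVC
grid inlet by flux-weighted summation (their confluence lies upstream of
the planar junction).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .geometry import JunctionGeometry, build_junction, characteristic_length
from .metrics import (compute_WSS, metrics_series, normalize_pressure,
                      port_fluxes)
from .solver import (BoundarySpec, FluidProperties, SolverConfig, run)
from .spectral import (SpectralError, cardiac_only_waveform,
                       separate_components)
from .waveforms import (CycleStructure, Waveform, WaveformSpec,
                        generate_inlet_waveform, generate_outlet_pressure,
                        sample_periodic, write_waveform)

__all__ = [
    "RunConfig",
    "ConfigError",
    "default_config",
    "build_boundary_traces",
    "run_condition",
    "compare_conditions",
]


class ConfigError(ValueError):
    pass


#: Default boundary-trace parameterization.  The amplitude scale is set by
#: the laminar operating regime of a small Fontan patient in a ~9 mm
#: junction: peak port Reynolds number near 800 under cardiac pulsatility
#: alone and below 1000 with respiration included, i.e. peak inlet speeds
#: of ~0.34 / ~0.40 m/s.  The IVC carries the dominant, strongly
#: respiration-modulated venous return; the innominate veins merge into an
#: SVC inflow of comparable mean.  Outlet pressures sit around 1.6 kPa
#: (~12 mmHg) with a small cardiac ripple and a gentle, slightly
#: phase-asymmetric respiratory swing between the two lungs.
DEFAULT_WAVEFORMS = {
    "IVC": dict(mean_level=0.24,
                cardiac_harmonics=[[1, 0.06, 0.0], [2, 0.025, 0.8], [3, 0.01, 1.6]],
                resp_mod_depth=0.20, resp_phase=0.0),
    "LIV": dict(mean_level=0.12,
                cardiac_harmonics=[[1, 0.03, 0.3], [2, 0.012, 1.1]],
                resp_mod_depth=0.18, resp_phase=0.3),
    "RIV": dict(mean_level=0.12,
                cardiac_harmonics=[[1, 0.03, 0.5], [2, 0.012, 1.3]],
                resp_mod_depth=0.18, resp_phase=0.3),
    "LPA": dict(mean_level=1600.0,
                cardiac_harmonics=[[1, 40.0, 0.0]],
                resp_mod_depth=0.04, resp_phase=0.0),
    "RPA": dict(mean_level=1600.0,
                cardiac_harmonics=[[1, 40.0, 0.03]],
                resp_mod_depth=0.04, resp_phase=0.03),
}


@dataclass
class RunConfig:
    """Validated single-file configuration of a full experiment."""

    seed: int
    waveforms: dict = field(default_factory=lambda: DEFAULT_WAVEFORMS)
    heart_period: float = 0.6
    beats_per_breath: int = 4
    sampling_rate: float = 1000.0
    geometry: JunctionGeometry = field(default_factory=JunctionGeometry)
    props: FluidProperties = field(default_factory=FluidProperties)
    cells_across: int = 20           # across the narrowest channel
    cr_max: float = 0.3
    n_heart_cycles: int = 3          # Condition I total (first discarded)
    n_breaths: int = 2               # Condition II total (first discarded)
    discard_heart_cycles: int = 1
    discard_breaths: int = 1
    inlet_profile: str = "parabolic"
    snapshots_per_cycle: int = 40
    include_unsteady_el: bool = False
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory in the run configuration")
        if not (0 <= int(self.seed) < 2**31):
            raise ConfigError("seed must be a non-negative 32-bit integer")
        for port in ("IVC", "LIV", "RIV"):
            if port not in self.waveforms:
                raise ConfigError(f"missing inlet waveform spec for {port}")
        for port in ("LPA", "RPA"):
            if port not in self.waveforms:
                raise ConfigError(
                    f"missing outlet pressure spec for {port} "
                    "(required by the with-respiration condition)"
                )
        if self.inlet_profile not in ("flat", "parabolic"):
            raise ConfigError("inlet_profile must be 'flat' or 'parabolic'")
        if self.n_heart_cycles <= self.discard_heart_cycles:
            raise ConfigError("n_heart_cycles must exceed discard_heart_cycles")
        if self.n_breaths <= self.discard_breaths:
            raise ConfigError("n_breaths must exceed discard_breaths")

    @property
    def cycles(self) -> CycleStructure:
        return CycleStructure(self.heart_period, self.beats_per_breath)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "geometry" in d and isinstance(d["geometry"], dict):
            d["geometry"] = JunctionGeometry(**d["geometry"])
        if "props" in d and isinstance(d["props"], dict):
            d["props"] = FluidProperties(**d["props"])
        if "seed" not in d:
            raise ConfigError("seed is mandatory in the run configuration")
        try:
            return cls(**d)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def default_config(seed: int, **overrides) -> RunConfig:
    return RunConfig(seed=seed, **overrides)


def _spec(port: str, cfg: RunConfig) -> WaveformSpec:
    d = dict(cfg.waveforms[port])
    d["cardiac_harmonics"] = tuple(tuple(x) for x in d.get("cardiac_harmonics", ()))
    return WaveformSpec(port=port, **d)


def build_boundary_traces(cfg: RunConfig) -> dict:
    """Generate the full (with-respiration) boundary traces for every port.

    Seeds are spawned per port from the master seed so traces are
    independent but jointly reproducible.
    """
    ss = np.random.SeedSequence(cfg.seed)
    subs = ss.spawn(5)
    cycles = cfg.cycles
    traces = {}
    for sub, port in zip(subs, ("IVC", "LIV", "RIV", "LPA", "RPA")):
        seed = int(sub.generate_state(1)[0] % (2**31))
        gen = (generate_inlet_waveform if port in ("IVC", "LIV", "RIV")
               else generate_outlet_pressure)
        traces[port] = gen(_spec(port, cfg), cycles, n_breaths=cfg.n_breaths,
                           seed=seed, sampling_rate=cfg.sampling_rate)
    return traces


def merge_innominate(liv: Waveform, riv: Waveform,
                     geometry: JunctionGeometry) -> Waveform:
    """Flux-weighted LIV+RIV merger feeding the SVC grid inlet.

    The innominate veins join upstream of the junction; their volumetric
    flows add and re-divide by the SVC section area.  With equal widths and
    the shared depth this is an area-weighted mean velocity.
    """
    # each innominate vein is assigned half the SVC section by default
    a_liv = a_riv = geometry.d_svc * geometry.depth / 2
    a_svc = geometry.d_svc * geometry.depth
    v = (liv.v * a_liv + riv.v * a_riv) / a_svc
    return Waveform("SVC", liv.t.copy(), v, "m/s")


def condition_boundaries(cfg: RunConfig, condition: str,
                         traces: dict | None = None) -> tuple:
    """Boundary spec + cycle period for one regime.

    Condition "I": cardiac-only inlets (spectral separation + beat folding
    of the Condition II traces), zero-pressure outlets, heart-period cycles.
    Condition "II": full traces, pressure outlets, breath-period cycles.
    """
    if condition not in ("I", "II"):
        raise ConfigError("condition must be 'I' or 'II'")
    traces = traces or build_boundary_traces(cfg)
    svc = merge_innominate(traces["LIV"], traces["RIV"], cfg.geometry)
    cycles = cfg.cycles
    if condition == "II":
        inlets = {"IVC": (traces["IVC"], cfg.inlet_profile),
                  "SVC": (svc, cfg.inlet_profile)}
        outlets = {"LPA": traces["LPA"], "RPA": traces["RPA"]}
        return (BoundarySpec(inlets, outlets), cycles.breath_period,
                cfg.n_breaths, cfg.discard_breaths, traces)
    inlets = {}
    for port, trace in (("IVC", traces["IVC"]), ("SVC", svc)):
        try:
            dec = separate_components(trace,
                                      beats_per_breath=cfg.beats_per_breath)
            beat = cardiac_only_waveform(dec)
        except SpectralError:
            # constant trace (no periodicity): the cardiac-only beat is the
            # constant itself over one heart period
            n_beat = int(round(cycles.heart_period * trace.sampling_rate))
            beat = Waveform(trace.port, trace.t[:n_beat],
                            np.full(n_beat, trace.v.mean()), trace.units)
        inlets[port] = (beat, cfg.inlet_profile)
    outlets = {"LPA": 0.0, "RPA": 0.0}
    return (BoundarySpec(inlets, outlets), cycles.heart_period,
            cfg.n_heart_cycles, cfg.discard_heart_cycles, traces)


def run_condition(cfg: RunConfig, condition: str, traces: dict | None = None,
                  outdir=None) -> dict:
    """Simulate one regime; returns artifacts and optionally writes them."""
    bc, period, n_cycles, discard, traces = condition_boundaries(
        cfg, condition, traces)
    w_min = min(cfg.geometry.widths.values())
    grid = build_junction(cfg.geometry, w_min / cfg.cells_across)
    scfg = SolverConfig(cr_max=cfg.cr_max, n_cycles=n_cycles,
                        discard_cycles=discard,
                        snapshots_per_cycle=cfg.snapshots_per_cycle)
    result = run(grid, bc, cfg.props, scfg, period)
    char = {p: characteristic_length(cfg.geometry, p)
            for p in ("IVC", "SVC", "LPA", "RPA")}
    inertance = {p: cfg.geometry.arm_length for p in char}
    ms = metrics_series(result, char,
                        include_unsteady=cfg.include_unsteady_el,
                        inertance_lengths=inertance)
    artifacts = {"condition": condition, "bc": bc, "grid": grid,
                 "result": result, "metrics": ms, "traces": traces,
                 "config": cfg, "cycle_period": period}
    if outdir is not None:
        _write_artifacts(artifacts, Path(outdir))
    return artifacts


def _write_artifacts(art: dict, outdir: Path) -> None:
    from .vtk_io import write_snapshot_vtk

    outdir.mkdir(parents=True, exist_ok=True)
    cfg: RunConfig = art["config"]
    cfg.to_yaml(outdir / "config.yaml")
    (outdir / "provenance.json").write_text(json.dumps({
        "package": "hemolab", "version": __version__,
        "config_hash": cfg.config_hash(), "condition": art["condition"],
    }, indent=2))
    tdir = outdir / "traces"
    tdir.mkdir(exist_ok=True)
    for port, w in art["traces"].items():
        write_waveform(tdir / f"{port}.txt", w)
    art["metrics"].to_frame().to_csv(outdir / "metrics.csv", index=False)
    fdir = outdir / "fields"
    fdir.mkdir(exist_ok=True)
    res = art["result"]
    for k, snap in enumerate(res.snapshots[:: max(1, len(res.snapshots) // 8)]):
        write_snapshot_vtk(fdir / f"snapshot_{k:03d}.vtk", snap, art["grid"])


# ---------------------------------------------------------------------------
# Condition comparison
# ---------------------------------------------------------------------------

def _extreme_instants(cfg: RunConfig, art_II: dict) -> dict:
    """The four comparison instants: IVC peak/bottom x innominate peak/bottom.

    Selected inside the first kept breath of the with-respiration run from
    the normalized inlet boundary waveforms: t1 both at peak, t2 IVC peak /
    SVC bottom, t3 both at bottom, t4 IVC bottom / SVC peak.
    """
    res = art_II["result"]
    t0 = res.kept_from
    period = art_II["cycle_period"]
    tt = np.linspace(t0, t0 + period, 2000, endpoint=False)
    bc: BoundarySpec = art_II["bc"]
    ivc = np.array([bc.inlet_value("IVC", t) for t in tt])
    svc = np.array([bc.inlet_value("SVC", t) for t in tt])

    def norm(x):
        lo, hi = x.min(), x.max()
        return (x - lo) / (hi - lo) if hi > lo else np.zeros_like(x)

    a, b = norm(ivc), norm(svc)
    return {
        "t1": float(tt[np.argmax(a + b)]),
        "t2": float(tt[np.argmax(a - b)]),
        "t3": float(tt[np.argmin(a + b)]),
        "t4": float(tt[np.argmax(b - a)]),
    }


def compare_conditions(art_I: dict, art_II: dict) -> dict:
    """Side-by-side report of the two regimes at the four extreme instants.

    Tabulates instantaneous EL and FR at each instant, the time-averaged EL
    and FR of each regime, peak Reynolds numbers, maximum wall shear at the
    instants, and the EL ratio in both directions together with the signed
    and absolute FR difference.
    """
    cfg: RunConfig = art_II["config"]
    instants = _extreme_instants(cfg, art_II)
    rows = []
    for label, t_abs in instants.items():
        row = {"instant": label, "t_in_breath_s": t_abs - art_II["result"].kept_from}
        for name, art in (("I", art_I), ("II", art_II)):
            ms = art["metrics"]
            res = art["result"]
            # fold the instant into this run's kept window
            period = art["cycle_period"]
            tau = res.kept_from + (t_abs - art_II["result"].kept_from) % period
            k = int(np.argmin(np.abs(ms.t - tau)))
            snap = res.snapshot_nearest(tau)
            wss = compute_WSS(snap, res.grid, res.props)
            row[f"EL_W_{name}"] = float(ms.EL[k])
            row[f"FR_pct_{name}"] = float(ms.FR_LPA[k])
            row[f"WSS_max_Pa_{name}"] = wss.tau_max
        rows.append(row)
    table = pd.DataFrame(rows)
    ms_I, ms_II = art_I["metrics"], art_II["metrics"]
    el_I, el_II = ms_I.EL_time_averaged, ms_II.EL_time_averaged
    summary = {
        "EL_avg_W_I": el_I,
        "EL_avg_W_II": el_II,
        "EL_ratio_II_over_I": el_II / el_I if el_I else np.nan,
        "EL_ratio_I_over_II": el_I / el_II if el_II else np.nan,
        "FR_avg_pct_I": ms_I.FR_time_averaged,
        "FR_avg_pct_II": ms_II.FR_time_averaged,
        "FR_diff_signed_pct": ms_II.FR_time_averaged - ms_I.FR_time_averaged,
        "FR_diff_abs_pct": abs(ms_II.FR_time_averaged - ms_I.FR_time_averaged),
        "Re_max_I": max(float(np.max(s)) for s in ms_I.Re.values()),
        "Re_max_II": max(float(np.max(s)) for s in ms_II.Re.values()),
        "FR_range_pct_I": [float(ms_I.FR_LPA.min()), float(ms_I.FR_LPA.max())],
        "FR_range_pct_II": [float(ms_II.FR_LPA.min()), float(ms_II.FR_LPA.max())],
    }
    return {"instants": instants, "table": table, "summary": summary}


def write_report(report: dict, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report["table"].to_csv(outdir / "comparison_instants.csv", index=False)
    lines = ["Condition I (cardiac only) vs Condition II (with respiration)",
             "=" * 62, ""]
    lines.append(report["table"].to_string(index=False,
                                           float_format=lambda v: f"{v:.5g}"))
    lines.append("")
    for k, v in report["summary"].items():
        lines.append(f"{k:24s} {v}")
    path = outdir / "report.txt"
    path.write_text("\n".join(lines) + "\n")
    return path
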