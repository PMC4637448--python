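"""End-to-end scenario presets: geometry + initiation + solver + analysis.

Each preset assembles one study configuration — the homogeneous 2D sheet, the
tapering wedge, the ridge, and the three pectinate-muscle bridge geometries —
initiates a scroll wave by phase distribution, integrates the monodomain
model, tracks the filament tip, and summarises drift and rhythm.  ``desk``
scale runs seconds of activity so a full qualitative drift characterisation
fits on one workstation CPU; ``full`` scale reproduces the 40 s protocol.

The remodelled study condition (see :func:`atriadrift.cell_model.RemodelParams`)
is the conductance-remodelled CRN model with [ACh] = 0: that condition
produces a stable, stationary ~9 Hz rotor with an ~8 mm core in the
homogeneous sheet, the reference behaviour on which the drift analyses build;
cholinergic activation at 0.0035 umol/L is available as a config option and
accelerates the rotor to ~12.5 Hz.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import geometry as geo
from .cell_model import RemodelParams
from .config import RunConfig
from .errors import AtriaDriftError
from .filament import (TipTrace, average_tip_trace, classify_drift,
                       core_diameter, rotation_period, track_tips)
from .analysis import classify_morphology, cycle_lengths, psd
from .initiation import CycleLibrary, SpiralSpec, apply_phase_distribution, \
    record_cycle
from .tissue_solver import SolverConfig, build_weights, run

log = logging.getLogger("atriadrift")

__all__ = ["ScenarioSpec", "ScenarioResult", "run_scenario",
           "assert_drift_laws", "af_study_params", "PRESETS", "preset"]


def af_study_params() -> RemodelParams:
    """Remodelled parameter set used by the drift-study presets.

    gCaL x 0.35 and gKr/gKs x 9 with no cholinergic activation; this yields a
    short-APD, stable, non-meandering rotor (~9 Hz, ~8 mm core on the 25x25 mm
    sheet), the prerequisite for isolating anatomy-induced drift.
    """
    return RemodelParams(ach=0.0)


@dataclass
class ScenarioSpec:
    """One scenario run: geometry preset, initiation, duration, numerics."""

    name: str                          # sheet2d | wedge | ridge | pm1 | pm2 | pm3
    centre: tuple                      # initiation centre (mm)
    normal: tuple = (0.0, 0.0, 1.0)
    chirality: str = "ccw"
    duration: float = 2000.0           # ms
    dt: float = 0.01
    dx: float = 0.33
    scale: str = "desk"                # desk | full
    probe: tuple | None = None         # physical point (mm)
    site_label: str = ""

    def __post_init__(self):
        if self.name not in geo.BUILDERS:
            raise ValueError(f"unknown geometry preset {self.name!r}")
        if self.scale == "desk":
            if self.duration > 4000.0:
                raise ValueError("desk scale caps duration at 4000 ms")
        elif self.scale != "full":
            raise ValueError("scale must be 'desk' or 'full'")


@dataclass
class ScenarioResult:
    spec: ScenarioSpec
    result: object                     # SimResult
    trace: TipTrace
    summary: dict


# -- preset initiation sites -------------------------------------------------
_XC = 12.54        # centre of the 25 mm / dx 0.33 face (76*dx/2)


def _pm23_point(theta_deg: float, az_deg: float, radius: float = 13.5):
    th, az = np.radians(theta_deg), np.radians(az_deg)
    d = np.array([np.sin(th) * np.cos(az), np.sin(th) * np.sin(az),
                  np.cos(th)])
    return tuple(radius * d), tuple(d)


_PM23_SITE, _PM23_NORMAL = _pm23_point(50.0, 90.0)
_PM23_PROBE, _ = _pm23_point(70.0, 0.0)

PRESETS: dict = {
    # homogeneous sheet: centred rotor, 4 s (rhythm anchors need >= 4 s)
    "sheet2d": dict(centre=(_XC, _XC, 0.0), duration=4000.0, dt=0.01,
                    probe=(18.81, 18.81, 0.0)),
    # wedge: initiation near the thick end (25 % of Lx), mid-y
    "wedge": dict(centre=(6.27, _XC, 0.0), duration=1200.0, dt=0.02,
                  probe=(20.13, 20.13, 0.0)),
    # ridge: default site close to the ridge on the -x side
    "ridge": dict(centre=(8.58, _XC, 0.0), duration=1000.0, dt=0.02,
                  probe=(20.13, 4.62, 0.0), site_label="left"),
    # PM1: under the bridge mid-span (junctions at x = 12.54 +/- 4.46); sites
    # keep the rotor core away from the domain edges so the finite-domain
    # boundary interaction does not confound the bridge's (null) effect
    "pm1": dict(centre=(_XC, _XC, 0.0), duration=1300.0, dt=0.02,
                probe=(20.13, 20.13, 0.0), site_label="mid-span"),
    "pm2": dict(centre=_PM23_SITE, normal=_PM23_NORMAL, duration=1500.0,
                dt=0.02, probe=_PM23_PROBE),
    # PM3: rotor seeded over the ridge (the pole); it drifts toward/along the
    # ridge and anchors near a junction within the desk window
    "pm3": dict(centre=(0.0, 0.0, 13.5), normal=(0.0, 0.0, 1.0),
                duration=1500.0, dt=0.02, probe=_PM23_PROBE),
}

ALT_SITES: dict = {
    # ridge: mirror site (+x side), directly on the ridge, and far away
    "ridge": {"right": dict(centre=(16.5, _XC, 0.0), site_label="right"),
              "on": dict(centre=(_XC, _XC, 0.0), site_label="on"),
              "far": dict(centre=(5.0, _XC, 0.0), site_label="far")},
    "wedge": {"corner": dict(centre=(6.27, 18.81, 0.0), site_label="corner")},
    "pm1": {"near-j2": dict(centre=(15.5, _XC, 0.0), site_label="near-J2")},
}


def preset(name: str, chirality: str = "ccw", scale: str = "desk",
           site: str | None = None, duration: float | None = None,
           dt: float | None = None) -> ScenarioSpec:
    """Build a ScenarioSpec from the named preset."""
    if name not in PRESETS:
        raise ValueError(f"no preset named {name!r}")
    kw = dict(PRESETS[name])
    if site is not None:
        alt = ALT_SITES.get(name, {})
        if site not in alt:
            raise ValueError(f"no site {site!r} for preset {name!r}")
        kw.update(alt[site])
    if scale == "full":
        kw["duration"] = 40000.0
        kw["dt"] = 0.01
    if duration is not None:
        kw["duration"] = duration
    if dt is not None:
        kw["dt"] = dt
    return ScenarioSpec(name=name, chirality=chirality, scale=scale, **kw)


_LIB_CACHE: dict = {}


def _library(params: RemodelParams, cfg: RunConfig) -> CycleLibrary:
    key = (params, cfg.library_bcl, cfg.dx, cfg.library_dt)
    if key not in _LIB_CACHE:
        _LIB_CACHE[key] = record_cycle(
            params, bcl=cfg.library_bcl, dx=cfg.dx, dt=cfg.dt if cfg.dt <= 0.01
            else 0.01, dt_lib=cfg.library_dt, stim_pA=cfg.stim_pA,
            stim_ms=cfg.stim_ms)
    return _LIB_CACHE[key]


def _nearest_tissue_voxel(geom, W, point):
    pos = W.voxels * geom.dx + np.asarray(geom.origin)
    return tuple(int(v) for v in W.voxels[
        np.argmin(np.linalg.norm(pos - np.asarray(point), axis=1))])


def run_scenario(spec: ScenarioSpec, params: RemodelParams | None = None,
                 cfg: RunConfig | None = None, outdir=None,
                 write_snapshots: bool = False) -> ScenarioResult:
    """Execute one scenario end to end (deterministic).

    Returns the simulation result, the tip trace (averaged and classified),
    and a summary dict; optionally writes config.json / tips.csv /
    summary.json / VTK snapshots to ``outdir``.
    """
    t_start = time.time()
    params = params if params is not None else af_study_params()
    cfg = cfg if cfg is not None else RunConfig(dt=spec.dt, dx=spec.dx)
    stage = "geometry"
    try:
        builder = geo.BUILDERS[spec.name]
        geom = builder(dx=spec.dx)
        W = build_weights(geom)

        stage = "initiation"
        lib = _library(params, cfg)
        sw = SpiralSpec(centre=spec.centre, chirality=spec.chirality,
                        normal=spec.normal)
        init = apply_phase_distribution(geom, lib, sw, weights=W)

        stage = "simulation"
        probe = spec.probe if spec.probe is not None else spec.centre
        probe_vox = _nearest_tissue_voxel(geom, W, probe)
        scfg = SolverConfig(D=cfg.D, dt=spec.dt, duration=spec.duration,
                            record_interval=cfg.record_interval,
                            probe_dt=cfg.probe_dt, probes=(probe_vox,),
                            params=params)
        res = run(geom, init, scfg)

        stage = "tracking"
        trace = track_tips(res, geom, v_iso=cfg.v_iso, oi_iso=cfg.oi_iso)
        try:
            period = rotation_period(trace)
        except AtriaDriftError:
            period = np.nan
        if np.isfinite(period):
            trace = average_tip_trace(trace, period)
            trace = classify_drift(
                trace, threshold=cfg.drift_threshold_mm,
                reference_duration=cfg.drift_reference_ms,
                discard_rotations=cfg.discard_rotations,
                excluded_ratio=cfg.excluded_ratio)
        core = core_diameter(trace, period if np.isfinite(period) else None)

        stage = "analysis"
        v = res.probe_V[0]
        t = res.probe_t
        keep = t >= min(500.0, 0.25 * spec.duration)
        summary: dict = {
            "scenario": spec.name, "site": spec.site_label,
            "chirality": spec.chirality, "duration_ms": spec.duration,
            "dt_ms": spec.dt, "dx_mm": spec.dx,
            "n_tissue": geom.n_tissue,
            "rotation_period_ms": float(period),
            "core_diameter_mm": float(core),
            "classification": trace.classification,
            "displacement_mm": float(trace.displacement),
            "path_length_mm": float(trace.path_length),
        }
        if np.isfinite(period) and trace.avg_xyz.shape[0] > cfg.discard_rotations + 1:
            a = trace.avg_xyz[cfg.discard_rotations:]
            tt = trace.avg_t[cfg.discard_rotations:]
            vec = a[-1] - a[0]
            summary["drift_vector_mm"] = vec.tolist()
            summary["drift_speed_mm_per_s"] = float(
                1e3 * np.linalg.norm(vec) / (tt[-1] - tt[0]))
        try:
            spect = psd(v[keep], cfg.probe_dt)
            summary["dominant_frequency_hz"] = spect.dominant
            summary["psd_peaks"] = spect.peaks
            summary["morphology"] = classify_morphology(
                spect, rel_power=cfg.psd_rel_peak,
                harmonic_tol=cfg.harmonic_tol)
        except AtriaDriftError as exc:
            summary["dominant_frequency_hz"] = float("nan")
            summary["morphology"] = f"unavailable ({exc})"
        try:
            rm = cycle_lengths(v[keep], cfg.probe_dt, threshold=cfg.v_iso)
            summary["mean_cycle_length_ms"] = rm.mean_cl
            summary["cycle_lengths_ms"] = rm.cycle_lengths.tolist()
        except AtriaDriftError:
            summary["mean_cycle_length_ms"] = float("nan")
        summary["elapsed_s"] = round(time.time() - t_start, 1)
        summary["config"] = json.loads(cfg.to_json())
    except AtriaDriftError as exc:
        raise AtriaDriftError(f"scenario {spec.name!r} failed during "
                              f"{stage}: {exc}") from exc

    if outdir is not None:
        from . import io_vtk

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        cfg.to_json(out / "config.json")
        io_vtk.write_tips_csv(out / "tips.csv", trace)
        io_vtk.write_trace_csv(out / "probe.csv", t, v)
        io_vtk.write_summary_json(out / "summary.json", summary)
        if write_snapshots:
            for k, ts in enumerate(res.snap_times):
                io_vtk.write_structured_points(
                    out / f"snap_{k:05d}.vtk",
                    {"V": res.snapshot_field(k, "V"),
                     "oi": res.snapshot_field(k, "oi")},
                    dx=geom.dx, origin=geom.origin)
            (out / "snapshots.index").write_text(
                "\n".join(f"snap_{k:05d}.vtk {ts:.3f}"
                          for k, ts in enumerate(res.snap_times)))
    return ScenarioResult(spec=spec, result=res, trace=trace, summary=summary)


def _drift_vec(sr: ScenarioResult) -> np.ndarray:
    return np.asarray(sr.summary.get("drift_vector_mm", [0.0, 0.0, 0.0]))


def assert_drift_laws(results: dict) -> dict:
    """Boolean report of the qualitative drift laws over a set of scenarios.

    Expected keys (each a ScenarioResult) when available: ``wedge``,
    ``ridge_left``, ``ridge_right`` (mirror initiation sides), optionally
    ``ridge_left_cw`` (opposite chirality), ``pm1``, ``pm3``.  Missing keys
    are simply omitted from the report.
    """
    report: dict = {}
    if "wedge" in results:
        v = _drift_vec(results["wedge"])
        # wall is thick at x=0: thick->thin drift has positive x component
        report["wedge_drifts_thick_to_thin"] = bool(
            v[0] > 0 and abs(v[0]) > abs(v[2]))
        report["wedge_drift_speed_mm_per_s"] = results["wedge"].summary.get(
            "drift_speed_mm_per_s", 0.0)
    if "ridge_left" in results:
        v = _drift_vec(results["ridge_left"])
        report["ridge_drift_ridge_parallel"] = bool(abs(v[1]) > 2 * abs(v[0]))
        report["ridge_drift_speed_mm_per_s"] = results["ridge_left"].summary.get(
            "drift_speed_mm_per_s", 0.0)
        if "wedge" in results:
            report["ridge_faster_than_wedge"] = bool(
                report["ridge_drift_speed_mm_per_s"]
                > report["wedge_drift_speed_mm_per_s"])
    if "ridge_left" in results and "ridge_right" in results:
        vl, vr = _drift_vec(results["ridge_left"]), _drift_vec(results["ridge_right"])
        report["ridge_direction_flips_with_side"] = bool(vl[1] * vr[1] < 0)
    if "ridge_left" in results and "ridge_left_cw" in results:
        vl = _drift_vec(results["ridge_left"])
        vc = _drift_vec(results["ridge_left_cw"])
        report["ridge_direction_flips_with_chirality"] = bool(vl[1] * vc[1] < 0)
    if "pm1" in results:
        report["pm1_stationary"] = all(
            sr.summary["classification"] == "stationary"
            for sr in ([results["pm1"]] if isinstance(results["pm1"], ScenarioResult)
                       else results["pm1"]))
    if "pm3" in results:
        sr = results["pm3"]
        report["pm3_polymorphic"] = sr.summary.get("morphology") == "polymorphic"
        cl = np.asarray(sr.summary.get("cycle_lengths_ms", []))
        if cl.size >= 6:
            d = cl - np.mean(cl)
            r1 = float(np.corrcoef(d[:-1], d[1:])[0, 1]) if np.std(d) > 0 else 0.0
            report["pm3_long_short_alternation"] = bool(r1 < 0)
            report["pm3_cl_lag1_corr"] = r1
    return report
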