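"""Run configuration: every tunable constant of the pipeline with its
physiological/numerical default, serialisable to JSON losslessly."""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """All solver/cell/initiation/analysis parameters (mm, ms, mV, pA)."""

    # numerics
    dt: float = 0.01                 # ms
    dx: float = 0.33                 # mm
    D: float = 0.07                  # mm^2/ms
    record_interval: float = 10.0    # ms, 3D snapshot cadence
    probe_dt: float = 1.0            # ms, probe-trace sampling
    # cell model (AF-remodelled defaults)
    scale_gCaL: float = 0.35
    scale_gKr: float = 9.0
    scale_gKs: float = 9.0
    ach: float = 0.0035              # umol/L
    kach_exp: float = 0.477          # O_ACh exponent (printed as "0.47")
    Cm: float = 100.0                # pF
    # stimulus
    stim_pA: float = -2000.0
    stim_ms: float = 2.0
    # initiation
    library_bcl: float = 200.0       # ms, strand pacing cycle length
    library_dt: float = 0.5          # ms, library sampling
    chirality: str = "ccw"
    # filament / drift analysis
    v_iso: float = -50.0             # mV
    oi_iso: float = 0.5
    drift_threshold_mm: float = 10.0
    drift_reference_ms: float = 40000.0
    discard_rotations: int = 2
    excluded_ratio: float = 4.0
    # spectral analysis
    psd_rel_peak: float = 0.2
    harmonic_tol: float = 0.08
    # misc
    schema_version: int = SCHEMA_VERSION
    tag: str = ""

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, src) -> "RunConfig":
        if isinstance(src, (str, Path)) and Path(str(src)).exists():
            doc = json.loads(Path(src).read_text())
        else:
            doc = json.loads(src)
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def cell_params(self):
        from .cell_model import RemodelParams

        return RemodelParams(scale_gCaL=self.scale_gCaL,
                             scale_gKr=self.scale_gKr,
                             scale_gKs=self.scale_gKs,
                             ach=self.ach, Cm=self.Cm,
                             kach_exp=self.kach_exp)
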