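"""CSV readers/writers, session manifests and run configuration.

All files are plain comma-separated UTF-8 with a header row, seconds as the
only time unit and SI units throughout except the footpod's native contact
time (ms) and leg-spring stiffness (kN/m).  Every artifact directory
carries a JSON manifest embedding the subject, protocol, bias model, seed
and a hash of the generating configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .grf_pipeline import ForceTrace, ValidationError
from .simulate import (
    DeviceBiasModel,
    GaitModel,
    ProtocolConfig,
    SubjectProfile,
    SyntheticSession,
)
from .stiffness_kinematics import MarkerTrace


@dataclass(frozen=True)
class TimeseriesSchema:
    """Column contract for one CSV stream."""

    columns: tuple[str, ...]
    time_column: str = "t"
    monotone: bool = True


SCHEMAS = {
    "force": TimeseriesSchema(("t", "Fz", "Fx")),
    "marker": TimeseriesSchema(("t", "z_heel")),
    "breath": TimeseriesSchema(("t", "vo2")),
    "pod": TimeseriesSchema(("t", "power", "gct_ms", "lss", "distance")),
}


@dataclass(frozen=True)
class RunConfig:
    """Processing and sampler settings shared by the pipeline stages.

    Validated on construction so a bad configuration fails before any
    stage runs.
    """

    force_threshold_n: float = 20.0
    debounce_s: float = 0.010
    filter_order: int = 5          # breath moving-average width (odd)
    habituation_s: float = 60.0
    vo2_rest: float = 5.0          # ml/kg/min resting baseline
    window_offset_m: float = 0.0   # platform window start within the lap
    sampler_walkers: int = 32
    sampler_burn: int = 700
    sampler_draws: int = 800
    sampler_runs: int = 4          # independent ensembles for R-hat

    def __post_init__(self) -> None:
        if self.force_threshold_n <= 0:
            raise ValidationError("force threshold must be positive")
        if self.debounce_s < 0 or self.habituation_s < 0:
            raise ValidationError("durations must be non-negative")
        if self.filter_order < 1 or self.filter_order % 2 == 0:
            raise ValidationError("filter order must be odd and >= 1")
        if self.vo2_rest < 0:
            raise ValidationError("resting VO2 must be non-negative")
        if min(self.sampler_walkers, self.sampler_burn, self.sampler_draws,
               self.sampler_runs) < 1:
            raise ValidationError("sampler settings must be positive")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))

    def sampler_kwargs(self) -> dict:
        return {
            "n_walkers": self.sampler_walkers,
            "n_burn": self.sampler_burn,
            "n_draws": self.sampler_draws,
            "n_runs": self.sampler_runs,
        }


def read_timeseries_csv(path: str | Path, schema: TimeseriesSchema) -> pd.DataFrame:
    """Read and validate one CSV stream against its schema.

    Checks column presence, finiteness, and strict time monotonicity; the
    error message names the first offending column/row.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"missing file: {path}")
    df = pd.read_csv(path)
    for col in schema.columns:
        if col not in df.columns:
            raise ValidationError(f"{path.name}: missing column {col!r}")
        bad = ~np.isfinite(df[col].to_numpy(dtype=float))
        if bad.any():
            raise ValidationError(
                f"{path.name}: non-finite value in column {col!r} "
                f"at row {int(np.flatnonzero(bad)[0])}"
            )
    t = df[schema.time_column].to_numpy(dtype=float)
    if schema.monotone and t.size >= 2:
        diffs = np.diff(t)
        if diffs.min() <= 0:
            row = int(np.flatnonzero(diffs <= 0)[0]) + 1
            raise ValidationError(
                f"{path.name}: non-monotone time at row {row}"
            )
    return df


def _config_dict(session: SyntheticSession) -> dict:
    return {
        "subject": dataclasses.asdict(session.subject),
        "protocol": dataclasses.asdict(session.protocol),
        "bias": dataclasses.asdict(session.bias),
        "gait": dataclasses.asdict(session.gait),
        "seed": session.seed,
    }


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_session(session: SyntheticSession, outdir: str | Path) -> Path:
    """Write all session streams as CSV plus a JSON manifest.

    Emits ``force_<lap>.csv`` (t, Fz, Fx), ``marker.csv`` (t, z_heel),
    ``breath.csv`` (t, vo2), ``pod.csv``, ``truth.csv`` and
    ``manifest.json``; returns the manifest path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    float_fmt = "%.17g"
    for lap, trace in sorted(session.force_traces.items()):
        name = f"force_{lap}.csv"
        pd.DataFrame({"t": trace.t, "Fz": trace.fz, "Fx": trace.fx}).to_csv(
            outdir / name, index=False, float_format=float_fmt
        )
        files[f"force_{lap}"] = name
    pd.DataFrame({"t": session.marker.t, "z_heel": session.marker.z}).to_csv(
        outdir / "marker.csv", index=False, float_format=float_fmt
    )
    files["marker"] = "marker.csv"
    session.breaths.to_csv(outdir / "breath.csv", index=False, float_format=float_fmt)
    files["breath"] = "breath.csv"
    session.pod.to_csv(outdir / "pod.csv", index=False, float_format=float_fmt)
    files["pod"] = "pod.csv"
    session.truth.to_csv(outdir / "truth.csv", index=False, float_format=float_fmt)
    files["truth"] = "truth.csv"

    config = _config_dict(session)
    manifest = {
        "config": config,
        "config_hash": config_hash(config),
        "files": files,
        "stage_table": {
            str(i): float(v) for i, v in enumerate(session.stage_speeds_kmh)
        },
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def load_session(manifest_path: str | Path) -> SyntheticSession:
    """Rebuild an in-memory session from a written manifest directory."""
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / "manifest.json"
    manifest = json.loads(manifest_path.read_text())
    root = manifest_path.parent
    cfg = manifest["config"]
    subject = SubjectProfile(**cfg["subject"])
    protocol = ProtocolConfig(**cfg["protocol"])
    bias = DeviceBiasModel(**cfg["bias"])
    gait_cfg = dict(cfg["gait"])
    for key in ("duty_speeds", "duty_values"):
        gait_cfg[key] = tuple(gait_cfg[key])
    gait = GaitModel(**gait_cfg)

    force_traces: dict[int, ForceTrace] = {}
    for key, name in manifest["files"].items():
        if not key.startswith("force_"):
            continue
        lap = int(key.split("_", 1)[1])
        df = read_timeseries_csv(root / name, SCHEMAS["force"])
        force_traces[lap] = ForceTrace(
            t=df["t"].to_numpy(),
            fz=df["Fz"].to_numpy(),
            fx=df["Fx"].to_numpy(),
            mass=subject.mass,
        )
    mk = read_timeseries_csv(root / manifest["files"]["marker"], SCHEMAS["marker"])
    breaths = read_timeseries_csv(root / manifest["files"]["breath"], SCHEMAS["breath"])
    pod = read_timeseries_csv(root / manifest["files"]["pod"], SCHEMAS["pod"])
    truth = pd.read_csv(root / manifest["files"]["truth"])
    speeds = np.asarray(
        [manifest["stage_table"][k] for k in sorted(manifest["stage_table"], key=int)]
    )
    return SyntheticSession(
        subject=subject,
        protocol=protocol,
        bias=bias,
        gait=gait,
        seed=int(cfg["seed"]),
        stage_speeds_kmh=speeds,
        force_traces=force_traces,
        marker=MarkerTrace(t=mk["t"].to_numpy(), z=mk["z_heel"].to_numpy()),
        breaths=breaths,
        pod=pod,
        truth=truth,
        truth_1hz=pd.DataFrame(),
    )
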