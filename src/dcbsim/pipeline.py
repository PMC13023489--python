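"""Configuration and orchestration of the full analysis pipeline.

A run configuration names a geometry (preset or explicit dimensions), the
transport parameters, the loss schedule, the candidate dilation times and
the numerical controls.  :func:`run_pipeline` executes transfer, retention
and dosimetry for every candidate time, selects the optimal one, and writes
a self-describing bundle: one series CSV per candidate, optional VTK
snapshots, a JSON report with every effective parameter value, and a file
manifest.  All internal units are SI; ug/g appears only at the dosimetry
boundary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .dosimetry import make_report, select_optimal
from .errors import ValidationError
from .geometry import VesselDims
from .mesh import mesh_geometry
from .retention import WEEK, LossSchedule, run_retention
from .synthetic import make_fixture
from .transfer import TransportParams, run_transfer
from .vtkio import write_field_csv, write_vtk

__all__ = ["RunConfig", "load_config", "run_pipeline"]

log = logging.getLogger("dcbsim")


@dataclass
class RunConfig:
    """Validated pipeline configuration (SI units throughout)."""

    geometry: str | None = "s50"
    dims: VesselDims = field(default_factory=VesselDims)
    stenosis_rate: float | None = None  # used when geometry preset is None
    params: TransportParams = field(default_factory=TransportParams)
    schedule: LossSchedule = field(default_factory=LossSchedule)
    dilation_times: tuple = (20.0, 40.0, 60.0, 80.0, 100.0, 120.0)
    spacing: float = 5e-5
    transfer_dt: float = 1.0
    retention_dt: float = 600.0
    horizon_weeks: float = 8.0
    seed: int = 0
    outdir: str = "dcbsim_out"
    write_vtk_snapshots: bool = False

    def __post_init__(self) -> None:
        if self.geometry is None and self.stenosis_rate is None:
            raise ValidationError("config field 'geometry' is required")
        if not self.dilation_times:
            raise ValidationError("config field 'dilation_times' must be non-empty")
        for name in ("spacing", "transfer_dt", "retention_dt", "horizon_weeks"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"config field {name!r} must be positive")

    def build_geometry(self):
        if self.geometry is not None:
            return make_fixture(self.geometry, self.dims)
        from .geometry import build_geometry

        return build_geometry(self.stenosis_rate, self.dims)


def load_config(path) -> RunConfig:
    """Load a YAML run configuration; unknown keys raise, missing use defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValidationError("config file must contain a mapping")
    kwargs = {}
    known = set(RunConfig.__dataclass_fields__)
    for key, value in raw.items():
        if key not in known:
            raise ValidationError(f"unknown config field {key!r}")
        if key == "dims":
            value = VesselDims(**{k: float(v) for k, v in value.items()})
        elif key == "params":
            value = TransportParams(**{k: float(v) for k, v in value.items()})
        elif key == "schedule":
            value = LossSchedule(**{k: float(v) for k, v in value.items()})
        elif key == "dilation_times":
            value = tuple(float(t) for t in value)
        kwargs[key] = value
    return RunConfig(**kwargs)


def run_pipeline(config: RunConfig) -> dict:
    """Execute geometry -> transfer -> retention -> dosimetry for a config.

    Returns the report dictionary (also written to ``report.json`` in the
    output directory) whose ``manifest`` lists every file the run produced.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []

    geom = config.build_geometry()
    mesh = mesh_geometry(geom, config.spacing)
    log.info(
        "meshed %s: %d x %d cells (%d active)",
        config.geometry or f"stenosis {geom.stenosis_rate:.2f}",
        mesh.nr,
        mesh.nz,
        int((mesh.labels != 0).sum()),
    )
    if config.write_vtk_snapshots:
        mesh_path = outdir / "mesh.vtk"
        write_vtk(mesh, mesh_path)
        manifest.append(mesh_path.name)

    horizon = config.horizon_weeks * WEEK
    reports = []
    for t_dil in config.dilation_times:
        tag = f"{int(round(t_dil)):03d}s"
        res = run_transfer(mesh, config.params, t_dil, dt=config.transfer_dt)
        log.info("transfer %s: absorbed %.3f%%", tag, res.absorbed_percent)
        ret = run_retention(
            res.field,
            mesh,
            config.params,
            config.schedule,
            horizon=horizon,
            dt=config.retention_dt,
        )
        series_path = outdir / f"series_{tag}.csv"
        ret.series.to_frame().to_csv(series_path, index=False)
        manifest.append(series_path.name)
        ledger_path = outdir / f"ledger_{tag}.csv"
        ret.ledger.to_csv(ledger_path, index=False)
        manifest.append(ledger_path.name)
        field_path = outdir / f"field_{tag}.csv"
        write_field_csv(res.field, field_path)
        manifest.append(field_path.name)
        if config.write_vtk_snapshots:
            vtk_path = outdir / f"retention_final_{tag}.vtk"
            write_vtk(mesh, vtk_path, {"phi_kg_per_m3": ret.final_field.values})
            manifest.append(vtk_path.name)
        reports.append(
            make_report(
                t_dil,
                ret.series,
                config.params.c_toxic,
                config.params.c_effective,
                config.horizon_weeks,
            )
        )

    optimal = select_optimal(reports)
    report = {
        "config": _config_dict(config),
        "mesh": {"nr": mesh.nr, "nz": mesh.nz, "spacing_m": config.spacing},
        "reports": [r.to_dict() for r in reports],
        "optimal_dilation_time_s": (
            optimal.dilation_time if optimal else "no admissible dilation time"
        ),
        "manifest": manifest + ["report.json"],
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    d["dilation_times"] = list(config.dilation_times)
    return d
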