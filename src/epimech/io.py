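"""Run configuration, file readers/writers and the simulation driver.

The run configuration is a YAML document validated against a pydantic
schema (unknown keys are rejected); every run snapshots its fully-resolved
configuration into the output directory for provenance.  Meshes and fields
are written as legacy-ASCII VTK (readable by ParaView and friends); curves
and summaries travel as CSV with unit-suffixed column names.  All
floating-point CSV output uses 17 significant digits so values round-trip
exactly.
"""

from __future__ import annotations

import io as _io
import json
import logging
import sys
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import fem, geometry, stress
from .geometry import PlanarMesh, SubdomainLabel, VariantId
from .hertz import ForceDistanceCurve
from .mechtest import LoadDeformationRecord

logger = logging.getLogger("epimech")

__all__ = [
    "RunConfig",
    "ResultBundle",
    "load_config",
    "run_simulation",
    "write_vtk",
    "read_vtk_mesh",
    "write_curve_table",
    "read_curve_table",
    "setup_logging",
]

_FLOAT_FMT = "%.17g"


def setup_logging(level: str = "INFO", logfile: Path | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )


# ---------------------------------------------------------------------------
# configuration schema
# ---------------------------------------------------------------------------


class GeometryConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    total_height: float = 66.0
    top_radius: float = 17.0
    bottom_width: float = 25.0
    cortical_width: float = 2.5
    thickness: float = 1.0
    gp_band_y: float = 50.5
    gp_band_height: float = 3.0
    soc_center: tuple[float, float] = (0.0, 53.0)
    soc_semi_axes: tuple[float, float] = (12.0, 8.0)
    arc_segments: int = 96

    def to_params(self) -> geometry.EpiphysisParams:
        return geometry.EpiphysisParams(**self.model_dump())


class MaterialConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    E: float = Field(gt=0)
    nu: float = Field(ge=0, lt=0.5)


class LoadCaseConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str = ""
    peak_pressure: float = Field(ge=0)
    sector_center_angle: float = 90.0
    sector_half_width: float = 22.5
    follower: bool = True
    wide_support: bool = False
    n_steps: Optional[int] = None

    def to_load(self) -> fem.LoadCase:
        return fem.LoadCase(
            peak_pressure=self.peak_pressure,
            sector_center_angle=self.sector_center_angle,
            sector_half_width=self.sector_half_width,
            follower=self.follower,
            wide_support=self.wide_support,
            n_steps=self.n_steps,
        )


class SolverConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    tolerance: float = 1e-8
    max_iterations: int = 25
    small_strain: bool = False
    max_halvings: int = 4

    def to_options(self) -> fem.SolverOptions:
        return fem.SolverOptions(
            tolerance=self.tolerance,
            max_iterations=self.max_iterations,
            small_strain=self.small_strain,
            max_halvings=self.max_halvings,
        )


_DEFAULT_MATERIALS = {
    "epiphyseal_cartilage": MaterialConfig(E=6.0, nu=0.47),
    "growth_plate_band": MaterialConfig(E=6.0, nu=0.47),
    "stiff_insert": MaterialConfig(E=500.0, nu=0.20),
    "cortical_bone": MaterialConfig(E=5000.0, nu=0.30),
    "metaphyseal_bone": MaterialConfig(E=500.0, nu=0.20),
}


class RunConfig(BaseModel):
    """Schema-validated simulation run: variants x load cases."""

    model_config = ConfigDict(extra="forbid")
    variants: list[Literal[
        "no_soc", "with_soc", "protrusions_small", "protrusions_extended"
    ]] = ["no_soc", "with_soc", "protrusions_small", "protrusions_extended"]
    geometry: GeometryConfig = GeometryConfig()
    materials: dict[str, MaterialConfig] = dict(_DEFAULT_MATERIALS)
    load_cases: list[LoadCaseConfig] = [
        LoadCaseConfig(name="vertical", peak_pressure=0.3, sector_center_angle=90.0),
        LoadCaseConfig(name="angled", peak_pressure=0.3, sector_center_angle=45.0),
    ]
    solver: SolverConfig = SolverConfig()
    mesh_target_edge: float = Field(default=0.9, gt=0)
    output_dir: str = "results"
    seed: int = 0

    def material_map(self, variant: VariantId) -> fem.MaterialMap:
        mm = {}
        for lab in SubdomainLabel:
            mc = self.materials[lab.value]
            mm[lab] = fem.Material(E=mc.E, nu=mc.nu)
        if variant is VariantId.NO_SOC:
            mm[SubdomainLabel.STIFF_INSERT] = mm[SubdomainLabel.EPIPHYSEAL_CARTILAGE]
        return fem.MaterialMap(mm)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(data)


# ---------------------------------------------------------------------------
# VTK (legacy ASCII) writer / reader
# ---------------------------------------------------------------------------


def write_vtk(
    mesh: PlanarMesh,
    path: str | Path,
    *,
    point_data: dict[str, np.ndarray] | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
    coordinates: np.ndarray | None = None,
) -> Path:
    """Write the (corner-node) mesh and fields as legacy ASCII VTK.

    ``coordinates`` overrides node positions (deformed-shape output);
    point data must be sized to nodes, cell data to triangles.
    """
    path = Path(path)
    coords = mesh.nodes if coordinates is None else np.asarray(coordinates)
    if coords.shape[0] != mesh.n_nodes:
        raise ValueError("coordinate array does not match node count")
    for name, arr in (point_data or {}).items():
        if len(arr) != mesh.n_nodes:
            raise ValueError(f"point data {name!r} does not match node count")
    for name, arr in (cell_data or {}).items():
        if len(arr) != mesh.n_elements:
            raise ValueError(f"cell data {name!r} does not match cell count")

    buf = _io.StringIO()
    buf.write("# vtk DataFile Version 3.0\nepimech mesh\nASCII\n")
    buf.write("DATASET UNSTRUCTURED_GRID\n")
    buf.write(f"POINTS {mesh.n_nodes} double\n")
    for x, y in coords:
        buf.write(f"{x:.17g} {y:.17g} 0\n")
    m = mesh.n_elements
    buf.write(f"CELLS {m} {4 * m}\n")
    for tri in mesh.triangles:
        buf.write(f"3 {tri[0]} {tri[1]} {tri[2]}\n")
    buf.write(f"CELL_TYPES {m}\n")
    buf.write("\n".join(["5"] * m) + "\n")
    buf.write(f"CELL_DATA {m}\n")
    buf.write("SCALARS subdomain int 1\nLOOKUP_TABLE default\n")
    buf.write("\n".join(str(int(l)) for l in mesh.labels) + "\n")
    for name, arr in (cell_data or {}).items():
        buf.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
        buf.write("\n".join(f"{v:.17g}" for v in np.asarray(arr, float)) + "\n")
    if point_data:
        buf.write(f"POINT_DATA {mesh.n_nodes}\n")
        for name, arr in point_data.items():
            arr = np.asarray(arr, float)
            if arr.ndim == 2:
                buf.write(f"VECTORS {name} double\n")
                for row in arr:
                    buf.write(f"{row[0]:.17g} {row[1]:.17g} 0\n")
            else:
                buf.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                buf.write("\n".join(f"{v:.17g}" for v in arr) + "\n")
    path.write_text(buf.getvalue())
    return path


def read_vtk_mesh(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read back points, triangles and subdomain labels from a VTK file."""
    tokens = Path(path).read_text().split("\n")
    i = 0
    pts = tris = labels = None
    while i < len(tokens):
        line = tokens[i].strip()
        if line.startswith("POINTS"):
            n = int(line.split()[1])
            pts = np.array(
                [list(map(float, tokens[i + 1 + j].split()))[:2] for j in range(n)]
            )
            i += n
        elif line.startswith("CELLS"):
            m = int(line.split()[1])
            tris = np.array(
                [list(map(int, tokens[i + 1 + j].split()))[1:] for j in range(m)]
            )
            i += m
        elif line.startswith("SCALARS subdomain"):
            m = len(tris)
            labels = np.array([int(tokens[i + 2 + j]) for j in range(m)])
            i += m + 1
        i += 1
    return pts, tris, labels


# ---------------------------------------------------------------------------
# curve tables
# ---------------------------------------------------------------------------

_MECH_COLUMNS = {"time_s", "position_mm", "load_N"}


def write_curve_table(obj, path: str | Path) -> Path:
    """Write a force–distance curve or load–deformation record as CSV.

    The metadata block (including any generator ground truth) is embedded
    as ``# key: json`` header comments and round-trips through
    :func:`read_curve_table`.
    """
    path = Path(path)
    lines = []
    if isinstance(obj, LoadDeformationRecord):
        meta = {
            "kind": "load_deformation",
            "load_rate_N_per_s": obj.load_rate_N_per_s,
            "specimen_id": obj.specimen_id,
            "orientation": obj.orientation,
            **obj.metadata,
        }
        t = np.arange(len(obj.load_N)) * 1.0
        df = pd.DataFrame(
            {"time_s": t, "position_mm": obj.position_mm, "load_N": obj.load_N}
        )
    elif isinstance(obj, ForceDistanceCurve):
        meta = {
            "kind": "force_distance",
            "spring_constant_N_per_m": obj.spring_constant_N_per_m,
            "tip_radius_um": obj.tip_radius_um,
            "direction": obj.direction,
            "instrument": obj.instrument,
            **obj.metadata,
        }
        cols = {"z_um": obj.z_um}
        if obj.deflection_nm is not None:
            cols["deflection_nm"] = obj.deflection_nm
        else:
            cols["force_nN"] = obj.force_nN
        df = pd.DataFrame(cols)
    else:
        raise TypeError(f"cannot serialize {type(obj).__name__}")
    for k, v in meta.items():
        lines.append(f"# {k}: {json.dumps(v)}")
    csv = df.to_csv(index=False, float_format=_FLOAT_FMT)
    path.write_text("\n".join(lines) + "\n" + csv)
    return path


class CurveParseError(ValueError):
    pass


_UNIT_SUFFIXES = ("_mm", "_N", "_um", "_nN", "_nm", "_s")


def read_curve_table(path: str | Path, dialect: str | None = None):
    """Read a CSV/TSV curve table into a typed record.

    Column units are validated from the header suffixes (_mm, _N, _um,
    _nN, _nm); a missing or differently-suffixed column is a parse error
    naming the column.
    """
    path = Path(path)
    meta: dict = {}
    header_lines = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                header_lines += 1
                body = line[1:].strip()
                if ":" in body:
                    k, v = body.split(":", 1)
                    try:
                        meta[k.strip()] = json.loads(v.strip())
                    except json.JSONDecodeError:
                        meta[k.strip()] = v.strip()
            else:
                break
    sep = "\t" if (dialect == "tsv" or path.suffix.lower() == ".tsv") else ","
    df = pd.read_csv(path, skiprows=header_lines, sep=sep)
    if df.empty:
        raise CurveParseError("empty data section")
    for col in df.columns:
        if not col.endswith(_UNIT_SUFFIXES):
            raise CurveParseError(
                f"column {col!r} lacks a recognized unit suffix {_UNIT_SUFFIXES}"
            )
    kind = meta.pop("kind", None)
    if kind == "load_deformation" or _MECH_COLUMNS <= set(df.columns):
        missing = _MECH_COLUMNS - set(df.columns)
        if missing:
            raise CurveParseError(f"missing column(s) {sorted(missing)}")
        rec = LoadDeformationRecord(
            position_mm=df["position_mm"].to_numpy(),
            load_N=df["load_N"].to_numpy(),
            load_rate_N_per_s=meta.pop("load_rate_N_per_s", 0.1),
            specimen_id=meta.pop("specimen_id", ""),
            orientation=meta.pop("orientation", "vertical"),
        )
        rec.metadata.update(meta)
        return rec
    if kind == "force_distance" or "z_um" in df.columns:
        if "z_um" not in df.columns:
            raise CurveParseError("missing column 'z_um'")
        kwargs = {}
        if "deflection_nm" in df.columns:
            kwargs["deflection_nm"] = df["deflection_nm"].to_numpy()
        elif "force_nN" in df.columns:
            kwargs["force_nN"] = df["force_nN"].to_numpy()
        else:
            raise CurveParseError("missing column 'deflection_nm' or 'force_nN'")
        curve = ForceDistanceCurve(
            z_um=df["z_um"].to_numpy(),
            spring_constant_N_per_m=meta.pop("spring_constant_N_per_m"),
            tip_radius_um=meta.pop("tip_radius_um"),
            direction=meta.pop("direction", "retract"),
            instrument=meta.pop("instrument", "afm"),
            **kwargs,
        )
        curve.metadata.update(meta)
        return curve
    raise CurveParseError("unrecognized curve table layout")


# ---------------------------------------------------------------------------
# simulation driver
# ---------------------------------------------------------------------------


@dataclass
class ResultBundle:
    """Complete output of one simulation run."""

    output_dir: Path
    summary: pd.DataFrame  # one row per (variant, load case)
    zone_rows: pd.DataFrame  # long-format zone summaries
    meshes: dict[str, PlanarMesh]
    solutions: dict[tuple[str, str], fem.Solution]


def run_simulation(config: RunConfig, write_fields: bool = True) -> ResultBundle:
    """Mesh, solve, post-process and export every (variant, load case).

    The growth-plate band summaries (peak/mean of each stress measure, per
    third) plus the deflection under the load sector go into one summary
    row per combination; fields are exported to VTK on both reference and
    deformed coordinates.  Any stage failure aborts the run with a
    stage-named error; partial logs are preserved.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(
        yaml.safe_dump(json.loads(config.model_dump_json()), sort_keys=True)
    )

    params = config.geometry.to_params()
    bc = fem.BoundaryConditions.epiphysis_default()
    rows = []
    zone_rows = []
    meshes: dict[str, PlanarMesh] = {}
    solutions: dict[tuple[str, str], fem.Solution] = {}

    for vname in config.variants:
        variant = VariantId(vname)
        try:
            geom = geometry.build_geometry(params, variant)
            mesh = geometry.generate_mesh(geom, config.mesh_target_edge)
        except Exception as exc:
            raise RuntimeError(f"[stage: mesh/{vname}] {exc}") from exc
        meshes[vname] = mesh
        if write_fields:
            write_vtk(mesh, out / f"mesh_{vname}.vtk")
        mat = config.material_map(variant)
        band = mesh.elements_with_label(SubdomainLabel.GROWTH_PLATE_BAND)

        for lc_cfg in config.load_cases:
            lc_name = lc_cfg.name or f"sector{lc_cfg.sector_center_angle:g}"
            load = lc_cfg.to_load()
            try:
                sol = fem.assemble_and_solve(
                    mesh, mat, bc, load, config.solver.to_options()
                )
            except fem.NonConvergenceError as exc:
                raise RuntimeError(f"[stage: solve/{vname}/{lc_name}] {exc}") from exc
            solutions[(vname, lc_name)] = sol
            S = stress.second_pk_stress(sol, mesh, mat)
            sc = stress.scalar_measures(S)
            defl = stress.deflection(sol, mesh, load)
            summary = stress.zone_summary(sc, mesh, band, zone="growth_plate_band")
            thirds = geometry.band_thirds(mesh, band)
            row = {
                "variant": vname,
                "load_case": lc_name,
                "peak_pressure_MPa": lc_cfg.peak_pressure,
                "deflection_mm": defl,
                "band_elements": summary.n_elements,
            }
            for m, v in summary.peak.items():
                row[f"band_peak_{m}"] = v
            for m, v in summary.mean.items():
                row[f"band_mean_{m}"] = v
            rows.append(row)
            for zname, zel in [("band", band)] + list(thirds.items()):
                zs = stress.zone_summary(sc, mesh, zel, zone=zname)
                for m in zs.peak:
                    zone_rows.append(
                        {
                            "variant": vname,
                            "load_case": lc_name,
                            "zone": zname,
                            "measure": m,
                            "peak": zs.peak[m],
                            "mean": zs.mean[m],
                        }
                    )
            if write_fields:
                cell_data = {
                    "tau_oct_MPa": sc.tau_oct,
                    "hydrostatic_MPa": sc.hydrostatic,
                    "min_principal_MPa": sc.s3,
                }
                u_corner = sol.u[: mesh.n_nodes]
                write_vtk(
                    mesh,
                    out / f"fields_{vname}_{lc_name}_reference.vtk",
                    cell_data=cell_data,
                    point_data={"displacement_mm": u_corner},
                )
                write_vtk(
                    mesh,
                    out / f"fields_{vname}_{lc_name}_deformed.vtk",
                    cell_data=cell_data,
                    coordinates=stress.deformed_coordinates(mesh, sol),
                )
                conv = pd.DataFrame(
                    [
                        {
                            "load_fraction": s.load_fraction,
                            "iterations": s.iterations,
                            "final_residual": s.residuals[-1] if s.residuals else 0.0,
                        }
                        for s in sol.steps
                    ]
                )
                conv.to_csv(
                    out / f"convergence_{vname}_{lc_name}.csv",
                    index=False,
                    float_format=_FLOAT_FMT,
                )

    summary = pd.DataFrame(rows)
    zones = pd.DataFrame(zone_rows)
    summary.to_csv(out / "summary.csv", index=False, float_format=_FLOAT_FMT)
    zones.to_csv(out / "zone_summaries.csv", index=False, float_format=_FLOAT_FMT)
    logger.info("run complete: %d combinations -> %s", len(rows), out)
    return ResultBundle(
        output_dir=out,
        summary=summary,
        zone_rows=zones,
        meshes=meshes,
        solutions=solutions,
    )
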