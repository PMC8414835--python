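"""File I/O: patient table, contour CSV, VTK export, HDF5 run containers.

Clinical units at every file boundary (mmHg, mm, L/min).  VTK output is
ASCII XML (.vtu unstructured grids, .vtp polydata, .pvd time-series
manifests) written directly; a matching minimal reader exists for round-trip
verification.  Full runs go into one HDF5 container with the configuration
and seed stored as attributes.
"""

from __future__ import annotations

import ast
import importlib.resources
import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .geometry import Contour, ContourStack, LumenSurfaceMesh, WallMesh
from .wall_fem import WallState, von_mises

__all__ = [
    "PatientRecord",
    "read_patient_table",
    "default_patient_table_path",
    "stack_to_csv",
    "stack_from_csv",
    "write_vtu",
    "read_vtu",
    "write_pvd",
    "export_wall_state",
    "export_surface",
    "export_contours_vtp",
    "save_run",
    "load_run_attrs",
]


class TableError(ValueError):
    pass


@dataclass(frozen=True)
class PatientRecord:
    """One row of the patient summary table."""

    id: str
    d_max: float  # mm
    l_aaa: float  # cm
    brachial_dia: float  # mmHg
    brachial_sys: float  # mmHg
    group: str  # S | M | L


def default_patient_table_path() -> Path:
    return Path(importlib.resources.files("aaafsi") / "data" / "patient_table.csv")


def _group_from_dmax(d: float) -> str:
    if d < 39.5:
        return "S"
    if d < 49.5:
        return "M"
    return "L"


def read_patient_table(path=None) -> list[PatientRecord]:
    """Read and validate the patient table CSV.

    Expects columns id, d_max_mm, l_aaa_cm, brachial_dia_mmhg,
    brachial_sys_mmhg; the size group is recomputed from the maximum
    diameter and checked against the id prefix.  Malformed rows are reported
    with their line numbers.
    """
    p = Path(path) if path is not None else default_patient_table_path()
    df = pd.read_csv(p)
    required = ["id", "d_max_mm", "l_aaa_cm", "brachial_dia_mmhg", "brachial_sys_mmhg"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableError(f"{p}: missing columns {missing}")
    records = []
    errors = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            rec = PatientRecord(
                id=str(row["id"]),
                d_max=float(row["d_max_mm"]),
                l_aaa=float(row["l_aaa_cm"]),
                brachial_dia=float(row["brachial_dia_mmhg"]),
                brachial_sys=float(row["brachial_sys_mmhg"]),
                group=_group_from_dmax(float(row["d_max_mm"])),
            )
        except (TypeError, ValueError) as err:
            errors.append(f"line {line}: {err}")
            continue
        if rec.brachial_sys <= rec.brachial_dia:
            errors.append(f"line {line} ({rec.id}): systolic <= diastolic")
            continue
        if not rec.id.startswith(rec.group):
            errors.append(
                f"line {line} ({rec.id}): id prefix inconsistent with computed "
                f"group {rec.group} (d_max {rec.d_max} mm)"
            )
            continue
        records.append(rec)
    if errors:
        raise TableError(f"{p}: " + "; ".join(errors))
    return records


# --------------------------------------------------------------------------- #
# contour CSV
# --------------------------------------------------------------------------- #

_STACK_COLUMNS = [
    "station_mm", "cx_mm", "cy_mm", "cz_mm", "major_mm", "minor_mm",
    "rotation_rad", "nx", "ny", "nz",
]


def stack_to_csv(stack: ContourStack, path) -> None:
    rows = [
        [c.axial_station, *c.center, c.major_radius, c.minor_radius, c.rotation, *c.normal]
        for c in stack.contours
    ]
    df = pd.DataFrame(rows, columns=_STACK_COLUMNS)
    df.attrs["frame_label"] = stack.frame_label
    with open(path, "w") as fh:
        span = f"({stack.native_span[0]!r},{stack.native_span[1]!r})"
        fh.write(
            f"# frame_label={stack.frame_label} spacing={stack.spacing!r} "
            f"elongated={stack.elongated} native_span={span}\n"
        )
        df.to_csv(fh, index=False)


def stack_from_csv(path) -> ContourStack:
    with open(path) as fh:
        header = fh.readline()
        df = pd.read_csv(fh)
    meta = dict(tok.split("=", 1) for tok in header.lstrip("# ").split() if "=" in tok)
    contours = [
        Contour(
            center=np.array([r.cx_mm, r.cy_mm, r.cz_mm]),
            major_radius=r.major_mm,
            minor_radius=r.minor_mm,
            normal=np.array([r.nx, r.ny, r.nz]),
            rotation=r.rotation_rad,
            axial_station=r.station_mm,
        )
        for r in df.itertuples()
    ]
    return ContourStack(
        contours=contours,
        spacing=float(ast.literal_eval(meta.get("spacing", "1.0"))),
        frame_label=meta.get("frame_label", "diastole"),
        elongated=meta.get("elongated", "False") == "True",
        native_span=tuple(ast.literal_eval(meta.get("native_span", "(0.0,0.0)"))),
    )


# --------------------------------------------------------------------------- #
# VTK XML writers (+ minimal reader for round trips)
# --------------------------------------------------------------------------- #

_VTK_QUAD = 9
_VTK_HEX = 12


def _fmt(a: np.ndarray) -> str:
    return " ".join(repr(float(x)) for x in np.asarray(a, dtype=float).ravel())


def write_vtu(path, points: np.ndarray, cells: np.ndarray, cell_type: int,
              point_data: dict | None = None) -> None:
    """Write an ASCII XML .vtu unstructured grid."""
    points = np.asarray(points, dtype=float)
    cells = np.asarray(cells, dtype=int)
    n_pts, n_cells = len(points), len(cells)
    k = cells.shape[1]
    pd_xml = ""
    for name, arr in (point_data or {}).items():
        arr = np.asarray(arr)
        ncomp = 1 if arr.ndim == 1 else arr.shape[1]
        pd_xml += (
            f'<DataArray type="Float64" Name="{name}" '
            f'NumberOfComponents="{ncomp}" format="ascii">{_fmt(arr)}</DataArray>\n'
        )
    xml = f"""<?xml version="1.0"?>
<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">
<UnstructuredGrid>
<Piece NumberOfPoints="{n_pts}" NumberOfCells="{n_cells}">
<Points>
<DataArray type="Float64" NumberOfComponents="3" format="ascii">{_fmt(points)}</DataArray>
</Points>
<Cells>
<DataArray type="Int64" Name="connectivity" format="ascii">{" ".join(map(str, cells.ravel()))}</DataArray>
<DataArray type="Int64" Name="offsets" format="ascii">{" ".join(str(k * (i + 1)) for i in range(n_cells))}</DataArray>
<DataArray type="UInt8" Name="types" format="ascii">{" ".join([str(cell_type)] * n_cells)}</DataArray>
</Cells>
<PointData>
{pd_xml}</PointData>
</Piece>
</UnstructuredGrid>
</VTKFile>
"""
    Path(path).write_text(xml)


def read_vtu(path) -> tuple[np.ndarray, np.ndarray, dict]:
    """Read back a .vtu written by :func:`write_vtu`."""
    root = ET.parse(path).getroot()
    piece = root.find(".//Piece")
    pts = np.fromstring(piece.find("Points/DataArray").text, sep=" ").reshape(-1, 3)
    conn = np.fromstring(
        piece.find("Cells/DataArray[@Name='connectivity']").text, dtype=int, sep=" "
    )
    offsets = np.fromstring(
        piece.find("Cells/DataArray[@Name='offsets']").text, dtype=int, sep=" "
    )
    k = offsets[0]
    cells = conn.reshape(-1, k)
    point_data = {}
    for da in piece.findall("PointData/DataArray"):
        arr = np.fromstring(da.text, sep=" ")
        ncomp = int(da.get("NumberOfComponents", "1"))
        point_data[da.get("Name")] = arr.reshape(-1, ncomp) if ncomp > 1 else arr
    return pts, cells, point_data


def write_pvd(path, entries: list[tuple[float, str]]) -> None:
    """Write a .pvd manifest: one (time, file) entry per saved step."""
    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="Collection" version="0.1" byte_order="LittleEndian">',
        "<Collection>",
    ]
    for t, f in entries:
        lines.append(f'<DataSet timestep="{t!r}" group="" part="0" file="{f}"/>')
    lines += ["</Collection>", "</VTKFile>", ""]
    Path(path).write_text("\n".join(lines))


def _hex27_to_linear(mesh: WallMesh) -> np.ndarray:
    """Subdivide each 27-node hex into 8 linear hexes for VTK display."""
    out = []
    for e in mesh.hex_elements:
        lat = e.reshape(3, 3, 3)  # [c, b, a]
        for c in range(2):
            for b in range(2):
                for a in range(2):
                    out.append([
                        lat[c, b, a], lat[c, b, a + 1], lat[c, b + 1, a + 1], lat[c, b + 1, a],
                        lat[c + 1, b, a], lat[c + 1, b, a + 1], lat[c + 1, b + 1, a + 1], lat[c + 1, b + 1, a],
                    ])
    return np.array(out, dtype=int)


def export_wall_state(mesh: WallMesh, state: WallState, path) -> None:
    """Wall mesh + state to .vtu: displacement, von Mises, node-set masks."""
    cells = _hex27_to_linear(mesh)
    vm_nodal = _gauss_to_nodal_vm(mesh, state)
    point_data = {"displacement_mm": state.displacement, "von_mises_kpa": vm_nodal}
    for name, ids in mesh.node_sets.items():
        mask = np.zeros(mesh.n_nodes)
        mask[ids] = 1.0
        point_data[f"set_{name}"] = mask
    write_vtu(path, mesh.nodes + state.displacement, cells, _VTK_HEX, point_data)


def _gauss_to_nodal_vm(mesh: WallMesh, state: WallState) -> np.ndarray:
    vm = von_mises(state.cauchy_stress)  # (ne, 27)
    out = np.zeros(mesh.n_nodes)
    cnt = np.zeros(mesh.n_nodes)
    # nearest-gauss-point lumping: local gauss grid matches the local node grid
    np.add.at(out, mesh.hex_elements, vm)
    np.add.at(cnt, mesh.hex_elements, 1.0)
    return out / np.maximum(cnt, 1.0)


def export_surface(surface: LumenSurfaceMesh, path, point_data: dict | None = None) -> None:
    write_vtu(path, surface.nodes, surface.quads, _VTK_QUAD, point_data)


def export_contours_vtp(stack: ContourStack, path, n_theta: int = 64) -> None:
    """Contour rings as VTK polydata polylines."""
    rings = stack.sample_points(n_theta)
    n, m = rings.shape[0], n_theta
    pts = rings.reshape(-1, 3)
    lines = []
    for i in range(n):
        ids = list(range(i * m, (i + 1) * m)) + [i * m]
        lines.append(ids)
    conn = " ".join(" ".join(map(str, l)) for l in lines)
    offs = " ".join(str((m + 1) * (i + 1)) for i in range(n))
    xml = f"""<?xml version="1.0"?>
<VTKFile type="PolyData" version="0.1" byte_order="LittleEndian">
<PolyData>
<Piece NumberOfPoints="{len(pts)}" NumberOfLines="{n}">
<Points>
<DataArray type="Float64" NumberOfComponents="3" format="ascii">{_fmt(pts)}</DataArray>
</Points>
<Lines>
<DataArray type="Int64" Name="connectivity" format="ascii">{conn}</DataArray>
<DataArray type="Int64" Name="offsets" format="ascii">{offs}</DataArray>
</Lines>
</Piece>
</PolyData>
</VTKFile>
"""
    Path(path).write_text(xml)


# --------------------------------------------------------------------------- #
# HDF5 run container
# --------------------------------------------------------------------------- #


def save_run(path, result, config: dict, seed: int) -> None:
    """Save one FSI arm to HDF5 with config and seed as attributes."""
    with h5py.File(path, "w") as f:
        f.attrs["config_json"] = json.dumps(config, sort_keys=True)
        f.attrs["seed"] = int(seed)
        f.attrs["prestressed"] = bool(result.prestressed)
        for name in ("time", "stations", "pressure", "flow", "wss", "radii",
                     "displacements", "native_mask"):
            f.create_dataset(name, data=getattr(result, name))
        for tag in ("systolic", "diastolic"):
            st = getattr(result, f"{tag}_state")
            grp = f.create_group(tag)
            grp.create_dataset("displacement", data=st.displacement)
            grp.create_dataset("cauchy_stress", data=st.cauchy_stress)
            grp.attrs["applied_pressure"] = st.applied_pressure
            grp.attrs["prestressed"] = st.prestressed
        f.create_dataset("periodicity", data=np.asarray(result.periodicity))


def load_run_attrs(path) -> dict:
    with h5py.File(path, "r") as f:
        return {
            "config": json.loads(f.attrs["config_json"]),
            "seed": int(f.attrs["seed"]),
            "prestressed": bool(f.attrs["prestressed"]),
        }


def save_wall_state(path, state: WallState) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("displacement", data=state.displacement)
        f.create_dataset("cauchy_stress", data=state.cauchy_stress)
        f.attrs["applied_pressure"] = state.applied_pressure
        f.attrs["prestressed"] = state.prestressed


def load_wall_state(path) -> WallState:
    with h5py.File(path, "r") as f:
        return WallState(
            displacement=f["displacement"][()],
            cauchy_stress=f["cauchy_stress"][()],
            applied_pressure=float(f.attrs["applied_pressure"]),
            prestressed=bool(f.attrs["prestressed"]),
        )
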