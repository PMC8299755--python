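"""Cohort CSV round-trip and VTK export.

Cohorts are stored as two UTF-8 comma-separated files with header rows: a
wide per-patient table and a long-format deposit table keyed by patient id.
Floats are written with Python's shortest round-trip representation, so
``read_cohort(write_cohort(c)) == c`` field for field.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from .records import AorticRootGeometry, CalciumDeposit, PatientRecord

__all__ = [
    "CohortParseError",
    "write_cohort",
    "read_cohort",
    "write_vtk",
    "write_deposits_vtk",
    "deposits_path_for",
]

_COHORT_COLUMNS = [
    "id", "sex", "age", "bmi", "systolic_bp", "diastolic_bp", "lvef",
    "diabetes", "afib_history", "stroke_history", "icb_history",
    "avb_label", "applied_valve_size",
    "annulus_circumference", "wall_thickness", "annulus_height",
    "wall_stiffness", "root_volume", "leaflet_volume",
    "commissure_angle_ncc_rcc",
]

_DEPOSIT_COLUMNS = [
    "patient_id", "center_r", "center_phi", "center_z",
    "thickness", "length", "volume", "cusp", "shape",
    "end1_r", "end1_phi", "end1_z", "end2_r", "end2_phi", "end2_z",
]


class CohortParseError(ValueError):
    """Malformed cohort/deposit file; the message names the offending line."""


def deposits_path_for(cohort_path) -> Path:
    """Companion deposit-table path for a cohort table path."""
    p = Path(cohort_path)
    return p.with_name(p.stem + ".deposits" + p.suffix)


def write_cohort(cohort: list[PatientRecord], path, deposits_path=None) -> tuple[Path, Path]:
    """Write a cohort to ``path`` and its deposits to the companion file."""
    path = Path(path)
    deposits_path = Path(deposits_path) if deposits_path else deposits_path_for(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_COHORT_COLUMNS)
        for r in cohort:
            g = r.geometry
            w.writerow([
                r.id, r.sex, repr(r.age), repr(r.bmi), repr(r.systolic_bp),
                repr(r.diastolic_bp), repr(r.lvef),
                int(r.diabetes), int(r.afib_history), int(r.stroke_history),
                int(r.icb_history), r.avb_label, repr(r.applied_valve_size),
                repr(g.annulus_circumference), repr(g.wall_thickness),
                repr(g.annulus_height), repr(g.wall_stiffness),
                repr(g.root_volume), repr(g.leaflet_volume),
                repr(g.commissure_angle_ncc_rcc),
            ])
    with open(deposits_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_DEPOSIT_COLUMNS)
        for r in cohort:
            for d in r.deposits:
                ends = d.endpoints or ((None,) * 3, (None,) * 3)
                w.writerow([
                    r.id, repr(d.center[0]), repr(d.center[1]), repr(d.center[2]),
                    repr(d.thickness), repr(d.length), repr(d.volume),
                    d.cusp, d.shape,
                    *["" if v is None else repr(v) for e in ends for v in e],
                ])
    return path, deposits_path


def _parse_float(value: str, line: int, column: str, path) -> float:
    try:
        return float(value)
    except ValueError as exc:
        raise CohortParseError(
            f"{path}, line {line}: non-numeric value {value!r} in column {column!r}"
        ) from exc


def _parse_bool(value: str, line: int, column: str, path) -> bool:
    if value not in ("0", "1"):
        raise CohortParseError(
            f"{path}, line {line}: expected 0/1 in column {column!r}, got {value!r}"
        )
    return value == "1"


def read_cohort(path, deposits_path=None) -> list[PatientRecord]:
    """Read a cohort written by :func:`write_cohort`.

    Raises :class:`CohortParseError` (naming the file and line) on a
    malformed header, a non-numeric field, or a deposit row referencing an
    unknown patient id.
    """
    path = Path(path)
    deposits_path = Path(deposits_path) if deposits_path else deposits_path_for(path)

    deposits: dict[int, list[CalciumDeposit]] = {}
    with open(deposits_path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != _DEPOSIT_COLUMNS:
            raise CohortParseError(
                f"{deposits_path}, line 1: malformed header {header!r}"
            )
        for line_no, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(_DEPOSIT_COLUMNS):
                raise CohortParseError(
                    f"{deposits_path}, line {line_no}: expected "
                    f"{len(_DEPOSIT_COLUMNS)} fields, got {len(row)}"
                )
            rec = dict(zip(_DEPOSIT_COLUMNS, row))
            pid = int(_parse_float(rec["patient_id"], line_no, "patient_id", deposits_path))
            shape = rec["shape"]
            endpoints = None
            if shape == "irregular":
                endpoints = tuple(
                    tuple(
                        _parse_float(rec[f"end{k}_{c}"], line_no, f"end{k}_{c}", deposits_path)
                        for c in ("r", "phi", "z")
                    )
                    for k in (1, 2)
                )
            deposits.setdefault(pid, []).append(
                CalciumDeposit(
                    center=tuple(
                        _parse_float(rec[f"center_{c}"], line_no, f"center_{c}", deposits_path)
                        for c in ("r", "phi", "z")
                    ),
                    thickness=_parse_float(rec["thickness"], line_no, "thickness", deposits_path),
                    length=_parse_float(rec["length"], line_no, "length", deposits_path),
                    volume=_parse_float(rec["volume"], line_no, "volume", deposits_path),
                    cusp=rec["cusp"],
                    shape=shape,
                    endpoints=endpoints,
                )
            )

    cohort: list[PatientRecord] = []
    seen: set[int] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != _COHORT_COLUMNS:
            raise CohortParseError(f"{path}, line 1: malformed header {header!r}")
        for line_no, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(_COHORT_COLUMNS):
                raise CohortParseError(
                    f"{path}, line {line_no}: expected "
                    f"{len(_COHORT_COLUMNS)} fields, got {len(row)}"
                )
            rec = dict(zip(_COHORT_COLUMNS, row))
            pid = int(_parse_float(rec["id"], line_no, "id", path))
            seen.add(pid)
            geometry = AorticRootGeometry(
                annulus_circumference=_parse_float(rec["annulus_circumference"], line_no, "annulus_circumference", path),
                wall_thickness=_parse_float(rec["wall_thickness"], line_no, "wall_thickness", path),
                annulus_height=_parse_float(rec["annulus_height"], line_no, "annulus_height", path),
                wall_stiffness=_parse_float(rec["wall_stiffness"], line_no, "wall_stiffness", path),
                root_volume=_parse_float(rec["root_volume"], line_no, "root_volume", path),
                leaflet_volume=_parse_float(rec["leaflet_volume"], line_no, "leaflet_volume", path),
                commissure_angle_ncc_rcc=_parse_float(rec["commissure_angle_ncc_rcc"], line_no, "commissure_angle_ncc_rcc", path),
            )
            cohort.append(
                PatientRecord(
                    id=pid,
                    sex=rec["sex"],
                    age=_parse_float(rec["age"], line_no, "age", path),
                    bmi=_parse_float(rec["bmi"], line_no, "bmi", path),
                    systolic_bp=_parse_float(rec["systolic_bp"], line_no, "systolic_bp", path),
                    diastolic_bp=_parse_float(rec["diastolic_bp"], line_no, "diastolic_bp", path),
                    lvef=_parse_float(rec["lvef"], line_no, "lvef", path),
                    diabetes=_parse_bool(rec["diabetes"], line_no, "diabetes", path),
                    afib_history=_parse_bool(rec["afib_history"], line_no, "afib_history", path),
                    stroke_history=_parse_bool(rec["stroke_history"], line_no, "stroke_history", path),
                    icb_history=_parse_bool(rec["icb_history"], line_no, "icb_history", path),
                    geometry=geometry,
                    deposits=deposits.pop(pid, []),
                    avb_label=int(_parse_float(rec["avb_label"], line_no, "avb_label", path)),
                    applied_valve_size=_parse_float(rec["applied_valve_size"], line_no, "applied_valve_size", path),
                )
            )
    if deposits:
        orphan = sorted(deposits)[0]
        raise CohortParseError(
            f"{deposits_path}: deposit rows reference unknown patient id {orphan}"
        )
    return cohort


def write_deposits_vtk(remodeled, path) -> Path:
    """Write remodeled deposit centers (and rod endpoints) as legacy VTK.

    Centers carry the deposit thickness as point data; irregular deposits
    contribute line cells between their endpoints for visual inspection of
    the displacement/rotation step.
    """
    from .records import cyl_to_cart

    path = Path(path)
    points: list[np.ndarray] = []
    thickness: list[float] = []
    lines: list[tuple[int, int]] = []
    for rd in remodeled:
        dep = rd.deposit
        points.append(cyl_to_cart(dep.center))
        thickness.append(dep.thickness)
        if dep.endpoints is not None:
            i0 = len(points)
            points.append(cyl_to_cart(dep.endpoints[0]))
            points.append(cyl_to_cart(dep.endpoints[1]))
            thickness.extend([dep.thickness, dep.thickness])
            lines.append((i0, i0 + 1))
    lines_block = [f"2 {a} {b}" for a, b in lines]
    text = [
        "# vtk DataFile Version 3.0",
        "tavrisk remodeled calcium deposits",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(points)} double",
        *(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}" for p in points),
        f"LINES {len(lines)} {3 * len(lines)}",
        *lines_block,
        f"POINT_DATA {len(points)}",
        "SCALARS thickness_mm double 1",
        "LOOKUP_TABLE default",
        *(f"{t:.9g}" for t in thickness),
    ]
    path.write_text("\n".join(text) + "\n", encoding="utf-8")
    return path


def write_vtk(mesh, path, point_data: dict[str, np.ndarray] | None = None) -> Path:
    """Write a hex mesh (and optional nodal fields) as legacy ASCII VTK.

    Vector fields (n, 3) become VECTORS; everything else SCALARS.
    """
    path = Path(path)
    lines = [
        "# vtk DataFile Version 3.0",
        "tavrisk annulus mesh",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    for p in mesh.node_coords:
        lines.append(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}")
    lines.append(f"CELLS {mesh.n_elements} {mesh.n_elements * 9}")
    for e in mesh.elements:
        lines.append("8 " + " ".join(str(int(i)) for i in e))
    lines.append(f"CELL_TYPES {mesh.n_elements}")
    lines.extend(["12"] * mesh.n_elements)  # VTK_HEXAHEDRON
    if point_data:
        lines.append(f"POINT_DATA {mesh.n_nodes}")
        for name, arr in point_data.items():
            arr = np.asarray(arr)
            if arr.ndim == 2 and arr.shape[1] == 3:
                lines.append(f"VECTORS {name} double")
                for v in arr:
                    lines.append(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}")
            else:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines.extend(f"{v:.9g}" for v in arr.ravel())
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
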