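"""Measurement error as a function of mesh resolution.

Scan-processing software lets the operator choose the final mesh
resolution (mean distance between connected vertices).  Finer meshes cost
memory and time; coarser ones bias every measurement.  This module
re-creates the standard experiment: remesh one model to a ladder of
coarser resolutions, recompute each measurement, and express each row as
a percentage error relative to the densest model

    error = |reference − model| / reference · 100 %

(the absolute value is used so that a model overshooting the reference
still reports a positive error).  The coarsest resolution whose errors
all stay below a tolerance is the recommended working resolution.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decimate import collapse_to_mean_edge
from .errors import PhytomeshError
from .geodesics import build_edge_graph, dijkstra_path
from .mesh import (
    MorphometricReport,
    TriangleMesh,
    boundary_loops,
    measure,
    validate_mesh,
)

__all__ = [
    "relative_error",
    "remesh_to_resolution",
    "resolution_study",
    "resolution_threshold",
    "ResolutionErrorTable",
]


def relative_error(reference_value: float, model_value: float) -> float:
    """Percentage deviation of ``model_value`` from ``reference_value``."""
    if reference_value == 0:
        raise ZeroDivisionError("relative error undefined for a zero reference")
    return abs(reference_value - model_value) / abs(reference_value) * 100.0


@dataclass
class ResolutionRow:
    target_mean_edge: float | None  # None for the reference model
    report: MorphometricReport
    path_length: float | None = None
    errors: dict[str, float] = field(default_factory=dict)


@dataclass
class ResolutionErrorTable:
    """Per-resolution measurements plus errors against the densest model.

    Rows are ordered coarse → fine; the last row is the reference (the
    input mesh itself) whose errors are identically zero.
    """

    rows: list[ResolutionRow]
    warnings: list[str] = field(default_factory=list)

    @property
    def reference(self) -> ResolutionRow:
        return self.rows[-1]

    def to_dataframe(self) -> pd.DataFrame:
        recs = []
        for i, row in enumerate(self.rows):
            rec = {
                "model": i + 1,
                "target_mean_edge_mm": row.target_mean_edge,
                "mean_edge_length_mm": row.report.mean_edge_length,
                "vertices": row.report.vertex_count,
                "faces": row.report.face_count,
                "area_mm2": row.report.area,
                "volume_mm3": row.report.volume,
                "sv_ratio": row.report.sv_ratio,
                "path_length_mm": row.path_length,
            }
            for k, v in row.errors.items():
                rec[f"{k}_error_pct"] = v
            recs.append(rec)
        return pd.DataFrame.from_records(recs)

    def to_csv(self) -> str:
        """Wide layout: one row per quantity, one column per model."""
        df = self.to_dataframe().set_index("model")
        buf = io.StringIO()
        df.T.to_csv(buf)
        return buf.getvalue()

    def to_json(self, **kw) -> str:
        df = self.to_dataframe()
        return json.dumps(
            {
                "models": json.loads(df.to_json(orient="records")),
                "warnings": self.warnings,
            },
            **kw,
        )


def remesh_to_resolution(
    mesh: TriangleMesh, target_mean_edge: float, iterations: int | None = None
) -> TriangleMesh:
    """Coarsen ``mesh`` until its mean edge length is ≈ ``target_mean_edge``.

    Stops inside the band ``target·[0.9, 1.1]``; topology (closedness,
    boundary loop count, genus) is preserved.  Coarsening only — the
    target must not be finer than the input's mean edge length.
    """
    return collapse_to_mean_edge(mesh, target_mean_edge, max_collapses=iterations)


def _snap(mesh: TriangleMesh, point: np.ndarray) -> int:
    d = np.linalg.norm(mesh.vertices - point[None, :], axis=1)
    return int(np.argmin(d))


def resolution_study(
    mesh: TriangleMesh,
    targets: list[float],
    measurements: tuple[str, ...] = ("area", "volume", "sv"),
    path: tuple[int, int] | None = None,
) -> ResolutionErrorTable:
    """Remesh to each target (coarse → fine) and tabulate Eq.-style errors.

    ``targets`` must be sorted coarse → fine; the finest model is the
    input mesh itself and serves as the reference.  ``path`` optionally
    names two vertex indices of the *input* mesh whose Dijkstra distance
    is measured on every model (endpoints are snapped to the nearest
    vertex after remeshing).
    """
    if not targets:
        raise ValueError("need at least one target resolution")
    if sorted(targets, reverse=True) != list(targets):
        raise ValueError("targets must be sorted coarse -> fine (decreasing mm)")
    warnings: list[str] = []
    want = set(measurements)
    rep = validate_mesh(mesh)
    if ("volume" in want or "sv" in want) and not (rep.is_closed and rep.is_manifold):
        warnings.append(
            "volume and S/V omitted: the surface is open "
            f"({rep.boundary_edge_count} boundary edges)"
        )
        want -= {"volume", "sv"}

    src_pt = dst_pt = None
    if path is not None:
        src_pt = mesh.vertices[path[0]].copy()
        dst_pt = mesh.vertices[path[1]].copy()

    models = [(t, remesh_to_resolution(mesh, t)) for t in targets]
    models.append((None, mesh))

    rows: list[ResolutionRow] = []
    for target, m in models:
        report = measure(m)
        plen = None
        if path is not None:
            g = build_edge_graph(m)
            plen = dijkstra_path(m, _snap(m, src_pt), _snap(m, dst_pt), graph=g).length
        rows.append(ResolutionRow(target_mean_edge=target, report=report, path_length=plen))

    ref = rows[-1]
    for row in rows:
        err: dict[str, float] = {}
        if "area" in want:
            err["area"] = relative_error(ref.report.area, row.report.area)
        if "volume" in want and ref.report.volume and row.report.volume:
            err["volume"] = relative_error(ref.report.volume, row.report.volume)
        if "sv" in want and ref.report.sv_ratio and row.report.sv_ratio:
            err["sv"] = relative_error(ref.report.sv_ratio, row.report.sv_ratio)
        if path is not None and ref.path_length:
            err["path"] = relative_error(ref.path_length, row.path_length)
        row.errors = err
    return ResolutionErrorTable(rows=rows, warnings=warnings)


def resolution_threshold(table: ResolutionErrorTable, tolerance_percent: float) -> float:
    """Coarsest mean edge length whose every error is ≤ the tolerance."""
    if not table.rows:
        raise ValueError("empty resolution table")
    for row in table.rows:  # coarse -> fine
        if row.errors and all(e <= tolerance_percent for e in row.errors.values()):
            return row.report.mean_edge_length
    raise PhytomeshError(
        f"no resolution in the table meets the {tolerance_percent}% tolerance"
    )
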