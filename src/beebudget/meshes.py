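"""Surface area and volume of calibrated, labelled specimen meshes.

Photogrammetric specimen models arrive as triangulated surfaces in
model units with per-face body-part labels (head / mesosoma / metasoma
/ wing / leg / ...).  This module loads them, applies scale-bar
calibration, and measures external surface area (sum of triangle
areas) and enclosed volume (divergence theorem: the absolute sum of
signed origin-tetrahedron volumes).

Per-tagma volume needs a closed region, but cutting a tagma out of a
closed body leaves boundary loops; those are fan-capped before the
signed-volume sum, and the cap area never enters surface area (which
reports external surface only).

Geometry file IO and global watertightness checks are delegated to
:mod:`trimesh`; label handling is layered on top because standard mesh
containers carry no per-face group names.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import trimesh

logger = logging.getLogger(__name__)

__all__ = [
    "TAGMA_LABELS",
    "APPENDAGE_LABELS",
    "MeshFormatError",
    "NotWatertightError",
    "CalibrationError",
    "LabeledMesh",
    "CalibrationRecord",
    "WatertightReport",
    "load_mesh",
    "write_obj",
    "read_label_sidecar",
    "write_label_sidecar",
    "apply_calibration",
    "surface_area",
    "volume",
    "watertight_report",
    "measure_specimen",
    "measurements_to_frame",
]

TAGMA_LABELS = ("head", "mesosoma", "metasoma")
APPENDAGE_LABELS = ("wing", "leg", "antenna", "tongue", "stinger", "other")

#: Faces thinner than this (mm^2) are treated as degenerate and dropped.
DEGENERATE_AREA_MM2 = 1e-12


class MeshFormatError(ValueError):
    """Unreadable or structurally invalid mesh file."""


class NotWatertightError(ValueError):
    """Volume requested for an open surface without capping."""


class CalibrationError(ValueError):
    """Scale verification failed against the known check lengths."""


@dataclass
class LabeledMesh:
    """A triangle mesh plus optional per-face tagma/appendage labels.

    ``face_labels`` is a length-``n_faces`` array of strings, or None
    for an unlabelled mesh (measured whole-body only, with a warning).
    """

    mesh: trimesh.Trimesh
    face_labels: np.ndarray | None = None
    units_calibrated: bool = False

    def __post_init__(self) -> None:
        if self.face_labels is not None:
            self.face_labels = np.asarray(self.face_labels, dtype=object)
            if len(self.face_labels) != len(self.mesh.faces):
                raise MeshFormatError(
                    f"{len(self.face_labels)} labels for "
                    f"{len(self.mesh.faces)} faces"
                )

    @property
    def labels(self) -> set[str]:
        if self.face_labels is None:
            return set()
        return set(self.face_labels.tolist())

    def face_mask(self, label_filter: str | Sequence[str] | None) -> np.ndarray:
        """Boolean mask over faces for a label (or iterable of labels)."""
        n = len(self.mesh.faces)
        if label_filter is None:
            return np.ones(n, dtype=bool)
        if self.face_labels is None:
            logger.warning(
                "mesh has no face labels; label filter %r ignores nothing "
                "— measuring whole mesh",
                label_filter,
            )
            return np.ones(n, dtype=bool)
        if isinstance(label_filter, str):
            label_filter = (label_filter,)
        wanted = set(label_filter)
        return np.fromiter(
            (lab in wanted for lab in self.face_labels), dtype=bool, count=n
        )


@dataclass(frozen=True)
class CalibrationRecord:
    """Scale-bar calibration: model units -> mm, with verification pairs.

    The scale factor is ``known_length_mm / measured_length_model_units``.
    Three independent (known mm, measured model-unit) pairs re-check the
    factor after scaling.
    """

    known_length_mm: float
    measured_length_model_units: float
    verification_lengths: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.known_length_mm <= 0 or self.measured_length_model_units <= 0:
            raise CalibrationError("calibration lengths must be positive")
        for known, measured in self.verification_lengths:
            if known <= 0 or measured <= 0:
                raise CalibrationError("verification lengths must be positive")

    @property
    def scale_factor(self) -> float:
        return self.known_length_mm / self.measured_length_model_units


@dataclass(frozen=True)
class WatertightReport:
    boundary_edge_count: int
    nonmanifold_edge_count: int
    winding_consistent: bool
    euler_characteristic: int
    watertight: bool


# ---------------------------------------------------------------------------
# IO

def _parse_obj_face_labels(path: Path) -> np.ndarray | None:
    """Per-face group labels from ``o``/``g`` lines, in file face order."""
    labels: list[str] = []
    current = None
    saw_group = False
    with open(path) as fh:
        for line in fh:
            if line.startswith(("o ", "g ")):
                current = line[2:].strip() or None
                saw_group = True
            elif line.startswith("f "):
                labels.append(current if current is not None else "other")
    if not saw_group or not labels:
        return None
    return np.asarray(labels, dtype=object)


def load_mesh(
    path: str | Path,
    label_sidecar: str | Path | None = None,
    units_calibrated: bool = False,
) -> LabeledMesh:
    """Load an OBJ/PLY/STL mesh, validate it, and attach face labels.

    Degenerate (zero-area) faces are removed with a logged count.
    Labels come from an explicit sidecar table if given, else from OBJ
    object/group lines; STL and unlabelled files yield no labels.
    """
    path = Path(path)
    if not path.exists():
        raise MeshFormatError(f"no such mesh file: {path}")
    suffix = path.suffix.lower()
    if suffix not in (".obj", ".ply", ".stl"):
        raise MeshFormatError(f"unsupported mesh format {suffix!r}")
    try:
        mesh = trimesh.load(str(path), file_type=suffix[1:], process=False)
    except Exception as exc:  # noqa: BLE001 - normalize loader failures
        raise MeshFormatError(f"could not read {path}: {exc}") from exc
    if isinstance(mesh, trimesh.Scene):
        geoms = list(mesh.geometry.values())
        if not geoms:
            raise MeshFormatError(f"{path} contains no geometry")
        mesh = trimesh.util.concatenate(geoms)
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise MeshFormatError(f"{path} contains no triangle faces")
    # STL stores per-face vertices; merge exact duplicates so edges connect
    mesh.merge_vertices(merge_tex=True, merge_norm=True)

    labels: np.ndarray | None = None
    if label_sidecar is not None:
        labels = read_label_sidecar(label_sidecar, n_faces=len(mesh.faces))
    elif suffix == ".obj":
        labels = _parse_obj_face_labels(path)
        if labels is not None and len(labels) != len(mesh.faces):
            logger.warning(
                "OBJ group labels (%d) do not match loaded face count (%d); "
                "ignoring labels",
                len(labels),
                len(mesh.faces),
            )
            labels = None

    areas = _triangle_areas(mesh.vertices, mesh.faces)
    keep = areas > DEGENERATE_AREA_MM2
    dropped = int((~keep).sum())
    if dropped:
        logger.info("removed %d degenerate faces from %s", dropped, path.name)
        mesh = trimesh.Trimesh(
            vertices=mesh.vertices, faces=mesh.faces[keep], process=False
        )
        if labels is not None:
            labels = labels[keep]
    return LabeledMesh(mesh, labels, units_calibrated=units_calibrated)


def write_obj(
    lm: LabeledMesh, path: str | Path, float_fmt: str = "%.17g"
) -> Path:
    """Write an OBJ with faces grouped by label (``o <label>`` blocks).

    Labelled faces are written grouped so the labels round-trip through
    :func:`load_mesh`; unlabelled meshes are written as a single object.
    """
    path = Path(path)
    v = np.asarray(lm.mesh.vertices, dtype=float)
    f = np.asarray(lm.mesh.faces, dtype=int)
    lines = ["# beebudget mesh export"]
    for x, y, z in v:
        lines.append("v %s %s %s" % (float_fmt % x, float_fmt % y, float_fmt % z))
    if lm.face_labels is None:
        order = [(None, np.arange(len(f)))]
    else:
        seen: list[str] = []
        for lab in lm.face_labels:
            if lab not in seen:
                seen.append(lab)
        order = [(lab, np.flatnonzero(lm.face_labels == lab)) for lab in seen]
    for lab, idx in order:
        if lab is not None:
            lines.append(f"o {lab}")
        for a, b, c in f[idx]:
            lines.append(f"f {a + 1} {b + 1} {c + 1}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_label_sidecar(path: str | Path, n_faces: int) -> np.ndarray:
    """Read a face-label sidecar: CSV with columns face_start,face_end,label.

    Ranges are inclusive 0-based face indices; unlisted faces get
    ``"other"``.
    """
    import pandas as pd

    df = pd.read_csv(path)
    labels = np.full(n_faces, "other", dtype=object)
    for _, row in df.iterrows():
        start, end = int(row["face_start"]), int(row["face_end"])
        if not (0 <= start <= end < n_faces):
            raise MeshFormatError(
                f"label range [{start}, {end}] outside 0..{n_faces - 1}"
            )
        labels[start : end + 1] = str(row["label"])
    return labels


def write_label_sidecar(lm: LabeledMesh, path: str | Path) -> Path:
    """Write contiguous face-label runs as a face_start,face_end,label CSV."""
    import pandas as pd

    if lm.face_labels is None:
        raise MeshFormatError("mesh has no face labels to write")
    rows = []
    start = 0
    labs = lm.face_labels
    for i in range(1, len(labs) + 1):
        if i == len(labs) or labs[i] != labs[start]:
            rows.append({"face_start": start, "face_end": i - 1, "label": labs[start]})
            start = i
    pd.DataFrame(rows).to_csv(path, index=False)
    return Path(path)


# ---------------------------------------------------------------------------
# calibration

def apply_calibration(
    lm: LabeledMesh,
    record: CalibrationRecord,
    rel_tolerance: float = 0.02,
) -> LabeledMesh:
    """Scale a model-unit mesh into mm and verify against known lengths.

    Every verification pair must satisfy
    ``|known - measured*scale| / known <= rel_tolerance`` (default 2%).
    """
    scale = record.scale_factor
    failures = [
        (known, measured)
        for known, measured in record.verification_lengths
        if abs(known - measured * scale) / known > rel_tolerance
    ]
    if failures:
        raise CalibrationError(
            f"scale factor {scale:.6g} fails verification beyond "
            f"{rel_tolerance:.1%} for pairs: {failures}"
        )
    scaled = lm.mesh.copy()
    scaled.apply_scale(scale)
    return LabeledMesh(
        scaled,
        None if lm.face_labels is None else lm.face_labels.copy(),
        units_calibrated=True,
    )


# ---------------------------------------------------------------------------
# measurement

def _triangle_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    v = np.asarray(vertices, dtype=float)
    f = np.asarray(faces, dtype=int)
    cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    return 0.5 * np.linalg.norm(cross, axis=1)


def surface_area(
    lm: LabeledMesh, label_filter: str | Sequence[str] | None = None
) -> float:
    """Total area (mm²) of faces passing the label filter.

    Half-cross-product sum over selected triangles.  An empty selection
    returns 0 with a warning rather than raising.
    """
    mask = lm.face_mask(label_filter)
    if not mask.any():
        logger.warning("label filter %r selects no faces; area = 0", label_filter)
        return 0.0
    return float(_triangle_areas(lm.mesh.vertices, lm.mesh.faces[mask]).sum())


def _boundary_loops(faces: np.ndarray) -> list[list[int]]:
    """Vertex loops of edges used exactly once, each closed and ordered."""
    edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    keys = np.sort(edges, axis=1)
    _, inverse, counts = np.unique(
        keys, axis=0, return_inverse=True, return_counts=True
    )
    boundary = edges[counts[inverse] == 1]
    if len(boundary) == 0:
        return []
    nxt = {int(a): int(b) for a, b in boundary}
    loops: list[list[int]] = []
    while nxt:
        start, cur = next(iter(nxt.items()))
        loop = [start]
        while cur != start:
            loop.append(cur)
            cur = nxt.pop(cur)
        nxt.pop(start, None)
        loops.append(loop)
    return loops


def _signed_volume(vertices: np.ndarray, faces: np.ndarray) -> float:
    v = np.asarray(vertices, dtype=float)
    f = np.asarray(faces, dtype=int)
    return float(np.einsum("ij,ij->i", v[f[:, 0]], np.cross(v[f[:, 1]], v[f[:, 2]])).sum() / 6.0)


def volume(
    lm: LabeledMesh,
    label_filter: str | Sequence[str] | None = None,
    cap_boundaries: bool = True,
) -> float:
    """Enclosed volume (mm³) of the faces passing the label filter.

    Uses the divergence theorem (signed origin-tetrahedra).  A closed
    selection is summed directly; an open one is planar-fan capped at
    each boundary loop first, or rejected with
    :class:`NotWatertightError` when ``cap_boundaries`` is false.
    Inconsistent winding is repaired via trimesh before summation so a
    stray flipped face can never silently corrupt the signed sum.
    """
    mask = lm.face_mask(label_filter)
    if not mask.any():
        logger.warning("label filter %r selects no faces; volume = 0", label_filter)
        return 0.0
    faces = np.asarray(lm.mesh.faces[mask], dtype=int)
    vertices = np.asarray(lm.mesh.vertices, dtype=float)

    sub = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    if not sub.is_winding_consistent:
        trimesh.repair.fix_normals(sub)
        if not sub.is_winding_consistent:
            raise NotWatertightError(
                "selection has inconsistent winding that could not be repaired"
            )
        faces = np.asarray(sub.faces, dtype=int)

    loops = _boundary_loops(faces)
    if loops:
        if not cap_boundaries:
            raise NotWatertightError(
                f"selection is not watertight ({len(loops)} boundary loops) "
                "and cap_boundaries is disabled"
            )
        cap_faces = []
        extra_vertices = []
        next_idx = len(vertices)
        for loop in loops:
            centroid = vertices[loop].mean(axis=0)
            extra_vertices.append(centroid)
            c = next_idx
            next_idx += 1
            for a, b in zip(loop, loop[1:] + loop[:1]):
                # the loop follows the interior faces' winding, so the cap
                # must traverse each edge the opposite way to close outward
                cap_faces.append((b, a, c))
        vertices = np.vstack([vertices, np.asarray(extra_vertices)])
        faces = np.vstack([faces, np.asarray(cap_faces, dtype=int)])
    return abs(_signed_volume(vertices, faces))


def watertight_report(lm: LabeledMesh) -> WatertightReport:
    """Boundary/non-manifold edge counts, winding, Euler characteristic."""
    mesh = lm.mesh
    faces = np.asarray(mesh.faces, dtype=int)
    edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    keys = np.sort(edges, axis=1)
    unique_edges, counts = np.unique(keys, axis=0, return_counts=True)
    n_boundary = int((counts == 1).sum())
    n_nonmanifold = int((counts > 2).sum())
    used_vertices = np.unique(faces)
    euler = int(len(used_vertices) - len(unique_edges) + len(faces))
    return WatertightReport(
        boundary_edge_count=n_boundary,
        nonmanifold_edge_count=n_nonmanifold,
        winding_consistent=bool(mesh.is_winding_consistent),
        euler_characteristic=euler,
        watertight=bool(
            n_boundary == 0 and n_nonmanifold == 0 and mesh.is_winding_consistent
        ),
    )


# ---------------------------------------------------------------------------
# specimen-level measurement

def measure_specimen(
    lm: LabeledMesh,
    specimen_id: str,
    include_whole_body: bool = True,
) -> list[dict]:
    """Measure per-tagma, tagmata-sum and whole-body SA/V of one specimen.

    Per-tagma rows use the face labels (appendages excluded from the
    tagmata sum); the whole-body row includes every face.  Returns rows
    matching :func:`measurements_to_frame`.
    """
    if not lm.units_calibrated:
        logger.warning(
            "%s: mesh not flagged units_calibrated; values are model units",
            specimen_id,
        )
    rows = []
    labelled = lm.face_labels is not None
    if labelled:
        sum_sa = 0.0
        sum_v = 0.0
        for tagma in TAGMA_LABELS:
            sa = surface_area(lm, tagma)
            vol = volume(lm, tagma)
            sum_sa += sa
            sum_v += vol
            rows.append(
                {
                    "specimen_id": specimen_id,
                    "method": "model_tagmata",
                    "scope": tagma,
                    "surface_area_mm2": sa,
                    "volume_mm3": vol,
                }
            )
        rows.append(
            {
                "specimen_id": specimen_id,
                "method": "model_tagmata",
                "scope": "tagmata_sum",
                "surface_area_mm2": sum_sa,
                "volume_mm3": sum_v,
            }
        )
    if include_whole_body or not labelled:
        rows.append(
            {
                "specimen_id": specimen_id,
                "method": "model_whole_body",
                "scope": "whole_body",
                "surface_area_mm2": surface_area(lm),
                "volume_mm3": volume(lm),
            }
        )
    return rows


def measurements_to_frame(rows: Iterable[dict]):
    import pandas as pd

    return pd.DataFrame(
        list(rows),
        columns=["specimen_id", "method", "scope", "surface_area_mm2", "volume_mm3"],
    )
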