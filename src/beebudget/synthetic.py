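"""Synthetic specimens, cohorts and thermal presets with known truth.

Everything the pipeline consumes can be generated here with its ground
truth attached, so every stage is testable without any specimen data:

* watertight tessellations of the ideal solids (icosphere, capped
  cylinder, cone, cylinder+cone metasoma) whose analytic surface area
  and volume are returned alongside, with conventions matched exactly
  to :mod:`beebudget.measurements`;
* a three-component "composite bee" mesh with per-face tagma labels;
* a smooth, seeded radial perturbation that deforms a solid away from
  its ideal shape while preserving watertightness and (per component)
  enclosed volume — a stand-in for the real-body deviation that the
  geometric method cannot see;
* measurement cohorts pairing "model" (true) with "geometric"
  (systematically deflated, noisy) per-tagma sizes, with every
  injected underestimation fraction recorded in a truth log;
* power-law (volume, surface-area) cohorts for scaling-exponent
  recovery;
* synthetic linear thermal-response coefficient sets, including a
  preset constructed so the fitted |Q_C| and |Q_R| lines cross at an
  exact target temperature.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import trimesh

from .budget import (
    DEFAULT_GRID_C,
    LinearResponse,
    RadiativeConstants,
    TagmaSurfaceAreas,
    ThermalModelSet,
    whole_body_radiative,
)
from .measurements import (
    DEFAULT_CONVENTION,
    EstimationConvention,
    LinearMeasurements,
    estimate_head,
    estimate_mesosoma,
    estimate_metasoma,
    estimate_specimen,
)
from .meshes import LabeledMesh

__all__ = [
    "BASELINE_WORKER",
    "SolidSpec",
    "CohortSpec",
    "SyntheticError",
    "make_sphere_mesh",
    "make_capped_cylinder_mesh",
    "make_cone_mesh",
    "make_metasoma_mesh",
    "make_composite_bee",
    "make_solid_mesh",
    "perturb_mesh",
    "simulate_cohort",
    "simulate_scaling_cohort",
    "default_thermal_models",
    "crossover_preset",
    "default_tagma_areas",
]


class SyntheticError(ValueError):
    """Invalid generator specification."""


#: Caliper measurements of a typical honey bee worker (mm), used as the
#: cohort baseline and for the default heat-budget surface areas.
BASELINE_WORKER = LinearMeasurements(
    specimen_id="baseline_worker",
    head_width_mm=3.5,
    head_thickness_mm=2.0,
    mesosoma_width_mm=4.0,
    metasoma_width_mm=4.2,
    metasoma_anterior_length_mm=4.0,
    metasoma_posterior_length_mm=3.5,
)

#: Underestimation fractions of geometric relative to model values, per
#: tagma and quantity.  Head and mesosoma biases are large and real;
#: the torpedo-shaped metasoma is well approximated by its solid, so
#: its bias is small (and statistically undetectable at cohort size).
DEFAULT_UNDERESTIMATION = {
    "head": {"volume": 0.393, "surface_area": 0.264},
    "mesosoma": {"volume": 0.503, "surface_area": 0.441},
    "metasoma": {"volume": 0.05, "surface_area": 0.05},
}


@dataclass(frozen=True)
class SolidSpec:
    """Specification of one analytic test solid.

    ``dimensions`` carries the solid's lengths in mm (keys depend on
    ``kind``); ``tessellation_level`` is icosphere subdivisions for
    spheres and the number of angular sections for cylinders/cones.
    """

    kind: str  # sphere | capped_cylinder | cone | composite_bee
    dimensions: Mapping[str, float]
    tessellation_level: int = 4


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a paired geometric-vs-model measurement cohort.

    n_specimens
        Cohort size (default 11 workers).
    size_sigma_log10_volume
        Spread of specimen size: sd of log10 body volume across the
        cohort (default 0.1, i.e. about ±26% volume at 1 sd).
    true_scaling_exponent
        Slope of log10(SA) on log10(V) in the true (model) values;
        2/3 is isometry.
    underestimation
        tagma -> {"volume": f, "surface_area": f} fractions in [0, 1)
        by which the geometric method understates the true value.
    noise_sd
        SD (natural-log scale) of the multiplicative log-normal noise
        on the observed geometric values (default 0.10, matching
        standard errors of a few percentage points at n = 11).
    shape_jitter_sd
        SD (natural-log scale) of independent per-measurement shape
        variation around isometric scaling (default 0.02).
    seed
        Mandatory RNG seed.
    """

    seed: int
    n_specimens: int = 11
    size_sigma_log10_volume: float = 0.1
    true_scaling_exponent: float = 2.0 / 3.0
    underestimation: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_UNDERESTIMATION
    )
    noise_sd: float = 0.10
    shape_jitter_sd: float = 0.02
    baseline: LinearMeasurements = BASELINE_WORKER

    def __post_init__(self) -> None:
        if self.n_specimens < 2:
            raise SyntheticError("n_specimens must be >= 2")
        for tagma, entry in self.underestimation.items():
            for quantity, f in entry.items():
                if not 0 <= f < 1:
                    raise SyntheticError(
                        f"underestimation[{tagma}][{quantity}] = {f} not in [0, 1)"
                    )
        if self.noise_sd < 0 or self.shape_jitter_sd < 0:
            raise SyntheticError("noise SDs must be >= 0")


# ---------------------------------------------------------------------------
# analytic solid meshes

MIN_SPHERE_SUBDIV = 2
MIN_SECTIONS = 16


def make_sphere_mesh(
    diameter_mm: float, subdivisions: int = 4
) -> tuple[trimesh.Trimesh, dict]:
    """Icosphere with vertices exactly on the sphere (inscribed).

    Because every vertex lies on the sphere, the tessellated surface is
    inscribed: its area and volume approach the analytic values from
    below, monotonically in the subdivision level.
    """
    if subdivisions < MIN_SPHERE_SUBDIV:
        raise SyntheticError(f"subdivisions must be >= {MIN_SPHERE_SUBDIV}")
    r = diameter_mm / 2.0
    mesh = trimesh.creation.icosphere(subdivisions=subdivisions, radius=r)
    truth = {
        "surface_area_mm2": math.pi * diameter_mm ** 2,
        "volume_mm3": math.pi * diameter_mm ** 3 / 6.0,
    }
    return mesh, truth


def _ring(radius: float, z: float, sections: int, phase: float = 0.0) -> np.ndarray:
    theta = phase + 2.0 * np.pi * np.arange(sections) / sections
    return np.column_stack(
        [radius * np.cos(theta), radius * np.sin(theta), np.full(sections, z)]
    )


def _fan(center_idx: int, ring: np.ndarray, flip: bool) -> list[tuple[int, int, int]]:
    n = len(ring)
    faces = []
    for i in range(n):
        j = (i + 1) % n
        if flip:
            faces.append((center_idx, ring[j], ring[i]))
        else:
            faces.append((center_idx, ring[i], ring[j]))
    return faces


def _band(lower: np.ndarray, upper: np.ndarray) -> list[tuple[int, int, int]]:
    n = len(lower)
    faces = []
    for i in range(n):
        j = (i + 1) % n
        faces.append((lower[i], lower[j], upper[j]))
        faces.append((lower[i], upper[j], upper[i]))
    return faces


def make_capped_cylinder_mesh(
    diameter_mm: float, length_mm: float, sections: int = 128
) -> tuple[trimesh.Trimesh, dict]:
    """Closed cylinder along +z with both end caps (inscribed prism)."""
    if sections < MIN_SECTIONS:
        raise SyntheticError(f"sections must be >= {MIN_SECTIONS}")
    r = diameter_mm / 2.0
    bottom = _ring(r, 0.0, sections)
    top = _ring(r, length_mm, sections)
    vertices = np.vstack([bottom, top, [[0, 0, 0]], [[0, 0, length_mm]]])
    ib = np.arange(sections)
    it = np.arange(sections) + sections
    c_bot, c_top = 2 * sections, 2 * sections + 1
    faces = _band(ib, it)
    faces += _fan(c_bot, ib, flip=True)  # bottom cap faces -z
    faces += _fan(c_top, it, flip=False)  # top cap faces +z
    mesh = trimesh.Trimesh(vertices=vertices, faces=np.asarray(faces), process=False)
    truth = {
        "surface_area_mm2": math.pi * diameter_mm * length_mm
        + 2.0 * math.pi * r * r,
        "volume_mm3": math.pi * r * r * length_mm,
    }
    return mesh, truth


def make_cone_mesh(
    diameter_mm: float, height_mm: float, sections: int = 128
) -> tuple[trimesh.Trimesh, dict]:
    """Closed cone (base cap + lateral surface), apex on +z."""
    if sections < MIN_SECTIONS:
        raise SyntheticError(f"sections must be >= {MIN_SECTIONS}")
    r = diameter_mm / 2.0
    base = _ring(r, 0.0, sections)
    vertices = np.vstack([base, [[0, 0, 0]], [[0, 0, height_mm]]])
    ib = np.arange(sections)
    c_base, apex = sections, sections + 1
    faces = _fan(c_base, ib, flip=True)
    faces += _fan(apex, ib, flip=False)
    mesh = trimesh.Trimesh(vertices=vertices, faces=np.asarray(faces), process=False)
    slant = math.hypot(r, height_mm)
    truth = {
        "surface_area_mm2": math.pi * r * slant + math.pi * r * r,
        "volume_mm3": math.pi * r * r * height_mm / 3.0,
    }
    return mesh, truth


def make_metasoma_mesh(
    width_mm: float,
    anterior_length_mm: float,
    posterior_length_mm: float,
    sections: int = 128,
) -> tuple[trimesh.Trimesh, dict]:
    """Cylinder+cone metasoma solid: anterior cap, cylinder, cone tip.

    The cylinder and cone share the junction ring, so the composite is
    watertight and the junction disc is not part of the surface —
    exactly the convention of
    :func:`beebudget.measurements.estimate_metasoma`.
    """
    if sections < MIN_SECTIONS:
        raise SyntheticError(f"sections must be >= {MIN_SECTIONS}")
    r = width_mm / 2.0
    length, h = anterior_length_mm, posterior_length_mm
    front = _ring(r, 0.0, sections)
    junction = _ring(r, length, sections)
    vertices = np.vstack(
        [front, junction, [[0, 0, 0]], [[0, 0, length + h]]]
    )
    i_front = np.arange(sections)
    i_junction = np.arange(sections) + sections
    c_front, apex = 2 * sections, 2 * sections + 1
    faces = _band(i_front, i_junction)
    faces += _fan(c_front, i_front, flip=True)
    faces += _fan(apex, i_junction, flip=False)
    mesh = trimesh.Trimesh(vertices=vertices, faces=np.asarray(faces), process=False)
    slant = math.hypot(r, h)
    truth = {
        "surface_area_mm2": math.pi * width_mm * length
        + math.pi * r * r
        + math.pi * r * slant,
        "volume_mm3": math.pi * r * r * length + math.pi * r * r * h / 3.0,
    }
    return mesh, truth


def make_composite_bee(
    measurements: LinearMeasurements = BASELINE_WORKER,
    tessellation_level: int = 4,
    sections: int = 128,
    convention: EstimationConvention = DEFAULT_CONVENTION,
) -> tuple[LabeledMesh, dict]:
    """Three-solid labelled bee: head cylinder, mesosoma sphere,
    metasoma cylinder+cone, laid out as disjoint components along +x.

    Returns the labelled mesh and an analytic truth dict holding the
    exact per-tagma and summed SA/V (identical, at infinite
    tessellation, to :func:`~beebudget.measurements.estimate_specimen`
    on the same measurements).
    """
    head, _ = make_capped_cylinder_mesh(
        measurements.head_thickness_mm
        if convention.head_diameter == "thickness"
        else measurements.head_width_mm,
        measurements.head_width_mm
        if convention.head_diameter == "thickness"
        else measurements.head_thickness_mm,
        sections=sections,
    )
    meso, _ = make_sphere_mesh(
        measurements.mesosoma_width_mm, subdivisions=tessellation_level
    )
    meta, _ = make_metasoma_mesh(
        measurements.metasoma_width_mm,
        measurements.metasoma_anterior_length_mm,
        measurements.metasoma_posterior_length_mm,
        sections=sections,
    )
    # disjoint layout: head at origin, mesosoma and metasoma shifted +x
    gap = 1.0
    dx = measurements.head_thickness_mm + measurements.mesosoma_width_mm + gap
    meso.apply_translation([dx, 0.0, 0.0])
    dx2 = dx + measurements.mesosoma_width_mm + measurements.metasoma_width_mm + gap
    meta.apply_translation([dx2, 0.0, 0.0])

    parts = [("head", head), ("mesosoma", meso), ("metasoma", meta)]
    vertices = []
    faces = []
    labels = []
    offset = 0
    for label, part in parts:
        vertices.append(np.asarray(part.vertices, dtype=float))
        faces.append(np.asarray(part.faces, dtype=int) + offset)
        labels.extend([label] * len(part.faces))
        offset += len(part.vertices)
    mesh = trimesh.Trimesh(
        vertices=np.vstack(vertices), faces=np.vstack(faces), process=False
    )
    record = estimate_specimen(measurements, convention)
    truth = {
        "per_tagma": {
            t: {
                "surface_area_mm2": record.tagma(t).surface_area_mm2,
                "volume_mm3": record.tagma(t).volume_mm3,
            }
            for t in ("head", "mesosoma", "metasoma")
        },
        "summed_surface_area_mm2": record.summed_surface_area_mm2,
        "summed_volume_mm3": record.summed_volume_mm3,
    }
    return LabeledMesh(mesh, np.asarray(labels, dtype=object), units_calibrated=True), truth


def make_solid_mesh(spec: SolidSpec):
    """Dispatch a :class:`SolidSpec` to the matching generator.

    Returns ``(mesh, truth)`` where ``mesh`` is a
    :class:`trimesh.Trimesh` (or :class:`LabeledMesh` for
    ``composite_bee``) and ``truth`` the analytic SA/V.
    """
    d = dict(spec.dimensions)
    if spec.kind == "sphere":
        return make_sphere_mesh(d["diameter_mm"], spec.tessellation_level)
    if spec.kind == "capped_cylinder":
        return make_capped_cylinder_mesh(
            d["diameter_mm"], d["length_mm"], _sections(spec.tessellation_level)
        )
    if spec.kind == "cone":
        return make_cone_mesh(
            d["diameter_mm"], d["height_mm"], _sections(spec.tessellation_level)
        )
    if spec.kind == "composite_bee":
        m = LinearMeasurements(specimen_id="solid_spec", **d)
        return make_composite_bee(m, tessellation_level=spec.tessellation_level)
    raise SyntheticError(f"unknown solid kind {spec.kind!r}")


def _sections(level: int) -> int:
    # map an icosphere-style level to an angular section count of
    # comparable resolution (level 4 -> 128 sections)
    return max(MIN_SECTIONS, 8 * 2 ** level)


# ---------------------------------------------------------------------------
# perturbation

def perturb_mesh(
    lm: LabeledMesh | trimesh.Trimesh,
    amplitude: float,
    frequency: int = 3,
    seed: int = 0,
    preserve_volume: bool = True,
) -> LabeledMesh:
    """Smooth seeded radial deformation of each connected component.

    Every vertex moves radially from its component centroid by a factor
    ``1 + amplitude * f(theta, phi)`` where ``f`` is a mean-centred sum
    of low-order sinusoids in the vertex direction angles (seeded, so
    the same seed gives bitwise-identical output).  Topology is
    untouched, so a watertight input stays watertight.  With
    ``preserve_volume`` each component is rescaled back to its original
    enclosed volume, so non-zero amplitude can only add surface area
    relative to the ideal shape.
    """
    if isinstance(lm, trimesh.Trimesh):
        lm = LabeledMesh(lm)
    if amplitude < 0:
        raise SyntheticError("amplitude must be >= 0")
    if amplitude == 0:
        return LabeledMesh(
            lm.mesh.copy(),
            None if lm.face_labels is None else lm.face_labels.copy(),
            lm.units_calibrated,
        )
    rng = np.random.default_rng(seed)
    n_terms = 4
    amp_k = rng.uniform(0.5, 1.0, size=n_terms)
    phase_t = rng.uniform(0, 2 * np.pi, size=n_terms)
    phase_p = rng.uniform(0, 2 * np.pi, size=n_terms)

    vertices = np.asarray(lm.mesh.vertices, dtype=float).copy()
    faces = np.asarray(lm.mesh.faces, dtype=int)
    components = _vertex_components(vertices.shape[0], faces)
    for comp in components:
        idx = np.asarray(comp)
        c = vertices[idx].mean(axis=0)
        u = vertices[idx] - c
        r = np.linalg.norm(u, axis=1)
        r = np.where(r == 0, 1.0, r)
        theta = np.arctan2(u[:, 1], u[:, 0])
        phi = np.arccos(np.clip(u[:, 2] / r, -1, 1))
        f = np.zeros(len(idx))
        for k in range(n_terms):
            f += amp_k[k] * np.sin((k + 1) * frequency * theta + phase_t[k]) * np.sin(
                (k + 1) * frequency * phi + phase_p[k]
            )
        f /= np.abs(f).max() or 1.0
        f -= f.mean()
        factor = 1.0 + amplitude * f
        if (factor <= 0).any():
            raise SyntheticError(
                "amplitude too large: radial factor crosses zero (reduce amplitude)"
            )
        new = c + u * factor[:, None]
        if preserve_volume:
            comp_faces = faces[np.isin(faces[:, 0], idx)]
            v_before = _component_volume(vertices, comp_faces)
            tmp = vertices.copy()
            tmp[idx] = new
            v_after = _component_volume(tmp, comp_faces)
            if v_after > 0 and v_before > 0:
                new = c + (new - c) * (v_before / v_after) ** (1.0 / 3.0)
        vertices[idx] = new
    mesh = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    return LabeledMesh(
        mesh,
        None if lm.face_labels is None else lm.face_labels.copy(),
        lm.units_calibrated,
    )


def _vertex_components(n_vertices: int, faces: np.ndarray) -> list[np.ndarray]:
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    rows = np.concatenate([faces[:, 0], faces[:, 1], faces[:, 2]])
    cols = np.concatenate([faces[:, 1], faces[:, 2], faces[:, 0]])
    adj = coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n_vertices, n_vertices)
    )
    n, labels = connected_components(adj, directed=False)
    return [np.flatnonzero(labels == i) for i in range(n)]


def _component_volume(vertices: np.ndarray, faces: np.ndarray) -> float:
    v = vertices
    f = faces
    return abs(
        float(
            np.einsum(
                "ij,ij->i", v[f[:, 0]], np.cross(v[f[:, 1]], v[f[:, 2]])
            ).sum()
            / 6.0
        )
    )


# ---------------------------------------------------------------------------
# measurement cohorts

_TAGMATA = ("head", "mesosoma", "metasoma")


def simulate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Paired geometric/model size tables with a full truth log.

    Per specimen, the six caliper measurements are an isometric rescale
    of the baseline worker (log-normal size distribution) with small
    per-measurement shape jitter.  The true ("model") per-tagma values
    are the solid-formula values inflated by the injected
    underestimation fractions — real bodies carry more surface and
    volume than their ideal solids — with the surface areas
    additionally tilted so log10(SA) scales on log10(V) with the
    requested exponent.  The observed "geometric" values are the
    formula values under multiplicative log-normal noise.

    Returns ``(geometric_table, model_table, truth)``; tables are in
    the long SizeRecord format (specimen_id, method, scope,
    surface_area_mm2, volume_mm3).
    """
    rng = np.random.default_rng(spec.seed)
    sigma_ln_length = spec.size_sigma_log10_volume / 3.0 * math.log(10.0)
    geo_rows = []
    model_rows = []
    scale_factors = []
    beta = spec.true_scaling_exponent
    for i in range(spec.n_specimens):
        s = float(np.exp(rng.normal(0.0, sigma_ln_length)))
        scale_factors.append(s)
        m = spec.baseline.scaled(s)
        if spec.shape_jitter_sd > 0:
            jitter = np.exp(rng.normal(0.0, spec.shape_jitter_sd, size=6))
            m = LinearMeasurements(
                specimen_id=f"synthetic_{i:03d}",
                head_width_mm=m.head_width_mm * jitter[0],
                head_thickness_mm=m.head_thickness_mm * jitter[1],
                mesosoma_width_mm=m.mesosoma_width_mm * jitter[2],
                metasoma_width_mm=m.metasoma_width_mm * jitter[3],
                metasoma_anterior_length_mm=m.metasoma_anterior_length_mm * jitter[4],
                metasoma_posterior_length_mm=m.metasoma_posterior_length_mm
                * jitter[5],
            )
        else:
            m = LinearMeasurements(
                specimen_id=f"synthetic_{i:03d}",
                head_width_mm=m.head_width_mm,
                head_thickness_mm=m.head_thickness_mm,
                mesosoma_width_mm=m.mesosoma_width_mm,
                metasoma_width_mm=m.metasoma_width_mm,
                metasoma_anterior_length_mm=m.metasoma_anterior_length_mm,
                metasoma_posterior_length_mm=m.metasoma_posterior_length_mm,
            )
        record = estimate_specimen(m)
        # allometric tilt: multiply SA by s^(3*(beta - 2/3)) so true SA
        # scales with true V to the requested exponent
        sa_tilt = s ** (3.0 * (beta - 2.0 / 3.0))
        geo_sum_sa = geo_sum_v = 0.0
        mod_sum_sa = mod_sum_v = 0.0
        for tagma in _TAGMATA:
            est = record.tagma(tagma)
            f_sa = float(spec.underestimation.get(tagma, {}).get("surface_area", 0.0))
            f_v = float(spec.underestimation.get(tagma, {}).get("volume", 0.0))
            model_sa = est.surface_area_mm2 * sa_tilt / (1.0 - f_sa)
            model_v = est.volume_mm3 / (1.0 - f_v)
            noise_sa = float(np.exp(rng.normal(0.0, spec.noise_sd)))
            noise_v = float(np.exp(rng.normal(0.0, spec.noise_sd)))
            geo_sa = est.surface_area_mm2 * sa_tilt * noise_sa
            geo_v = est.volume_mm3 * noise_v
            geo_rows.append(
                {
                    "specimen_id": m.specimen_id,
                    "method": "geometric",
                    "scope": tagma,
                    "surface_area_mm2": geo_sa,
                    "volume_mm3": geo_v,
                }
            )
            model_rows.append(
                {
                    "specimen_id": m.specimen_id,
                    "method": "model_tagmata",
                    "scope": tagma,
                    "surface_area_mm2": model_sa,
                    "volume_mm3": model_v,
                }
            )
            geo_sum_sa += geo_sa
            geo_sum_v += geo_v
            mod_sum_sa += model_sa
            mod_sum_v += model_v
        geo_rows.append(
            {
                "specimen_id": m.specimen_id,
                "method": "geometric",
                "scope": "tagmata_sum",
                "surface_area_mm2": geo_sum_sa,
                "volume_mm3": geo_sum_v,
            }
        )
        model_rows.append(
            {
                "specimen_id": m.specimen_id,
                "method": "model_tagmata",
                "scope": "tagmata_sum",
                "surface_area_mm2": mod_sum_sa,
                "volume_mm3": mod_sum_v,
            }
        )
    truth = {
        "seed": spec.seed,
        "n_specimens": spec.n_specimens,
        "underestimation": {
            t: dict(q) for t, q in spec.underestimation.items()
        },
        "true_scaling_exponent": beta,
        "noise_sd": spec.noise_sd,
        "shape_jitter_sd": spec.shape_jitter_sd,
        "scale_factors": scale_factors,
    }
    return pd.DataFrame(geo_rows), pd.DataFrame(model_rows), truth


def simulate_scaling_cohort(
    n: int,
    beta: float,
    seed: int,
    sigma_log10_sa: float = 0.03,
    sigma_log10_v: float = 0.1,
    v_ref_mm3: float = 100.0,
    alpha_log10: float = 1.1,
    method: str = "synthetic",
) -> pd.DataFrame:
    """Power-law (V, SA) cohort: log10 SA = alpha + beta log10 V + noise.

    Volumes are log-normal about ``v_ref_mm3``; noise defaults give an
    R² near 0.85 at beta about 0.7, matching a realistic worker cohort.
    """
    if n < 3:
        raise SyntheticError("n must be >= 3")
    rng = np.random.default_rng(seed)
    log_v = rng.normal(math.log10(v_ref_mm3), sigma_log10_v, size=n)
    log_sa = alpha_log10 + beta * log_v + rng.normal(0.0, sigma_log10_sa, size=n)
    return pd.DataFrame(
        {
            "specimen_id": [f"scal_{i:03d}" for i in range(n)],
            "method": method,
            "volume_mm3": 10.0 ** log_v,
            "surface_area_mm2": 10.0 ** log_sa,
        }
    )


# ---------------------------------------------------------------------------
# thermal presets

def default_tagma_areas(
    measurements: LinearMeasurements = BASELINE_WORKER,
    method: str = "geometric",
) -> TagmaSurfaceAreas:
    """Geometric tagma surface areas of the baseline worker, mapped to
    the heat-budget naming (mesosoma -> thorax, metasoma -> abdomen)."""
    record = estimate_specimen(measurements)
    return TagmaSurfaceAreas(
        head_mm2=record.head.surface_area_mm2,
        thorax_mm2=record.mesosoma.surface_area_mm2,
        abdomen_mm2=record.metasoma.surface_area_mm2,
        method=method,
    )


def default_thermal_models(preset: str = "synthetic-worker") -> ThermalModelSet:
    """Synthetic linear thermal-response coefficients for testing.

    These are NOT empirical flight-physiology coefficients: they are a
    synthetic stand-in shaped to the qualitative pattern of a flying
    worker — metabolic heat declining with air temperature, evaporative
    loss rising steeply, and tagma temperatures above air temperature
    with the excess shrinking as air warms.  Real analyses should load
    empirical coefficient sets via config
    (:func:`beebudget.budget.thermal_models_from_dict`).
    """
    if preset == "synthetic-worker":
        return ThermalModelSet(
            metabolic=LinearResponse(900.0, -8.0),  # mW/g
            evaporative=LinearResponse(-70.0, 4.2),  # mW/g loss magnitude
            head_temperature=LinearResponse(10.0, 0.82),
            thorax_temperature=LinearResponse(24.0, 0.55),
            abdomen_temperature=LinearResponse(6.0, 0.92),
            body_mass_g=0.0753,
            label="synthetic-worker",
        )
    raise SyntheticError(f"unknown preset {preset!r}")


def crossover_preset(
    target_c: float = 35.0,
    areas: TagmaSurfaceAreas | None = None,
    constants: RadiativeConstants = RadiativeConstants(),
    grid_c=DEFAULT_GRID_C,
) -> ThermalModelSet:
    """A thermal model set whose fitted |Q_C| and |Q_R| lines cross at
    exactly ``target_c`` (default 35 °C) for the given surface areas.

    Construction: with the preset's tagma temperatures fixed, the
    radiative series Q_R(T) is computed and a line fitted to |Q_R|.
    The metabolic and evaporative lines are chosen so that
    g(T) = Q_M - |Q_E| is exactly linear and g(target) equals twice the
    fitted |Q_R| line at the target; since Q_C = -(g(T) + Q_R), the
    fitted |Q_C| line is exactly g minus the fitted |Q_R| line, and the
    two fitted lines meet at the target by construction.
    """
    if areas is None:
        areas = default_tagma_areas()
    base = default_thermal_models()
    t = np.asarray(list(grid_c), dtype=float)
    q_r = whole_body_radiative(t, base, areas, constants)
    if (np.asarray(q_r) >= 0).any():
        raise SyntheticError("preset assumes net radiative loss over the grid")
    slope_r, icpt_r = np.polyfit(t, np.abs(q_r), 1)
    lr_target = float(icpt_r + slope_r * target_c)

    mass = base.body_mass_g
    # g(T) = Q_M - |Q_E| with gentle slope so Q_C stays a loss grid-wide
    evaporative = LinearResponse(-30.0, 2.64)  # mW/g magnitude, >0 for T>=12
    slope_g_mw = -0.5  # mW/°C
    metabolic_slope = slope_g_mw / mass + evaporative.slope
    metabolic_icpt = (
        2.0 * lr_target / mass
        + (evaporative.intercept + evaporative.slope * target_c)
        - metabolic_slope * target_c
    )
    models = ThermalModelSet(
        metabolic=LinearResponse(float(metabolic_icpt), float(metabolic_slope)),
        evaporative=evaporative,
        head_temperature=base.head_temperature,
        thorax_temperature=base.thorax_temperature,
        abdomen_temperature=base.abdomen_temperature,
        body_mass_g=mass,
        label=f"synthetic-crossover-{target_c:g}C",
    )
    # sanity: the residual must remain a loss so |Q_C| is linear-minus-|Q_R|
    q_m = models.metabolic(t) * mass
    q_e = -np.abs(models.evaporative(t)) * mass
    if ((q_m + q_e + np.asarray(q_r)) <= 0).any() or (q_m <= 0).any():
        raise SyntheticError("crossover preset construction failed for these areas")
    return models
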