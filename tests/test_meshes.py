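"""Mesh loading, calibration, area/volume sums and watertight checks."""

import math

import numpy as np
import pytest
import trimesh

from beebudget.meshes import (
    CalibrationError,
    CalibrationRecord,
    LabeledMesh,
    MeshFormatError,
    NotWatertightError,
    apply_calibration,
    load_mesh,
    measure_specimen,
    read_label_sidecar,
    surface_area,
    volume,
    watertight_report,
    write_label_sidecar,
    write_obj,
)
from beebudget.synthetic import make_composite_bee, make_sphere_mesh


def test_unit_cube_measures_exactly(unit_cube):
    assert surface_area(unit_cube) == pytest.approx(6.0, abs=1e-12)
    assert volume(unit_cube) == pytest.approx(1.0, abs=1e-12)


def test_icosphere_area_below_analytic_and_converging():
    """An inscribed tessellated sphere underestimates area and volume,
    and both converge monotonically under subdivision."""
    analytic_sa = 4 * math.pi
    analytic_v = math.pi * 8 / 6
    prev_sa, prev_v = -np.inf, -np.inf
    for level in (2, 3, 4):
        mesh, _ = make_sphere_mesh(2.0, subdivisions=level)
        lm = LabeledMesh(mesh, units_calibrated=True)
        sa, v = surface_area(lm), volume(lm)
        assert sa < analytic_sa and v < analytic_v
        assert sa > prev_sa and v > prev_v
        prev_sa, prev_v = sa, v
    assert prev_sa == pytest.approx(analytic_sa, rel=0.002)
    assert prev_v == pytest.approx(analytic_v, rel=0.005)


def test_volume_agrees_with_trimesh(composite_bee):
    """In-package divergence-theorem sums match trimesh's independent
    computation on the same watertight mesh."""
    lm, _ = composite_bee
    assert volume(lm) == pytest.approx(lm.mesh.volume, rel=1e-12)
    assert surface_area(lm) == pytest.approx(lm.mesh.area, rel=1e-12)


def test_partition_additivity(composite_bee):
    lm, _ = composite_bee
    total = surface_area(lm)
    parts = sum(surface_area(lm, t) for t in ("head", "mesosoma", "metasoma"))
    assert parts == pytest.approx(total, rel=1e-14)
    assert surface_area(lm, ("head", "mesosoma", "metasoma")) == pytest.approx(
        total, rel=1e-14
    )


def test_rigid_motion_invariance(composite_bee, rng):
    lm, _ = composite_bee
    v0 = volume(lm)
    a0 = surface_area(lm)
    moved = lm.mesh.copy()
    rotation = trimesh.transformations.rotation_matrix(
        angle=1.1, direction=[1, 2, 3], point=[5, -2, 1]
    )
    moved.apply_transform(rotation)
    moved.apply_translation(rng.normal(size=3) * 10)
    lm2 = LabeledMesh(moved, lm.face_labels, units_calibrated=True)
    assert volume(lm2) == pytest.approx(v0, rel=1e-9)
    assert surface_area(lm2) == pytest.approx(a0, rel=1e-9)


def test_calibration_scales_area_and_volume(unit_cube):
    record = CalibrationRecord(
        known_length_mm=2.0,
        measured_length_model_units=1.0,
        verification_lengths=((2.0, 1.0), (4.0, 2.0), (6.0, 3.0)),
    )
    calibrated = apply_calibration(unit_cube, record)
    assert calibrated.units_calibrated
    assert surface_area(calibrated) == pytest.approx(24.0)
    assert volume(calibrated) == pytest.approx(8.0)
    identity = apply_calibration(
        unit_cube, CalibrationRecord(1.0, 1.0, ((1.0, 1.0),))
    )
    assert volume(identity) == pytest.approx(1.0)


def test_calibration_verification_failure(unit_cube):
    record = CalibrationRecord(
        known_length_mm=2.0,
        measured_length_model_units=1.0,
        verification_lengths=((2.0, 1.0), (5.0, 2.0)),  # second pair off by 25%
    )
    with pytest.raises(CalibrationError, match="verification"):
        apply_calibration(unit_cube, record)


def test_open_cube_reported_and_capped(unit_cube):
    faces = unit_cube.mesh.faces[:-2]  # drop one quad (two triangles)
    open_lm = LabeledMesh(
        trimesh.Trimesh(vertices=unit_cube.mesh.vertices, faces=faces,
                        process=False)
    )
    report = watertight_report(open_lm)
    assert report.boundary_edge_count == 4
    assert not report.watertight
    with pytest.raises(NotWatertightError):
        volume(open_lm, cap_boundaries=False)
    assert volume(open_lm) == pytest.approx(1.0, abs=1e-12)


def test_flipped_face_repaired_not_silent(unit_cube):
    faces = unit_cube.mesh.faces.copy()
    faces[0] = faces[0][::-1]
    lm = LabeledMesh(
        trimesh.Trimesh(vertices=unit_cube.mesh.vertices, faces=faces,
                        process=False)
    )
    assert volume(lm) == pytest.approx(1.0, abs=1e-12)


def test_tagma_volume_via_capping_matches_analytic(composite_bee):
    """Cutting a labelled tagma from the composite leaves no boundary
    (disjoint components), but a label-split of a single closed solid
    must still produce the right capped volumes."""
    lm, truth = composite_bee
    for tagma in ("head", "mesosoma", "metasoma"):
        expected = truth["per_tagma"][tagma]["volume_mm3"]
        assert volume(lm, tagma) == pytest.approx(expected, rel=0.005)


def test_obj_round_trip_with_labels(tmp_path, composite_bee):
    lm, _ = composite_bee
    path = write_obj(lm, tmp_path / "bee.obj")
    loaded = load_mesh(path, units_calibrated=True)
    assert loaded.labels == {"head", "mesosoma", "metasoma"}
    assert surface_area(loaded) == pytest.approx(surface_area(lm), rel=1e-9)
    assert volume(loaded) == pytest.approx(volume(lm), rel=1e-9)
    for tagma in ("head", "mesosoma", "metasoma"):
        assert surface_area(loaded, tagma) == pytest.approx(
            surface_area(lm, tagma), rel=1e-9
        )


def test_label_sidecar_round_trip(tmp_path, composite_bee):
    lm, _ = composite_bee
    sidecar = write_label_sidecar(lm, tmp_path / "labels.csv")
    labels = read_label_sidecar(sidecar, n_faces=len(lm.mesh.faces))
    assert (labels == lm.face_labels).all()


def test_stl_loads_without_labels(tmp_path, unit_cube):
    path = tmp_path / "cube.stl"
    unit_cube.mesh.export(path)
    lm = load_mesh(path, units_calibrated=True)
    assert lm.face_labels is None
    assert volume(lm) == pytest.approx(1.0, rel=1e-9)
    # whole-mesh measurement with a warning, not an error
    rows = measure_specimen(lm, "cube")
    assert rows[-1]["scope"] == "whole_body"
    assert rows[-1]["surface_area_mm2"] == pytest.approx(6.0, rel=1e-9)


@pytest.mark.parametrize("content", ["", "not a mesh at all\n"])
def test_unreadable_file_is_format_error(tmp_path, content):
    path = tmp_path / "broken.obj"
    path.write_text(content)
    with pytest.raises(MeshFormatError):
        load_mesh(path)


def test_missing_file_is_format_error(tmp_path):
    with pytest.raises(MeshFormatError, match="no such"):
        load_mesh(tmp_path / "absent.ply")


def test_degenerate_faces_removed(tmp_path, unit_cube):
    v = np.vstack([unit_cube.mesh.vertices, unit_cube.mesh.vertices[0]])
    degenerate = np.vstack([unit_cube.mesh.faces, [[0, 0, 8]]])
    path = tmp_path / "degenerate.obj"
    write_obj(LabeledMesh(trimesh.Trimesh(vertices=v, faces=degenerate,
                                          process=False)), path)
    lm = load_mesh(path, units_calibrated=True)
    assert len(lm.mesh.faces) == 12
    assert surface_area(lm) == pytest.approx(6.0, rel=1e-9)


def test_measure_specimen_tagmata_sum(composite_bee):
    lm, truth = composite_bee
    rows = measure_specimen(lm, "bee01")
    by_scope = {r["scope"]: r for r in rows if r["method"] == "model_tagmata"}
    assert by_scope["tagmata_sum"]["surface_area_mm2"] == pytest.approx(
        sum(by_scope[t]["surface_area_mm2"] for t in ("head", "mesosoma", "metasoma")),
        rel=1e-12,
    )
    assert by_scope["tagmata_sum"]["surface_area_mm2"] == pytest.approx(
        truth["summed_surface_area_mm2"], rel=0.003
    )
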