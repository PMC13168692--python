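import numpy as np
import pytest
import trimesh

from beebudget.measurements import LinearMeasurements
from beebudget.meshes import LabeledMesh


@pytest.fixture
def worker_measurements() -> LinearMeasurements:
    """A worker-scale set of the six caliper measurements (mm)."""
    return LinearMeasurements(
        specimen_id="w01",
        head_width_mm=3.5,
        head_thickness_mm=2.0,
        mesosoma_width_mm=4.0,
        metasoma_width_mm=4.2,
        metasoma_anterior_length_mm=4.0,
        metasoma_posterior_length_mm=3.5,
    )


@pytest.fixture
def unit_cube() -> LabeledMesh:
    box = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    return LabeledMesh(
        trimesh.Trimesh(vertices=box.vertices, faces=box.faces, process=False),
        units_calibrated=True,
    )


@pytest.fixture
def composite_bee():
    from beebudget.synthetic import make_composite_bee

    return make_composite_bee()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260101)
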