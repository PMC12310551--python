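import numpy as np
import pytest

import fieldray as fr
from fieldray.experiments import ExperimentConfig, eye_rig, render_template_set


@pytest.fixture(scope="session")
def synthetic_model():
    """Three-parameter synthetic head (nose / brow / cheek morphs)."""
    return fr.make_synthetic_model(fr.SyntheticHeadSpec(n_ids=3, seed=7))


@pytest.fixture(scope="session")
def small_cfg():
    """Desk-scale experiment configuration for fast end-to-end runs."""
    return ExperimentConfig(res=96, n_bins=180, n_faces=5, seed=1)


@pytest.fixture(scope="session")
def synthetic_rig(synthetic_model, small_cfg):
    return eye_rig(synthetic_model, small_cfg)


@pytest.fixture(scope="session")
def synthetic_templates(synthetic_model, small_cfg):
    """Rendered boundary templates of the synthetic head (7 faces)."""
    return render_template_set(synthetic_model, small_cfg)


def random_triangle_soup(rng: np.random.Generator, n_tris: int,
                         scale: float = 10.0) -> fr.TriangleMesh:
    """Random disconnected triangles filling a cube around the origin."""
    centers = rng.uniform(-scale, scale, size=(n_tris, 1, 3))
    corners = centers + rng.normal(scale=scale / 8, size=(n_tris, 3, 3))
    verts = corners.reshape(-1, 3)
    faces = np.arange(3 * n_tris).reshape(-1, 3)
    return fr.TriangleMesh(verts, faces)


def random_template_set(rng: np.random.Generator, n_ids: int,
                        n_bins: int) -> fr.TemplateSet:
    return fr.TemplateSet(
        rng.uniform(50.0, 90.0, n_bins),
        rng.uniform(45.0, 90.0, (n_ids, n_bins)),
        rng.uniform(45.0, 90.0, (n_ids, n_bins)),
    )
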