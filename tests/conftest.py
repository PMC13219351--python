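import pytest

from cropwater import synthetic
from cropwater.pipeline import assemble_observations


@pytest.fixture(scope="session")
def small_layout():
    return synthetic.generate_field_layout(3, seed=5)


@pytest.fixture(scope="session")
def small_truth(small_layout):
    return synthetic.generate_truth(small_layout, seed=5, n_days=60)


@pytest.fixture(scope="session")
def full_experiment():
    """Full-size synthetic campaign: 180 plots, three stages, 90 days."""
    layout = synthetic.generate_field_layout(30, seed=11)
    truth = synthetic.generate_truth(layout, seed=11)
    scenes = {s: synthetic.render_scene(truth, layout, s, seed=11) for s in synthetic.STAGES}
    return layout, truth, scenes


@pytest.fixture(scope="session")
def full_observations(full_experiment):
    """Per-plot observation table assembled from the full-size scenes."""
    layout, truth, scenes = full_experiment
    return assemble_observations(layout, truth, scenes)
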