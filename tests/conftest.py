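"""Shared fixtures: a small synthetic scene battery with its affordance RDM.

Everything is generated programmatically at test time from fixed seeds; the
session-scoped battery keeps the expensive rendering/rasterization work out
of individual tests.
"""

import numpy as np
import pytest

from navaff.affordance import affordance_rdm, histogram_from_map
from navaff.pipeline import PipelineConfig, sample_scene_specs
from navaff.rdm import compute_rdm
from navaff.synthetic import render_scene, simulate_rater_paths


@pytest.fixture(scope="session")
def battery():
    """20 scenes, their rater histograms, and the affordance RDM (seed 123)."""
    config = PipelineConfig(seed=123, n_scenes=20)
    specs = sample_scene_specs(config, seed=123)
    rng = np.random.default_rng(321)
    scenes, hists = [], []
    for spec in specs:
        scenes.append(render_scene(spec))
        hm = simulate_rater_paths(
            spec.opening_azimuths, config.n_raters, config.rater_noise_sd,
            spec.image_size, seed=int(rng.integers(2**31 - 1)),
        )
        hists.append(histogram_from_map(hm.values))
    labels = [f"scene{i:02d}" for i in range(len(specs))]
    return {
        "specs": specs,
        "scenes": scenes,
        "histograms": hists,
        "labels": labels,
        "affordance_rdm": affordance_rdm(hists, labels),
    }


@pytest.fixture()
def random_rdm_pair():
    """Two independent random RDMs over the same 12 conditions."""

    def make(seed, n=12, n_features=15):
        rng = np.random.default_rng(seed)
        labels = [f"c{i}" for i in range(n)]
        a = compute_rdm(rng.standard_normal((n, n_features)), labels)
        b = compute_rdm(rng.standard_normal((n, n_features)), labels)
        return a, b

    return make
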