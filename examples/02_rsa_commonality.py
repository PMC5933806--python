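"""RSA and commonality analysis on a planted voxel cohort.

Builds a 12-scene affordance RDM, plants it in an 8-subject voxel cohort
with run noise, recovers the group RDM, and asks how much of the affordance
model's explained variance in the (synthetic) neural RDM is shared with a
network layer RDM — the variance-partitioning question at the heart of the
analysis.
"""

import numpy as np

from navaff import (
    build_network, commonality, default_network_config, generate_cohort,
    group_rdm, noise_ceiling, permutation_test, spearman_rsa,
)
from navaff.affordance import affordance_rdm, histogram_from_map
from navaff.pipeline import PipelineConfig, sample_scene_specs
from navaff.rdm import compute_rdm
from navaff.stimuli import layer_rdms
from navaff.synthetic import render_scene, simulate_rater_paths

config = PipelineConfig(n_scenes=12)
specs = sample_scene_specs(config, seed=5)
labels = [f"scene{i:02d}" for i in range(12)]
hists = [histogram_from_map(simulate_rater_paths(
    s.opening_azimuths, 32, 8.0, s.image_size, seed=100 + i).values)
    for i, s in enumerate(specs)]
aff = affordance_rdm(hists, labels)

cohort = generate_cohort(aff, n_subjects=8, n_runs=2, n_voxels=64,
                         noise_sd=0.5, seed=0)
subject_rdms = [compute_rdm(cohort.patterns[s].mean(axis=0), labels)
                for s in range(8)]
neural = group_rdm(subject_rdms)
print(f"group-RDM recovery of the planted affordance RDM: "
      f"rho = {spearman_rsa(neural, aff):.3f}")
print(f"noise ceiling (mean subject-to-group rho): "
      f"{noise_ceiling(subject_rdms).value:.3f}")

net = build_network(default_network_config((64, 64), seed=0))
layer = layer_rdms(net, [render_scene(s) for s in specs], labels,
                   pca_k=10, layer_names=["norm1"])["norm1"]
perm = permutation_test(aff, layer, n_iterations=1000, seed=0)
print(f"layer norm1 vs affordance RDM: rho = {perm.statistic:.3f}, "
      f"permutation p = {perm.p_value:.4f}")

res = commonality(neural, aff, layer)
print(f"commonality (target=neural, X1=affordance, X2=layer): "
      f"R2_full={res.r2_full:.3f}, SV={res.shared_variance_pct:.1f}%")
print("SV is the share of the affordance model's explained neural variance "
      "that the network layer also accounts for")
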