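"""End-to-end synthetic study: generate -> forward -> RDMs -> inference.

``run_pipeline`` executes the whole analysis on synthetic inputs with known
ground truth: it renders a battery of indoor scenes with planted doorway
azimuths, simulates rater path maps and builds the affordance RDM, plants
that RDM in a multi-subject voxel cohort and recovers it, forwards the scenes
through the mini network and compares layer RDMs with the affordance and
synthetic-neural RDMs (permutation tests, bootstrap SEs, commonality), runs
the stimulus-filter and slice-occlusion experiments, maps and clusters
receptive fields of the most affordance-correlated units, and classifies a
planted navigability property from labeled unit activations against a
unit-resampling null.

Two group RDMs are computed for the cohort: the *recovery* RDM, built
directly from run-averaged patterns (this is the RDM the generator's planting
contract guarantees, and it reproduces the target exactly at zero noise), and
the *normalized* RDM from the full fMRI normalization chain (per-voxel
z-score within run, run average, per-pattern z-score across voxels), which is
what one would apply to real recordings and which also feeds the noise
ceiling.

Every stage derives its seed from the master seed, so a rerun with the same
configuration reproduces the summary bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from ._utils import spawn_seeds
from .affordance import affordance_rdm, histogram_from_map
from .classify import (
    compare_accuracies,
    loo_lda_classify,
    min_distance_classify,
    resampling_null,
)
from .inference import (
    bonferroni,
    bootstrap_se,
    bootstrap_sv_contrast,
    commonality,
    noise_ceiling,
    permutation_test,
    spearman_rsa,
)
from .network import NetworkConfig, build_network, default_network_config
from .rdm import RDM, compute_rdm, group_rdm, normalize_fmri
from .receptive import embed_and_cluster_units, map_discrepancy, select_units
from .stimuli import (
    FilterSpec,
    SliceOcclusionConfig,
    run_feature_experiment,
    run_slice_experiment,
)
from .synthetic import (
    SceneSpec,
    generate_cohort,
    generate_labeled_activations,
    render_scene,
    simulate_rater_paths,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "sample_scene_specs"]


@dataclass(frozen=True)
class PipelineConfig:
    """Desk-scale defaults: 20 scenes, 8 subjects, 500 inference iterations."""

    seed: int = 0
    out_dir: str | None = None
    # scenes and raters
    n_scenes: int = 20
    image_size: tuple[int, int] = (227, 227)
    n_raters: int = 32
    rater_noise_sd: float = 8.0
    max_openings: int = 3
    azimuth_range: tuple[float, float] = (8.0, 172.0)
    min_azimuth_separation: float = 25.0
    opening_width_range: tuple[float, float] = (14.0, 30.0)
    # cohort
    n_subjects: int = 8
    n_runs: int = 2
    n_voxels: int = 64
    noise_sd: float = 0.5
    # network / RDMs
    network_input: tuple[int, int] = (64, 64)
    pca_k: int = 45
    report_layers: tuple[str, ...] = ("norm1", "norm2", "relu3", "dense1")
    # inference
    n_iterations: int = 500
    # slice occlusion
    slice_height: int = 41
    slice_stride: int = 5
    # receptive fields
    rf_n_units: int = 8
    rf_n_images: int = 8
    rf_layer: str = "relu3"
    rf_occluder: int = 11
    rf_stride: int = 9
    # landscape-style classification
    class_n_images: int = 100
    class_n_units: int = 2000
    class_n_informative: int = 50
    class_effect_size: float = 2.0


@dataclass
class PipelineResult:
    summary: dict
    affordance: RDM
    group_recovery: RDM
    group_normalized: RDM
    layer_rdms: dict
    feature_table: "object"
    slice_profile: "object"
    clustering: "object"

    def summary_json(self) -> str:
        return json.dumps(self.summary, sort_keys=True, indent=1)


def sample_scene_specs(config: PipelineConfig, seed: int) -> list[SceneSpec]:
    """Draw the scene battery: 1..max_openings doorways per scene, azimuths
    spread over the configured range with a minimum separation."""
    rng = np.random.default_rng(seed)
    lo, hi = config.azimuth_range
    specs = []
    for i in range(config.n_scenes):
        k = int(rng.integers(1, config.max_openings + 1))
        widths = tuple(
            float(rng.uniform(*config.opening_width_range)) for _ in range(k)
        )
        # neighbors must clear each other's angular half-widths so doorways
        # never overlap after rendering
        for _ in range(500):
            azs = np.sort(rng.uniform(lo, hi, size=k))
            gaps_ok = all(
                azs[j + 1] - azs[j] >= max(
                    config.min_azimuth_separation,
                    (widths[j] + widths[j + 1]) / 2.0 + 6.0,
                )
                for j in range(k - 1)
            )
            if gaps_ok:
                break
        else:
            azs = np.linspace(lo + 15, hi - 15, k)  # deterministic fallback
        specs.append(
            SceneSpec(
                image_size=config.image_size,
                opening_azimuths=tuple(float(a) for a in azs),
                opening_widths=widths,
                seed=int(rng.integers(2**31 - 1)),
            )
        )
    return specs


def _round(x, nd=6):
    if isinstance(x, dict):
        return {k: _round(v, nd) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_round(v, nd) for v in x]
    if isinstance(x, (float, np.floating)):
        return round(float(x), nd)
    if isinstance(x, (int, np.integer)):
        return int(x)
    return x


def run_pipeline(config: PipelineConfig = PipelineConfig()) -> PipelineResult:
    seeds = spawn_seeds(config.seed, 12)
    out = Path(config.out_dir) if config.out_dir else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # -- stage 1: scenes ----------------------------------------------------
    specs = sample_scene_specs(config, seeds[0])
    scenes = [render_scene(s) for s in specs]
    labels = [f"scene{i:02d}" for i in range(config.n_scenes)]
    if out is not None:
        (out / "scenes").mkdir(exist_ok=True)
        for lbl, sc in zip(labels, scenes):
            sc.save_png(out / "scenes" / f"{lbl}.png")

    # -- stage 2: rater paths -> affordance RDM -----------------------------
    rater_seeds = spawn_seeds(seeds[1], config.n_scenes)
    hists = []
    for spec, rs in zip(specs, rater_seeds):
        hm = simulate_rater_paths(
            spec.opening_azimuths, config.n_raters, config.rater_noise_sd,
            config.image_size, seed=rs,
        )
        hists.append(histogram_from_map(hm.values))
    aff_rdm = affordance_rdm(hists, labels)
    peak_err = [
        min(abs(h.argmax_deg() + 0.5 - a) for a in spec.opening_azimuths)
        for h, spec in zip(hists, specs)
    ]
    if out is not None:
        (out / "histograms").mkdir(exist_ok=True)
        for lbl, h in zip(labels, hists):
            h.to_frame().to_csv(out / "histograms" / f"{lbl}.csv", index=False)
        aff_rdm.save_csv(out / "affordance_rdm.csv")

    # -- stage 3: cohort, recovery, noise ceiling ---------------------------
    cohort = generate_cohort(
        aff_rdm, config.n_subjects, config.n_runs, config.n_voxels,
        config.noise_sd, seed=seeds[2],
    )
    subj_raw = [
        compute_rdm(cohort.patterns[s].mean(axis=0), labels, source=f"sub{s}")
        for s in range(config.n_subjects)
    ]
    group_rec = group_rdm(subj_raw, source="group-recovery")
    subj_norm = [
        compute_rdm(normalize_fmri(cohort.subject_runs(s)), labels,
                    source=f"sub{s}-norm")
        for s in range(config.n_subjects)
    ]
    group_norm = group_rdm(subj_norm, source="group-normalized")
    ceiling = noise_ceiling(subj_norm)
    rho_recovery = spearman_rsa(group_rec, aff_rdm)
    rho_normalized = spearman_rsa(group_norm, aff_rdm)

    # -- stage 4/5: network layer RDMs and RSA ------------------------------
    net = build_network(default_network_config(config.network_input,
                                               seed=seeds[3]))
    from .stimuli import layer_rdms as _layer_rdms

    lrdms = _layer_rdms(net, scenes, labels, pca_k=config.pca_k,
                        layer_names=list(config.report_layers))
    rsa_rows, p_aff = {}, []
    for name, lr in lrdms.items():
        rho_a = spearman_rsa(lr, aff_rdm)
        rho_n = spearman_rsa(lr, group_norm)
        perm = permutation_test(aff_rdm, lr, config.n_iterations, seed=seeds[4])
        se = bootstrap_se(aff_rdm, lr, n_iterations=config.n_iterations,
                          seed=seeds[5])
        rsa_rows[name] = {
            "rho_affordance": rho_a,
            "rho_neural": rho_n,
            "p_affordance": perm.p_value,
            "bootstrap_se": se,
        }
        p_aff.append(perm.p_value)
    corrected = bonferroni(p_aff, len(p_aff))
    for name, pc in zip(rsa_rows, corrected):
        rsa_rows[name]["p_affordance_corrected"] = pc
    best_layer = max(rsa_rows, key=lambda k: rsa_rows[k]["rho_affordance"])

    # -- stage 6: commonality (neural target, affordance + best layer) ------
    common = commonality(group_norm, aff_rdm, lrdms[best_layer])

    # -- stage 7: feature-filter experiment ---------------------------------
    targets = {"affordance": aff_rdm, "neural": group_norm}
    feat = run_feature_experiment(
        scenes, net, targets, pca_k=config.pca_k,
        layer_names=list(config.report_layers), labels=labels,
    )
    feat_summary = feat.attrs["summary"]
    from .stimuli import apply_filter, layer_rdms as _lr

    def _filtered_rdm(kind):
        imgs = [apply_filter(im.pixels, FilterSpec(kind)) for im in scenes]
        return _lr(net, imgs, labels, config.pca_k, [best_layer])[best_layer]

    contrasts = {}
    for name, a, b in (("highpass_minus_lowpass", "highpass", "lowpass"),
                       ("cardinal_minus_oblique", "cardinal", "oblique")):
        contrasts[name] = {
            t: bootstrap_sv_contrast(
                targets[t], lrdms[best_layer], _filtered_rdm(a),
                _filtered_rdm(b), n_iterations=config.n_iterations,
                seed=seeds[6],
            )
            for t in targets
        }
    if out is not None:
        feat.to_csv(out / "feature_sv.tsv", sep="\t", index=False)

    # -- stage 8: slice-occlusion experiment --------------------------------
    sl_config = SliceOcclusionConfig(slice_height=config.slice_height,
                                     stride=config.slice_stride)
    profile = run_slice_experiment(
        scenes, net, targets, sl_config, pca_k=config.pca_k,
        layer_names=list(config.report_layers), labels=labels,
    )
    if out is not None:
        profile.per_slice.to_csv(out / "slice_sv.tsv", sep="\t", index=False)

    # -- stage 9: receptive fields ------------------------------------------
    acts = net.forward(scenes)[config.rf_layer]
    selection = select_units(acts, aff_rdm, group_norm, n=config.rf_n_units)
    rf_images = scenes[: config.rf_n_images]
    unit_maps = {int(u): [] for u in selection.unit_ids}
    for img_idx, sc in enumerate(rf_images):
        maps = map_discrepancy(
            net, sc, config.rf_layer, selection.unit_ids,
            patch_size=config.rf_occluder, stride=config.rf_stride,
            seed=seeds[7],
        )
        for u, m in maps.items():
            m.image_id = img_idx
            unit_maps[u].append(m)
    clustering = embed_and_cluster_units(
        unit_maps, rf_images, net, config.rf_layer,
        k_range=range(2, min(10, config.rf_n_units - 1) + 1), seed=seeds[8],
    )

    # -- stage 10: classification -------------------------------------------
    lab = generate_labeled_activations(
        config.class_n_images, config.class_n_units,
        config.class_n_informative, config.class_effect_size,
        n_properties=2, seed=seeds[9],
    )
    y = lab.labels.iloc[:, 0].to_numpy()
    md = min_distance_classify(lab.activations, y, property_name="navigability")
    null = resampling_null(
        lab.activations, lab.informative_units, y,
        n_iterations=config.n_iterations, seed=seeds[10],
        property_name="navigability",
    )
    y2 = lab.labels.iloc[:, 1].to_numpy()
    lda_other = loo_lda_classify(lab.activations, y2, lab.informative_units,
                                 property_name="property_1")
    lda_focal = loo_lda_classify(lab.activations, y, lab.informative_units,
                                 property_name="navigability")
    chi = compare_accuracies(lda_focal, lda_other, n_comparisons=1)

    # -- summary ------------------------------------------------------------
    summary = {
        "config": {k: v for k, v in asdict(config).items() if k != "out_dir"},
        "affordance": {
            "n_scenes": config.n_scenes,
            "mean_peak_error_deg": float(np.mean(peak_err)),
        },
        "cohort": {
            "rho_recovery": rho_recovery,
            "rho_normalized": rho_normalized,
            "noise_ceiling": ceiling.value,
        },
        "rsa": rsa_rows,
        "best_layer": best_layer,
        "commonality": {
            "r2_full": common.r2_full,
            "r2_affordance": common.r2_x1,
            "r2_layer": common.r2_x2,
            "shared_variance_pct": common.shared_variance_pct,
        },
        "feature_sv_mean": {
            f"{r.feature}|{r.target}": r["mean"]
            for _, r in feat_summary.iterrows()
        },
        "feature_contrasts": {
            name: {t: d["lower_95_one_tailed"] for t, d in per.items()}
            for name, per in contrasts.items()
        },
        "slice": {
            "n_positions": len(profile.positions),
            "lower_minus_upper": profile.lower_minus_upper,
        },
        "receptive_fields": {
            "n_units": int(len(selection.unit_ids)),
            "mean_score": float(np.mean(selection.scores)),
            "k_clusters": int(clustering.k),
            "silhouette": (None if clustering.silhouette is None
                           else float(clustering.silhouette)),
        },
        "classification": {
            "min_distance_accuracy": md.accuracy,
            "lda_focal_accuracy": null.focal_accuracy,
            "lda_other_property_accuracy": lda_other.accuracy,
            "focal_percentile": null.percentile,
            "chi2_p_navigability_vs_other": chi["p_value"],
        },
    }
    summary = _round(summary)
    if out is not None:
        (out / "summary.json").write_text(
            json.dumps(summary, sort_keys=True, indent=1))
        manifest = {
            "seed": config.seed,
            "stage_seeds": seeds,
            "config": summary["config"],
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, sort_keys=True, indent=1))
    return PipelineResult(
        summary=summary,
        affordance=aff_rdm,
        group_recovery=group_rec,
        group_normalized=group_norm,
        layer_rdms=lrdms,
        feature_table=feat,
        slice_profile=profile,
        clustering=clustering,
    )
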