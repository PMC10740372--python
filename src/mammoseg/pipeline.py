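"""End-to-end orchestration on synthetic phantoms: training-set assembly,
cascade training/evaluation, the fusion-classifier experiment, and a
one-command demo that exercises every stage and reports its own metrics.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sp_stats

from . import cascade, fusion, histmatch, metrics, phantom, preprocess, segmentation
from .io import ImageVolume, LabelMask

__all__ = [
    "DemoConfig",
    "make_phantom_set",
    "build_gland_training_set",
    "build_lesion_training_set",
    "train_cascade_models",
    "evaluate_cascade",
    "build_fusion_samples",
    "fusion_experiment",
    "harmonization_experiment",
    "run_demo",
]


def make_phantom_set(n: int, spec: phantom.PhantomSpec, center_id: str, seed0: int):
    """n deterministic phantoms with consecutive seeds."""
    out = [phantom.generate_phantom(spec, seed0 + i, center_id=center_id) for i in range(n)]
    return [v for v, _ in out], [t for _, t in out]


def build_gland_training_set(vols, truths):
    return [
        (preprocess.zscore_normalize(v), t.gland_mask) for v, t in zip(vols, truths)
    ]


def build_lesion_training_set(
    vols, truths, margin_mm: float = 5.0, patch_size: int = 24, normalize: bool = True
):
    """Step-2 training pairs: gland bounding-box crops (true gland masks),
    z-scored only, padded up to the patch size; lesion labels cropped
    identically. ``normalize=False`` returns raw-intensity crops so that
    histogram matching can run before normalization."""
    pairs = []
    for v, t in zip(vols, truths):
        crop, off = cascade.crop_to_mask(v, t.gland_mask, margin_mm=margin_mm)
        lab = t.lesion_mask.data[
            tuple(slice(o, o + s) for o, s in zip(off, crop.shape))
        ]
        pad = [max(0, patch_size - s) for s in crop.shape]
        if any(pad):
            crop = crop.with_data(np.pad(crop.data, [(0, p) for p in pad], mode="edge"))
            lab = np.pad(lab, [(0, p) for p in pad])
        if normalize:
            crop = preprocess.zscore_normalize(crop)
        pairs.append((crop, LabelMask(data=lab.astype(np.uint8), spacing=crop.spacing)))
    return pairs


def train_cascade_models(
    vols,
    truths,
    seed: int = 0,
    patch_size: int = 24,
    gland_epochs: int = 30,
    lesion_epochs: int = 60,
    lr0: float = 1e-3,
    steps_per_epoch: int = 8,
    lesion_steps_per_epoch: int = 10,
    batch_size: int = 2,
    lesion_pairs=None,
):
    """Train the step-1 gland and step-2 lesion segmenters at desk scale."""
    cfg = segmentation.SegNetConfig(
        depth=3, base_channels=8, patch_size=patch_size, num_classes=2
    )
    gmodel = segmentation.build_segnet(cfg, seed=seed)
    segmentation.train_segmenter(
        gmodel,
        build_gland_training_set(vols, truths),
        segmentation.TrainSchedule(lr0=lr0, max_epochs=gland_epochs),
        seed=seed + 1,
        steps_per_epoch=steps_per_epoch,
        batch_size=batch_size,
    )
    if lesion_pairs is None:
        lesion_pairs = build_lesion_training_set(vols, truths, patch_size=patch_size)
    lmodel = segmentation.build_segnet(cfg, seed=seed + 2)
    segmentation.train_segmenter(
        lmodel,
        lesion_pairs,
        segmentation.TrainSchedule(lr0=lr0, max_epochs=lesion_epochs),
        seed=seed + 3,
        steps_per_epoch=lesion_steps_per_epoch,
        batch_size=batch_size,
        fg_oversample=0.6,
    )
    return gmodel, lmodel


def evaluate_cascade(gmodel, lmodel, vols, truths, config=None):
    """Per-phantom lesion Dice and overlap with the true heart mask."""
    dices, heart_overlap = [], []
    for v, t in zip(vols, truths):
        pred = cascade.run_two_step(v, gmodel, lmodel, config=config)
        dices.append(metrics.dice_coefficient(pred, t.lesion_mask))
        heart_overlap.append(int((pred.data & t.heart_mask.data).sum()))
    return {"lesion_dice": dices, "heart_overlap_vox": heart_overlap}


def build_fusion_samples(cohort, spec: phantom.PhantomSpec, cube: int = 16):
    """(crop, markers, label) triples; phantoms are regenerated from each
    record's stored seed and cropped around the true lesion."""
    samples = []
    for r in cohort:
        v, t = phantom.generate_phantom(spec, r.phantom_seed, center_id=r.center_id)
        crop = fusion.crop_resample_lesion(v, t.lesion_mask, cube=cube)
        samples.append((crop.data, fusion.encode_markers(r), r.pcr_label))
    return samples


def fusion_experiment(
    train_samples,
    test_samples,
    cube: int = 16,
    seeds=(1, 2, 3),
    epochs: int = 15,
    lr: float = 1e-3,
    channels=(4, 8, 16, 16, 16),
):
    """Train multi-modal and image-only (gates forced to one) classifiers
    for each seed; returns per-seed test AUC/accuracy and predictions of
    the last seed for the paired statistics."""
    cfg = fusion.FusionNetConfig(
        num_stages=len(channels), image_channels=tuple(channels), input_cube=cube
    )
    labels = [int(s[2]) for s in test_samples]
    out = {"multi_auc": [], "image_auc": [], "multi_acc": [], "image_acc": []}
    preds = {}
    for seed in seeds:
        for mode, key in (("normal", "multi"), ("ones", "image")):
            model = fusion.build_fusion_net(cfg, seed=seed)
            fusion.train_fusion(
                model, train_samples, lr=lr, epochs=epochs, seed=seed + 10, gate_mode=mode
            )
            scores = [
                float(model.predict_proba(c, m, gate_mode=mode)[1])
                for c, m, _ in test_samples
            ]
            out[f"{key}_auc"].append(metrics.auc(labels, scores))
            out[f"{key}_acc"].append(
                metrics.accuracy(labels, [int(s >= 0.5) for s in scores])
            )
            preds[key] = [int(s >= 0.5) for s in scores]
    out["labels"] = labels
    out["last_seed_predictions"] = preds
    return out


def harmonization_experiment(
    spec: phantom.PhantomSpec, n_per_center: int = 20, seed: int = 0, L: int = 256
):
    """Cross-center KS distance of gland-voxel intensities before and
    after matching center-A volumes to random center-B histograms."""
    vols_a, truths_a = make_phantom_set(n_per_center, spec, "A", seed)
    vols_b, truths_b = make_phantom_set(n_per_center, spec, "B", seed + 10000)
    hists_b = [histmatch.compute_histogram(v, L=L) for v in vols_b]
    rng = np.random.default_rng(seed + 555)
    ks_raw, ks_matched = [], []
    for (va, ta), (vb, tb) in zip(zip(vols_a, truths_a), zip(vols_b, truths_b)):
        ga = va.data[ta.gland_mask.data > 0]
        gb = vb.data[tb.gland_mask.data > 0]
        ks_raw.append(float(sp_stats.ks_2samp(ga, gb).statistic))
        vm = histmatch.match_histogram(va, hists_b[int(rng.integers(len(hists_b)))])
        ks_matched.append(
            float(sp_stats.ks_2samp(vm.data[ta.gland_mask.data > 0], gb).statistic)
        )
    return {
        "ks_raw_mean": float(np.mean(ks_raw)),
        "ks_matched_mean": float(np.mean(ks_matched)),
        "reduction": 1.0 - float(np.mean(ks_matched)) / float(np.mean(ks_raw)),
    }


@dataclass
class DemoConfig:
    """Desk-scale sizes for the one-command demo."""

    spec: phantom.PhantomSpec = field(default_factory=phantom.PhantomSpec)
    outcome: phantom.OutcomeModel = field(default_factory=phantom.OutcomeModel)
    n_seg_train: int = 6
    n_seg_test: int = 4
    n_harmonization: int = 10
    n_fusion: int = 120
    fusion_train_frac: float = 0.65
    fusion_cube: int = 16
    fusion_epochs: int = 10
    gland_epochs: int = 20
    lesion_epochs: int = 25
    use_histogram_matching: bool = True


def run_demo(config: DemoConfig | None = None, seed: int = 0) -> dict:
    """Exercise the full pipeline on synthetic data and report the metrics
    it computes along the way."""
    config = config or DemoConfig()
    spec = config.spec
    report: dict = {"seed": seed, "stages": {}}

    def stage(name):
        report["stages"][name] = round(time.time() - t0, 1)

    t0 = time.time()
    vols, truths = make_phantom_set(
        config.n_seg_train + config.n_seg_test, spec, "A", 100 + seed
    )
    tr_v, tr_t = vols[: config.n_seg_train], truths[: config.n_seg_train]
    te_v, te_t = vols[config.n_seg_train :], truths[config.n_seg_train :]
    stage("phantoms")

    t0 = time.time()
    if config.use_histogram_matching:
        # match raw-intensity crops to test-center histograms, then z-score
        raw_pairs = build_lesion_training_set(tr_v, tr_t, normalize=False)
        vols_b, _ = make_phantom_set(config.n_seg_train, spec, "B", 5000 + seed)
        hists_b = [histmatch.compute_histogram(v) for v in vols_b]
        augmented = histmatch.augment_cohort_by_matching(raw_pairs, hists_b, seed=seed + 7)
        lesion_pairs = [
            (preprocess.zscore_normalize(vol), lab) for vol, lab, _ in augmented
        ]
    else:
        lesion_pairs = build_lesion_training_set(tr_v, tr_t)
    gmodel, lmodel = train_cascade_models(
        tr_v,
        tr_t,
        seed=seed,
        gland_epochs=config.gland_epochs,
        lesion_epochs=config.lesion_epochs,
        lesion_pairs=lesion_pairs,
    )
    stage("cascade_training")

    t0 = time.time()
    ev = evaluate_cascade(gmodel, lmodel, te_v, te_t)
    report["lesion_dice_mean"] = float(np.mean(ev["lesion_dice"]))
    report["lesion_dice"] = [round(d, 3) for d in ev["lesion_dice"]]
    report["heart_overlap_vox"] = ev["heart_overlap_vox"]
    stage("cascade_inference")

    t0 = time.time()
    report["harmonization"] = harmonization_experiment(
        spec, n_per_center=config.n_harmonization, seed=seed + 21
    )
    stage("harmonization")

    t0 = time.time()
    cohort = phantom.generate_cohort(
        config.n_fusion, spec=spec, outcome=config.outcome, center_mix=0.0, seed=seed + 31
    )
    samples = build_fusion_samples(cohort, spec, cube=config.fusion_cube)
    n_tr = int(round(config.fusion_train_frac * len(samples)))
    fx = fusion_experiment(
        samples[:n_tr],
        samples[n_tr:],
        cube=config.fusion_cube,
        seeds=(seed + 1,),
        epochs=config.fusion_epochs,
    )
    report["fusion"] = {
        "multi_auc": [round(a, 3) for a in fx["multi_auc"]],
        "image_auc": [round(a, 3) for a in fx["image_auc"]],
        "multi_acc": [round(a, 3) for a in fx["multi_acc"]],
        "image_acc": [round(a, 3) for a in fx["image_acc"]],
    }
    stage("fusion")

    # paired statistics on the demo's own test predictions
    labels = fx["labels"]
    p_multi = fx["last_seed_predictions"]["multi"]
    p_image = fx["last_seed_predictions"]["image"]
    table = metrics.PairedOutcomeTable.from_predictions(p_multi, p_image)
    report["mcnemar"] = {"a": table.a, "b": table.b, "c": table.c, "d": table.d}
    if table.b + table.c > 0:
        chi2, p = metrics.mcnemar_chi2(table)
        report["mcnemar"].update({"chi2": round(chi2, 3), "p": round(p, 4)})
    truth_counts = np.array(
        [sum(1 for y in labels if y == 1), sum(1 for y in labels if y == 0)]
    )
    for key, pred in (("gof_multi", p_multi), ("gof_image", p_image)):
        obs = np.array([sum(pred), len(pred) - sum(pred)])
        chi2, p = metrics.chisq_gof(metrics.GofInput(observed=obs, expected_source=truth_counts))
        report[key] = {"chi2": round(chi2, 3), "p": round(p, 4)}
    return report
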