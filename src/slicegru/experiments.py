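"""Reference desk-scale experiments on synthetic phantoms.

These drivers define the study conditions under which the package
demonstrates its statistical behaviour end to end:

* ``signal_experiment`` — 40 subjects per class, 48^3 voxels, a strong
  focal deficit (0.8 intensity units against noise 0.3): the full
  three-view pipeline should recover the class structure with high
  held-out AUC, and fused validation accuracy can never fall below the
  best single view (the weight grid contains the degenerate corners).
* ``null_experiment`` — the same protocol at effect size 0: test AUC must
  be statistically indistinguishable from 0.5.  Several fold rotations are
  pooled so the Monte-Carlo null band is informative.
* ``attention_experiment`` — a well-separated single-view run whose
  aggregate occlusion attention map should peak inside the (dilated)
  planted deficit region.

Problem sizes are chosen so a full run stays in the minutes range on one
CPU; the recurrent and convolutional layer widths are scaled down
accordingly while every structural element of the full model is retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .attention import OcclusionConfig
from .cnn import TrainConfig
from .ensemble import null_auc_band, roc_auc
from .gru import SequenceTrainConfig
from .pipeline import ExperimentResult, PipelineConfig, attention_analysis, run_split, simple_split
from .synthetic import PhantomSpec, generate_dataset
from .ensemble import make_folds


def desk_config(seed: int = 0, views=("axial", "sagittal", "coronal"), crop: int = 48) -> PipelineConfig:
    """Desk-scale pipeline settings used by all reference experiments."""
    return PipelineConfig(
        views=tuple(views),
        crop=crop,
        cnn=TrainConfig(learning_rate=2e-3, epochs=8, patience=3, dropout_rate=0.3, batch_size=40),
        seq=SequenceTrainConfig(learning_rate=1e-3, epochs=40, patience=8, hidden_dim=32,
                                fc_sizes=(64, 32), dropout_rate=0.2, batch_size=40),
        seed=seed,
    )


def desk_phantoms(seed: int, effect_size: float = 0.8, n_per_class: int = 40):
    return generate_dataset(PhantomSpec(shape=(48, 48, 48), n_per_class=n_per_class,
                                        effect_size=effect_size, noise_sd=0.3,
                                        n_regions=3, region_radii=(6, 6, 6), jitter=3, seed=seed))


@dataclass
class SignalSummary:
    result: ExperimentResult
    test_auc: float
    test_acc: float
    fused_val_accuracy: float
    best_view_val_accuracy: float
    n_test: int


def signal_experiment(seed: int = 0) -> SignalSummary:
    """Full three-view pipeline on well-separated phantoms, one fold rotation."""
    ds = desk_phantoms(seed, effect_size=0.8)
    cfg = desk_config(seed)
    split = make_folds(ds.labels, k=10, seed=seed)
    train_idx, val_idx, test_idx = split.rotation(0)
    res = run_split(ds.volumes, ds.labels, train_idx, val_idx, test_idx, cfg)
    return SignalSummary(
        result=res,
        test_auc=float(res.test_auc),
        test_acc=float(res.test_report.acc),
        fused_val_accuracy=float(res.fused_val_accuracy),
        best_view_val_accuracy=float(max(res.view_val_accuracy.values())),
        n_test=len(test_idx),
    )


@dataclass
class NullSummary:
    pooled_auc: float
    band: tuple[float, float]
    inside_band: bool
    n_test: int


def null_experiment(seed: int = 0, n_rotations: int = 4) -> NullSummary:
    """The same protocol at effect size 0, pooling test scores over rotations.

    Each subject is tested in exactly one rotation, so pooling is legitimate;
    the 95% Monte-Carlo null band is computed for the pooled test size.
    """
    ds = desk_phantoms(seed + 500, effect_size=0.0)
    cfg = desk_config(seed)
    split = make_folds(ds.labels, k=10, seed=seed)
    pooled_scores, pooled_labels = [], []
    for r in range(n_rotations):
        train_idx, val_idx, test_idx = split.rotation(r)
        res = run_split(ds.volumes, ds.labels, train_idx, val_idx, test_idx, cfg)
        pooled_scores.append(res.fused_test_scores[:, 1])
        pooled_labels.append(ds.labels[test_idx])
    scores = np.concatenate(pooled_scores)
    labels = np.concatenate(pooled_labels)
    _, auc = roc_auc(scores, labels)
    band = null_auc_band(int((labels == 1).sum()), int((labels == 0).sum()), n_draws=2000, seed=seed)
    return NullSummary(pooled_auc=float(auc), band=band, inside_band=band[0] <= auc <= band[1],
                       n_test=len(labels))


@dataclass
class AttentionSummary:
    test_auc: float
    peak_inside: bool
    n_maps: int


def attention_experiment(seed: int = 0) -> AttentionSummary:
    """Single-view pipeline on strongly separated phantoms + occlusion maps.

    Success means the aggregate attention volume peaks inside the union of
    the contributing subjects' planted deficit masks, dilated by half the
    occluder side.
    """
    ds = desk_phantoms(seed + 900, effect_size=1.0, n_per_class=20)
    cfg = desk_config(seed, views=("axial",))
    train_idx, val_idx, test_idx = simple_split(ds.labels, (0.5, 0.25, 0.25), seed=seed)
    res = run_split(ds.volumes, ds.labels, train_idx, val_idx, test_idx, cfg)
    occ = OcclusionConfig(square=8, stride=4, fill=0.0)
    agg, maps, used = attention_analysis(res, ds.volumes, ds.labels, val_idx, occ,
                                         top_k=3, max_subjects=4)
    union = np.zeros(ds.volumes[0].shape, dtype=bool)
    for si in used:
        union |= ds.region_truth[si]
    dilated = ndimage.binary_dilation(union, iterations=occ.square // 2)
    peak = np.unravel_index(np.argmax(agg), agg.shape)
    return AttentionSummary(test_auc=float(res.test_auc), peak_inside=bool(dilated[peak]),
                            n_maps=len(maps))


def attention_localization_rate(seeds) -> tuple[float, list[AttentionSummary]]:
    """Fraction of seeded runs whose attention peak lands inside the truth mask."""
    summaries = [attention_experiment(s) for s in seeds]
    rate = float(np.mean([s.peak_inside for s in summaries]))
    return rate, summaries


def gru_oracle_max_error(n_instances: int = 200, seed: int = 2024) -> float:
    """Max deviation between the vectorised recurrence and a scalar-loop oracle."""
    import math

    from .gru import GRUParams, run_gru

    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        F = int(rng.integers(1, 9))
        H = int(rng.integers(1, 9))
        p = GRUParams.random(F, H, rng, scale=1.5)
        n = int(rng.integers(1, 11))
        seq = rng.standard_normal((n, F)) * 2.0
        states = run_gru(p, seq)
        h = np.zeros(H)
        for i in range(n):
            z = np.array([1.0 / (1.0 + math.exp(-(p.W_xz[a] @ seq[i] + p.W_hz[a] @ h))) for a in range(H)])
            r = np.array([1.0 / (1.0 + math.exp(-(p.W_xr[a] @ seq[i] + p.W_hr[a] @ h))) for a in range(H)])
            hc = np.array([math.tanh(p.W_xh[a] @ seq[i] + p.W_hh[a] @ (h * r)) for a in range(H)])
            h = (1.0 - z) * hc + z * h
            worst = max(worst, float(np.abs(states[i] - h).max()))
    return worst
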