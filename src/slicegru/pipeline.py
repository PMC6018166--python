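"""End-to-end orchestration: volumes -> per-view CNN+BGRU models -> fusion.

Training is two-stage per view, mirroring the intended use of the parts:

1. every slice group gets its own 2D CNN, pre-trained on slice-level labels
   inherited from the subject; groups whose slice-level validation accuracy
   is weak are pruned;
2. per subject, a fixed number of equally spaced slices from each retained
   group are embedded by that group's (now frozen) CNN and spliced, in
   ascending slice order, into one feature sequence per view, on which the
   stacked bidirectional GRU classifier is trained.

The three per-view subject scores are finally fused by grid-searched
weighted averaging; evaluation uses the stratified rotation protocol from
:mod:`slicegru.ensemble`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .attention import AttentionMap, OcclusionConfig, compile_attention, occlusion_map, select_top_groups
from .cnn import CNNArchitecture, TrainConfig, TrainedGroupCNN, scaled_architecture, train_group_cnn
from .ensemble import (
    FusionWeights,
    MetricsReport,
    evaluate_scores,
    fused_accuracy,
    grid_search_weights,
    make_folds,
    prune_cnns,
)
from .gru import SequenceTrainConfig, TrainedSequenceModel, select_group_slices, train_sequence_model
from .volume_io import GroupingScheme, Volume, center_crop, decompose, make_groups

VIEWS = ("axial", "sagittal", "coronal")


@dataclass
class PipelineConfig:
    """All knobs of one experiment, with desk-scale defaults."""

    views: tuple[str, ...] = VIEWS
    crop: int = 48
    scheme: GroupingScheme = field(default_factory=GroupingScheme)
    slices_per_group: int = 4
    prune_threshold: float = 0.55
    grid_step: float = 0.1
    cnn: TrainConfig = field(default_factory=lambda: TrainConfig(
        learning_rate=2e-3, epochs=8, patience=3, dropout_rate=0.3, batch_size=40))
    seq: SequenceTrainConfig = field(default_factory=lambda: SequenceTrainConfig(
        hidden_dim=32, fc_sizes=(64, 32), epochs=40, patience=8, dropout_rate=0.2, batch_size=40))
    arch: CNNArchitecture | None = None  # default: scaled_architecture(crop)
    seed: int = 0

    def architecture(self) -> CNNArchitecture:
        return self.arch if self.arch is not None else scaled_architecture(self.crop)


def view_slice_tensor(volumes: list[Volume], view: str, crop: int) -> np.ndarray:
    """(N_subjects, n_slices, crop, crop) slice array for one view."""
    stacks = []
    for v in volumes:
        stack = decompose(v, view)
        stacks.append(np.stack([center_crop(sl, (crop, crop)) for sl in stack.slices]))
    return np.stack(stacks)


@dataclass
class ViewModel:
    """Everything needed to score a subject volume from one view."""

    view: str
    crop: int
    scheme: GroupingScheme
    group_starts: list[int]
    group_models: dict[int, TrainedGroupCNN]
    retained: list[int]
    slice_offsets: list[int]  # offsets within a group that feed the sequence
    seq_model: TrainedSequenceModel
    norm_mean: float
    norm_sd: float
    val_accuracy: float = 0.0

    @property
    def group_val_accuracies(self) -> dict[int, float]:
        return {s: m.val_accuracy for s, m in self.group_models.items()}

    def _normalize(self, x: np.ndarray) -> np.ndarray:
        return (x - self.norm_mean) / self.norm_sd

    def sequences(self, volumes: list[Volume]) -> np.ndarray:
        tensor = self._normalize(view_slice_tensor(volumes, self.view, self.crop))
        chunks = []
        for start in self.retained:
            model = self.group_models[start].model
            for off in self.slice_offsets:
                sl = tensor[:, start + off]
                chunks.append(model.features(sl[:, None]))
        return np.stack(chunks, axis=1)  # (N, n_retained * m, F)

    def score(self, volumes: list[Volume]) -> np.ndarray:
        return self.seq_model.model.predict_proba(self.sequences(volumes))

    def slice_classifier(self, volume: Volume, group_start: int, offset: int):
        """A callable (raw 2D slice) -> class probabilities for occlusion analysis.

        Only the named slice is treated as free input: its feature vector is
        recomputed and substituted into the subject's cached sequence.
        """
        base = self.sequences([volume])[0]
        pos = None
        k = 0
        for start in self.retained:
            for off in self.slice_offsets:
                if start == group_start and off == offset:
                    pos = k
                k += 1
        if pos is None:
            raise ValueError(f"group {group_start} offset {offset} not part of the model's sequence")
        model = self.group_models[group_start].model

        def classify(slice_2d: np.ndarray) -> np.ndarray:
            """Accepts one (H, W) slice or a batch (P, H, W) of variants."""
            arr = self._normalize(np.asarray(slice_2d, dtype=np.float64))
            single = arr.ndim == 2
            if single:
                arr = arr[None]
            feats = model.features(arr[:, None])
            seqs = np.repeat(base[None], len(feats), axis=0)
            seqs[:, pos] = feats
            probs = self.seq_model.model.predict_proba(seqs)
            return probs[0] if single else probs

        classify.accepts_batch = True
        return classify


def train_view_model(
    volumes: list[Volume],
    labels: np.ndarray,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    view: str,
    cfg: PipelineConfig,
) -> ViewModel:
    """Two-stage training of one view: per-group CNNs, pruning, then the BGRU."""
    labels = np.asarray(labels, dtype=int)
    tensor = view_slice_tensor(volumes, view, cfg.crop)
    mean = float(tensor[train_idx].mean())
    sd = float(tensor[train_idx].std()) or 1.0
    tensor = (tensor - mean) / sd
    n_slices = tensor.shape[1]
    starts = make_groups(n_slices, cfg.scheme)
    if not starts:
        raise ValueError(f"no complete slice group fits {n_slices} slices")
    L = cfg.scheme.group_size

    group_models: dict[int, TrainedGroupCNN] = {}
    for gi, start in enumerate(starts):
        tr = tensor[train_idx][:, start : start + L].reshape(-1, cfg.crop, cfg.crop)
        tr_y = np.repeat(labels[train_idx], L)
        va = tensor[val_idx][:, start : start + L].reshape(-1, cfg.crop, cfg.crop)
        va_y = np.repeat(labels[val_idx], L)
        gcfg = replace(cfg.cnn, seed=cfg.seed * 1000 + gi)
        group_models[start] = train_group_cnn(tr, tr_y, va, va_y, gcfg, arch=cfg.architecture())

    retained = prune_cnns({s: m.val_accuracy for s, m in group_models.items()}, cfg.prune_threshold)
    offsets = select_group_slices(L, cfg.slices_per_group)

    def sequences_of(idx: np.ndarray) -> np.ndarray:
        chunks = []
        for start in retained:
            model = group_models[start].model
            for off in offsets:
                chunks.append(model.features(tensor[idx][:, start + off][:, None]))
        return np.stack(chunks, axis=1)

    scfg = replace(cfg.seq, seed=cfg.seed * 1000 + 777)
    seq = train_sequence_model(sequences_of(train_idx), labels[train_idx], sequences_of(val_idx), labels[val_idx], scfg)
    return ViewModel(
        view=view,
        crop=cfg.crop,
        scheme=cfg.scheme,
        group_starts=starts,
        group_models=group_models,
        retained=retained,
        slice_offsets=offsets,
        seq_model=seq,
        norm_mean=mean,
        norm_sd=sd,
        val_accuracy=seq.val_accuracy,
    )


@dataclass
class ExperimentResult:
    view_models: dict[str, ViewModel]
    weights: FusionWeights
    view_val_accuracy: dict[str, float]
    fused_val_accuracy: float
    view_test_scores: dict[str, np.ndarray]
    fused_test_scores: np.ndarray
    test_labels: np.ndarray
    test_report: MetricsReport

    @property
    def test_auc(self) -> float:
        return self.test_report.auc


def run_split(
    volumes: list[Volume],
    labels: np.ndarray,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    test_idx: np.ndarray,
    cfg: PipelineConfig,
) -> ExperimentResult:
    """Train all views on one train/validation split and score the test set."""
    labels = np.asarray(labels, dtype=int)
    view_models = {
        view: train_view_model(volumes, labels, train_idx, val_idx, view, cfg) for view in cfg.views
    }
    val_volumes = [volumes[i] for i in val_idx]
    test_volumes = [volumes[i] for i in test_idx]
    val_scores = {v: m.score(val_volumes) for v, m in view_models.items()}
    test_scores = {v: m.score(test_volumes) for v, m in view_models.items()}
    if set(cfg.views) == set(VIEWS):
        weights, fused_val_acc = grid_search_weights(val_scores, labels[val_idx], cfg.grid_step)
    else:  # degenerate single/dual-view runs: uniform over the present views
        w = {v: (1.0 / len(cfg.views) if v in cfg.views else 0.0) for v in VIEWS}
        for v in VIEWS:
            val_scores.setdefault(v, next(iter(val_scores.values())) * 0.0 + 0.5)
            test_scores.setdefault(v, next(iter(test_scores.values())) * 0.0 + 0.5)
        weights = FusionWeights(w["axial"], w["sagittal"], w["coronal"])
        fused_val_acc = fused_accuracy(val_scores, labels[val_idx], (w["axial"], w["sagittal"], w["coronal"]))
    wt = (weights.w_axial, weights.w_sagittal, weights.w_coronal)
    fused_test = sum(wv * test_scores[v] for wv, v in zip(wt, VIEWS))
    report = evaluate_scores(fused_test, labels[test_idx])
    return ExperimentResult(
        view_models=view_models,
        weights=weights,
        view_val_accuracy={v: float((val_scores[v].argmax(axis=1) == labels[val_idx]).mean()) for v in cfg.views},
        fused_val_accuracy=fused_val_acc,
        view_test_scores=test_scores,
        fused_test_scores=fused_test,
        test_labels=labels[test_idx],
        test_report=report,
    )


def run_rotation(volumes, labels, cfg: PipelineConfig, k: int = 10, rotation: int = 0) -> ExperimentResult:
    """One rotation of the k-fold protocol: fold r tests, fold r+1 validates."""
    split = make_folds(np.asarray(labels, dtype=int), k=k, seed=cfg.seed)
    train_idx, val_idx, test_idx = split.rotation(rotation)
    return run_split(volumes, labels, train_idx, val_idx, test_idx, cfg)


def simple_split(labels: np.ndarray, fractions=(0.6, 0.2, 0.2), seed: int = 0):
    """Stratified train/validation/test split by class-wise proportions."""
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    parts: list[list[int]] = [[], [], []]
    for cls in np.unique(labels):
        idx = rng.permutation(np.flatnonzero(labels == cls))
        n = len(idx)
        n_train = int(round(fractions[0] * n))
        n_val = int(round(fractions[1] * n))
        parts[0].extend(idx[:n_train])
        parts[1].extend(idx[n_train : n_train + n_val])
        parts[2].extend(idx[n_train + n_val :])
    return tuple(np.sort(np.asarray(p, dtype=int)) for p in parts)


def attention_analysis(
    result: ExperimentResult,
    volumes: list[Volume],
    labels: np.ndarray,
    subject_idx: np.ndarray,
    occlusion: OcclusionConfig,
    top_k: int = 3,
    max_subjects: int | None = None,
) -> tuple[np.ndarray, list[AttentionMap], list[int]]:
    """Aggregate occlusion attention over correctly classified subjects.

    For each view, the ``top_k`` groups by slice-level validation accuracy
    are selected; each of a subject's sequence slices in those groups is
    occluded in turn.  Returns (aggregate attention volume, individual
    maps, indices of contributing subjects).
    """
    labels = np.asarray(labels, dtype=int)
    shape = volumes[0].shape
    view_axes = volumes[0].view_axes
    maps: list[AttentionMap] = []
    used: list[int] = []
    for view, vm in result.view_models.items():
        axis = view_axes[view]
        plane_axes = [a for a in range(3) if a != axis]
        plane_shape = (shape[plane_axes[0]], shape[plane_axes[1]])
        offset = ((plane_shape[0] - vm.crop) // 2, (plane_shape[1] - vm.crop) // 2)
        top = [g for g in select_top_groups(vm.group_val_accuracies, top_k) if g in vm.retained]
        chosen = subject_idx if max_subjects is None else subject_idx[:max_subjects]
        for si in chosen:
            vol = volumes[si]
            pred = vm.score([vol])[0].argmax()
            if pred != labels[si]:
                continue  # drops are sign-ambiguous for misclassified subjects
            if si not in used:
                used.append(si)
            stack = decompose(vol, view)
            tensor = np.stack([center_crop(sl, (vm.crop, vm.crop)) for sl in stack.slices])
            for start in top:
                for off in vm.slice_offsets:
                    raw_slice = tensor[start + off]
                    clf = vm.slice_classifier(vol, start, off)
                    maps.append(
                        occlusion_map(
                            clf,
                            raw_slice,
                            int(labels[si]),
                            occlusion,
                            provenance={"view": view, "slice_index": start + off, "offset": offset},
                        )
                    )
    if not maps:
        raise ValueError("no correctly classified subjects to analyse")
    return compile_attention(maps, shape, view_axes), maps, used
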