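"""Labelled 3D phantom volumes for exercising the classification pipeline.

The generator emulates the statistical structure the classifier relies on in
metabolic brain imaging, at desk scale and without any download:

* a smooth baseline intensity field (superposed broad Gaussian bumps over a
  constant plateau) shared by all subjects up to a small per-subject
  amplitude factor;
* class-dependent focal intensity *deficits* — ellipsoidal regions where
  class-1 subjects lose ``effect_size`` intensity units, mimicking focal
  hypometabolism;
* additive Gaussian voxel noise, clipped at zero to keep intensities valid;
* a small random integer translation per subject, standing in for the
  absence of rigid registration.

``region_truth`` records each subject's post-jitter deficit mask (recorded
for both classes; the deficit is only applied in class 1), which the
occlusion-attention tests use as ground truth for localization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .volume_io import Volume, write_volume


class PhantomSpecError(ValueError):
    """Raised when a phantom specification cannot be realised."""


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int] = (48, 48, 48)
    n_per_class: int = 40
    effect_size: float = 0.8
    noise_sd: float = 0.3
    n_regions: int = 3
    region_radii: tuple[int, int, int] = (6, 6, 6)
    jitter: int = 3
    seed: int = 0
    base_intensity: float = 1.5
    n_baseline_blobs: int = 6
    subject_scale_sd: float = 0.03

    def __post_init__(self):
        if self.effect_size < 0:
            raise PhantomSpecError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise PhantomSpecError("noise_sd must be > 0")
        if self.n_per_class < 1:
            raise PhantomSpecError("need at least one subject per class")
        for extent, radius in zip(self.shape, self.region_radii):
            if 2 * radius + 2 * self.jitter + 4 >= extent:
                raise PhantomSpecError(
                    f"region radius {radius} plus jitter {self.jitter} does not fit inside extent {extent}"
                )


@dataclass
class PhantomDataset:
    volumes: list[Volume]
    labels: np.ndarray
    region_truth: list[np.ndarray]
    subject_ids: list[str]
    spec: PhantomSpec = field(repr=False, default=None)

    def __post_init__(self):
        if not (len(self.volumes) == len(self.labels) == len(self.region_truth) == len(self.subject_ids)):
            raise ValueError("volumes, labels, region_truth and subject_ids must align")


def _gaussian_bump(grid, center, sigma):
    d2 = sum(((g - c) / s) ** 2 for g, c, s in zip(grid, center, sigma))
    return np.exp(-0.5 * d2)


def _ellipsoid_mask(shape, center, radii) -> np.ndarray:
    grid = np.ogrid[tuple(slice(0, e) for e in shape)]
    d2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grid, center, radii))
    return d2 <= 1.0


def generate_dataset(spec: PhantomSpec) -> PhantomDataset:
    """Generate a deterministic labelled phantom dataset from ``spec``."""
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(e) for e in spec.shape)
    grid = np.ogrid[tuple(slice(0, e) for e in shape)]

    # shared smooth baseline: plateau + broad bumps
    baseline = np.full(shape, spec.base_intensity)
    for _ in range(spec.n_baseline_blobs):
        center = [rng.uniform(0.2 * e, 0.8 * e) for e in shape]
        sigma = [rng.uniform(0.15 * e, 0.35 * e) for e in shape]
        baseline += 0.8 / spec.n_baseline_blobs * _gaussian_bump(grid, center, sigma)

    # template deficit regions, fixed across subjects, fully interior
    template_mask = np.zeros(shape, dtype=bool)
    for _ in range(spec.n_regions):
        center = [
            rng.uniform(r + spec.jitter + 2, e - r - spec.jitter - 2)
            for e, r in zip(shape, spec.region_radii)
        ]
        template_mask |= _ellipsoid_mask(shape, center, spec.region_radii)

    volumes, truths, ids = [], [], []
    labels = np.repeat([0, 1], spec.n_per_class)
    for i, label in enumerate(labels):
        scale = 1.0 + spec.subject_scale_sd * rng.standard_normal()
        vol = scale * baseline.copy()
        if label == 1:
            vol = vol - spec.effect_size * template_mask
        shift = rng.integers(-spec.jitter, spec.jitter + 1, size=3) if spec.jitter > 0 else np.zeros(3, int)
        vol = np.roll(vol, shift, axis=(0, 1, 2))
        truth = np.roll(template_mask, shift, axis=(0, 1, 2))
        vol = vol + spec.noise_sd * rng.standard_normal(shape)
        np.clip(vol, 0.0, None, out=vol)
        volumes.append(Volume(data=vol))
        truths.append(truth)
        ids.append(f"s{i:04d}")
    return PhantomDataset(volumes=volumes, labels=labels.copy(), region_truth=truths, subject_ids=ids, spec=spec)


def labels_table(ds: PhantomDataset, path) -> None:
    """Write the subject-label table as CSV with columns subject_id, class."""
    pd.DataFrame({"subject_id": ds.subject_ids, "class": ds.labels}).to_csv(path, index=False)


def read_labels(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str, "class": int})
    if list(df.columns) != ["subject_id", "class"]:
        raise ValueError("labels table must have columns subject_id, class")
    return df


def save_dataset(ds: PhantomDataset, out_dir) -> None:
    """Write NIfTI volumes, region-truth masks and the labels CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sid, vol, truth in zip(ds.subject_ids, ds.volumes, ds.region_truth):
        write_volume(vol, out / f"{sid}.nii.gz")
        write_volume(Volume(data=truth.astype(np.float64)), out / f"{sid}_truth.nii.gz")
    labels_table(ds, out / "labels.csv")
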