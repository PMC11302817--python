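"""Model-ready instances: resampling, normalization, augmentation, splitting."""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .simulate import DetectorGeometry, DetectorMap, PlanSample

N_CLASSES = 5

__all__ = [
    "ModelInstance",
    "SplitPlan",
    "resample_grid",
    "normalize_pair",
    "augment",
    "make_split",
    "instances_to_arrays",
]


@dataclasses.dataclass(frozen=True)
class ModelInstance:
    """Dual-channel normalized input: channel 0 calculated, channel 1 measured."""

    channels: np.ndarray          # (2, n_axial, n_circ), values in [0, 1]
    label: np.ndarray             # one-hot, length 5
    plan_id: str
    origin: str                   # plan_id plus augmentation tag

    def __post_init__(self) -> None:
        ch = np.asarray(self.channels, dtype=np.float64)
        if ch.ndim != 3 or ch.shape[0] != 2:
            raise ValueError(f"channels must be (2, H, W), got {ch.shape}")
        if ch.min() < 0 or ch.max() > 1 + 1e-12:
            raise ValueError("channel values must lie in [0, 1]")
        lab = np.asarray(self.label, dtype=np.float64)
        if lab.shape != (N_CLASSES,) or not np.isclose(lab.sum(), 1.0) \
                or not np.all(np.isin(lab, (0.0, 1.0))):
            raise ValueError("label must be a one-hot vector of length 5")
        object.__setattr__(self, "channels", ch)
        object.__setattr__(self, "label", lab)

    @property
    def label_index(self) -> int:
        return int(np.argmax(self.label))


@dataclasses.dataclass(frozen=True)
class SplitPlan:
    """Train/test plan ids plus the fold assignment of every training plan."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    folds: tuple[tuple[str, ...], ...]
    seed: int

    def __post_init__(self) -> None:
        train, test = set(self.train_ids), set(self.test_ids)
        if train & test:
            raise ValueError("train and test ids overlap")
        fold_union: set[str] = set()
        for f in self.folds:
            fs = set(f)
            if fs & fold_union:
                raise ValueError("folds are not disjoint")
            fold_union |= fs
        if fold_union != train:
            raise ValueError("folds must partition the training ids")

    def fold_of(self, plan_id: str) -> int:
        for k, f in enumerate(self.folds):
            if plan_id in f:
                return k
        raise KeyError(plan_id)

    def to_dict(self) -> dict:
        return {
            "train_ids": list(self.train_ids),
            "test_ids": list(self.test_ids),
            "folds": [list(f) for f in self.folds],
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SplitPlan":
        return cls(tuple(d["train_ids"]), tuple(d["test_ids"]),
                   tuple(tuple(f) for f in d["folds"]), int(d["seed"]))


def resample_grid(dose_grid: np.ndarray, axial_coords: np.ndarray,
                  circ_coords: np.ndarray,
                  target_geometry: DetectorGeometry) -> DetectorMap:
    """Bilinearly resample an arbitrary surface dose grid onto the diode lattice.

    ``axial_coords`` are mm from row 0 (increasing toward the last row) and
    ``circ_coords`` arc-length mm from column 0; the grid must cover the full
    diode lattice.  Exact at lattice-coincident nodes.
    """
    grid = np.asarray(dose_grid, dtype=float)
    az = np.asarray(axial_coords, dtype=float)
    cz = np.asarray(circ_coords, dtype=float)
    if grid.shape != (az.size, cz.size):
        raise ValueError("dose_grid shape does not match coordinate vectors")
    tg = target_geometry
    target_ax = np.arange(tg.n_axial) * tg.axial_pitch
    target_ci = np.arange(tg.n_circ) * tg.circ_pitch
    if az[0] > target_ax[0] + 1e-9 or az[-1] < target_ax[-1] - 1e-9 \
            or cz[0] > target_ci[0] + 1e-9 or cz[-1] < target_ci[-1] - 1e-9:
        raise ValueError("input grid does not cover the detector extent")
    interp = RegularGridInterpolator((az, cz), grid, method="linear",
                                     bounds_error=False, fill_value=None)
    aa, cc = np.meshgrid(target_ax, target_ci, indexing="ij")
    vals = interp(np.stack([aa.ravel(), cc.ravel()], axis=1)).reshape(tg.shape)
    return DetectorMap(np.clip(vals, 0.0, None), tg)


def normalize_pair(sample: PlanSample) -> ModelInstance:
    """Scale both channels by their joint maximum (preserves the dose ratio)."""
    m = max(sample.calculated.max, sample.measured.max)
    if m <= 0:
        raise ValueError(f"all-zero sample {sample.plan_id}")
    channels = np.stack([sample.calculated.values, sample.measured.values]) / m
    label = np.zeros(N_CLASSES)
    label[int(sample.label.error_class)] = 1.0
    return ModelInstance(channels=channels, label=label,
                         plan_id=sample.plan_id, origin=sample.plan_id)


_ROLL_CHOICES = np.array([-5, -4, -3, -2, -1, 1, 2, 3, 4, 5])
_AUG_NOISE_SIGMA = 0.002  # fraction of instance max


def augment(instances: Sequence[ModelInstance], factor: int = 5,
            seed: int = 0) -> list[ModelInstance]:
    """Expand the training set by label-preserving variants.

    Each original is kept and ``factor - 1`` variants are added, combining a
    joint circumferential roll of both channels by 1..5 columns either way, an
    optional joint axial flip, and additive Gaussian noise (0.2% of max) on
    the measured channel.  All geometric transforms hit both channels
    identically, so the calculated/measured relationship — and hence the
    label — is untouched.
    """
    if factor < 1:
        raise ValueError(f"factor must be >= 1, got {factor}")
    rng = np.random.default_rng(seed)
    out: list[ModelInstance] = []
    for inst in instances:
        out.append(inst)
        for j in range(factor - 1):
            ch = inst.channels
            k = int(rng.choice(_ROLL_CHOICES))
            ch = np.roll(ch, k, axis=2)
            if rng.random() < 0.5:
                ch = ch[:, ::-1, :]
            noise = rng.normal(0.0, _AUG_NOISE_SIGMA * ch.max(), ch.shape[1:])
            ch = ch.copy()
            ch[1] = np.clip(ch[1] + noise, 0.0, 1.0)
            out.append(ModelInstance(channels=ch, label=inst.label.copy(),
                                     plan_id=inst.plan_id,
                                     origin=f"{inst.plan_id}#aug{j}"))
    return out


def make_split(samples: Sequence[PlanSample], seed: int = 0,
               n_folds: int = 5, test_fraction: float = 0.25) -> SplitPlan:
    """Stratified 3:1 train/test split plus stratified fold assignment.

    All augmented variants of a plan follow its plan id, so fold membership
    is decided at the plan level and augmentation cannot leak across folds.
    """
    rng = np.random.default_rng(seed)
    by_class: dict[int, list[str]] = {}
    for s in samples:
        by_class.setdefault(int(s.label.error_class), []).append(s.plan_id)
    train_ids: list[str] = []
    test_ids: list[str] = []
    folds: list[list[str]] = [[] for _ in range(n_folds)]
    counter = 0  # global round-robin keeps folds balanced for any size
    for cls in sorted(by_class):
        ids = sorted(by_class[cls])
        rng.shuffle(ids)
        n_test = max(1, int(round(test_fraction * len(ids))))
        cls_train, cls_test = ids[:len(ids) - n_test], ids[len(ids) - n_test:]
        train_ids.extend(cls_train)
        test_ids.extend(cls_test)
        for pid in cls_train:
            folds[counter % n_folds].append(pid)
            counter += 1
    if len(train_ids) < n_folds:
        raise ValueError(
            f"{len(train_ids)} training plans is too few for {n_folds} folds")
    return SplitPlan(tuple(train_ids), tuple(test_ids),
                     tuple(tuple(f) for f in folds), seed)


def instances_to_arrays(instances: Sequence[ModelInstance]
                        ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Stack instances into (X, one-hot Y, plan ids) for training."""
    x = np.stack([i.channels for i in instances]).astype(np.float32)
    y = np.stack([i.label for i in instances]).astype(np.float32)
    return x, y, [i.plan_id for i in instances]
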