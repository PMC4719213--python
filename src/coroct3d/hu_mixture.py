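"""Stage 3: the four-component Gaussian mixture over Hounsfield units.

The HU distribution over the artery region is modeled as

    p(x | lambda) = sum_i w_i N(x | mu_i, sigma_i),   i in {lumen, CP, NCP, background}

with lambda = {w_i, mu_i, sigma_i}.  One representative point per class
(plus five random neighbors within a 1-pixel in-plane radius of each)
initializes the per-class means and standard deviations; expectation-
maximization then refines the parameters on HU samples from the vessel
region.  Components never get reordered during EM, so the component ->
class mapping inherited from the initialization is preserved.  Voxels
are classified by maximum posterior probability

    P(k | x) = w_k N(x; mu_k, sigma_k) / sum_i w_i N(x; mu_i, sigma_i).

The module also hosts the initialization-sensitivity utilities: random
+/- delta-T perturbation of the class HU points and the volume-retention
percentage C = 100 * (1 - |V_dT - V_0| / V_0).
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.special import logsumexp

from .volume_io import ImageVolume

#: class order; also the tie-break priority (earlier wins)
CLASSES = ("lumen", "CP", "NCP", "background")
CLASS_INDEX = {c: i for i, c in enumerate(CLASSES)}

SIGMA_FLOOR = 1.0          # HU; prevents component collapse
WEIGHT_FLOOR = 1e-6
INIT_SIGMA_FLOOR = 20.0    # HU; six neighborhood samples are too few to
                           # pin a width, so initialization gets a wide floor

DELTA_T_GRID = (20, 40, 60, 80, 100, 120, 140, 160, 180, 200)


@dataclass
class ClassSeed:
    """One class-representative point: voxel index and its HU value.

    ``hu`` is normally read from the image; the sensitivity experiment
    overrides it with a perturbed value.
    """

    index: tuple[int, int, int]
    hu: float | None = None


ClassSeedSet = dict  # class name -> ClassSeed, exactly one per class


def validate_seed_set(seeds: ClassSeedSet) -> None:
    if set(seeds) != set(CLASSES):
        raise ValueError(f"seed set must contain exactly the classes {CLASSES}")


def resolve_seed_hu(vol: ImageVolume, seeds: ClassSeedSet) -> ClassSeedSet:
    """Fill in each seed's HU from the volume where not already set."""
    validate_seed_set(seeds)
    out = {}
    for c, s in seeds.items():
        hu = s.hu if s.hu is not None else float(vol.voxels[tuple(s.index)])
        out[c] = ClassSeed(tuple(int(v) for v in s.index), hu)
    return out


def expand_seeds(vol: ImageVolume, seeds: ClassSeedSet, n_random: int = 5,
                 radius_px: float = 1.0, rng_seed: int = 0) -> dict[str, np.ndarray]:
    """Each seed plus ``n_random`` random in-plane points within ``radius_px``.

    Neighbor HU values are read from the image with bilinear in-plane
    interpolation; the seed itself contributes its (possibly overridden)
    HU value.  Returns per class an array of ``n_random + 1`` labeled
    samples — 24 in total with the defaults.  Deterministic per rng_seed.
    """
    seeds = resolve_seed_hu(vol, seeds)
    rng = np.random.default_rng(rng_seed)
    ni, nj, _ = vol.shape
    out: dict[str, np.ndarray] = {}
    for c in CLASSES:
        s = seeds[c]
        i0, j0, k0 = s.index
        if any(v < 0 or v >= n for v, n in zip(s.index, vol.shape)):
            raise ValueError(f"seed for {c} at {s.index} outside grid {vol.shape}")
        rr = radius_px * np.sqrt(rng.random(n_random))
        th = rng.random(n_random) * 2.0 * np.pi
        pi = i0 + rr * np.cos(th)
        pj = j0 + rr * np.sin(th)
        if np.any(pi < 0) or np.any(pi > ni - 1) or np.any(pj < 0) or np.any(pj > nj - 1):
            warnings.warn(f"seed for {c} at the grid border: neighborhood clipped",
                          stacklevel=2)
            pi = np.clip(pi, 0, ni - 1)
            pj = np.clip(pj, 0, nj - 1)
        vals = map_coordinates(vol.voxels[:, :, k0], np.vstack([pi, pj]), order=1)
        out[c] = np.concatenate([[s.hu], vals]).astype(float)
    return out


@dataclass
class HuMixtureModel:
    """Fitted 4-component 1D Gaussian mixture with a class per component."""

    weights: np.ndarray
    means: np.ndarray
    stds: np.ndarray
    classes: tuple[str, ...] = CLASSES
    ll_history: list[float] = field(default_factory=list, repr=False)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.stds = np.asarray(self.stds, dtype=float)
        if not (len(self.weights) == len(self.means) == len(self.stds) == len(self.classes)):
            raise ValueError("component arrays must have one entry per class")
        if abs(self.weights.sum() - 1.0) > 1e-9 or np.any(self.weights < 0):
            raise ValueError("weights must be non-negative and sum to 1")
        if np.any(self.stds < SIGMA_FLOOR - 1e-12):
            raise ValueError(f"stds must respect the {SIGMA_FLOOR} HU floor")

    # -- probabilities ----------------------------------------------------
    def _log_joint(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)[..., None]
        z = (x - self.means) / self.stds
        return (np.log(self.weights) - np.log(self.stds)
                - 0.5 * np.log(2.0 * np.pi) - 0.5 * z * z)

    def posterior(self, x) -> np.ndarray:
        """P(class | x) for scalar or array x; last axis orders CLASSES."""
        lj = self._log_joint(x)
        p = np.exp(lj - logsumexp(lj, axis=-1, keepdims=True))
        return p

    def classify(self, x) -> np.ndarray:
        """Index into CLASSES of the max-posterior class; ties resolve to
        the earlier (higher-priority) class because argmax keeps the first
        maximum and CLASSES is ordered lumen > CP > NCP > background."""
        lj = self._log_joint(x)
        return np.argmax(lj, axis=-1)

    def classify_labels(self, x) -> np.ndarray:
        return np.asarray(self.classes)[self.classify(x)]

    # -- serialization ----------------------------------------------------
    def to_json(self, path=None):
        d = {"weights": self.weights.tolist(), "means": self.means.tolist(),
             "stds": self.stds.tolist(), "classes": list(self.classes)}
        if path is not None:
            Path(path).write_text(json.dumps(d, indent=1))
        return d

    @classmethod
    def from_json(cls, source) -> "HuMixtureModel":
        if isinstance(source, (str, Path)):
            source = json.loads(Path(source).read_text())
        return cls(np.array(source["weights"]), np.array(source["means"]),
                   np.array(source["stds"]), tuple(source["classes"]))


def fit_em(samples: np.ndarray, init: dict[str, np.ndarray], tol: float = 1e-6,
           max_iter: int = 500) -> HuMixtureModel:
    """EM maximum-likelihood fit of the 4-component mixture.

    ``init`` maps each class to its labeled HU samples (seed + neighbors);
    initialization uses the per-class sample mean and a robust
    (median-absolute-deviation) scale floored at ``INIT_SIGMA_FLOOR``,
    with equal weights.  The robust scale matters: with only six labeled
    samples per class a single outlying value would inflate a plain
    standard deviation enough to let two components collapse onto the
    same cluster.  Iterations stop when the log-likelihood gain drops
    below ``tol`` per sample or after ``max_iter`` rounds; the
    log-likelihood is non-decreasing throughout.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite HU in samples")
    if len(x) < 4 * 10:
        raise ValueError(f"need at least 40 samples to fit 4 components, got {len(x)}")
    if set(init) != set(CLASSES):
        raise ValueError("init must label one cluster per class")

    means = np.array([np.mean(init[c]) for c in CLASSES], dtype=float)
    mad = np.array([np.median(np.abs(np.asarray(init[c])
                                     - np.median(init[c])))
                    for c in CLASSES])
    stds = np.maximum(1.4826 * mad, INIT_SIGMA_FLOOR)
    weights = np.full(len(CLASSES), 1.0 / len(CLASSES))

    n = len(x)
    ll_hist: list[float] = []
    ll_prev = -np.inf
    for _ in range(max_iter):
        z = (x[:, None] - means) / stds
        log_joint = (np.log(weights) - np.log(stds)
                     - 0.5 * np.log(2.0 * np.pi) - 0.5 * z * z)
        log_norm = logsumexp(log_joint, axis=1)
        ll = float(log_norm.sum())
        ll_hist.append(ll)
        resp = np.exp(log_joint - log_norm[:, None])

        nk = resp.sum(axis=0)
        weights = nk / n
        if np.any(weights < WEIGHT_FLOOR):
            warnings.warn("mixture weight hit the floor; component nearly empty",
                          stacklevel=2)
            weights = np.maximum(weights, WEIGHT_FLOOR)
            weights /= weights.sum()
        safe_nk = np.maximum(nk, 1e-12)
        means = (resp * x[:, None]).sum(axis=0) / safe_nk
        var = (resp * (x[:, None] - means) ** 2).sum(axis=0) / safe_nk
        new_stds = np.sqrt(var)
        if np.any(new_stds < SIGMA_FLOOR):
            warnings.warn(f"sigma clamped to the {SIGMA_FLOOR} HU floor", stacklevel=2)
        stds = np.maximum(new_stds, SIGMA_FLOOR)

        if ll - ll_prev < tol * n and np.isfinite(ll_prev):
            break
        ll_prev = ll
    return HuMixtureModel(weights, means, stds, CLASSES, ll_hist)


# -------------------------------------------------- initialization sensitivity

def sensitivity_C(volume_0: float, volume_dT: float) -> float:
    """Volume-retention percentage C = 100 * (1 - |V_dT - V_0| / V_0)."""
    if volume_0 <= 0:
        raise ValueError("reference volume must be > 0")
    return 100.0 * (1.0 - abs(volume_dT - volume_0) / volume_0)


def perturb_seeds(seeds: ClassSeedSet, delta_T: float, rng_seed: int = 0) -> ClassSeedSet:
    """Shift each class HU value by +delta_T or -delta_T with probability 0.5.

    Seeds must carry resolved HU values.  Deterministic per rng_seed;
    class order is fixed so the sign pattern is reproducible.
    """
    validate_seed_set(seeds)
    if delta_T < 0:
        raise ValueError("delta_T must be >= 0")
    rng = np.random.default_rng(rng_seed)
    out = {}
    for c in CLASSES:
        s = seeds[c]
        if s.hu is None:
            raise ValueError(f"seed for {c} has no resolved HU value")
        sign = 1.0 if rng.random() < 0.5 else -1.0
        out[c] = ClassSeed(tuple(s.index), s.hu + sign * delta_T)
    return out
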