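"""Seeded generator of artificial count-fingerprint screening datasets.

Licensed screening benchmarks (such as the MDDR activity classes) cannot
be redistributed, so this module fabricates datasets with the same
*shape*: a handful of activity classes whose intra-class mean pairwise
Tanimoto similarity is controllable — homogeneous classes around 0.23–0.36
and heterogeneous ones around 0.10–0.13, as in the published benchmark
subsets — plus a pool of unlabelled background molecules acting as decoys.

Generative model per class:

1. a *prototype* support of ≈ d·F features is drawn (d = prototype
   density, default 0.05 of F = 1024 features);
2. each member keeps each prototype feature with probability θ
   (*retention*) and gains each non-prototype feature with a small
   background rate r = |S|(1−θ)/(F−|S|), chosen so the expected number of
   on-features equals the prototype size;
3. counts on on-features are shifted-Poisson, 1 + Poisson(λ−1), so every
   occurring substructure has count ≥ 1 (mean λ).

θ controls homogeneity: θ=1 (and hence r=0) makes all members share the
prototype support exactly (binary diversity 1); small θ approaches random
overlap.  :func:`calibrate_homogeneity` inverts the map θ ↦ measured mean
pairwise similarity by bisection on a simulated pilot class, since the
count-noise model has no convenient closed form.

Background molecules draw independent supports at density d.  Everything
is driven by per-class substreams of a single seed, so a spec + seed pins
the dataset exactly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import yaml

from .fingerprints import BACKGROUND_LABEL, FingerprintDataset, mean_pairwise_binary_tanimoto


@dataclass
class ClassSpec:
    """One activity class: label, size, and either a target mean pairwise
    Tanimoto similarity (to be calibrated) or an explicit retention θ."""

    label: str
    size: int
    target_similarity: float | None = None
    theta: float | None = None

    def __post_init__(self):
        if self.size < 2:
            raise ValueError(f"class {self.label!r}: size must be >= 2")
        if (self.target_similarity is None) == (self.theta is None):
            raise ValueError(f"class {self.label!r}: give exactly one of "
                             "target_similarity or theta")
        if self.target_similarity is not None and not (0.0 < self.target_similarity <= 1.0):
            raise ValueError(f"class {self.label!r}: target must lie in (0, 1]")
        if self.theta is not None and not (0.0 < self.theta <= 1.0):
            raise ValueError(f"class {self.label!r}: theta must lie in (0, 1]")


@dataclass
class SyntheticSpec:
    """Full description of an artificial screening dataset."""

    classes: list[ClassSpec]
    feature_dim: int = 1024
    n_background: int = 0
    density: float = 0.05
    intensity: float = 3.0  # mean count λ on an on-feature
    seed: int = 0

    def __post_init__(self):
        self.classes = [c if isinstance(c, ClassSpec) else ClassSpec(**c) for c in self.classes]
        if not self.classes:
            raise ValueError("need at least one activity class")
        if not (0.0 < self.density < 1.0):
            raise ValueError("density must lie in (0, 1)")
        if self.intensity < 1.0:
            raise ValueError("intensity (mean on-feature count) must be >= 1")
        if self.n_background < 0:
            raise ValueError("n_background must be >= 0")
        labels = [c.label for c in self.classes]
        if len(set(labels)) != len(labels) or BACKGROUND_LABEL in labels:
            raise ValueError("class labels must be unique and not the background label")


# ----------------------------------------------------------------------

def _substream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, zlib.crc32(name.encode()))))


def _counts_on(rng: np.random.Generator, mask: np.ndarray, lam: float) -> np.ndarray:
    """Shifted-Poisson counts (>= 1, mean lam) where mask is true, else 0."""
    counts = np.zeros(mask.shape, dtype=float)
    counts[mask] = 1.0 + rng.poisson(lam - 1.0, size=int(mask.sum()))
    return counts


def _sample_class_bits(rng: np.random.Generator, F: int, support: np.ndarray,
                       theta: float, size: int) -> np.ndarray:
    """On-feature masks for *size* members around one prototype support."""
    n_on = support.sum()
    off = ~support
    r = 0.0 if theta >= 1.0 else n_on * (1.0 - theta) / max(F - n_on, 1)
    keep = rng.random((size, F)) < theta
    gain = rng.random((size, F)) < r
    mask = (keep & support) | (gain & off)
    # a molecule with no features at all has an undefined similarity;
    # force one prototype feature on in that (rare, small-F) case
    empty = ~mask.any(axis=1)
    if empty.any():
        first = np.argmax(support)
        mask[empty, first] = True
    return mask


def _simulate_class_diversity(F: int, d: float, lam: float, theta: float,
                              size: int, rng: np.random.Generator) -> float:
    support = np.zeros(F, dtype=bool)
    n_proto = max(1, int(round(d * F)))
    support[rng.choice(F, size=n_proto, replace=False)] = True
    bits = _sample_class_bits(rng, F, support, theta, size)
    return mean_pairwise_binary_tanimoto(bits.astype(float))


def calibrate_homogeneity(target: float, density: float, feature_dim: int,
                          intensity: float, seed: int = 1234,
                          pilot_size: int = 500, tol: float = 0.02,
                          max_iter: int = 40) -> tuple[float, float]:
    """Find the retention θ whose simulated class diversity hits *target*.

    Bisection on θ ∈ (0, 1], measuring the mean pairwise binary Tanimoto
    of a seeded pilot class (default 500 members).  Returns (θ, achieved
    similarity).  Raises if the target stays out of reach after
    ``max_iter`` halvings, reporting the closest achieved value.
    """
    if not (0.0 < target <= 1.0):
        raise ValueError("target similarity must lie in (0, 1]")
    if target == 1.0:
        return 1.0, 1.0

    def measure(theta: float) -> float:
        rng = np.random.default_rng(np.random.SeedSequence((seed, 0xCA11)))
        return _simulate_class_diversity(feature_dim, density, intensity,
                                         theta, pilot_size, rng)

    lo, hi = 1e-6, 1.0
    best = (1.0, measure(1.0))
    if best[1] + tol < target:
        raise ValueError(f"target {target} unattainable; max achieved {best[1]:.4f}")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        val = measure(mid)
        if abs(val - target) < abs(best[1] - target):
            best = (mid, val)
        if abs(val - target) <= tol:
            return mid, val
        if val < target:
            lo = mid
        else:
            hi = mid
    if abs(best[1] - target) <= tol:
        return best
    raise ValueError(f"calibration did not converge: target {target}, "
                     f"closest achieved {best[1]:.4f} at theta={best[0]:.4f}")


def generate_dataset(spec: SyntheticSpec) -> FingerprintDataset:
    """Draw a complete synthetic screening dataset from *spec*.

    Per class, θ is taken from the spec or calibrated from its target
    similarity; members are sampled around the class prototype and
    background molecules from independent supports.  Fully determined by
    ``spec.seed``.
    """
    F = spec.feature_dim
    ids: list[str] = []
    labels: list[str] = []
    rows: list[np.ndarray] = []
    for cls in spec.classes:
        rng = _substream(spec.seed, f"class:{cls.label}")
        theta = cls.theta
        if theta is None:
            theta, _ = calibrate_homogeneity(cls.target_similarity, spec.density,
                                             F, spec.intensity,
                                             seed=spec.seed)
        support = np.zeros(F, dtype=bool)
        n_proto = max(1, int(round(spec.density * F)))
        support[rng.choice(F, size=n_proto, replace=False)] = True
        bits = _sample_class_bits(rng, F, support, theta, cls.size)
        counts = _counts_on(rng, bits, spec.intensity)
        rows.append(counts)
        ids.extend(f"{cls.label}_{k:04d}" for k in range(cls.size))
        labels.extend([cls.label] * cls.size)
    if spec.n_background:
        rng = _substream(spec.seed, "background")
        mask = rng.random((spec.n_background, F)) < spec.density
        empty = ~mask.any(axis=1)
        if empty.any():
            cols = rng.integers(0, F, size=int(empty.sum()))
            mask[np.flatnonzero(empty), cols] = True
        rows.append(_counts_on(rng, mask, spec.intensity))
        ids.extend(f"bg_{k:05d}" for k in range(spec.n_background))
        labels.extend([BACKGROUND_LABEL] * spec.n_background)
    counts = np.vstack(rows)
    return FingerprintDataset(ids=ids, labels=labels, counts=counts,
                              meta={"synthetic": True, "seed": spec.seed})


# ----------------------------------------------------------------------
# YAML spec I/O

def spec_from_yaml(path) -> SyntheticSpec:
    """Load a :class:`SyntheticSpec` from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    classes = [ClassSpec(**c) for c in raw.pop("classes")]
    return SyntheticSpec(classes=classes, **raw)


def spec_to_yaml(spec: SyntheticSpec, path) -> str:
    doc = {
        "feature_dim": spec.feature_dim,
        "n_background": spec.n_background,
        "density": spec.density,
        "intensity": spec.intensity,
        "seed": spec.seed,
        "classes": [
            {k: v for k, v in
             {"label": c.label, "size": c.size,
              "target_similarity": c.target_similarity, "theta": c.theta}.items()
             if v is not None}
            for c in spec.classes
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return str(path)
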