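"""Count-fingerprint datasets: container, CSV I/O, scaling, diversity.

A :class:`FingerprintDataset` holds one molecule per row: a unique string
id, an activity-class label (the reserved label ``__bg__`` marks inactive /
background molecules), and a dense nonnegative feature vector.  Raw
fingerprints are integer substructure counts (ECFC-style, default 1024
features); after min–max scaling or autoencoder encoding the entries are
reals in [0, 1] and the dataset is flagged ``scaled``.

The CSV layout is ``id,activity,f0000,...,f1023`` (feature names zero-padded
to the width of the feature dimension), comma-delimited, header required,
UTF-8, no index column.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .similarity import binary_tanimoto, continuous_tanimoto

#: Reserved activity label for inactive / background molecules.
BACKGROUND_LABEL = "__bg__"


@dataclass(frozen=True)
class ScalingParams:
    """Per-feature minimum and maximum recorded when a dataset is scaled."""

    minimum: np.ndarray
    maximum: np.ndarray

    def __post_init__(self):
        mn = np.asarray(self.minimum, dtype=float)
        mx = np.asarray(self.maximum, dtype=float)
        if mn.shape != mx.shape or mn.ndim != 1:
            raise ValueError("scaling min/max must be equal-length vectors")
        if np.any(mx < mn):
            raise ValueError("scaling max must be >= min elementwise")
        object.__setattr__(self, "minimum", mn)
        object.__setattr__(self, "maximum", mx)


@dataclass
class FingerprintDataset:
    """Molecule ids, activity labels and an M × F nonnegative matrix."""

    ids: list[str]
    labels: list[str]
    counts: np.ndarray
    scaled: bool = False
    scaling: ScalingParams | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.ids = [str(i) for i in self.ids]
        self.labels = [str(l) for l in self.labels]
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if len(self.ids) != self.counts.shape[0] or len(self.labels) != len(self.ids):
            raise ValueError("ids, labels and count rows must have equal length")
        seen: set[str] = set()
        for mol_id in self.ids:
            if mol_id in seen:
                raise ValueError(f"duplicate molecule id {mol_id!r}")
            seen.add(mol_id)
        if np.any(self.counts < 0):
            r, c = np.argwhere(self.counts < 0)[0]
            raise ValueError(f"negative count at row {r}, column {c}")
        if not self.scaled and not np.all(self.counts == np.floor(self.counts)):
            raise ValueError("unscaled datasets must hold integer counts")

    # ------------------------------------------------------------------
    @property
    def n_molecules(self) -> int:
        return self.counts.shape[0]

    @property
    def feature_dim(self) -> int:
        return self.counts.shape[1]

    def class_labels(self) -> list[str]:
        """Distinct activity labels in first-appearance order, background excluded."""
        out: list[str] = []
        for lab in self.labels:
            if lab != BACKGROUND_LABEL and lab not in out:
                out.append(lab)
        return out

    def class_members(self, label: str) -> list[int]:
        idx = [i for i, lab in enumerate(self.labels) if lab == label]
        if not idx:
            raise KeyError(f"unknown activity class {label!r}")
        return idx

    def index_of(self, mol_id: str) -> int:
        try:
            return self.ids.index(mol_id)
        except ValueError:
            raise KeyError(f"unknown molecule id {mol_id!r}") from None


# ----------------------------------------------------------------------
# CSV I/O

def _feature_names(feature_dim: int) -> list[str]:
    width = max(4, len(str(feature_dim - 1)))
    return [f"f{i:0{width}d}" for i in range(feature_dim)]


def write_dataset(ds: FingerprintDataset, path) -> str:
    """Write *ds* as CSV (``id,activity,f0000,...``); returns the path."""
    frame = pd.DataFrame(ds.counts, columns=_feature_names(ds.feature_dim))
    if not ds.scaled:
        frame = frame.astype(np.int64)
    frame.insert(0, "activity", ds.labels)
    frame.insert(0, "id", ds.ids)
    frame.to_csv(path, index=False, float_format="%.17g")
    return str(path)


def read_dataset(path, format: str = "csv") -> FingerprintDataset:
    """Read a fingerprint dataset from CSV, validating all invariants.

    Raises ``ValueError`` naming the offending id / cell for duplicate ids,
    negative or non-numeric counts, and ragged rows (pandas raises on the
    latter while parsing).
    """
    if format != "csv":
        raise ValueError(f"unsupported format {format!r}")
    frame = pd.read_csv(path, dtype={"id": str, "activity": str})
    for col in ("id", "activity"):
        if col not in frame.columns:
            raise ValueError(f"missing required column {col!r} in {path}")
    feature_cols = [c for c in frame.columns if c not in ("id", "activity")]
    if not feature_cols:
        raise ValueError(f"no feature columns in {path}")
    values = frame[feature_cols].to_numpy()
    if len(frame) == 0:
        return FingerprintDataset(ids=[], labels=[],
                                  counts=np.zeros((0, len(feature_cols))))
    if not np.issubdtype(values.dtype, np.number):
        bad = frame[feature_cols].map(lambda v: not np.isreal(v))
        r = int(bad.any(axis=1).idxmax())
        raise ValueError(f"non-numeric count in row {r}")
    values = values.astype(float)
    if np.any(np.isnan(values)):
        r, c = np.argwhere(np.isnan(values))[0]
        raise ValueError(f"missing/non-numeric count at row {r}, column {feature_cols[c]}")
    if np.any(values < 0):
        r, c = np.argwhere(values < 0)[0]
        raise ValueError(f"negative count at row {r}, column {feature_cols[c]}")
    scaled = not bool(np.all(values == np.floor(values)))
    return FingerprintDataset(
        ids=list(frame["id"]),
        labels=list(frame["activity"]),
        counts=values,
        scaled=scaled,
    )


# ----------------------------------------------------------------------
# Transformations

def minmax_scale(ds: FingerprintDataset) -> tuple[FingerprintDataset, ScalingParams]:
    """Map every feature to [0, 1] via (x − min) / (max − min).

    Constant features map to 0.  The returned :class:`ScalingParams` allow
    exact inversion with :func:`inverse_scale`.  Scaling an already-scaled
    dataset is an error.
    """
    if ds.scaled:
        raise ValueError("dataset is already scaled")
    mn = ds.counts.min(axis=0) if ds.n_molecules else np.zeros(ds.feature_dim)
    mx = ds.counts.max(axis=0) if ds.n_molecules else np.zeros(ds.feature_dim)
    span = mx - mn
    safe = np.where(span == 0, 1.0, span)
    scaled = (ds.counts - mn) / safe
    scaled[:, span == 0] = 0.0
    params = ScalingParams(minimum=mn, maximum=mx)
    out = replace(ds, counts=scaled, scaled=True, scaling=params)
    return out, params


def inverse_scale(ds: FingerprintDataset, params: ScalingParams | None = None) -> FingerprintDataset:
    """Invert :func:`minmax_scale`; constant features are restored from params."""
    params = params or ds.scaling
    if not ds.scaled or params is None:
        raise ValueError("dataset is not scaled or has no scaling parameters")
    span = params.maximum - params.minimum
    counts = ds.counts * span + params.minimum
    return replace(ds, counts=np.round(counts, 12), scaled=False, scaling=None)


def binarize(ds: FingerprintDataset) -> FingerprintDataset:
    """Presence/absence fingerprint: entry 1 iff the count is > 0."""
    if ds.scaled:
        raise ValueError("binarize expects raw (unscaled) counts")
    return replace(ds, counts=(ds.counts > 0).astype(float))


# ----------------------------------------------------------------------
# Intra-class diversity

def class_diversity(ds: FingerprintDataset, label: str, variant: str = "binary") -> float:
    """Mean pairwise Tanimoto similarity within an activity class.

    The class "pairwise similarity" statistic of screening benchmarks: every
    member is matched against every other member of its class and the
    similarities are averaged over all unordered pairs.  By default the
    binary Tanimoto coefficient on binarised counts is used; pass
    ``variant="standard"`` for the continuous form on raw counts.  A high
    value marks a structurally homogeneous class, a low value a diverse one.
    """
    members = ds.class_members(label)
    if len(members) < 2:
        raise ValueError(f"class {label!r} has fewer than 2 members")
    X = ds.counts[members]
    if variant == "binary":
        X = (X > 0).astype(float)
        sim = binary_tanimoto
    else:
        def sim(a, b):
            return continuous_tanimoto(a, b, variant=variant)
    total = 0.0
    n_pairs = 0
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            total += sim(X[i], X[j])
            n_pairs += 1
    return total / n_pairs


def mean_pairwise_binary_tanimoto(bits: np.ndarray) -> float:
    """Vectorised mean pairwise binary Tanimoto over the rows of a 0/1 matrix.

    Equivalent to averaging :func:`aefs.similarity.binary_tanimoto` over all
    unordered row pairs; used where classes are large (synthetic calibration).
    """
    B = np.asarray(bits, dtype=float)
    if B.ndim != 2 or B.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    inter = B @ B.T
    sizes = B.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    if np.any(union == 0):
        raise ValueError("pair of all-zero fingerprints: similarity undefined")
    sim = inter / union
    iu = np.triu_indices(B.shape[0], k=1)
    return float(sim[iu].mean())
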