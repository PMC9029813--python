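"""Simulated virtual-screening experiments and recall summary tables.

The protocol mirrors standard ligand-based benchmark practice: for each
activity class a fixed number of reference (query) structures is drawn at
random; every database molecule is scored against each reference and the
database is ranked in decreasing similarity order; recall is the
percentage of the class's actives retrieved within the top 1% / 5% of the
ranking; per-class recall is the mean over the references, and a benchmark
table collects one column per similarity method with a per-method mean row
and a count of classes on which each method was best.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fingerprints import BACKGROUND_LABEL, FingerprintDataset
from .similarity import bulk_similarity

SUMMARY_ROWS = ("Mean", "Best")


@dataclass
class ScreeningConfig:
    """Knobs of the simulated screening experiment.

    ``n_references`` queries per class (default 10), recall ``cutoffs`` in
    percent (default 1 and 5), the similarity ``variant`` used for scoring,
    and whether the reference itself is excluded from the ranked database
    and the active count (the common benchmark protocol; toggleable).
    Similarity ties are broken by molecule id ascending so ranked lists are
    reproducible.
    """

    n_references: int = 10
    cutoffs: tuple[float, ...] = (1.0, 5.0)
    seed: int = 0
    exclude_reference: bool = True
    variant: str = "standard"

    def __post_init__(self):
        self.cutoffs = tuple(float(c) for c in self.cutoffs)
        if self.n_references < 1:
            raise ValueError("n_references must be >= 1")
        if any(c <= 0 or c > 100 for c in self.cutoffs):
            raise ValueError("cutoffs must lie in (0, 100]")


def _class_rng(seed: int, label: str) -> np.random.Generator:
    # Per-class substream: reference picks are identical across methods
    # (unified references) and independent of class iteration order.
    return np.random.default_rng(np.random.SeedSequence((seed, zlib.crc32(label.encode()))))


def select_references(ds: FingerprintDataset, label: str, cfg: ScreeningConfig) -> list[str]:
    """Sample ``cfg.n_references`` query ids from a class without replacement.

    If the class is smaller than requested, all members are used and a
    warning is emitted.  Deterministic in (seed, label).
    """
    members = ds.class_members(label)
    ids = [ds.ids[i] for i in members]
    if len(ids) <= cfg.n_references:
        if len(ids) < cfg.n_references:
            warnings.warn(
                f"class {label!r} has {len(ids)} members < n_references="
                f"{cfg.n_references}; using all members"
            )
        return list(ids)
    rng = _class_rng(cfg.seed, label)
    pick = rng.choice(len(ids), size=cfg.n_references, replace=False)
    return [ids[i] for i in sorted(pick)]


def rank_database(query_id: str, ds: FingerprintDataset, cfg: ScreeningConfig) -> list[tuple[str, float]]:
    """Score the query against every database molecule and rank decreasing.

    Returns ``[(id, score), ...]`` sorted by score descending, ties broken
    by id ascending; the query itself is excluded when
    ``cfg.exclude_reference``.
    """
    qi = ds.index_of(query_id)
    scores = bulk_similarity(ds.counts, ds.counts[qi], variant=cfg.variant)
    entries = [
        (ds.ids[i], float(scores[i]))
        for i in range(ds.n_molecules)
        if not (cfg.exclude_reference and i == qi)
    ]
    entries.sort(key=lambda e: (-e[1], e[0]))
    return entries


def recall_at_cutoff(ranked_ids, actives, cutoff: float, db_size: int) -> float:
    """Percent of actives found within the top ``cutoff``% of the ranking.

    The shortlist size is k = round(cutoff · db_size / 100), at least 1.
    """
    ranked_ids = list(ranked_ids)
    actives = set(actives)
    if not actives:
        raise ValueError("actives must be nonempty")
    if len(ranked_ids) != db_size:
        raise ValueError("ranking length must equal db_size")
    k = max(1, int(np.floor(cutoff * db_size / 100.0 + 0.5)))
    hits = sum(1 for mol in ranked_ids[:k] if mol in actives)
    return 100.0 * hits / len(actives)


def screen_class(ds: FingerprintDataset, label: str, cfg: ScreeningConfig) -> dict[float, float]:
    """Mean recall per cutoff for one activity class over its references.

    For each reference the class's other actives are the retrieval targets
    (the reference is dropped from both the database and the active set
    when ``exclude_reference``); recalls are averaged over references.
    """
    refs = select_references(ds, label, cfg)
    class_ids = {ds.ids[i] for i in ds.class_members(label)}
    sums = {c: 0.0 for c in cfg.cutoffs}
    for ref in refs:
        ranked = rank_database(ref, ds, cfg)
        actives = class_ids - {ref} if cfg.exclude_reference else class_ids
        if not actives:
            raise ValueError(f"class {label!r} has no retrievable actives for reference {ref!r}")
        for c in cfg.cutoffs:
            sums[c] += recall_at_cutoff([mol for mol, _ in ranked], actives, c, len(ranked))
    return {c: sums[c] / len(refs) for c in cfg.cutoffs}


# ----------------------------------------------------------------------
# Recall tables

@dataclass
class RecallTable:
    """Classes × methods matrix of mean recall percentages at one cutoff."""

    cutoff: float
    frame: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        vals = self.frame.to_numpy(dtype=float)
        if vals.size and (np.any(vals < 0) or np.any(vals > 100)):
            raise ValueError("recall cells must lie in [0, 100]")

    @property
    def methods(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def classes(self) -> list[str]:
        return list(self.frame.index)

    @property
    def mean_row(self) -> pd.Series:
        """Per-method arithmetic mean recall over classes."""
        return self.frame.mean(axis=0)

    @property
    def best_counts(self) -> pd.Series:
        """Per method, the number of classes where it attains the row maximum.

        Ties credit every tied method, so the counts sum to at least the
        number of classes.
        """
        row_max = self.frame.max(axis=1)
        return self.frame.eq(row_max, axis=0).sum(axis=0)


def summarize_table(table: RecallTable) -> tuple[pd.Series, pd.Series]:
    """Return (mean_row, best_counts) of a recall table."""
    if table.frame.empty:
        raise ValueError("empty recall table")
    return table.mean_row, table.best_counts


def write_recall_table(table: RecallTable, path) -> str:
    """CSV with a class column, one column per method, and regenerated
    Mean / Best summary rows appended."""
    out = table.frame.copy()
    out.loc["Mean"] = table.mean_row
    out.loc["Best"] = table.best_counts.astype(float)
    out.index.name = "activity_class"
    out.to_csv(path)
    return str(path)


def read_recall_table(path, cutoff: float) -> RecallTable:
    """Load a per-class recall CSV; summary rows, if present, are dropped
    (means and best counts are always recomputed, never trusted)."""
    frame = pd.read_csv(path, index_col=0)
    frame.index = frame.index.astype(str)
    frame = frame.loc[[i for i in frame.index if i not in SUMMARY_ROWS]]
    return RecallTable(cutoff=cutoff, frame=frame.astype(float))


def run_benchmark(
    method_datasets: dict[str, FingerprintDataset],
    cfg: ScreeningConfig,
    variants: dict[str, str] | None = None,
) -> dict[float, RecallTable]:
    """Screen every activity class with every method's descriptor set.

    ``method_datasets`` maps a method name (column) to the dataset holding
    that method's molecular representation (e.g. ``TAN`` → binarised raw
    fingerprints, ``AE3_DR`` → 400-d autoencoder codes).  All datasets must
    share ids and labels; reference selection depends only on (seed, class)
    so every method is queried with the same references.  ``variants``
    optionally overrides the similarity variant per method (e.g. ``binary``
    for the raw-fingerprint baseline).
    """
    if not method_datasets:
        raise ValueError("need at least one method dataset")
    ref_ids = None
    ref_labels = None
    for name, ds in method_datasets.items():
        if ref_ids is None:
            ref_ids, ref_labels = ds.ids, ds.labels
        elif ds.ids != ref_ids or ds.labels != ref_labels:
            raise ValueError(f"method {name!r} has mismatched ids/labels")
    variants = variants or {}
    first = next(iter(method_datasets.values()))
    labels = first.class_labels()
    per_cutoff: dict[float, dict[str, dict[str, float]]] = {c: {} for c in cfg.cutoffs}
    for name, ds in method_datasets.items():
        mcfg = ScreeningConfig(
            n_references=cfg.n_references,
            cutoffs=cfg.cutoffs,
            seed=cfg.seed,
            exclude_reference=cfg.exclude_reference,
            variant=variants.get(name, cfg.variant),
        )
        for label in labels:
            res = screen_class(ds, label, mcfg)
            for c in cfg.cutoffs:
                per_cutoff[c].setdefault(name, {})[label] = res[c]
    tables = {}
    for c in cfg.cutoffs:
        frame = pd.DataFrame(per_cutoff[c], columns=list(method_datasets)).loc[labels]
        tables[c] = RecallTable(
            cutoff=c,
            frame=frame,
            meta={"seed": cfg.seed, "n_references": cfg.n_references,
                  "variants": {m: variants.get(m, cfg.variant) for m in method_datasets}},
        )
    return tables
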