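"""Published MDDR benchmark recall tables, shipped as package data.

These are the per-class mean recall percentages (top 1% and top 5% of the
ranked database) reported for the three MDDR benchmark subsets:

- ``ds1`` — 11 activity classes of mixed homogeneity;
- ``ds2`` — 10 structurally homogeneous classes;
- ``ds3`` — 10 structurally heterogeneous classes (no ASMTP column).

Columns are the similarity methods compared: the binary Tanimoto baseline
(TAN), the text-processing similarity measure (ASMTP), the quantum-based
measure (SQB), and continuous Tanimoto on the three autoencoder-reduced
descriptors (AE1_DR, AE2_DR, AE3_DR).  The TAN/ASMTP/SQB columns are
external published numbers consumed as evaluation inputs only; this
package implements none of those scoring functions beyond TAN.

The tables feed the summary statistics (column means, best-method counts)
and the Kendall concordance analysis.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .screening import RecallTable

DATASETS = ("ds1", "ds2", "ds3")
CUTOFFS = (1, 5)


def load_benchmark_table(dataset: str, cutoff: int) -> RecallTable:
    """Load one published recall table, e.g. ``("ds1", 1)``.

    Returns a :class:`~aefs.screening.RecallTable` whose rows are MDDR
    activity-index strings and whose columns are method names; means and
    best counts are recomputed properties, never stored.
    """
    dataset = dataset.lower()
    if dataset not in DATASETS:
        raise ValueError(f"unknown benchmark dataset {dataset!r}; expected one of {DATASETS}")
    if int(cutoff) not in CUTOFFS:
        raise ValueError(f"unknown cutoff {cutoff!r}; expected 1 or 5")
    name = f"mddr_{dataset}_top{int(cutoff)}.csv"
    with resources.files("aefs.data").joinpath(name).open() as fh:
        frame = pd.read_csv(fh, index_col=0, dtype={"activity_class": str})
    frame.index = frame.index.astype(str)
    return RecallTable(cutoff=float(cutoff), frame=frame.astype(float),
                       meta={"source": f"published MDDR {dataset.upper()} benchmark"})
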