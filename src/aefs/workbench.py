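"""End-to-end pipeline: dataset → scaling → autoencoder(s) → screening →
recall tables → Kendall concordance, with a hashed run manifest.

All randomness derives from one global seed through named substreams
(synthetic generation, training, reference selection), so each stage is
independently reproducible and a rerun with the same config produces
byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autoencoder import AEArchitecture, TrainConfig, encode_dataset, preset_architecture, save_model, train
from .fingerprints import FingerprintDataset, binarize, minmax_scale, read_dataset, write_dataset
from .kendall import concordance_from_recalls
from .screening import ScreeningConfig, run_benchmark, write_recall_table
from .synthetic import SyntheticSpec, generate_dataset

log = logging.getLogger("aefs.workbench")


def _derived_seed(seed: int, name: str) -> int:
    # named substream seed, kept below 2**31
    return int(np.random.SeedSequence((seed, zlib.crc32(name.encode()))).generate_state(1)[0] % (2 ** 31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class PipelineConfig:
    """Everything a full run needs.

    Either ``dataset_path`` (an existing fingerprint CSV) or ``synthetic``
    (a generator spec) supplies the data.  ``architectures`` are preset
    names or explicit :class:`AEArchitecture` objects; the raw-fingerprint
    binary-Tanimoto baseline column ``TAN`` is always produced.
    """

    outdir: str
    dataset_path: str | None = None
    synthetic: SyntheticSpec | None = None
    architectures: list = field(default_factory=lambda: ["AE1-DR"])
    train: TrainConfig = field(default_factory=TrainConfig)
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    seed: int = 0

    def __post_init__(self):
        if (self.dataset_path is None) == (self.synthetic is None):
            raise ValueError("give exactly one of dataset_path or synthetic spec")
        if not self.architectures:
            raise ValueError("need at least one architecture")
        self.architectures = [
            a if isinstance(a, AEArchitecture) else preset_architecture(a)
            for a in self.architectures
        ]


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            log.info("stage %-10s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapper
    return deco


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute the full experiment; returns the output directory.

    Artifacts: ``dataset.csv`` (when synthetic), one ``model_<arch>.npz``
    and ``codes_<arch>.csv`` per architecture, ``recall_top<cutoff>.csv``
    per cutoff, ``kendall_top<cutoff>.json``, and ``manifest.json`` with a
    sha256 for every output plus the seed and config fingerprint.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []

    @_stage("data")
    def load_data() -> FingerprintDataset:
        if cfg.synthetic is not None:
            spec = cfg.synthetic
            spec.seed = _derived_seed(cfg.seed, "synthetic")
            ds = generate_dataset(spec)
            p = outdir / "dataset.csv"
            write_dataset(ds, p)
            outputs.append(p)
            return ds
        return read_dataset(cfg.dataset_path)

    ds = load_data()
    scaled, _params = minmax_scale(ds)
    raw_binary = binarize(ds)

    method_datasets = {"TAN": raw_binary}
    variants = {"TAN": "binary"}
    for arch in cfg.architectures:
        name = arch.name

        @_stage(f"train:{name}")
        def fit(arch=arch, name=name):
            tc = TrainConfig(
                tolerance=cfg.train.tolerance, max_epochs=cfg.train.max_epochs,
                step_size=cfg.train.step_size, batch_size=cfg.train.batch_size,
                seed=_derived_seed(cfg.seed, f"train:{name}"),
                init_mode=cfg.train.init_mode, per_molecule=cfg.train.per_molecule,
            )
            model, report = train(scaled, arch, tc)
            log.info("  %s: %d epochs, final loss %.5f (%s)",
                     name, report.epochs, report.errors[-1], report.stopped_by)
            mp = outdir / f"model_{name}.npz"
            save_model(model, mp, extra={"seed": tc.seed, "final_loss": report.errors[-1],
                                         "epochs": report.epochs})
            outputs.append(mp)
            codes = encode_dataset(model, scaled)
            cp = outdir / f"codes_{name}.csv"
            write_dataset(codes, cp)
            outputs.append(cp)
            return codes

        method_datasets[name.replace("-", "_")] = fit()

    @_stage("screen")
    def screen():
        scfg = ScreeningConfig(
            n_references=cfg.screening.n_references, cutoffs=cfg.screening.cutoffs,
            seed=_derived_seed(cfg.seed, "screening"),
            exclude_reference=cfg.screening.exclude_reference,
            variant=cfg.screening.variant,
        )
        return run_benchmark(method_datasets, scfg, variants=variants)

    tables = screen()

    @_stage("summarize")
    def summarize():
        for cutoff, table in tables.items():
            p = outdir / f"recall_top{cutoff:g}.csv"
            write_recall_table(table, p)
            outputs.append(p)
            log.info("  top %g%%: means %s", cutoff,
                     {m: round(v, 2) for m, v in table.mean_row.items()})
            res = concordance_from_recalls(table.frame.to_numpy(), offset=0,
                                           objects=table.methods)
            kp = outdir / f"kendall_top{cutoff:g}.json"
            kp.write_text(json.dumps({
                "W": res.w, "S": res.s, "chi_square": res.chi_square,
                "df": res.df, "p_value": res.p_value,
                "mean_ranks": dict(zip(res.objects, res.mean_ranks.tolist())),
                "rank_totals": dict(zip(res.objects, res.rank_totals.tolist())),
            }, indent=2, sort_keys=True) + "\n")
            outputs.append(kp)

    summarize()

    manifest = {
        "package": "aefs",
        "version": "0.1.0",
        "seed": cfg.seed,
        "config": {
            "architectures": [a.name for a in cfg.architectures],
            "train": {"tolerance": cfg.train.tolerance, "max_epochs": cfg.train.max_epochs,
                      "step_size": cfg.train.step_size, "batch_size": cfg.train.batch_size,
                      "init_mode": cfg.train.init_mode},
            "screening": {"n_references": cfg.screening.n_references,
                          "cutoffs": list(cfg.screening.cutoffs),
                          "exclude_reference": cfg.screening.exclude_reference,
                          "variant": cfg.screening.variant},
        },
        "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return outdir


def verify_manifest(outdir) -> bool:
    """Re-hash every artifact listed in ``manifest.json``; True iff intact."""
    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    for name, digest in manifest["outputs"].items():
        p = outdir / name
        if not p.exists() or _sha256(p) != digest:
            return False
    return True
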