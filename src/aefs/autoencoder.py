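"""Tied-weight sigmoid autoencoder for fingerprint dimensionality reduction.

The model stacks fully connected sigmoid layers: an encoder maps a
[0, 1]-scaled fingerprint x through h_i = σ(W_i x + b_i) down to a
low-dimensional code, and a decoder mirrors the stack back to a
reconstruction z of the input.  With tied weights (the default) each
decoder layer reuses the transpose of the mirrored encoder weight matrix,
so the only decoder-specific parameters are its bias vectors.  Training
minimises the mean squared reconstruction error

    ℒ = mean_i (x_i − z_i)²

by minibatch gradient descent with exact backpropagation; tied weights
accumulate the gradient contributions of both their encoder and decoder
uses.  Training stops when the epoch-mean loss drops below the tolerance
α (default 0.01) or after ``max_epochs`` (default 100) epochs.

Three preset architectures reduce 1024-feature fingerprints to 500, 300
and 400 dimensions respectively; the code layer activations are the
reduced molecular descriptor used for similarity searching.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .fingerprints import FingerprintDataset

#: Preset encoder layer widths (input first, code layer last).
PRESETS: dict[str, tuple[int, ...]] = {
    "AE1-DR": (1024, 900, 700, 500),
    "AE2-DR": (1024, 800, 600, 400, 300),
    "AE3-DR": (1024, 900, 800, 600, 400),
}


def sigmoid(x: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# ----------------------------------------------------------------------
# Architecture / model containers

@dataclass(frozen=True)
class AEArchitecture:
    """Layer-width description of an autoencoder.

    ``encoder_sizes`` starts at the input width and ends at the code width;
    when ``tied`` the decoder widths are the reversed encoder widths (its
    weight matrices are transposes of the encoder's).  An untied
    architecture may specify free ``decoder_sizes`` (code width first,
    input width last).
    """

    name: str
    encoder_sizes: tuple[int, ...]
    tied: bool = True
    decoder_sizes: tuple[int, ...] | None = None

    def __post_init__(self):
        enc = tuple(int(s) for s in self.encoder_sizes)
        if len(enc) < 2 or any(s <= 0 for s in enc):
            raise ValueError("encoder_sizes must be >= 2 strictly positive widths")
        object.__setattr__(self, "encoder_sizes", enc)
        if self.tied:
            if self.decoder_sizes is not None and tuple(self.decoder_sizes) != enc[::-1]:
                raise ValueError("tied architectures mirror the encoder widths")
            object.__setattr__(self, "decoder_sizes", enc[::-1])
        else:
            dec = tuple(int(s) for s in (self.decoder_sizes or enc[::-1]))
            if dec[0] != enc[-1] or dec[-1] != enc[0] or any(s <= 0 for s in dec):
                raise ValueError("decoder_sizes must run code width -> input width")
            object.__setattr__(self, "decoder_sizes", dec)

    @property
    def input_dim(self) -> int:
        return self.encoder_sizes[0]

    @property
    def code_size(self) -> int:
        return self.encoder_sizes[-1]

    @property
    def n_layers(self) -> int:
        return len(self.encoder_sizes) - 1


def preset_architecture(name: str, tied: bool = True) -> AEArchitecture:
    """One of the three standard reduction architectures.

    ``AE1-DR``: 1024→900→700→500 (code 500); ``AE2-DR``:
    1024→800→600→400→300 (code 300); ``AE3-DR``: 1024→900→800→600→400
    (code 400).
    """
    if name not in PRESETS:
        raise ValueError(f"unknown architecture {name!r}; expected one of {sorted(PRESETS)}")
    return AEArchitecture(name=name, encoder_sizes=PRESETS[name], tied=tied)


@dataclass
class TrainConfig:
    """Training hyperparameters.

    ``tolerance`` is the stopping threshold α on the epoch-mean
    reconstruction MSE; ``step_size`` is the gradient-descent step;
    ``init_mode`` is ``glorot`` (scaled symmetric uniform, zero biases) or
    ``uniform01`` (all weights and biases uniform on (0, 1) — prone to
    sigmoid saturation, kept for fidelity experiments).  ``per_molecule``
    switches from dataset-level epochs to training each molecule in turn
    to tolerance.
    """

    tolerance: float = 0.01
    max_epochs: int = 100
    step_size: float = 0.05
    batch_size: int = 32
    seed: int = 0
    init_mode: str = "glorot"
    per_molecule: bool = False

    def __post_init__(self):
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.step_size <= 0:
            raise ValueError("step_size must be > 0")
        if self.init_mode not in ("glorot", "uniform01"):
            raise ValueError(f"unknown init_mode {self.init_mode!r}")


@dataclass
class TrainReport:
    """Per-epoch mean reconstruction error trace and stopping reason."""

    errors: list[float]
    epochs: int
    stopped_by: str  # "tolerance" | "max_epochs"

    def __post_init__(self):
        if len(self.errors) != self.epochs:
            raise ValueError("error trace length must equal epochs run")


@dataclass
class AEModel:
    """Weights and biases of a (possibly tied) autoencoder.

    ``enc_w[i]`` has shape (fan_in, fan_out) so a batch X propagates as
    ``sigmoid(X @ W + b)``.  When tied, decoder weight j is the transpose
    of encoder weight N−1−j taken at use time — mutating an encoder weight
    is immediately visible to the decoder.
    """

    architecture: AEArchitecture
    enc_w: list[np.ndarray]
    enc_b: list[np.ndarray]
    dec_b: list[np.ndarray]
    dec_w: list[np.ndarray] | None = None  # only for untied models

    def __post_init__(self):
        arch = self.architecture
        sizes = arch.encoder_sizes
        for i, w in enumerate(self.enc_w):
            if w.shape != (sizes[i], sizes[i + 1]):
                raise ValueError(f"encoder weight {i} has shape {w.shape}, "
                                 f"expected {(sizes[i], sizes[i + 1])}")
        if arch.tied:
            if self.dec_w is not None:
                raise ValueError("tied models carry no independent decoder weights")
        else:
            dsizes = arch.decoder_sizes
            if self.dec_w is None or len(self.dec_w) != len(dsizes) - 1:
                raise ValueError("untied model requires explicit decoder weights")

    def decoder_weight(self, j: int) -> np.ndarray:
        """Decoder weight for layer j (transposed encoder view when tied)."""
        if self.architecture.tied:
            return self.enc_w[self.architecture.n_layers - 1 - j].T
        return self.dec_w[j]


def init_model(arch: AEArchitecture, cfg: TrainConfig) -> AEModel:
    """Seeded random initialisation.

    ``glorot``: W ~ U(−s, s) with s = sqrt(6/(fan_in+fan_out)), biases 0.
    ``uniform01``: all weights and biases ~ U(0, 1).
    """
    rng = np.random.default_rng(cfg.seed)
    enc_w, enc_b = [], []
    for fi, fo in zip(arch.encoder_sizes[:-1], arch.encoder_sizes[1:]):
        if cfg.init_mode == "uniform01":
            enc_w.append(rng.uniform(0.0, 1.0, size=(fi, fo)))
            enc_b.append(rng.uniform(0.0, 1.0, size=fo))
        else:
            s = np.sqrt(6.0 / (fi + fo))
            enc_w.append(rng.uniform(-s, s, size=(fi, fo)))
            enc_b.append(np.zeros(fo))
    dec_sizes = arch.decoder_sizes
    dec_b = []
    for fo in dec_sizes[1:]:
        if cfg.init_mode == "uniform01":
            dec_b.append(rng.uniform(0.0, 1.0, size=fo))
        else:
            dec_b.append(np.zeros(fo))
    dec_w = None
    if not arch.tied:
        dec_w = []
        for fi, fo in zip(dec_sizes[:-1], dec_sizes[1:]):
            if cfg.init_mode == "uniform01":
                dec_w.append(rng.uniform(0.0, 1.0, size=(fi, fo)))
            else:
                s = np.sqrt(6.0 / (fi + fo))
                dec_w.append(rng.uniform(-s, s, size=(fi, fo)))
    return AEModel(architecture=arch, enc_w=enc_w, enc_b=enc_b, dec_b=dec_b, dec_w=dec_w)


# ----------------------------------------------------------------------
# Forward passes

def _as_batch(x: np.ndarray, width: int, what: str) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    if x.ndim != 2 or x.shape[1] != width:
        raise ValueError(f"{what} width {x.shape[-1]} does not match model width {width}")
    return x, single


def encode(model: AEModel, x) -> np.ndarray:
    """Code-layer activations for a vector or batch of scaled inputs."""
    h, single = _as_batch(x, model.architecture.input_dim, "input")
    for w, b in zip(model.enc_w, model.enc_b):
        h = sigmoid(h @ w + b)
    return h[0] if single else h


def decode(model: AEModel, h) -> np.ndarray:
    """Reconstruction from code-layer activations."""
    z, single = _as_batch(h, model.architecture.code_size, "code")
    for j, b in enumerate(model.dec_b):
        z = sigmoid(z @ model.decoder_weight(j) + b)
    return z[0] if single else z


def reconstruction_error(x, z) -> float:
    """Mean squared error between input and reconstruction."""
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    if x.shape != z.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {z.shape}")
    return float(np.mean((x - z) ** 2))


# ----------------------------------------------------------------------
# Gradients and training

def loss_and_grads(model: AEModel, X: np.ndarray):
    """Mean reconstruction MSE of a batch and exact parameter gradients.

    Returns ``(loss, grads)`` where ``grads`` holds ``enc_w``, ``enc_b``,
    ``dec_b`` (and ``dec_w`` for untied models) matching the model's
    parameter shapes.  For tied models each encoder weight gradient is the
    sum of its encoder-pass and (transposed) decoder-pass contributions.
    """
    X, _ = _as_batch(X, model.architecture.input_dim, "input")
    n_layers = model.architecture.n_layers
    # forward, keeping activations
    acts = [X]
    h = X
    for w, b in zip(model.enc_w, model.enc_b):
        h = sigmoid(h @ w + b)
        acts.append(h)
    for j, b in enumerate(model.dec_b):
        h = sigmoid(h @ model.decoder_weight(j) + b)
        acts.append(h)
    Z = h
    B, F = X.shape
    loss = float(np.mean((X - Z) ** 2))

    g_enc_w = [np.zeros_like(w) for w in model.enc_w]
    g_enc_b = [np.zeros_like(b) for b in model.enc_b]
    g_dec_b = [np.zeros_like(b) for b in model.dec_b]
    g_dec_w = None if model.architecture.tied else [np.zeros_like(w) for w in model.dec_w]

    # dL/dZ for L = mean over batch and features
    delta = 2.0 * (Z - X) / (B * F)
    # decoder layers, backwards
    for j in range(n_layers - 1, -1, -1):
        out = acts[n_layers + 1 + j]       # activation of decoder layer j
        inp = acts[n_layers + j]           # its input
        dpre = delta * out * (1.0 - out)
        g_dec_b[j] += dpre.sum(axis=0)
        gw = inp.T @ dpre                  # grad wrt decoder weight (inp×out)
        if model.architecture.tied:
            g_enc_w[n_layers - 1 - j] += gw.T
        else:
            g_dec_w[j] += gw
        delta = dpre @ model.decoder_weight(j).T
    # encoder layers, backwards
    for i in range(n_layers - 1, -1, -1):
        out = acts[i + 1]
        inp = acts[i]
        dpre = delta * out * (1.0 - out)
        g_enc_b[i] += dpre.sum(axis=0)
        g_enc_w[i] += inp.T @ dpre
        delta = dpre @ model.enc_w[i].T
    grads = {"enc_w": g_enc_w, "enc_b": g_enc_b, "dec_b": g_dec_b}
    if g_dec_w is not None:
        grads["dec_w"] = g_dec_w
    return loss, grads


def _apply_grads(model: AEModel, grads: dict, step: float) -> None:
    for w, g in zip(model.enc_w, grads["enc_w"]):
        w -= step * g
    for b, g in zip(model.enc_b, grads["enc_b"]):
        b -= step * g
    for b, g in zip(model.dec_b, grads["dec_b"]):
        b -= step * g
    if not model.architecture.tied:
        for w, g in zip(model.dec_w, grads["dec_w"]):
            w -= step * g


def dataset_loss(model: AEModel, X: np.ndarray) -> float:
    """Mean reconstruction MSE over a whole data matrix."""
    return reconstruction_error(X, decode(model, encode(model, X)))


def train(ds: FingerprintDataset, arch: AEArchitecture, cfg: TrainConfig) -> tuple[AEModel, TrainReport]:
    """Fit an autoencoder to a [0, 1]-scaled fingerprint dataset.

    Minibatch gradient descent (seeded shuffling) on the mean squared
    reconstruction error; stops as soon as the full-dataset mean loss
    falls below ``cfg.tolerance`` or ``cfg.max_epochs`` is reached.  With
    ``cfg.per_molecule`` each molecule is instead descended to tolerance
    in turn (one pass), a mode retained for fidelity experiments.
    """
    if ds.n_molecules == 0:
        raise ValueError("cannot train on an empty dataset")
    X = np.asarray(ds.counts, dtype=float)
    if X.min() < 0.0 or X.max() > 1.0:
        raise ValueError("training data must be scaled to [0, 1]")
    if X.shape[1] != arch.input_dim:
        raise ValueError(f"data width {X.shape[1]} != architecture input {arch.input_dim}")
    model = init_model(arch, cfg)
    return _train_loop(model, X, cfg)


def _train_loop(model: AEModel, X: np.ndarray, cfg: TrainConfig) -> tuple[AEModel, TrainReport]:
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 1)))
    errors: list[float] = []
    stopped_by = "max_epochs"
    if cfg.per_molecule:
        for k in range(X.shape[0]):
            x = X[k:k + 1]
            for _ in range(cfg.max_epochs):
                loss, grads = loss_and_grads(model, x)
                if loss < cfg.tolerance:
                    break
                _apply_grads(model, grads, cfg.step_size)
        errors.append(dataset_loss(model, X))
        return model, TrainReport(errors=errors, epochs=1,
                                  stopped_by="tolerance" if errors[-1] < cfg.tolerance else "max_epochs")
    for _epoch in range(cfg.max_epochs):
        order = rng.permutation(X.shape[0])
        for start in range(0, X.shape[0], cfg.batch_size):
            batch = X[order[start:start + cfg.batch_size]]
            _, grads = loss_and_grads(model, batch)
            _apply_grads(model, grads, cfg.step_size)
        epoch_loss = dataset_loss(model, X)
        errors.append(epoch_loss)
        if epoch_loss < cfg.tolerance:
            stopped_by = "tolerance"
            break
    return model, TrainReport(errors=errors, epochs=len(errors), stopped_by=stopped_by)


def encode_dataset(model: AEModel, ds: FingerprintDataset) -> FingerprintDataset:
    """Encode every molecule; the codes become the new descriptor matrix.

    Ids, labels and row order carry over; the result is flagged scaled
    since sigmoid codes lie in (0, 1).
    """
    codes = encode(model, np.asarray(ds.counts, dtype=float))
    return FingerprintDataset(
        ids=list(ds.ids), labels=list(ds.labels), counts=codes, scaled=True,
        meta={**ds.meta, "descriptor": model.architecture.name,
              "code_size": model.architecture.code_size},
    )


# ----------------------------------------------------------------------
# Persistence: single-file .npz with a JSON manifest

def save_model(model: AEModel, path, extra: dict | None = None) -> str:
    """Serialise to one ``.npz`` file (JSON manifest + weight arrays)."""
    manifest = {
        "format": "aefs-ae-model-1",
        "architecture": {
            "name": model.architecture.name,
            "encoder_sizes": list(model.architecture.encoder_sizes),
            "tied": model.architecture.tied,
            "decoder_sizes": list(model.architecture.decoder_sizes),
        },
        "extra": extra or {},
    }
    arrays = {"manifest": np.frombuffer(json.dumps(manifest).encode(), dtype=np.uint8)}
    for i, w in enumerate(model.enc_w):
        arrays[f"enc_w{i}"] = w
    for i, b in enumerate(model.enc_b):
        arrays[f"enc_b{i}"] = b
    for j, b in enumerate(model.dec_b):
        arrays[f"dec_b{j}"] = b
    if model.dec_w is not None:
        for j, w in enumerate(model.dec_w):
            arrays[f"dec_w{j}"] = w
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)
    return str(path)


def load_model(path) -> tuple[AEModel, dict]:
    """Inverse of :func:`save_model`; returns (model, manifest extras)."""
    with np.load(path) as data:
        manifest = json.loads(bytes(data["manifest"]).decode())
        if manifest.get("format") != "aefs-ae-model-1":
            raise ValueError(f"{path}: not an aefs autoencoder model file")
        spec = manifest["architecture"]
        arch = AEArchitecture(
            name=spec["name"], encoder_sizes=tuple(spec["encoder_sizes"]),
            tied=spec["tied"],
            decoder_sizes=None if spec["tied"] else tuple(spec["decoder_sizes"]),
        )
        n = arch.n_layers
        enc_w = [data[f"enc_w{i}"] for i in range(n)]
        enc_b = [data[f"enc_b{i}"] for i in range(n)]
        dec_b = [data[f"dec_b{j}"] for j in range(n)]
        dec_w = None if arch.tied else [data[f"dec_w{j}"] for j in range(n)]
    model = AEModel(architecture=arch, enc_w=enc_w, enc_b=enc_b, dec_b=dec_b, dec_w=dec_w)
    return model, manifest["extra"]
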