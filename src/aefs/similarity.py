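"""Similarity coefficients between fingerprint or descriptor vectors.

Two families are provided: the continuous Tanimoto coefficient for
nonnegative real-valued vectors (the measure used on autoencoder codes and
raw count fingerprints), and the classical binary Tanimoto coefficient for
0/1 fingerprints.

The continuous coefficient comes in two variants.  The ``standard`` form,

    S(a, b) = Σ a_i b_i / (Σ a_i² + Σ b_i² − Σ a_i b_i),

is the textbook generalisation of Tanimoto to count/real vectors and has
self-similarity 1.  The ``as_printed`` variant replaces the minus with a
plus in the denominator; it is kept selectable because some descriptions of
the measure are typeset that way, but note its self-similarity is 1/3 for
any nonzero vector.  Rankings can differ between variants, so every result
object in this package records which one was used.
"""

from __future__ import annotations

import numpy as np

#: Recognised similarity variants.
VARIANTS = ("standard", "as_printed", "binary")


def _check_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"vectors must be 1-D with equal length, got {a.shape} and {b.shape}")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("similarity is defined for nonnegative vectors only")
    return a, b


def continuous_tanimoto(a, b, variant: str = "standard") -> float:
    """Continuous Tanimoto similarity between two nonnegative vectors.

    Parameters
    ----------
    a, b:
        Equal-length nonnegative 1-D arrays (counts or real descriptors).
    variant:
        ``"standard"`` — denominator ``Σa²+Σb²−Σab`` (default);
        ``"as_printed"`` — denominator ``Σa²+Σb²+Σab``.

    Raises
    ------
    ValueError
        On length mismatch, negative entries, both vectors all-zero, or an
        unknown variant.
    """
    a, b = _check_pair(a, b)
    ab = float(a @ b)
    aa = float(a @ a)
    bb = float(b @ b)
    if aa == 0.0 and bb == 0.0:
        raise ValueError("similarity undefined: both vectors are all-zero")
    if variant == "standard":
        return ab / (aa + bb - ab)
    if variant == "as_printed":
        return ab / (aa + bb + ab)
    raise ValueError(f"unknown continuous variant {variant!r}")


def binary_tanimoto(a, b) -> float:
    """Binary Tanimoto: ``|a∧b| / (|a| + |b| − |a∧b|)`` for 0/1 vectors."""
    a, b = _check_pair(a, b)
    if not (np.isin(a, (0.0, 1.0)).all() and np.isin(b, (0.0, 1.0)).all()):
        raise ValueError("binary Tanimoto requires 0/1 vectors")
    c = float(a @ b)
    na = float(a.sum())
    nb = float(b.sum())
    if na == 0.0 and nb == 0.0:
        raise ValueError("similarity undefined: both vectors are all-zero")
    return c / (na + nb - c)


def similarity(a, b, variant: str = "standard") -> float:
    """Dispatch on *variant* (``standard`` | ``as_printed`` | ``binary``)."""
    if variant == "binary":
        return binary_tanimoto(a, b)
    return continuous_tanimoto(a, b, variant=variant)


def bulk_similarity(X: np.ndarray, q: np.ndarray, variant: str = "standard") -> np.ndarray:
    """Similarity of query vector *q* against every row of matrix *X*.

    Vectorised equivalent of calling :func:`similarity` row by row; rows of
    ``X`` that are all-zero against an all-zero query would be undefined and
    raise.  Used by the screening module to score whole databases.
    """
    X = np.asarray(X, dtype=float)
    q = np.asarray(q, dtype=float)
    if X.ndim != 2 or q.ndim != 1 or X.shape[1] != q.shape[0]:
        raise ValueError(f"shape mismatch: X {X.shape} vs q {q.shape}")
    if np.any(X < 0) or np.any(q < 0):
        raise ValueError("similarity is defined for nonnegative vectors only")
    if variant == "binary":
        if not (np.isin(X, (0.0, 1.0)).all() and np.isin(q, (0.0, 1.0)).all()):
            raise ValueError("binary Tanimoto requires 0/1 vectors")
        c = X @ q
        denom = X.sum(axis=1) + q.sum() - c
    else:
        c = X @ q
        xx = np.einsum("ij,ij->i", X, X)
        qq = q @ q
        if variant == "standard":
            denom = xx + qq - c
        elif variant == "as_printed":
            denom = xx + qq + c
        else:
            raise ValueError(f"unknown variant {variant!r}")
    if np.any(denom == 0):
        raise ValueError("similarity undefined: encountered an all-zero pair")
    return c / denom
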