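"""Fixed-length cosine-series compression of per-residue profiles.

A length-L profile X is mapped to its first ``n_terms`` coefficients

    X'_k = (2/L) * sum_{n=0}^{L-1} X_n * cos((pi/L) * (n + 1/2) * (k + 1/2))

which is a scaled type-IV discrete cosine transform truncated to the leading
terms. The sum runs over the L defined elements of the profile. No
normalization is applied beyond the 2/L factor and profiles shorter than
``n_terms`` are allowed (no zero-padding).
"""

from __future__ import annotations

import numpy as np

from .encoding_types import CompressedVector, RawProfile
from .errors import DomainError

DEFAULT_N_TERMS = 10


def compress_values(values: np.ndarray, n_terms: int = DEFAULT_N_TERMS) -> np.ndarray:
    """Compress a raw value series to its leading cosine coefficients."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise DomainError("profile values must be one-dimensional")
    L = x.shape[0]
    if L < 1:
        raise DomainError("cannot compress an empty profile")
    if n_terms < 1:
        raise DomainError("n_terms must be >= 1")
    n = np.arange(L) + 0.5
    k = np.arange(n_terms) + 0.5
    basis = np.cos((np.pi / L) * np.outer(k, n))  # (n_terms, L)
    return (2.0 / L) * (basis @ x)


def compress(profile: RawProfile, n_terms: int = DEFAULT_N_TERMS) -> CompressedVector:
    """Compress a :class:`RawProfile`, carrying its channel tag through."""
    return CompressedVector(
        tag=profile.tag, coefficients=compress_values(profile.values, n_terms)
    )
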