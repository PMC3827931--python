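"""Shared value types for the encoding pipeline."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError


@dataclass(frozen=True, eq=False)
class RawProfile:
    """A per-residue numeric series for one channel of one sequence."""

    tag: str
    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1 or arr.shape[0] < 1:
            raise ValidationError(f"profile {self.tag!r} must be a non-empty 1-D series")
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return int(self.values.shape[0])


@dataclass(frozen=True, eq=False)
class CompressedVector:
    """The fixed-length spectral compression of a :class:`RawProfile`."""

    tag: str
    coefficients: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.coefficients, dtype=float)
        if arr.ndim != 1 or arr.shape[0] < 1:
            raise ValidationError(f"compressed vector {self.tag!r} must be 1-D")
        if not np.all(np.isfinite(arr)):
            raise ValidationError(f"compressed vector {self.tag!r} has non-finite values")
        object.__setattr__(self, "coefficients", arr)

    def __len__(self) -> int:
        return int(self.coefficients.shape[0])
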