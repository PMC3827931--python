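"""Protein secondary-structure backends producing 3-state {H, E, C} strings.

The built-in predictor applies classic sliding-window nucleation/extension
rules over helix and sheet conformational propensities. It only needs to
supply a plausible deterministic 3-state assignment; an adapter ingests
state strings computed by external predictors.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Protocol, runtime_checkable

from .errors import BackendContractError, ParseError
from .scales import PropensityScale, builtin_scale
from .seq_io import ProteinSequence

STATES = frozenset("HEC")


@runtime_checkable
class ProteinSsBackend(Protocol):
    def predict(self, seq: ProteinSequence) -> str:
        ...


def validate_states(seq: ProteinSequence, states: str) -> None:
    if len(states) != len(seq):
        raise BackendContractError(
            f"state string length {len(states)} != sequence length "
            f"{len(seq)} for {seq.id!r}"
        )
    bad = set(states) - STATES
    if bad:
        raise BackendContractError(
            f"state string for {seq.id!r} contains invalid states {sorted(bad)}"
        )


class SlidingWindowPredictor:
    """Propensity-window 3-state predictor.

    Helix: any window of 6 with >= 4 residues of helix propensity > 1.0
    nucleates; the region extends while the local 4-residue mean stays
    >= 1.0. Sheet: window of 5 with >= 3 residues of sheet propensity > 1.0,
    same extension rule. Overlaps go to the state with the larger mean
    propensity over the overlap; everything else is coil.
    """

    def __init__(
        self,
        helix: PropensityScale | None = None,
        sheet: PropensityScale | None = None,
    ):
        self.helix = helix or builtin_scale("chou_fasman_helix")
        self.sheet = sheet or builtin_scale("chou_fasman_sheet")

    def predict(self, seq: ProteinSequence) -> str:
        L = len(seq)
        ph = [self.helix.value(r) for r in seq.residues]
        pe = [self.sheet.value(r) for r in seq.residues]
        hmask = self._regions(ph, window=6, formers=4)
        emask = self._regions(pe, window=5, formers=3)
        out = []
        for i in range(L):
            if hmask[i] and emask[i]:
                out.append("H" if ph[i] >= pe[i] else "E")
            elif hmask[i]:
                out.append("H")
            elif emask[i]:
                out.append("E")
            else:
                out.append("C")
        return "".join(out)

    @staticmethod
    def _regions(p: list[float], window: int, formers: int) -> list[bool]:
        L = len(p)
        mask = [False] * L
        for i in range(L - window + 1):
            if sum(1 for v in p[i : i + window] if v > 1.0) >= formers:
                for j in range(i, i + window):
                    mask[j] = True
        # extension: grow marked regions while the adjacent 4-window mean >= 1.0
        changed = True
        while changed:
            changed = False
            for i in range(L):
                if mask[i]:
                    continue
                near = (i > 0 and mask[i - 1]) or (i + 1 < L and mask[i + 1])
                if not near:
                    continue
                lo, hi = max(0, i - 3), min(L, i + 1)
                segment = p[lo:hi]
                if segment and sum(segment) / len(segment) >= 1.0:
                    mask[i] = True
                    changed = True
        return mask


@dataclass
class PrecomputedSsPredictor:
    """Adapter serving externally computed state strings by sequence id."""

    states: Mapping[str, str]

    def predict(self, seq: ProteinSequence) -> str:
        try:
            return self.states[seq.id]
        except KeyError as exc:
            raise BackendContractError(
                f"no precomputed secondary structure for {seq.id!r}"
            ) from exc


def read_ss_states(path: str | Path) -> dict[str, str]:
    """Read a FASTA-like file of 3-state strings (``>id`` then state lines)."""
    states: dict[str, str] = {}
    current: str | None = None
    chunks: list[str] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            if current is not None:
                states[current] = "".join(chunks)
            current = line[1:].split()[0]
            chunks = []
        else:
            if current is None:
                raise ParseError(f"{path}: state data before any header")
            chunks.append(line.upper())
    if current is not None:
        states[current] = "".join(chunks)
    return states
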