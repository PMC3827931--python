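"""RNA secondary-structure backends producing dot-bracket ensembles.

The built-in folder is a Nussinov-style maximum base-pairing algorithm whose
traceback enumerates co-optimal structures (all structures achieving the
maximum number of pairs), in a deterministic order. It is a desk-scale proxy
for a thermodynamic suboptimal-folding engine; an adapter ingests externally
computed dot-bracket ensembles in the usual "sequence line then one structure
per line" layout.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping, Protocol, runtime_checkable

from .errors import BackendContractError, DomainError, ParseError
from .seq_io import RnaSequence

#: canonical + wobble pairs
_PAIRABLE = frozenset(
    {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
)


@runtime_checkable
class RnaFolderBackend(Protocol):
    """Anything that can produce ``n`` dot-bracket strings for a sequence."""

    def fold(self, seq: RnaSequence, n: int) -> list[str]:
        ...


def is_balanced(structure: str) -> bool:
    depth = 0
    for ch in structure:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                return False
        elif ch != ".":
            return False
    return depth == 0


def validate_structures(seq: RnaSequence, structures: list[str], n: int) -> None:
    """Enforce the folder contract: n structures, right length, balanced."""
    if len(structures) != n:
        raise BackendContractError(
            f"folder returned {len(structures)} structures, expected {n}"
        )
    for s in structures:
        if len(s) != len(seq):
            raise BackendContractError(
                f"structure length {len(s)} != sequence length {len(seq)} "
                f"for {seq.id!r}"
            )
        if not is_balanced(s):
            raise BackendContractError(
                f"unbalanced or malformed dot-bracket string for {seq.id!r}: {s!r}"
            )


class NussinovFolder:
    """Maximum base-pairing folder with co-optimal traceback enumeration.

    Structures are returned in a deterministic order; if fewer than ``n``
    co-optimal structures exist, the last one is repeated so the caller
    always receives exactly ``n`` strings.
    """

    def __init__(self, min_loop: int = 3):
        if min_loop < 0:
            raise ValueError("min_loop must be >= 0")
        self.min_loop = min_loop

    def fold(self, seq: RnaSequence, n: int) -> list[str]:
        if n < 1:
            raise DomainError("n must be >= 1")
        structures = list(self._enumerate(seq.residues, limit=n))
        if not structures:  # length-0 impossible; defensive
            structures = ["." * len(seq)]
        while len(structures) < n:
            structures.append(structures[-1])
        return structures

    # -- internals ---------------------------------------------------------

    def _dp_table(self, s: str) -> list[list[int]]:
        L = len(s)
        dp = [[0] * L for _ in range(L)]
        for span in range(self.min_loop + 1, L):
            for i in range(L - span):
                j = i + span
                best = dp[i][j - 1]
                for k in range(i, j - self.min_loop):
                    if (s[k], s[j]) in _PAIRABLE:
                        left = dp[i][k - 1] if k > i else 0
                        inner = dp[k + 1][j - 1] if k + 1 <= j - 1 else 0
                        best = max(best, left + 1 + inner)
                dp[i][j] = best
        return dp

    def _enumerate(self, s: str, limit: int) -> Iterator[str]:
        L = len(s)
        if L == 0:
            return
        dp = self._dp_table(s)
        emitted = 0

        def rec(i: int, j: int) -> Iterator[list[str]]:
            # yields partial structures for s[i..j] achieving dp[i][j]
            if i > j:
                yield []
                return
            if j - i <= self.min_loop:
                yield ["."] * (j - i + 1)
                return
            target = dp[i][j]
            # option: j unpaired
            if dp[i][j - 1] == target:
                for left in rec(i, j - 1):
                    yield left + ["."]
            # option: j paired with k
            for k in range(i, j - self.min_loop):
                if (s[k], s[j]) not in _PAIRABLE:
                    continue
                left = dp[i][k - 1] if k > i else 0
                inner = dp[k + 1][j - 1] if k + 1 <= j - 1 else 0
                if left + 1 + inner != target:
                    continue
                for lpart in rec(i, k - 1):
                    for ipart in rec(k + 1, j - 1):
                        yield lpart + ["("] + ipart + [")"]

        seen: set[str] = set()
        for parts in rec(0, L - 1):
            structure = "".join(parts)
            if structure in seen:  # decomposition is unique, but stay safe
                continue
            seen.add(structure)
            yield structure
            emitted += 1
            if emitted >= limit:
                return


@dataclass
class PrecomputedFolder:
    """Adapter serving externally computed dot-bracket ensembles by sequence id.

    Truncates to ``n`` structures, or pads by repeating the last one, so the
    [0, n] pairedness range stays comparable with the built-in folder.
    """

    structures: Mapping[str, list[str]]

    def fold(self, seq: RnaSequence, n: int) -> list[str]:
        if n < 1:
            raise DomainError("n must be >= 1")
        try:
            available = list(self.structures[seq.id])
        except KeyError as exc:
            raise BackendContractError(
                f"no precomputed structures for sequence {seq.id!r}"
            ) from exc
        if not available:
            raise BackendContractError(
                f"empty structure list for sequence {seq.id!r}"
            )
        out = available[:n]
        while len(out) < n:
            out.append(out[-1])
        return out


def read_subopt_file(path: str | Path) -> tuple[str, list[str]]:
    """Read a suboptimal-structure file: sequence line, then one dot-bracket
    string per line (trailing free-energy columns are ignored)."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise ParseError(f"{path} is empty")
    sequence = lines[0].split()[0].upper()
    structures = []
    for ln in lines[1:]:
        token = ln.split()[0]
        if set(token) <= {".", "(", ")"}:
            structures.append(token)
    if not structures:
        raise ParseError(f"{path} contains no dot-bracket structures")
    return sequence, structures
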