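"""Sequence domain types plus FASTA and labeled-pair-table I/O.

RNA sequences are normalized to uppercase with T mapped to U; protein
sequences are uppercased. Both are validated against their alphabets at
construction time, so every object in the rest of the package can assume a
clean sequence. Ambiguity letters (N for RNA; B, Z, X, U for protein) are
accepted here and resolved at encoding time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ParseError, SchemaError, ValidationError

RNA_ALPHABET = frozenset("ACGUN")
PROTEIN_STANDARD = "ACDEFGHIKLMNPQRSTVWY"
PROTEIN_ALPHABET = frozenset(PROTEIN_STANDARD + "BZXU")

INTERACTIVE = "interactive"
NON_INTERACTIVE = "non-interactive"
LABELS = frozenset({INTERACTIVE, NON_INTERACTIVE})


def normalize_rna(residues: str) -> str:
    """Deterministic RNA normalization: uppercase, T -> U."""
    return residues.upper().replace("T", "U")


def normalize_protein(residues: str) -> str:
    return residues.upper()


@dataclass(frozen=True)
class RnaSequence:
    """An RNA sequence over {A, C, G, U, N}, normalized at construction."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        normalized = normalize_rna(self.residues)
        object.__setattr__(self, "residues", normalized)
        if len(normalized) == 0:
            raise ValidationError(f"RNA sequence {self.id!r} is empty")
        bad = set(normalized) - RNA_ALPHABET
        if bad:
            raise ValidationError(
                f"RNA sequence {self.id!r} contains invalid residues "
                f"{sorted(bad)} after normalization"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence over the 20 standard letters plus B, Z, X, U."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        normalized = normalize_protein(self.residues)
        object.__setattr__(self, "residues", normalized)
        if len(normalized) == 0:
            raise ValidationError(f"protein sequence {self.id!r} is empty")
        bad = set(normalized) - PROTEIN_ALPHABET
        if bad:
            raise ValidationError(
                f"protein sequence {self.id!r} contains invalid residues "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class LabeledPair:
    """An (RNA, protein) pair with an interactivity label.

    ``provenance`` optionally records the source complex or database entry.
    """

    rna_id: str
    protein_id: str
    label: str
    provenance: str | None = None

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValidationError(
                f"unknown label {self.label!r} for pair "
                f"({self.rna_id!r}, {self.protein_id!r}); "
                f"expected one of {sorted(LABELS)}"
            )

    @property
    def is_interactive(self) -> bool:
        return self.label == INTERACTIVE


SequenceCollection = dict[str, RnaSequence] | dict[str, ProteinSequence]


def read_fasta(path: str | Path, kind: str) -> list[RnaSequence | ProteinSequence]:
    """Read a multi-record FASTA file into normalized sequence objects.

    Parameters
    ----------
    path:
        FASTA file (wrapped or unwrapped lines).
    kind:
        ``"rna"`` or ``"protein"``.
    """
    if kind not in ("rna", "protein"):
        raise ValueError(f"kind must be 'rna' or 'protein', got {kind!r}")
    path = Path(path)
    cls = RnaSequence if kind == "rna" else ProteinSequence
    records: list[RnaSequence | ProteinSequence] = []
    seen: set[str] = set()
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # malformed FASTA
        raise ParseError(f"cannot parse FASTA file {path}: {exc}") from exc
    if not parsed and path.stat().st_size > 0:
        raise ParseError(f"{path} is not empty but contains no FASTA records")
    for rec in parsed:
        if not rec.id:
            raise ParseError(f"record with empty header in {path}")
        if len(rec.seq) == 0:
            raise ParseError(f"record {rec.id!r} in {path} has an empty sequence")
        if rec.id in seen:
            raise ValidationError(f"duplicate id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(cls(rec.id, str(rec.seq)))
    return records


def write_fasta(
    sequences: Iterable[RnaSequence | ProteinSequence], path: str | Path
) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in sequences
    ]
    SeqIO.write(records, str(path), "fasta")


def as_mapping(
    sequences: Iterable[RnaSequence | ProteinSequence],
) -> dict[str, RnaSequence | ProteinSequence]:
    """Index a sequence collection by id, rejecting duplicates."""
    out: dict[str, RnaSequence | ProteinSequence] = {}
    for s in sequences:
        if s.id in out:
            raise ValidationError(f"duplicate sequence id {s.id!r}")
        out[s.id] = s
    return out


PAIR_COLUMNS = ("rna_id", "protein_id", "label")


def read_pairs(path: str | Path) -> list[LabeledPair]:
    """Read a labeled pair table (TSV with a header row).

    Required columns: ``rna_id``, ``protein_id``, ``label``. An optional
    ``provenance`` column is carried through. An empty file yields an empty
    list.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return []
    missing = [c for c in PAIR_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path} is missing required column(s) {missing}")
    has_prov = "provenance" in frame.columns
    pairs = []
    for row in frame.itertuples(index=False):
        prov = getattr(row, "provenance", "") if has_prov else ""
        pairs.append(
            LabeledPair(
                rna_id=row.rna_id,
                protein_id=row.protein_id,
                label=row.label,
                provenance=prov or None,
            )
        )
    return pairs


def write_pairs(pairs: Sequence[LabeledPair], path: str | Path) -> None:
    frame = pd.DataFrame(
        {
            "rna_id": [p.rna_id for p in pairs],
            "protein_id": [p.protein_id for p in pairs],
            "label": [p.label for p in pairs],
            "provenance": [p.provenance or "" for p in pairs],
        }
    )
    frame.to_csv(path, sep="\t", index=False)
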