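"""Labeled training-set construction from PDB-format complexes.

Chains are extracted from the first model of a coordinate file, classified
as RNA or protein by majority residue type, deduplicated within a complex
(identical sequences of the same polymer kind collapse to one
representative), and every (RNA, protein) representative pair is labeled
interactive when the least atom distance is strictly below the cutoff.
Length filtering, sequence-identity redundancy removal, evidence-code
classification and negative-set shuffling follow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.PDB import PDBParser
from scipy.spatial.distance import cdist

from .errors import DomainError, ParseError, ValidationError
from .seq_io import (
    INTERACTIVE,
    NON_INTERACTIVE,
    LabeledPair,
    ProteinSequence,
    RnaSequence,
)

logger = logging.getLogger(__name__)

_AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "SEC": "U", "MSE": "M", "ASX": "B", "GLX": "Z", "UNK": "X",
}
_NT_NAMES = {"A": "A", "C": "C", "G": "G", "U": "U", "T": "U", "N": "N",
             "DA": "A", "DC": "C", "DG": "G", "DT": "U", "DU": "U"}
_SOLVENT = {"HOH", "WAT", "DOD"}


@dataclass(frozen=True)
class ChainRecord:
    """One polymer chain: id, kind, one-letter sequence, atom coordinates."""

    chain_id: str
    kind: str  # "rna" or "protein"
    sequence: str
    coords: np.ndarray  # (n_atoms, 3), Angstrom

    def __post_init__(self) -> None:
        arr = np.asarray(self.coords, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] < 1:
            raise ValidationError(
                f"chain {self.chain_id!r} needs at least one (x, y, z) atom"
            )
        if not np.all(np.isfinite(arr)):
            raise ValidationError(f"chain {self.chain_id!r} has non-finite coordinates")
        object.__setattr__(self, "coords", arr)
        if self.kind not in ("rna", "protein"):
            raise ValidationError(f"unknown polymer kind {self.kind!r}")


@dataclass(frozen=True)
class ComplexRecord:
    complex_id: str
    chains: tuple[ChainRecord, ...]

    def rna_chains(self) -> list[ChainRecord]:
        return [c for c in self.chains if c.kind == "rna"]

    def protein_chains(self) -> list[ChainRecord]:
        return [c for c in self.chains if c.kind == "protein"]


@dataclass(frozen=True)
class DatasetConfig:
    """Filtering and labeling knobs for training-set construction."""

    distance_cutoff: float = 5.0
    min_rna_len: int = 100
    max_rna_len: int = 4095
    protein_identity_cutoff: float = 0.9
    rna_identity_cutoff: float = 0.9
    heavy_atoms_only: bool = False

    def __post_init__(self) -> None:
        if self.distance_cutoff <= 0:
            raise ValidationError("distance_cutoff must be positive")
        for name in ("protein_identity_cutoff", "rna_identity_cutoff"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValidationError(f"{name} must be in (0, 1]")


# -- PDB I/O ---------------------------------------------------------------


def read_pdb_complex(
    path: str | Path,
    complex_id: str | None = None,
    heavy_atoms_only: bool = False,
) -> ComplexRecord:
    """Parse the first model of a PDB-format file into a ComplexRecord.

    Solvent is skipped; each remaining chain is typed by majority residue
    kind and its sequence is taken from the residues present (unknown
    residues become X / N).
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure(path.stem, str(path))
    except Exception as exc:
        raise ParseError(f"cannot parse PDB file {path}: {exc}") from exc
    try:
        model = next(structure.get_models())
    except StopIteration:
        raise ParseError(f"{path} contains no models")
    chains: list[ChainRecord] = []
    for chain in model:
        letters: list[tuple[str, str]] = []  # (kind, one-letter)
        coords: list[np.ndarray] = []
        for residue in chain:
            resname = residue.get_resname().strip()
            if resname in _SOLVENT:
                continue
            if resname in _AA_3TO1:
                letters.append(("protein", _AA_3TO1[resname]))
            elif resname in _NT_NAMES:
                letters.append(("rna", _NT_NAMES[resname]))
            else:
                letters.append(("unknown", "X"))
            for atom in residue:
                if heavy_atoms_only and (atom.element or "").strip() == "H":
                    continue
                coords.append(atom.coord)
        if not letters or not coords:
            continue
        kinds = [k for k, _ in letters if k != "unknown"]
        if not kinds:
            logger.warning(
                "%s chain %s: no recognizable polymer residues; skipped",
                path.name, chain.id,
            )
            continue
        kind = max(("rna", "protein"), key=kinds.count)
        if len(set(kinds)) > 1:
            logger.warning(
                "%s chain %s: mixed residue kinds, using majority %r",
                path.name, chain.id, kind,
            )
        seq = "".join(
            letter if k == kind or k == "unknown" else ("X" if kind == "protein" else "N")
            for k, letter in letters
        )
        if kind == "rna":
            seq = seq.replace("X", "N")
        chains.append(
            ChainRecord(
                chain_id=chain.id.strip() or chain.id,
                kind=kind,
                sequence=seq,
                coords=np.array(coords, dtype=float),
            )
        )
    return ComplexRecord(complex_id=complex_id or path.stem, chains=tuple(chains))


def write_pdb_complex(complex_record: ComplexRecord, path: str | Path) -> None:
    """Write a minimal single-atom-per-coordinate PDB file (round-trippable)."""
    lines = []
    serial = 1
    for chain in complex_record.chains:
        n_res = len(chain.sequence)
        n_atoms = chain.coords.shape[0]
        # distribute atoms across residues as evenly as possible
        per_res = [n_atoms // n_res] * n_res
        for i in range(n_atoms % n_res):
            per_res[i] += 1
        atom_i = 0
        for res_i, letter in enumerate(chain.sequence):
            if chain.kind == "protein":
                resname = next(
                    (k for k, v in _AA_3TO1.items() if v == letter), "UNK"
                )
                atom_name = " CA "
                element = " C"
            else:
                resname = letter if letter in "ACGU" else "N"
                atom_name = " P  "
                element = " P"
            for _ in range(per_res[res_i]):
                x, y, z = chain.coords[atom_i]
                lines.append(
                    f"ATOM  {serial:5d} {atom_name}{'':1s}{resname:>3s} "
                    f"{chain.chain_id[:1]}{res_i + 1:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                    f"          {element:>2s}"
                )
                serial += 1
                atom_i += 1
        lines.append(f"TER   {serial:5d}      {resname:>3s} {chain.chain_id[:1]}")
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# -- geometry and labeling -------------------------------------------------


def least_atom_distance(atoms_a: np.ndarray, atoms_b: np.ndarray) -> float:
    """Minimum Euclidean distance over all cross pairs of atoms (Angstrom)."""
    a = np.atleast_2d(np.asarray(atoms_a, dtype=float))
    b = np.atleast_2d(np.asarray(atoms_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise DomainError("both atom sets must be nonempty")
    return float(cdist(a, b).min())


def label_interactivity(
    rna_chain: ChainRecord, protein_chain: ChainRecord, cutoff: float
) -> str:
    """``interactive`` iff the least atom distance is strictly below cutoff."""
    d = least_atom_distance(rna_chain.coords, protein_chain.coords)
    return INTERACTIVE if d < cutoff else NON_INTERACTIVE


def _dedup_chains(
    chains: Sequence[ChainRecord],
) -> list[tuple[ChainRecord, list[ChainRecord]]]:
    """Collapse chains with identical sequences (within one polymer kind)
    to (representative, copies) groups, keeping first-seen order."""
    groups: dict[str, list[ChainRecord]] = {}
    order: list[str] = []
    for chain in chains:
        if chain.sequence not in groups:
            groups[chain.sequence] = []
            order.append(chain.sequence)
        groups[chain.sequence].append(chain)
    return [(groups[s][0], groups[s]) for s in order]


def extract_pairs(
    complex_record: ComplexRecord, config: DatasetConfig | None = None
) -> tuple[list[LabeledPair], dict[str, RnaSequence], dict[str, ProteinSequence]]:
    """Deduplicate chains within a complex and label every cross pair.

    A collapsed chain is labeled interactive when ANY of its copies is
    within the cutoff of any copy of the partner. Returns the labeled
    pairs plus id-indexed sequence collections (ids are
    ``<complex>_<chain>``).
    """
    config = config or DatasetConfig()
    rna_groups = _dedup_chains(complex_record.rna_chains())
    protein_groups = _dedup_chains(complex_record.protein_chains())
    if not rna_groups or not protein_groups:
        logger.warning(
            "complex %s has %d RNA and %d protein chains after dedup; no pairs",
            complex_record.complex_id, len(rna_groups), len(protein_groups),
        )
        return [], {}, {}
    rnas: dict[str, RnaSequence] = {}
    proteins: dict[str, ProteinSequence] = {}
    pairs: list[LabeledPair] = []
    for rna_rep, rna_copies in rna_groups:
        rna_id = f"{complex_record.complex_id}_{rna_rep.chain_id}"
        rnas[rna_id] = RnaSequence(rna_id, rna_rep.sequence)
        for prot_rep, prot_copies in protein_groups:
            prot_id = f"{complex_record.complex_id}_{prot_rep.chain_id}"
            if prot_id not in proteins:
                proteins[prot_id] = ProteinSequence(prot_id, prot_rep.sequence)
            d = min(
                least_atom_distance(rc.coords, pc.coords)
                for rc in rna_copies
                for pc in prot_copies
            )
            labels = {
                label_interactivity(rc, pc, config.distance_cutoff)
                for rc in rna_copies
                for pc in prot_copies
            }
            if len(labels) > 1:
                logger.warning(
                    "complex %s: copies of (%s, %s) disagree on interactivity; "
                    "using any-copy rule",
                    complex_record.complex_id, rna_rep.chain_id, prot_rep.chain_id,
                )
            label = INTERACTIVE if d < config.distance_cutoff else NON_INTERACTIVE
            pairs.append(
                LabeledPair(
                    rna_id=rna_id,
                    protein_id=prot_id,
                    label=label,
                    provenance=complex_record.complex_id,
                )
            )
    return pairs, rnas, proteins


# -- filtering -------------------------------------------------------------


def filter_rna_length(
    pairs: Sequence[LabeledPair],
    rnas: Mapping[str, RnaSequence],
    min_len: int = 100,
    max_len: int = 4095,
) -> list[LabeledPair]:
    """Keep pairs whose RNA is strictly longer than min_len and <= max_len."""
    return [p for p in pairs if min_len < len(rnas[p.rna_id]) <= max_len]


_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1
_aligner.mismatch_score = 0
_aligner.open_gap_score = -1
_aligner.extend_gap_score = -1


def sequence_identity(a: str, b: str) -> float:
    """Global-alignment identity: matches / alignment columns.

    Scoring is match=1, mismatch=0, linear gap -1. This is a built-in
    approximation of word-based clustering identity; use a cluster-file
    adapter for exact reproduction of an external clustering.
    """
    if not a or not b:
        raise DomainError("cannot align empty sequences")
    if a == b:
        return 1.0
    alignment = _aligner.align(a, b)[0]
    counts = alignment.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / columns if columns else 0.0


def remove_redundancy(
    pairs: Sequence[LabeledPair],
    rnas: Mapping[str, RnaSequence],
    proteins: Mapping[str, ProteinSequence],
    config: DatasetConfig | None = None,
    clusters: tuple[Mapping[str, int], Mapping[str, int]] | None = None,
) -> list[LabeledPair]:
    """Greedy in-order scan dropping pairs similar to an already-kept pair.

    A pair is dropped iff some retained pair matches it on BOTH sides:
    protein identity >= cutoff AND RNA identity >= cutoff. Input order is
    preserved (no silent re-sorting); the operation is idempotent.
    ``clusters`` optionally supplies (rna_cluster_map, protein_cluster_map)
    from an external clustering, replacing the built-in identity.
    """
    config = config or DatasetConfig()
    kept: list[LabeledPair] = []
    cache: dict[tuple[str, str], float] = {}

    def ident(x: str, y: str, seqs: Mapping, kind_cluster: Mapping | None) -> float:
        if kind_cluster is not None:
            return 1.0 if kind_cluster.get(x) == kind_cluster.get(y) else 0.0
        key = (x, y) if x <= y else (y, x)
        if key not in cache:
            cache[key] = sequence_identity(seqs[x].residues, seqs[y].residues)
        return cache[key]

    rna_clusters, protein_clusters = clusters if clusters else (None, None)
    for pair in pairs:
        redundant = False
        for kept_pair in kept:
            rna_id_frac = ident(pair.rna_id, kept_pair.rna_id, rnas, rna_clusters)
            if rna_id_frac < config.rna_identity_cutoff:
                continue
            prot_id_frac = ident(
                pair.protein_id, kept_pair.protein_id, proteins, protein_clusters
            )
            if prot_id_frac >= config.protein_identity_cutoff:
                redundant = True
                break
        if not redundant:
            kept.append(pair)
    return kept


def read_cdhit_clusters(path: str | Path) -> dict[str, int]:
    """Parse a CD-HIT ``.clstr`` file into a sequence-id -> cluster-index map."""
    clusters: dict[str, int] = {}
    current = -1
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">Cluster"):
            current = int(line.split()[1])
            continue
        if current < 0:
            raise ParseError(f"{path}: member line before any cluster header")
        # member lines look like: 0	123aa, >seqid... *
        start = line.find(">")
        end = line.find("...", start)
        if start < 0 or end < 0:
            raise ParseError(f"{path}: malformed member line {line!r}")
        clusters[line[start + 1 : end]] = current
    return clusters


# -- external-evidence handling -------------------------------------------

DIRECT_EVIDENCE_CODES = frozenset({1, 5, 6})


def classify_npinter_evidence(code: int) -> str:
    """Evidence-code grouping: codes 1, 5, 6 are direct, 2-4 and 7-8 indirect."""
    if code not in range(1, 9):
        raise DomainError(f"evidence code must be in 1..8, got {code}")
    return "direct" if code in DIRECT_EVIDENCE_CODES else "indirect"


def shuffle_pairs(pairs: Sequence[LabeledPair], seed: int) -> list[LabeledPair]:
    """Seeded re-pairing of RNA ids against a permutation of protein ids.

    Preserves the pair count; retries the permutation so that no output
    pair reproduces an input pair, unless that is unavoidable (then a
    warning is logged).
    """
    if not pairs:
        return []
    rng = np.random.default_rng(seed)
    original = {(p.rna_id, p.protein_id) for p in pairs}
    protein_ids = [p.protein_id for p in pairs]
    best: list[str] | None = None
    for _ in range(200):
        perm = [protein_ids[i] for i in rng.permutation(len(protein_ids))]
        collisions = sum(
            1 for p, prot in zip(pairs, perm) if (p.rna_id, prot) in original
        )
        if best is None or collisions < best[0]:  # type: ignore[index]
            best = [collisions, perm]  # type: ignore[assignment]
        if collisions == 0:
            break
    collisions, perm = best  # type: ignore[misc]
    if collisions:
        logger.warning(
            "shuffle_pairs: %d of %d shuffled pairs reproduce an input pair "
            "(unavoidable for this input)",
            collisions, len(pairs),
        )
    return [
        replace(p, protein_id=prot, label=NON_INTERACTIVE, provenance="shuffled")
        for p, prot in zip(pairs, perm)
    ]


# -- whole-directory driver ------------------------------------------------


@dataclass
class StageCounts:
    """Bookkeeping of pair counts through the construction stages."""

    complexes: int = 0
    chains_total: int = 0
    chains_after_dedup: int = 0
    pairs_extracted: int = 0
    pairs_after_length_filter: int = 0
    pairs_after_redundancy: int = 0
    interactive: int = 0
    non_interactive: int = 0


def build_dataset(
    pdb_paths: Iterable[str | Path], config: DatasetConfig | None = None
) -> tuple[list[LabeledPair], dict[str, RnaSequence], dict[str, ProteinSequence], StageCounts]:
    """Run the full construction pipeline over PDB-format files."""
    config = config or DatasetConfig()
    counts = StageCounts()
    all_pairs: list[LabeledPair] = []
    rnas: dict[str, RnaSequence] = {}
    proteins: dict[str, ProteinSequence] = {}
    for path in pdb_paths:
        record = read_pdb_complex(path, heavy_atoms_only=config.heavy_atoms_only)
        counts.complexes += 1
        counts.chains_total += len(record.chains)
        counts.chains_after_dedup += len(_dedup_chains(record.rna_chains())) + len(
            _dedup_chains(record.protein_chains())
        )
        pairs, c_rnas, c_proteins, = extract_pairs(record, config)
        all_pairs.extend(pairs)
        rnas.update(c_rnas)
        proteins.update(c_proteins)
    counts.pairs_extracted = len(all_pairs)
    filtered = filter_rna_length(
        all_pairs, rnas, min_len=config.min_rna_len, max_len=config.max_rna_len
    )
    counts.pairs_after_length_filter = len(filtered)
    non_redundant = remove_redundancy(filtered, rnas, proteins, config)
    counts.pairs_after_redundancy = len(non_redundant)
    counts.interactive = sum(1 for p in non_redundant if p.is_interactive)
    counts.non_interactive = len(non_redundant) - counts.interactive
    used_rnas = {p.rna_id: rnas[p.rna_id] for p in non_redundant}
    used_proteins = {p.protein_id: proteins[p.protein_id] for p in non_redundant}
    return non_redundant, used_rnas, used_proteins, counts
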