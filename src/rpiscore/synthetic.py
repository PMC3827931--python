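"""Deterministic generators for test and benchmark inputs.

Three families: i.i.d. random sequences, toy coordinate complexes whose
chain separations (and therefore labels) are known by construction, and
planted-rule pair datasets for parameter-recovery experiments.

Planted datasets define their labels in compressed-feature space: each
channel pairing has a hidden rank-one direction u (x) v, positive pairs
have their protein channel vectors shifted along +u and negative pairs
along -u, so the class means in outer-product space differ by a multiple
of vec(u v') — the planted discriminant direction. The generated sequences
are random carriers; their features are served by a
:class:`~rpiscore.encoding.PrecomputedEncoder`, which plugs into the same
encoder slot as the standard pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dataset import ChainRecord, ComplexRecord
from .encoding import PrecomputedEncoder
from .errors import DomainError, ValidationError
from .scales import PROTEIN_TAGS, RNA_TAGS
from .seq_io import (
    INTERACTIVE,
    NON_INTERACTIVE,
    PROTEIN_STANDARD,
    LabeledPair,
    ProteinSequence,
    RnaSequence,
)

_ALPHABETS = {"rna": "ACGU", "protein": PROTEIN_STANDARD}


def random_sequences(
    n: int,
    length_range: tuple[int, int],
    kind: str,
    seed: int,
    prefix: str | None = None,
) -> list[RnaSequence | ProteinSequence]:
    """n i.i.d.-uniform random sequences, reproducible from the seed."""
    if kind not in _ALPHABETS:
        raise DomainError(f"kind must be 'rna' or 'protein', got {kind!r}")
    lo, hi = length_range
    if not 1 <= lo <= hi:
        raise DomainError(f"invalid length range {length_range}")
    rng = np.random.default_rng(seed)
    alphabet = np.array(list(_ALPHABETS[kind]))
    cls = RnaSequence if kind == "rna" else ProteinSequence
    prefix = prefix or kind
    out = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        residues = "".join(rng.choice(alphabet, size=length))
        out.append(cls(f"{prefix}_{i:04d}", residues))
    return out


# -- toy complexes ---------------------------------------------------------


@dataclass(frozen=True)
class ToyChainSpec:
    """A chain laid out along the x axis: atoms at start_x, start_x+1, ...

    With all chains on the same line (y = z = 0), the least atom distance
    between two chains is exactly the gap between their x intervals, so
    every expected label is known by construction.
    """

    chain_id: str
    kind: str
    sequence: str
    start_x: float

    @property
    def end_x(self) -> float:
        return self.start_x + len(self.sequence) - 1


def toy_complex(complex_id: str, chains: Sequence[ToyChainSpec]) -> ComplexRecord:
    """Build a ComplexRecord with one atom per residue at 1 A spacing."""
    records = []
    for spec in chains:
        xs = spec.start_x + np.arange(len(spec.sequence), dtype=float)
        coords = np.column_stack([xs, np.zeros_like(xs), np.zeros_like(xs)])
        records.append(
            ChainRecord(
                chain_id=spec.chain_id,
                kind=spec.kind,
                sequence=spec.sequence,
                coords=coords,
            )
        )
    return ComplexRecord(complex_id=complex_id, chains=tuple(records))


def two_chain_complex(
    distance: float,
    rna_len: int = 12,
    protein_len: int = 8,
    complex_id: str = "toy",
    seed: int = 0,
) -> ComplexRecord:
    """An RNA and a protein chain placed exactly ``distance`` apart."""
    rna = random_sequences(1, (rna_len, rna_len), "rna", seed)[0]
    protein = random_sequences(1, (protein_len, protein_len), "protein", seed + 1)[0]
    return toy_complex(
        complex_id,
        [
            ToyChainSpec("R", "rna", rna.residues, start_x=0.0),
            ToyChainSpec("P", "protein", protein.residues, start_x=(rna_len - 1) + distance),
        ],
    )


# -- planted-rule datasets -------------------------------------------------


@dataclass(frozen=True)
class PlantedDatasetSpec:
    """Parameters of a planted-rule pair dataset."""

    n_pairs: int = 400
    rna_length_range: tuple[int, int] = (60, 120)
    protein_length_range: tuple[int, int] = (40, 80)
    separation: float = 4.0  # class-mean distance along the planted direction, pooled-SD units
    noise: float = 0.1  # within-class channel-vector noise SD
    seed: int = 0
    n_terms: int = 10

    def __post_init__(self) -> None:
        if self.n_pairs < 4 or self.n_pairs % 2:
            raise ValidationError("n_pairs must be an even number >= 4")
        if self.separation < 0:
            raise ValidationError("separation must be >= 0")
        if self.noise < 0:
            raise ValidationError("noise must be >= 0")
        if self.separation == 0 and self.noise == 0:
            raise DomainError(
                "separation 0 with noise 0 gives identical classes (degenerate)"
            )


@dataclass
class PlantedDataset:
    """A planted dataset plus its hidden per-pairing directions."""

    spec: PlantedDatasetSpec
    pairs: list[LabeledPair]
    rnas: dict[str, RnaSequence]
    proteins: dict[str, ProteinSequence]
    encoder: PrecomputedEncoder
    hidden_directions: dict[str, np.ndarray]  # pairing tag -> unit vec, dim n_terms^2


def planted_pair_dataset(spec: PlantedDatasetSpec) -> PlantedDataset:
    """Generate a labeled pair set whose channel features follow hidden
    rank-one linear rules, with exact class balance.

    For every channel pairing, the protein channel vector of a pair with
    class y in {+1, -1} is y*s*u + noise*eps and the RNA channel vector is
    s*v + noise*eps', with s chosen so the class means in outer-product
    space are ``separation`` pooled standard deviations apart along the
    planted direction vec(u v'). With noise = 0 the classes are separated
    exactly (s = 1).
    """
    from .discriminant import CHANNEL_PAIRINGS, pairing_tag  # local: avoid cycle

    rng = np.random.default_rng(spec.seed)
    d = spec.n_terms
    half = spec.n_pairs // 2
    if spec.noise > 0:
        # class-mean distance along w is 2s^2, pooled SD along w approx
        # noise * s * sqrt(2) for s >> noise  =>  s = separation * noise / sqrt(2)
        s = spec.separation * spec.noise / math.sqrt(2.0)
    else:
        s = 1.0

    def unit(size: int) -> np.ndarray:
        v = rng.standard_normal(size)
        return v / np.linalg.norm(v)

    u = {pt: unit(d) for pt in PROTEIN_TAGS}
    v = {rt: unit(d) for rt in RNA_TAGS}
    hidden = {
        pairing_tag(pt, rt): np.outer(u[pt], v[rt]).ravel()
        for pt, rt in CHANNEL_PAIRINGS
    }

    rna_seqs = random_sequences(
        spec.n_pairs, spec.rna_length_range, "rna", spec.seed + 1, prefix="prna"
    )
    prot_seqs = random_sequences(
        spec.n_pairs, spec.protein_length_range, "protein", spec.seed + 2, prefix="pprot"
    )
    classes = np.array([1] * half + [-1] * half)

    rna_features: dict[str, dict[str, np.ndarray]] = {}
    protein_features: dict[str, dict[str, np.ndarray]] = {}
    pairs: list[LabeledPair] = []
    for j in range(spec.n_pairs):
        y = int(classes[j])
        rna_features[rna_seqs[j].id] = {
            rt: s * v[rt] + spec.noise * rng.standard_normal(d) for rt in RNA_TAGS
        }
        protein_features[prot_seqs[j].id] = {
            pt: y * s * u[pt] + spec.noise * rng.standard_normal(d)
            for pt in PROTEIN_TAGS
        }
        pairs.append(
            LabeledPair(
                rna_id=rna_seqs[j].id,
                protein_id=prot_seqs[j].id,
                label=INTERACTIVE if y > 0 else NON_INTERACTIVE,
                provenance="planted",
            )
        )
    encoder = PrecomputedEncoder(rna_features, protein_features, n_terms=d)
    return PlantedDataset(
        spec=spec,
        pairs=pairs,
        rnas={r.id: r for r in rna_seqs},
        proteins={p.id: p for p in prot_seqs},
        encoder=encoder,
        hidden_directions=hidden,
    )


def permute_labels(pairs: Sequence[LabeledPair], seed: int) -> list[LabeledPair]:
    """Randomly reassign the existing labels across pairs (null control)."""
    from dataclasses import replace

    rng = np.random.default_rng(seed)
    labels = [p.label for p in pairs]
    permuted = [labels[i] for i in rng.permutation(len(labels))]
    return [replace(p, label=lab) for p, lab in zip(pairs, permuted)]
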