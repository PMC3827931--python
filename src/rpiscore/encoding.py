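"""Sequence -> numeric channel encoding.

Each RNA yields three channels: a pairedness count summed over an ensemble
of predicted secondary structures (brackets -> 1, dots -> 0, added across
the ensemble), a hydrogen-bonding propensity series, and a van der Waals
propensity series. Each protein yields five: a secondary-structure channel
(Chou-Fasman conformational propensity selected by the predicted per-residue
state) plus Grantham, Zimmerman, Kyte-Doolittle and Bull-Breese propensity
series. All channels are then compressed to a fixed number of cosine terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .encoding_types import CompressedVector, RawProfile
from .errors import BackendContractError, DomainError, EncodingError, ValidationError
from .folding import NussinovFolder, RnaFolderBackend, validate_structures
from .protein_ss import ProteinSsBackend, SlidingWindowPredictor, validate_states
from .scales import (
    PROTEIN_TAGS,
    RNA_TAGS,
    PropensityScale,
    default_chou_fasman,
    default_protein_scales,
    default_rna_scales,
)
from .seq_io import ProteinSequence, RnaSequence
from .spectral import DEFAULT_N_TERMS, compress

DEFAULT_N_STRUCT = 6
MAX_N_STRUCT = 16
MAX_RNA_LEN = 4095


def encode_rna_structure(
    seq: RnaSequence, folder: RnaFolderBackend, n: int = DEFAULT_N_STRUCT
) -> RawProfile:
    """Per-residue pairedness count over ``n`` predicted structures.

    Position i holds the number of structures in which residue i is paired,
    an integer in [0, n].
    """
    if n < 1:
        raise DomainError("n must be >= 1")
    structures = folder.fold(seq, n)
    validate_structures(seq, structures, n)
    counts = np.zeros(len(seq), dtype=float)
    for structure in structures:
        counts += np.frombuffer(structure.encode(), dtype=np.uint8) != ord(".")
    return RawProfile(tag="rna_structure", values=counts)


def encode_rna_propensity(
    seq: RnaSequence, scale: PropensityScale, tag: str
) -> RawProfile:
    return RawProfile(tag=tag, values=np.array(scale.encode(seq.residues)))


def encode_protein_structure(
    seq: ProteinSequence,
    predictor: ProteinSsBackend,
    chou_fasman: Mapping[str, PropensityScale],
) -> RawProfile:
    """Conformational propensity selected per residue by predicted state.

    ``chou_fasman`` maps each state in {H, E, C} to its propensity table
    (helix, sheet, and turn-for-coil by default).
    """
    states = predictor.predict(seq)
    validate_states(seq, states)
    missing = set(states) - set(chou_fasman)
    if missing:
        raise BackendContractError(
            f"no propensity table for state(s) {sorted(missing)}"
        )
    values = [
        chou_fasman[state].value(res) for res, state in zip(seq.residues, states)
    ]
    return RawProfile(tag="prot_structure", values=np.array(values))


def encode_protein_propensity(
    seq: ProteinSequence, scale: PropensityScale, tag: str
) -> RawProfile:
    return RawProfile(tag=tag, values=np.array(scale.encode(seq.residues)))


@dataclass
class EncodingConfig:
    """Tunable knobs of the encoding pipeline."""

    n_struct: int = DEFAULT_N_STRUCT
    n_terms: int = DEFAULT_N_TERMS
    max_rna_len: int = MAX_RNA_LEN
    long_rna_policy: str = "error"  # or "truncate"

    def __post_init__(self) -> None:
        if not 1 <= self.n_struct <= MAX_N_STRUCT:
            raise ValidationError(f"n_struct must be in [1, {MAX_N_STRUCT}]")
        if self.n_terms < 1:
            raise ValidationError("n_terms must be >= 1")
        if self.long_rna_policy not in ("error", "truncate"):
            raise ValidationError("long_rna_policy must be 'error' or 'truncate'")


def _apply_long_policy(seq: RnaSequence, config: EncodingConfig) -> RnaSequence:
    if len(seq) <= config.max_rna_len:
        return seq
    if config.long_rna_policy == "truncate":
        return RnaSequence(seq.id, seq.residues[: config.max_rna_len])
    raise EncodingError(
        f"RNA {seq.id!r} has length {len(seq)} > {config.max_rna_len}; "
        "set long_rna_policy='truncate' to encode the leading residues"
    )


def encode_rna(
    seq: RnaSequence,
    folder: RnaFolderBackend,
    scales: Mapping[str, PropensityScale],
    n_terms: int = DEFAULT_N_TERMS,
    n_struct: int = DEFAULT_N_STRUCT,
    config: EncodingConfig | None = None,
) -> dict[str, CompressedVector]:
    """Encode one RNA into its three compressed channel vectors."""
    if config is None:
        config = EncodingConfig(n_struct=n_struct, n_terms=n_terms)
    seq = _apply_long_policy(seq, config)
    profiles = [
        encode_rna_structure(seq, folder, config.n_struct),
        encode_rna_propensity(seq, scales["rna_hbond"], "rna_hbond"),
        encode_rna_propensity(seq, scales["rna_vdw"], "rna_vdw"),
    ]
    return {p.tag: compress(p, config.n_terms) for p in profiles}


def encode_protein(
    seq: ProteinSequence,
    predictor: ProteinSsBackend,
    scales: Mapping[str, PropensityScale],
    chou_fasman: Mapping[str, PropensityScale],
    n_terms: int = DEFAULT_N_TERMS,
) -> dict[str, CompressedVector]:
    """Encode one protein into its five compressed channel vectors."""
    profiles = [encode_protein_structure(seq, predictor, chou_fasman)]
    for tag in ("prot_grantham", "prot_zimmerman", "prot_kd", "prot_bb"):
        profiles.append(encode_protein_propensity(seq, scales[tag], tag))
    return {p.tag: compress(p, n_terms) for p in profiles}


class PipelineEncoder:
    """The standard sequence -> compressed-channel encoder.

    Bundles the folding backend, the secondary-structure predictor, the
    propensity tables and the compression settings; caches encodings by
    sequence id, so repeated scoring of the same sequences is cheap.
    """

    kind = "pipeline"

    def __init__(
        self,
        folder: RnaFolderBackend | None = None,
        ss_predictor: ProteinSsBackend | None = None,
        rna_scales: Mapping[str, PropensityScale] | None = None,
        protein_scales: Mapping[str, PropensityScale] | None = None,
        chou_fasman: Mapping[str, PropensityScale] | None = None,
        config: EncodingConfig | None = None,
    ):
        self.folder = folder if folder is not None else NussinovFolder()
        self.ss_predictor = (
            ss_predictor if ss_predictor is not None else SlidingWindowPredictor()
        )
        self.rna_scales = dict(rna_scales) if rna_scales else default_rna_scales()
        self.protein_scales = (
            dict(protein_scales) if protein_scales else default_protein_scales()
        )
        self.chou_fasman = dict(chou_fasman) if chou_fasman else default_chou_fasman()
        self.config = config or EncodingConfig()
        self._rna_cache: dict[str, dict[str, CompressedVector]] = {}
        self._protein_cache: dict[str, dict[str, CompressedVector]] = {}

    @property
    def n_terms(self) -> int:
        return self.config.n_terms

    def encode_rna(self, seq: RnaSequence) -> dict[str, CompressedVector]:
        if seq.id not in self._rna_cache:
            self._rna_cache[seq.id] = encode_rna(
                seq, self.folder, self.rna_scales, config=self.config
            )
        return self._rna_cache[seq.id]

    def encode_protein(self, seq: ProteinSequence) -> dict[str, CompressedVector]:
        if seq.id not in self._protein_cache:
            self._protein_cache[seq.id] = encode_protein(
                seq,
                self.ss_predictor,
                self.protein_scales,
                self.chou_fasman,
                n_terms=self.config.n_terms,
            )
        return self._protein_cache[seq.id]

    def describe(self) -> dict:
        """Serializable snapshot of the encoder configuration."""
        return {
            "kind": self.kind,
            "n_struct": self.config.n_struct,
            "n_terms": self.config.n_terms,
            "max_rna_len": self.config.max_rna_len,
            "long_rna_policy": self.config.long_rna_policy,
            "folder": type(self.folder).__name__,
            "ss_predictor": type(self.ss_predictor).__name__,
            "rna_scales": {t: s.to_dict() for t, s in self.rna_scales.items()},
            "protein_scales": {t: s.to_dict() for t, s in self.protein_scales.items()},
            "chou_fasman": {t: s.to_dict() for t, s in self.chou_fasman.items()},
        }


class PrecomputedEncoder:
    """Encoder backed by precomputed compressed channel vectors.

    Used by the synthetic planted-rule datasets (where the channel vectors
    are the ground truth) and by workflows that cache encodings.
    """

    kind = "precomputed"

    def __init__(
        self,
        rna_features: Mapping[str, Mapping[str, np.ndarray]],
        protein_features: Mapping[str, Mapping[str, np.ndarray]],
        n_terms: int = DEFAULT_N_TERMS,
    ):
        self._rna = {
            sid: {t: _as_vector(t, v) for t, v in feats.items()}
            for sid, feats in rna_features.items()
        }
        self._protein = {
            sid: {t: _as_vector(t, v) for t, v in feats.items()}
            for sid, feats in protein_features.items()
        }
        self.n_terms = n_terms

    def encode_rna(self, seq: RnaSequence) -> dict[str, CompressedVector]:
        try:
            return self._rna[seq.id]
        except KeyError as exc:
            raise EncodingError(f"no precomputed features for RNA {seq.id!r}") from exc

    def encode_protein(self, seq: ProteinSequence) -> dict[str, CompressedVector]:
        try:
            return self._protein[seq.id]
        except KeyError as exc:
            raise EncodingError(
                f"no precomputed features for protein {seq.id!r}"
            ) from exc

    def describe(self) -> dict:
        return {"kind": self.kind, "n_terms": self.n_terms}


def _as_vector(tag: str, value) -> CompressedVector:
    if isinstance(value, CompressedVector):
        return value
    return CompressedVector(tag=tag, coefficients=np.asarray(value, dtype=float))


def write_features(
    encoder, sequences, path, kind: str
) -> None:
    """Write compressed channel vectors to a TSV (id, tag, c0..c{K-1})."""
    import csv

    rows = []
    n_terms = None
    for seq in sequences:
        feats = (
            encoder.encode_rna(seq) if kind == "rna" else encoder.encode_protein(seq)
        )
        for tag, vec in sorted(feats.items()):
            n_terms = len(vec)
            rows.append([seq.id, tag] + [repr(float(c)) for c in vec.coefficients])
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["seq_id", "tag"] + [f"c{i}" for i in range(n_terms or 0)])
        writer.writerows(rows)


def read_features(rna_path, protein_path) -> PrecomputedEncoder:
    """Rebuild a :class:`PrecomputedEncoder` from feature TSVs."""
    import csv

    def load(path):
        out: dict[str, dict[str, np.ndarray]] = {}
        with open(path, newline="") as fh:
            reader = csv.reader(fh, delimiter="\t")
            header = next(reader)
            if header[:2] != ["seq_id", "tag"]:
                raise ValidationError(f"{path} is not a feature table")
            for row in reader:
                sid, tag, *coeffs = row
                out.setdefault(sid, {})[tag] = np.array([float(c) for c in coeffs])
        return out

    rna = load(rna_path)
    protein = load(protein_path)
    any_feats = next(iter(rna.values()), None) or next(iter(protein.values()), {})
    n_terms = len(next(iter(any_feats.values()))) if any_feats else DEFAULT_N_TERMS
    return PrecomputedEncoder(rna, protein, n_terms=n_terms)
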