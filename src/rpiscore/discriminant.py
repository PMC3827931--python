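"""Bilinear pair scoring via per-channel Fisher linear discriminants.

For a protein channel vector p and an RNA channel vector r, the pair
feature is the flattened outer product x = (p1 r1, p1 r2, ..., p_d r_d).
A weight vector k (equivalently a d x d matrix M with k.x = p' M r) is
fitted per channel as the closed-form Fisher discriminant direction
(S_W + ridge I)^-1 (m1 - m2), oriented so the interactive class mean scores
higher. Raw scores are calibrated onto (0, 100) via

    Y = (100 / pi) * arctan(2 (X - c) / (c1 - c2)) + 50

with c1 = k.m1, c2 = k.m2, c = (c1 + c2) / 2, and the five calibrated
channel scores are fused by a (default arithmetic-mean) weighted average.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .encoding import PipelineEncoder, PrecomputedEncoder
from .encoding_types import CompressedVector
from .errors import (
    CalibrationError,
    DegenerateTrainingError,
    DomainError,
    ModelIOError,
    TrainingError,
    ValidationError,
)
from .scales import PropensityScale
from .seq_io import (
    INTERACTIVE,
    NON_INTERACTIVE,
    LabeledPair,
    ProteinSequence,
    RnaSequence,
)

MODEL_FORMAT = "rpiscore-model"
MODEL_VERSION = 1

#: the five (protein channel, RNA channel) pairings that are scored
CHANNEL_PAIRINGS: tuple[tuple[str, str], ...] = (
    ("prot_structure", "rna_structure"),
    ("prot_grantham", "rna_hbond"),
    ("prot_zimmerman", "rna_hbond"),
    ("prot_kd", "rna_vdw"),
    ("prot_bb", "rna_vdw"),
)

DEFAULT_RIDGE = 1e-6
DEFAULT_THRESHOLD = 50.0
#: alternative fusion weighting grouping the two hydrogen-bond channels and
#: the two van der Waals channels (rejected in favor of the plain mean)
GROUPED_FUSION_WEIGHTS = (1 / 3, 1 / 6, 1 / 6, 1 / 6, 1 / 6)


def pairing_tag(protein_tag: str, rna_tag: str) -> str:
    return f"{protein_tag}*{rna_tag}"


def pair_feature(p: CompressedVector | np.ndarray, r: CompressedVector | np.ndarray) -> np.ndarray:
    """Flattened outer product in (p1 r1, p1 r2, ..., p_d r_d) order."""
    pv = p.coefficients if isinstance(p, CompressedVector) else np.asarray(p, float)
    rv = r.coefficients if isinstance(r, CompressedVector) else np.asarray(r, float)
    if pv.ndim != 1 or rv.ndim != 1:
        raise DomainError("channel vectors must be one-dimensional")
    if pv.shape[0] != rv.shape[0]:
        raise DomainError(
            f"channel dimension mismatch: {pv.shape[0]} vs {rv.shape[0]}"
        )
    return np.outer(pv, rv).ravel()


@dataclass
class FisherDiagnostics:
    j: float
    s1_sq: float
    s2_sq: float
    n_pos: int
    n_neg: int


def fisher_direction(
    positives: Sequence[np.ndarray] | np.ndarray,
    negatives: Sequence[np.ndarray] | np.ndarray,
    ridge: float = DEFAULT_RIDGE,
) -> tuple[np.ndarray, FisherDiagnostics]:
    """Closed-form Fisher discriminant direction.

    Solves (S_W + lambda I) k = m1 - m2 where S_W is the pooled within-class
    scatter (sum of squared deviations, not the covariance) and
    lambda = ridge * trace(S_W) / dim, falling back to a pseudo-inverse if
    the regularized system is still singular. k is oriented so that
    k.m1 > k.m2.
    """
    pos = np.atleast_2d(np.asarray(positives, dtype=float))
    neg = np.atleast_2d(np.asarray(negatives, dtype=float))
    if pos.size == 0 or neg.size == 0:
        raise DomainError("both classes must be nonempty")
    if pos.shape[1] != neg.shape[1]:
        raise DomainError("class feature dimensions differ")
    dim = pos.shape[1]
    m1 = pos.mean(axis=0)
    m2 = neg.mean(axis=0)
    diff = m1 - m2
    scale = max(np.linalg.norm(m1), np.linalg.norm(m2), 1.0)
    if np.linalg.norm(diff) <= 1e-12 * scale:
        raise DegenerateTrainingError("class means are identical; J is undefined")
    dev1 = pos - m1
    dev2 = neg - m2
    s_w = dev1.T @ dev1 + dev2.T @ dev2
    lam = ridge * (np.trace(s_w) / dim) if np.trace(s_w) > 0 else ridge
    try:
        k = np.linalg.solve(s_w + lam * np.eye(dim), diff)
    except np.linalg.LinAlgError:
        k = np.linalg.pinv(s_w + lam * np.eye(dim)) @ diff
    if k @ m1 < k @ m2:
        k = -k
    proj_pos = pos @ k
    proj_neg = neg @ k
    s1_sq = float(np.sum((proj_pos - proj_pos.mean()) ** 2))
    s2_sq = float(np.sum((proj_neg - proj_neg.mean()) ** 2))
    sep = float(proj_pos.mean() - proj_neg.mean()) ** 2
    denom = s1_sq + s2_sq
    j = sep / denom if denom > 0 else math.inf
    return k, FisherDiagnostics(
        j=j, s1_sq=s1_sq, s2_sq=s2_sq, n_pos=pos.shape[0], n_neg=neg.shape[0]
    )


@dataclass
class ChannelModel:
    """Trained weights and calibration constants for one channel pairing."""

    protein_tag: str
    rna_tag: str
    k: np.ndarray
    m1: np.ndarray
    m2: np.ndarray
    c1: float
    c2: float
    j: float = math.nan
    s1_sq: float = math.nan
    s2_sq: float = math.nan
    n_pos: int = 0
    n_neg: int = 0

    def __post_init__(self) -> None:
        self.k = np.asarray(self.k, dtype=float)
        self.m1 = np.asarray(self.m1, dtype=float)
        self.m2 = np.asarray(self.m2, dtype=float)
        if not self.c1 > self.c2:
            raise ValidationError(
                f"channel {self.tag}: c1 must exceed c2 (got {self.c1} <= {self.c2})"
            )

    @property
    def tag(self) -> str:
        return pairing_tag(self.protein_tag, self.rna_tag)

    @property
    def c(self) -> float:
        return (self.c1 + self.c2) / 2.0

    @property
    def matrix(self) -> np.ndarray:
        """k reshaped row-major to the bilinear-form matrix M (p' M r = k.x)."""
        d = int(round(math.sqrt(self.k.shape[0])))
        return self.k.reshape(d, d)

    @classmethod
    def fit(
        cls,
        protein_tag: str,
        rna_tag: str,
        positives: Sequence[np.ndarray],
        negatives: Sequence[np.ndarray],
        ridge: float = DEFAULT_RIDGE,
    ) -> "ChannelModel":
        k, diag = fisher_direction(positives, negatives, ridge=ridge)
        m1 = np.mean(np.asarray(positives, float), axis=0)
        m2 = np.mean(np.asarray(negatives, float), axis=0)
        return cls(
            protein_tag=protein_tag,
            rna_tag=rna_tag,
            k=k,
            m1=m1,
            m2=m2,
            c1=float(k @ m1),
            c2=float(k @ m2),
            j=diag.j,
            s1_sq=diag.s1_sq,
            s2_sq=diag.s2_sq,
            n_pos=diag.n_pos,
            n_neg=diag.n_neg,
        )


def raw_score(channel: ChannelModel, x: np.ndarray) -> float:
    """k.x, identical to p' M r for M = reshape(k)."""
    x = np.asarray(x, dtype=float)
    if x.shape != channel.k.shape:
        raise DomainError(
            f"feature dimension {x.shape} does not match weights {channel.k.shape}"
        )
    return float(channel.k @ x)


def transform_score(channel: ChannelModel, x_raw: float) -> float:
    """Calibrate a raw score onto the open interval (0, 100)."""
    if channel.c1 == channel.c2:
        raise CalibrationError(f"channel {channel.tag}: c1 == c2")
    return (100.0 / math.pi) * math.atan(
        2.0 * (x_raw - channel.c) / (channel.c1 - channel.c2)
    ) + 50.0


@dataclass
class ScoreReport:
    """Scores for a single (RNA, protein) pair."""

    rna_id: str
    protein_id: str
    raw: dict[str, float]
    calibrated: dict[str, float]
    final: float
    predicted: str

    @property
    def is_interactive(self) -> bool:
        return self.predicted == INTERACTIVE


class InteractionModel:
    """Five trained channel models plus fusion weights and a config snapshot."""

    def __init__(
        self,
        channels: Sequence[ChannelModel],
        fusion_weights: Sequence[float] | None = None,
        threshold: float = DEFAULT_THRESHOLD,
        encoder_config: Mapping | None = None,
        ridge: float = DEFAULT_RIDGE,
    ):
        channels = list(channels)
        expected = [pairing_tag(pt, rt) for pt, rt in CHANNEL_PAIRINGS]
        got = [ch.tag for ch in channels]
        if got != expected:
            raise ValidationError(
                f"model must contain exactly the channels {expected}, got {got}"
            )
        if fusion_weights is None:
            fusion_weights = [1.0 / len(channels)] * len(channels)
        weights = np.asarray(list(fusion_weights), dtype=float)
        if weights.shape[0] != len(channels):
            raise ValidationError("one fusion weight per channel is required")
        if np.any(weights < 0) or not math.isclose(weights.sum(), 1.0, rel_tol=1e-9):
            raise ValidationError("fusion weights must be nonnegative and sum to 1")
        self.channels = channels
        self.fusion_weights = weights
        self.threshold = float(threshold)
        self.encoder_config = dict(encoder_config) if encoder_config else {}
        self.ridge = float(ridge)

    def channel(self, protein_tag: str, rna_tag: str) -> ChannelModel:
        tag = pairing_tag(protein_tag, rna_tag)
        for ch in self.channels:
            if ch.tag == tag:
                return ch
        raise KeyError(tag)

    def score_features(
        self,
        rna_id: str,
        protein_id: str,
        rna_feats: Mapping[str, CompressedVector],
        prot_feats: Mapping[str, CompressedVector],
    ) -> ScoreReport:
        raw: dict[str, float] = {}
        calibrated: dict[str, float] = {}
        for ch in self.channels:
            x = pair_feature(prot_feats[ch.protein_tag], rna_feats[ch.rna_tag])
            raw[ch.tag] = raw_score(ch, x)
            calibrated[ch.tag] = transform_score(ch, raw[ch.tag])
        final = float(
            np.dot(self.fusion_weights, [calibrated[ch.tag] for ch in self.channels])
        )
        predicted = INTERACTIVE if final > self.threshold else NON_INTERACTIVE
        return ScoreReport(
            rna_id=rna_id,
            protein_id=protein_id,
            raw=raw,
            calibrated=calibrated,
            final=final,
            predicted=predicted,
        )

    def build_encoder(self) -> PipelineEncoder:
        """Reconstruct the standard encoder from the stored config snapshot."""
        cfg = self.encoder_config
        if cfg.get("kind") != "pipeline":
            raise ModelIOError(
                "model was trained with a non-standard encoder; pass one explicitly"
            )
        from .encoding import EncodingConfig

        return PipelineEncoder(
            rna_scales={
                t: PropensityScale.from_dict(d) for t, d in cfg["rna_scales"].items()
            },
            protein_scales={
                t: PropensityScale.from_dict(d)
                for t, d in cfg["protein_scales"].items()
            },
            chou_fasman={
                t: PropensityScale.from_dict(d) for t, d in cfg["chou_fasman"].items()
            },
            config=EncodingConfig(
                n_struct=cfg["n_struct"],
                n_terms=cfg["n_terms"],
                max_rna_len=cfg["max_rna_len"],
                long_rna_policy=cfg["long_rna_policy"],
            ),
        )


def _encode_pairs(
    pairs: Sequence[LabeledPair],
    rnas: Mapping[str, RnaSequence],
    proteins: Mapping[str, ProteinSequence],
    encoder,
) -> list[tuple[LabeledPair, dict, dict]]:
    encoded = []
    for pair in pairs:
        if pair.rna_id not in rnas:
            raise ValidationError(f"pair references unknown RNA {pair.rna_id!r}")
        if pair.protein_id not in proteins:
            raise ValidationError(
                f"pair references unknown protein {pair.protein_id!r}"
            )
        encoded.append(
            (
                pair,
                encoder.encode_rna(rnas[pair.rna_id]),
                encoder.encode_protein(proteins[pair.protein_id]),
            )
        )
    return encoded


def train(
    pairs: Sequence[LabeledPair],
    rnas: Mapping[str, RnaSequence],
    proteins: Mapping[str, ProteinSequence],
    encoder,
    ridge: float = DEFAULT_RIDGE,
    fusion_weights: Sequence[float] | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> InteractionModel:
    """Fit the five channel discriminants from a labeled pair set."""
    n_pos = sum(1 for p in pairs if p.is_interactive)
    n_neg = len(pairs) - n_pos
    if n_pos < 2 or n_neg < 2:
        raise TrainingError(
            f"need >= 2 pairs per class, got {n_pos} interactive / {n_neg} non-interactive"
        )
    encoded = _encode_pairs(pairs, rnas, proteins, encoder)
    channels = []
    for protein_tag, rna_tag in CHANNEL_PAIRINGS:
        pos_x, neg_x = [], []
        for pair, rna_feats, prot_feats in encoded:
            x = pair_feature(prot_feats[protein_tag], rna_feats[rna_tag])
            (pos_x if pair.is_interactive else neg_x).append(x)
        try:
            channels.append(
                ChannelModel.fit(protein_tag, rna_tag, pos_x, neg_x, ridge=ridge)
            )
        except DegenerateTrainingError as exc:
            raise TrainingError(
                f"channel {pairing_tag(protein_tag, rna_tag)} is degenerate: {exc}"
            ) from exc
    return InteractionModel(
        channels,
        fusion_weights=fusion_weights,
        threshold=threshold,
        encoder_config=encoder.describe(),
        ridge=ridge,
    )


def score_pair(
    model: InteractionModel,
    rna: RnaSequence,
    protein: ProteinSequence,
    encoder=None,
) -> ScoreReport:
    """Score one (RNA, protein) pair with a trained model."""
    if encoder is None:
        encoder = model.build_encoder()
    return model.score_features(
        rna.id, protein.id, encoder.encode_rna(rna), encoder.encode_protein(protein)
    )


def score_pairs(
    model: InteractionModel,
    pairs: Iterable[tuple[RnaSequence, ProteinSequence]],
    encoder=None,
) -> list[ScoreReport]:
    if encoder is None:
        encoder = model.build_encoder()
    return [score_pair(model, rna, protein, encoder) for rna, protein in pairs]


# -- persistence -----------------------------------------------------------


def save_model(model: InteractionModel, path: str | Path) -> None:
    """Serialize to a self-describing JSON archive (bit-exact round-trip)."""
    payload = {
        "format": MODEL_FORMAT,
        "version": MODEL_VERSION,
        "threshold": model.threshold,
        "ridge": model.ridge,
        "fusion_weights": model.fusion_weights.tolist(),
        "encoder_config": model.encoder_config,
        "channels": [
            {
                "protein_tag": ch.protein_tag,
                "rna_tag": ch.rna_tag,
                "k": ch.k.tolist(),
                "m1": ch.m1.tolist(),
                "m2": ch.m2.tolist(),
                "c1": ch.c1,
                "c2": ch.c2,
                "j": ch.j,
                "s1_sq": ch.s1_sq,
                "s2_sq": ch.s2_sq,
                "n_pos": ch.n_pos,
                "n_neg": ch.n_neg,
            }
            for ch in model.channels
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path: str | Path) -> InteractionModel:
    path = Path(path)
    if not path.exists():
        raise ModelIOError(f"model file {path} does not exist")
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ModelIOError(f"model file {path} is corrupted: {exc}") from exc
    if payload.get("format") != MODEL_FORMAT:
        raise ModelIOError(f"{path} is not a model archive")
    if payload.get("version") != MODEL_VERSION:
        raise ModelIOError(
            f"unsupported model version {payload.get('version')!r} in {path}"
        )
    channels = [
        ChannelModel(
            protein_tag=ch["protein_tag"],
            rna_tag=ch["rna_tag"],
            k=np.array(ch["k"]),
            m1=np.array(ch["m1"]),
            m2=np.array(ch["m2"]),
            c1=ch["c1"],
            c2=ch["c2"],
            j=ch["j"],
            s1_sq=ch["s1_sq"],
            s2_sq=ch["s2_sq"],
            n_pos=ch["n_pos"],
            n_neg=ch["n_neg"],
        )
        for ch in payload["channels"]
    ]
    return InteractionModel(
        channels,
        fusion_weights=payload["fusion_weights"],
        threshold=payload["threshold"],
        encoder_config=payload["encoder_config"],
        ridge=payload["ridge"],
    )
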