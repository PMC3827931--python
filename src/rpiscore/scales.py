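"""Per-residue propensity scales and their tabular on-disk format.

A scale is a named mapping from residue letter to a real value. Scales ship
as editable TSV files under ``rpiscore/data`` so a trained model can embed
the exact tables it was built with. Ambiguity letters are resolved here:
N (RNA) averages over {A,C,G,U}; B averages {D,N}; Z averages {E,Q};
X and U (protein) average over the 20 standard residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

from .errors import EncodingError
from .seq_io import PROTEIN_STANDARD

RNA_STANDARD = "ACGU"

# residue -> set of compatible residues, per alphabet
_RNA_AMBIGUITY = {"N": RNA_STANDARD}
_PROTEIN_AMBIGUITY = {
    "B": "DN",
    "Z": "EQ",
    "X": PROTEIN_STANDARD,
    "U": PROTEIN_STANDARD,
}


@dataclass(frozen=True, eq=False)
class PropensityScale:
    """A named residue -> value mapping with provenance."""

    name: str
    source: str
    mapping: Mapping[str, float]
    alphabet: str = "protein"  # "rna" or "protein"

    def __post_init__(self) -> None:
        if not self.mapping:
            raise EncodingError(f"scale {self.name!r} has an empty mapping")

    def value(self, residue: str) -> float:
        """Look a residue up, resolving ambiguity letters by averaging."""
        try:
            return float(self.mapping[residue])
        except KeyError:
            pass
        ambiguity = _RNA_AMBIGUITY if self.alphabet == "rna" else _PROTEIN_AMBIGUITY
        members = ambiguity.get(residue)
        if members is None:
            raise EncodingError(
                f"residue {residue!r} is not covered by scale {self.name!r}"
            )
        values = [self.mapping[m] for m in members if m in self.mapping]
        if not values:
            raise EncodingError(
                f"ambiguous residue {residue!r} has no compatible residues "
                f"in scale {self.name!r}"
            )
        return float(sum(values)) / len(values)

    def encode(self, residues: str) -> list[float]:
        return [self.value(r) for r in residues]

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "source": self.source,
            "alphabet": self.alphabet,
            "mapping": dict(self.mapping),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "PropensityScale":
        return cls(
            name=payload["name"],
            source=payload["source"],
            mapping={k: float(v) for k, v in payload["mapping"].items()},
            alphabet=payload["alphabet"],
        )


def load_scale(path: str | Path) -> PropensityScale:
    """Load a scale from its TSV representation.

    Format: ``# name:``, ``# source:`` and ``# alphabet:`` comment headers
    followed by tab-separated ``residue<TAB>value`` lines.
    """
    name, source, alphabet = Path(path).stem, "", "protein"
    mapping: dict[str, float] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            for key in ("name", "source", "alphabet"):
                prefix = key + ":"
                if body.lower().startswith(prefix):
                    value = body[len(prefix):].strip()
                    if key == "name":
                        name = value
                    elif key == "source":
                        source = value
                    else:
                        alphabet = value
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise EncodingError(f"malformed scale line in {path}: {raw!r}")
        mapping[fields[0].strip().upper()] = float(fields[1])
    return PropensityScale(name=name, source=source, mapping=mapping, alphabet=alphabet)


def write_scale(scale: PropensityScale, path: str | Path) -> None:
    lines = [
        f"# name: {scale.name}",
        f"# source: {scale.source}",
        f"# alphabet: {scale.alphabet}",
    ]
    lines += [f"{res}\t{val!r}" for res, val in scale.mapping.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def builtin_scale(name: str) -> PropensityScale:
    """Load one of the scales bundled with the package by file stem."""
    ref = resources.files("rpiscore.data").joinpath(f"{name}.tsv")
    with resources.as_file(ref) as path:
        return load_scale(path)


# Channel tags used throughout the pipeline.
RNA_TAGS = ("rna_structure", "rna_hbond", "rna_vdw")
PROTEIN_TAGS = ("prot_structure", "prot_grantham", "prot_zimmerman", "prot_kd", "prot_bb")

#: builtin scale file stems for the propensity-backed channels
BUILTIN_RNA_SCALES = {"rna_hbond": "rna_hbond", "rna_vdw": "rna_vdw"}
BUILTIN_PROTEIN_SCALES = {
    "prot_grantham": "grantham",
    "prot_zimmerman": "zimmerman",
    "prot_kd": "kyte_doolittle",
    "prot_bb": "bull_breese",
}
BUILTIN_CHOU_FASMAN = {
    "H": "chou_fasman_helix",
    "E": "chou_fasman_sheet",
    "C": "chou_fasman_turn",
}


def default_rna_scales() -> dict[str, PropensityScale]:
    return {tag: builtin_scale(stem) for tag, stem in BUILTIN_RNA_SCALES.items()}


def default_protein_scales() -> dict[str, PropensityScale]:
    return {tag: builtin_scale(stem) for tag, stem in BUILTIN_PROTEIN_SCALES.items()}


def default_chou_fasman() -> dict[str, PropensityScale]:
    return {state: builtin_scale(stem) for state, stem in BUILTIN_CHOU_FASMAN.items()}
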