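import numpy as np
import pytest

from rpiscore.scales import PropensityScale
from rpiscore.seq_io import INTERACTIVE, NON_INTERACTIVE, LabeledPair
from rpiscore.synthetic import ToyChainSpec, toy_complex


@pytest.fixture
def toy_rna_scale():
    return PropensityScale(
        name="toy_rna", source="test", mapping={"A": 1, "C": 2, "G": 3, "U": 4},
        alphabet="rna",
    )


@pytest.fixture
def toy_protein_scale():
    # covers the 20 standard residues with distinct values
    mapping = {aa: float(i + 1) for i, aa in enumerate("ACDEFGHIKLMNPQRSTVWY")}
    return PropensityScale(
        name="toy_prot", source="test", mapping=mapping, alphabet="protein"
    )


class AllStatePredictor:
    """Protein SS backend returning one fixed state for every residue."""

    def __init__(self, state="H"):
        self.state = state

    def predict(self, seq):
        return self.state * len(seq)


class FixedStringPredictor:
    """Protein SS backend returning a caller-supplied string verbatim."""

    def __init__(self, states):
        self.states = states

    def predict(self, seq):
        return self.states


@pytest.fixture
def all_h_predictor():
    return AllStatePredictor("H")


def make_dedup_fixture_complex():
    """An 18-chain complex (1 RNA + 17 proteins, two of which share a
    sequence) with hand-known geometry.

    The RNA spans x in [0, 119] (length 120 > 100). Every protein chain is
    placed to the right at a chosen gap, so its least atom distance to the
    RNA is exactly that gap. Chains Q and R are sequence-identical (the
    duplicated pair); Q sits interactive (gap 3), R non-interactive
    (gap 9), exercising the any-copy labeling rule.
    """
    from rpiscore.synthetic import random_sequences

    rna_seq = ("ACGU" * 30)  # length 120
    gaps = {
        "A": 3.0, "B": 4.9, "C": 5.0, "D": 5.1, "E": 7.0, "F": 2.0,
        "G": 10.0, "H": 4.0, "I": 6.0, "J": 8.0, "K": 1.0, "L": 4.5,
        "M": 5.5, "N": 12.0, "O": 0.5,
    }
    # mutually dissimilar random proteins so only the planted duplicate is
    # ever collapsed or flagged as redundant
    randoms = random_sequences(16, (20, 20), "protein", seed=123)
    protein_seqs = {cid: randoms[i].residues for i, cid in enumerate(sorted(gaps))}
    chains = [ToyChainSpec("Z", "rna", rna_seq, start_x=0.0)]
    for cid in sorted(gaps):
        chains.append(
            ToyChainSpec(cid, "protein", protein_seqs[cid], start_x=119.0 + gaps[cid])
        )
    dup_seq = randoms[15].residues
    chains.append(ToyChainSpec("Q", "protein", dup_seq, start_x=119.0 + 3.0))
    chains.append(ToyChainSpec("R", "protein", dup_seq, start_x=119.0 + 9.0))
    expected_labels = {
        cid: (INTERACTIVE if gap < 5.0 else NON_INTERACTIVE)
        for cid, gap in gaps.items()
    }
    expected_labels["Q"] = INTERACTIVE  # any-copy rule: Q at 3.0 wins over R at 9.0
    return toy_complex("dedup18", chains), expected_labels


@pytest.fixture
def dedup_fixture():
    return make_dedup_fixture_complex()
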