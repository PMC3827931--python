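import math

import numpy as np
import pytest

from rpiscore.discriminant import (
    CHANNEL_PAIRINGS,
    ChannelModel,
    GROUPED_FUSION_WEIGHTS,
    InteractionModel,
    fisher_direction,
    load_model,
    pair_feature,
    pairing_tag,
    raw_score,
    save_model,
    score_pair,
    train,
    transform_score,
)
from rpiscore.errors import (
    CalibrationError,
    DegenerateTrainingError,
    DomainError,
    ModelIOError,
    TrainingError,
    ValidationError,
)
from rpiscore.seq_io import INTERACTIVE, NON_INTERACTIVE, LabeledPair
from rpiscore.synthetic import PlantedDatasetSpec, planted_pair_dataset


class TestPairFeature:
    def test_outer_product_order(self):
        x = pair_feature(np.array([1.0, 2.0]), np.array([3.0, 4.0]))
        assert x.tolist() == [3.0, 4.0, 6.0, 8.0]

    def test_zero_vector(self):
        assert np.array_equal(
            pair_feature(np.zeros(3), np.ones(3)), np.zeros(9)
        )

    def test_bilinearity(self):
        rng = np.random.default_rng(0)
        p, r = rng.normal(size=4), rng.normal(size=4)
        assert np.allclose(pair_feature(2 * p, r), 2 * pair_feature(p, r))
        assert np.allclose(pair_feature(p, 3 * r), 3 * pair_feature(p, r))

    def test_dimension_mismatch(self):
        with pytest.raises(DomainError):
            pair_feature(np.zeros(3), np.zeros(4))


class TestFisherDirection:
    def test_2d_toy_closed_form(self):
        # S_W = 0.5 I, m1 - m2 = (1.5, -1.5) -> direction proportional to (1, -1)
        positives = [np.array([1.0, 0.0]), np.array([2.0, 0.0])]
        negatives = [np.array([0.0, 1.0]), np.array([0.0, 2.0])]
        k, diag = fisher_direction(positives, negatives)
        assert k[0] > 0 > k[1]
        assert k[0] == pytest.approx(-k[1], rel=1e-9)
        assert diag.n_pos == diag.n_neg == 2

    def test_identical_classes_degenerate(self):
        pts = [np.array([1.0, 2.0]), np.array([3.0, 4.0])]
        with pytest.raises(DegenerateTrainingError):
            fisher_direction(pts, pts)

    def test_empty_class_rejected(self):
        with pytest.raises(DomainError):
            fisher_direction(np.empty((0, 2)), [np.array([1.0, 2.0])])

    def test_orientation(self):
        positives = [np.array([-2.0, 0.0]), np.array([-3.0, 0.0])]
        negatives = [np.array([2.0, 0.1]), np.array([3.0, -0.1])]
        k, _ = fisher_direction(positives, negatives)
        m1 = np.mean(positives, axis=0)
        m2 = np.mean(negatives, axis=0)
        assert k @ m1 > k @ m2

    def test_optimality_against_random_directions(self):
        rng = np.random.default_rng(7)
        positives = rng.normal(loc=[1, 0.5, 0], scale=[1, 2, 0.5], size=(40, 3))
        negatives = rng.normal(loc=[-1, 0, 0.2], scale=[1, 2, 0.5], size=(40, 3))

        def j_value(direction):
            pp, nn = positives @ direction, negatives @ direction
            sep = (pp.mean() - nn.mean()) ** 2
            scatter = ((pp - pp.mean()) ** 2).sum() + ((nn - nn.mean()) ** 2).sum()
            return sep / scatter

        k, diag = fisher_direction(positives, negatives)
        j_best = j_value(k)
        assert diag.j == pytest.approx(j_best, rel=1e-12)
        for _ in range(1000):
            u = rng.normal(size=3)
            assert j_best >= j_value(u / np.linalg.norm(u)) - 1e-12

    def test_closed_form_agreement(self):
        # independent closed-form evaluation on nonsingular data
        rng = np.random.default_rng(3)
        positives = rng.normal(loc=1.0, size=(30, 4))
        negatives = rng.normal(loc=-1.0, size=(30, 4))
        m1, m2 = positives.mean(axis=0), negatives.mean(axis=0)
        dev1, dev2 = positives - m1, negatives - m2
        s_w = dev1.T @ dev1 + dev2.T @ dev2
        expected = np.linalg.solve(s_w, m1 - m2)
        k, _ = fisher_direction(positives, negatives, ridge=0.0)
        assert np.allclose(k, expected, rtol=1e-9)


def make_channel(k, m1, m2, protein_tag="prot_kd", rna_tag="rna_vdw"):
    k = np.asarray(k, float)
    m1, m2 = np.asarray(m1, float), np.asarray(m2, float)
    return ChannelModel(
        protein_tag=protein_tag, rna_tag=rna_tag, k=k, m1=m1, m2=m2,
        c1=float(k @ m1), c2=float(k @ m2),
    )


class TestRawScore:
    def test_identity_matrix_inner_product(self):
        channel = make_channel([1.0, 0.0, 0.0, 1.0], [10, 0, 0, 10], [0, 0, 0, 0])
        x = pair_feature(np.array([1.0, 2.0]), np.array([3.0, 4.0]))
        assert raw_score(channel, x) == pytest.approx(11.0)

    def test_zero_feature(self):
        channel = make_channel([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1], [0, 0, 0, 0])
        assert raw_score(channel, np.zeros(4)) == 0.0

    def test_mismatch(self):
        channel = make_channel([1.0, 0.0, 0.0, 1.0], [1, 0, 0, 1], [0, 0, 0, 0])
        with pytest.raises(DomainError):
            raw_score(channel, np.zeros(9))

    @pytest.mark.parametrize("seed", range(5))
    def test_reshape_identity_oracle(self, seed):
        # k.x must equal p' M r with M = reshape(k) row-major
        rng = np.random.default_rng(seed)
        d = 10
        k = rng.normal(size=d * d)
        p, r = rng.normal(size=d), rng.normal(size=d)
        m1 = np.zeros(d * d)
        m1[np.argmax(k)] = 1.0  # ensure c1 > c2 = 0
        if k @ m1 <= 0:
            k = -k
        channel = make_channel(k, m1, np.zeros(d * d))
        lhs = raw_score(channel, pair_feature(p, r))
        rhs = p @ channel.matrix @ r
        assert lhs == pytest.approx(rhs, rel=1e-12, abs=1e-12)


class TestTransformScore:
    def setup_method(self):
        self.channel = make_channel(
            [1.0, 0.0], [10.0, 0.0], [-10.0, 0.0]
        )  # c1=10, c2=-10, c=0

    def test_midpoint_maps_to_50(self):
        assert transform_score(self.channel, self.channel.c) == pytest.approx(50.0)

    def test_c1_maps_to_75(self):
        assert transform_score(self.channel, self.channel.c1) == pytest.approx(75.0)

    def test_c2_maps_to_25(self):
        assert transform_score(self.channel, self.channel.c2) == pytest.approx(25.0)

    def test_monotone_and_bounded(self):
        xs = np.linspace(-1e6, 1e6, 201)
        ys = [transform_score(self.channel, x) for x in xs]
        assert all(0 < y < 100 for y in ys)
        assert all(b > a for a, b in zip(ys, ys[1:]))

    def test_equal_calibration_constants_rejected(self):
        self.channel.c1 = self.channel.c2 = 1.0  # corrupt in place
        with pytest.raises(CalibrationError):
            transform_score(self.channel, 0.0)

    def test_constructor_requires_c1_above_c2(self):
        with pytest.raises(ValidationError):
            make_channel([1.0, 0.0], [-1.0, 0.0], [1.0, 0.0])

    def test_scale_invariance_of_calibration(self):
        # multiplying k (and therefore c1, c2, c) by a positive constant
        # leaves every calibrated score unchanged
        rng = np.random.default_rng(1)
        k = rng.normal(size=4)
        m1, m2 = rng.normal(size=4) + 2, rng.normal(size=4) - 2
        if k @ m1 < k @ m2:
            k = -k
        base = make_channel(k, m1, m2)
        scaled = make_channel(5.0 * k, m1, m2)
        for x in rng.normal(size=20):
            x_vec = rng.normal(size=4)
            assert transform_score(base, raw_score(base, x_vec)) == pytest.approx(
                transform_score(scaled, raw_score(scaled, x_vec)), rel=1e-12
            )


@pytest.fixture(scope="module")
def planted():
    return planted_pair_dataset(PlantedDatasetSpec(n_pairs=60, seed=11))


@pytest.fixture(scope="module")
def trained(planted):
    ds = planted
    return train(ds.pairs, ds.rnas, ds.proteins, ds.encoder)


class TestTrain:
    def test_exactly_five_channels(self, trained):
        assert len(trained.channels) == 5
        assert [ch.tag for ch in trained.channels] == [
            pairing_tag(pt, rt) for pt, rt in CHANNEL_PAIRINGS
        ]

    def test_c1_above_c2_per_channel(self, trained):
        for ch in trained.channels:
            assert ch.c1 > ch.c2
            assert ch.c == (ch.c1 + ch.c2) / 2

    def test_deterministic(self, planted):
        ds = planted
        m1 = train(ds.pairs, ds.rnas, ds.proteins, ds.encoder)
        m2 = train(ds.pairs, ds.rnas, ds.proteins, ds.encoder)
        for a, b in zip(m1.channels, m2.channels):
            assert np.array_equal(a.k, b.k)
            assert a.c1 == b.c1 and a.c2 == b.c2

    def test_too_few_pairs_per_class(self, planted):
        ds = planted
        positives = [p for p in ds.pairs if p.is_interactive]
        with pytest.raises(TrainingError):
            train(positives + ds.pairs[-1:], ds.rnas, ds.proteins, ds.encoder)

    def test_unknown_sequence_rejected(self, planted):
        ds = planted
        bad = ds.pairs + [LabeledPair("ghost", ds.pairs[0].protein_id, INTERACTIVE)]
        with pytest.raises(ValidationError):
            train(bad, ds.rnas, ds.proteins, ds.encoder)


class TestScorePair:
    def test_final_is_mean_of_calibrated(self, planted, trained):
        ds = planted
        pair = ds.pairs[0]
        report = score_pair(
            trained, ds.rnas[pair.rna_id], ds.proteins[pair.protein_id], ds.encoder
        )
        assert report.final == pytest.approx(
            np.mean(list(report.calibrated.values()))
        )
        assert all(0 < y < 100 for y in report.calibrated.values())
        assert 0 < report.final < 100

    def test_threshold_is_strict(self, trained):
        # a final score of exactly 50 is non-interactive
        feats = {tag: np.zeros(10) for tag in ("rna_structure", "rna_hbond", "rna_vdw")}
        pfeats = {
            tag: np.zeros(10)
            for tag in ("prot_structure", "prot_grantham", "prot_zimmerman",
                        "prot_kd", "prot_bb")
        }
        # zero features give raw score 0 on every channel; calibrated scores
        # are channel-dependent, so check the rule directly instead
        report = trained.score_features("r", "p", feats, pfeats)
        assert report.predicted == (
            INTERACTIVE if report.final > 50 else NON_INTERACTIVE
        )

    def test_grouped_fusion_weights(self, planted):
        ds = planted
        model = train(
            ds.pairs, ds.rnas, ds.proteins, ds.encoder,
            fusion_weights=GROUPED_FUSION_WEIGHTS,
        )
        pair = ds.pairs[0]
        report = score_pair(
            model, ds.rnas[pair.rna_id], ds.proteins[pair.protein_id], ds.encoder
        )
        weights = np.array(GROUPED_FUSION_WEIGHTS)
        ys = np.array([report.calibrated[ch.tag] for ch in model.channels])
        assert report.final == pytest.approx(float(weights @ ys))

    def test_invalid_fusion_weights(self, planted):
        ds = planted
        with pytest.raises(ValidationError):
            train(ds.pairs, ds.rnas, ds.proteins, ds.encoder,
                  fusion_weights=[0.5, 0.5, 0.5, -0.25, -0.25])


class TestPersistence:
    def test_roundtrip_scores_identical(self, planted, trained, tmp_path):
        ds = planted
        path = tmp_path / "model.json"
        save_model(trained, path)
        loaded = load_model(path)
        for pair in ds.pairs[:5]:
            a = score_pair(trained, ds.rnas[pair.rna_id],
                           ds.proteins[pair.protein_id], ds.encoder)
            b = score_pair(loaded, ds.rnas[pair.rna_id],
                           ds.proteins[pair.protein_id], ds.encoder)
            assert a.final == b.final
            assert a.raw == b.raw

    def test_roundtrip_bit_exact_weights(self, trained, tmp_path):
        path = tmp_path / "model.json"
        save_model(trained, path)
        loaded = load_model(path)
        for a, b in zip(trained.channels, loaded.channels):
            assert np.array_equal(a.k, b.k)
            assert np.array_equal(a.m1, b.m1)
            assert (a.c1, a.c2, a.j) == (b.c1, b.c2, b.j)

    def test_missing_file(self, tmp_path):
        with pytest.raises(ModelIOError):
            load_model(tmp_path / "nope.json")

    def test_corrupted_file(self, tmp_path):
        path = tmp_path / "model.json"
        path.write_text("{not json")
        with pytest.raises(ModelIOError):
            load_model(path)

    def test_wrong_format(self, tmp_path):
        path = tmp_path / "model.json"
        path.write_text('{"format": "something-else"}')
        with pytest.raises(ModelIOError):
            load_model(path)

    def test_pipeline_config_snapshot_self_contained(self, tmp_path):
        # a model trained with the standard encoder embeds its scale tables
        # and can rebuild an equivalent encoder after loading
        from rpiscore.encoding import PipelineEncoder
        from rpiscore.synthetic import random_sequences

        rnas = random_sequences(6, (15, 25), "rna", 5)
        prots = random_sequences(6, (10, 20), "protein", 6)
        pairs = [
            LabeledPair(r.id, p.id, INTERACTIVE if i % 2 else NON_INTERACTIVE)
            for i, (r, p) in enumerate(zip(rnas, prots))
        ]
        encoder = PipelineEncoder()
        model = train(pairs, {r.id: r for r in rnas}, {p.id: p for p in prots}, encoder)
        path = tmp_path / "model.json"
        save_model(model, path)
        loaded = load_model(path)
        direct = score_pair(model, rnas[0], prots[0], encoder)
        rebuilt = score_pair(loaded, rnas[0], prots[0])  # encoder from snapshot
        assert direct.final == rebuilt.final
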