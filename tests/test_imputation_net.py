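"""Encoding, ensemble training, imputation, and serialization."""

from __future__ import annotations

import numpy as np
import pytest

from twodcg import (
    Encoder,
    EnsembleConfig,
    SixDDPDataset,
    TrainingError,
    impute,
    load_ensemble,
    save_ensemble,
    train_ensemble,
)
from twodcg.imputation_net import RE_PAIRS, _Head, ModelEnsemble, TwoHeadModel
from twodcg.synthetic_data import (
    make_domain_vocabulary,
    make_phenotype_vocabulary,
    make_population_order,
    simulate_learnable_dataset,
)

from .conftest import make_record

QUICK = EnsembleConfig(pool_size=4, ensemble_size=2, hidden_width=64,
                       max_iter=400, learning_rate_init=0.01)


@pytest.fixture(scope="module")
def world():
    domains = make_domain_vocabulary(n_a=8, n_b=5)
    pop_vocab, order = make_population_order(6)
    phenotypes = make_phenotype_vocabulary(4)
    encoder = Encoder(domains, pop_vocab, phenotypes)
    return domains, pop_vocab, order, phenotypes, encoder


class TestEncoding:
    def test_exactly_four_active_units(self, world, record_factory):
        *_, encoder = world
        domains = world[0]
        rec = make_record(cd=domains.codes[0], po=world[1].codes[2], ph="f0")
        vec = encoder.encode(rec)
        assert vec.sum() == 4
        assert set(np.unique(vec)) == {0.0, 1.0}
        assert len(vec) == encoder.n_features

    def test_af_difference_changes_two_positions(self, world):
        *_, encoder = world
        domains = world[0]
        r0 = make_record(cd=domains.codes[0], po=world[1].codes[0], ph="f0", af=0)
        r1 = make_record(cd=domains.codes[0], po=world[1].codes[0], ph="f0", af=1)
        assert int(np.sum(encoder.encode(r0) != encoder.encode(r1))) == 2

    @pytest.mark.parametrize("seed", [0, 1])
    def test_round_trip(self, world, seed):
        domains, pop_vocab, order, phenotypes, encoder = world
        ds, _ = simulate_learnable_dataset(domains, order, phenotypes,
                                           n_records=20, seed=seed)
        for r in ds.records:
            cd, re_pair, po, af = encoder.decode(encoder.encode(r))
            assert (cd, re_pair, po, af) == (
                r.cd, (r.re.ref_class, r.re.sub_class), r.po, r.af
            )

    def test_feature_layout(self, world):
        *_, encoder = world
        assert encoder.n_features == 13 + len(RE_PAIRS) + 6 + 2


class TestTraining:
    def test_degenerate_single_class_is_perfect(self, world):
        domains, pop_vocab, order, phenotypes, encoder = world
        ds = SixDDPDataset(
            [make_record(cd=domains.codes[i % 5], po=order.codes[i % 3], ph="f0")
             for i in range(40)]
        )
        ensemble = train_ensemble(ds, encoder, QUICK, seed=0)
        assert max(ensemble.scores) == 1.0

    def test_determinism(self, world):
        domains, pop_vocab, order, phenotypes, encoder = world
        ds, _ = simulate_learnable_dataset(domains, order, phenotypes,
                                           n_records=150, seed=2)
        e1 = train_ensemble(ds, encoder, QUICK, seed=9)
        e2 = train_ensemble(ds, encoder, QUICK, seed=9)
        assert e1.scores == e2.scores
        assert [m.seed for m in e1.models] == [m.seed for m in e2.models]

    def test_learnable_rule_reaches_floor(self, world):
        domains, pop_vocab, order, phenotypes, encoder = world
        ds, _ = simulate_learnable_dataset(domains, order, phenotypes,
                                           n_records=500, seed=3)
        ensemble = train_ensemble(ds, encoder, QUICK, seed=1)
        assert max(ensemble.scores) >= 0.60

    def test_score_monotone_with_sample_size(self, world):
        """With a noiseless domain -> outcome rule, exact reproduction
        approaches 100% as the sample grows."""
        domains, pop_vocab, order, phenotypes, encoder = world
        best = []
        for n in (100, 500, 2000):
            ds, _ = simulate_learnable_dataset(domains, order, phenotypes,
                                               n_records=n, seed=4)
            cfg = EnsembleConfig(pool_size=2, ensemble_size=1, hidden_width=64,
                                 max_iter=400, learning_rate_init=0.01)
            best.append(max(train_ensemble(ds, encoder, cfg, seed=0).scores))
        assert best[2] >= best[0]
        assert best[2] >= 0.9

    def test_floor_violation_reports_best(self, world):
        domains, pop_vocab, order, phenotypes, encoder = world
        # outcomes independent of features: nothing can reach a 0.99 floor
        rng = np.random.default_rng(0)
        pas = ("pt", "be", "lp", "lb")
        ds = SixDDPDataset(
            [make_record(cd=domains.codes[rng.integers(13)],
                         po=order.codes[rng.integers(6)],
                         ph=phenotypes.codes[rng.integers(4)],
                         pa=pas[rng.integers(4)])
             for _ in range(120)]
        )
        cfg = EnsembleConfig(pool_size=2, ensemble_size=1, hidden_width=16,
                             max_iter=60, floor=0.99)
        with pytest.raises(TrainingError, match="below floor"):
            train_ensemble(ds, encoder, cfg, seed=0)

    def test_score_invariant_to_record_order(self, world):
        domains, pop_vocab, order, phenotypes, encoder = world
        ds, _ = simulate_learnable_dataset(domains, order, phenotypes,
                                           n_records=200, seed=5)
        ensemble = train_ensemble(ds, encoder, QUICK, seed=2)
        model = ensemble.models[0]
        X = encoder.matrix(ds)
        y_ph = np.array([r.ph for r in ds.records])
        y_pa = np.array([r.pa for r in ds.records])
        s1 = model.exact_reproduction(X, y_ph, y_pa)
        perm = np.random.default_rng(1).permutation(len(ds))
        s2 = model.exact_reproduction(X[perm], y_ph[perm], y_pa[perm])
        assert s1 == pytest.approx(s2)


class TestImputation:
    def test_no_unknowns_identity(self, world):
        domains, pop_vocab, order, phenotypes, encoder = world
        ds, _ = simulate_learnable_dataset(domains, order, phenotypes,
                                           n_records=100, seed=6)
        ensemble = train_ensemble(ds, encoder, QUICK, seed=3)
        out = impute(ensemble, ds)
        assert out.records == ds.records

    def test_planted_truth_recovered(self, world):
        domains, pop_vocab, order, phenotypes, encoder = world
        train, rule = simulate_learnable_dataset(domains, order, phenotypes,
                                                 n_records=600, seed=7)
        ensemble = train_ensemble(train, encoder, QUICK, seed=4)
        masked, _ = simulate_learnable_dataset(domains, order, phenotypes,
                                               n_records=300, seed=8,
                                               masking_fraction=0.4)
        completed = impute(ensemble, masked)
        assert all(completed.fulfilled_mask)
        unknown_idx = [i for i, r in enumerate(masked.records) if not r.fulfilled]
        correct = sum(
            1 for i in unknown_idx
            if (completed.records[i].ph, completed.records[i].pa)
            == rule[completed.records[i].cd]
        )
        assert correct / len(unknown_idx) >= 0.9

    def test_independent_fields_untouched(self, world):
        domains, pop_vocab, order, phenotypes, encoder = world
        ds, _ = simulate_learnable_dataset(domains, order, phenotypes,
                                           n_records=150, seed=9,
                                           masking_fraction=0.5)
        ensemble = train_ensemble(ds.fulfilled(), encoder, QUICK, seed=5)
        completed = impute(ensemble, ds)
        for before, after in zip(ds.records, completed.records):
            assert (before.cd, before.re, before.po, before.af) == (
                after.cd, after.re, after.po, after.af
            )
            if before.fulfilled:
                assert (before.ph, before.pa) == (after.ph, after.pa)

    def test_vote_tie_lowest_class_index(self, world):
        domains, pop_vocab, order, phenotypes, encoder = world

        def constant_head(label: str) -> _Head:
            return _Head(
                coefs=[np.zeros((encoder.n_features, 1)), np.zeros((1, 1))],
                intercepts=[np.zeros(1), np.ones(1)],
                classes=(label, label),
                activation="logistic",
            )

        # two models voting f1/pt vs f0/be: tie resolves to the lowest
        # class index in vocabulary order (f0; pt precedes be in the code set)
        models = [
            TwoHeadModel(constant_head("f1"), constant_head("pt"), seed=0),
            TwoHeadModel(constant_head("f0"), constant_head("be"), seed=1),
        ]
        ensemble = ModelEnsemble(models=models, encoder=encoder,
                                 config=QUICK, seed=0)
        ds = SixDDPDataset(
            [make_record(cd=domains.codes[0], po=order.codes[0], ph="uk", pa="uk")]
        )
        out = impute(ensemble, ds)
        assert out.records[0].ph == "f0"
        assert out.records[0].pa == "pt"


class TestSerialization:
    def test_round_trip_predictions(self, world, tmp_path):
        domains, pop_vocab, order, phenotypes, encoder = world
        ds, _ = simulate_learnable_dataset(domains, order, phenotypes,
                                           n_records=200, seed=10)
        ensemble = train_ensemble(ds, encoder, QUICK, seed=6)
        save_ensemble(ensemble, tmp_path / "bundle")
        loaded = load_ensemble(tmp_path / "bundle", encoder)
        assert loaded.scores == ensemble.scores
        X = encoder.matrix(ds)
        for m1, m2 in zip(ensemble.models, loaded.models):
            ph1, pa1 = m1.predict(X)
            ph2, pa2 = m2.predict(X)
            assert np.array_equal(ph1, ph2)
            assert np.array_equal(pa1, pa2)
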