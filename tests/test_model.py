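"""Discriminator training: class weighting, per-epoch boosters, the pooled
training protocol, prediction semantics and persistence."""

import numpy as np
import pytest

from cypsom import fixtures as fx
from cypsom.chem import label_soms, record_from_smiles
from cypsom.errors import ConfigError, DataError
from cypsom.model import (
    BoosterConfig,
    SitePredictor,
    fit_epoch_booster,
    pos_weight,
    train,
)

SMALL = dict(hidden_size=32, depth=2, epochs=3, batch_size=8)


class TestPosWeight:
    def test_precision_mode_uses_default_weight(self):
        assert pos_weight("precision", 100, 900) == 1.0

    def test_recall_mode_balanced_classes(self):
        assert pos_weight("recall", 50, 50, c=1.0) == 1.0

    def test_conventional_orientation_upweights_minority(self):
        assert pos_weight("recall", 100, 900, c=3.0) == pytest.approx(27.0)

    def test_printed_orientation_is_exposed(self):
        got = pos_weight("recall", 100, 900, c=3.0, weight_formula="pos_over_neg")
        assert got == pytest.approx(1 / 3)

    def test_zero_negatives_is_an_error(self):
        with pytest.raises(DataError):
            pos_weight("recall", 10, 0)


class TestEpochBooster:
    def test_separable_embeddings_reach_perfect_jaccard(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(200, 4))
        y = (X[:, 0] > 0).astype(int)
        booster, block = fit_epoch_booster(
            X[:150], y[:150], X[150:], y[150:], BoosterConfig(), seed=1
        )
        assert block["val_jaccard"] == 1.0
        assert block["train_jaccard"] == 1.0

    def test_single_class_labels_name_the_isoform(self):
        X = np.zeros((10, 3))
        with pytest.raises(DataError, match="2E1"):
            fit_epoch_booster(X, np.zeros(10), X, np.zeros(10), BoosterConfig(), 0, "2E1")

    def test_agrees_with_independent_boosted_reference_on_noisy_clouds(self):
        """On overlapping Gaussian clouds with a known Bayes error, the
        booster's validation Jaccard lands near an independent boosted-tree
        implementation fit on the same data."""
        from sklearn.ensemble import GradientBoostingClassifier
        from cypsom.metrics import jaccard_score_from_calls

        rng = np.random.default_rng(42)
        n = 600
        y = rng.integers(0, 2, n)
        X = rng.normal(size=(n, 3)) + 1.2 * y[:, None]
        Xt, yt, Xv, yv = X[:450], y[:450], X[450:], y[450:]
        _, block = fit_epoch_booster(Xt, yt, Xv, yv, BoosterConfig(), seed=3)
        ref = GradientBoostingClassifier(random_state=3).fit(Xt, yt)
        ref_j = jaccard_score_from_calls(yv, ref.predict_proba(Xv)[:, 1] > 0.5)
        assert abs(block["val_jaccard"] - ref_j) < 0.15


class TestTrainingProtocol:
    def test_planted_rule_is_learnable(self, planted_dataset):
        est = SitePredictor(target_isoform="3A4", random_state=5, **SMALL)
        est.fit(planted_dataset)
        by_id = {r.mol_id: r for r in planted_dataset}
        val = [by_id[i] for i in est.split_.val_ids]
        assert est.score(val) >= 0.6

    def test_same_seed_reproduces_everything(self, planted_dataset):
        kw = dict(target_isoform="3A4", random_state=9, **SMALL)
        a = SitePredictor(**kw).fit(planted_dataset)
        b = SitePredictor(**kw).fit(planted_dataset)
        assert a.best_epoch_ == b.best_epoch_
        by_id = {r.mol_id: r for r in planted_dataset}
        val = [by_id[i] for i in a.split_.val_ids]
        assert np.array_equal(a.predict_proba(val), b.predict_proba(val))
        assert a.history_.equals(b.history_)

    def test_retained_epoch_never_worse_than_first(self, planted_dataset):
        est = SitePredictor(target_isoform="3A4", random_state=2, **SMALL)
        est.fit(planted_dataset)
        assert est.best_val_jaccard_ >= est.history_.val_jaccard.iloc[0]

    def test_selection_jaccard_matches_metrics_module(self, planted_dataset):
        est = SitePredictor(target_isoform="3A4", random_state=4, **SMALL)
        est.fit(planted_dataset)
        by_id = {r.mol_id: r for r in planted_dataset}
        val = [by_id[i] for i in est.split_.val_ids]
        assert est.score(val) == pytest.approx(est.best_val_jaccard_)

    def test_scaled_equal_loss_weights_behave_like_unweighted(self, planted_dataset):
        base = SitePredictor(target_isoform="3A4", random_state=6, **SMALL)
        scaled = SitePredictor(
            target_isoform="3A4", random_state=6, loss_a=1.5, loss_b=1.5, **SMALL
        )
        j1 = base.fit(planted_dataset).best_val_jaccard_
        j2 = scaled.fit(planted_dataset).best_val_jaccard_
        assert abs(j1 - j2) <= 0.25

    def test_missing_isoform_raises(self, planted_dataset):
        with pytest.raises(DataError):
            SitePredictor(target_isoform="2E1", **SMALL).fit(planted_dataset)

    def test_unknown_isoform_is_config_error(self, planted_dataset):
        with pytest.raises(ConfigError):
            SitePredictor(target_isoform="4X9", **SMALL).fit(planted_dataset)

    def test_functional_wrapper_matches_estimator(self, planted_dataset):
        est = train(planted_dataset, "3A4", seed=5, config=SMALL)
        assert est.best_epoch_ >= 1

    def test_sklearn_param_interface(self):
        est = SitePredictor()
        params = est.get_params()
        assert params["mode"] == "precision" and params["epochs"] == 30
        est.set_params(mode="recall", c=2.0)
        assert est.mode == "recall"


@pytest.fixture(scope="module")
def fitted(planted_dataset):
    return SitePredictor(target_isoform="3A4", random_state=5, **SMALL).fit(
        planted_dataset
    )


class TestPrediction:
    def test_calls_are_strictly_above_half(self, fitted, planted_dataset):
        report = fitted.predict_sites(planted_dataset[:10])
        f = report.frame
        assert ((f.probability > 0.5) == f.called).all()
        assert f.probability.between(0, 1).all()

    def test_duplicate_molecule_scores_identically(self, fitted):
        rec = record_from_smiles("CSc1ccccc1", "dup")
        rec2 = record_from_smiles("CSc1ccccc1", "dup2")
        r = fitted.predict_sites([rec, rec2]).frame
        a = r[r.mol_id == "dup"].probability.to_numpy()
        b = r[r.mol_id == "dup2"].probability.to_numpy()
        np.testing.assert_array_equal(a, b)

    def test_report_sorted_by_molecule_then_probability(self, fitted, planted_dataset):
        f = fitted.predict_sites(planted_dataset[:4]).frame
        for _, grp in f.groupby("mol_id", sort=False):
            assert (grp.probability.diff().dropna() <= 1e-12).all()

    def test_bad_record_goes_to_error_channel(self, fitted):
        import rdkit.Chem as Chem
        from cypsom.chem import MoleculeRecord

        bad = MoleculeRecord("empty", Chem.Mol())
        good = record_from_smiles("CCS", "ok")
        report = fitted.predict_sites([good, bad])
        assert [e[0] for e in report.errors] == ["empty"]
        assert set(report.frame.mol_id) == {"ok"}

    def test_bundle_round_trip_preserves_predictions(self, fitted, tmp_path, planted_dataset):
        fitted.save_bundle(tmp_path / "bundle")
        loaded = SitePredictor.load_bundle(tmp_path / "bundle")
        sub = planted_dataset[:6]
        np.testing.assert_allclose(
            fitted.predict_proba(sub), loaded.predict_proba(sub), atol=1e-6
        )
        assert loaded.best_epoch_ == fitted.best_epoch_


class TestMolFeatureVariants:
    @pytest.mark.parametrize("mf", ["fixed", "encoder"])
    def test_molecular_features_still_learn_the_rule(self, planted_dataset, mf):
        est = SitePredictor(
            target_isoform="3A4", random_state=8, mol_features=mf,
            mol_hidden_size=16, mol_out_dim=8, **SMALL,
        ).fit(planted_dataset)
        assert est.best_val_jaccard_ >= 0.5
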