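import numpy as np
import pytest
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split

from neuralfp import predictor as pr
from neuralfp import synthetic_data as sd


def small_config(seed=0, **kw):
    """Cheap configuration for unit tests (full defaults live in acceptance)."""
    defaults = dict(R=2, K=12, hidden_units=16, epochs=8, seed=seed)
    defaults.update(kw)
    return pr.TrainConfig(**defaults)


@pytest.fixture(scope="module")
def tiny_task():
    spec = sd.SyntheticSpec(n_molecules=150, seed=3)
    mols, labels, truth = sd.generate_corpus(spec)
    return mols, labels.y[:, 0].astype(int)


class TestLoss:
    def _linear_head(self, K, lam1=0.0, lam2=0.0, w=None, b=0.0):
        head = pr.PredictorParams(lambda1=lam1, lambda2=lam2, hidden_units=0)
        head.w = np.zeros(K) if w is None else np.asarray(w, float)
        head.b = b
        return head

    def test_zero_model_gives_ln2_per_sample(self, rng):
        Z = rng.normal(size=(6, 4))
        y = np.array([0, 1, 1, 0, 1, 0])
        assert np.isclose(pr.loss(Z, y, self._linear_head(4)), np.log(2), atol=1e-12)

    def test_fingerprint_penalty_closed_form(self):
        Z = np.array([[3.0, 4.0]])
        head = self._linear_head(2, lam2=0.01)
        assert np.isclose(pr.loss(Z, [1], head), np.log(2) + 0.25, atol=1e-12)

    def test_matches_scalar_loop_oracle(self, rng):
        K = 5
        Z = rng.normal(size=(9, K))
        y = (rng.random(9) < 0.5).astype(float)
        w = rng.normal(size=K)
        head = self._linear_head(K, lam1=0.07, lam2=0.013, w=w, b=0.4)
        # independent brute-force loop
        total = 0.0
        for i in range(9):
            s = 1.0 / (1.0 + np.exp(-(Z[i] @ w + 0.4)))
            total += -(y[i] * np.log(s) + (1 - y[i]) * np.log(1 - s))
        expected = total / 9 + 0.07 * np.sum(w**2) + 0.013 * np.sum(Z**2)
        assert np.isclose(pr.loss(Z, y, head), expected, rtol=1e-10)

    def test_length_mismatch_rejected(self):
        with pytest.raises(pr.PredictorError):
            pr.loss(np.zeros((3, 2)), [1, 0], self._linear_head(2))


class TestTraining:
    def test_loss_decreases(self, tiny_task):
        mols, y = tiny_task
        model = pr.train_adr_model(mols, y, small_config(seed=1))
        assert model.history[-1] < model.history[0]

    def test_seed_determinism_end_to_end(self, tiny_task):
        mols, y = tiny_task
        cfg = small_config(seed=5, epochs=3)
        m1 = pr.train_adr_model(mols, y, cfg)
        m2 = pr.train_adr_model(mols, y, cfg)
        p1 = pr.predict_proba(m1, mols[:20])
        p2 = pr.predict_proba(m2, mols[:20])
        assert np.array_equal(p1, p2)

    def test_planted_signal_learnable(self, tiny_task):
        mols, y = tiny_task
        idx = np.arange(len(mols))
        tr, te = train_test_split(idx, test_size=0.3, stratify=y, random_state=0)
        model = pr.train_adr_model([mols[i] for i in tr], y[tr], small_config(seed=1, epochs=20))
        auc = roc_auc_score(y[te], pr.predict_proba(model, [mols[i] for i in te]))
        assert auc >= 0.8

    def test_permuted_labels_near_chance(self, tiny_task):
        mols, y = tiny_task
        rng = np.random.default_rng(0)
        y_perm = rng.permutation(y)
        idx = np.arange(len(mols))
        tr, te = train_test_split(idx, test_size=0.3, stratify=y_perm, random_state=0)
        model = pr.train_adr_model([mols[i] for i in tr], y_perm[tr], small_config(seed=1, epochs=10))
        auc = roc_auc_score(y_perm[te], pr.predict_proba(model, [mols[i] for i in te]))
        assert 0.35 <= auc <= 0.65

    def test_l1_regularization_path_monotone(self, tiny_task):
        mols, y = tiny_task
        norms = []
        for lam1 in (1e-5, 1e-2, 10.0):
            model = pr.train_adr_model(mols, y, small_config(seed=2, epochs=6, lambda1=lam1))
            norms.append(float((model.head.W1**2).sum() + (model.head.W2**2).sum()))
        assert norms[0] >= norms[1] >= norms[2]

    def test_l2_penalty_shrinks_fingerprint_norms(self, tiny_task):
        mols, y = tiny_task
        small = pr.train_adr_model(mols, y, small_config(seed=2, epochs=6, lambda2=1e-4))
        large = pr.train_adr_model(mols, y, small_config(seed=2, epochs=6, lambda2=10.0))
        assert (large.fingerprints(mols[:50]) ** 2).sum() < (small.fingerprints(mols[:50]) ** 2).sum()

    def test_too_few_positives_rejected(self, tiny_task):
        mols, _ = tiny_task
        y = np.zeros(len(mols))
        y[0] = 1
        with pytest.raises(pr.PredictorError, match="positives"):
            pr.train_adr_model(mols, y, small_config())


class TestPredictProba:
    def test_inference_deterministic(self, tiny_task):
        mols, y = tiny_task
        model = pr.train_adr_model(mols, y, small_config(seed=1, epochs=2))
        assert np.array_equal(pr.predict_proba(model, mols[:10]), pr.predict_proba(model, mols[:10]))

    def test_zeroed_head_outputs_half(self, tiny_task):
        mols, y = tiny_task
        model = pr.train_adr_model(mols[:60], y[:60], small_config(seed=1, epochs=1))
        model.head.W2[:] = 0.0
        model.head.b2 = 0.0
        assert np.allclose(pr.predict_proba(model, mols[:5]), 0.5, atol=1e-12)

    def test_probabilities_in_open_interval(self, tiny_task):
        mols, y = tiny_task
        model = pr.train_adr_model(mols, y, small_config(seed=1, epochs=2))
        p = pr.predict_proba(model, mols[:30])
        assert np.all((p > 0) & (p < 1))


class TestCrossValidate:
    def test_out_of_fold_coverage_and_reproducibility(self, tiny_task):
        mols, y = tiny_task
        cfg = small_config(seed=7, epochs=2)
        s1, a1 = pr.cross_validate(mols, y.reshape(-1, 1), cfg, folds=3)
        s2, a2 = pr.cross_validate(mols, y.reshape(-1, 1), cfg, folds=3)
        assert not np.isnan(s1).any()  # every drug scored exactly once
        assert np.array_equal(a1, a2) and np.array_equal(s1, s2)

    def test_few_positives_falls_back_to_fewer_folds(self, tiny_task, caplog):
        mols, _ = tiny_task
        y = np.zeros(len(mols), dtype=int)
        y[:4] = 1
        cfg = small_config(seed=7, epochs=1)
        with caplog.at_level("WARNING"):
            scores, assignments = pr.cross_validate(mols, y.reshape(-1, 1), cfg, folds=10)
        assert "folds" in caplog.text
        assert assignments.max() == 3  # 4 positives -> 4 folds

    def test_cv_auc_consistent_with_holdout(self, tiny_task):
        mols, y = tiny_task
        cfg = small_config(seed=1, epochs=20)
        scores, _ = pr.cross_validate(mols, y.reshape(-1, 1), cfg, folds=4)
        cv_auc = roc_auc_score(y, scores[:, 0])
        idx = np.arange(len(mols))
        tr, te = train_test_split(idx, test_size=0.25, stratify=y, random_state=1)
        model = pr.train_adr_model([mols[i] for i in tr], y[tr], cfg)
        holdout_auc = roc_auc_score(y[te], pr.predict_proba(model, [mols[i] for i in te]))
        assert abs(cv_auc - holdout_auc) < 0.12


class TestGridSearch:
    def test_selects_max_f1_with_regularization_tiebreak(self, tiny_task):
        mols, y = tiny_task
        base = small_config(seed=1, epochs=3)
        best, results = pr.grid_search(
            mols[:100], y[:100], base, {"lambda1": [1e-5, 1e-3], "lambda2": [1e-3, 1e-1]}, folds=2,
        )
        best_f1 = max(f1 for _, f1 in results)
        contenders = [c for c, f1 in results if f1 == best_f1]
        expect = max(contenders, key=lambda c: (c.lambda1, c.lambda2))
        assert (best.lambda1, best.lambda2) == (expect.lambda1, expect.lambda2)
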