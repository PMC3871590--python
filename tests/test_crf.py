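"""Linear-chain CRF: featurization geometry, inference oracles, training."""

import numpy as np
import pytest

from shapestring import FeatureSequence, ShapeCRF, featurize, split_at_undefined
from shapestring.crf import FeatureError, N_LETTER_VALUES
from oracles import brute_force_log_partition, brute_force_viterbi

LETTERS = "LADCQMVWPGN"


def random_feature_sequence(rng, L, n_base, window):
    rows = tuple(
        "".join(rng.choice(list(LETTERS), size=n_base)) for _ in range(L)
    )
    return FeatureSequence(letters=rows, window=window)


def small_model(rng, n_base=2, window=0, scale=1.0):
    """An untrained model with random weights set directly."""
    m = ShapeCRF(window=window)
    m.n_base = n_base
    m.w_obs = rng.normal(0, scale, size=(m.n_flat, 8))
    m.w_trans = rng.normal(0, scale, size=(8, 8))
    return m


class TestFeaturize:
    def test_window_zero_gives_fourteen_observations(self):
        shift = ["LADCQM"] * 4
        prof = ["VWPGLADC"] * 4
        fs = featurize(shift, prof, window=0)
        assert fs.n_base == 14
        assert fs.n_observations == 14
        assert fs.observation_indices().shape == (4, 14)

    def test_window_two_gives_five_fold_expansion(self):
        fs = featurize(["LADCQM"] * 6, ["VWPGLADC"] * 6, window=2)
        assert fs.n_observations == 14 * 5

    def test_boundary_tokens_at_sequence_start(self):
        fs = featurize(["LADCQM"] * 5, ["VWPGLADC"] * 5, window=2)
        obs = fs.observation_indices()
        boundary = N_LETTER_VALUES - 1
        # first position: offsets -2 and -1 (first two blocks of 14) padded
        assert (obs[0, :28] == boundary).all()
        assert (obs[0, 28:42] != boundary).all()

    def test_length_mismatch_rejected(self):
        with pytest.raises(FeatureError):
            featurize(["LADCQM"] * 3, ["VWPGLADC"] * 4)

    def test_single_family_allowed_for_ablation(self):
        fs = featurize(["LADCQ"] * 3, None, window=1)
        assert fs.n_base == 5

    def test_split_at_undefined_runs(self):
        fs = featurize(["LADCQM"] * 7, None, window=0)
        parts = split_at_undefined(fs, "SSXXATG")
        assert [(len(f), lab) for f, lab in parts] == [(2, "SS"), (3, "ATG")]


class TestInferenceOracles:
    @pytest.mark.parametrize("L", [1, 2, 3, 4, 5, 6])
    def test_partition_function_matches_enumeration(self, L):
        rng = np.random.default_rng(L)
        m = small_model(rng)
        fs = random_feature_sequence(rng, L, n_base=2, window=0)
        E = m._emissions(fs)
        assert m.log_partition(fs) == pytest.approx(
            brute_force_log_partition(E, m.w_trans), abs=1e-9
        )

    @pytest.mark.parametrize("L", [1, 2, 3, 4, 5, 6])
    def test_viterbi_matches_enumeration(self, L):
        rng = np.random.default_rng(100 + L)
        m = small_model(rng)
        fs = random_feature_sequence(rng, L, n_base=2, window=0)
        E = m._emissions(fs)
        best_score, best_path = brute_force_viterbi(E, m.w_trans)
        path, score = m.best_path(fs)
        assert score == pytest.approx(best_score, abs=1e-9)
        assert [("SRUVKATG").index(c) for c in path] == list(best_path)

    def test_zero_transitions_reduce_viterbi_to_argmax(self):
        rng = np.random.default_rng(0)
        m = small_model(rng)
        m.w_trans = np.zeros((8, 8))
        fs = random_feature_sequence(rng, 10, n_base=2, window=0)
        E = m._emissions(fs)
        path, _ = m.best_path(fs)
        assert path == "".join("SRUVKATG"[i] for i in np.argmax(E, axis=1))

    def test_viterbi_dominates_randomly_sampled_paths(self):
        rng = np.random.default_rng(17)
        m = small_model(rng, window=1)
        fs = random_feature_sequence(rng, 12, n_base=2, window=1)
        _, best = m.best_path(fs)
        for _ in range(1000):
            labels = "".join(rng.choice(list("SRUVKATG"), size=12))
            assert m.sequence_score(fs, labels) <= best + 1e-9

    def test_marginals_sum_to_one(self):
        rng = np.random.default_rng(4)
        m = small_model(rng, n_base=3, window=2, scale=2.0)
        fs = random_feature_sequence(rng, 30, n_base=3, window=2)
        marg = m.marginals(fs)
        assert np.allclose(marg.sum(axis=1), 1.0, atol=1e-9)

    def test_marginals_match_enumeration(self):
        rng = np.random.default_rng(8)
        m = small_model(rng)
        fs = random_feature_sequence(rng, 4, n_base=2, window=0)
        E = m._emissions(fs)
        from oracles import enumerate_paths

        paths = enumerate_paths(4, 8)
        scores = E[np.arange(4), paths].sum(axis=1)
        scores += m.w_trans[paths[:, :-1], paths[:, 1:]].sum(axis=1)
        w = np.exp(scores - scores.max())
        w /= w.sum()
        expected = np.zeros((4, 8))
        for t in range(4):
            for k in range(8):
                expected[t, k] = w[paths[:, t] == k].sum()
        assert np.allclose(m.marginals(fs), expected, atol=1e-9)

    def test_template_mismatch_rejected(self):
        rng = np.random.default_rng(2)
        m = small_model(rng, n_base=2, window=0)
        fs = random_feature_sequence(rng, 5, n_base=3, window=0)
        with pytest.raises(FeatureError):
            m.best_path(fs)


def separable_corpus(rng, n_seqs=8, length=30, window=0):
    """HA letter uniquely determines the label: perfectly separable."""
    label_to_letter = dict(zip("SRUVKATG", "LADCQMVW"))
    corpus = []
    for _ in range(n_seqs):
        labels = "".join(rng.choice(list("SRUVKATG"), size=length))
        rows = tuple(
            label_to_letter[c] + "".join(rng.choice(list(LETTERS), size=5))
            for c in labels
        )
        corpus.append((FeatureSequence(letters=rows, window=window), labels))
    return corpus


class TestTraining:
    def test_objective_trace_non_increasing_overall(self):
        rng = np.random.default_rng(5)
        corpus = separable_corpus(rng, n_seqs=4, length=20)
        m = ShapeCRF(window=0, l2=0.1, max_iter=40).fit(corpus)
        trace = m.objective_trace_
        # L-BFGS line search may probe uphill, but accepted progress must
        # leave the final objective at the running minimum
        assert m.final_objective_ == pytest.approx(min(trace), abs=1e-6)
        assert trace[-1] <= trace[0]

    def test_separable_corpus_reaches_perfect_held_in_accuracy(self):
        rng = np.random.default_rng(6)
        corpus = separable_corpus(rng)
        m = ShapeCRF(window=0, l2=0.01, max_iter=150).fit(corpus)
        for fs, labels in corpus:
            path, _ = m.best_path(fs)
            assert path == labels

    def test_same_seed_reproduces_identical_weights(self):
        rng = np.random.default_rng(7)
        corpus = separable_corpus(rng, n_seqs=3, length=15, window=1)
        m1 = ShapeCRF(window=1, l2=1.0, max_iter=30, seed=1).fit(corpus)
        m2 = ShapeCRF(window=1, l2=1.0, max_iter=30, seed=1).fit(corpus)
        assert np.array_equal(m1.w_obs, m2.w_obs)
        assert np.array_equal(m1.w_trans, m2.w_trans)

    def test_all_undefined_corpus_rejected(self):
        fs = featurize(["LADCQM"] * 4, None, window=0)
        with pytest.raises(ValueError):
            ShapeCRF(window=0).fit([(fs, "XXXX")])

    def test_gradient_matches_finite_differences(self):
        # spot check of the analytic gradient on a tiny problem
        rng = np.random.default_rng(9)
        corpus = separable_corpus(rng, n_seqs=2, length=6)
        m = ShapeCRF(window=0, l2=0.5, max_iter=0)
        # reuse fit() to build the objective, then probe it directly
        m.fit(corpus)  # maxiter 0 leaves weights at the start point
        # rebuild objective internals via one training step on a clone
        import scipy.optimize as so

        m2 = ShapeCRF(window=0, l2=0.5, max_iter=1)
        captured = {}

        orig_min = so.minimize

        def capture(fun, x0, **kw):
            captured["fun"] = fun
            return orig_min(fun, x0, **kw)

        so.minimize, _saved = capture, so.minimize
        try:
            m2.fit(corpus)
        finally:
            so.minimize = _saved
        fun = captured["fun"]
        theta = rng.normal(0, 0.1, size=(m2.n_flat * 8 + 64))
        f0, g = fun(theta)
        eps = 1e-6
        idx = rng.choice(theta.size, size=12, replace=False)
        for i in idx:
            tp = theta.copy()
            tp[i] += eps
            fp, _ = fun(tp)
            assert (fp - f0) / eps == pytest.approx(g[i], rel=1e-3, abs=1e-5)


class TestSerialization:
    def test_save_load_bit_stable(self, tmp_path):
        rng = np.random.default_rng(11)
        corpus = separable_corpus(rng, n_seqs=3, length=12, window=1)
        m = ShapeCRF(window=1, l2=1.0, max_iter=25).fit(corpus)
        path = tmp_path / "model.json"
        m.save(path)
        back = ShapeCRF.load(path)
        assert np.array_equal(back.w_obs, m.w_obs)
        assert np.array_equal(back.w_trans, m.w_trans)
        fs = corpus[0][0]
        assert back.best_path(fs) == m.best_path(fs)


class TestFeatureDump:
    def test_column_text_has_one_row_per_residue(self, tmp_path):
        from shapestring.crf import write_feature_columns

        fs = featurize(["LADCQM"] * 3, ["VWPGLADC"] * 3, window=0)
        path = tmp_path / "dump.tsv"
        write_feature_columns(fs, "SRT", path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 3
        assert all(len(line.split("\t")) == 15 for line in lines)  # 14 + label
        assert lines[0].split("\t")[-1] == "S"
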