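import warnings

import numpy as np
import pytest

from fcsubnet import fc_io
from fcsubnet.decomposition import (
    DecompositionError,
    infomax_ica,
    pca_reduce,
    raicar_align,
    select_components,
)
from fcsubnet.synthetic import SyntheticConfig, generate_cohort


def _quiet_ica(*args, **kwargs):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return infomax_ica(*args, **kwargs)


class TestPcaReduce:
    def test_rank_one_input_gives_single_component(self, rng):
        base = rng.uniform(0, 1, size=200)
        X = np.outer(rng.uniform(0.5, 2.0, size=10), base) + 0.3
        red = pca_reduce(X, variance_target=0.90)
        assert red.C == 1
        assert red.explained_variance == pytest.approx(1.0)

    def test_full_variance_keeps_N_minus_1(self, rng):
        X = rng.uniform(0, 1, size=(8, 50))
        red = pca_reduce(X, variance_target=1.0)
        assert red.C == 7  # centering removes one dimension

    def test_reconstruction_captures_target_variance(self, rng):
        X = rng.uniform(0, 1, size=(15, 120))
        red = pca_reduce(X, variance_target=0.90)
        Xc = X - X.mean(axis=0)
        recon = red.projector.T @ red.Xprime
        captured = 1 - np.sum((Xc - recon) ** 2) / np.sum(Xc ** 2)
        assert captured >= 0.90
        # independent SVD oracle for the retained-variance fraction
        s = np.linalg.svd(Xc, compute_uv=False)
        oracle = np.cumsum(s ** 2) / np.sum(s ** 2)
        assert red.explained_variance == pytest.approx(oracle[red.C - 1],
                                                       abs=1e-9)

    def test_projector_applied_to_data_matches_Xprime(self, rng):
        # X' is quantized on a 1e-6-relative grid, hence the tolerance
        X = rng.uniform(0, 1, size=(12, 80))
        red = pca_reduce(X, variance_target=0.95)
        Xc = X - red.column_means
        q = 1e-6 * np.abs(red.Xprime).max()
        assert np.allclose(red.projector @ Xc, red.Xprime, atol=q)

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(DecompositionError):
            pca_reduce(rng.uniform(size=(2, 30)))


class TestInfomaxIca:
    def test_recovers_planted_laplace_sources(self, rng):
        S_true = rng.laplace(size=(2, 4000))
        A_true = rng.normal(size=(2, 2))
        X = A_true @ S_true
        dec = _quiet_ica(X, seed=3)
        cc = np.abs(np.corrcoef(np.vstack([dec.S, S_true]))[:2, 2:])
        # each true source matched by exactly one recovered component
        assert cc.max(axis=1).min() > 0.99

    def test_same_seed_reproduces_bitwise(self, rng):
        X = rng.laplace(size=(3, 1000))
        d1 = _quiet_ica(X, seed=11)
        d2 = _quiet_ica(X, seed=11)
        assert np.array_equal(d1.S, d2.S) and np.array_equal(d1.A, d2.A)

    def test_mixing_times_sources_reproduces_input(self, rng):
        X = np.random.default_rng(5).laplace(size=(4, 2000))
        dec = _quiet_ica(X, seed=2)
        err = np.linalg.norm(X - dec.A @ dec.S) / np.linalg.norm(X)
        assert err < 1e-6

    def test_unit_variance_and_sign_convention(self, rng):
        X = rng.laplace(size=(3, 1500))
        dec = _quiet_ica(X, seed=8)
        assert np.allclose(dec.S.std(axis=1), 1.0, atol=1e-9)
        peak = dec.S[np.arange(3), np.argmax(np.abs(dec.S), axis=1)]
        assert np.all(peak > 0)

    def test_single_component_rejected(self, rng):
        with pytest.raises(DecompositionError):
            infomax_ica(rng.normal(size=(1, 100)), seed=0)


class TestRaicarAlign:
    def test_identical_runs_score_one(self, rng):
        X = rng.laplace(size=(3, 800))
        dec = _quiet_ica(X, seed=4)
        ranked = raicar_align([dec, dec, dec, dec])
        assert all(c.reproducibility == pytest.approx(1.0)
                   for c in ranked.components)
        assert all(c.match_count == 3 for c in ranked.components)

    def test_noise_component_ranked_last(self, rng):
        """A run carrying a pure-noise extra component ranks it last."""
        S_shared = rng.laplace(size=(3, 2000))
        runs = []
        for k in range(4):
            S = S_shared.copy()
            if k == 0:
                S = np.vstack([S_shared[:2], rng.normal(size=2000)[None, :]])
            A = np.eye(3)
            from fcsubnet.decomposition import Decomposition
            runs.append(Decomposition(A=A, S=S, run_seed=k, converged=True,
                                      n_iter=1))
        ranked = raicar_align(runs)
        # reference is one of the three identical runs; its third component
        # finds no partner in the noise-carrying run
        worst = ranked.components[-1]
        assert worst.source_index == 2
        assert worst.match_count == 2
        assert worst.reproducibility < 1.0
        for c in ranked.components[:-1]:
            assert c.reproducibility == pytest.approx(1.0)

    def test_adding_identical_run_never_lowers_scores(self, rng):
        X = rng.laplace(size=(3, 600))
        runs = [_quiet_ica(X, seed=s) for s in range(4)]
        r1 = raicar_align(runs)
        ref = r1.reference_run
        r2 = raicar_align(runs + [runs[ref]])
        s1 = {c.source_index: c.reproducibility for c in r1.components}
        s2 = {c.source_index: c.reproducibility for c in r2.components}
        assert all(s2[i] >= s1[i] - 1e-12 for i in s1)

    def test_scores_bounded_and_sorted(self, decomposed):
        _, ranked = decomposed
        scores = [c.reproducibility for c in ranked.components]
        assert all(0.0 <= s <= 1.0 for s in scores)
        assert scores == sorted(scores, reverse=True)

    def test_fewer_than_two_runs_rejected(self, rng):
        X = rng.laplace(size=(2, 300))
        with pytest.raises(DecompositionError):
            raicar_align([_quiet_ica(X, seed=0)])


class TestSelectionAndStability:
    def test_select_all_and_too_many(self, decomposed):
        _, ranked = decomposed
        assert len(select_components(ranked, len(ranked))) == len(ranked)
        with pytest.raises(DecompositionError):
            select_components(ranked, len(ranked) + 1)

    def test_top_components_match_planted_sources(self, cohort, decomposed):
        _, truth = cohort
        _, ranked = decomposed
        top = ranked.S[:truth.config.n_components]
        for src in truth.sources:
            best = max(abs(np.corrcoef(src, row)[0, 1]) for row in top)
            assert best > 0.9

    def test_subject_shuffle_leaves_decomposition_identical(self, cohort):
        """Shuffling subject order must not change the ranked components."""
        from fcsubnet.decomposition import decompose
        stack, _ = cohort
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            _, ranked0 = decompose(stack, n_runs=5, seed=21, n_select=6)
        perm = np.random.default_rng(1).permutation(stack.N)
        shuffled = fc_io.CohortStack(
            X=stack.X[perm], labels=stack.labels[perm],
            subject_ids=tuple(np.array(stack.subject_ids)[perm]),
            node_names=stack.node_names)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            _, ranked1 = decompose(shuffled, n_runs=5, seed=21, n_select=6)
        assert np.array_equal(ranked0.S, ranked1.S)
        assert np.array_equal(ranked0.A, ranked1.A)
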