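"""Latent-cause model: prior, likelihood, inference, prediction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from splitlearn import (ModelParams, SchemaLibrary, crp_prior, infer_step,
                        predict_2afc, predict_distribution, process_story,
                        sample_story, transition_likelihood)


def make_params(**kw):
    base = dict(alpha=1.0, beta=1.0, lam=0.5,
                inference_unit="transition")
    base.update(kw)
    return ModelParams(**base)


def library_with_usage(usages, active=-1):
    lib = SchemaLibrary()
    for u in usages:
        k = lib.spawn()
        lib.usage[k] = u
    lib.active = active
    lib.prev_story_cause = active
    return lib


class TestParams:
    @pytest.mark.parametrize("bad", [
        dict(alpha=-1.0), dict(beta=-0.5), dict(lam=0.0), dict(tau=0.0),
        dict(predict_mode="mean"), dict(inference_unit="block")])
    def test_invalid_rejected(self, bad):
        with pytest.raises(ValueError):
            make_params(**bad)


class TestCrpPrior:
    def test_empty_library_all_mass_on_new(self):
        p = crp_prior(SchemaLibrary(), make_params(alpha=3.0))
        assert p.shape == (1,) and p[0] == 1.0

    def test_sticky_hand_example(self):
        # N = {k1: 3}, previous cause k1, alpha=2, beta=1 -> [2/3, 1/3]
        lib = library_with_usage([3.0], active=0)
        p = crp_prior(lib, make_params(alpha=2.0, beta=1.0))
        assert np.allclose(p, [2 / 3, 1 / 3])

    def test_no_stickiness_hand_example(self):
        # beta = 0, N = {1, 1}, alpha = 2 -> [0.25, 0.25, 0.5]
        lib = library_with_usage([1.0, 1.0], active=0)
        p = crp_prior(lib, make_params(alpha=2.0, beta=0.0))
        assert np.allclose(p, [0.25, 0.25, 0.5])

    @given(st.lists(st.integers(0, 50), min_size=0, max_size=6),
           st.floats(0.01, 50), st.floats(0, 50))
    @settings(max_examples=50, deadline=None)
    def test_normalization(self, usages, alpha, beta):
        lib = library_with_usage([float(u) for u in usages],
                                 active=0 if usages else -1)
        p = crp_prior(lib, make_params(alpha=alpha, beta=beta))
        assert abs(p.sum() - 1.0) < 1e-9
        assert p.shape == (len(usages) + 1,)


class TestTransitionLikelihood:
    def test_all_zero_counts_uniform(self):
        lib = library_with_usage([1.0], active=0)
        p = transition_likelihood(lib, 0, 0, 2, make_params(lam=0.7))
        assert abs(p - 1 / 9) < 1e-12

    def test_hand_example(self):
        # M[i][j] = 4, row otherwise zero, lam = 1 -> 5/13
        lib = library_with_usage([1.0], active=0)
        for _ in range(4):
            lib.credit(0, 3, 5)
        p = transition_likelihood(lib, 0, 3, 5, make_params(lam=1.0))
        assert abs(p - 5 / 13) < 1e-12

    def test_new_slot_is_uniform(self):
        lib = library_with_usage([2.0], active=0)
        lib.credit(0, 3, 5)
        assert transition_likelihood(lib, 1, 3, 5, make_params()) == 1 / 9

    @given(st.lists(st.integers(0, 30), min_size=9, max_size=9),
           st.floats(0.01, 5))
    @settings(max_examples=50, deadline=None)
    def test_row_normalizes(self, row, lam):
        lib = library_with_usage([1.0], active=0)
        for j, c in enumerate(row):
            for _ in range(c):
                lib.credit(0, 4, j)
        params = make_params(lam=lam)
        total = sum(transition_likelihood(lib, 0, 4, j, params)
                    for j in range(9))
        assert abs(total - 1.0) < 1e-9

    def test_out_of_range_state_rejected(self):
        lib = library_with_usage([1.0], active=0)
        with pytest.raises(ValueError):
            transition_likelihood(lib, 0, 0, 9, make_params())


class TestInferStep:
    def test_first_transition_creates_schema(self):
        lib = SchemaLibrary()
        snap = infer_step(lib, (0, 1), make_params())
        assert snap.split and snap.switched
        assert lib.n_schemas == 1
        assert lib.counts[0][0][1] == 1 and lib.usage[0] == 1
        assert lib.active == 0 and lib.history == [0]

    def test_posterior_sums_to_one(self):
        lib = SchemaLibrary()
        params = make_params()
        rng = np.random.default_rng(1)
        for _ in range(3):
            process_story(lib, sample_story("A", rng), params)
        snap = infer_step(lib, (0, 2), params)
        assert abs(snap.probabilities.sum() - 1.0) < 1e-9

    def test_block_boundary_split(self, sim1_params):
        """After a 40-story single-chain block, the first transition of the
        other chain carries a large prediction error and spawns a new cause."""
        params = ModelParams(alpha=4.775, beta=96.792, lam=0.051,
                             inference_unit="transition")
        lib = SchemaLibrary()
        rng = np.random.default_rng(2)
        for _ in range(40):
            process_story(lib, sample_story("A", rng), params)
        assert lib.n_schemas == 1
        snap = infer_step(lib, (0, 2), params)
        assert snap.split and lib.n_schemas == 2

    def test_usage_counts_equal_inference_steps(self):
        lib = SchemaLibrary()
        params = make_params()
        rng = np.random.default_rng(3)
        for lab in ("A", "B", "A"):
            process_story(lib, sample_story(lab, rng), params)
        assert sum(lib.usage) == lib.total_inference_steps()
        total_counts = sum(lib.count_matrix(k).sum()
                           for k in range(lib.n_schemas))
        assert total_counts == lib.total_inference_steps()  # 4 per story


class TestBatchOracle:
    """Incremental posteriors equal a from-scratch batch recomputation.

    The oracle replays a recorded assignment history, rebuilding all
    count tables from nothing, and evaluates prior x likelihood
    directly from their defining formulas at every step.
    """

    @staticmethod
    def _oracle_posterior(assignments, transitions, t, params):
        """Posterior at step t given frozen history, from first principles."""
        S = 9
        K = len(set(assignments[:t]))
        counts = np.zeros((K + 1, S, S))
        usage = np.zeros(K + 1)
        for s, (i, j) in zip(assignments[:t], transitions[:t]):
            counts[s, i, j] += 1
            usage[s] += 1
        prev = assignments[t - 1] if t else None
        i, j = transitions[t]
        w = np.zeros(K + 1)
        for k in range(K):
            prior = usage[k] + (params.beta if k == prev else 0.0)
            lik = (params.lam + counts[k, i, j]) / (
                S * params.lam + counts[k, i].sum())
            w[k] = prior * lik
        w[K] = params.alpha * (1.0 / S)
        return w / w.sum() if w.sum() > 0 else np.eye(K + 1)[K]

    @pytest.mark.parametrize("labels", [("A",), ("A", "B"), ("A", "B", "A"),
                                        ("B", "B", "A")])
    @pytest.mark.parametrize("triple", [(1.703, 1.848, 0.211),
                                        (4.775, 96.792, 0.051),
                                        (0.5, 0.0, 1.0)])
    def test_incremental_equals_batch(self, labels, triple):
        a, b, l = triple
        params = make_params(alpha=a, beta=b, lam=l)
        lib = SchemaLibrary()
        rng = np.random.default_rng(42)
        transitions, snapshots = [], []
        for lab in labels:
            story = sample_story(lab, rng)
            recs = process_story(lib, story, params)
            for r in recs:
                transitions.append((r.from_state, r.to_state))
                snapshots.append(r.snapshot)
        assignments = lib.history
        assert len(assignments) == len(transitions)
        for t, snap in enumerate(snapshots):
            expected = self._oracle_posterior(assignments, transitions, t,
                                              params)
            assert np.allclose(snap.probabilities, expected, atol=1e-9), \
                f"posterior mismatch at step {t}"

    @pytest.mark.parametrize("labels", [("A",), ("A", "B"), ("B", "A", "A")])
    def test_story_unit_commit_equals_batch(self, labels, sim3_params):
        """Story-level commits match a from-scratch product-of-likelihood
        recomputation of the end-of-story posterior."""
        params = sim3_params  # story unit, skip active
        S = 9
        lib = SchemaLibrary()
        rng = np.random.default_rng(7)
        story_transitions, commit_snaps = [], []
        for lab in labels:
            recs = process_story(lib, sample_story(lab, rng), params)
            story_transitions.append([(r.from_state, r.to_state, r.skipped)
                                      for r in recs])
            commit_snaps.append(recs[-1].snapshot)
        commits = lib.history
        for t, snap in enumerate(commit_snaps):
            K = len(set(commits[:t]))
            counts = np.zeros((K + 1, S, S))
            usage = np.zeros(K + 1)
            for s, trs in zip(commits[:t], story_transitions[:t]):
                usage[s] += 1
                for (i, j, _) in trs:
                    counts[s, i, j] += 1
            prev = commits[t - 1] if t else None
            w = np.zeros(K + 1)
            for k in range(K):
                lik = 1.0
                for (i, j, skipped) in story_transitions[t]:
                    if skipped:
                        continue
                    lik *= (params.lam + counts[k, i, j]) / (
                        S * params.lam + counts[k, i].sum())
                    counts[k, i, j] += 1  # sequential predictive product
                prior = usage[k] + (params.beta if k == prev else 0.0)
                w[k] = prior * lik
                for (i, j, skipped) in story_transitions[t]:
                    if not skipped:
                        counts[k, i, j] -= 1
            n_terms = sum(1 for (_, _, sk) in story_transitions[t] if not sk)
            w[K] = params.alpha * (1.0 / S) ** n_terms
            expected = w / w.sum() if w.sum() > 0 else np.eye(K + 1)[K]
            assert np.allclose(snap.probabilities, expected, atol=1e-9), \
                f"commit posterior mismatch at story {t}"


class TestPrediction:
    def test_zero_counts_uniform(self):
        lib = library_with_usage([1.0], active=0)
        d = predict_distribution(lib, 3, make_params())
        assert np.allclose(d, np.full(9, 1 / 9))

    def test_saturated_softmax(self):
        # a 40-count row at temperature 4 -> e^10 / (e^10 + 8)
        lib = library_with_usage([1.0], active=0)
        for _ in range(40):
            lib.credit(0, 3, 5)
        d = predict_distribution(lib, 3, make_params(tau=4.0))
        assert abs(d[5] - math.exp(10) / (math.exp(10) + 8)) < 1e-12

    def test_softmax_shift_invariance(self):
        lib1 = library_with_usage([1.0], active=0)
        lib2 = library_with_usage([1.0], active=0)
        rng = np.random.default_rng(0)
        row = rng.integers(0, 10, size=9)
        for j, c in enumerate(row):
            for _ in range(c):
                lib1.credit(0, 4, j)
            for _ in range(c + 5):  # add the same constant to every score
                lib2.credit(0, 4, j)
        params = make_params()
        assert np.allclose(predict_distribution(lib1, 4, params),
                           predict_distribution(lib2, 4, params), atol=1e-12)

    def test_2afc_values(self):
        lib = library_with_usage([1.0], active=0)
        params = make_params(tau=4.0)
        assert predict_2afc(lib, 3, 5, 6, params) == 0.5
        for _ in range(40):
            lib.credit(0, 3, 5)
        p = predict_2afc(lib, 3, 5, 6, params)
        assert abs(p - math.exp(10) / (math.exp(10) + 1)) < 1e-9
        for _ in range(40):
            lib.credit(0, 3, 6)  # now 40 vs 40 -> symmetric
        assert predict_2afc(lib, 3, 5, 6, params) == 0.5
        with pytest.raises(ValueError):
            predict_2afc(lib, 3, 5, 5, params)

    def test_marginal_mode_mixes_schemas(self):
        lib = library_with_usage([5.0, 5.0], active=0)
        for _ in range(30):
            lib.credit(0, 3, 5)
            lib.credit(1, 3, 6)
        d = predict_distribution(lib, 3, make_params(predict_mode="marginal",
                                                     beta=0.0))
        assert abs(d.sum() - 1.0) < 1e-9
        assert np.isclose(d[5], d[6])  # equal priors, mirror evidence
        # active-only mode instead commits to schema 0's row
        da = predict_distribution(lib, 3, make_params())
        assert da[5] > 0.99


class TestProcessStory:
    def test_probed_records(self, rng):
        lib = SchemaLibrary()
        recs = process_story(lib, sample_story("A", rng), make_params())
        probed = [(r.from_state, r.to_state) for r in recs if r.probed]
        assert len(probed) == 2
        assert probed[0][0] in (3, 4) and probed[1][0] in (5, 6)
        assert all(0 <= r.p_2afc <= 1 for r in recs if r.probed)

    def test_first_story_probes_at_chance(self, rng):
        lib = SchemaLibrary()
        recs = process_story(lib, sample_story("B", rng), make_params())
        assert all(r.p_2afc == 0.5 for r in recs if r.probed)

    def test_terminal_state_dropped(self, rng):
        lib = SchemaLibrary()
        recs = process_story(lib, sample_story("A", rng), make_params())
        assert len(recs) == 4  # transitions 0->x, x->b, b->y, y->z
        assert all(r.to_state < 9 for r in recs)

    def test_skip_reduces_history(self, rng):
        params = make_params(skip_unpredictable=True)
        lib = SchemaLibrary()
        process_story(lib, sample_story("A", rng), params)
        assert lib.total_inference_steps() == 3  # not 4
        # the skipped transition is still credited to the active schema
        assert lib.count_matrix(0).sum() == 4

    def test_skip_without_crediting(self, rng):
        params = make_params(skip_unpredictable=True, credit_skipped=False)
        lib = SchemaLibrary()
        process_story(lib, sample_story("A", rng), params)
        assert lib.count_matrix(0).sum() == 3

    def test_delayed_skip_activates_after_40_same_chain(self):
        params = make_params(skip_unpredictable=True,
                             skip_after_first_block=True)
        lib = SchemaLibrary()
        rng = np.random.default_rng(0)
        for _ in range(40):
            process_story(lib, sample_story("A", rng), params)
        assert lib.skip_enabled
        before = lib.total_inference_steps()
        process_story(lib, sample_story("A", rng), params)
        assert lib.total_inference_steps() - before == 3  # now skipping

    def test_illegal_story_rejected(self):
        lib = SchemaLibrary()
        with pytest.raises(ValueError):
            process_story(lib, [5], make_params())


class TestLimitingBehaviour:
    def test_vanishing_concentration_never_splits(self):
        """alpha -> 0 forces over-lumping: one schema and chance accuracy."""
        from splitlearn import RunConfig, run_condition
        params = ModelParams(alpha=1e-12, beta=1.0, lam=0.3,
                             skip_unpredictable=True)
        cfg = RunConfig(base_params=params, condition_name="interleaved",
                        n_seeds=5, master_seed=0)
        res = run_condition(cfg)
        assert np.all(res.n_causes == 1)
        # single lumped schema -> near-chance on average (individual seeds
        # wobble with the random count imbalance of the 50/50 rows)
        assert abs(res.test_accuracy.mean() - 0.5) < 0.05
        assert np.all(np.abs(res.test_accuracy - 0.5) < 0.2)

    def test_huge_stickiness_pins_active_schema(self):
        """With beta ~ 1e6 the previous schema is re-selected at every
        within-story step once two schemas exist."""
        params = make_params(alpha=1.0, beta=1e6, lam=0.3)
        lib = SchemaLibrary()
        rng = np.random.default_rng(4)
        for lab in ("A",) * 5:
            process_story(lib, sample_story(lab, rng), params)
        assert lib.n_schemas == 1
        assert all(h == 0 for h in lib.history[1:])

    def test_determinism(self, sim2_params):
        from splitlearn import build_curriculum, run_seed
        cur = build_curriculum("interleaved", 9)
        t1, l1 = run_seed(sim2_params, cur, 9)
        t2, l2 = run_seed(sim2_params, cur, 9)
        assert np.array_equal(t1.values, t2.values)
        assert l1.history == l2.history

    def test_library_json_roundtrip(self, rng, sim2_params):
        lib = SchemaLibrary()
        for lab in ("A", "B", "A"):
            process_story(lib, sample_story(lab, rng), sim2_params)
        clone = SchemaLibrary.from_json(lib.to_json())
        assert clone.history == lib.history
        assert clone.counts == lib.counts
        assert clone.usage == lib.usage
        assert clone.active == lib.active
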