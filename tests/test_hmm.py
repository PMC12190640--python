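"""HMM correctness: FRET efficiency, EM fitting against closed forms and
exhaustive-enumeration oracles, model selection, Viterbi decoding, and
canonical state mapping."""

import itertools

import numpy as np
import pytest

import ribofret as rf
from ribofret._hmm_core import forward_backward, gaussian_loglik_matrix, viterbi_decode
from ribofret.hmm import (
    FretTrace,
    _suppress_single_frame_runs,
    compute_efret,
    fit_hmm_em,
    map_to_canonical,
    select_model,
    viterbi,
)
from ribofret.io import Trace

from conftest import two_state_trace


def make_ft(values, frame_rate=10.0):
    values = np.asarray(values, float)
    return FretTrace(
        "m", np.arange(len(values)) / frame_rate, values,
        np.ones(len(values), bool), frame_rate,
    )


# ---------------------------------------------------------------- oracles

def brute_force_loglik(x, means, variances, a, pi):
    """Total likelihood by explicit summation over all K^T paths."""
    k, t_len = len(means), len(x)
    total = 0.0
    for path in itertools.product(range(k), repeat=t_len):
        p = pi[path[0]] * gauss(x[0], means[path[0]], variances[path[0]])
        for t in range(1, t_len):
            p *= a[path[t - 1], path[t]] * gauss(x[t], means[path[t]], variances[path[t]])
        total += p
    return np.log(total)


def brute_force_viterbi(x, means, variances, a, pi):
    """Maximum path log-probability by explicit enumeration."""
    k, t_len = len(means), len(x)
    best = -np.inf
    for path in itertools.product(range(k), repeat=t_len):
        lp = np.log(pi[path[0]]) + np.log(gauss(x[0], means[path[0]], variances[path[0]]))
        for t in range(1, t_len):
            lp += np.log(a[path[t - 1], path[t]])
            lp += np.log(gauss(x[t], means[path[t]], variances[path[t]]))
        best = max(best, lp)
    return best


def gauss(x, mu, var):
    return np.exp(-0.5 * (x - mu) ** 2 / var) / np.sqrt(2 * np.pi * var)


def random_instance(rng, t_max=8, k_max=3):
    t_len = rng.integers(2, t_max + 1)
    k = rng.integers(1, k_max + 1)
    x = rng.uniform(-0.1, 1.1, t_len)
    means = np.sort(rng.uniform(0, 1, k))
    variances = rng.uniform(0.002, 0.05, k)
    a = rng.uniform(0.05, 1, (k, k))
    a /= a.sum(axis=1, keepdims=True)
    pi = rng.uniform(0.05, 1, k)
    pi /= pi.sum()
    return x, means, variances, a, pi


class TestComputeEfret:
    def test_basic_ratio(self):
        tr = Trace("m", [0.0], [200.0], [800.0], 10.0)
        assert compute_efret(tr).efret[0] == pytest.approx(0.8)

    def test_equal_channels_give_half(self):
        tr = Trace("m", [0.0, 0.1], [300.0, 300.0], [300.0, 300.0], 10.0)
        np.testing.assert_allclose(compute_efret(tr).efret, 0.5)

    def test_zero_acceptor_gives_zero(self):
        tr = Trace("m", [0.0], [500.0], [0.0], 10.0)
        assert compute_efret(tr).efret[0] == pytest.approx(0.0)

    def test_low_intensity_frames_invalid(self):
        donor = np.full(100, 500.0)
        acceptor = np.full(100, 500.0)
        donor[40:45] = 1.0
        acceptor[40:45] = 1.0
        tr = Trace("m", np.arange(100) / 10, donor, acceptor, 10.0)
        ft = compute_efret(tr)
        assert not ft.valid[40:45].any() and ft.valid.sum() == 95

    def test_all_invalid_is_error(self):
        tr = Trace("m", np.arange(3) / 10, np.zeros(3), np.zeros(3), 10.0)
        with pytest.raises(ValueError):
            compute_efret(tr)

    def test_clamped_to_window(self):
        tr = Trace("m", [0.0], [-100.0], [600.0], 10.0)  # ratio 1.2 -> clamp
        assert compute_efret(tr).efret[0] <= 1.2


class TestEmFit:
    def test_k1_closed_form(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0.5, 0.1, 400)
        m = fit_hmm_em(make_ft(x), k=1)
        assert m.means[0] == pytest.approx(x.mean(), abs=1e-9)
        assert m.variances[0] == pytest.approx(x.var(), rel=1e-6)

    def test_forward_loglik_matches_enumeration(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            x, means, var, a, pi = random_instance(rng)
            logb = gaussian_loglik_matrix(x, means, var)
            b = np.exp(logb - logb.max(axis=1, keepdims=True))
            ll, _, _ = forward_backward(b, a, pi)
            ll += logb.max(axis=1).sum()
            assert ll == pytest.approx(brute_force_loglik(x, means, var, a, pi), abs=1e-10)

    def test_em_loglik_monotone(self):
        """Baum-Welch never decreases the log-likelihood."""
        for seed in range(5):
            tr = two_state_trace(n_frames=300, seed=seed)
            ft = compute_efret(tr)
            for k in (1, 2, 3):
                m = fit_hmm_em(ft, k)
                diffs = np.diff(m.loglik_history)
                assert diffs.min() > -1e-7, f"seed={seed} K={k}: decrease {diffs.min()}"

    def test_two_state_mean_recovery(self):
        errs = []
        for seed in range(20):
            tr = two_state_trace(n_frames=1000, seed=seed)
            ft = compute_efret(tr)
            m = fit_hmm_em(ft, 2)
            errs.extend(np.abs(np.sort(m.means) - [0.2, 0.8]))
        assert np.mean(errs) <= 0.03

    def test_constant_trace_degenerate_flagged(self):
        m = fit_hmm_em(make_ft(np.full(50, 0.5)), k=2)
        assert m.degenerate

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError):
            fit_hmm_em(make_ft([0.1, 0.2, 0.3]), k=2)

    def test_label_permutation_leaves_idealized_unchanged(self):
        tr = two_state_trace(n_frames=500, seed=3)
        ft = compute_efret(tr)
        m = fit_hmm_em(ft, 2)
        path = viterbi(m, ft)
        perm = [1, 0]
        m.means = m.means[perm]
        m.variances = m.variances[perm]
        m.transition_matrix = m.transition_matrix[np.ix_(perm, perm)]
        m.initial_probs = m.initial_probs[perm]
        path2 = viterbi(m, ft)
        np.testing.assert_allclose(path.idealized_efret, path2.idealized_efret)


class TestSelectModel:
    def test_constant_noiseless_trace_selects_one_state(self):
        m = select_model(make_ft(np.full(200, 0.7)))
        assert m.n_states == 1

    def test_two_state_trace_prefers_two_over_three(self):
        tr = two_state_trace(n_frames=1000, seed=4)
        ft = compute_efret(tr)
        m2 = fit_hmm_em(ft, 2)
        m3 = fit_hmm_em(ft, 3)
        assert m2.bic < m3.bic

    def test_three_state_trace_selects_three(self):
        """BIC selects K=3 on long three-state traces in >=90% of replicates."""
        fix = rf.get_fixture("noMg_occupancy")
        emission = fix.emission
        rm = fix.rate_matrix()
        rng = np.random.default_rng(5)
        hits = 0
        n_rep = 30
        for _ in range(n_rep):
            cps, states = rf.simulate_state_path(rm, 100.0, rng)
            while len(np.unique(states)) < 3:  # ensure all states visited
                cps, states = rf.simulate_state_path(rm, 100.0, rng)
            occ = rf.discretize_path(cps, states, 3, 100.0, 0.1)
            tr = rf.emit_trace(occ, emission, rng)
            m = select_model(compute_efret(tr))
            hits += m.n_states == 3
        assert hits >= 0.9 * n_rep


class TestViterbi:
    def test_k1_all_frames_state_zero(self):
        ft = make_ft(np.linspace(0.4, 0.6, 30))
        m = fit_hmm_em(ft, 1)
        assert np.all(viterbi(m, ft).states == 0)

    def test_matches_exhaustive_maximum(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            x, means, var, a, pi = random_instance(rng)
            logb = gaussian_loglik_matrix(x, means, var)
            path, lp = viterbi_decode(logb, np.log(a), np.log(pi))
            assert lp == pytest.approx(brute_force_viterbi(x, means, var, a, pi), abs=1e-10)

    def test_noiseless_well_separated_path_exact(self):
        x = np.array([0.2] * 20 + [0.8] * 20 + [0.2] * 10)
        ft = make_ft(x)
        m = fit_hmm_em(ft, 2)
        path = viterbi(m, ft)
        expected = np.array([0] * 20 + [1] * 20 + [0] * 10)
        order = np.argsort(m.means)
        np.testing.assert_array_equal(order[path.states], expected)


class TestCanonicalMapping:
    def path_with_means(self, means, states):
        means = np.asarray(means, float)
        states = np.asarray(states, int)
        return rf.IdealizedPath("m", states, means[states], means, 10.0)

    def test_three_means_map_to_three_labels(self):
        p = self.path_with_means([0.21, 0.58, 0.83], [0, 1, 2, 1, 0])
        p = map_to_canonical(p, suppress_blur=False)
        assert list(p.canonical_labels) == [0, 1, 2, 1, 0]

    def test_tie_maps_to_lower_center(self):
        p = self.path_with_means([0.4], [0, 0])
        p = map_to_canonical(p, suppress_blur=False)
        assert np.all(p.canonical_labels == 0)  # 0.4 equidistant -> apo

    def test_nearby_means_merge_to_static(self):
        p = self.path_with_means([0.18, 0.25], [0, 1, 0, 1, 0, 1])
        p = map_to_canonical(p)
        assert np.all(p.canonical_labels == 0)
        assert p.n_transitions == 0

    def test_blur_frame_folded_into_next_dwell(self):
        # apo ... one transit frame ... holo: the single frame joins holo
        labels = np.array([0] * 10 + [1] + [2] * 10)
        cleaned = _suppress_single_frame_runs(labels)
        np.testing.assert_array_equal(cleaned, [0] * 10 + [2] * 11)

    def test_flicker_round_trip_erased(self):
        labels = np.array([2] * 10 + [0] + [2] * 10)
        cleaned = _suppress_single_frame_runs(labels)
        np.testing.assert_array_equal(cleaned, [2] * 21)

    def test_real_dwells_untouched(self):
        labels = np.array([0] * 5 + [1] * 3 + [2] * 4)
        np.testing.assert_array_equal(_suppress_single_frame_runs(labels), labels)
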