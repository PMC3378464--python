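import numpy as np
import pytest

from nucstruct.calls import ReferenceMap, check_non_overlapping
from nucstruct.hmm import (
    NucleosomeHMM,
    allowed_transitions,
    labels_to_state_path,
    path_to_calls,
)
from nucstruct.profiles import BinnedTrack

from .conftest import make_profile
from .oracles import viterbi_bruteforce


def track(n_bins, chrom="chrT"):
    return BinnedTrack(
        chrom=chrom, values=np.zeros(n_bins), origin_bp=0, step_bp=10, window_bp=100
    )


def random_model(rng, n_channels=2, allow_abutting=True):
    """A NucleosomeHMM with random (legal) parameters, no fitting."""
    m = NucleosomeHMM(allow_abutting=allow_abutting)
    mask = allowed_transitions(allow_abutting)
    trans = np.zeros((16, 16))
    for s in range(16):
        allowed = np.flatnonzero(mask[s])
        w = rng.random(len(allowed)) + 0.1
        trans[s, allowed] = w / w.sum()
    m.transitions_ = trans
    m.transition_mask_ = mask
    start = rng.random(16) + 0.05
    m.start_probs_ = start / start.sum()
    m.means_ = rng.normal(0, 2, size=(16, n_channels))
    m.variances_ = rng.uniform(0.3, 2.0, size=(16, n_channels))
    m.n_channels_ = n_channels
    return m


class TestLabels:
    def test_single_nucleosome_path(self):
        t = track(60)
        ref = ReferenceMap({"chrT": [300]})
        path = labels_to_state_path(ref, t)
        nuc = np.flatnonzero(path)
        assert len(nuc) == 15
        assert np.array_equal(path[nuc], np.arange(1, 16))
        assert path[: nuc[0]].sum() == 0 and path[nuc[-1] + 1 :].sum() == 0

    def test_empty_reference_all_linker(self):
        assert labels_to_state_path(ReferenceMap({}), track(30)).sum() == 0

    def test_adjacent_nucleosomes_leave_linker_gap(self):
        # 147-bp cores with a 20-bp linker: centers 167 bp apart
        ref = ReferenceMap({"chrT": [300, 467]})
        path = labels_to_state_path(ref, track(80))
        i15 = np.flatnonzero(path == 15)[0]
        after = path[i15 + 1 :]
        i1 = np.flatnonzero(after == 1)[0]
        assert i1 >= 1  # at least one linker bin between the runs
        assert np.all(after[:i1] == 0)

    def test_overlapping_reference_errors(self):
        ref = ReferenceMap({"chrT": [300, 360]})
        with pytest.raises(ValueError, match="overlap"):
            labels_to_state_path(ref, track(80))

    def test_truncated_nucleosome_skipped(self):
        ref = ReferenceMap({"chrT": [60]})  # window extends before the track
        path = labels_to_state_path(ref, track(40))
        assert path.sum() == 0


def synthetic_observations(rng, n_nuc=20, linker_bins=3, sep=3.0):
    """Observations with well separated state means, plus the true path."""
    path = []
    for _ in range(n_nuc):
        path.extend([0] * linker_bins)
        path.extend(range(1, 16))
    path.extend([0] * linker_bins)
    path = np.array(path)
    means = np.linspace(0, sep * 15, 16)  # distinct mean per state
    X = means[path][:, None] + rng.normal(0, 0.5, size=(len(path), 1))
    return X, path


class TestTraining:
    def test_recovers_state_means(self):
        rng = np.random.default_rng(0)
        X, path = synthetic_observations(rng)
        m = NucleosomeHMM().fit(X, path)
        means = np.linspace(0, 45, 16)
        for s in range(16):
            n_s = (path == s).sum()
            se = 0.5 / np.sqrt(n_s)
            assert abs(m.means_[s, 0] - means[s]) < 3 * se + 1e-9

    def test_unused_transition_gets_smoothing_floor(self):
        rng = np.random.default_rng(1)
        X, path = synthetic_observations(rng)  # never uses N15 -> N1
        m = NucleosomeHMM().fit(X, path)
        n15_total = (path[:-1] == 15).sum()
        assert m.transitions_[15, 1] == pytest.approx(1.0 / (n15_total + 2))

    def test_linker_self_loop_probability_consistent(self):
        rng = np.random.default_rng(2)
        X, path = synthetic_observations(rng, n_nuc=5, linker_bins=50)
        m = NucleosomeHMM().fit(X, path)
        stays = ((path[:-1] == 0) & (path[1:] == 0)).sum()
        leaves = ((path[:-1] == 0) & (path[1:] == 1)).sum()
        assert m.transitions_[0, 0] == pytest.approx(
            (stays + 1) / (stays + leaves + 2)
        )

    def test_understaffed_state_errors(self):
        # one complete run: every nucleosome state has a single bin
        path = np.concatenate([[0, 0], np.arange(1, 16), [0, 0]])
        X = np.zeros((len(path), 1))
        with pytest.raises(ValueError, match="state .* bin"):
            NucleosomeHMM().fit(X, path)

    def test_illegal_training_transition_errors(self):
        X = np.zeros((4, 1))
        with pytest.raises(ValueError, match="illegal"):
            NucleosomeHMM().fit(X, [0, 1, 5, 6])

    def test_transition_rows_sum_to_one(self):
        rng = np.random.default_rng(3)
        X, path = synthetic_observations(rng)
        m = NucleosomeHMM().fit(X, path)
        assert np.allclose(m.transitions_.sum(axis=1), 1.0)
        assert np.all(m.variances_ > 0)


class TestViterbi:
    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_bruteforce_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(25):
            m = random_model(rng, n_channels=int(rng.integers(1, 3)))
            n = int(rng.integers(2, 9))
            X = rng.normal(0, 3, size=(n, m.n_channels_))
            lp, path = m.decode(X)
            blp, bpath = viterbi_bruteforce(m, X)
            assert lp == pytest.approx(blp, abs=1e-9)
            assert m.path_log_prob(X, path) == pytest.approx(blp, abs=1e-9)

    def test_decoded_path_beats_generating_path(self):
        rng = np.random.default_rng(5)
        X, true_path = synthetic_observations(rng, n_nuc=8)
        m = NucleosomeHMM().fit(X, true_path)
        lp, path = m.decode(X)
        assert lp >= m.path_log_prob(X, true_path) - 1e-9

    def test_separated_means_recover_complete_runs(self):
        rng = np.random.default_rng(6)
        X, true_path = synthetic_observations(rng, n_nuc=10)
        m = NucleosomeHMM().fit(X, true_path)
        path = m.predict(X)
        assert np.mean(path == true_path) > 0.95

    def test_uniform_emissions_follow_transitions(self):
        rng = np.random.default_rng(7)
        m = random_model(rng, n_channels=1)
        m.means_[:] = 0.0
        m.variances_[:] = 1.0
        # linker-dominant start and self-loop (note Nk -> Nk+1 is forced,
        # so entering a nucleosome must be penalised at the start/entry)
        start = np.full(16, 0.01 / 15)
        start[0] = 0.99
        m.start_probs_ = start
        m.transitions_[0, 0], m.transitions_[0, 1] = 0.999, 0.001
        X = np.zeros((10, 1))
        path = m.predict(X)
        assert np.all(path == 0)

    def test_masked_channels_ignored(self):
        rng = np.random.default_rng(8)
        X, true_path = synthetic_observations(rng, n_nuc=6)
        m = NucleosomeHMM().fit(X, true_path)
        X2 = np.column_stack([X, np.full(len(X), np.nan)])
        m2 = NucleosomeHMM().fit(
            np.column_stack([X, rng.normal(size=len(X))]), true_path
        )
        m2.means_[:, 0] = m.means_[:, 0]
        m2.variances_[:, 0] = m.variances_[:, 0]
        assert np.array_equal(m2.predict(X2), m.predict(X))


class TestCalls:
    def test_single_run_centered(self):
        path = np.zeros(40, dtype=int)
        path[10:25] = np.arange(1, 16)
        t = track(40)
        calls = path_to_calls(path, t)
        assert len(calls) == 1
        assert calls[0].center_bp == int((t.coords()[10] + t.coords()[24]) / 2)

    def test_all_linker_no_calls(self):
        assert path_to_calls(np.zeros(30, dtype=int), track(30)) == []

    def test_incomplete_run_discarded(self):
        path = np.zeros(20, dtype=int)
        path[12:] = np.arange(1, 9)  # truncated at the end
        assert path_to_calls(path, track(20)) == []

    def test_abutting_runs_give_two_calls(self):
        path = np.concatenate(
            [np.zeros(5, dtype=int), np.arange(1, 16), np.arange(1, 16), np.zeros(5, dtype=int)]
        )
        calls = path_to_calls(path, track(len(path)))
        assert len(calls) == 2
        check_non_overlapping(calls)

    def test_roundtrip_recovers_interior_centers(self):
        t = track(200)
        centers = [400, 600, 800, 1200]
        ref = ReferenceMap({"chrT": centers})
        path = labels_to_state_path(ref, t)
        calls = path_to_calls(path, t)
        assert len(calls) == len(centers)
        for call, c in zip(calls, centers):
            assert abs(call.center_bp - c) <= t.step_bp / 2
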