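import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rdikit import (
    DataError,
    FeatureCountTable,
    PerturbationVector,
    ProbabilityVector,
    baseline_from_counts,
    draw_repertoire,
    geometric_baseline,
    null_split,
    perturb,
    perturbation_with_deviation,
    sample_perturbation,
    simulate_perturbed_set,
    true_deviation,
)


class TestBaseline:
    def test_baseline_from_counts_hand_average(self):
        t = FeatureCountTable(["a", "b"], ["V1", "V2"], np.array([[1, 1], [3, 1]]))
        # freqs [.5,.5] and [.75,.25] -> mean [.625,.375]
        assert baseline_from_counts(t).probs.tolist() == [0.625, 0.375]

    def test_single_row(self):
        t = FeatureCountTable(["a"], ["V1", "V2"], np.array([[2, 2]]))
        assert baseline_from_counts(t).probs.tolist() == [0.5, 0.5]

    def test_geometric_baseline_shape(self):
        b = geometric_baseline(50)
        assert len(b) == 50
        assert b.probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert (np.diff(b.probs) < 0).all()


class TestPerturbation:
    def test_sigma_zero_gives_zero_vector(self):
        r = sample_perturbation(5, 0.0, np.random.default_rng(0))
        assert (r.r == 0).all()

    def test_half_normal_mean(self):
        r = sample_perturbation(10_000, 1.0, np.random.default_rng(1))
        assert np.abs(r.r).mean() == pytest.approx(np.sqrt(2 / np.pi), abs=0.02)

    def test_perturb_hand_values(self):
        p = ProbabilityVector(np.array([0.5, 0.5]))
        out = perturb(p, PerturbationVector(np.array([1.0, -1.0])))
        assert out.probs == pytest.approx([0.8, 0.2], rel=1e-12)
        out2 = perturb(
            ProbabilityVector(np.array([0.25, 0.75])),
            PerturbationVector(np.array([2.0, 0.0])),
        )
        assert out2.probs == pytest.approx([1.0 / 1.75, 0.75 / 1.75], rel=1e-12)

    def test_perturb_identity_and_shift_invariance(self):
        p = ProbabilityVector(np.array([0.2, 0.3, 0.5]))
        assert perturb(p, PerturbationVector(np.zeros(3))).probs == pytest.approx(
            p.probs, rel=1e-12
        )
        r = np.array([0.4, -1.2, 0.7])
        a = perturb(p, PerturbationVector(r))
        b = perturb(p, PerturbationVector(r + 3.33))
        assert a.probs == pytest.approx(b.probs, rel=1e-9)

    def test_zero_baseline_entries_stay_zero(self):
        p = ProbabilityVector(np.array([0.0, 0.4, 0.6]))
        out = perturb(p, PerturbationVector(np.array([5.0, 0.0, 0.0])))
        assert out.probs[0] == 0.0


class TestTrueDeviation:
    def test_identity_is_zero(self):
        p = ProbabilityVector(np.array([0.3, 0.7]))
        assert true_deviation(p, p, "log2fc") == pytest.approx(0.0, abs=1e-9)
        assert true_deviation(p, p, "pct_change") == pytest.approx(0.0, abs=1e-9)

    def test_hand_values(self):
        base = ProbabilityVector(np.array([0.5, 0.5]))
        fc = ProbabilityVector(np.array([0.8, 0.2]))
        assert true_deviation(fc, base, "log2fc") == pytest.approx(1.0, rel=1e-12)
        assert true_deviation(fc, base, "pct_change") == pytest.approx(60.0, rel=1e-12)

    def test_targeted_perturbation_hits_requested_deviation(self):
        base = geometric_baseline(30)
        rng = np.random.default_rng(5)
        for target in [0.5, 2.0, 6.0]:
            _, p_fc = perturbation_with_deviation(base, target, rng)
            assert true_deviation(p_fc, base, "log2fc") == pytest.approx(
                target, abs=1e-9
            )


class TestDrawAndSplit:
    def test_point_mass(self):
        p = ProbabilityVector(np.array([1.0, 0.0, 0.0]))
        assert draw_repertoire(p, 10, np.random.default_rng(0)).tolist() == [10, 0, 0]

    def test_single_draw_is_one_hot(self):
        p = geometric_baseline(8)
        out = draw_repertoire(p, 1, np.random.default_rng(0))
        assert out.sum() == 1 and (out >= 0).all()

    def test_binomial_moments(self):
        p = ProbabilityVector(np.array([0.5, 0.5]))
        rng = np.random.default_rng(2)
        draws = np.array([draw_repertoire(p, 10_000, rng)[0] for _ in range(1000)])
        assert draws.mean() == pytest.approx(5000, abs=10)
        assert draws.std() == pytest.approx(50, rel=0.15)

    @given(st.lists(st.integers(0, 50), min_size=2, max_size=6), st.data())
    @settings(max_examples=50, deadline=None)
    def test_null_split_conserves_counts(self, counts, data):
        counts = np.array(counts)
        if counts.sum() < 2:
            counts[0] += 2
        m = data.draw(st.integers(1, int(counts.sum()) - 1))
        a, b = null_split(counts, m, np.random.default_rng(9))
        assert a.sum() == m
        assert ((a + b) == counts).all()

    def test_forced_split(self):
        a, b = null_split(np.array([4, 0]), 2, np.random.default_rng(0))
        assert a.tolist() == [2, 0] and b.tolist() == [2, 0]

    def test_invalid_split_size(self):
        with pytest.raises(DataError):
            null_split(np.array([2, 2]), 4, np.random.default_rng(0))


class TestSimulatedSet:
    def test_truth_bookkeeping(self):
        base = geometric_baseline(20)
        sim = simulate_perturbed_set(
            base, [0.0, 0.5, 1.0, 2.0], 500, 3, np.random.default_rng(3)
        )
        assert sim.counts.n_repertoires == 7
        assert (sim.counts.row_sums() == 500).all()
        assert sim.truth["perturbed_1"] == (0.0, 0.0)  # sigma 0 -> no change
        for k in range(1, 4):
            assert sim.truth[f"baseline_{k}"] == (0.0, 0.0)
        assert all(sim.truth[f"perturbed_{k}"][0] > 0 for k in (2, 3, 4))

    def test_larger_sigma_gives_larger_deviation_stochastically(self):
        base = geometric_baseline(20)
        rng = np.random.default_rng(17)
        low, high = [], []
        for _ in range(200):
            lo = perturb(base, sample_perturbation(20, 0.5, rng))
            hi = perturb(base, sample_perturbation(20, 2.0, rng))
            low.append(true_deviation(lo, base, "log2fc"))
            high.append(true_deviation(hi, base, "log2fc"))
        from scipy.stats import mannwhitneyu

        assert mannwhitneyu(high, low, alternative="greater").pvalue < 1e-6

    def test_airr_round_trip(self, tmp_path):
        from rdikit import counts_to_airr, read_airr, tabulate_features

        base = geometric_baseline(6)
        sim = simulate_perturbed_set(base, [1.0], 40, 2, np.random.default_rng(1))
        path = tmp_path / "sim.tsv"
        counts_to_airr(sim.counts, path)
        parsed = tabulate_features(
            read_airr(path, id_column="repertoire_id", feature_columns=["v_call"]),
            "v_call",
            level="gene",
        )
        orig = sim.counts.to_dataframe().sort_index()
        back = parsed.to_dataframe().sort_index()
        # drop all-zero columns the TSV cannot represent
        orig = orig.loc[:, orig.sum() > 0]
        assert (orig.values == back[orig.columns].values).all()
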