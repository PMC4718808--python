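import numpy as np
import pandas as pd
import pingouin as pg
import pytest

from spikerhythm.stats import (amplitude_comodulation, chisq_contingency,
                               chisq_pairwise_posthoc, chisq_uniform,
                               circular_correlation, paired_magnitude_tests,
                               rm_anova_one_factor, rm_anova_two_factor,
                               solve_category_counts)

# published interneuron / principal-cell category populations, reported as
# (N_total, N_correct-v-incorrect, N_correct-v-all, N_incorrect-v-all)
POPULATIONS = {
    "int_theta": (126, 42, 124, 86),
    "int_beta": (66, 53, 62, 17),
    "int_low_gamma": (91, 49, 88, 45),
    "int_high_gamma": (107, 71, 104, 39),
    "pc_theta": (349, 298, 311, 89),
    "pc_beta": (91, 88, 76, 18),
    "pc_high_gamma": (134, 128, 116, 24),
}


class TestChiSquare:
    def test_uniform_counts_give_zero(self):
        chi2, df, p = chisq_uniform([22, 22, 22])
        assert chi2 == 0.0 and df == 2 and p == pytest.approx(1.0)

    @pytest.mark.parametrize("pop,expected", [
        ("int_beta", 51.54), ("int_theta", 80.19), ("int_low_gamma", 37.21),
        ("int_high_gamma", 59.23), ("pc_theta", 266.86), ("pc_beta", 92.40),
    ])
    def test_published_omnibus_values(self, pop, expected):
        counts = solve_category_counts(*POPULATIONS[pop])
        chi2, df, _ = chisq_uniform(counts)
        assert df == 2
        # agreement at the printed two-decimal precision (the published
        # 51.54 for beta is a truncation of 51.5455)
        assert chi2 == pytest.approx(expected, abs=0.01)

    @pytest.mark.parametrize("counts,expected", [
        ((49, 4), 38.21),    # beta correct vs incorrect
        ((2, 84), 78.19),    # theta incorrect vs all
        ((10, 10), 0.0),
    ])
    def test_pairwise_posthoc_values(self, counts, expected):
        chi2, df, _ = chisq_uniform(counts)
        assert df == 1
        assert round(chi2, 2) == pytest.approx(expected, abs=0.005)

    def test_posthoc_structure(self):
        rows = chisq_pairwise_posthoc(solve_category_counts(
            *POPULATIONS["int_beta"]))
        assert len(rows) == 3
        assert all(r["adjusted_alpha"] == pytest.approx(0.05 / 3)
                   for r in rows)
        by_pair = {r["pair"]: r for r in rows}
        assert round(by_pair[(0, 1)]["chi2"], 2) == 38.21
        assert by_pair[(0, 1)]["significant"]
        assert not by_pair[(1, 2)]["significant"]  # 4.77, p=0.029 > 0.05/3

    def test_contingency_published_value(self):
        theta = solve_category_counts(*POPULATIONS["int_theta"])
        beta = solve_category_counts(*POPULATIONS["int_beta"])
        chi2, df, _ = chisq_contingency([theta, beta])
        assert df == 2
        assert round(chi2, 2) == pytest.approx(38.56, abs=0.005)

    def test_contingency_edge_cases(self):
        assert chisq_contingency([[5, 6, 7], [5, 6, 7]])[0] == pytest.approx(0.0)
        assert chisq_contingency([[10, 0], [0, 10]])[0] == pytest.approx(20.0)
        with pytest.raises(ValueError):
            chisq_contingency([[1, 0], [2, 0]])

    def test_matches_brute_force_pearson(self, rng):
        """Exhaustive-style oracle: direct sum (O-E)^2/E on small tables."""
        for _ in range(50):
            counts = rng.integers(1, 11, size=3)
            chi2, _, _ = chisq_uniform(counts)
            e = counts.sum() / 3
            assert chi2 == pytest.approx(np.sum((counts - e) ** 2 / e))
            table = rng.integers(1, 11, size=(2, 3))
            chi2, _, _ = chisq_contingency(table)
            exp = np.outer(table.sum(1), table.sum(0)) / table.sum()
            assert chi2 == pytest.approx(np.sum((table - exp) ** 2 / exp))

    def test_solved_counts_consistent_for_all_populations(self):
        expected = {
            "int_theta": (40, 2, 84), "int_beta": (49, 4, 13),
            "int_low_gamma": (46, 3, 42), "int_high_gamma": (68, 3, 36),
            "pc_theta": (260, 38, 51), "pc_beta": (73, 15, 3),
            "pc_high_gamma": (110, 18, 6)}
        for pop, ns in POPULATIONS.items():
            assert solve_category_counts(*ns) == expected[pop]
        with pytest.raises(ValueError):
            solve_category_counts(120, 116, 101, 21)  # inconsistent printed Ns

    def test_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            chisq_uniform([0, 0, 0])


class TestCircularCorrelation:
    def test_shifted_angles_perfectly_correlated(self, rng):
        a = rng.vonmises(0.0, 1.0, 50)
        r, p = circular_correlation(a, np.angle(np.exp(1j * (a + 1.0))))
        assert r == pytest.approx(1.0)
        assert p < 0.01

    def test_mirrored_angles_anticorrelated(self, rng):
        a = rng.vonmises(0.0, 1.0, 50)
        r, _ = circular_correlation(a, -a)
        assert r == pytest.approx(-1.0)

    def test_independent_angles_near_zero(self, rng):
        hits = 0
        for _ in range(100):
            a = rng.uniform(-np.pi, np.pi, 1000)
            b = rng.uniform(-np.pi, np.pi, 1000)
            r, _ = circular_correlation(a, b)
            hits += abs(r) < 0.1
        assert hits >= 95

    def test_matches_pingouin(self, rng):
        a = rng.vonmises(0.0, 2.0, 80)
        b = np.angle(np.exp(1j * (0.8 * a + rng.vonmises(0.0, 3.0, 80))))
        r, _ = circular_correlation(a, b)
        r_ref = pg.circ_corrcc(a, b)[0]
        assert r == pytest.approx(r_ref, abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            circular_correlation(np.zeros(10), np.linspace(0, 1, 10))
        with pytest.raises(ValueError):
            circular_correlation(np.zeros(3), np.zeros(3))


class TestPairedTests:
    def test_identical_pairs_null(self):
        out = paired_magnitude_tests(np.ones(10), np.ones(10))
        assert out["z"] == 0.0 and out["p"] == 1.0

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            paired_magnitude_tests(np.ones(3), np.zeros(3))

    def test_shift_detected_with_power(self, rng):
        rejections = 0
        for _ in range(50):
            x = rng.uniform(0.05, 0.4, 60)
            y = x - 0.05 + rng.normal(0, 0.02, 60)
            out = paired_magnitude_tests(x, y)
            rejections += out["p"] < 0.05
        assert rejections / 50 > 0.9

    def test_reports_medians(self, rng):
        x, y = rng.uniform(0, 1, 20), rng.uniform(0, 1, 20)
        out = paired_magnitude_tests(x, y)
        assert out["median_correct"] == pytest.approx(np.median(x))


def _comod_trials(onsets):
    return pd.DataFrame({"trial": range(len(onsets)), "onset": onsets,
                         "outcome": "correct", "odor": "A", "position": 1,
                         "context": 1, "block": 0})


class TestComodulation:
    FS = 200.0

    def _amp(self, rng, n, envelope=None):
        base = 1.0 + 0.2 * rng.standard_normal(n)
        if envelope is not None:
            base = base + envelope
        return np.abs(base)

    def test_identical_traces_flagged(self, rng):
        n = int(120 * self.FS)
        x = self._amp(rng, n)
        out = amplitude_comodulation({"theta": x, "beta": x.copy()},
                                     self.FS, _comod_trials([20.0, 60.0, 90.0]),
                                     n_jitters=100, rng=1, margin_s=10.0)
        row = out.iloc[0]
        assert row["r"] == pytest.approx(1.0)
        assert row["outside_null"]

    def test_independent_traces_within_null(self, rng):
        n = int(120 * self.FS)
        flags = []
        for k in range(20):
            out = amplitude_comodulation(
                {"theta": self._amp(rng, n), "beta": self._amp(rng, n)},
                self.FS, _comod_trials([20.0, 60.0, 90.0]),
                n_jitters=60, rng=k, margin_s=10.0)
            flags.append(out.iloc[0]["outside_null"])
        assert np.mean(flags) <= 0.25

    def test_shared_slow_envelope_flagged(self, rng):
        # aperiodic shared slow envelope (smoothed noise): circular shifts
        # decorrelate it, so the observed correlation escapes the null band
        from scipy.ndimage import gaussian_filter1d
        n = int(120 * self.FS)
        env = gaussian_filter1d(rng.standard_normal(n), sigma=0.3 * self.FS)
        env = 0.8 * env / env.std()
        out = amplitude_comodulation(
            {"theta": self._amp(rng, n, env), "beta": self._amp(rng, n, env)},
            self.FS, _comod_trials(list(np.arange(15.0, 105.0, 7.5))),
            n_jitters=100, rng=2, margin_s=10.0)
        row = out.iloc[0]
        assert row["r"] > 0.3 and row["outside_null"]

    def test_no_correct_trials_rejected(self, rng):
        tr = _comod_trials([20.0])
        tr["outcome"] = "incorrect"
        with pytest.raises(ValueError):
            amplitude_comodulation({"a": np.ones(1000), "b": np.ones(1000)},
                                   self.FS, tr, 10, 0, margin_s=1.0)


class TestRmAnova:
    def test_all_equal_data_gives_zero_F(self):
        out = rm_anova_two_factor(np.ones((5, 6, 2)))
        assert all(v["F"] == 0.0 and v["p"] == 1.0 for v in out.values())
        one = rm_anova_one_factor(np.ones((5, 6)))
        assert one["F"] == 0.0

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            rm_anova_two_factor(np.zeros((1, 6, 2)))
        with pytest.raises(ValueError):
            rm_anova_one_factor(np.zeros((1, 6)))

    def test_missing_cells_rejected(self):
        bad = np.ones((4, 6, 2))
        bad[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            rm_anova_two_factor(bad)

    def test_matches_pingouin_two_factor(self, rng):
        data = rng.standard_normal((8, 4, 2)) + \
            np.linspace(0, 1, 4)[None, :, None]
        out = rm_anova_two_factor(data)
        n, a, b = data.shape
        long = pd.DataFrame({
            "subj": np.repeat(np.arange(n), a * b),
            "A": np.tile(np.repeat(np.arange(a), b), n),
            "B": np.tile(np.arange(b), n * a),
            "y": data.ravel()})
        ref = pg.rm_anova(long, dv="y", within=["A", "B"], subject="subj",
                          detailed=True)
        for name, key in (("A", "A"), ("B", "B"), ("A * B", "AxB")):
            row = ref[ref["Source"] == name].iloc[0]
            assert out[key]["F"] == pytest.approx(row["F"], rel=1e-6)
            assert out[key]["p"] == pytest.approx(row["p_unc"], rel=1e-6)

    def test_matches_pingouin_one_factor(self, rng):
        data = rng.standard_normal((10, 6))
        out = rm_anova_one_factor(data)
        n, k = data.shape
        long = pd.DataFrame({
            "subj": np.repeat(np.arange(n), k),
            "lvl": np.tile(np.arange(k), n),
            "y": data.ravel()})
        ref = pg.rm_anova(long, dv="y", within="lvl", subject="subj")
        assert out["F"] == pytest.approx(ref["F"].iloc[0], rel=1e-6)
        assert out["p"] == pytest.approx(ref["p_unc"].iloc[0], rel=1e-6)

    def test_one_elevated_level_detected(self, rng):
        rejections = 0
        for _ in range(20):
            data = rng.normal(0.2, 0.1, (50, 6))
            data[:, 2] += 0.1
            rejections += rm_anova_one_factor(data)["p"] < 0.05
        assert rejections == 20
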