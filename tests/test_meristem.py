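"""Mixture fitting, zonation scan rules and positional smoothing."""

import numpy as np
import pytest

from seedscreen.errors import InputError, NotFoundSignal
from seedscreen.meristem import (
    GmmFit,
    classify_meristematic,
    count_isodiametric,
    count_transition,
    first_elongated_length,
    fit_two_gaussian_em,
    mature_cell_length,
    mitotic_summary,
    positional_curve,
    posterior_short,
)
from seedscreen.synthgen import CellFile


def bimodal_sample(rng, n_short=200, n_long=100, mu=(8.0, 60.0), sd=(1.5, 15.0)):
    x = np.concatenate([rng.normal(mu[0], sd[0], n_short),
                        rng.normal(mu[1], sd[1], n_long)])
    return np.abs(x) + 1e-6


def make_file(lengths, widths, root_id="r1"):
    return CellFile(root_id, "dark", "wt", np.asarray(lengths, float),
                    np.asarray(widths, float))


def iso_oracle(lengths, widths):
    """Independent scan: position of the first longer-than-wide cell."""
    flags = [ln <= w for ln, w in zip(lengths, widths)]
    return flags.index(False) if False in flags else len(flags)


def transition_oracle(lengths, widths):
    """Independent scan built from explicit ratio flags."""
    starts = [i for i, (ln, w) in enumerate(zip(lengths, widths)) if ln > w]
    if not starts:
        return 0
    s = starts[0]
    ok = [lengths[i] < 1.5 * lengths[i - 1] for i in range(s + 1, len(lengths))]
    count = 1
    for flag in ok:
        if not flag:
            break
        count += 1
    return count


class TestEM:
    def test_parameter_recovery(self, rng):
        fit = fit_two_gaussian_em(bimodal_sample(rng), seed=0)
        assert fit.converged
        assert fit.mu_short == pytest.approx(8.0, rel=0.1)
        assert fit.mu_long == pytest.approx(60.0, rel=0.1)
        assert 0.55 < fit.weight_short < 0.8  # 200 of 300 cells are short

    def test_loglikelihood_monotone(self, rng):
        fit = fit_two_gaussian_em(bimodal_sample(rng), seed=0)
        assert np.all(np.diff(fit.log_likelihood_trace) >= -1e-9)

    def test_component_label_order(self, rng):
        fit = fit_two_gaussian_em(bimodal_sample(rng), seed=0)
        assert fit.mu_short <= fit.mu_long

    def test_single_tight_cluster_degenerates_gracefully(self, rng):
        x = np.full(50, 8.0)
        x[:25] += 1e-9
        with pytest.warns(UserWarning, match="degenerate"):
            fit = fit_two_gaussian_em(x, seed=0)
        assert fit.degenerate
        assert x.min() - 1 <= fit.mu_short <= fit.mu_long <= x.max() + 1

    def test_small_or_constant_samples_rejected(self):
        with pytest.raises(InputError):
            fit_two_gaussian_em(np.arange(5.0))
        with pytest.raises(InputError):
            fit_two_gaussian_em(np.full(20, 3.0))

    def test_against_sklearn_mixture(self, rng):
        """Independent EM implementation recovers the same component means."""
        sklearn = pytest.importorskip("sklearn.mixture")
        x = bimodal_sample(rng)
        fit = fit_two_gaussian_em(x, seed=0)
        gm = sklearn.GaussianMixture(2, tol=1e-8, random_state=0, n_init=3).fit(x[:, None])
        ref = np.sort(gm.means_.ravel())
        assert fit.mu_short == pytest.approx(ref[0], rel=0.05)
        assert fit.mu_long == pytest.approx(ref[1], rel=0.05)


class TestMeristemClassification:
    def test_threshold_is_strict(self):
        fit = GmmFit(8, 60, 1.5, 15, 0.6, np.array([0.81, 0.80, 0.0]),
                     np.array([-1.0]), True, 1)
        labels = classify_meristematic(fit, threshold=0.8)
        assert labels.tolist() == [True, False, False]

    def test_all_zero_posteriors(self):
        fit = GmmFit(8, 60, 1.5, 15, 0.6, np.zeros(4), np.array([-1.0]), True, 1)
        assert classify_meristematic(fit).sum() == 0

    def test_bad_threshold_rejected(self):
        fit = GmmFit(8, 60, 1.5, 15, 0.6, np.zeros(4), np.array([-1.0]), True, 1)
        with pytest.raises(InputError):
            classify_meristematic(fit, threshold=1.0)

    def test_posterior_evaluated_for_new_lengths(self, rng):
        fit = fit_two_gaussian_em(bimodal_sample(rng), seed=0)
        labels = classify_meristematic(fit, lengths=np.array([8.0, 60.0]))
        assert labels.tolist() == [True, False]
        post = posterior_short(np.array([8.0]), fit.mu_short, fit.sigma_short,
                               fit.mu_long, fit.sigma_long, fit.weight_short)
        assert post[0] > 0.99


class TestScanRules:
    def test_isodiametric_hand_example(self):
        f = make_file([5, 6, 7, 5, 5], [6, 6, 6, 6, 6])
        assert count_isodiametric(f) == 2  # run stops at the 7/6 cell

    def test_isodiametric_boundaries(self):
        assert count_isodiametric(make_file([7, 5, 5, 5, 5], [6] * 5)) == 0
        assert count_isodiametric(make_file([5] * 6, [6] * 6)) == 6

    def test_transition_hand_example(self):
        # lengths (5,5,7,9,14,30), widths 6: span starts at the 7 µm cell,
        # 9/7 < 1.5 keeps the next, 14/9 >= 1.5 stops -> 2 cells
        f = make_file([5, 5, 7, 9, 14, 30], [6] * 6)
        assert count_transition(f) == 2

    def test_transition_empty_and_full_span(self):
        assert count_transition(make_file([5] * 6, [6] * 6)) == 0
        lengths = [5, 5, 7, 7.7, 8.47, 9.3]
        f = make_file(lengths, [6] * 6)
        assert count_transition(f) == 4  # monotone 10% growth runs to file end

    def test_agrees_with_bruteforce_oracle(self, rng):
        """500 random short files: scan rules match an independent oracle."""
        for _ in range(500):
            n = int(rng.integers(5, 16))
            lengths = rng.uniform(2, 20, n)
            widths = rng.uniform(2, 20, n)
            f = make_file(lengths, widths)
            assert count_isodiametric(f) == iso_oracle(lengths, widths)
            assert count_transition(f) == transition_oracle(lengths, widths)
            assert count_isodiametric(f) + count_transition(f) <= n


class TestLengthSummaries:
    def test_mature_cell_length(self):
        lengths = np.arange(1.0, 21.0)
        assert mature_cell_length(lengths, k=10) == pytest.approx(15.5)
        assert mature_cell_length(lengths, k=20) == pytest.approx(lengths.mean())
        assert mature_cell_length(lengths, k=1) == 20.0
        with pytest.raises(InputError):
            mature_cell_length(lengths[:5], k=10)

    def test_first_elongated_length(self):
        f = make_file([8, 9, 22, 40, 50], [10] * 5)
        labels = [True, True, False, False, False]
        assert first_elongated_length(f, labels) == 22.0
        assert first_elongated_length(f, [False] * 5) == 8.0
        with pytest.raises(NotFoundSignal):
            first_elongated_length(f, [True] * 5)


class TestMitoticSummary:
    def test_fold_change_hand_example(self):
        means, table = mitotic_summary(
            {"darkW": [8, 10, 6], "dark": [1, 1, 2]}, pairs=[("darkW", "dark")])
        assert means["darkW"] == pytest.approx(8.0)
        assert table["fold_change"].iloc[0] == pytest.approx(6.0)
        assert "p_adjusted" in table.columns

    def test_identical_conditions_fold_one(self):
        _, table = mitotic_summary({"a": [3, 4, 5], "b": [3, 4, 5]}, pairs=[("a", "b")])
        assert table["fold_change"].iloc[0] == pytest.approx(1.0)

    def test_zero_denominator_warns_nan(self):
        with pytest.warns(UserWarning, match="undefined"):
            _, table = mitotic_summary({"a": [3, 4], "b": [0, 0]}, pairs=[("a", "b")])
        assert np.isnan(table["fold_change"].iloc[0])

    def test_empty_condition_rejected(self):
        with pytest.raises(InputError):
            mitotic_summary({"a": []})


class TestPositionalCurve:
    @staticmethod
    def _files(values, n_files=4, noise=None, rng=None):
        files = []
        for j in range(n_files):
            v = np.asarray(values, dtype=float)
            if noise is not None:
                v = v + rng.normal(0, noise, v.size)
            files.append(CellFile(f"r{j}", "dark", "wt", np.abs(v) + 1e-9,
                                  np.full(v.size, 10.0)))
        return files

    def test_constant_input_flat_curve(self):
        curve = positional_curve(self._files([8.0] * 20), "length", n_boot=20, seed=0)
        np.testing.assert_allclose(curve.fit, 8.0, atol=1e-8)
        np.testing.assert_allclose(curve.upper - curve.lower, 0.0, atol=1e-8)

    def test_linear_data_reproduced(self):
        values = 2.0 + 0.5 * np.arange(1, 31)
        curve = positional_curve(self._files(values), "length", span=1.0,
                                 degree=1, n_boot=10, seed=0)
        np.testing.assert_allclose(curve.fit, values, rtol=1e-6)
        assert curve.max_slope == pytest.approx(0.5, rel=1e-3)

    def test_bootstrap_determinism(self, rng):
        files = self._files(np.linspace(5, 50, 25), noise=1.0, rng=rng)
        a = positional_curve(files, "length", n_boot=30, seed=5)
        b = positional_curve(files, "length", n_boot=30, seed=5)
        np.testing.assert_array_equal(a.lower, b.lower)
        np.testing.assert_array_equal(a.upper, b.upper)

    def test_kink_located_at_elongation_onset(self, demo_cell_files):
        files = [f for f in demo_cell_files if f.condition == "darkW"]
        curve = positional_curve(files, "length", n_boot=10, seed=0)
        # steepest fitted slope sits in the elongation zone, past the
        # configured darkW onset (index 15)
        assert curve.max_slope_index >= 15

    def test_invalid_arguments_rejected(self, demo_cell_files):
        with pytest.raises(InputError):
            positional_curve(demo_cell_files[:1], "length")
        with pytest.raises(InputError):
            positional_curve(demo_cell_files[:3], "length", span=0.0)
        with pytest.raises(InputError):
            positional_curve(demo_cell_files[:3], "length", degree=3)
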