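"""Masking, correlation selection, refined completion and NRMSE harness."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from hrvmc import (
    FULL_BAND,
    HF_BAND,
    LF_BAND,
    GaussianComponent,
    MaskSpec,
    ObservationMask,
    RefinedMCImputer,
    RefinedSelection,
    SpectrumMatrix,
    SpectrumModel,
    apply_mask,
    benchmark,
    build_refined_matrix,
    complete_matrix,
    modeled_correlation,
    nrmse,
    rmc_estimate,
    select_top_k,
    svt_complete,
    sweep_k,
)


def hundred_bin_matrix(n_rows=4) -> SpectrumMatrix:
    freqs = np.linspace(0.0, 0.99, 100)
    rng = np.random.default_rng(0)
    return SpectrumMatrix(freqs=freqs, rows=np.abs(rng.standard_normal((n_rows, 100))))


def duplicate_row_matrix() -> SpectrumMatrix:
    """Target row has an exact duplicate, so completion is fully determined."""
    from hrvmc import eval_model

    freqs = np.arange(np.ceil(0.04 * 256), np.floor(0.4 * 256) + 1) / 256.0
    rows = []
    rng = np.random.default_rng(3)
    for _ in range(8):
        model = SpectrumModel(components={
            "LF": [GaussianComponent(rng.uniform(300, 800), rng.uniform(0.08, 0.12),
                                     rng.uniform(0.015, 0.03))],
            "HF": [GaussianComponent(rng.uniform(150, 500), rng.uniform(0.2, 0.3),
                                     rng.uniform(0.02, 0.04))],
        })
        rows.append(eval_model(model, freqs))
    rows.append(rows[0].copy())  # duplicate of row 0
    return SpectrumMatrix(freqs=freqs, rows=np.vstack(rows))


class TestApplyMask:
    def test_exact_hidden_count(self):
        S = hundred_bin_matrix()
        mask = apply_mask(S, MaskSpec(target_row=1, ratio=0.3))
        assert (~mask.known[1]).sum() == 30
        assert mask.known[[0, 2, 3]].all()

    def test_band_pattern_stays_in_band(self):
        S = hundred_bin_matrix()
        mask = apply_mask(S, MaskSpec(target_row=0, ratio=0.2, band=HF_BAND))
        hidden_f = S.freqs[~mask.known[0]]
        assert hidden_f.min() >= HF_BAND.f_left
        assert hidden_f.max() <= HF_BAND.f_right
        idx = np.nonzero(~mask.known[0])[0]
        assert np.array_equal(idx, np.arange(idx[0], idx[-1] + 1))  # contiguous

    def test_random_pattern_seed_determinism(self):
        S = hundred_bin_matrix()
        spec = MaskSpec(target_row=2, ratio=0.5, pattern="random", seed=12)
        a = apply_mask(S, spec)
        b = apply_mask(S, spec)
        assert np.array_equal(a.known, b.known)

    def test_degenerate_ratio_rejected(self):
        freqs = np.linspace(0, 0.9, 10)
        S = SpectrumMatrix(freqs=freqs, rows=np.ones((2, 10)))
        with pytest.raises(ValueError):
            apply_mask(S, MaskSpec(target_row=0, ratio=0.04))

    def test_ratio_bounds_validated(self):
        with pytest.raises(ValueError):
            MaskSpec(target_row=0, ratio=1.5)


class TestModeledCorrelation:
    GRID = np.arange(257) / 256.0

    def _model(self, a=1.0):
        return SpectrumModel(
            components={"LF": [GaussianComponent(a * 400, 0.1, 0.02)],
                        "HF": [GaussianComponent(a * 200, 0.25, 0.03)]},
            freqs=self.GRID,
        )

    def test_identical_models(self):
        m = self._model()
        assert modeled_correlation(m, m, np.arange(20, 100)) == pytest.approx(1.0)

    def test_positive_scaling_invariance(self):
        r = modeled_correlation(self._model(1.0), self._model(3.5),
                                np.arange(20, 100))
        assert r == pytest.approx(1.0)

    def test_matches_direct_pearson_formula(self):
        idx = np.array([20, 30, 40, 55, 70])
        a = self._model(1.0)
        b = SpectrumModel(
            components={"LF": [GaussianComponent(500, 0.11, 0.025)]},
            freqs=self.GRID,
        )
        x = a(self.GRID[idx])
        y = b(self.GRID[idx])
        xc, yc = x - x.mean(), y - y.mean()
        expected = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        assert modeled_correlation(a, b, idx) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_rejected(self):
        # narrow lobes whose far tail underflows to exactly zero
        narrow = SpectrumModel(
            components={"LF": [GaussianComponent(400, 0.1, 0.005)]},
            freqs=self.GRID,
        )
        idx = np.arange(245, 255)  # ~0.96-0.99 Hz, 170 sigma away
        with pytest.raises(ValueError):
            modeled_correlation(narrow, narrow, idx)


class TestSelectTopK:
    def test_single_best(self):
        assert select_top_k(np.array([0.2, 0.9, 0.5]), 1) == [1]

    def test_all_candidates(self):
        t = np.array([0.3, np.nan, 0.8, 0.1])
        assert set(select_top_k(t, 3)) == {0, 2, 3}

    def test_tie_breaks_to_smaller_index(self):
        assert select_top_k(np.array([0.5, 0.5, 0.1]), 1) == [0]

    def test_k_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            select_top_k(np.array([0.1, 0.2]), 3)


class TestBuildRefinedMatrix:
    def test_target_first_then_descending(self):
        S = hundred_bin_matrix(6)
        mask = apply_mask(S, MaskSpec(target_row=2, ratio=0.3))
        refined, rmask, row_map = build_refined_matrix(S, mask, 2, [4, 0, 5])
        assert row_map == [2, 4, 0, 5]
        assert refined.shape == (4, 100)
        assert np.array_equal(refined.rows[0], S.rows[2])

    def test_only_target_row_masked(self):
        S = hundred_bin_matrix(6)
        mask = apply_mask(S, MaskSpec(target_row=2, ratio=0.3))
        _, rmask, _ = build_refined_matrix(S, mask, 2, [1, 3])
        assert rmask.known[1:].all()
        assert np.array_equal(rmask.known[0], mask.known[2])

    def test_k_equal_one_gives_two_rows(self):
        S = hundred_bin_matrix(6)
        mask = apply_mask(S, MaskSpec(target_row=2, ratio=0.3))
        refined, _, _ = build_refined_matrix(S, mask, 2, [0])
        assert refined.shape[0] == 2

    def test_target_in_selection_rejected(self):
        S = hundred_bin_matrix(6)
        mask = apply_mask(S, MaskSpec(target_row=2, ratio=0.3))
        with pytest.raises(ValueError):
            build_refined_matrix(S, mask, 2, [2, 3])


class TestRMCEstimate:
    def test_duplicate_row_recovery(self):
        S = duplicate_row_matrix()
        mask = apply_mask(S, MaskSpec(target_row=0, ratio=0.3, band=HF_BAND))
        estimate, result, selection = rmc_estimate(S, mask, 0, k=3)
        hidden = mask.hidden[0]
        rel = np.linalg.norm((estimate - S.rows[0])[hidden]) / np.linalg.norm(
            S.rows[0][hidden]
        )
        assert rel < 1e-2
        assert 8 in selection.selected  # the duplicate is picked

    def test_known_bins_unaltered(self):
        S = duplicate_row_matrix()
        mask = apply_mask(S, MaskSpec(target_row=0, ratio=0.3))
        estimate, _, _ = rmc_estimate(S, mask, 0, k=4)
        known = mask.known[0]
        assert np.array_equal(estimate[known], S.rows[0][known])

    def test_full_k_equals_completion_on_permuted_matrix(self):
        S = duplicate_row_matrix()
        mask = apply_mask(S, MaskSpec(target_row=0, ratio=0.3))
        n_rows = S.shape[0]
        estimate, _, selection = rmc_estimate(S, mask, 0, k=n_rows - 1)
        perm = [0, *selection.selected]
        full = complete_matrix(S.rows[perm], mask.known[perm])
        hidden = mask.hidden[0]
        scale = np.abs(S.rows).max()
        assert np.allclose(estimate[hidden], full.X[0][hidden],
                           atol=1e-9 * scale, rtol=0)

    def test_unmodellable_target_falls_back_with_warning(self, caplog):
        S = duplicate_row_matrix()
        rows = S.rows.copy()
        mask = apply_mask(S, MaskSpec(target_row=0, ratio=0.3))
        rows[0, mask.known[0]] = 0.0  # zero band power defeats the Gaussian fit
        S_bad = SpectrumMatrix(freqs=S.freqs, rows=rows)
        with caplog.at_level("WARNING", logger="hrvmc.rmc"):
            rmc_estimate(S_bad, mask, 0, k=2)
        assert any("falling back" in rec.message for rec in caplog.records)

    def test_other_rows_must_be_known(self):
        S = duplicate_row_matrix()
        known = np.ones(S.shape, bool)
        known[0, 60:80] = False
        known[1, 10] = False
        with pytest.raises(ValueError):
            rmc_estimate(S, ObservationMask(known), 0)


class TestNRMSE:
    def test_perfect_estimate(self):
        truth = np.array([1.0, 2.0, 3.0, 4.0])
        assert nrmse(truth, truth, np.arange(4)) == 0.0

    def test_mean_estimate_closed_form(self):
        rng = np.random.default_rng(5)
        truth = rng.uniform(1, 10, 100)
        estimate = np.full(100, truth.mean())
        expected = np.sqrt(99.0 / 100.0)
        assert nrmse(estimate, truth, np.arange(100)) == pytest.approx(expected)
        assert expected == pytest.approx(0.99499, abs=1e-5)

    def test_hand_computed_value(self):
        truth = np.array([1.0, 2.0, 3.0])
        estimate = np.array([1.0, 2.0, 4.0])
        assert nrmse(estimate, truth, np.arange(3)) == pytest.approx(
            np.sqrt(1.0 / 3.0), abs=1e-12
        )

    @given(st.floats(0.01, 1e4))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, c):
        truth = np.array([1.0, 2.5, 3.0, 7.0])
        estimate = np.array([1.2, 2.0, 3.3, 6.0])
        base = nrmse(estimate, truth, np.arange(4))
        scaled = nrmse(c * estimate, c * truth, np.arange(4))
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            nrmse(np.ones(5), np.full(5, 2.0), np.arange(5))


class TestSweepAndBenchmark:
    def test_singleton_sweep_matches_estimate(self):
        S = duplicate_row_matrix()
        mask = apply_mask(S, MaskSpec(target_row=0, ratio=0.3))
        results, best_k = sweep_k(S, mask, 0, [3])
        estimate, _, _ = rmc_estimate(S, mask, 0, k=3)
        expected = nrmse(estimate, S.rows[0], mask.hidden[0])
        assert results == [(3, pytest.approx(expected))]
        assert best_k == 3

    def test_best_k_dominates_full_k(self):
        S = duplicate_row_matrix()
        mask = apply_mask(S, MaskSpec(target_row=0, ratio=0.3))
        n = S.shape[0]
        results, best_k = sweep_k(S, mask, 0, [1, 3, n - 1])
        errors = dict(results)
        assert errors[best_k] <= errors[n - 1]

    def test_sweep_deterministic(self):
        S = duplicate_row_matrix()
        mask = apply_mask(S, MaskSpec(target_row=0, ratio=0.3))
        assert sweep_k(S, mask, 0, [2, 4]) == sweep_k(S, mask, 0, [2, 4])

    def test_benchmark_single_cell(self):
        S = duplicate_row_matrix()
        table = benchmark(S, [MaskSpec(target_row=0, ratio=0.3)],
                          methods=("mc",), seeds=(0,))
        assert len(table) == 1
        assert table.iloc[0]["method"] == "mc"
        assert table.iloc[0]["nrmse"] >= 0

    def test_benchmark_table_round_trips(self, tmp_path):
        import pandas as pd

        S = duplicate_row_matrix()
        table = benchmark(S, [MaskSpec(target_row=0, ratio=0.3)],
                          methods=("mc", "rmc"), seeds=(0, 1), k=3)
        path = tmp_path / "results.tsv"
        table.to_csv(path, sep="\t", index=False)
        back = pd.read_csv(path, sep="\t")
        assert np.allclose(back["nrmse"], table["nrmse"])
        assert list(back["method"]) == list(table["method"])


class TestSelectionSanity:
    def test_selected_rows_share_target_cluster(self, cluster_matrix):
        S, weights = cluster_matrix
        clusters = np.argmax(weights, axis=1)
        fractions = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            j = int(rng.integers(0, S.shape[0]))
            mask = apply_mask(S, MaskSpec(target_row=j, ratio=0.3, band=HF_BAND))
            _, _, selection = rmc_estimate(S, mask, j, k=9)
            same = np.mean([clusters[q] == clusters[j] for q in selection.selected])
            fractions.append(same)
        assert np.median(fractions) >= 0.8


class TestRefinedMCImputer:
    def test_transform_fills_target_row(self):
        S = duplicate_row_matrix()
        mask = apply_mask(S, MaskSpec(target_row=0, ratio=0.3))
        X_nan = np.where(mask.known, S.rows, np.nan)
        imputer = RefinedMCImputer(freqs=S.freqs, k=3)
        out = imputer.fit_transform(X_nan)
        assert not np.isnan(out).any()
        hidden = mask.hidden[0]
        rel = np.linalg.norm((out[0] - S.rows[0])[hidden]) / np.linalg.norm(
            S.rows[0][hidden]
        )
        assert rel < 1e-2
        assert len(imputer.selections_) == 1
        assert imputer.results_[0].converged

    def test_sklearn_param_interface(self):
        imputer = RefinedMCImputer(freqs=np.arange(10) / 10.0, k=5)
        cloned = clone(imputer)
        assert cloned.get_params()["k"] == 5
        imputer.set_params(k=7)
        assert imputer.k == 7

    def test_missing_freqs_rejected(self):
        with pytest.raises(ValueError):
            RefinedMCImputer().fit(np.zeros((3, 4)))
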