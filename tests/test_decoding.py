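"""dF/F summaries, directionality index, PCA and SVM decoding machinery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import silhouette_score

from pitchkit.decoding import (
    build_cell_response,
    classify_tuning,
    decode_accuracy,
    dff,
    directionality_index,
    integrated_response,
    least_tuned_subset,
    pca_projection,
    peak_first_second,
    per_fish_decode,
    pseudo_population_decode,
    response_matrix,
    shuffle_null,
    shuffle_null_pvalue,
)
from pitchkit.simulate import CellSimParams, generate_cell_trials


def _cells(params: CellSimParams, n_cells: int):
    M, labels = generate_cell_trials(params, n_cells)
    return [build_cell_response(f"c{i:02d}", M[:, i], labels) for i in range(n_cells)]


class TestDff:
    def test_baseline_trace_is_zero(self):
        assert np.all(dff(np.full(10, 4.0), 4.0) == 0.0)

    def test_triple_baseline(self):
        assert np.all(dff(np.full(5, 3.0), 1.0) == 2.0)

    def test_affine(self):
        t = np.linspace(0.0, 1.0, 11)
        out = dff(2.0 + 3.0 * t, 2.0)
        assert np.allclose(out, 1.5 * t)

    def test_nonpositive_baseline(self):
        with pytest.raises(ValueError):
            dff(np.ones(3), 0.0)


class TestIntegratedResponse:
    def test_constant_trace(self):
        # fs chosen so the 15 s window lands exactly on samples
        assert integrated_response(np.ones(61), fs=4.0) == pytest.approx(15.0)

    def test_zero_trace(self):
        assert integrated_response(np.zeros(61), fs=4.0) == 0.0

    def test_triangular_pulse_area(self):
        trace = np.concatenate([np.linspace(0, 2, 31), np.linspace(2, 0, 31)[1:]])
        assert integrated_response(trace, fs=4.0) == pytest.approx(15.0)

    def test_imaging_rate_window(self):
        # at 3.82 volumes/s the 15 s window needs floor(15*3.82)+1 = 58 samples
        assert integrated_response(np.ones(58), fs=3.82) == pytest.approx(57 / 3.82)
        with pytest.raises(ValueError):
            integrated_response(np.ones(57), fs=3.82)


class TestPeakFirstSecond:
    def test_decay_from_three(self):
        trace = np.array([0.0, 3.0, 2.5, 2.0, 1.5, 1.0])
        assert peak_first_second(trace, fs=3.82) == 3.0

    def test_window_is_three_samples_at_imaging_rate(self):
        trace = np.array([0.0, 0.1, 0.2, 0.3, 9.0])  # the 9 sits at k=4 > 1 s
        assert peak_first_second(trace, fs=3.82) == 0.3

    def test_flat_zero(self):
        assert peak_first_second(np.zeros(6), fs=3.82) == 0.0

    def test_too_short(self):
        with pytest.raises(ValueError):
            peak_first_second(np.zeros(3), fs=3.82)


class TestDirectionalityIndex:
    @pytest.mark.parametrize(
        "up,down,di", [(1.0, 0.0, 1.0), (2.0, 2.0, 0.0), (2.0, 1.0, 1 / 3)]
    )
    def test_values(self, up, down, di):
        assert directionality_index(up, down) == pytest.approx(di)

    def test_one_third_is_untuned(self):
        assert classify_tuning(directionality_index(2.0, 1.0)) == "untuned"

    @given(
        up=st.floats(0.01, 100.0), down=st.floats(0.01, 100.0),
        scale=st.floats(0.01, 100.0),
    )
    @settings(deadline=None, max_examples=50)
    def test_scale_invariance(self, up, down, scale):
        assert directionality_index(up * scale, down * scale) == pytest.approx(
            directionality_index(up, down)
        )

    def test_degenerate_denominator(self):
        with pytest.raises(ValueError):
            directionality_index(1.0, -1.0)


class TestClassifyTuning:
    @pytest.mark.parametrize(
        "di,cls",
        [(0.35, "untuned"), (-0.35, "untuned"), (0.4, "tuned_up"),
         (-0.5, "tuned_down"), (0.0, "untuned")],
    )
    def test_cutoff_strict(self, di, cls):
        assert classify_tuning(di) == cls


class TestCellResponse:
    def test_degenerate_cell_excluded(self):
        responses = np.array([1.0, 1.0, -2.0, -2.0])
        directions = np.array(["up", "up", "down", "down"], dtype=object)
        assert build_cell_response("bad", responses, directions) is None

    def test_matrix_stacking_and_labels(self):
        cells = _cells(CellSimParams(n_trials_per_direction=5, seed=0), 4)
        M, labels = response_matrix(cells)
        assert M.shape == (10, 4)
        assert list(labels[:5]) == ["up"] * 5


class TestPCA:
    def test_single_varying_column(self):
        rng = np.random.default_rng(0)
        M = np.zeros((20, 3))
        M[:, 1] = rng.normal(size=20)
        _, var = pca_projection(M)
        assert var[0] == pytest.approx(1.0)

    def test_duplicated_trials_identical_scores(self):
        rng = np.random.default_rng(1)
        row = rng.normal(size=5)
        M = np.vstack([row, row, rng.normal(size=5), rng.normal(size=5)])
        scores, _ = pca_projection(M)
        assert np.allclose(scores[0], scores[1])

    def test_separated_clusters_separate_on_pc1(self):
        M, labels = generate_cell_trials(
            CellSimParams(shared_direction_signal_sd=3.0, trial_noise_sd=0.5, seed=2), 8
        )
        scores, _ = pca_projection(M)
        assert silhouette_score(scores[:, :1], labels) > 0.0


class TestDecoding:
    def test_separable_clusters_perfect(self):
        n = 10
        M = np.vstack([np.full((n, 3), 5.0), np.full((n, 3), -5.0)])
        M += np.random.default_rng(0).normal(0, 0.1, M.shape)
        labels = np.array(["up"] * n + ["down"] * n, dtype=object)
        assert decode_accuracy(M, labels, seed=0) == 1.0

    def test_k_reduced_with_warning(self):
        M = np.random.default_rng(1).normal(size=(6, 2))
        labels = np.array(["up"] * 3 + ["down"] * 3, dtype=object)
        with pytest.warns(UserWarning, match="reducing k"):
            decode_accuracy(M, labels, k=5, seed=0)

    def test_shuffle_null_seeded_and_beaten_by_signal(self):
        M, labels = generate_cell_trials(
            CellSimParams(shared_direction_signal_sd=2.0, trial_noise_sd=0.5, seed=3), 10
        )
        obs = decode_accuracy(M, labels, seed=0)
        null_a = shuffle_null(M, labels, n_shuffles=30, seed=9)
        null_b = shuffle_null(M, labels, n_shuffles=30, seed=9)
        assert np.array_equal(null_a, null_b)
        assert obs > null_a.max()
        assert shuffle_null_pvalue(obs, null_a) == pytest.approx(1 / 31)


class TestPseudoPopulation:
    def test_full_pool_has_zero_spread(self):
        cells = _cells(CellSimParams(seed=4), 6)
        res = pseudo_population_decode(cells, sizes=(6,), n_draws=5, seed=0)[6]
        assert np.ptp(res.accuracies) == 0.0

    def test_oversized_requests_truncated(self):
        cells = _cells(CellSimParams(seed=5), 4)
        with pytest.warns(UserWarning, match="truncating"):
            res = pseudo_population_decode(cells, sizes=(3, 10), n_draws=3, seed=0)
        assert set(res) == {3}

    def test_per_fish_path(self):
        fish = {
            "f1": _cells(CellSimParams(seed=6), 5),
            "f2": _cells(CellSimParams(seed=7), 5),
        }
        out = per_fish_decode(fish, seed=0)
        assert set(out) == {"f1", "f2"}
        assert all(0.0 <= v <= 1.0 for v in out.values())


class TestLeastTuned:
    def test_smallest_absolute_di_selected(self):
        cells = _cells(CellSimParams(seed=8), 9)
        subset = least_tuned_subset(cells, 4)
        chosen = sorted(abs(c.di) for c in subset)
        others = [abs(c.di) for c in cells if c not in subset]
        assert max(chosen) <= min(others)

    def test_full_pool_identity(self):
        cells = _cells(CellSimParams(seed=9), 5)
        assert set(c.cell_id for c in least_tuned_subset(cells, 5)) == set(
            c.cell_id for c in cells
        )

    def test_order_property(self):
        cells = _cells(CellSimParams(seed=10), 6)
        # a moderately tuned extra cell never displaces a weakly tuned one
        weakest = least_tuned_subset(cells, 1)[0]
        assert weakest in least_tuned_subset(cells, 3)

    def test_n_too_large(self):
        with pytest.raises(ValueError):
            least_tuned_subset(_cells(CellSimParams(seed=11), 3), 4)
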