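import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kpcforest import (
    FeatureMatrix,
    SpectralBlock,
    autoscale,
    merge_blocks,
    peak_pick,
    pqn_normalize,
)
from kpcforest.preprocess import PreprocessError


def block_from(values, axis=None):
    values = np.asarray(values, dtype=float)
    axis = np.arange(values.shape[1], dtype=float) if axis is None else axis
    return SpectralBlock(values, axis, [f"s{i}" for i in range(values.shape[0])])


class TestPqn:
    def test_sample_identical_to_reference_unchanged(self):
        ref = np.array([1.0, 2.0, 3.0, 4.0])
        block = block_from([ref, 2 * ref])
        out, factors = pqn_normalize(block, reference=ref, return_factors=True)
        np.testing.assert_allclose(out.intensities[0], ref)
        assert factors[0] == pytest.approx(1.0)

    def test_three_times_reference_returns_reference(self):
        ref = np.array([1.0, 2.0, 3.0, 4.0])
        block = block_from([3 * ref])
        out, factors = pqn_normalize(block, reference=ref, return_factors=True)
        assert factors[0] == pytest.approx(3.0)
        np.testing.assert_allclose(out.intensities[0], ref)

    def test_quotient_median_oracle(self):
        # independent hand-rolled evaluation of the quotient-median definition
        r = np.array([1.0, 2.0, 4.0, 8.0])
        noise = np.array([0.1, -0.2, 0.3, -0.1])
        X = np.vstack([r, 2 * r, r + noise])
        block = block_from(X)
        out, factors = pqn_normalize(block, return_factors=True)

        sums = X.sum(axis=1)
        reference = np.median(X / sums[:, None], axis=0)
        expected = [float(np.median(X[i] / reference)) for i in range(3)]
        np.testing.assert_allclose(factors, expected, rtol=1e-12)
        np.testing.assert_allclose(out.intensities, X / np.array(expected)[:, None])

    def test_all_zero_sample_errors_with_name(self):
        block = block_from([[1, 2, 3], [0, 0, 0]])
        with pytest.raises(PreprocessError, match="s1"):
            pqn_normalize(block)

    def test_zero_reference_points_excluded(self):
        ref = np.array([0.0, 2.0, 4.0])
        block = block_from([[5.0, 4.0, 8.0]])
        _, factors = pqn_normalize(block, reference=ref, return_factors=True)
        assert factors[0] == pytest.approx(2.0)  # median of (2, 2); point 0 skipped

    def test_all_zero_reference_errors(self):
        with pytest.raises(PreprocessError, match="no positive points"):
            pqn_normalize(block_from([[1.0, 2.0, 3.0]]), reference=np.zeros(3))

    def test_dilution_invariance(self, spectral_block):
        out1 = pqn_normalize(spectral_block)
        scaled = SpectralBlock(
            spectral_block.intensities * np.array([3.7, 1, 1, 1, 1, 0.2])[:, None],
            spectral_block.axis,
            spectral_block.sample_ids,
        )
        out2 = pqn_normalize(scaled)
        np.testing.assert_allclose(out1.intensities, out2.intensities, rtol=1e-10)

    def test_idempotence(self, spectral_block):
        once = pqn_normalize(spectral_block)
        twice, factors = pqn_normalize(once, return_factors=True)
        np.testing.assert_allclose(factors, 1.0, atol=1e-10)
        np.testing.assert_allclose(twice.intensities, once.intensities, rtol=1e-10)

    @settings(max_examples=25, deadline=None)
    @given(
        c=st.floats(min_value=1e-3, max_value=1e3),
        row=st.integers(min_value=0, max_value=5),
    )
    def test_scale_invariance_property(self, c, row):
        rng = np.random.default_rng(7)
        X = rng.uniform(0.1, 2.0, size=(6, 16))
        scaled = X.copy()
        scaled[row] *= c
        out1 = pqn_normalize(block_from(X))
        out2 = pqn_normalize(block_from(scaled))
        np.testing.assert_allclose(out1.intensities, out2.intensities, rtol=1e-9)


class TestPeakPick:
    def test_flat_zero_spectrum_no_variables(self):
        block = block_from(np.zeros((3, 50)))
        out = peak_pick(block, min_height=0.1)
        assert out.n_variables == 0

    def test_single_triangular_peak(self):
        spec = np.zeros(101)
        spec[45:56] = np.concatenate([np.linspace(0, 1, 6), np.linspace(1, 0, 6)[1:]])
        block = block_from(np.vstack([spec, spec]))
        out = peak_pick(block, min_height=0.5)
        assert out.n_variables == 1
        assert out.variable_names == ["50"]

    def test_close_gaussians_higher_apex_wins(self):
        x = np.arange(200.0)
        spec = 2.0 * np.exp(-((x - 80) ** 2) / 20) + 1.0 * np.exp(-((x - 95) ** 2) / 20)
        block = block_from(np.vstack([spec, spec]), axis=x)

        # brute-force local-maxima oracle
        maxima = [
            i
            for i in range(1, 199)
            if spec[i] > spec[i - 1] and spec[i] >= spec[i + 1] and spec[i] > 0.5
        ]
        assert len(maxima) == 2  # two apexes closer than min_separation

        out = peak_pick(block, min_height=0.5, min_separation=30)
        assert out.n_variables == 1
        assert out.variable_names == ["80"]  # the higher apex

    def test_min_separation_validation(self, spectral_block):
        with pytest.raises(PreprocessError):
            peak_pick(spectral_block, min_height=0.1, min_separation=0)


class TestAutoscale:
    def test_columns_standardized(self, rng, matrix_factory):
        m = matrix_factory(rng.normal(5, 3, size=(20, 6)))
        out = autoscale(m)
        np.testing.assert_allclose(out.values.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(out.values.std(axis=0, ddof=1), 1, atol=1e-12)

    def test_closed_form_column(self, matrix_factory):
        out = autoscale(matrix_factory([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(out.values[:, 0], [-1.0, 0.0, 1.0])

    def test_constant_column_dropped(self, matrix_factory, caplog):
        m = matrix_factory([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]])
        out = autoscale(m)
        assert out.variable_names == ["v1"]
        np.testing.assert_allclose(out.values[:, 0], [-1.0, 0.0, 1.0])

    def test_idempotence(self, rng, matrix_factory):
        m = matrix_factory(rng.normal(size=(15, 4)))
        once = autoscale(m)
        twice = autoscale(once)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-10)

    def test_needs_two_samples(self, matrix_factory):
        with pytest.raises(PreprocessError):
            autoscale(matrix_factory([[1.0, 2.0]]))


class TestMerge:
    def test_shapes_concatenate(self, rng, matrix_factory):
        a = matrix_factory(rng.normal(size=(5, 10)))
        b = FeatureMatrix(
            rng.normal(size=(5, 3)),
            ["e1", "e2", "e3"],
            ["element"] * 3,
            a.sample_ids,
        )
        out = merge_blocks([a, b])
        assert out.values.shape == (5, 13)
        assert out.modalities[-1] == "element"

    def test_merge_with_empty_block_is_identity(self, rng, matrix_factory):
        a = matrix_factory(rng.normal(size=(4, 3)))
        empty = FeatureMatrix(np.empty((4, 0)), [], [], a.sample_ids)
        out = merge_blocks([a, empty])
        np.testing.assert_array_equal(out.values, a.values)
        assert out.variable_names == a.variable_names

    def test_row_order_insensitive(self, rng, matrix_factory):
        a = matrix_factory(rng.normal(size=(5, 4)))
        b = FeatureMatrix(
            rng.normal(size=(5, 2)), ["x", "y"], ["element"] * 2, a.sample_ids
        )
        shuffled = b.reorder_samples([a.sample_ids[i] for i in [3, 0, 4, 1, 2]])
        out1 = merge_blocks([a, b])
        out2 = merge_blocks([a, shuffled])
        np.testing.assert_array_equal(out1.values, out2.values)
        assert out1.sample_ids == out2.sample_ids

    def test_sample_mismatch_lists_difference(self, rng, matrix_factory):
        a = matrix_factory(rng.normal(size=(3, 2)))
        b = FeatureMatrix(
            rng.normal(size=(3, 2)), ["x", "y"], ["nmr"] * 2, ["s0", "s1", "zzz"]
        )
        with pytest.raises(PreprocessError, match="zzz"):
            merge_blocks([a, b])

    def test_name_collision_prefixed(self, rng):
        a = FeatureMatrix(np.ones((3, 1)), ["shared"], ["nmr"], ["s0", "s1", "s2"])
        b = FeatureMatrix(np.zeros((3, 1)), ["shared"], ["element"], ["s0", "s1", "s2"])
        out = merge_blocks([a, b])
        assert out.variable_names == ["shared", "elem:shared"]

    def test_associativity(self, rng, matrix_factory):
        ids = [f"s{i}" for i in range(4)]
        blocks = [
            FeatureMatrix(rng.normal(size=(4, k)), [f"b{k}_{j}" for j in range(k)],
                          ["nmr"] * k, ids)
            for k in (2, 3, 4)
        ]
        left = merge_blocks([merge_blocks(blocks[:2]), blocks[2]])
        right = merge_blocks([blocks[0], merge_blocks(blocks[1:])])
        np.testing.assert_array_equal(left.values, right.values)
        assert left.variable_names == right.variable_names


class TestIO:
    def test_tsv_round_trip(self, tmp_path, rng):
        m = FeatureMatrix(
            rng.normal(size=(4, 3)),
            ["a", "b", "c"],
            ["nmr", "element", "nutrient"],
            [f"s{i}" for i in range(4)],
            [f"subj{i % 2}" for i in range(4)],
        )
        path = tmp_path / "m.tsv"
        m.write_tsv(path)
        back = FeatureMatrix.read_tsv(path)
        np.testing.assert_allclose(back.values, m.values, rtol=1e-9)
        assert back.variable_names == m.variable_names
        assert back.modalities == m.modalities
        assert back.subject_ids == m.subject_ids

    def test_missing_values_rejected(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("sample_id\tv0\tv1\ns0\t1.0\t\ns1\t2.0\t3.0\n")
        with pytest.raises(PreprocessError, match="missing"):
            FeatureMatrix.read_tsv(path)
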