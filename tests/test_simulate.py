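import numpy as np
import pytest

from arbic.simulate import (
    GroundTruth,
    ImplantSpec,
    SimulationSpec,
    generate,
    inject_noise,
    spec_from_yaml,
)


def _trend_order_of(block: np.ndarray) -> np.ndarray | None:
    """A common column order along which every row is non-decreasing, if one
    exists (sort columns by the column-mean rank; verify directly)."""
    order = np.argsort(block.mean(axis=0), kind="stable")
    arranged = block[:, order]
    if np.all(np.diff(arranged, axis=1) >= -1e-12):
        return order
    return None


def _spec(**kw) -> SimulationSpec:
    base = dict(
        m=120,
        n=120,
        implants=[ImplantSpec(t=30, s=30), ImplantSpec(t=30, s=30)],
        rng_seed=5,
    )
    base.update(kw)
    return SimulationSpec(**base)


class TestGenerate:
    def test_deterministic_from_seed(self):
        m1, t1 = generate(_spec())
        m2, t2 = generate(_spec())
        np.testing.assert_array_equal(m1.values, m2.values)
        for a, b in zip(t1.biclusters, t2.biclusters):
            np.testing.assert_array_equal(a.rows, b.rows)

    def test_background_is_standard_normal(self):
        spec = _spec(implants=[], ties=0.0)
        matrix, _ = generate(spec)
        assert abs(matrix.values.mean()) < 0.05
        assert abs(matrix.values.std() - 1.0) < 0.05

    def test_trend_implants_share_a_common_order(self):
        matrix, truth = generate(_spec(ties=0.0))
        for b in truth.biclusters:
            sub = matrix.values[np.ix_(b.rows, b.cols)]
            assert _trend_order_of(sub) is not None

    def test_ties_duplicate_values_within_rows(self):
        matrix, _ = generate(_spec(implants=[], ties=0.1))
        n = matrix.shape[1]
        n_distinct = [len(np.unique(matrix.values[i])) for i in range(20)]
        assert all(d < n for d in n_distinct)

    def test_ground_truth_aligned_with_implants(self):
        matrix, truth = generate(_spec())
        assert isinstance(truth, GroundTruth)
        assert len(truth.biclusters) == 2
        assert truth.biclusters[0].n_rows == 30
        assert truth.biclusters[1].n_cols == 30

    def test_infeasible_placement_rejected(self):
        with pytest.raises(ValueError, match="fit"):
            generate(_spec(implants=[ImplantSpec(t=100, s=100)] * 2))


class TestOverlap:
    def test_region_constant_and_implants_trend_preserving(self):
        spec = _spec(overlap=(10, 10), ties=0.0)
        matrix, truth = generate(spec)
        b1, b2 = truth.biclusters
        shared_rows = np.intersect1d(b1.rows, b2.rows)
        shared_cols = np.intersect1d(b1.cols, b2.cols)
        assert shared_rows.size == 10 and shared_cols.size == 10
        region = matrix.values[np.ix_(shared_rows, shared_cols)]
        assert np.all(region == region[0, 0])
        for b in truth.biclusters:
            sub = matrix.values[np.ix_(b.rows, b.cols)]
            assert _trend_order_of(sub) is not None

    def test_three_overlapping_implants_all_trend_preserving(self):
        spec = SimulationSpec(
            m=200,
            n=200,
            implants=[ImplantSpec(t=40, s=40)] * 3,
            overlap=(12, 12),
            rng_seed=9,
            ties=0.0,
        )
        matrix, truth = generate(spec)
        for b in truth.biclusters:
            sub = matrix.values[np.ix_(b.rows, b.cols)]
            assert _trend_order_of(sub) is not None

    def test_excessive_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            generate(_spec(overlap=(16, 16)))

    def test_overlap_with_non_trend_pattern_rejected(self):
        spec = _spec(
            implants=[ImplantSpec(t=30, s=30, pattern="shift")] * 2,
            overlap=(5, 5),
        )
        with pytest.raises(ValueError, match="trend"):
            generate(spec)


class TestPatterns:
    @staticmethod
    def _block(pattern, seed=11):
        spec = SimulationSpec(
            m=80,
            n=80,
            implants=[ImplantSpec(t=20, s=25, pattern=pattern)],
            rng_seed=seed,
            ties=0.0,
        )
        matrix, truth = generate(spec)
        b = truth.biclusters[0]
        return matrix.values[np.ix_(b.rows, b.cols)]

    def test_shift_rows_differ_by_additive_constants(self):
        sub = self._block("shift")
        diffs = sub - sub[0]
        assert np.allclose(diffs, diffs[:, :1])

    def test_scale_rows_differ_by_positive_factors(self):
        sub = self._block("scale")
        ratios = sub / sub[0]
        assert np.allclose(ratios, ratios[:, :1])
        assert np.all(ratios[:, 0] > 0)

    def test_shift_scale_rows_affine_with_positive_slope(self):
        sub = self._block("shift+scale")
        base = sub[0]
        for row in sub[1:]:
            slope, intercept = np.polyfit(base, row, 1)
            assert slope > 0
            assert np.allclose(row, slope * base + intercept, atol=1e-8)

    def test_row_constant(self):
        sub = self._block("row-constant")
        assert np.allclose(sub, sub[:, :1])

    def test_column_constant(self):
        sub = self._block("column-constant")
        assert np.allclose(sub, sub[:1, :])

    def test_constant(self):
        sub = self._block("constant")
        assert np.allclose(sub, sub[0, 0])

    @pytest.mark.parametrize(
        "pattern",
        ["shift", "scale", "shift+scale", "row-constant", "column-constant"],
    )
    def test_all_patterns_are_trend_preserving(self, pattern):
        sub = self._block(pattern)
        assert _trend_order_of(sub) is not None

    def test_unknown_pattern_rejected(self):
        with pytest.raises(ValueError):
            ImplantSpec(t=5, s=5, pattern="zigzag")


class TestInjectNoise:
    def test_level_zero_leaves_block_unchanged(self, rng):
        block = rng.standard_normal((8, 40))
        out = inject_noise(block, 0.0, rng)
        np.testing.assert_array_equal(out, block)

    def test_exact_replacement_count_per_row(self, rng):
        block = rng.standard_normal((8, 40))
        out = inject_noise(block, 0.1, rng)
        changed = (out != block).sum(axis=1)
        assert np.all(changed == 4)  # floor(0.1 * 40)

    def test_positions_vary_across_rows_and_streams(self):
        block = np.zeros((30, 40))
        out1 = inject_noise(block, 0.2, np.random.default_rng(1))
        out2 = inject_noise(block, 0.2, np.random.default_rng(2))
        pos1 = {tuple(np.flatnonzero(out1[i])) for i in range(30)}
        pos2 = {tuple(np.flatnonzero(out2[i])) for i in range(30)}
        assert len(pos1) > 1  # rows draw different positions
        assert pos1 != pos2  # streams differ

    def test_measured_noise_level_bounded(self):
        # per row, removing the replaced entries restores the trend, so the
        # measured noise level never exceeds the requested one
        spec = SimulationSpec(
            m=100,
            n=100,
            implants=[ImplantSpec(t=25, s=40, noise=0.2)],
            rng_seed=3,
            ties=0.0,
        )
        matrix, truth = generate(spec)
        b = truth.biclusters[0]
        sub = matrix.values[np.ix_(b.rows, b.cols)]
        clean, _ = generate(
            SimulationSpec(
                m=100,
                n=100,
                implants=[ImplantSpec(t=25, s=40, noise=0.0)],
                rng_seed=3,
                ties=0.0,
            )
        )
        order = _trend_order_of(clean.values[np.ix_(b.rows, b.cols)])
        assert order is not None
        from arbic._kernels import chain_length

        s = b.cols.size
        for i in range(b.rows.size):
            vals = sub[i, order]
            ints = np.round(vals * 1e9).astype(np.int64)
            lis = chain_length(-np.arange(s), -ints)  # longest non-decreasing run
            assert (s - lis) / s <= 0.2

    def test_level_validation(self, rng):
        with pytest.raises(ValueError):
            inject_noise(np.zeros((2, 4)), 1.0, rng)


def test_spec_round_trip_through_yaml(tmp_path):
    p = tmp_path / "spec.yaml"
    p.write_text(
        "m: 50\nn: 60\nrng_seed: 4\nties: 0.02\n"
        "overlap: [5, 5]\n"
        "implants:\n  - {t: 20, s: 20}\n  - {t: 20, s: 20}\n"
    )
    spec = spec_from_yaml(p)
    assert (spec.m, spec.n) == (50, 60)
    assert spec.overlap == (5, 5)
    assert len(spec.implants) == 2
    assert spec.ties == 0.02
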