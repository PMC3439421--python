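"""AUC, thresholding, range similarity, range change and rank correlation.

Brute-force pair counting and hand-rolled midrank correlation serve as the
independent oracles for the rank statistics.
"""

import math

import numpy as np
import pytest

from sdmsense import (
    BinaryRange,
    GridSpec,
    SuitabilitySurface,
    apply_threshold,
    classify_trend,
    compare_to_reference,
    compute_auc,
    range_change,
    spearman_rho,
)
from sdmsense.exceptions import EvaluationError

GRID = GridSpec(n_rows=10, n_cols=10, x_origin=0.0, y_origin=10.0, cell_size=1.0)


def brute_auc(pres, bg):
    wins = 0.0
    for x in pres:
        for y in bg:
            wins += 1.0 if x > y else (0.5 if x == y else 0.0)
    return wins / (len(pres) * len(bg))


def brute_spearman(x, y):
    def midrank(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            r = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                ranks[order[k]] = r
            i = j + 1
        return ranks

    rx, ry = midrank(list(x)), midrank(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


def _surface(values):
    values = np.asarray(values, dtype=float)
    return SuitabilitySurface(
        grid=GRID,
        probability=values,
        valid_mask=np.isfinite(values),
        max_probability=float(np.nanmax(values)),
    )


def _range(present):
    return BinaryRange(grid=GRID, present=np.asarray(present, bool), threshold_used=0.5)


def _block(n):  # n cells present, filled row-major
    mask = np.zeros(100, bool)
    mask[:n] = True
    return _range(mask.reshape(10, 10))


class TestAUC:
    def test_perfect_separation(self):
        assert compute_auc([0.9, 0.8], [0.2, 0.1]) == 1.0

    def test_total_ties(self):
        assert compute_auc([0.5] * 4, [0.5] * 6) == 0.5

    def test_three_of_four_pairs_won(self):
        assert compute_auc([0.9, 0.4], [0.5, 0.1]) == 0.75

    def test_matches_bruteforce_on_random_score_sets(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            m = rng.integers(1, 51)
            n = rng.integers(1, 51)
            # quantize to force ties
            pres = np.round(rng.random(m), 1)
            bg = np.round(rng.random(n), 1)
            assert compute_auc(pres, bg) == pytest.approx(
                brute_auc(pres, bg), abs=1e-12
            )

    def test_invariant_under_strictly_increasing_transform(self):
        rng = np.random.default_rng(1)
        pres, bg = rng.random(30), rng.random(40)
        a = compute_auc(pres, bg)
        b = compute_auc(np.exp(3 * pres), np.exp(3 * bg))
        assert a == pytest.approx(b, abs=1e-12)

    def test_empty_input_is_an_error(self):
        with pytest.raises(EvaluationError):
            compute_auc([], [0.1])


class TestThreshold:
    def test_generous_threshold_keeps_constant_half_surface(self):
        surf = _surface(np.full((10, 10), 0.5))
        assert apply_threshold(surf, 0.1).area_cells == 100
        assert apply_threshold(surf, 0.4).area_cells == 100
        assert apply_threshold(surf, 0.6).area_cells == 0

    def test_cell_exactly_at_threshold_is_present(self):
        vals = np.full((10, 10), 0.05)
        vals[0, 0] = 0.4
        assert apply_threshold(_surface(vals), 0.4).area_cells == 1

    def test_present_count_matches_bruteforce_scan(self):
        rng = np.random.default_rng(8)
        vals = rng.random((10, 10))
        binary = apply_threshold(_surface(vals), 0.3)
        assert binary.area_cells == sum(
            1 for r in range(10) for c in range(10) if vals[r, c] >= 0.3
        )

    def test_threshold_nesting(self):
        rng = np.random.default_rng(9)
        surf = _surface(rng.random((10, 10)))
        lo = apply_threshold(surf, 0.1)
        hi = apply_threshold(surf, 0.4)
        assert not (hi.present & ~lo.present).any()
        assert hi.area_cells <= lo.area_cells


class TestCompareToReference:
    def test_identity_scores_hundred(self):
        r = _block(40)
        cmp = compare_to_reference(r, r)
        assert (cmp.pct_predicted_in_reference, cmp.pct_reference_covered,
                cmp.similarity) == (100.0, 100.0, 100.0)

    def test_disjoint_scores_zero(self):
        a = _block(30)
        b = _range(np.flip(_block(30).present))
        cmp = compare_to_reference(a, b)
        assert cmp.similarity == 0.0

    def test_fifty_inside_hundred_scores_seventyfive(self):
        cmp = compare_to_reference(_block(50), _block(100))
        assert cmp.pct_predicted_in_reference == 100.0
        assert cmp.pct_reference_covered == 50.0
        assert cmp.similarity == 75.0

    def test_swapping_arguments_swaps_components(self):
        rng = np.random.default_rng(2)
        a = _range(rng.random((10, 10)) > 0.5)
        b = _range(rng.random((10, 10)) > 0.3)
        ab = compare_to_reference(a, b)
        ba = compare_to_reference(b, a)
        assert ab.pct_predicted_in_reference == ba.pct_reference_covered
        assert ab.pct_reference_covered == ba.pct_predicted_in_reference

    def test_empty_reference_is_an_error(self):
        with pytest.raises(EvaluationError):
            compare_to_reference(_block(10), _block(0))

    def test_empty_prediction_warns_and_scores_zero(self, caplog):
        cmp = compare_to_reference(_block(0), _block(10))
        assert cmp.similarity == 0.0


class TestRangeChange:
    def test_no_change_scores_parity(self):
        r = _block(50)
        out = range_change(r, r)
        assert out.change_in_area == 100.0
        assert (out.lost_cells, out.gained_cells) == (0, 0)

    def test_expansion_with_overlap(self):
        current = _block(50)
        future = np.zeros(100, bool)
        future[5:65] = True  # 45 shared with current, 15 new
        out = range_change(current, _range(future.reshape(10, 10)))
        assert out.change_in_area == pytest.approx(120.0)
        assert (out.stable_cells, out.lost_cells, out.gained_cells) == (45, 5, 15)

    def test_total_loss(self):
        out = range_change(_block(30), _block(0))
        assert out.change_in_area == 0.0
        assert out.lost_cells == 30

    def test_empty_current_is_undefined(self):
        with pytest.raises(EvaluationError):
            range_change(_block(0), _block(10))

    def test_decomposition_identities_hold_for_random_ranges(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            c = _range(rng.random((10, 10)) > 0.4)
            f = _range(rng.random((10, 10)) > 0.6)
            if c.area_cells == 0:
                continue
            out = range_change(c, f)
            assert out.stable_cells + out.lost_cells == c.area_cells
            assert out.stable_cells + out.gained_cells == f.area_cells


class TestTrend:
    @pytest.mark.parametrize(
        "change,expected",
        [(86.0, "loser"), (100.0, "non-loser"), (118.0, "non-loser")],
    )
    def test_parity_boundary(self, change, expected):
        assert classify_trend(change) == expected


class TestSpearman:
    def test_monotone_extremes(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert spearman_rho(x, [2.0, 4.0, 5.0, 7.0, 11.0])[0] == pytest.approx(1.0)
        assert spearman_rho(x, [5.0, 4.0, 3.0, 2.0, 1.0])[0] == pytest.approx(-1.0)

    def test_worked_example(self):
        rho, n = spearman_rho([1, 2, 3, 4], [2, 1, 4, 3])
        assert rho == pytest.approx(0.6)
        assert n == 4

    def test_matches_bruteforce_midrank_correlation(self):
        rng = np.random.default_rng(77)
        checked = 0
        while checked < 100:
            n = int(rng.integers(3, 21))
            x = np.round(rng.random(n), 1)
            y = np.round(rng.random(n), 1)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rho, _ = spearman_rho(x, y)
            assert rho == pytest.approx(brute_spearman(x, y), abs=1e-12)
            checked += 1

    def test_constant_vector_is_undefined(self):
        with pytest.raises(EvaluationError):
            spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestAUCProperties:
    """Rank-statistic invariants checked over generated inputs."""

    from hypothesis import given, settings, strategies as st

    scores = st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30)

    @given(pres=scores, bg=scores)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_auc_is_a_probability_and_symmetric_under_role_swap(self, pres, bg):
        a = compute_auc(pres, bg)
        assert 0.0 <= a <= 1.0
        # swapping the roles of the two samples reflects the statistic
        assert compute_auc(bg, pres) == pytest.approx(1.0 - a, abs=1e-12)
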