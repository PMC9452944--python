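"""Association statistics against brute-force oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ataxic.containers import CellScoreTable
from ataxic.errors import ConstantInputError, ValidationError
from ataxic.stats import (
    bh_adjust,
    correlate_by_group,
    drug_screen,
    mann_whitney_one_tailed,
    shapiro_check,
    spearman,
)

from oracles import bh_brute, mann_whitney_enum_p, spearman_rank_pearson


class TestSpearman:
    def test_perfect_monotone(self):
        rho, _ = spearman([1, 2, 3], [10, 20, 30])
        assert rho == pytest.approx(1.0)
        rho, _ = spearman([1, 2, 3], [30, 20, 10])
        assert rho == pytest.approx(-1.0)

    def test_exact_p_small_n(self):
        # n=3: of the 6 orderings, two reach |rho| = 1
        _, p = spearman([1, 2, 3], [10, 20, 30])
        assert p == pytest.approx(2 / 6)

    def test_tied_input_matches_rank_then_pearson(self, rng):
        cases = [([1, 2, 2, 4], [1, 3, 2, 4])]
        for _ in range(20):
            x = rng.integers(0, 4, size=8).astype(float)
            y = rng.integers(0, 4, size=8).astype(float)
            if len(set(x)) > 1 and len(set(y)) > 1:
                cases.append((list(x), list(y)))
        for x, y in cases:
            rho, _ = spearman(x, y)
            assert rho == pytest.approx(spearman_rank_pearson(x, y), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        rho, p = spearman(x, y)
        rho2, p2 = spearman(np.exp(x), y**3 + 5 * y)
        assert rho2 == pytest.approx(rho, abs=1e-12)
        assert p2 == pytest.approx(p, abs=1e-12)

    def test_constant_vector_raises(self):
        with pytest.raises(ConstantInputError):
            spearman([1, 1, 1], [1, 2, 3])

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            spearman([1, 2], [3, 4])


class TestBHAdjust:
    def test_single_p_is_identity(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_uniform_grid_collapses_to_max(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_matches_brute_force_definition(self, rng):
        for _ in range(300):
            n = int(rng.integers(1, 13))
            p = rng.uniform(size=n)
            np.testing.assert_allclose(bh_adjust(p), bh_brute(p), atol=1e-12)

    def test_output_at_least_input(self, rng):
        p = rng.uniform(size=50)
        assert (bh_adjust(p) >= p - 1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
                    min_size=1, max_size=12))
    def test_property_matches_definition_and_stays_bounded(self, p):
        adj = bh_adjust(p)
        arr = np.asarray(p)
        assert (adj >= arr - 1e-15).all()
        assert (adj <= 1.0 + 1e-15).all()
        np.testing.assert_allclose(adj, bh_brute(arr), atol=1e-12)


class TestMannWhitney:
    def test_textbook_exact_case(self):
        rec = mann_whitney_one_tailed([1, 2], [3, 4], direction="a_less")
        assert rec.p_one_tailed == pytest.approx(1 / 6)
        assert rec.method == "exact"

    def test_identical_groups_not_significant(self):
        rec = mann_whitney_one_tailed([1, 2, 3], [1, 2, 3], direction="a_greater")
        assert rec.p_one_tailed >= 0.5

    def test_swapping_groups_and_direction_is_symmetric(self, rng):
        a = rng.normal(size=6)
        b = rng.normal(size=7)
        p1 = mann_whitney_one_tailed(a, b, "a_greater").p_one_tailed
        p2 = mann_whitney_one_tailed(b, a, "a_less").p_one_tailed
        assert p1 == pytest.approx(p2, abs=1e-12)

    @pytest.mark.parametrize("na", [1, 2, 3, 4, 5])
    @pytest.mark.parametrize("nb", [1, 2, 3, 4, 5])
    def test_matches_full_enumeration(self, na, nb, rng):
        for _ in range(3):
            pooled = rng.choice(1000, size=na + nb, replace=False).astype(float)
            a, b = pooled[:na], pooled[na:]
            for direction in ("a_greater", "a_less"):
                rec = mann_whitney_one_tailed(a, b, direction)
                assert rec.p_one_tailed == pytest.approx(
                    mann_whitney_enum_p(a, b, direction), abs=1e-12
                )

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney_one_tailed([], [1.0], "a_greater")


class TestShapiro:
    def test_near_constant_with_jitter_rejects_normality(self, rng):
        x = np.concatenate([np.full(99, 1.0) + rng.normal(0, 1e-6, 99), [2.0]])
        _, p = shapiro_check(x)
        assert p < 0.05

    def test_gaussian_samples_mostly_pass(self):
        passed = 0
        for seed in range(200):
            x = np.random.default_rng(seed).normal(size=100)
            _, p = shapiro_check(x)
            passed += p > 0.05
        assert passed >= 190  # >= 95% of 200 seeds

    def test_n_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            shapiro_check([1.0, 2.0])


class TestCorrelateByGroup:
    @staticmethod
    def table(cells, samples, scores):
        return CellScoreTable.from_arrays(cells, samples, scores)

    def test_two_monotone_groups_both_significant(self):
        cells = [f"c{i}" for i in range(12)]
        samples = ["A"] * 6 + ["B"] * 6
        x = list(range(6)) + list(range(6))
        y = [2 * v for v in range(6)] + [3 * v + 1 for v in range(6)]
        records = correlate_by_group(
            self.table(cells, samples, x), self.table(cells, samples, y)
        )
        assert all(r.rho == pytest.approx(1.0) for r in records)
        assert all(r.p_adj < 0.05 for r in records)

    def test_constant_group_flagged_and_excluded_from_adjustment(self):
        cells = [f"c{i}" for i in range(10)]
        samples = ["A"] * 5 + ["B"] * 5
        x = list(range(5)) * 2
        y = [1.0] * 5 + [0, 1, 2, 3, 4]
        records = correlate_by_group(
            self.table(cells, samples, x), self.table(cells, samples, y)
        )
        by_group = {r.group_id: r for r in records}
        assert by_group["A"].flag == "constant input"
        # only one test entered BH, so adjusted equals raw
        assert by_group["B"].p_adj == pytest.approx(by_group["B"].p_raw)

    def test_adjustment_composes_bh_over_raw_ps(self, rng):
        cells = [f"c{i}" for i in range(40)]
        samples = [f"P{i // 10}" for i in range(40)]
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        records = correlate_by_group(
            self.table(cells, samples, x), self.table(cells, samples, y)
        )
        raw = np.array([r.p_raw for r in records])
        adj = np.array([r.p_adj for r in records])
        np.testing.assert_allclose(adj, bh_brute(raw), atol=1e-12)

    def test_disjoint_tables_rejected(self):
        a = self.table(["c1", "c2", "c3"], ["A"] * 3, [1, 2, 3])
        b = self.table(["d1", "d2", "d3"], ["A"] * 3, [1, 2, 3])
        with pytest.raises(ValidationError):
            correlate_by_group(a, b)


class TestDrugScreen:
    @staticmethod
    def line_scores(n, rng=None, values=None):
        lines = [f"L{i}" for i in range(n)]
        vals = values if values is not None else rng.uniform(size=n)
        return lines, CellScoreTable.from_arrays(lines, ["cohort"] * n, vals)

    def test_monotone_compound_counted_positive(self):
        lines, scores = self.line_scores(10, values=np.arange(10.0))
        viability = pd.DataFrame([np.arange(10.0) * 2 + 1], index=["drugA"],
                                 columns=lines)
        result = drug_screen(scores, viability)
        assert result.n_significant_positive == 1
        assert result.n_significant_negative == 0
        assert result.records[0].rho == pytest.approx(1.0)

    def test_all_missing_compound_skipped_with_reason(self):
        lines, scores = self.line_scores(5, values=np.arange(5.0))
        viability = pd.DataFrame(
            [[np.nan] * 5, list(range(5))], index=["empty", "ok"], columns=lines
        )
        result = drug_screen(scores, viability)
        assert "empty" in result.skipped
        assert len(result.records) == 1

    def test_counts_match_brute_force_refilter(self, rng):
        lines, scores = self.line_scores(15, rng=rng)
        vals = rng.normal(size=(30, 15))
        vals[rng.uniform(size=vals.shape) < 0.1] = np.nan
        viability = pd.DataFrame(vals, columns=lines,
                                 index=[f"d{i}" for i in range(30)])
        result = drug_screen(scores, viability, fdr_threshold=0.25)
        pos = sum(1 for r in result.records
                  if not r.flag and r.p_adj < 0.25 and r.rho > 0)
        neg = sum(1 for r in result.records
                  if not r.flag and r.p_adj < 0.25 and r.rho < 0)
        assert (result.n_significant_positive, result.n_significant_negative) == (pos, neg)
        assert pos + neg <= len(result.records)

    def test_line_order_does_not_matter(self, rng):
        lines, scores = self.line_scores(12, rng=rng)
        viability = pd.DataFrame(
            rng.normal(size=(8, 12)), columns=lines,
            index=[f"d{i}" for i in range(8)],
        )
        r1 = drug_screen(scores, viability)
        perm = list(rng.permutation(lines))
        r2 = drug_screen(scores, viability.loc[:, perm])
        for a, b in zip(r1.records, r2.records):
            assert a.rho == pytest.approx(b.rho, abs=1e-12)
            assert a.p_adj == pytest.approx(b.p_adj, abs=1e-12)

    def test_no_usable_compound_rejected(self):
        lines, scores = self.line_scores(4, values=np.arange(4.0))
        viability = pd.DataFrame([[np.nan, 1.0, 2.0, np.nan]], index=["d"],
                                 columns=lines)
        with pytest.raises(ValidationError):
            drug_screen(scores, viability)
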