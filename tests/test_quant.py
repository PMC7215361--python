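import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gluquant import (
    QuantConfig,
    benjamini_hochberg,
    call_differential,
    collapse_technical_replicates,
    filter_peptides,
    mann_whitney_p,
    occupancy_from_ratio,
    ratio_from_occupancy,
    ratio_of_ratios,
    rollup_to_proteins,
    run_differential,
    summarize_group,
)
from gluquant.quant import (
    DifferentialCall,
    GroupSummary,
    InsufficientSubjectsError,
)

from conftest import balanced_design, make_measurement

KEY = ("P1", "ACK", (2,))


def summary(values, group="case", key=KEY, **cfg):
    return summarize_group(values, key, group, QuantConfig(**cfg))


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

class TestFilter:
    def test_both_thresholds_inclusive(self):
        rows = [
            make_measurement(confidence_pct=96, h_to_l=0.5),
            make_measurement(confidence_pct=94, h_to_l=0.5),
            make_measurement(confidence_pct=96, h_to_l=0.005),
            make_measurement(confidence_pct=95, h_to_l=0.01),
        ]
        kept, log = filter_peptides(rows)
        assert kept == [rows[0], rows[3]]
        assert log.n_low_confidence == 1
        assert log.n_low_ratio == 1
        assert log.n_retained == 2

    def test_empty_input(self):
        kept, log = filter_peptides([])
        assert kept == [] and log.n_input == 0 and log.n_rejected == 0

    def test_all_low_confidence(self):
        rows = [make_measurement(confidence_pct=80) for _ in range(5)]
        kept, log = filter_peptides(rows)
        assert not kept
        assert log.n_low_confidence == 5 == log.n_rejected


# ---------------------------------------------------------------------------
# Replicate collapse and group summaries
# ---------------------------------------------------------------------------

class TestCollapse:
    def test_duplicates_averaged_per_subject(self):
        ms = balanced_design({("S1", "case"): [1.0, 3.0]})
        out = collapse_technical_replicates(ms)
        assert out["h_to_l"].tolist() == [2.0]
        assert out["n_replicates"].tolist() == [2]

    def test_single_replicate_passes_through(self):
        out = collapse_technical_replicates(
            balanced_design({("S1", "case"): [1.7]})
        )
        assert out["h_to_l"].tolist() == [1.7]

    def test_two_subjects_kept_separate(self):
        out = collapse_technical_replicates(
            balanced_design({("S1", "case"): [1.0], ("S2", "case"): [3.0]})
        )
        assert sorted(out["h_to_l"]) == [1.0, 3.0]


class TestGroupSummary:
    def test_arithmetic_mean(self):
        assert summary([1.0, 2.0, 3.0]).group_mean == pytest.approx(2.0)

    def test_constant_values_both_mean_kinds(self):
        for kind in ("arithmetic", "geometric"):
            s = summary([1.3] * 4, mean_kind=kind)
            assert s.group_mean == pytest.approx(1.3)

    def test_geometric_mean(self):
        s = summary([1.0, 4.0], mean_kind="geometric", min_subjects_per_group=2)
        assert s.group_mean == pytest.approx(2.0)

    def test_insufficient_subjects_excluded(self):
        with pytest.raises(InsufficientSubjectsError, match="insufficient"):
            summary([1.0, 2.0], min_subjects_per_group=3)


class TestRatioOfRatios:
    def test_equal_means_give_unity(self):
        s = summary([2.0, 2.0, 2.0])
        assert ratio_of_ratios(s, s) == pytest.approx(1.0)

    def test_division(self):
        case = summary([3.0, 3.0, 3.0])
        ctrl = summary([1.5, 1.5, 1.5], group="control")
        assert ratio_of_ratios(case, ctrl) == pytest.approx(2.0)

    def test_zero_control_mean_is_error(self):
        case = summary([3.0, 3.0, 3.0])
        ctrl = GroupSummary(KEY, "control", (0.0, 0.0, 0.0), 0.0)
        with pytest.raises(ValueError, match="undefined ratio"):
            ratio_of_ratios(case, ctrl)


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

def brute_force_mw_p(a, b):
    """Independent oracle: enumerate all group labelings of the pooled sample.

    Two-sided p = probability, over all C(n_a+n_b, n_a) assignments, that the
    U statistic is at least as extreme (in |U - mn/2|) as observed.  U is
    computed from midranks, so U = #(x>y) + 0.5*#(x==y).
    """
    from scipy.stats import rankdata

    pooled = np.concatenate([np.asarray(a, float), np.asarray(b, float)])
    n_a, n_b = len(a), len(b)
    ranks = [float(r) for r in rankdata(pooled)]
    offset = n_a * (n_a + 1) / 2
    mu = n_a * n_b / 2
    observed = abs(sum(ranks[:n_a]) - offset - mu)
    count = total = 0
    for idx in itertools.combinations(range(n_a + n_b), n_a):
        u = sum(ranks[i] for i in idx) - offset
        total += 1
        if abs(u - mu) >= observed - 1e-12:
            count += 1
    return count / total


class TestMannWhitney:
    def test_fully_separated_small_groups(self):
        # U=0 attained by one labeling per tail among C(6,3)=20 -> p = 2/20
        assert mann_whitney_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_single_tied_pair(self):
        assert mann_whitney_p([5], [5]) == 1.0

    def test_identical_small_groups(self):
        assert mann_whitney_p([1, 2], [1, 2]) == pytest.approx(1.0)

    def test_empty_group_error(self):
        with pytest.raises(ValueError):
            mann_whitney_p([], [1.0])

    def test_exact_matches_enumeration_oracle(self):
        """Exact branch equals brute-force labeling enumeration to 1e-12."""
        rng = np.random.default_rng(2024)
        for _ in range(200):
            n_a = int(rng.integers(2, 6))
            n_b = int(rng.integers(2, 6))
            pooled = rng.permutation(np.arange(1, n_a + n_b + 1)).astype(float)
            a, b = pooled[:n_a], pooled[n_a:]
            p = mann_whitney_p(a, b, exact_test_max_n=12)
            assert p == pytest.approx(brute_force_mw_p(a, b), abs=1e-12)

    def test_asymptotic_branch_used_beyond_max_n(self):
        a = list(range(1, 12))
        b = list(range(12, 19))
        p_asym = mann_whitney_p(a, b, exact_test_max_n=12)
        assert 0 < p_asym <= 1

    @settings(max_examples=50, deadline=None)
    @given(
        scale=st.floats(0.01, 100),
        n_a=st.integers(3, 6),
        n_b=st.integers(3, 6),
        seed=st.integers(0, 10_000),
    )
    def test_scale_equivariance(self, scale, n_a, n_b, seed):
        """Multiplying all values by a constant leaves the p-value unchanged."""
        rng = np.random.default_rng(seed)
        a = rng.lognormal(0, 0.5, n_a)
        b = rng.lognormal(0, 0.5, n_b)
        assert mann_whitney_p(a, b) == pytest.approx(
            mann_whitney_p(a * scale, b * scale), rel=1e-9
        )


# ---------------------------------------------------------------------------
# Differential calls
# ---------------------------------------------------------------------------

class TestDifferentialCall:
    def call(self, case_vals, ctrl_vals, p, **cfg):
        config = QuantConfig(**cfg)
        case = summarize_group(case_vals, KEY, "case", config)
        ctrl = summarize_group(ctrl_vals, KEY, "control", config)
        return call_differential(case, ctrl, p, config)

    def test_fold_cutoff_strict(self):
        c = self.call([1.5] * 3, [1.0] * 3, p=0.01)
        assert c.ratio_of_ratios == pytest.approx(1.5)
        assert not c.passes_fold and not c.significant

    def test_fold_without_significance(self):
        c = self.call([2.0] * 3, [1.0] * 3, p=0.2)
        assert c.passes_fold and not c.passes_p and not c.significant

    def test_fold_and_significance(self):
        c = self.call([2.0] * 3, [1.0] * 3, p=0.01)
        assert c.significant

    def test_alpha_strict(self):
        c = self.call([2.0] * 3, [1.0] * 3, p=0.05)
        assert not c.passes_p

    def test_two_sided_calls_catch_decreases(self):
        c = self.call([0.5] * 3, [1.0] * 3, p=0.01, two_sided_calls=True)
        assert c.passes_fold and c.significant
        c1 = self.call([0.5] * 3, [1.0] * 3, p=0.01)
        assert not c1.passes_fold

    def test_bh_q_used_when_enabled(self):
        config = QuantConfig(mtc="benjamini_hochberg")
        case = summarize_group([2.0] * 3, KEY, "case", config)
        ctrl = summarize_group([1.0] * 3, KEY, "control", config)
        c = call_differential(case, ctrl, p_value=0.01, config=config, q_value=0.2)
        assert not c.passes_p


class TestBenjaminiHochberg:
    def test_q_monotone_and_never_below_p(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=40)
        q = benjamini_hochberg(p)
        assert np.all(q >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)


# ---------------------------------------------------------------------------
# Protein rollup
# ---------------------------------------------------------------------------

def call(acc, ror, p, sig):
    return DifferentialCall(
        key=(acc, "ACK", (2,)),
        ratio_of_ratios=ror,
        p_value=p,
        q_value=None,
        passes_fold=ror > 1.5,
        passes_p=p < 0.05,
        significant=sig,
    )


class TestRollup:
    def test_any_peptide_rule(self):
        calls = [call("P1", 2.0, 0.01, True), call("P1", 1.1, 0.5, False)]
        (pc,) = rollup_to_proteins(calls)
        assert pc.significant and pc.n_peptides_significant == 1
        assert pc.best_ratio_of_ratios == 2.0 and pc.best_p_value == 0.01

    def test_no_significant_peptides(self):
        (pc,) = rollup_to_proteins([call("P1", 1.1, 0.5, False)])
        assert not pc.significant

    def test_grouping_counts(self):
        calls = [call("P1", 2.0, 0.01, True) for _ in range(3)]
        (pc,) = rollup_to_proteins(calls)
        assert pc.n_peptides_total == 3 == pc.n_peptides_significant

    def test_conservation_of_peptide_counts(self):
        calls = [
            call(f"P{i % 4}", 1.0 + i / 10, 0.5, False) for i in range(10)
        ]
        rolled = rollup_to_proteins(calls)
        assert sum(pc.n_peptides_total for pc in rolled) == len(calls)


# ---------------------------------------------------------------------------
# Occupancy transform
# ---------------------------------------------------------------------------

class TestOccupancy:
    def test_symmetric_point(self):
        assert occupancy_from_ratio(1.0) == pytest.approx(0.5)

    def test_high_occupancy(self):
        assert ratio_from_occupancy(0.8) == pytest.approx(4.0)

    def test_zero(self):
        assert occupancy_from_ratio(0.0) == 0.0

    def test_unbounded_at_full_occupancy(self):
        with pytest.raises(ValueError):
            ratio_from_occupancy(1.0)

    def test_mutually_inverse_on_grid(self):
        for theta in np.linspace(0.0, 0.99, 200):
            assert occupancy_from_ratio(ratio_from_occupancy(theta)) == (
                pytest.approx(theta, abs=1e-12)
            )


# ---------------------------------------------------------------------------
# Full driver invariants
# ---------------------------------------------------------------------------

def design_measurements(case_values, ctrl_values, n_reps=1, **kwargs):
    by_subject = {}
    for i, v in enumerate(case_values):
        by_subject[(f"CASE{i}", "case")] = [v] * n_reps
    for i, v in enumerate(ctrl_values):
        by_subject[(f"CTRL{i}", "control")] = [v] * n_reps
    return balanced_design(by_subject, **kwargs)


class TestRunDifferential:
    def test_identical_groups_give_unity_and_no_calls(self):
        values = [0.8, 1.1, 1.4, 0.9]
        ms = design_measurements(values, values)
        res = run_differential(ms)
        row = res.peptide_calls.iloc[0]
        assert row.ratio_of_ratios == pytest.approx(1.0)
        assert not row.significant

    def test_scaling_case_values_never_decreases_ror(self):
        case = [1.0, 1.2, 0.9, 1.1]
        ctrl = [1.0, 0.8, 1.3, 0.95]
        base = run_differential(design_measurements(case, ctrl))
        for factor in (1.5, 2.0, 4.0):
            scaled = run_differential(
                design_measurements([v * factor for v in case], ctrl)
            )
            assert (
                scaled.peptide_calls.iloc[0].ratio_of_ratios
                >= base.peptide_calls.iloc[0].ratio_of_ratios
            )

    def test_global_scale_equivariance(self):
        case = [1.4, 1.8, 1.2, 1.6]
        ctrl = [1.0, 0.8, 1.1, 0.9]
        res1 = run_differential(design_measurements(case, ctrl))
        res2 = run_differential(
            design_measurements(
                [v * 7.3 for v in case], [v * 7.3 for v in ctrl]
            )
        )
        r1, r2 = res1.peptide_calls.iloc[0], res2.peptide_calls.iloc[0]
        assert r1.ratio_of_ratios == pytest.approx(r2.ratio_of_ratios)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_insufficient_subjects_logged_not_tested(self):
        ms = design_measurements([1.0, 1.1], [1.0, 1.1, 0.9])
        res = run_differential(ms)
        assert res.n_excluded_insufficient == 1
        assert len(res.peptide_calls) == 0

    def test_rollup_conservation(self, small_sim):
        from gluquant.pipeline import _frame_to_measurements

        res = run_differential(_frame_to_measurements(small_sim.table))
        assert (
            res.protein_calls["n_peptides_total"].sum()
            == len(res.peptide_calls)
        )
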