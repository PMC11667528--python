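"""Group summaries, exact tests, stage-marker correlations, progression."""
import itertools
import math

import numpy as np
import pytest
from scipy import stats

from amypath.cohort import Cohort, SubjectRecord
from amypath.evaluation import (compare_groups, fisher_exact_2xk,
                                progression_summary, stage_marker_correlation,
                                summarize_groups)
from amypath.sustain.model import SubjectAssignment


def _assignment(sid, subtype, stage):
    unsub = stage == 0
    post = [0.0, 0.0, 0.0]
    post[0 if subtype is None else subtype] = 1.0
    n_stages = 18
    stage_post = [0.0] * (n_stages + 1)
    stage_post[stage] = 1.0
    return SubjectAssignment(
        subject_id=sid, subtype_posterior=tuple(post),
        ml_subtype=None if unsub else subtype, ml_stage=stage,
        stage_posterior=tuple(stage_post), unsubtyped=unsub,
    )


def _case(sid, dx="MCI", fu=(), **kw):
    defaults = dict(csf_abeta=200.0, csf_ptau181=25.0, wmh_ml=4.0,
                    wbv_ml=1060.0, hip_ml=5.2, tiv_ml=1420.0, lm_score=9.0,
                    tmt_a_s=40.0, tmt_b_s=110.0, age_years=73.0, mmse=27.0)
    defaults.update(kw)
    return SubjectRecord(subject_id=sid, baseline_diagnosis=dx,
                         followup_diagnoses=fu, **defaults)


def _hand_fisher_2x2(table):
    """Exhaustive hypergeometric two-sided p (probability-mass rule)."""
    a, b = table[0]
    c, d = table[1]
    r1, c1, n = a + b, a + c, a + b + c + d

    def prob(x):
        return (math.comb(c1, x) * math.comb(n - c1, r1 - x)) / math.comb(n, r1)

    p_obs = prob(a)
    return sum(prob(x) for x in range(max(0, r1 - (n - c1)), min(r1, c1) + 1)
               if prob(x) <= p_obs * (1 + 1e-9))


class TestFisherExact:
    def test_hand_oracle_2x2(self):
        table = [[3, 7], [9, 1]]
        p, _ = fisher_exact_2xk(np.array(table))
        assert p == pytest.approx(_hand_fisher_2x2(table), abs=1e-12)
        assert p == pytest.approx(stats.fisher_exact(table).pvalue, abs=1e-12)

    def test_matches_scipy_on_small_tables(self):
        # every 2x2 table with margins summing to <= 40 and cells <= 6
        for a, b, c, d in itertools.product(range(5), repeat=4):
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            table = np.array([[a, b], [c, d]])
            p, _ = fisher_exact_2xk(table)
            assert p == pytest.approx(stats.fisher_exact(table).pvalue, abs=1e-9)

    def test_proportional_margins_give_p_one(self):
        p, _ = fisher_exact_2xk(np.array([[4, 4], [6, 6]]))
        assert p == pytest.approx(1.0)

    def test_2x3_against_r_reference(self):
        # R: fisher.test(matrix(c(8,2,4,5,3,9), nrow=2)) -> p = 0.0363986
        p, _ = fisher_exact_2xk(np.array([[8, 4, 3], [2, 5, 9]]))
        assert p == pytest.approx(0.0363986, abs=5e-5)

    def test_monte_carlo_fallback_agrees(self):
        table = np.array([[8, 4, 3], [2, 5, 9]])
        exact, _ = fisher_exact_2xk(table)
        mc, _ = fisher_exact_2xk(table, seed=1, max_tables=1, n_simulations=100_000)
        assert mc == pytest.approx(exact, abs=0.01)


class TestCompareGroups:
    def test_continuous_equals_one_way_anova(self, rng):
        groups = {f"g{i}": rng.normal(i * 0.5, 1.0, 30) for i in range(3)}
        f_stat, p = compare_groups(groups, "continuous")
        ref = stats.f_oneway(*[groups[g] for g in sorted(groups)])
        assert f_stat == pytest.approx(ref.statistic, rel=1e-6)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_degenerate_values_rejected(self):
        with pytest.raises(ValueError):
            compare_groups({"a": np.ones(5), "b": np.ones(5)}, "continuous")
        with pytest.raises(ValueError):
            compare_groups({"a": np.ones(5)}, "continuous")

    def test_categorical_routes_to_fisher(self):
        counts = {"a": [3, 7], "b": [9, 1]}
        _, p = compare_groups(counts, "categorical")
        assert p == pytest.approx(_hand_fisher_2x2([[3, 9], [7, 1]]), abs=1e-12)


class TestStageCorrelation:
    def test_perfect_linear_marker(self):
        assigns = [_assignment(f"S{i}", 0, i + 1) for i in range(10)]
        vals = {f"S{i}": 2.0 * (i + 1) + 3.0 for i in range(10)}
        r = stage_marker_correlation(assigns, vals, 0, "m")
        assert r.coefficient == pytest.approx(1.0)
        assert r.kind == "pairwise"

    def test_independent_marker_decorrelates(self):
        gen = np.random.default_rng(77)
        n = 500
        assigns = [_assignment(f"S{i}", 0, int(gen.integers(1, 19)))
                   for i in range(n)]
        vals = {f"S{i}": float(gen.normal()) for i in range(n)}
        r = stage_marker_correlation(assigns, vals, 0, "m")
        assert abs(r.coefficient) < 0.1

    def test_semi_partial_degenerate_adjustment(self):
        assigns = [_assignment(f"S{i}", 0, i + 1) for i in range(10)]
        vals = {f"S{i}": float(i) for i in range(10)}
        with pytest.raises(ValueError, match="degenerate|constant"):
            stage_marker_correlation(assigns, vals, 0, "m",
                                     adjustment_values=vals, adjustment_name="self")

    def test_semi_partial_equals_pairwise_for_orthogonal_covariate(self):
        gen = np.random.default_rng(5)
        n = 200
        stages = gen.integers(1, 19, n)
        marker = 0.5 * stages + gen.normal(0, 1, n)
        cov = gen.normal(0, 1, n)
        cov = cov - np.polyval(np.polyfit(marker, cov, 1), marker)  # orthogonalize
        assigns = [_assignment(f"S{i}", 0, int(s)) for i, s in enumerate(stages)]
        mvals = {f"S{i}": float(v) for i, v in enumerate(marker)}
        cvals = {f"S{i}": float(v) for i, v in enumerate(cov)}
        plain = stage_marker_correlation(assigns, mvals, 0, "m")
        semi = stage_marker_correlation(assigns, mvals, 0, "m",
                                        adjustment_values=cvals,
                                        adjustment_name="cov")
        assert semi.kind == "semi_partial"
        assert semi.coefficient == pytest.approx(plain.coefficient, abs=1e-6)

    def test_too_few_subjects(self):
        assigns = [_assignment("A", 0, 1), _assignment("B", 0, 2)]
        with pytest.raises(ValueError):
            stage_marker_correlation(assigns, {"A": 1.0, "B": 2.0}, 0, "m")


class TestSummaries:
    def test_group_sizes_and_percentages(self):
        cases = Cohort(tuple(
            [_case(f"S{i}", dx="MCI") for i in range(3)]
            + [_case(f"U{i}", dx="CN") for i in range(2)]
        ))
        assigns = [_assignment(f"S{i}", 0, i + 1) for i in range(3)]
        assigns += [_assignment(f"U{i}", None, 0) for i in range(2)]
        summary = summarize_groups(cases, assigns)
        assert summary.group_ns == {"unsubtyped": 2, "subtype_0": 3}
        assert sum(summary.group_ns.values()) == len(cases)
        # diagnosis mix row formats counts and nearest-integer percentages
        row = summary.table.loc["Diagnosis CN:MCI:AD (%)"]
        assert row["subtype_0"] == "0:3:0 (0:100:0)"

    def test_printed_share_arithmetic(self):
        # 43 unsubtyped of 376 cases is 11% to the nearest integer
        assert round(100 * 43 / 376) == 11
        # a 7:93:45 diagnosis split is 64% MCI
        assert round(100 * 93 / (7 + 93 + 45)) == 64


class TestProgression:
    def test_outcome_classification(self):
        cases = Cohort((
            _case("P1", dx="MCI", fu=((12, "AD"),)),          # progressed
            _case("M1", dx="CN", fu=((36, "MCI"),)),          # missing in horizon
            _case("R1", dx="MCI", fu=((6, "CN"), (24, "MCI"))),  # worst=MCI: stable
            _case("S1", dx="CN", fu=((24, "CN"),)),           # stable
        ))
        assigns = [_assignment(s, 0, 3) for s in ("P1", "M1", "R1", "S1")]
        table = progression_summary(cases, assigns)
        counts = table.counts.loc[("subtype_0", "MCI")]
        assert counts["progressed"] == 1 and counts["stable"] == 1
        cn = table.counts.loc[("subtype_0", "CN")]
        assert cn["missing"] == 1 and cn["stable"] == 1

    def test_reversion_detected(self):
        cases = Cohort((_case("R2", dx="MCI", fu=((12, "CN"), (24, "CN"))),))
        table = progression_summary(cases, [_assignment("R2", 0, 2)])
        assert table.counts.loc[("subtype_0", "MCI"), "reverted"] == 1

    def test_counts_conserved(self):
        gen = np.random.default_rng(3)
        cases, assigns = [], []
        for i in range(40):
            dx = "CN" if i % 2 else "MCI"
            fu = ((24, gen.choice(["CN", "MCI", "AD"])),) if i % 5 else ()
            cases.append(_case(f"S{i}", dx=dx, fu=fu))
            assigns.append(_assignment(f"S{i}", int(i % 2), 1 + i % 17))
        table = progression_summary(Cohort(tuple(cases)), assigns)
        assert int(table.counts.to_numpy().sum()) == 40
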