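import math

import numpy as np
import pytest
from scipy import stats as sps

from csfbc import stats as cst
from csfbc.fixtures_io import load_cohort_fixture


@pytest.fixture(scope="module")
def table2():
    return load_cohort_fixture("healthy")


@pytest.fixture(scope="module")
def table3():
    return load_cohort_fixture("patient")


class TestRoundHalfUp:
    @pytest.mark.parametrize("x,nd,expected", [
        (36.15, 1, 36.2), (2.25, 1, 2.3), (13.871, 1, 13.9), (0.805, 2, 0.81),
    ])
    def test_convention(self, x, nd, expected):
        assert cst.round_half_up(x, nd) == expected


class TestDescriptives:
    def test_two_point_closed_form(self):
        """(0, 2): mean 1, sd sqrt(2), se 1, CI 1 +/- t_{0.975,1} = 12.7062."""
        d = cst.descriptives([0.0, 2.0])
        assert d.mean == 1.0
        assert d.sd == pytest.approx(math.sqrt(2.0), rel=1e-12)
        assert d.se == pytest.approx(1.0, rel=1e-12)
        assert d.ci_lower == pytest.approx(1.0 - 12.7062, abs=1e-3)
        assert d.ci_upper == pytest.approx(1.0 + 12.7062, abs=1e-3)

    def test_constant_vector(self):
        d = cst.descriptives([5.0, 5.0, 5.0])
        assert d.sd == 0.0 and d.cv_percent == 0.0
        assert (d.ci_lower, d.ci_upper) == (5.0, 5.0)

    def test_healthy_sas_pressure_row(self, table2):
        """The healthy-group SAS pressure row under the sinusoidal-pressure
        scheme reproduces all its printed summary cells."""
        d = cst.descriptives(table2.values("max_pressure_SAS_BC_A_Pa"))
        assert cst.round_half_up(d.mean) == 650.0
        assert cst.round_half_up(d.sd) == 62.5
        assert cst.round_half_up(d.se) == 22.1
        assert cst.round_half_up(d.cv_percent) == 9.6
        assert cst.round_half_up(d.ci_lower) == 597.7
        assert cst.round_half_up(d.ci_upper) == 702.3

    def test_preconditions(self):
        with pytest.raises(ValueError):
            cst.descriptives([1.0])
        with pytest.raises(ValueError, match="zero mean"):
            cst.descriptives([-1.0, 1.0])


class TestFullTableRegression:
    @pytest.mark.parametrize("which", ["healthy", "patient"])
    def test_every_summary_cell(self, which):
        """Every printed Mean/SD/SE/CV/CI cell is recomputed from its
        per-subject row to one unit in the last printed decimal; the
        two cells typeset wrongly in the source are flagged, and the
        correct interval is asserted instead."""
        table = load_cohort_fixture(which)
        records = cst.verify_printed_summaries(table)
        bad = [r for r in records if not r["ok"] and not r["skipped"]]
        assert bad == []
        skipped = [r for r in records if r["skipped"]]
        if which == "patient":
            assert {(r["variable"], r["cell"]) for r in skipped} == {
                ("experimental_ICP_SAS_Pa", "ci_lower"),
                ("experimental_ICP_SAS_Pa", "ci_upper"),
            }
            d = cst.descriptives(table.values("experimental_ICP_SAS_Pa", drop_missing=True))
            assert cst.round_half_up(d.ci_lower) == 2553.5
            assert cst.round_half_up(d.ci_upper) == 2723.5
        else:
            assert skipped == []


class TestPearson:
    def test_perfect_correlations(self):
        x = np.array([1.0, 2.0, 4.0, 8.0])
        assert cst.pcc(x, 2 * x + 1).r == pytest.approx(1.0)
        assert cst.pcc(x, -x).r == pytest.approx(-1.0)

    def test_p_value_is_t_transform(self, rng):
        x = rng.standard_normal(12)
        y = x + rng.standard_normal(12)
        res = cst.pcc(x, y)
        t = res.r * math.sqrt((res.n - 2) / (1 - res.r**2))
        p = 2 * sps.t.sf(abs(t), res.n - 2)
        assert res.p_value == pytest.approx(p, rel=1e-9)

    def test_affine_invariance(self, rng):
        x = rng.standard_normal(10)
        y = rng.standard_normal(10)
        r0 = cst.pcc(x, y).r
        assert cst.pcc(3 * x - 7, y).r == pytest.approx(r0, rel=1e-12)
        assert cst.pcc(-2 * x, y).r == pytest.approx(-r0, rel=1e-12)

    def test_patient_pressure_volume_correlation(self, table3):
        """Recomputed from the printed patient rows, the flow-flow-scheme
        correlation between peak SAS pressure and ventricular volume is
        0.73 (the printed 0.81 is not derivable from the tables)."""
        res = cst.pcc(table3.values("max_pressure_SAS_BC_C_Pa"),
                      table3.values("ventricular_volume_ml"))
        assert cst.round_half_up(res.r, 2) == 0.73
        assert res.n == 11

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            cst.pcc([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestShapiroWilk:
    def test_normal_quantiles_score_high(self):
        q = sps.norm.ppf((np.arange(1, 9) - 0.5) / 8)
        W, p = cst.shapiro_wilk(q)
        assert W > 0.95

    def test_bimodal_rejected(self):
        W, p = cst.shapiro_wilk([-10.0] * 4 + [10.0] * 4)
        assert p < 0.05

    def test_location_scale_invariance(self, rng):
        x = rng.standard_normal(15)
        W1, _ = cst.shapiro_wilk(x)
        W2, _ = cst.shapiro_wilk(5.0 * x - 3.0)
        assert W1 == pytest.approx(W2, rel=1e-9)

    def test_n_range(self):
        with pytest.raises(ValueError):
            cst.shapiro_wilk([1.0, 2.0])


class TestAnovaTukey:
    def test_identical_groups(self):
        g = [1.0, 2.0, 3.0, 4.0]
        F, p, table = cst.anova_tukey([g, g, g])
        assert F == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)
        assert all(row["p_adj"] > 0.95 and not row["reject"] for row in table)

    def test_two_groups_equal_t_squared(self, rng):
        x = rng.standard_normal(9) + 0.3
        y = rng.standard_normal(7)
        F, pF, _ = cst.anova_tukey([x, y])
        t, pt, _ = cst.t_test(x, y)
        assert F == pytest.approx(t**2, rel=1e-9)
        assert pF == pytest.approx(pt, rel=1e-9)

    def test_single_shifted_group_detected(self, rng):
        a = rng.standard_normal(10)
        b = rng.standard_normal(10)
        c = rng.standard_normal(10) + 8.0
        _, _, table = cst.anova_tukey([a, b, c])
        by_pair = {(r["group1"], r["group2"]): r["reject"] for r in table}
        assert by_pair[(0, 2)] and by_pair[(1, 2)] and not by_pair[(0, 1)]

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            cst.anova_tukey([[1.0, 2.0]])


class TestStudentT:
    def test_identical_samples(self):
        x = [1.0, 2.0, 3.0, 4.0]
        t, p, var_p = cst.t_test(x, x)
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)
        assert var_p == pytest.approx(1.0)

    def test_textbook_value(self):
        """(1,2,3) vs (4,5,6): pooled sd 1, se sqrt(2/3), t = -3.6742."""
        t, _, _ = cst.t_test([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert t == pytest.approx(-3.0 / math.sqrt(2.0 / 3.0), rel=1e-9)
        assert t == pytest.approx(-3.6742, abs=1e-4)

    def test_antisymmetry(self, rng):
        x = rng.standard_normal(6)
        y = rng.standard_normal(8) + 1
        t_xy, _, _ = cst.t_test(x, y)
        t_yx, _, _ = cst.t_test(y, x)
        assert t_xy == pytest.approx(-t_yx, rel=1e-12)


@pytest.fixture(scope="module")
def report():
    return cst.claims_report(load_cohort_fixture("healthy"), load_cohort_fixture("patient"))


class TestClaimsReport:

    def test_lists_at_least_twelve_claims_with_inputs(self, report):
        assert len(report.claims) >= 12
        assert all(c.inputs for c in report.claims)

    def test_gate_passes_on_fixtures(self, report):
        assert report.gate_passed

    def test_volume_claims(self, report):
        assert report["ventricular_volume_ratio"].computed_rounded == 13.9
        assert report["brain_volume_reduction_percent"].computed_rounded == 17.4
        assert report["sas_volume_increase_percent"].computed <= 2.4

    def test_flagged_claims(self, report):
        assert report["icp_agreement_percent_bc_A"].flag == "borderline"
        for scheme in ("A", "B", "C"):
            assert report[f"pcc_bc_{scheme}"].flag == "irreproducible"

    def test_missing_variable_named(self, table2, table3):
        broken = load_cohort_fixture("patient")
        del broken.variables["ventricular_volume_ml"]
        with pytest.raises(KeyError, match="ventricular_volume_ml"):
            cst.claims_report(table2, broken)
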