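"""Fixed-ratio additivity arithmetic, t comparison and classification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from isobol import (
    MixtureED50,
    MixtureSpec,
    additive_mixture_ed50,
    compare_mixture_ed50,
    eligible_fixed_ratios,
    isobologram_projections,
    mixture_composition,
    ParallelismResult,
)

from conftest import make_fit


def _spec(*drugs, ratio=None):
    ratio = ratio or ":".join("1" for _ in drugs)
    return MixtureSpec.from_ratio(drugs, ratio)


def _par(a, b, parallel):
    p = 0.5 if parallel else 0.001
    return ParallelismResult(
        statistic=0.0 if parallel else 5.0,
        df_description="z",
        p_value=p,
        parallel=parallel,
        alpha=0.05,
        slope_a=6.0,
        slope_b=6.0 if parallel else 2.0,
    )


def _mix(kind, total, sem, drugs=("A", "B"), df=24):
    comp = {d: total / len(drugs) for d in drugs}
    comp[drugs[-1]] = total - sum(comp[d] for d in drugs[:-1])
    return MixtureED50(kind=kind, total_ed50=total, sem=sem,
                       component_doses=comp, df=df)


class TestMixtureSpec:
    def test_ratio_parsing_and_label(self):
        spec = _spec("A", "B", "C")
        assert spec.fractions == pytest.approx((1 / 3,) * 3)
        assert spec.ratio_label == "1:1:1"
        assert spec.is_equieffective
        uneven = MixtureSpec.from_ratio(("A", "B"), "1:3")
        assert uneven.fractions == pytest.approx((0.25, 0.75))
        assert not uneven.is_equieffective

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            MixtureSpec(("A",), (1.0,))
        with pytest.raises(ValueError):
            MixtureSpec(("A", "B"), (0.5, 0.6))
        with pytest.raises(ValueError):
            MixtureSpec(("A", "A"), (0.5, 0.5))


class TestAdditiveMixtureEd50:
    def test_homogeneous_components(self):
        fits = [make_fit(d, 10.0, sem_ed50=1.0) for d in "ABC"]
        add = additive_mixture_ed50(fits, _spec("A", "B", "C"))
        assert add.total_ed50 == pytest.approx(10.0)
        assert all(v == pytest.approx(10 / 3) for v in add.component_doses.values())

    def test_closed_form_sem_propagation(self):
        fits = [
            make_fit("A", 3.0, sem_ed50=3.0),
            make_fit("B", 6.0, sem_ed50=3.0),
            make_fit("C", 9.0, sem_ed50=3.0),
        ]
        add = additive_mixture_ed50(fits, _spec("A", "B", "C"))
        assert add.total_ed50 == pytest.approx(6.0)
        assert add.sem == pytest.approx(math.sqrt(27) / 3)

    def test_three_drug_worked_example_breakdown(self, three_drug_fits):
        # equi-effective 1:1:1 mixture of LCM/LTG/VPA: component doses are
        # one third of each ED50 and sum to the additive total
        add = additive_mixture_ed50(three_drug_fits, _spec("LCM", "LTG", "VPA"))
        assert add.component_doses["LCM"] == pytest.approx(2.42, abs=0.005)
        assert add.component_doses["LTG"] == pytest.approx(2.17, abs=0.005)
        assert add.component_doses["VPA"] == pytest.approx(99.53, abs=0.005)
        assert add.total_ed50 == pytest.approx(104.12, abs=0.005)

    def test_component_count_mismatch(self, three_drug_fits):
        with pytest.raises(ValueError):
            additive_mixture_ed50(three_drug_fits[:2], _spec("LCM", "LTG", "VPA"))

    @settings(derandomize=True, max_examples=50)
    @given(c=st.floats(0.01, 100.0))
    def test_homogeneity_in_component_ed50s(self, c):
        base = [make_fit(d, e, sem_ed50=0.1 * e) for d, e in
                zip("ABC", (3.0, 7.0, 40.0))]
        scaled = [make_fit(d, e * c, sem_ed50=0.1 * e * c) for d, e in
                  zip("ABC", (3.0, 7.0, 40.0))]
        spec = _spec("A", "B", "C")
        a0 = additive_mixture_ed50(base, spec)
        a1 = additive_mixture_ed50(scaled, spec)
        assert a1.total_ed50 == pytest.approx(c * a0.total_ed50, rel=1e-9)
        for d in "ABC":
            assert a1.component_doses[d] == pytest.approx(
                c * a0.component_doses[d], rel=1e-9
            )


class TestMixtureComposition:
    def test_identity_at_additive_total(self, three_drug_fits):
        spec = _spec("LCM", "LTG", "VPA")
        add = additive_mixture_ed50(three_drug_fits, spec)
        comp = mixture_composition(add.total_ed50, three_drug_fits, spec)
        for d in spec.drug_ids:
            assert comp[d] == pytest.approx(add.component_doses[d], rel=1e-9)

    def test_worked_example_at_experimental_total(self, three_drug_fits):
        # scaling the additive proportions up to a 131.70 mg/kg total
        comp = mixture_composition(131.70, three_drug_fits, _spec("LCM", "LTG", "VPA"))
        assert round(comp["VPA"], 2) == 125.89
        assert round(comp["LTG"], 2) == 2.74
        assert sum(comp.values()) == pytest.approx(131.70, abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(total=st.floats(0.01, 1e4))
    def test_conservation(self, total):
        fits = [make_fit(d, e) for d, e in zip("ABC", (7.26, 6.51, 298.59))]
        comp = mixture_composition(total, fits, _spec("A", "B", "C"))
        assert sum(comp.values()) == pytest.approx(total, rel=1e-12)


class TestEligibleFixedRatios:
    def test_all_parallel_allows_any_ratio(self):
        mat = {p: _par(*p, True) for p in
               [("A", "B"), ("A", "C"), ("B", "C")]}
        policy = eligible_fixed_ratios(mat, ["A", "B", "C"])
        assert policy.all_parallel
        assert policy.allows(_spec("A", "B", "C", ratio="1:2:3"))

    def test_one_nonparallel_pair_restricts_to_equieffective(self):
        # e.g. VPA non-parallel to both LCM and LTG: only 1:1:1 remains
        mat = {
            ("LCM", "LTG"): _par("LCM", "LTG", True),
            ("LCM", "VPA"): _par("LCM", "VPA", False),
            ("LTG", "VPA"): _par("LTG", "VPA", False),
        }
        policy = eligible_fixed_ratios(mat, ["LCM", "LTG", "VPA"])
        assert not policy.all_parallel
        assert policy.allows(_spec("LCM", "LTG", "VPA"))
        assert not policy.allows(_spec("LCM", "LTG", "VPA", ratio="1:1:2"))
        assert "VPA" in policy.reason

    def test_two_drug_nonparallel(self):
        mat = {("A", "B"): _par("A", "B", False)}
        policy = eligible_fixed_ratios(mat, ["A", "B"])
        assert policy.allows(_spec("A", "B"))
        assert not policy.allows(_spec("A", "B", ratio="1:3"))

    def test_incomplete_matrix_rejected(self):
        mat = {("A", "B"): _par("A", "B", True)}
        with pytest.raises(ValueError):
            eligible_fixed_ratios(mat, ["A", "B", "C"])


class TestCompareMixtureEd50:
    def test_null_case(self):
        exp = _mix("experimental", 100.0, 5.0)
        add = _mix("additive_theoretical", 100.0, 5.0)
        r = compare_mixture_ed50(exp, add, df=10)
        assert r.t_statistic == 0.0
        assert r.p_value == pytest.approx(1.0)
        assert r.classification == "additive"

    def test_t_formula_on_rounded_worked_example(self):
        # (131.70 - 104.12) / sqrt(8.30^2 + 5.06^2) = 2.8372
        exp = _mix("experimental", 131.70, 8.30)
        add = _mix("additive_theoretical", 104.12, 5.06)
        r = compare_mixture_ed50(exp, add, df=64)
        assert r.t_statistic == pytest.approx(2.8372, abs=5e-5)
        assert r.interaction_index == pytest.approx(131.70 / 104.12, rel=1e-9)
        assert r.classification == "sub_additive"

    def test_sign_coherence(self):
        exp_hi = _mix("experimental", 150.0, 4.0)
        exp_lo = _mix("experimental", 60.0, 4.0)
        add = _mix("additive_theoretical", 100.0, 4.0)
        sub = compare_mixture_ed50(exp_hi, add, df=60)
        sup = compare_mixture_ed50(exp_lo, add, df=60)
        assert sub.classification == "sub_additive"
        assert sub.t_statistic > 0 and sub.interaction_index > 1
        assert sup.classification == "supra_additive"
        assert sup.t_statistic < 0 and sup.interaction_index < 1

    def test_nonsignificant_difference_stays_additive(self):
        exp = _mix("experimental", 110.0, 20.0)
        add = _mix("additive_theoretical", 100.0, 20.0)
        r = compare_mixture_ed50(exp, add, df=20)
        assert r.classification == "additive"

    def test_p_decreasing_in_abs_t(self):
        add = _mix("additive_theoretical", 100.0, 5.0)
        ps = [
            compare_mixture_ed50(_mix("experimental", tot, 5.0), add, df=30).p_value
            for tot in (105.0, 115.0, 130.0, 160.0)
        ]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_df_policies(self):
        exp = _mix("experimental", 131.70, 8.30, df=24)
        add = _mix("additive_theoretical", 104.12, 5.06, df=88)
        by_animals = compare_mixture_ed50(exp, add, df_policy="animals")
        assert by_animals.df == 24 + 88 - 4
        with pytest.raises(ValueError):
            compare_mixture_ed50(exp, add)  # df never silently invented

    def test_degenerate_zero_sem(self):
        exp = _mix("experimental", 100.0, 0.0)
        add = _mix("additive_theoretical", 100.0, 0.0)
        r = compare_mixture_ed50(exp, add, df=10)
        assert r.p_value == 1.0 and r.classification == "additive"
        with pytest.raises(ValueError):
            compare_mixture_ed50(_mix("experimental", 120.0, 0.0), add, df=10)


class TestIsobologramProjections:
    def test_identical_mixtures_coincide(self):
        exp = _mix("experimental", 100.0, 5.0, drugs=("A", "B", "C"))
        add = _mix("additive_theoretical", 100.0, 5.0, drugs=("A", "B", "C"))
        proj = isobologram_projections(exp, add)
        assert len(proj) == 3
        for panel in proj.values():
            assert panel["M"]["point"] == pytest.approx(panel["A"]["point"])

    def test_experimental_above_additive_on_every_panel(self, three_drug_fits):
        spec = _spec("LCM", "LTG", "VPA")
        add = additive_mixture_ed50(three_drug_fits, spec)
        comp = mixture_composition(131.70, three_drug_fits, spec)
        exp = MixtureED50("experimental", 131.70, 8.30, comp, df=24)
        proj = isobologram_projections(exp, add)
        for (x, y), panel in proj.items():
            assert panel["M"]["point"][0] > panel["A"]["point"][0]
            assert panel["M"]["point"][1] > panel["A"]["point"][1]
            assert all(s > 0 for s in panel["M"]["sem"])

    def test_component_order_only_relabels(self):
        exp = _mix("experimental", 100.0, 5.0, drugs=("A", "B"))
        add = _mix("additive_theoretical", 90.0, 5.0, drugs=("B", "A"))
        proj = isobologram_projections(exp, add)
        (pair, panel), = proj.items()
        x, y = pair
        assert panel["A"]["point"][0] == pytest.approx(add.component_doses[x])
        assert panel["A"]["point"][1] == pytest.approx(add.component_doses[y])

    def test_mismatched_components_rejected(self):
        exp = _mix("experimental", 100.0, 5.0, drugs=("A", "B"))
        add = _mix("additive_theoretical", 100.0, 5.0, drugs=("A", "C"))
        with pytest.raises(ValueError):
            isobologram_projections(exp, add)


def test_component_doses_must_conserve_total():
    with pytest.raises(ValueError):
        MixtureED50("experimental", 100.0, 5.0, {"A": 10.0, "B": 20.0}, df=10)
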