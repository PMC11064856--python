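"""Diet summaries and the Fisher exact / Fisher combined machinery."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pittaforage.diet import (
    age_contingency,
    composition,
    fisher_combined,
    fisher_exact_2x2,
    length_summary,
    visit_type_proportions,
)
from pittaforage.synthetic import SyntheticConfig, generate

from conftest import make_item, make_visit


def _counts_visits(n_noe, n_onlye, n_mix, worms_onlye_each=1, mix_load=(1, 1)):
    """Build a visit list with exact type counts (arbitrary item details)."""
    visits = []
    mk = lambda taxa, i: make_visit(
        [make_item(taxon=t, item_id=f"{i}:{j}") for j, t in enumerate(taxa)],
        visit_id=f"v{i}",
        order=i + 2,
    )
    i = 0
    for _ in range(n_noe):
        visits.append(mk(["centipede"], i)); i += 1
    for _ in range(n_onlye):
        visits.append(mk(["earthworm"] * worms_onlye_each, i)); i += 1
    w, o = mix_load
    for _ in range(n_mix):
        visits.append(mk(["earthworm"] * w + ["beetle"] * o, i)); i += 1
    return visits


class TestComposition:
    def test_observed_study_counts(self):
        """547 earthworms of 647 identified items -> 84.5%; 34 centipedes -> 5.3%."""
        from conftest import printed_counts_visits

        comp = composition(printed_counts_visits())
        assert comp.total_identified == 647
        assert comp.counts["earthworm"] == 547
        assert comp.percentage("earthworm") == 84.5
        assert comp.counts["centipede"] == 34
        assert comp.percentage("centipede") == 5.3

    def test_single_taxon_is_100_percent(self):
        visits = _counts_visits(0, 5, 0)
        assert composition(visits).percentage("earthworm") == 100.0

    def test_unknown_items_excluded_from_denominator(self):
        visits = _counts_visits(2, 8, 0)
        with_unknown = visits + [
            make_visit(
                [make_item(taxon="unknown", length_bu=None, item_id="u"),
                 make_item(item_id="w")],
                visit_id="vu", order=99,
            )
        ]
        c1, c2 = composition(visits), composition(with_unknown)
        assert c2.excluded_unknown == 1
        assert c2.total_identified == c1.total_identified + 1  # the extra worm
        # row order invariance
        c3 = composition(list(reversed(with_unknown)))
        assert c3.counts == c2.counts

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            composition([])


class TestVisitTypeProportions:
    def test_printed_shares(self):
        """11 NoE / 151 OnlyE / 71 MIX of 233 -> 4.7 / 64.8 / 30.5, YesE 95.3."""
        visits = _counts_visits(11, 151, 71)
        vtp = visit_type_proportions(visits).set_index("visit_type")
        assert vtp.loc["NoE", "percent"] == 4.7
        assert vtp.loc["OnlyE", "percent"] == 64.8
        assert vtp.loc["MIX", "percent"] == 30.5
        assert vtp.loc["YesE", "percent"] == 95.3
        assert vtp.loc["YesE", "count"] == 222

    def test_all_onlye(self):
        vtp = visit_type_proportions(_counts_visits(0, 4, 0)).set_index("visit_type")
        assert vtp.loc["OnlyE", "percent"] == 100.0


class TestLengthSummary:
    def test_sample_sd_arithmetic(self):
        visits = [
            make_visit(
                [make_item(length_bu=b, item_id=str(b)) for b in (2.0, 3.0, 4.0)]
            )
        ]
        s = length_summary(visits)["earthworm"]
        assert s.mean_cm == pytest.approx(6.0)
        assert s.sd_cm == pytest.approx(2.0)  # sample (n-1) convention
        assert (s.min_cm, s.max_cm) == (4.0, 8.0)

    def test_single_item_sd_undefined(self):
        s = length_summary([make_visit([make_item()])])["earthworm"]
        assert math.isnan(s.sd_cm)

    def test_unmeasured_excluded_and_counted(self):
        visits = [
            make_visit(
                [make_item(item_id="a"), make_item(length_bu=None, item_id="b")]
            )
        ]
        s = length_summary(visits)["earthworm"]
        assert s.n == 1 and s.n_unmeasured == 1


def fisher_enumeration_oracle(t):
    """Exact two-sided p by brute force: sum fixed-margins hypergeometric
    probabilities not exceeding the observed one (integer arithmetic, with
    the standard relative guard on the comparison)."""
    (a, b), (c, d) = t
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    num_obs = math.comb(r1, a) * math.comb(r2, c1 - a)
    total = 0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        num = math.comb(r1, x) * math.comb(r2, c1 - x)
        if num * 10**7 <= num_obs * (10**7 + 1):
            total += num
    return min(total / math.comb(n, c1), 1.0)


class TestFisherExact:
    def test_no_association(self):
        assert fisher_exact_2x2([[2, 2], [2, 2]]) == pytest.approx(1.0)

    def test_enumerated_values(self):
        assert fisher_exact_2x2([[3, 1], [1, 3]]) == pytest.approx(34 / 70)
        assert fisher_exact_2x2([[5, 0], [0, 5]]) == pytest.approx(2 / 252)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[0, 0], [0, 0]])

    @given(st.lists(st.integers(0, 15), min_size=4, max_size=4))
    @settings(max_examples=300, deadline=None)
    def test_matches_enumeration(self, cells):
        """Agrees with brute-force enumeration for margins up to 30."""
        t = [[cells[0], cells[1]], [cells[2], cells[3]]]
        if sum(cells) == 0:
            return
        assert fisher_exact_2x2(t) == pytest.approx(
            fisher_enumeration_oracle(t), abs=1e-9
        )


class TestFisherCombined:
    def test_null_inputs(self):
        stat, df, p = fisher_combined([1.0, 1.0])
        assert stat == pytest.approx(0.0) and df == 4 and p == pytest.approx(1.0)

    def test_known_value(self):
        stat, df, p = fisher_combined([0.05, 0.05])
        assert stat == pytest.approx(-2 * 2 * math.log(0.05))
        assert df == 4
        assert p == pytest.approx(stats.chi2.sf(stat, 4))

    def test_single_p_inverts_exactly(self):
        for x in (0.001, 0.2, 0.77, 1.0):
            _, df, p = fisher_combined([x])
            assert df == 2 and p == pytest.approx(x, rel=1e-12)

    @given(
        st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=6),
        st.integers(0, 5),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_each_input(self, ps, idx):
        """Decreasing any input p never increases the combined p."""
        idx = idx % len(ps)
        _, _, p_before = fisher_combined(ps)
        smaller = list(ps)
        smaller[idx] = smaller[idx] / 2
        _, _, p_after = fisher_combined(smaller)
        assert p_after <= p_before + 1e-12

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_invalid_p_rejected(self, bad):
        with pytest.raises(ValueError):
            fisher_combined([0.5, bad])


class TestAgeContingency:
    def test_null_not_small(self):
        """Identical young/old composition gives an unremarkable combined p."""
        cfg = SyntheticConfig(
            n_nests=20,
            sessions_per_nest=10,
            old_visit_type_odds={"OnlyE": 1.0, "MIX": 1.0, "NoE": 1.0},
        )
        visits, _, _ = generate(cfg, seed=7)
        res = age_contingency(visits, mode="items")
        assert res.combined_p > 0.01
        assert res.df == 2 * len(res.p_values)

    def test_power_under_strong_age_effect(self):
        cfg = SyntheticConfig(
            n_nests=20,
            sessions_per_nest=10,
            old_visit_type_odds={"OnlyE": 1.0, "MIX": 3.0, "NoE": 8.0},
        )
        visits, _, _ = generate(cfg, seed=7)
        assert age_contingency(visits, mode="items").combined_p < 0.01
        assert age_contingency(visits, mode="visits").combined_p < 0.01

    def test_single_nest_equals_its_exact_p(self):
        young = [
            make_visit([make_item(item_id=f"y{i}")], visit_id=f"y{i}", age=3, order=i + 2)
            for i in range(8)
        ]
        old = [
            make_visit(
                [make_item(taxon="beetle", item_id=f"o{i}")],
                visit_id=f"o{i}", age=10, order=i + 20,
            )
            for i in range(8)
        ]
        res = age_contingency(young + old, mode="items")
        (table,) = res.tables.values()
        assert res.combined_p == pytest.approx(fisher_exact_2x2(table), rel=1e-9)

    def test_nest_missing_age_class_skipped(self):
        mixed_nest = [
            make_visit([make_item(item_id=f"a{i}")], visit_id=f"a{i}", age=3, order=i + 2)
            for i in range(4)
        ] + [
            make_visit(
                [make_item(taxon="moth", item_id=f"b{i}")],
                visit_id=f"b{i}", age=9, order=i + 10,
            )
            for i in range(4)
        ]
        young_only = [
            make_visit(
                [make_item(item_id=f"c{i}")],
                visit_id=f"c{i}", nest_id="nest2", age=2, order=i + 2,
            )
            for i in range(4)
        ]
        with pytest.warns(UserWarning, match="age class unobserved"):
            res = age_contingency(mixed_nest + young_only, mode="items")
        assert res.skipped_nests == ("nest2",)
        assert res.df == 2
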