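"""Weighted estimation: means, percentiles, congeners, proxies, recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dietexposome.estimation import (
    DEFAULT_CONGENER_MAPS,
    ConcentrationEstimate,
    aggregate_congeners,
    estimate_all,
    estimate_food_contaminant,
    expansion_oracle,
    proxy_fill,
    weighted_mean,
    weighted_percentile,
)
from dietexposome.occurrence import apply_exclusions
from dietexposome.synthetic import GeneratorConfig, generate_occurrence

from conftest import make_record


def est(food="rice", contaminant="cadmium", chem_class="heavy_metal",
        value=1.0, provenance="direct", **kw):
    fields = dict(w_mean=value, p25=value, p50=value, p75=value,
                  n_records=1, total_weight=1.0)
    fields.update(kw)
    return ConcentrationEstimate(food=food, contaminant=contaminant,
                                 chem_class=chem_class, provenance=provenance, **fields)


class TestWeightedMean:
    def test_equal_weights(self):
        assert weighted_mean([2, 4], [1, 1]) == pytest.approx(3.0)

    def test_direct_formula(self):
        assert weighted_mean([2, 4], [3, 1]) == pytest.approx(2.5)

    def test_matches_expanded_multiset(self):
        rng = np.random.default_rng(42)
        values = rng.lognormal(1.0, 0.8, size=200)
        weights = rng.integers(1, 30, size=200)
        expanded = np.repeat(values, weights)
        assert weighted_mean(values, weights) == pytest.approx(expanded.mean())

    def test_all_zero_weights_error(self):
        with pytest.raises(ValueError):
            weighted_mean([1, 2], [0, 0])

    @given(
        st.lists(st.floats(0, 1e6, allow_nan=False), min_size=1, max_size=20),
        st.data(),
    )
    @settings(max_examples=200, deadline=None)
    def test_bounded_by_extremes(self, values, data):
        weights = data.draw(
            st.lists(st.floats(0.1, 100), min_size=len(values), max_size=len(values))
        )
        m = weighted_mean(values, weights)
        assert min(values) - 1e-9 <= m <= max(values) + 1e-9


class TestWeightedPercentile:
    def test_symmetric_median(self):
        assert weighted_percentile([1, 2, 3, 4], [1, 1, 1, 1], 0.5) == pytest.approx(2.5)

    @pytest.mark.parametrize("q", [0.1, 0.25, 0.5, 0.75, 0.9])
    @pytest.mark.parametrize("convention", ["expansion", "midpoint", "inverted_cdf"])
    def test_single_value_degenerate(self, q, convention):
        assert weighted_percentile([7.0], [3.0], q, convention) == 7.0

    def test_heavy_weight_plateau(self):
        got = weighted_percentile([10, 20, 30], [1, 1, 8], 0.75)
        assert got == expansion_oracle([10, 20, 30], [1, 1, 8], 0.75) == 30.0

    def test_q_out_of_range(self):
        for q in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                weighted_percentile([1.0], [1.0], q)

    @given(
        st.integers(1, 8).flatmap(
            lambda n: st.tuples(
                st.lists(st.floats(-100, 100, allow_nan=False), min_size=n, max_size=n),
                st.lists(st.integers(1, 10), min_size=n, max_size=n),
            )
        ),
        st.floats(0.001, 0.999),
    )
    @settings(max_examples=1200, deadline=None)
    def test_expansion_oracle_equality(self, vw, q):
        """Integer-weight instances agree exactly with the brute-force expansion."""
        values, weights = vw
        got = weighted_percentile(values, weights, q)
        want = expansion_oracle(values, weights, q)
        assert got == pytest.approx(want, rel=1e-12, abs=1e-12)

    @given(
        st.lists(st.floats(0, 1000, allow_nan=False), min_size=2, max_size=10),
        st.data(),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_q(self, values, data):
        weights = data.draw(
            st.lists(st.integers(1, 5), min_size=len(values), max_size=len(values))
        )
        qs = sorted(data.draw(st.lists(st.floats(0.01, 0.99), min_size=3, max_size=3)))
        results = [weighted_percentile(values, weights, q) for q in qs]
        assert results == sorted(results)

    def test_midpoint_convention_rescaling_invariant(self):
        values = [3.0, 1.0, 4.0, 1.5]
        weights = [2.0, 1.0, 5.0, 3.0]
        for q in (0.2, 0.5, 0.8):
            a = weighted_percentile(values, weights, q, "midpoint")
            b = weighted_percentile(values, [w * 7.5 for w in weights], q, "midpoint")
            assert a == pytest.approx(b)

    def test_equal_unit_weights_match_unweighted_hazen(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=25)
        for q in (0.25, 0.5, 0.75):
            got = weighted_percentile(values, np.ones(25), q)
            assert got == pytest.approx(np.quantile(values, q, method="hazen"))


class TestEstimateFoodContaminant:
    def test_single_record_collapses(self):
        e = estimate_food_contaminant([make_record(value=7.0)])
        assert e.w_mean == e.p25 == e.p50 == e.p75 == 7.0
        assert e.provenance == "direct"

    def test_two_record_weighted_mean(self):
        recs = [
            make_record(study_id="a", value=10.0, n=1),
            make_record(study_id="b", value=20.0, n=3),
        ]
        assert estimate_food_contaminant(recs).w_mean == pytest.approx(17.5)

    def test_missing_n_counts_as_one(self):
        recs = [
            make_record(study_id="a", value=10.0, n=None),
            make_record(study_id="b", value=20.0, n=1),
        ]
        assert estimate_food_contaminant(recs).w_mean == pytest.approx(15.0)

    def test_median_fallback_within_study(self):
        # a study's median is ignored when that study also reports a mean
        recs = [
            make_record(study_id="a", value=10.0, stat_type="mean"),
            make_record(study_id="a", value=99.0, stat_type="median"),
            make_record(study_id="b", value=20.0, stat_type="median"),
        ]
        e = estimate_food_contaminant(recs)
        assert e.n_records == 2
        assert e.w_mean == pytest.approx(15.0)

    def test_mixed_pairs_rejected(self):
        with pytest.raises(ValueError):
            estimate_food_contaminant([make_record(), make_record(food="apple")])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            estimate_food_contaminant([])

    def test_quartile_ordering_invariant(self):
        records = generate_occurrence(GeneratorConfig(seed=9, studies_per_pair=(3, 6)))
        kept = apply_exclusions(records).kept_records(records)
        for e in estimate_all(kept):
            assert e.p25 <= e.p50 <= e.p75
            assert e.total_weight > 0

    def test_lognormal_parameter_recovery(self):
        """Many studies at GM 10, GSD 2: the weighted median recovers the GM."""
        config = GeneratorConfig(
            foods=["apple"], contaminants=["cadmium"],
            studies_per_pair=(200, 200), seed=11,
        )
        records = generate_occurrence(config)
        kept = apply_exclusions(records).kept_records(records)
        e = estimate_all(kept)[0]
        assert e.p50 == pytest.approx(10.0, rel=0.05)


class TestCongenersAndProxies:
    def test_enniatin_sum(self):
        members = [
            est(contaminant=f"enniatin {x}", chem_class="mycotoxin", value=v)
            for x, v in zip(["A", "B", "A1", "B1"], [1, 2, 3, 4])
        ]
        out = aggregate_congeners(members, DEFAULT_CONGENER_MAPS)
        assert len(out) == 1
        agg = out[0]
        assert agg.contaminant == "ENNs" and agg.provenance == "congener_sum"
        assert agg.p50 == agg.w_mean == 10

    def test_partial_membership_counts_absent_as_zero(self):
        out = aggregate_congeners(
            [est(contaminant="enniatin A", chem_class="mycotoxin", value=1.0)]
        )
        assert out[0].contaminant == "ENNs" and out[0].p50 == 1.0

    def test_alternaria_sum_and_passthrough(self):
        ests = [
            est(contaminant="alternariol", chem_class="mycotoxin", value=2.0),
            est(contaminant="alternariol methyl ether", chem_class="mycotoxin", value=3.0),
            est(contaminant="cadmium", value=1.0),
        ]
        out = aggregate_congeners(ests)
        by_name = {e.contaminant: e for e in out}
        assert by_name["ATs"].p75 == 5.0
        assert by_name["cadmium"].p50 == 1.0
        assert "alternariol" not in by_name

    def test_mass_conservation_per_food(self):
        ests = [
            est(food=f, contaminant=f"enniatin {x}", chem_class="mycotoxin", value=v)
            for f in ("wheat", "maize")
            for x, v in zip(["A", "B"], [1.5, 2.5])
        ]
        out = aggregate_congeners(ests)
        assert sorted((e.food, e.p25) for e in out) == [("maize", 4.0), ("wheat", 4.0)]

    def test_proxy_fill_copies_with_provenance(self):
        maize = est(food="maize", contaminant="aflatoxin B1",
                    chem_class="mycotoxin", value=2.0)
        out = proxy_fill([maize])
        bread = [e for e in out if e.food == "bread"]
        assert len(bread) == 1
        assert bread[0].p50 == 2.0 and bread[0].provenance == "proxy_from_maize"

    def test_proxy_never_overwrites_direct(self):
        maize = est(food="maize", contaminant="lead", value=2.0)
        bread = est(food="bread", contaminant="lead", value=9.0)
        out = proxy_fill([maize, bread])
        kept = [e for e in out if e.food == "bread" and e.contaminant == "lead"]
        assert len(kept) == 1 and kept[0].p50 == 9.0 and kept[0].provenance == "direct"

    def test_empty_proxy_map_is_identity(self):
        ests = [est()]
        assert proxy_fill(ests, {}) == ests

    def test_missing_source_warns(self):
        with pytest.warns(UserWarning, match="proxy source"):
            out = proxy_fill([est(food="apple")], {"bread": "maize"})
        assert all(e.food == "apple" for e in out)
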