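import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import uhcd
from uhcd.index import AggregationSpec, classify_terciles, geometric_mean, orient, summarize

from conftest import constant_record

values_0_100 = st.floats(min_value=0.0, max_value=100.0, allow_nan=False)
values_1_100 = st.floats(min_value=1.0, max_value=100.0, allow_nan=False)


# ---------------------------------------------------------------- orient

class TestOrient:
    @pytest.mark.parametrize(
        "incidence, expected", [(8.0, 92.0), (11.2, 88.8), (0.0, 100.0)]
    )
    def test_adverse_complement(self, incidence, expected):
        assert orient(incidence, "adverse_incidence") == pytest.approx(expected)

    @given(values_0_100)
    def test_coverage_passthrough(self, v):
        assert orient(v, "coverage") == v

    @pytest.mark.parametrize("bad", [-0.1, 100.5])
    def test_out_of_range(self, bad):
        with pytest.raises(ValueError):
            orient(bad, "coverage")


# ---------------------------------------------------------------- GM

class TestGeometricMean:
    def test_constant(self):
        assert geometric_mean([50, 50, 50]) == pytest.approx(50.0)

    def test_sqrt(self):
        assert geometric_mean([25, 100]) == pytest.approx(50.0)

    def test_domain_median_profile(self):
        # frozen oracle: exp(mean(log([64.8, 82.8, 9.8, 54.9, 66.6])))
        assert geometric_mean([64.8, 82.8, 9.8, 54.9, 66.6]) == pytest.approx(
            45.370712388168776, abs=1e-9
        )

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            geometric_mean([])

    def test_floor_applied(self):
        assert geometric_mean([0.0, 100.0], floor=0.1) == pytest.approx(
            np.sqrt(0.1 * 100.0)
        )

    @given(st.lists(values_0_100, min_size=1, max_size=10))
    def test_bounds(self, vals):
        g = geometric_mean(vals, floor=0.1)
        assert 0.1 <= g <= 100.0 + 1e-12

    @given(st.lists(values_1_100, min_size=1, max_size=10))
    def test_am_gm(self, vals):
        g = geometric_mean(vals, floor=0.1)
        assert g <= np.mean(vals) + 1e-9

    @given(
        st.lists(values_1_100, min_size=1, max_size=8),
        st.floats(min_value=0.2, max_value=1.0),
    )
    def test_homogeneity(self, vals, k):
        # floor inactive: values >= 1, scaled values >= 0.2 > floor
        g1 = geometric_mean(vals, floor=0.1)
        g2 = geometric_mean([k * v for v in vals], floor=0.1)
        assert g2 == pytest.approx(k * g1, rel=1e-9)


class TestAggregationSpec:
    def test_bad_method(self):
        with pytest.raises(ValueError):
            AggregationSpec(method="harmonic")

    @pytest.mark.parametrize("floor", [0.0, 1.0, -0.5])
    def test_bad_floor(self, floor):
        with pytest.raises(ValueError):
            AggregationSpec(method="geometric", floor=floor)

    def test_arithmetic_ignores_floor(self):
        AggregationSpec(method="arithmetic", floor=5.0)  # no error


# ---------------------------------------------------------------- compute_index

class TestComputeIndex:
    def test_all_100(self, registry):
        rec = constant_record(registry, 100.0)
        res = uhcd.compute_index(rec, registry)
        assert res.uhcd == pytest.approx(100.0)
        assert res.service_coverage == pytest.approx(100.0)
        assert res.financial_risk_protection == pytest.approx(100.0)

    @pytest.mark.parametrize("method", ["geometric", "arithmetic"])
    def test_constancy(self, registry, method):
        rec = constant_record(registry, 37.0)
        spec = AggregationSpec(method=method)
        res = uhcd.compute_index(rec, registry, spec)
        assert res.uhcd == pytest.approx(37.0)

    def test_toy_district(self, toy_record, registry):
        res = uhcd.compute_index(toy_record, registry)
        assert res.area_scores["cancer_screening"] == pytest.approx(0.5)
        # frozen oracle: (50*50*50*0.5)**0.25
        assert res.domain_scores["ncd"] == pytest.approx(15.811388300841893, abs=1e-9)
        # frozen oracle: (50**4 * 15.811388300841893)**0.2 over the 5 domains
        assert res.uhcd == pytest.approx(39.71641173621407, abs=1e-9)

    def test_missing_indicator_named(self, registry):
        rec = constant_record(registry, 50.0)
        del rec.values["tb_success"]
        with pytest.raises(ValueError, match="tb_success"):
            uhcd.compute_index(rec, registry)

    def test_decomposition_consistency(self, default_sim):
        # uhcd = (sc^4 * frp)^(1/5) for the hierarchical geometric spec
        _, _, _, results = default_sim
        for res in results[::25]:
            recon = (res.service_coverage**4 * res.financial_risk_protection) ** 0.2
            assert res.uhcd == pytest.approx(recon, rel=1e-9)

    def test_bounds_on_simulated(self, default_sim):
        _, _, _, results = default_sim
        for res in results:
            assert 0.1 <= res.uhcd <= 100.0
            for s in res.domain_scores.values():
                assert 0.1 <= s <= 100.0

    def test_am_gm_per_district(self, default_sim, registry):
        _, records, _, results = default_sim
        arith = AggregationSpec(method="arithmetic")
        for rec, res in list(zip(records, results))[::50]:
            res_a = uhcd.compute_index(rec, registry, arith)
            assert res.uhcd <= res_a.uhcd + 1e-9

    def test_am_gm_equality_iff_constant(self, registry):
        rec = constant_record(registry, 42.0)
        g = uhcd.compute_index(rec, registry).uhcd
        a = uhcd.compute_index(rec, registry, AggregationSpec(method="arithmetic")).uhcd
        assert g == pytest.approx(a, abs=1e-9)

    def test_monotonicity(self, default_sim, registry):
        _, records, _, results = default_sim
        rec = records[0].copy()
        base = uhcd.compute_index(rec, registry).uhcd
        for iid in registry.indicator_ids:
            bumped = rec.copy()
            ind = registry.get(iid)
            if ind.orientation == "adverse_incidence":
                bumped.values[iid] = max(0.0, bumped.values[iid] - 5.0)
            else:
                bumped.values[iid] = min(100.0, bumped.values[iid] + 5.0)
            assert uhcd.compute_index(bumped, registry).uhcd >= base - 1e-9

    def test_permutation_invariance(self, registry, default_sim, rng):
        # rebuild the registry with indicators/areas/domains in reverse order
        reversed_defs = list(reversed(registry.indicators))
        shuffled = uhcd.IndicatorRegistry(reversed_defs, registry.equity_subset)
        _, records, _, _ = default_sim
        for rec in records[::100]:
            a = uhcd.compute_index(rec, registry)
            b = uhcd.compute_index(rec, shuffled)
            assert a.uhcd == pytest.approx(b.uhcd, rel=1e-12)
            assert a.domain_scores == pytest.approx(b.domain_scores, rel=1e-12)

    def test_flat_differs_from_hierarchical(self, toy_record, registry):
        # areas have unequal indicator counts -> weights differ
        flat = uhcd.compute_index(
            toy_record, registry, AggregationSpec(method="flat_geometric")
        )
        hier = uhcd.compute_index(toy_record, registry)
        assert flat.uhcd != pytest.approx(hier.uhcd, abs=1e-6)


# ---------------------------------------------------------------- terciles

class TestTerciles:
    def test_687_distinct(self, rng):
        vals = rng.permutation(687) + rng.random(687) * 0.5
        labels = classify_terciles({f"d{i}": float(v) for i, v in enumerate(vals)})
        counts = {lab: sum(1 for v in labels.values() if v == lab)
                  for lab in ("low", "medium", "high")}
        assert counts == {"low": 229, "medium": 229, "high": 229}

    def test_six(self):
        labels = classify_terciles({f"d{i}": float(i) for i in range(6)})
        assert [labels[f"d{i}"] for i in range(6)] == [
            "low", "low", "medium", "medium", "high", "high",
        ]

    def test_seven_low_gets_extra(self):
        labels = classify_terciles({f"d{i}": float(i) for i in range(7)})
        counts = [sum(1 for v in labels.values() if v == lab)
                  for lab in ("low", "medium", "high")]
        assert counts == [3, 2, 2]

    def test_ties_broken_by_id(self):
        labels = classify_terciles({"b": 1.0, "a": 1.0, "c": 1.0})
        assert labels == {"a": "low", "b": "medium", "c": "high"}

    def test_fewer_than_three(self):
        with pytest.raises(ValueError):
            classify_terciles({"a": 1.0, "b": 2.0})


# ---------------------------------------------------------------- summarize

def _results_from_values(vals):
    return [
        uhcd.IndexResult(
            district_id=f"d{i}", uhcd=float(v), domain_scores={"frp": float(v)},
            area_scores={}, service_coverage=float(v),
            financial_risk_protection=float(v),
        )
        for i, v in enumerate(vals)
    ]


class TestSummarize:
    def test_single_district(self):
        df = summarize(_results_from_values([44.0]))
        row = df[df.measure == "uhcd"].iloc[0]
        assert row["median"] == 44.0
        assert row["sd"] == 0.0
        assert row["n"] == 1

    def test_share_above_half(self):
        df = summarize(_results_from_values(range(1, 101)), threshold=50.0)
        row = df[df.measure == "uhcd"].iloc[0]
        assert row["n_above"] == 50
        assert row["share_above_pct"] == 50.0

    def test_paper_threshold_share(self):
        vals = [60.0] * 145 + [40.0] * (687 - 145)
        df = summarize(_results_from_values(vals), threshold=50.0)
        row = df[df.measure == "uhcd"].iloc[0]
        assert row["n_above"] == 145
        assert row["n_total"] == 687
        assert row["share_above_pct"] == 21.1

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            summarize([])
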