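import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from riboquant import ribometh as rm
from riboquant import synthetic_data as sd
from riboquant.config import (
    FlowParams,
    FragmentationParams,
    GrowthParams,
    LuciferaseParams,
    QpcrParams,
    SimulationConfig,
    TraceParams,
    TracePeak,
)
from riboquant.reference import ReferenceSet, TrueMethylationProfile

from conftest import random_reference


class TestFragmentation:
    def test_full_protection_forbids_cleavage_at_site(self):
        ref = random_reference(80, seed=3)
        truth = TrueMethylationProfile.from_mapping({"mol": {40: 1.0}})
        cfg = SimulationConfig(
            seed=5,
            fragmentation=FragmentationParams(
                n_molecules=2000, p_cleave=0.2, fragment_min=10, fragment_max=30
            ),
        )
        res = sd.simulate_fragmentation_reads(ref, truth, cfg)
        assert res.cleavage_counts("mol")[40 - 1] == 0
        mapping = rm.map_reads_exact(res.reads, ref)
        assert mapping.alignments, "expected some uniquely mapped reads"
        for aln in mapping.alignments:
            assert aln.start != 41, "read 5' end implies cleavage at protected bond"
            assert aln.end != 40, "read 3' end implies cleavage at protected bond"

    def test_no_cleavage_no_reads(self):
        ref = random_reference(100, seed=3)
        truth = TrueMethylationProfile.from_mapping({"mol": {}})
        cfg = SimulationConfig(
            seed=5, fragmentation=FragmentationParams(n_molecules=100, p_cleave=0.0)
        )
        res = sd.simulate_fragmentation_reads(ref, truth, cfg)
        assert res.reads == []
        assert (res.cleavage_truth["count"] == 0).all()

    def test_cleavage_uniform_without_methylation(self):
        # chi-square GOF vs uniform, alpha = 0.01, over 20 seeds: expect <= 1 rejection
        ref = random_reference(500, seed=3)
        truth = TrueMethylationProfile.from_mapping({"mol": {}})
        rejections = 0
        for seed in range(20):
            cfg = SimulationConfig(
                seed=seed,
                fragmentation=FragmentationParams(n_molecules=5000, p_cleave=0.05),
            )
            res = sd.simulate_fragmentation_reads(ref, truth, cfg)
            counts = res.cleavage_counts("mol")
            _stat, p = stats.chisquare(counts)
            if p < 0.01:
                rejections += 1
        assert rejections <= 1

    def test_truth_counts_equal_realized_cleavage_events(self):
        # conservation: every emitted fragment's internal ends are cut bonds,
        # and Sum(counts) equals total cut bonds; cross-check via a tiny run
        # where every fragment is emitted (no size selection losses).
        ref = random_reference(30, seed=1)
        truth = TrueMethylationProfile.from_mapping({"mol": {}})
        cfg = SimulationConfig(
            seed=2,
            fragmentation=FragmentationParams(
                n_molecules=500, p_cleave=0.3, fragment_min=1, fragment_max=30
            ),
        )
        res = sd.simulate_fragmentation_reads(ref, truth, cfg)
        total_cuts = int(res.cleavage_truth["count"].sum())
        # fragments per molecule = cuts + 1 => total fragments = cuts + n_molecules
        assert len(res.reads) == total_cuts + 500

    def test_end_count_monotone_in_f(self, f_grid_run):
        _cfg, _res, _mapping, profiles = f_grid_run
        prof = profiles["mol"]
        counts_by_f = [prof.n(pos) for pos in (100, 180, 260, 340, 420)]
        assert counts_by_f == sorted(counts_by_f, reverse=True)
        assert counts_by_f[-1] == 0  # f = 1: full protection

    def test_rejects_site_outside_reference(self):
        ref = random_reference(50, seed=1)
        truth = TrueMethylationProfile.from_mapping({"mol": {60: 0.5}})
        with pytest.raises(ValueError, match="mol:60"):
            sd.simulate_fragmentation_reads(ref, truth, SimulationConfig())

    def test_deterministic(self):
        ref = random_reference(120, seed=9)
        truth = TrueMethylationProfile.from_mapping({"mol": {60: 0.5}})
        cfg = SimulationConfig(
            seed=42, fragmentation=FragmentationParams(n_molecules=1000)
        )
        a = sd.simulate_fragmentation_reads(ref, truth, cfg)
        b = sd.simulate_fragmentation_reads(ref, truth, cfg)
        assert [r.sequence for r in a.reads] == [r.sequence for r in b.reads]
        pd.testing.assert_frame_equal(a.cleavage_truth, b.cleavage_truth)


class TestCqTable:
    def test_halved_level_raises_cq_by_one(self):
        cfg = SimulationConfig(qpcr=QpcrParams(noise_sd=0.0, efficiency=2.0))
        table = sd.simulate_cq_table({"wt": {"x": 1.0}, "mut": {"x": 0.5}}, cfg)
        wt = table[(table["sample"] == "wt") & (table["target"] == "x")]["cq"].iloc[0]
        mut = table[(table["sample"] == "mut") & (table["target"] == "x")]["cq"].iloc[0]
        assert mut - wt == pytest.approx(1.0, abs=1e-12)

    def test_level_point_two_gives_log2_5_delta(self):
        cfg = SimulationConfig(qpcr=QpcrParams(noise_sd=0.0, efficiency=2.0))
        table = sd.simulate_cq_table({"a": {"x": 1.0}, "b": {"x": 0.2}}, cfg)
        a = table[(table["sample"] == "a") & (table["target"] == "x")]["cq"].iloc[0]
        b = table[(table["sample"] == "b") & (table["target"] == "x")]["cq"].iloc[0]
        assert b - a == pytest.approx(math.log2(5), abs=1e-12)

    def test_identical_levels_identical_cq(self):
        cfg = SimulationConfig(qpcr=QpcrParams(noise_sd=0.0))
        table = sd.simulate_cq_table({"a": {"x": 0.7}, "b": {"x": 0.7}}, cfg)
        cqs = table[table["target"] == "x"].groupby("sample")["cq"].first()
        assert cqs["a"] == cqs["b"]

    def test_reference_target_always_included(self):
        table = sd.simulate_cq_table({"a": {"x": 2.0}}, SimulationConfig())
        assert set(table["target"]) == {"x", "reference"}

    def test_rejects_non_positive_level(self):
        with pytest.raises(ValueError, match="positive"):
            sd.simulate_cq_table({"a": {"x": 0.0}}, SimulationConfig())


class TestRtlpCq:
    def test_empty_region_equal_conditions(self):
        cfg = SimulationConfig(qpcr=QpcrParams(noise_sd=0.0))
        table = sd.simulate_rtlp_cq({"wt": {"region1": []}}, cfg)
        piv = table.pivot_table(index="replicate", columns="condition", values="cq")
        assert (piv["low"] == piv["high"]).all()

    def test_closed_form_delta(self):
        # one site, f=1, d=0.5, E=2 -> surviving template 0.5 -> dCq = 1
        cfg = SimulationConfig(qpcr=QpcrParams(noise_sd=0.0, efficiency=2.0, dropoff=0.5))
        table = sd.simulate_rtlp_cq({"wt": {"r": [(10, 1.0)]}}, cfg)
        piv = table.pivot_table(index="replicate", columns="condition", values="cq")
        assert (piv["low"] - piv["high"]).iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_delta_increases_with_f(self):
        cfg = SimulationConfig(qpcr=QpcrParams(noise_sd=0.0, dropoff=0.8))
        deltas = []
        for f in (0.2, 0.5, 0.9):
            table = sd.simulate_rtlp_cq({"wt": {"r": [(10, f)]}}, cfg)
            piv = table.pivot_table(index="replicate", columns="condition", values="cq")
            deltas.append(float((piv["low"] - piv["high"]).iloc[0]))
        assert deltas[0] < deltas[1] < deltas[2]

    def test_rejects_bad_f(self):
        with pytest.raises(ValueError, match="outside"):
            sd.simulate_rtlp_cq({"wt": {"r": [(10, 1.5)]}}, SimulationConfig())


class TestGrowth:
    def test_exponential_doubles_every_doubling_time(self):
        cfg = SimulationConfig(
            growth=GrowthParams(n0=0.05, carrying_capacity=None, doubling_time=90,
                                interval=45, duration=90, noise_sd=0.0)
        )
        curve = sd.simulate_growth_curve(cfg)
        assert curve["od"].iloc[2] / curve["od"].iloc[0] == pytest.approx(2.0, rel=1e-12)

    def test_n0_scales_whole_curve(self):
        base = GrowthParams(n0=0.05, carrying_capacity=None, doubling_time=90,
                            interval=20, duration=400, noise_sd=0.0)
        c1 = sd.simulate_growth_curve(SimulationConfig(growth=base))
        base2 = GrowthParams(n0=0.10, carrying_capacity=None, doubling_time=90,
                             interval=20, duration=400, noise_sd=0.0)
        c2 = sd.simulate_growth_curve(SimulationConfig(growth=base2))
        np.testing.assert_allclose(c2["od"], 2 * c1["od"], rtol=1e-12)

    def test_planted_doubling_time_recovered(self):
        from riboquant.phenotype import fit_doubling_time

        ok = 0
        for seed in range(50):
            cfg = SimulationConfig(
                seed=seed,
                growth=GrowthParams(n0=0.01, carrying_capacity=100.0,
                                    doubling_time=100.0, interval=20,
                                    duration=800, noise_sd=0.01),
            )
            curve = sd.simulate_growth_curve(cfg)
            td = fit_doubling_time(curve)
            if abs(td - 100.0) / 100.0 <= 0.05:
                ok += 1
        assert ok >= 45

    def test_rejects_bad_params(self):
        with pytest.raises(ValueError):
            GrowthParams(n0=-1)
        with pytest.raises(ValueError):
            GrowthParams(doubling_time=0)
        with pytest.raises(ValueError):
            GrowthParams(carrying_capacity=0.01, n0=0.05)


class TestPolysomeTrace:
    def test_single_unit_area_gaussian(self):
        cfg = SimulationConfig(
            trace=TraceParams(baseline=0.0, noise_sd=0.0,
                              peaks=[TracePeak(center=5.0, width=0.2, area=1.0)])
        )
        trace, truth = sd.simulate_polysome_trace(cfg)
        total = np.trapezoid(trace["a260"], trace["position"])
        assert total == pytest.approx(1.0, abs=0.01)
        assert truth["area"].iloc[0] == pytest.approx(1.0)

    def test_two_peak_truth_ratio(self):
        cfg = SimulationConfig(
            trace=TraceParams(peaks=[
                TracePeak(center=3.0, width=0.1, area=2.0, label="80S"),
                TracePeak(center=6.0, width=0.1, area=1.0, label="polysome"),
            ])
        )
        _trace, truth = sd.simulate_polysome_trace(cfg)
        areas = truth.set_index("label")["area"]
        assert areas["80S"] / areas["polysome"] == pytest.approx(2.0)


class TestLuciferase:
    def test_no_noise_unit_ratios_give_one(self):
        from riboquant.reporters import fidelity_metric

        cfg = SimulationConfig(luciferase=LuciferaseParams(cv=0.0))
        table = sd.simulate_luciferase_table({"WT": 1.0, "mut": 1.0}, cfg)
        out = fidelity_metric(table, "WT")
        assert np.allclose(out["value"], 1.0)

    def test_planted_half_recovered_exactly_without_noise(self):
        from riboquant.reporters import fidelity_metric

        cfg = SimulationConfig(luciferase=LuciferaseParams(cv=0.0))
        table = sd.simulate_luciferase_table({"WT": 1.0, "mut": 0.5}, cfg)
        out = fidelity_metric(table, "WT")
        mut = out[out["strain"] == "mut"]["value"].iloc[0]
        assert mut == pytest.approx(0.5, rel=1e-12)

    def test_rejects_non_positive_ratio(self):
        with pytest.raises(ValueError, match="positive"):
            sd.simulate_luciferase_table({"WT": -0.5}, SimulationConfig())


class TestFlowEvents:
    def test_event_count_bounds_enforced(self):
        cfg = SimulationConfig(flow=FlowParams(n_events=100, min_events=500,
                                               max_events=1000))
        with pytest.raises(ValueError, match="outside configured bounds"):
            sd.simulate_flow_events({"WT": 1.0}, cfg)

    def test_deterministic(self):
        cfg = SimulationConfig(seed=3, flow=FlowParams(n_events=1000, min_events=100,
                                                       max_events=10_000))
        a = sd.simulate_flow_events({"WT": 1.0, "mut": 0.7}, cfg)
        b = sd.simulate_flow_events({"WT": 1.0, "mut": 0.7}, cfg)
        pd.testing.assert_frame_equal(a, b)


class TestDeterminism:
    def test_generators_reproduce_bit_identical_tables(self):
        cfg = SimulationConfig(seed=123, qpcr=QpcrParams(noise_sd=0.3),
                               growth=GrowthParams(noise_sd=0.05),
                               trace=TraceParams(noise_sd=0.01))
        levels = {"a": {"x": 1.0}, "b": {"x": 0.4}}
        pd.testing.assert_frame_equal(
            sd.simulate_cq_table(levels, cfg), sd.simulate_cq_table(levels, cfg)
        )
        pd.testing.assert_frame_equal(
            sd.simulate_growth_curve(cfg), sd.simulate_growth_curve(cfg)
        )
        t1, _ = sd.simulate_polysome_trace(cfg)
        t2, _ = sd.simulate_polysome_trace(cfg)
        pd.testing.assert_frame_equal(t1, t2)

    def test_substreams_are_independent_of_call_order(self):
        cfg = SimulationConfig(seed=123, qpcr=QpcrParams(noise_sd=0.3))
        levels = {"a": {"x": 1.0}}
        first = sd.simulate_cq_table(levels, cfg)
        sd.simulate_growth_curve(cfg)  # interleave another generator
        second = sd.simulate_cq_table(levels, cfg)
        pd.testing.assert_frame_equal(first, second)
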