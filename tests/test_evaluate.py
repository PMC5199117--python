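"""DVH metrics, conformity, normalization and the clinical acceptance check."""

import numpy as np
import pytest

import lexiplan as lp
from lexiplan.beams import DoseDistribution
from lexiplan.evaluate import (PlanMetrics, acceptance_check, conformity_index,
                               dvh, evaluate_plan, normalize_to_median, v_above)
from lexiplan.phantom import GridSpec, Phantom


def grid_dose(values):
    arr = np.asarray(values, dtype=float).reshape(-1, 1, 1)
    return DoseDistribution(arr)


def mask_of(n, rows):
    m = np.zeros((n, 1, 1), dtype=bool)
    m[list(rows)] = True
    return m


class TestVAbove:
    def test_counting_example(self):
        dose = grid_dose([10, 20, 50, 50])
        assert v_above(dose, mask_of(4, range(4)), 45.0) == 50.0

    def test_threshold_above_max(self):
        dose = grid_dose([10, 20, 30])
        assert v_above(dose, mask_of(3, range(3)), 100.0) == 0.0

    def test_strict_inequality_at_threshold(self):
        dose = grid_dose([45.0, 45.0001])
        assert v_above(dose, mask_of(2, range(2)), 45.0) == 50.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 60, 200)
        mask = rng.random(200) > 0.5
        dose = grid_dose(vals)
        expected = 100.0 * sum(v > 30.0 for v in vals[mask]) / mask.sum()
        assert v_above(dose, mask_of(200, np.flatnonzero(mask)), 30.0) == pytest.approx(expected)

    def test_empty_structure_rejected(self):
        with pytest.raises(ValueError):
            v_above(grid_dose([1.0]), mask_of(1, []), 1.0)


class TestDVH:
    def test_uniform_step(self):
        curve = dvh(grid_dose([20.0] * 10), mask_of(10, range(10)), 0.5)
        assert curve["volume_pct"].iloc[0] == 100.0
        at = lambda d: curve.loc[(curve["dose_gy"] - d).abs().idxmin(), "volume_pct"]
        assert at(19.0) == 100.0
        assert at(21.0) == 0.0

    def test_monotone_non_increasing(self):
        rng = np.random.default_rng(1)
        curve = dvh(grid_dose(rng.uniform(0, 50, 300)), mask_of(300, range(300)))
        assert (np.diff(curve["volume_pct"]) <= 1e-12).all()

    def test_agrees_with_v_above_within_one_bin(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(0, 50, 400)
        dose = grid_dose(vals)
        mask = mask_of(400, range(400))
        bw = 0.1
        curve = dvh(dose, mask, bw)
        for thr in rng.uniform(0, 55, 100):
            v_ref = v_above(dose, mask, thr)
            i = np.searchsorted(curve["dose_gy"].values, thr, side="right") - 1
            nearby = curve["volume_pct"].values[max(0, i - 1):i + 2]
            assert nearby.min() - 1e-9 <= v_ref <= nearby.max() + 1e-9


class TestConformityIndex:
    def test_exact_coverage_is_one(self):
        dose = grid_dose([46.0, 46.0, 0.0, 0.0])
        assert conformity_index(dose, mask_of(4, [0, 1]), 46.0) == 1.0

    def test_double_volume_is_two(self):
        dose = grid_dose([46.0, 46.0, 45.0, 45.0])
        assert conformity_index(dose, mask_of(4, [0, 1]), 46.0) == 2.0

    def test_counts_all_grid_voxels(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0, 60, 100)
        ptv = mask_of(100, range(0, 10))
        expected = np.sum(vals >= 0.95 * 46.0) / 10
        assert conformity_index(grid_dose(vals), ptv, 46.0) == pytest.approx(expected)


class TestNormalization:
    @pytest.fixture(scope="class")
    def setup(self, default_phantom):
        infl = lp.compute_dose_influence(default_phantom, lp.BeamConfig(n_beams=6))
        rng = np.random.default_rng(4)
        plan = lp.FluencePlan(rng.uniform(0.5, 2.0, infl.n_beamlets))
        return default_phantom, infl, plan

    def test_median_exact_after_normalization(self, setup):
        ph, infl, plan = setup
        normed = normalize_to_median(plan, infl, ph.mask("ptv"), 46.0)
        dose = lp.dose_from_fluence(infl, normed.weights)
        med = np.median(dose.values_in(ph.mask("ptv")))
        assert med == pytest.approx(46.0, rel=1e-9)

    def test_idempotent_at_target(self, setup):
        ph, infl, plan = setup
        once = normalize_to_median(plan, infl, ph.mask("ptv"), 46.0)
        twice = normalize_to_median(once, infl, ph.mask("ptv"), 46.0)
        assert np.allclose(once.weights, twice.weights, rtol=1e-12)

    def test_scaled_thresholds_invariant(self, setup):
        # V at threshold t before == V at threshold s*t after scaling by s
        ph, infl, plan = setup
        normed = normalize_to_median(plan, infl, ph.mask("ptv"), 46.0)
        d0 = lp.dose_from_fluence(infl, plan.weights)
        d1 = lp.dose_from_fluence(infl, normed.weights)
        s = normed.weights[0] / plan.weights[0]
        sb = ph.mask("small_bowel")
        assert v_above(d1, sb, 15.0) == pytest.approx(v_above(d0, sb, 15.0 / s))


class TestAcceptanceCheck:
    def _metrics(self, v95, v110):
        return PlanMetrics(prescription_dose=46, ptv_v95=v95, ptv_v110=v110,
                           ptv_median=46, ptv_max=48, ci95=1.2)

    def test_pass(self):
        ok, reasons = acceptance_check(self._metrics(100.0, 0.0))
        assert ok and reasons == []

    def test_coverage_failure(self):
        ok, reasons = acceptance_check(self._metrics(99.0, 0.0))
        assert not ok and len(reasons) == 1 and "V95" in reasons[0]

    def test_boundary_inclusive(self):
        ok, _ = acceptance_check(self._metrics(99.5, 0.2))
        assert ok

    def test_hotspot_failure(self):
        ok, reasons = acceptance_check(self._metrics(100.0, 0.3))
        assert not ok and "V110" in reasons[0]


class TestEvaluatePlan:
    def test_zero_dose(self, default_phantom):
        dose = DoseDistribution(np.zeros(default_phantom.grid.shape))
        m = evaluate_plan(dose, default_phantom, 46.0)
        assert m.ptv_v95 == 0.0 and m.ci95 == 0.0
        assert m.per_structure["small_bowel"]["v45"] == 0.0
        assert m.per_structure["bladder"]["dmean"] == 0.0

    def test_uniform_prescription_in_body(self, default_phantom):
        arr = np.where(default_phantom.mask("body"), 46.0, 0.0)
        m = evaluate_plan(DoseDistribution(arr), default_phantom, 46.0)
        assert m.ptv_v95 == 100.0
        assert m.ptv_v110 == 0.0

    def test_fields_match_standalone_operations(self, default_phantom):
        infl = lp.compute_dose_influence(default_phantom, lp.BeamConfig(n_beams=6))
        rng = np.random.default_rng(5)
        dose = lp.dose_from_fluence(infl, rng.uniform(0, 2, infl.n_beamlets))
        m = evaluate_plan(dose, default_phantom, 46.0)
        ph = default_phantom
        assert m.per_structure["small_bowel"]["v45"] == v_above(dose, ph.mask("small_bowel"), 45.0)
        assert m.per_structure["small_bowel"]["v15"] == v_above(dose, ph.mask("small_bowel"), 15.0)
        assert m.ci95 == conformity_index(dose, ph.mask("ptv"), 46.0)
        d = dose.values_in(ph.mask("rectum"))
        assert m.per_structure["rectum"]["dmean"] == pytest.approx(d.mean())
        # pure function: identical inputs give identical metrics
        m2 = evaluate_plan(dose, default_phantom, 46.0)
        assert m.to_series().equals(m2.to_series())

    def test_metric_id_accessors(self, default_phantom):
        infl = lp.compute_dose_influence(default_phantom, lp.BeamConfig(n_beams=6))
        dose = lp.dose_from_fluence(infl, np.ones(infl.n_beamlets))
        m = evaluate_plan(dose, default_phantom, 46.0)
        assert m.get("sb_v45") == m.per_structure["small_bowel"]["v45"]
        assert m.get("ci95") == m.ci95
        assert m.get("rectum/dmax") == m.per_structure["rectum"]["dmax"]
        with pytest.raises(KeyError):
            m.get("nonexistent_metric")
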