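"""PDD normalization, alignment, relative dose and extremum detection."""

import numpy as np
import pandas as pd
import pytest

from bolusdose.analysis import (
    GridError,
    NormalizationError,
    PDDCurve,
    RegionError,
    WaterReferenceError,
    align_to_water,
    detect_extremum,
    find_dmax,
    practical_range,
    rank_tail_means,
    relative_dose,
    study_report,
    tail_summary,
    to_pdd,
)
from bolusdose.curves import DepthDoseCurve
from bolusdose.phantoms import ScenarioSpec
from bolusdose.synthetic import analytic_pdd, generate_study_set, params_from_energy

GRID = np.arange(0.05, 12.0, 0.1)


def water_curve(seed=None, noise=False):
    p = params_from_energy(6.0)
    vals = analytic_pdd(p, GRID)
    return DepthDoseCurve(GRID, vals, np.zeros_like(vals),
                          {"material": "water"}), p


class TestToPdd:
    def test_constant_curve_max_convention(self):
        c = DepthDoseCurve(GRID, np.full_like(GRID, 3.0))
        pdd = to_pdd(c, "max")
        np.testing.assert_allclose(pdd.pdd, 100.0)

    def test_synthetic_water_peak_location(self):
        c, p = water_curve()
        pdd = to_pdd(c, "max")
        fine = np.linspace(1e-4, p.Rp, 20001)
        true_dmax = fine[np.argmax(analytic_pdd(p, fine))]
        assert abs(pdd.reference_depth - true_dmax) <= 0.05 + 1e-9
        assert pdd.pdd.max() == pytest.approx(100.0)

    def test_reference_voxel_reads_100(self):
        c, _ = water_curve()
        pdd = to_pdd(c, "reference", reference_depth=1.75)
        i = int(np.argmin(np.abs(GRID - 1.75)))
        assert pdd.pdd[i] == pytest.approx(100.0)
        assert pdd.reference_depth == pytest.approx(1.75)

    def test_off_grid_reference_rejected(self):
        c, _ = water_curve()
        with pytest.raises(NormalizationError):
            to_pdd(c, "reference", reference_depth=1.777)

    def test_zero_reference_dose_rejected(self):
        vals = np.zeros_like(GRID)
        vals[3] = 1.0
        c = DepthDoseCurve(GRID, vals)
        with pytest.raises(NormalizationError):
            to_pdd(c, "reference", reference_depth=GRID[50])

    def test_idempotent(self):
        c, _ = water_curve()
        once = to_pdd(c, "max")
        again = to_pdd(DepthDoseCurve(once.depths, once.pdd), "max")
        np.testing.assert_allclose(again.pdd, once.pdd, rtol=1e-12)


class TestFindDmax:
    def test_quadratic_vertex_recovered(self):
        vertex = 1.2345
        vals = 10.0 - (GRID - vertex) ** 2
        c = DepthDoseCurve(GRID, np.maximum(vals, 0.0))
        assert find_dmax(c) == pytest.approx(vertex, abs=1e-6)

    def test_plateau_tie_goes_shallow(self):
        vals = np.ones_like(GRID)
        vals[30:35] = 2.0
        c = DepthDoseCurve(GRID, vals)
        assert find_dmax(c) == pytest.approx(GRID[30])

    def test_boundary_maximum_warns(self):
        vals = np.linspace(1.0, 2.0, len(GRID))
        c = DepthDoseCurve(GRID, vals)
        with pytest.warns(UserWarning):
            assert find_dmax(c) == pytest.approx(GRID[-1])

    def test_noiseless_synthetic_within_half_voxel(self):
        c, p = water_curve()
        fine = np.linspace(1e-4, p.Rp, 20001)
        true_dmax = fine[np.argmax(analytic_pdd(p, fine))]
        assert abs(find_dmax(c) - true_dmax) <= 0.05


class TestAlignment:
    def test_water_self_identity(self):
        c, _ = water_curve()
        w = to_pdd(c, "max")
        (aligned,) = align_to_water([w], w)
        np.testing.assert_allclose(aligned.pdd, w.pdd, rtol=1e-9)

    def test_known_shift_recovered(self):
        # curve generated 0.2 cm shallower than water: shift of +0.2 undoes it
        p = params_from_energy(6.0)
        w = to_pdd(DepthDoseCurve(GRID, analytic_pdd(p, GRID)), "max")
        m = to_pdd(DepthDoseCurve(GRID, analytic_pdd(p, GRID + 0.2)), "max")
        (aligned,) = align_to_water([m], w)
        assert float(aligned.metadata["alignment_shift_cm"]) == pytest.approx(
            0.2, abs=0.01)
        sel = (w.depths > 1.0) & (w.pdd > 5.0)
        np.testing.assert_allclose(aligned.pdd[sel], w.pdd[sel], rtol=0.01)

    def test_post_alignment_dmax_coincide(self):
        specs = [ScenarioSpec.from_table("ST", 1.0, m)
                 for m in ("water", "glycerol", "silica-gel")]
        ss = generate_study_set(specs, seed=2, noise=False)
        w = to_pdd(ss.curve(specs[0].label, "water"), "max")
        others = [to_pdd(ss.curve(specs[0].label, m), "max")
                  for m in ("glycerol", "silica-gel")]
        aligned = align_to_water(others, w)
        for a in aligned:
            assert find_dmax(a) == pytest.approx(find_dmax(w), abs=0.05)

    def test_oversized_shift_rejected(self):
        c, _ = water_curve()
        w = to_pdd(c, "max")
        short = PDDCurve(np.array([0.0, 0.1, 0.2]),
                         np.array([50.0, 100.0, 50.0]), "max", 0.1)
        w_far = PDDCurve(w.depths, w.pdd, "max", find_dmax(w))
        with pytest.raises(ValueError, match="shift"):
            align_to_water([short], w_far)


class TestRelativeDose:
    def test_identity_is_100(self):
        c, _ = water_curve()
        w = to_pdd(c, "max")
        rd = relative_dose(w, w, from_depth=find_dmax(w))
        finite = np.isfinite(rd.rd)
        np.testing.assert_allclose(rd.rd[finite], 100.0, rtol=1e-12)
        assert finite.any()

    def test_pointwise_ratio(self):
        depths = np.array([1.0, 2.0])
        m = PDDCurve(depths, np.array([0.5, 0.5]), "max", 1.0)
        w = PDDCurve(depths, np.array([1.0, 1.0]), "max", 1.0)
        rd = relative_dose(m, w, from_depth=0.0)
        np.testing.assert_allclose(rd.rd, 50.0)

    def test_matches_bruteforce_loop(self):
        specs = [ScenarioSpec.from_table("PB", 0.5, m)
                 for m in ("water", "glycerol")]
        ss = generate_study_set(specs, seed=4)
        ref = specs[0].reference_depth
        w = to_pdd(ss.curve(specs[0].label, "water"), "reference", ref)
        m = to_pdd(ss.curve(specs[0].label, "glycerol"), "reference", ref)
        rd = relative_dose(m, w, from_depth=ref)
        # independent index-by-index oracle
        expected = []
        for i in range(len(w.depths)):
            if w.depths[i] < ref - 1e-9:
                continue
            if w.pdd[i] >= 0.01:
                expected.append(100.0 * m.pdd[i] / w.pdd[i])
            else:
                expected.append(np.nan)
        np.testing.assert_allclose(rd.rd, expected, rtol=1e-12)

    def test_grid_mismatch_rejected(self):
        c, _ = water_curve()
        w = to_pdd(c, "max")
        other = PDDCurve(w.depths + 0.05, w.pdd, "max", 1.0)
        with pytest.raises(GridError):
            relative_dose(other, w, from_depth=1.0)


class TestExtremumAndTail:
    def rd_profile(self, rd_values, water_pdd, depths=None):
        from bolusdose.analysis import RDProfile
        depths = depths if depths is not None else \
            np.arange(0.05, 0.05 + 0.1 * len(rd_values), 0.1)
        return RDProfile(depths=depths, rd=np.asarray(rd_values, float),
                         material="x", water_pdd=np.asarray(water_pdd, float),
                         from_depth=0.0)

    def test_flat_profile_extremum_100(self):
        rd = self.rd_profile([100.0] * 30, np.linspace(80, 0.5, 30))
        ext = detect_extremum(rd)
        assert ext.rd_pct == 100.0

    def test_constructed_dip_recovered(self):
        water = np.linspace(85, 0.2, 40)
        vals = np.full(40, 100.0)
        vals[20] = 60.0                      # known dip inside the band
        rd = self.rd_profile(vals, water)
        ext = detect_extremum(rd)
        assert ext.rd_pct == 60.0
        assert ext.depth_cm == pytest.approx(rd.depths[20])
        assert ext.water_pdd_pct == pytest.approx(water[20])

    def test_noisy_pb_glycerol_extremum_is_minimum(self):
        specs = [ScenarioSpec.from_table("PB", 0.5, m)
                 for m in ("water", "glycerol")]
        ss = generate_study_set(specs, seed=6)
        ref = specs[0].reference_depth
        w = to_pdd(ss.curve(specs[0].label, "water"), "reference", ref)
        m = to_pdd(ss.curve(specs[0].label, "glycerol"), "reference", ref)
        ext = detect_extremum(relative_dose(m, w, from_depth=ref))
        assert ext.rd_pct < 100.0

    def test_empty_region_rejected(self):
        rd = self.rd_profile([100.0] * 5, [95.0] * 5)
        with pytest.raises(RegionError):
            detect_extremum(rd)

    def test_tail_mean_flat(self):
        rd = self.rd_profile([100.0] * 30, np.linspace(5, 0.02, 30))
        assert tail_summary(rd).mean_rd_pct == pytest.approx(100.0)

    def test_masked_points_excluded_from_tail(self):
        water = np.array([0.9, 0.5, 0.005, 0.5])
        vals = np.array([100.0, 100.0, np.nan, 100.0])
        rd = self.rd_profile(vals, water)
        summary = tail_summary(rd)
        assert summary.mean_rd_pct == pytest.approx(100.0)

    def test_silica_ranks_highest_tail(self):
        mats = ["water", "PLA", "polystyrene", "silica-gel", "glycerol"]
        specs = [ScenarioSpec.from_table("ST", 1.0, m) for m in mats]
        ss = generate_study_set(specs, seed=8)
        label = specs[0].label
        w = to_pdd(ss.curve(label, "water"), "max")
        d_w = find_dmax(w)
        others = [to_pdd(ss.curve(label, m), "max") for m in mats[1:]]
        aligned = align_to_water(others, w)
        profiles = []
        for m, a in zip(mats[1:], aligned):
            prof = relative_dose(a, w, from_depth=d_w)
            prof.material = m
            profiles.append(prof)
        ranking = rank_tail_means(profiles)
        assert ranking[0][0] == "silica-gel"


class TestPracticalRange:
    def test_synthetic_range_between_r50_and_support(self):
        c, p = water_curve()
        rp = practical_range(c)
        assert p.R50 < rp < GRID[-1]


class TestStudyReport:
    def make_results(self, family, layer3, seed=0):
        mats = ["water", "PLA", "polystyrene", "silica-gel", "glycerol"]
        specs = [ScenarioSpec.from_table(family, layer3, m) for m in mats]
        ss = generate_study_set(specs, seed=seed)
        label = specs[0].label
        return {label: (specs[0],
                        {m: ss.curve(label, m) for m in mats})}

    def test_water_excluded_and_row_count(self):
        results = {}
        for layer3 in (0.5, 1.0, 1.5):
            results.update(self.make_results("ST", layer3))
        report = study_report(results)
        assert len(report) == 12          # 3 scenarios x 4 non-water materials
        assert "water" not in set(report["material"])

    def test_depth_reported_from_both_origins(self):
        report = study_report(self.make_results("PB", 0.5))
        diff = (report["extremum_depth_cm_from_bolus_top"]
                - report["extremum_depth_cm_from_skin"])
        np.testing.assert_allclose(diff, 1.0)   # bolus thickness in this row

    def test_regeneration_bit_identical(self):
        results = self.make_results("PB", 1.0, seed=5)
        r1 = study_report(results)
        r2 = study_report(results)
        pd.testing.assert_frame_equal(r1, r2)

    def test_missing_water_rejected(self):
        results = self.make_results("ST", 1.0)
        (label, (spec, curves)), = results.items()
        del curves["water"]
        with pytest.raises(WaterReferenceError):
            study_report(results)
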