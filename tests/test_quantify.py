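"""Nucleus segmentation, signal clustering, per-nucleus counting and summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

import fishquant as fq
from fishquant.errors import CalibrationError, InvalidParameterError
from fishquant.quantify import SIGNAL_COLUMNS, SignalSet, _empty_signals
from fishquant.simulate import emitter_image
from fishquant.stackio import empty_localizations
from oracles import brute_force_linkage_clusters


def make_signals(channel, rows):
    """rows: list of (x_nm, y_nm, est_count, ambiguous)."""
    tbl = pd.DataFrame(
        [
            {
                "x_nm": x,
                "y_nm": y,
                "strength": float(est),
                "extent_nm": 50.0,
                "est_count": est,
                "ambiguous": amb,
            }
            for x, y, est, amb in rows
        ],
        columns=SIGNAL_COLUMNS,
    )
    return SignalSet(channel=channel, table=tbl)


class TestSegmentNuclei:
    def test_single_disc_found_with_centroid(self):
        img = np.full((64, 64), 100.0)
        yy, xx = np.mgrid[0:64, 0:64]
        img[(xx - 30) ** 2 + (yy - 25) ** 2 <= 100] = 250.0
        nm = fq.segment_nuclei(img, min_area_px=50)
        assert nm.n_nuclei == 1
        assert nm.table.loc[0, "x_nm"] == pytest.approx(3050, abs=100)
        assert nm.table.loc[0, "y_nm"] == pytest.approx(2550, abs=100)

    def test_simulated_ellipses_recovered_with_areas(self):
        p = fq.SimulationParams(
            field_px=96, n_frames_signal=2, n_frames_dapi=60, n_nuclei=5,
            nucleus_radius_px=(8, 11), her2_per_nucleus=0, cep17_per_nucleus=0, seed=21,
        )
        _, _, dapi, truth = fq.simulate_field(p)
        nm = fq.segment_nuclei(fq.widefield_projection(dapi))
        assert nm.n_nuclei == 5
        for nuc in truth.nuclei:
            d = np.hypot(nm.table["x_nm"] - nuc.centroid_nm[0], nm.table["y_nm"] - nuc.centroid_nm[1])
            seg_area = nm.table.loc[d.idxmin(), "area_px"]
            assert abs(seg_area - nuc.mask.sum()) / nuc.mask.sum() < 0.05

    def test_touching_ellipses_split(self):
        img = np.full((64, 96), 100.0)
        yy, xx = np.mgrid[0:64, 0:96]
        img[((xx - 35) / 14.0) ** 2 + ((yy - 32) / 11.0) ** 2 <= 1] = 250.0
        img[((xx - 62) / 14.0) ** 2 + ((yy - 32) / 11.0) ** 2 <= 1] = 250.0
        nm = fq.segment_nuclei(img, min_area_px=50)
        assert nm.n_nuclei == 2

    def test_blank_image_gives_empty_map(self):
        nm = fq.segment_nuclei(np.full((32, 32), 5.0))
        assert nm.n_nuclei == 0


class TestClusterLocalizations:
    def test_single_tight_cluster(self, rng):
        table = empty_localizations()
        for k in range(10):
            table.loc[k] = [k, 1000 + rng.normal(0, 10), 1000 + rng.normal(0, 10), 130, 1500, 0, 5]
        ss = fq.cluster_localizations(table, eps_nm=150, min_pts=3)
        assert len(ss) == 1
        assert ss.table.loc[0, "strength"] == 10

    def test_two_separated_clusters_match_linkage_oracle(self, rng):
        table = empty_localizations()
        pts = []
        for k in range(12):
            x = 1000 + (k % 2) * 500 + rng.normal(0, 15)
            y = 1000 + rng.normal(0, 15)
            pts.append((x, y))
            table.loc[k] = [k, x, y, 130, 1500, 0, 5]
        ss = fq.cluster_localizations(table, eps_nm=150, min_pts=3)
        oracle = brute_force_linkage_clusters(np.asarray(pts), 150.0)
        assert len(ss) == sum(1 for g in oracle if len(g) >= 3) == 2

    def test_random_points_match_linkage_oracle(self, rng):
        pts = rng.uniform(0, 2000, (60, 2))
        table = empty_localizations()
        for k, (x, y) in enumerate(pts):
            table.loc[k] = [k, x, y, 130, 1500, 0, 5]
        ss = fq.cluster_localizations(table, eps_nm=120, min_pts=3)
        oracle = [g for g in brute_force_linkage_clusters(pts, 120.0) if len(g) >= 3]
        assert len(ss) == len(oracle)
        assert sorted(ss.table["strength"]) == sorted(float(len(g)) for g in oracle)

    def test_empty_table_gives_empty_set(self):
        assert len(fq.cluster_localizations(empty_localizations())) == 0

    def test_noise_points_discarded(self, rng):
        table = empty_localizations()
        table.loc[0] = [0, 100, 100, 130, 1500, 0, 5]
        table.loc[1] = [1, 5000, 5000, 130, 1500, 0, 5]
        assert len(fq.cluster_localizations(table, eps_nm=150, min_pts=3)) == 0


class TestEstimateClusterCount:
    def test_reference_strength_is_one_copy(self):
        assert fq.estimate_cluster_count(200.0, 200.0, extent_nm=40) == (1, False)

    def test_many_copies_in_wide_signal_is_more_than_four(self):
        est, amb = fq.estimate_cluster_count(12 * 200.0, 200.0, extent_nm=250)
        assert (est, amb) == (5, True)

    def test_rounding_rule(self):
        assert fq.estimate_cluster_count(3.4 * 200.0, 200.0, extent_nm=40) == (3, False)

    def test_compact_many_copy_signal_stays_countable(self):
        # >4 copies in a sub-diffraction signal: countable, not ambiguous
        est, amb = fq.estimate_cluster_count(5 * 200.0, 200.0, extent_nm=60)
        assert (est, amb) == (5, False)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(CalibrationError):
            fq.estimate_cluster_count(100.0, 0.0)


class TestWidefieldSpots:
    def test_blank_image_gives_empty_set(self):
        assert len(fq.detect_spots_widefield(np.full((48, 48), 30.0))) == 0

    def test_three_isolated_spots_counted(self):
        emitters = [[1200, 1200, 3000], [3300, 1400, 3000], [2200, 3400, 3000]]
        img = emitter_image((48, 48), emitters, 130, 100) + 30.0
        ss = fq.detect_spots_widefield(img)
        assert len(ss) == 3
        assert ss.table["est_count"].tolist() == [1, 1, 1]

    def test_sub_diffraction_doublet_merges_but_sr_route_resolves(self, rng):
        # one fixture, both routes: 150 nm doublet
        emitters = [[2225, 2400, 3000], [2375, 2400, 3000], [4000, 4000, 3000]]
        img = emitter_image((64, 64), emitters, 130, 100) + 30.0
        cr = fq.detect_spots_widefield(img)
        assert len(cr) == 2  # doublet unresolved + reference spot

        table = empty_localizations()
        for k in range(40):
            which = k % 2
            table.loc[k] = [k, 2225 + 150 * which + rng.normal(0, 5),
                            2400 + rng.normal(0, 5), 130, 1500, 0, 5]
        sr = fq.cluster_localizations(table, eps_nm=120, min_pts=3)
        assert len(sr) == 2  # the doublet alone yields two signals


class TestCounting:
    def make_nucleus_map(self):
        labels = np.zeros((64, 64), dtype=int)
        labels[10:30, 10:30] = 1
        labels[40:60, 40:60] = 2
        table = pd.DataFrame(
            [
                {"id": 1, "x_nm": 2000.0, "y_nm": 2000.0, "area_px": 400},
                {"id": 2, "x_nm": 5000.0, "y_nm": 5000.0, "area_px": 400},
            ]
        )
        return fq.NucleusMap(labels=labels, table=table, pixel_size_nm=100.0)

    def test_amplified_nucleus_worked_example(self):
        # 12 HER2 signals and one CEP17 signal in a single nucleus
        nuclei = self.make_nucleus_map()
        her2 = make_signals(
            "HER2", [(1500 + 40 * k, 1500, 1, False) for k in range(12)]
        )
        cep17 = make_signals("CEP17", [(2000, 2500, 1, False)])
        counts = fq.count_per_nucleus(her2, cep17, nuclei)
        row = counts[counts["nucleus_id"] == 1].iloc[0]
        assert row["H"] == 12 and row["C"] == 1

    def test_empty_nucleus_not_countable(self):
        nuclei = self.make_nucleus_map()
        counts = fq.count_per_nucleus(_empty_signals("HER2"), _empty_signals("CEP17"), nuclei)
        row = counts[counts["nucleus_id"] == 2].iloc[0]
        assert row["H"] == 0 and row["C"] == 0 and not row["cep17_countable"]

    def test_signal_outside_nuclei_dropped_and_logged(self):
        nuclei = self.make_nucleus_map()
        her2 = make_signals("HER2", [(3500, 3500, 1, False)])
        counts = fq.count_per_nucleus(her2, _empty_signals("CEP17"), nuclei)
        assert counts["H"].sum() == 0
        assert counts.attrs["n_dropped"]["HER2"] == 1

    def test_ambiguous_flag_propagates_to_nucleus(self):
        nuclei = self.make_nucleus_map()
        her2 = make_signals("HER2", [(2000, 2000, 5, True), (2500, 2500, 1, False)])
        counts = fq.count_per_nucleus(her2, _empty_signals("CEP17"), nuclei)
        assert bool(counts[counts["nucleus_id"] == 1]["her2_ambiguous"].iloc[0])


class TestSummarize:
    def make_counts(self, rows):
        df = pd.DataFrame(
            rows,
            columns=["nucleus_id", "H", "her2_ambiguous", "C", "cep17_ambiguous"],
        )
        df["cep17_countable"] = (df["C"] >= 1) & (~df["cep17_ambiguous"])
        return df

    def test_eligibility_rule_hand_arithmetic(self):
        counts = self.make_counts(
            [(1, 3, False, 2, False), (2, 5, False, 2, False), (3, 4, False, 0, False)]
        )
        res = fq.summarize_counts(counts)
        assert res.ratio == pytest.approx(2.0)  # (3+5)/(2+2) over eligible nuclei
        assert res.nuclei_with_her2 == 3
        assert res.her2_signals == 12
        assert res.her2_per_nucleus == pytest.approx(4.0)

    def test_single_negative_nucleus(self):
        res = fq.summarize_counts(self.make_counts([(1, 3, False, 2, False)]))
        assert res.ratio == pytest.approx(1.5)
        assert res.her2_per_nucleus == pytest.approx(3.0)
        assert res.cep17_per_nucleus == pytest.approx(2.0)

    def test_all_cep17_uncountable_gives_null_ratio(self):
        res = fq.summarize_counts(self.make_counts([(1, 3, False, 0, False), (2, 2, False, 3, True)]))
        assert res.ratio is None and res.ratio_undefined_reason

    def test_ambiguous_nuclei_excluded_from_totals(self):
        counts = self.make_counts([(1, 3, False, 2, False), (2, 9, True, 2, False)])
        res = fq.summarize_counts(counts)
        assert res.her2_signals == 3
        assert res.nuclei_ambiguous_her2 == 1
        assert res.her2_per_nucleus == pytest.approx(3.0)

    def test_coordinate_scaling_leaves_counts_invariant(self, rng):
        # scaling all localization coordinates (and eps) is a pure unit change
        table = empty_localizations()
        for k in range(30):
            table.loc[k] = [k, 1000 + (k % 3) * 600 + rng.normal(0, 10),
                            1000 + rng.normal(0, 10), 130, 1500, 0, 5]
        a = fq.cluster_localizations(table, eps_nm=150, min_pts=3)
        scaled = table.copy()
        scaled[["x_nm", "y_nm"]] *= 10.0
        b = fq.cluster_localizations(scaled, eps_nm=1500, min_pts=3)
        assert sorted(a.table["strength"]) == sorted(b.table["strength"])

    def test_no_nuclei_rejected(self):
        with pytest.raises(InvalidParameterError):
            fq.summarize_counts(self.make_counts([]))
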