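import numpy as np
import pytest

from histobridge import (
    SegmentationMap,
    Tissue,
    agglomerate_stats,
    compute_areas,
    compute_report,
    periosteal_void,
    round_half_up,
)
from oracles import components_8, count_classes, reachable_8


def segmap(labels, pitch=100.0):
    return SegmentationMap(labels=np.asarray(labels, dtype=np.uint8), pixel_pitch_um=pitch)


class TestComputeAreas:
    def test_hand_counted_grid(self, flat_frame):
        labels = np.full((10, 10), np.uint8(Tissue.SOFT))
        labels.ravel()[:30] = Tissue.SUBSTITUTE
        labels.ravel()[30:80] = Tissue.NEW_BONE
        areas = compute_areas(segmap(labels), flat_frame, "cortical")
        assert areas == {
            "tv_px": 100,
            "nbv_px": 50,
            "bsv_px": 30,
            "vdv_px": 20,
            "ov_px": 0,
        }
        m = _roi_metrics(labels, flat_frame)
        assert m.bsv_tv_pct == pytest.approx(30.0)
        assert m.nbv_tv_pct == pytest.approx(50.0)
        assert m.cov_tv_pct == pytest.approx(80.0)

    def test_full_new_bone_roi_is_100_percent(self, flat_frame):
        labels = np.full((10, 10), np.uint8(Tissue.NEW_BONE))
        m = _roi_metrics(labels, flat_frame)
        assert m.nbv_tv_pct == 100.0 and m.cov_tv_pct == 100.0

    def test_partition_of_tv_is_exact_in_pixels(self, flat_frame):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 4, size=(10, 10)).astype(np.uint8)
        areas = compute_areas(segmap(labels), flat_frame, "cortical")
        assert (
            areas["nbv_px"] + areas["bsv_px"] + areas["vdv_px"] + areas["ov_px"]
            == areas["tv_px"]
        )

    def test_matches_loop_oracle(self, flat_frame):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 4, size=(10, 10)).astype(np.uint8)
        areas = compute_areas(segmap(labels), flat_frame, "cortical")
        oracle = count_classes(labels, flat_frame.cortical_mask)
        assert areas["nbv_px"] == oracle.get(int(Tissue.NEW_BONE), 0)
        assert areas["bsv_px"] == oracle.get(int(Tissue.SUBSTITUTE), 0)
        assert areas["vdv_px"] == oracle.get(int(Tissue.SOFT), 0)


class TestAgglomerates:
    def test_three_equal_discs(self, flat_frame):
        labels = np.full((10, 10), np.uint8(Tissue.SOFT))
        for c in (0, 4, 8):  # three 2x2 squares, separated
            labels[0:2, c : c + 2] = Tissue.SUBSTITUTE
        aggl = agglomerate_stats(segmap(labels), flat_frame, "cortical")
        assert len(aggl) == 3
        assert all(a.area_px == 4 for a in aggl)
        m = _roi_metrics(labels, flat_frame)
        assert m.bs_pa_ar_mm2 == pytest.approx(4 * 0.01)  # 100 um px

    def test_touching_blobs_are_one_component(self, flat_frame):
        labels = np.full((10, 10), np.uint8(Tissue.SOFT))
        labels[0:2, 0:2] = Tissue.SUBSTITUTE
        labels[2, 2] = Tissue.SUBSTITUTE  # diagonal touch: 8-connected
        aggl = agglomerate_stats(segmap(labels), flat_frame, "cortical")
        assert len(aggl) == 1 and aggl[0].area_px == 5

    def test_no_agglomerates_mean_area_missing_not_zero(self, flat_frame):
        labels = np.full((10, 10), np.uint8(Tissue.SOFT))
        m = _roi_metrics(labels, flat_frame)
        assert m.bs_pa_n == 0 and m.bs_pa_ar_mm2 is None

    def test_component_clipped_to_roi_counted_once(self):
        from histobridge import DefectGeometry, DefectROIs

        geom = DefectGeometry(
            0, 10, np.zeros(20, int), np.full(20, 10), pixel_pitch_um=100.0
        )
        cort = np.zeros((10, 20), bool)
        cort[:, :10] = True
        rois = DefectROIs(cort, np.zeros((10, 20), bool), geom)
        labels = np.full((10, 20), np.uint8(Tissue.SOFT))
        labels[4:6, 8:14] = Tissue.SUBSTITUTE  # straddles the ROI edge
        aggl = agglomerate_stats(segmap(labels), rois, "cortical")
        assert len(aggl) == 1
        assert aggl[0].area_px == 2 * 2  # only the in-ROI part

    def test_matches_bfs_component_oracle(self, flat_frame):
        rng = np.random.default_rng(4)
        labels = np.where(
            rng.random((10, 10)) < 0.3, np.uint8(Tissue.SUBSTITUTE), np.uint8(0)
        )
        aggl = agglomerate_stats(segmap(labels), flat_frame, "cortical")
        comps = components_8(labels == Tissue.SUBSTITUTE)
        assert len(aggl) == len(comps)
        assert sorted(a.area_px for a in aggl) == sorted(len(c) for c in comps)


class TestPeriostealVoid:
    def _rois(self):
        from histobridge import DefectGeometry, DefectROIs

        geom = DefectGeometry(
            2, 18, np.full(20, 5), np.full(20, 15), pixel_pitch_um=100.0
        )
        cort = np.zeros((20, 20), bool)
        cort[5:15, 2:18] = True
        return DefectROIs(cort, np.zeros((20, 20), bool), geom)

    def test_no_soft_tissue_in_roi_gives_zero(self):
        rois = self._rois()
        labels = np.full((20, 20), np.uint8(Tissue.NEW_BONE))
        assert periosteal_void(segmap(labels), rois, "cortical") == 0

    def test_canal_counts_island_does_not(self):
        rois = self._rois()
        labels = np.full((20, 20), np.uint8(Tissue.NEW_BONE))
        labels[0:5, :] = Tissue.SOFT  # periosteal region
        labels[5:15, 8:10] = Tissue.SOFT  # canal: 20 px, touches the top
        labels[10:12, 14:16] = Tissue.SOFT  # enclosed island: 4 px
        got = periosteal_void(segmap(labels), rois, "cortical")
        assert got == 20
        # flood-fill oracle seeded in the periosteal zone
        soft = labels == Tissue.SOFT
        seeds = [(r, c) for r in range(5) for c in range(20)]
        reach = reachable_8(soft, seeds)
        assert got == int((reach & rois.cortical_mask).sum())

    def test_endosteal_only_soft_band_excluded(self):
        rois = self._rois()
        labels = np.full((20, 20), np.uint8(Tissue.NEW_BONE))
        labels[13:20, :] = Tissue.SOFT  # touches the endosteal side and below
        assert periosteal_void(segmap(labels), rois, "cortical") == 0


class TestReportInvariants:
    def test_report_equals_loop_oracle_on_phantom(self, noiseless_truth):
        t = noiseless_truth
        report = compute_report(
            SegmentationMap(t.labels, t.config.pixel_pitch_um), t.rois
        )
        for roi in ("cortical", "medullary"):
            m = report[roi]
            oracle = count_classes(t.labels, t.rois.mask(roi))
            assert m.nbv_px == oracle.get(2, 0)
            assert m.bsv_px == oracle.get(3, 0)
            assert m.vdv_px == oracle.get(0, 0)
            assert m.tv_px == sum(oracle.values())
            comps = components_8(t.labels == Tissue.SUBSTITUTE)
            in_roi = [
                c for c in comps if any(t.rois.mask(roi)[r, cc] for r, cc in c)
            ]
            assert m.bs_pa_n == len(in_roi)

    def test_scale_equivariance_of_mm2_areas(self):
        from conftest import small_config
        from histobridge import generate_section

        fine = generate_section(
            small_config(seed=5, pixel_pitch_um=20.0, canal_spec=[0.5])
        )
        coarse = generate_section(
            small_config(seed=5, pixel_pitch_um=40.0, canal_spec=[0.5])
        )
        for roi in ("cortical", "medullary"):
            a = fine.true_report[roi]
            b = coarse.true_report[roi]
            assert b.tv_mm2 == pytest.approx(a.tv_mm2, rel=0.02)
            assert b.nbv_tv_pct == pytest.approx(a.nbv_tv_pct, abs=3.0)

    def test_composite_dominates_components(self, noiseless_truth):
        for m in noiseless_truth.true_report.rois.values():
            assert m.cov_tv_pct >= max(m.nbv_tv_pct, m.bsv_tv_pct) - 1e-9
            assert m.cov_tv_pct <= 100.0 + 1e-9


def _roi_metrics(labels, rois):
    from histobridge.metrics import ROIMetrics, agglomerate_stats, compute_areas

    sm = segmap(labels)
    areas = compute_areas(sm, rois, "cortical")
    return ROIMetrics(
        roi="cortical",
        pixel_pitch_um=100.0,
        psvdv_px=0,
        agglomerates=agglomerate_stats(sm, rois, "cortical"),
        **areas,
    )


@pytest.mark.parametrize(
    "x,expect",
    [(54.545, 55), (87.5, 88), (20.833, 21), (69.7, 70), (0.5, 1), (-0.4, 0)],
)
def test_round_half_up(x, expect):
    assert round_half_up(x) == expect
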