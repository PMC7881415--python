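import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

from neoresp import image_quant as iq
from neoresp import synthetic_data as sd


def brute_force_glcm_props(q, mask, levels, offset):
    """Symmetric, normalized co-occurrence of quantized levels 1..levels
    inside the mask, by direct pair enumeration."""
    dr, dc = offset
    P = np.zeros((levels, levels))
    h, w = q.shape
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                P[q[r, c] - 1, q[r2, c2] - 1] += 1
                P[q[r2, c2] - 1, q[r, c] - 1] += 1
    P /= max(P.sum(), 1)
    i, j = np.mgrid[0:levels, 0:levels]
    return {
        "contrast": float(np.sum(P * (i - j) ** 2)),
        "energy": float(np.sqrt(np.sum(P ** 2))),
        # inverse difference moment (the usual "homogeneity")
        "homogeneity": float(np.sum(P / (1.0 + (i - j) ** 2))),
    }


class TestSegmentation:
    def test_single_blob(self):
        img = np.zeros((64, 64))
        rr, cc = np.mgrid[0:64, 0:64]
        img[(rr - 32) ** 2 + (cc - 32) ** 2 < 49] = 100.0
        labels, table = iq.segment_nuclei(img, min_area_px=20)
        assert labels.max() == 1
        assert table["centroid_row"].iloc[0] == pytest.approx(32, abs=1)

    def test_background_only_image_is_empty(self):
        labels, table = iq.segment_nuclei(np.zeros((64, 64)))
        assert labels.max() == 0 and len(table) == 0

    def test_count_and_centroids_vs_ground_truth(self, nuclei_image):
        spec, stack, truth = nuclei_image
        labels, table = iq.segment_nuclei(stack[0])
        assert abs(labels.max() - spec.n_nuclei) <= 2
        d, _ = cKDTree(truth[["centroid_row", "centroid_col"]].to_numpy()).query(
            table[["centroid_row", "centroid_col"]].to_numpy())
        assert d.max() < 2.0

    def test_labels_contiguous(self, nuclei_image):
        _, stack, _ = nuclei_image
        labels, _ = iq.segment_nuclei(stack[0])
        ids = np.unique(labels)
        assert np.array_equal(ids, np.arange(labels.max() + 1))


class TestKmeansDomain:
    def test_separable_groups_recovered(self):
        rng = np.random.default_rng(0)
        a = rng.normal([100, 100], 5, size=(30, 2))
        b = rng.normal([400, 120], 5, size=(25, 2))
        obj = pd.DataFrame(np.vstack([a, b]),
                           columns=["centroid_row", "centroid_col"])
        dom = iq.kmeans_domain(obj, k=2, seed=1)
        assert dom.in_domain[:30].sum() in (0, 30)  # no split groups
        # the ventral (max-row) cluster is group b
        assert dom.in_domain[30:].all()
        assert not dom.in_domain[:30].any()

    def test_k_one_is_single_cluster(self):
        obj = pd.DataFrame({"centroid_row": [1.0, 2, 3], "centroid_col": [0.0, 0, 0]})
        dom = iq.kmeans_domain(obj, k=1)
        assert np.all(dom.cluster == 0) and dom.in_domain.all()

    def test_seed_determinism(self):
        rng = np.random.default_rng(2)
        obj = pd.DataFrame(rng.uniform(0, 500, size=(80, 2)),
                           columns=["centroid_row", "centroid_col"])
        d1 = iq.kmeans_domain(obj, k=3, seed=9)
        d2 = iq.kmeans_domain(obj, k=3, seed=9)
        assert np.array_equal(d1.cluster, d2.cluster)
        assert d1.domain_cluster == d2.domain_cluster

    def test_invalid_k_rejected(self):
        obj = pd.DataFrame({"centroid_row": [1.0, 2], "centroid_col": [0.0, 0]})
        with pytest.raises(ValueError):
            iq.kmeans_domain(obj, k=3)


class TestFeatures:
    def test_uniform_object_mean_and_zero_contrast(self):
        labels = np.zeros((32, 32), dtype=np.int32)
        labels[8:24, 8:24] = 1
        chan = np.where(labels > 0, 37.0, 0.0)
        obj = iq.extract_features(labels, {"ch": chan})
        assert obj["ch_mean"].iloc[0] == pytest.approx(37.0)
        assert obj["ch_glcm_contrast"].iloc[0] == 0.0
        assert obj["ch_glcm_energy"].iloc[0] == pytest.approx(1.0)

    def test_circular_object_low_eccentricity(self):
        labels = np.zeros((64, 64), dtype=np.int32)
        rr, cc = np.mgrid[0:64, 0:64]
        labels[(rr - 32) ** 2 + (cc - 32) ** 2 < 15 ** 2] = 1
        obj = iq.extract_features(labels, {})
        assert obj["eccentricity"].iloc[0] < 0.05

    def test_stripe_texture_matches_brute_force_glcm(self):
        labels = np.zeros((20, 20), dtype=np.int32)
        labels[4:16, 4:16] = 1
        img = np.zeros((20, 20))
        img[:, ::2] = 1.0  # 2-px-period vertical stripes
        levels = 32
        obj = iq.extract_features(labels, {"ch": img}, glcm_levels=levels,
                                  glcm_angles=(0.0,))
        mask = labels == 1
        q = np.zeros_like(labels, dtype=int)
        q[mask] = np.where(img[mask] > 0, levels, 1)
        # offset for angle 0 is (0, +1) in (row, col)
        brute = brute_force_glcm_props(q, mask, levels, (0, 1))
        assert obj["ch_glcm_contrast"].iloc[0] == pytest.approx(brute["contrast"])
        assert obj["ch_glcm_energy"].iloc[0] == pytest.approx(brute["energy"])
        assert obj["ch_glcm_homogeneity"].iloc[0] == pytest.approx(brute["homogeneity"])

    def test_mask_faithfulness(self):
        labels = np.zeros((40, 40), dtype=np.int32)
        labels[5:15, 5:15] = 1
        rng = np.random.default_rng(3)
        chan = rng.uniform(0, 100, (40, 40))
        base = iq.extract_features(labels, {"ch": chan})
        tampered = chan.copy()
        tampered[labels == 0] = rng.uniform(0, 1000, int((labels == 0).sum()))
        after = iq.extract_features(labels, {"ch": tampered})
        pd.testing.assert_frame_equal(base, after)

    def test_geometry_mismatch_rejected(self):
        labels = np.zeros((10, 10), dtype=np.int32)
        with pytest.raises(ValueError, match="geometry"):
            iq.extract_features(labels, {"ch": np.zeros((5, 5))})


class TestMarkerPositivity:
    def test_bimodal_split_exact(self):
        obj = pd.DataFrame({"brdu_mean": [10.0] * 40 + [200.0] * 25})
        pos, n = iq.classify_marker_positive(obj, "brdu")
        assert n == 25
        assert pos[40:].all() and not pos[:40].any()

    def test_fixed_threshold_all_below(self):
        obj = pd.DataFrame({"brdu_mean": [1.0, 2.0, 3.0]})
        _, n = iq.classify_marker_positive(obj, "brdu", method="fixed", threshold=10)
        assert n == 0

    def test_identical_intensities_reject_otsu(self):
        obj = pd.DataFrame({"brdu_mean": [5.0] * 10})
        with pytest.raises(ValueError, match="fixed"):
            iq.classify_marker_positive(obj, "brdu")

    def test_positivity_matches_simulated_state_fractions(self, nuclei_image):
        spec, stack, truth = nuclei_image
        labels, _ = iq.segment_nuclei(stack[0])
        obj = iq.extract_features(labels, {"brdu": stack[1], "edu": stack[2]})
        _, n_brdu = iq.classify_marker_positive(obj, "brdu")
        assert n_brdu / len(obj) == pytest.approx(truth["cldu_pos"].mean(), abs=0.02)


class TestProliferationAndSPhase:
    def test_fractions(self):
        c = iq.PulseLabelCounts(n_dapi=200, n_brdu_pos=50, n_edu_pos=30,
                                n_brdu_pos_edu_neg=20)
        df = iq.proliferation_metrics(c)
        assert df["brdu_frac"].iloc[0] == 0.25
        assert df["edu_frac"].iloc[0] == 0.15

    def test_zero_brdu(self):
        c = iq.PulseLabelCounts(n_dapi=100, n_brdu_pos=0, n_edu_pos=0,
                                n_brdu_pos_edu_neg=0)
        assert iq.proliferation_metrics(c)["brdu_frac"].iloc[0] == 0.0

    def test_scaled_fractions_are_zscores(self):
        counts = [iq.PulseLabelCounts(100, b, 10, 5, region_id=i)
                  for i, b in enumerate((20, 40, 60))]
        df = iq.proliferation_metrics(counts)
        assert df["brdu_frac_scaled"].mean() == pytest.approx(0.0, abs=1e-12)
        assert df["brdu_frac_scaled"].std(ddof=0) == pytest.approx(1.0, rel=1e-9)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            iq.PulseLabelCounts(n_dapi=10, n_brdu_pos=11, n_edu_pos=0,
                                n_brdu_pos_edu_neg=0)

    def test_s_phase_direct_formula(self):
        c = iq.PulseLabelCounts(1000, 300, 100, 20)
        est = iq.estimate_s_phase(c, interval_h=2.0)
        assert est.t_s_h == pytest.approx(10.0)

    def test_s_phase_equal_cohorts(self):
        c = iq.PulseLabelCounts(1000, 300, 50, 50)
        assert iq.estimate_s_phase(c, interval_h=2.0).t_s_h == pytest.approx(2.0)

    def test_s_phase_zero_leaving_rejected(self):
        c = iq.PulseLabelCounts(1000, 300, 100, 0)
        with pytest.raises(ValueError, match="leaving"):
            iq.estimate_s_phase(c)

    def test_recovery_from_simulated_population(self):
        spec = sd.CellCycleSpec(n_cells=10_000, t_cycle_h=14.0, t_s_h=6.0, seed=8)
        cells = sd.gen_cellcycle_population(spec)
        c = iq.PulseLabelCounts(
            n_dapi=len(cells),
            n_brdu_pos=int(cells["cldu_pos"].sum()),
            n_edu_pos=int(cells["edu_pos"].sum()),
            n_brdu_pos_edu_neg=int((cells["cldu_pos"] & ~cells["edu_pos"]).sum()))
        est = iq.estimate_s_phase(c, interval_h=2.0, edu_window_h=0.5)
        assert est.t_s_h == pytest.approx(6.0, rel=0.10)


class TestProjectionPunctaRoi:
    def test_identical_planes(self):
        plane = np.arange(12.0).reshape(3, 4)
        assert np.array_equal(iq.max_projection([plane] * 5), plane)

    def test_bright_pixel_survives(self):
        stack = np.zeros((9, 8, 8))
        stack[6, 3, 4] = 99.0
        proj = iq.max_projection(stack)
        assert proj[3, 4] == 99.0
        assert np.all(proj >= stack.max(axis=0) - 1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            iq.max_projection([np.zeros((4, 4)), np.zeros((5, 4))])

    def test_puncta_count_and_intensity_invariance(self):
        rng = np.random.default_rng(9)
        img = np.zeros((256, 256))
        rr, cc = np.mgrid[-6:7, -6:7]
        spot = np.exp(-(rr ** 2 + cc ** 2) / (2 * 2.0 ** 2))
        centers = [(20 + 45 * i, 20 + 45 * j) for i in range(5) for j in range(5)]
        for r, c in centers:
            img[r - 6:r + 7, c - 6:c + 7] += spot
        n, _ = iq.count_puncta(img, log_sigma_px=2.0)
        assert n == 25
        n2, _ = iq.count_puncta(2.0 * img, log_sigma_px=2.0)
        assert n2 == 25

    def test_blank_image_zero_puncta(self):
        assert iq.count_puncta(np.zeros((64, 64)))[0] == 0

    def test_roi_mean_constant(self):
        img = np.full((30, 30), 17.0)
        mask = np.zeros((30, 30), bool)
        mask[5:10, 5:10] = True
        assert iq.roi_mean_gray(img, mask) == 17.0

    def test_roi_mean_half_and_half(self):
        img = np.zeros((10, 10))
        img[:, 5:] = 100.0
        mask = np.ones((10, 10), bool)
        assert iq.roi_mean_gray(img, mask) == 50.0

    def test_polygon_roi_matches_enumeration(self):
        rng = np.random.default_rng(10)
        img = rng.uniform(0, 255, (50, 50))
        poly = np.array([[5, 5], [5, 30], [40, 30], [40, 5]])
        from skimage.draw import polygon2mask
        mask = polygon2mask(img.shape, poly)
        assert iq.roi_mean_gray(img, poly) == pytest.approx(img[mask].mean())

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            iq.roi_mean_gray(np.zeros((5, 5)), np.zeros((5, 5), bool))
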