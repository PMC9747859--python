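"""Threshold segmentation, tissue k-means, the spatial-relationship
majority pass and the combined clustered scan."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ccsmar.clustering import (
    AIR_LABEL,
    METAL_LABEL,
    ClusterPriors,
    LabelMap,
    NeighborhoodSpec,
    apply_spatial_relationships,
    build_clustered_image,
    combine_clustered,
    kmeans_cluster,
    segment_threshold,
)
from ccsmar.imaging_io import CTImage


class TestSegmentThreshold:
    def test_metal_and_air_thresholds(self):
        px = np.full((8, 8), 0.0)
        px[2, 3] = 2500.0
        px[5, 5:7] = -990.0
        img = CTImage(px)
        metal = segment_threshold(img, 2000.0, "ge")
        air = segment_threshold(img, -950.0, "le")
        assert metal.sum() == 1 and metal[2, 3]
        assert air.sum() == 2 and air[5, 5] and air[5, 6]
        assert not segment_threshold(CTImage(np.full((4, 4), -1000.0)), 2000.0, "ge").any()

    @given(t1=st.floats(-500, 500), t2=st.floats(-500, 500))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_ge_threshold_monotone(self, t1, t2):
        """Raising a ge-threshold never adds pixels to the mask."""
        rng = np.random.default_rng(7)
        img = CTImage(rng.uniform(-1000, 1000, (12, 12)))
        lo, hi = min(t1, t2), max(t1, t2)
        assert not (segment_threshold(img, hi, "ge") & ~segment_threshold(img, lo, "ge")).any()


class TestKMeans:
    def test_perfectly_separated_clusters(self, rng):
        vals = rng.choice([-800.0, 0.0, 800.0], size=(16, 16))
        lm = kmeans_cluster(CTImage(vals), None, k=3, seed=0)
        for code, hu in ((0, -800.0), (1, 0.0), (2, 800.0)):
            assert np.array_equal(lm.labels == code, vals == hu)

    def test_seed_independence_on_separated_input(self, rng):
        vals = rng.choice([-800.0, 0.0, 800.0], size=(16, 16))
        a = kmeans_cluster(CTImage(vals), None, 3, seed=1)
        b = kmeans_cluster(CTImage(vals), None, 3, seed=12345)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_excluded_pixels_do_not_shift_centroids(self, rng):
        vals = rng.choice([-800.0, 0.0, 800.0], size=(16, 16))
        polluted = vals.copy()
        polluted[0, :] = 4000.0  # metal row
        exclude = polluted >= 2000.0
        lm = kmeans_cluster(CTImage(polluted), exclude, 3)
        assert np.all(lm.labels[0, :] == METAL_LABEL)
        inner = kmeans_cluster(CTImage(vals), None, 3)
        np.testing.assert_array_equal(lm.labels[1:], inner.labels[1:])

    def test_thorax_populations_match_hu_rank(self, clean_phantom):
        """Modal label per tissue agrees with an exhaustive 1-D oracle crop."""
        # region spanning lung, heart, soft tissue and spine
        crop = CTImage(clean_phantom.pixels[168:220, 100:152])
        air = crop.pixels <= -950.0
        lm = kmeans_cluster(crop, air, 3)
        oracle = _best_1d_kmeans(crop.pixels[~air], 3)
        for pop_hu, rank in ((-800.0, 0), (40.0, 1), (50.0, 1), (700.0, 2)):
            members = crop.pixels == pop_hu
            if members.any():
                labels = lm.labels[members]
                assert np.bincount(labels, minlength=3).argmax() == rank
                # oracle assignment agrees: nearest oracle centroid has same rank
                assert np.abs(oracle - pop_hu).argmin() == rank

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            kmeans_cluster(CTImage(np.full((4, 4), 40.0)), None, 3)


def _best_1d_kmeans(values: np.ndarray, k: int) -> np.ndarray:
    """Exhaustive oracle: Lloyd's from every sorted-quantile triple init,
    keeping the lowest-inertia solution. Independent of the package path."""
    vals = np.sort(values.ravel())
    qs = np.linspace(0.05, 0.95, 6)
    best, best_inertia = None, np.inf
    from itertools import combinations

    for combo in combinations(qs, k):
        cent = np.quantile(vals, combo)
        if np.unique(cent).size < k:
            continue
        for _ in range(200):
            d = np.abs(vals[:, None] - cent[None, :])
            lab = d.argmin(axis=1)
            new = np.array([vals[lab == j].mean() if (lab == j).any() else cent[j] for j in range(k)])
            if np.allclose(new, cent, atol=1e-9):
                break
            cent = new
        inertia = ((vals - cent[lab]) ** 2).sum()
        if inertia < best_inertia:
            best, best_inertia = np.sort(cent), inertia
    return best


def _majority_oracle(labels: np.ndarray, k: int, size: int) -> np.ndarray:
    """Per-pixel loop implementing the majority-vote contract directly."""
    codes = list(range(k)) + [AIR_LABEL, METAL_LABEL]
    h = size // 2
    n, m = labels.shape
    out = labels.copy()
    for i in range(n):
        for j in range(m):
            if labels[i, j] < 0:
                continue
            win = labels[max(0, i - h) : i + h + 1, max(0, j - h) : j + h + 1]
            counts = {c: int((win == c).sum()) for c in codes}
            best = max(counts.values())
            if counts[labels[i, j]] == best:
                continue
            out[i, j] = next(c for c in codes if counts[c] == best)
    return out


class TestSpatialRelationships:
    def test_isolated_pixel_flips_to_surrounding_label(self):
        lab = np.ones((3, 3), dtype=int)
        lab[1, 1] = 2
        out = apply_spatial_relationships(LabelMap(lab, 3))
        assert out.labels[1, 1] == 1

    def test_uniform_field_is_fixed_point(self):
        lab = np.full((6, 6), 2, dtype=int)
        out = apply_spatial_relationships(LabelMap(lab, 3))
        np.testing.assert_array_equal(out.labels, lab)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_oracle_on_random_maps(self, seed):
        rng = np.random.default_rng(seed)
        lab = rng.choice([0, 1, 2, AIR_LABEL, METAL_LABEL], size=(16, 16), p=[0.3, 0.3, 0.2, 0.1, 0.1])
        out = apply_spatial_relationships(LabelMap(lab, 3))
        np.testing.assert_array_equal(out.labels, _majority_oracle(lab, 3, 3))

    def test_reserved_codes_never_reassigned(self, rng):
        lab = rng.choice([0, AIR_LABEL, METAL_LABEL], size=(8, 8))
        out = apply_spatial_relationships(LabelMap(lab, 2))
        np.testing.assert_array_equal(out.labels[lab < 0], lab[lab < 0])

    def test_never_introduces_absent_label(self, rng):
        lab = rng.choice([0, 2], size=(10, 10))
        out = apply_spatial_relationships(LabelMap(lab, 3))
        assert 1 not in out.labels

    def test_isolated_singletons_do_not_increase(self, rng):
        def singletons(lab):
            count = 0
            for i in range(1, lab.shape[0] - 1):
                for j in range(1, lab.shape[1] - 1):
                    win = lab[i - 1 : i + 2, j - 1 : j + 2]
                    if (win == lab[i, j]).sum() == 1:
                        count += 1
            return count

        lab = rng.choice([0, 1, 2], size=(12, 12))
        out = apply_spatial_relationships(LabelMap(lab, 3))
        assert singletons(out.labels) <= singletons(lab)

    def test_mask_size_validation(self):
        with pytest.raises(ValueError):
            NeighborhoodSpec(4)


class TestClusteredImage:
    def test_priors_paint_piecewise_constant(self):
        lab = LabelMap(np.array([[0, 1], [2, AIR_LABEL]]), 3)
        priors = ClusterPriors({0: -800.0, 1: 0.0, 2: 700.0, AIR_LABEL: -1000.0, METAL_LABEL: 700.0})
        img = build_clustered_image(lab, priors)
        np.testing.assert_array_equal(img.pixels, [[-800.0, 0.0], [700.0, -1000.0]])

    def test_all_air_labels_give_uniform_air(self):
        lab = LabelMap(np.full((4, 4), AIR_LABEL), 3)
        priors = ClusterPriors({AIR_LABEL: -1000.0})
        np.testing.assert_array_equal(build_clustered_image(lab, priors).pixels, -1000.0)

    def test_missing_prior_raises(self):
        lab = LabelMap(np.zeros((2, 2), dtype=int), 2)
        with pytest.raises(KeyError):
            build_clustered_image(lab, ClusterPriors({1: 0.0}))

    def test_idempotent_on_already_clustered_image(self, rng):
        vals = rng.choice([-800.0, 0.0, 700.0], size=(12, 12))
        img = CTImage(vals)
        lm = kmeans_cluster(img, None, 3)
        priors = ClusterPriors.from_image(img, lm)
        np.testing.assert_allclose(build_clustered_image(lm, priors).pixels, vals)

    def test_output_value_count_bounded(self, clean_phantom):
        air = clean_phantom.pixels <= -950.0
        lm = kmeans_cluster(clean_phantom, air, 3)
        lm.labels[air] = AIR_LABEL
        priors = ClusterPriors.from_image(clean_phantom, lm)
        img = build_clustered_image(lm, priors)
        assert np.unique(img.pixels).size <= 3 + 2


class TestCombineClustered:
    def test_identity_when_equal(self, rng):
        x = CTImage(rng.uniform(-1000, 1000, (8, 8)))
        np.testing.assert_array_equal(combine_clustered(x, x).pixels, x.pixels)

    def test_absdiff_rule_lifts_dark_mislabels(self):
        initial = CTImage(np.array([[-800.0, 0.0]]))
        spatial = CTImage(np.array([[0.0, -800.0]]))
        out = combine_clustered(initial, spatial)
        # -800 + |0-(-800)| = 0, but 0 + |-800-0| = 800: the rule is asymmetric
        np.testing.assert_array_equal(out.pixels, [[0.0, 800.0]])

    def test_replace_rule(self):
        initial = CTImage(np.array([[-800.0, 0.0]]))
        spatial = CTImage(np.array([[0.0, 0.0]]))
        out = combine_clustered(initial, spatial, "replace-where-different")
        np.testing.assert_array_equal(out.pixels, [[0.0, 0.0]])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            combine_clustered(CTImage(np.zeros((2, 2))), CTImage(np.zeros((3, 3))))
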