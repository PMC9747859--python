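"""Tissue clustering for the prior ("clustered") scans.

The normalized-inpainting core needs a piecewise-constant prior image
whose sinogram approximates the uncorrupted anatomy. For a thorax slice
this is built by

1. threshold segmentation of metal (≥ 2000 HU by default) and air
   (≤ −950 HU),
2. k-means clustering of the remaining pixels into k = 3 tissue classes
   (lung / soft tissue / bone) on the 1-D HU axis,
3. optionally, a single spatial-relationship pass that reassigns each
   pixel to the cluster holding the majority of a 3×3 neighbourhood —
   this repairs isolated mislabels caused by residual streaks,
4. stamping the air segmentation back in and painting each class with a
   representative HU value (the per-image cluster mean; air −1000 HU;
   metal pixels take the top cluster's value so the prior stays smooth
   where the sinogram will be inpainted).

Label codes: tissue clusters are ``0..k−1`` ordered by increasing
centroid HU; ``AIR_LABEL`` and ``METAL_LABEL`` are reserved negatives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from sklearn.cluster import KMeans

from .imaging_io import AIR_HU, CTImage

__all__ = [
    "AIR_LABEL",
    "METAL_LABEL",
    "LabelMap",
    "NeighborhoodSpec",
    "ClusterPriors",
    "segment_threshold",
    "kmeans_cluster",
    "apply_spatial_relationships",
    "build_clustered_image",
    "combine_clustered",
]

AIR_LABEL = -1
METAL_LABEL = -2


@dataclass
class LabelMap:
    """Per-pixel cluster assignment: tissue codes 0..k−1 plus reserved codes."""

    labels: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        valid = ((self.labels >= 0) & (self.labels < self.k)) | (self.labels == AIR_LABEL) | (self.labels == METAL_LABEL)
        if not valid.all():
            bad = np.unique(self.labels[~valid])
            raise ValueError(f"label codes {bad} outside 0..{self.k - 1} plus reserved codes")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def copy(self) -> "LabelMap":
        return LabelMap(self.labels.copy(), self.k)


@dataclass(frozen=True)
class NeighborhoodSpec:
    """Square window for the spatial-relationship pass (odd side, default 3)."""

    mask_size: int = 3

    def __post_init__(self) -> None:
        if self.mask_size < 3 or self.mask_size % 2 == 0:
            raise ValueError("mask_size must be odd and >= 3")


class ClusterPriors(dict):
    """Mapping label code → representative HU value for the prior image."""

    @classmethod
    def from_image(cls, image: CTImage, labels: LabelMap) -> "ClusterPriors":
        """Per-image cluster means; air −1000 HU; metal → top cluster mean."""
        priors = cls()
        top = AIR_HU
        for j in range(labels.k):
            members = image.pixels[labels.labels == j]
            priors[j] = float(members.mean()) if members.size else AIR_HU
            top = priors[j]
        priors[AIR_LABEL] = AIR_HU
        priors[METAL_LABEL] = top
        return priors


def segment_threshold(image: CTImage, threshold: float, direction: str = "ge") -> np.ndarray:
    """Boolean mask where ``pixel >= threshold`` (``ge``) or ``<=`` (``le``)."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if direction == "ge":
        return image.pixels >= threshold
    if direction == "le":
        return image.pixels <= threshold
    raise ValueError(f"direction must be 'ge' or 'le', got {direction!r}")


#: Canonical thorax tissue HU values anchoring the k = 3 initialisation.
TISSUE_ANCHORS_HU = (-800.0, 40.0, 700.0)  # lung, soft tissue, bone


def _initial_centroids(values: np.ndarray, k: int) -> np.ndarray:
    """Deterministic centroid initialisation.

    For the thorax default k = 3, centroids start at canonical lung /
    soft-tissue / bone HU values (clipped to the observed range), which
    pins Lloyd's algorithm to the tissue-aligned optimum even when
    streak pixels form a broad mode between lung and soft tissue. Other
    k fall back to evenly spread quantiles; either way the result is
    seed-independent.
    """
    if k == len(TISSUE_ANCHORS_HU):
        centers = np.clip(TISSUE_ANCHORS_HU, values.min(), values.max())
        if np.unique(centers).size == k:
            return np.asarray(centers, dtype=np.float64)
    qs = (2 * np.arange(k) + 1) / (2 * k)
    centers = np.quantile(values, qs)
    if np.unique(centers).size < k:
        centers = np.linspace(values.min(), values.max(), k)
    return centers


def kmeans_cluster(image: CTImage, exclude: np.ndarray | None, k: int = 3, seed: int = 0) -> LabelMap:
    """1-D k-means over HU values of the non-excluded pixels.

    Centroids are fitted by Lloyd's algorithm from the deterministic
    initialisation of :func:`_initial_centroids`, so the result does not
    depend on ``seed`` in practice (the seed still feeds scikit-learn
    for reproducibility of any internal fallback). Labels are renumbered
    so centroid HU increases with label index; excluded pixels get
    ``METAL_LABEL`` / ``AIR_LABEL`` according to the masks stamped by
    the caller — here every excluded pixel is marked ``METAL_LABEL`` and
    the caller overwrites air afterwards.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if exclude is None:
        exclude = np.zeros(image.shape, dtype=bool)
    included = image.pixels[~exclude]
    if np.unique(included).size < k:
        raise ValueError(f"degenerate input: fewer than k={k} distinct HU values among included pixels")
    init = _initial_centroids(included, k).reshape(-1, 1)
    km = KMeans(n_clusters=k, init=init, n_init=1, random_state=seed)
    fitted = km.fit_predict(included.reshape(-1, 1))
    order = np.argsort(km.cluster_centers_.ravel())
    relabel = np.empty(k, dtype=np.int64)
    relabel[order] = np.arange(k)
    labels = np.full(image.shape, METAL_LABEL, dtype=np.int64)
    labels[~exclude] = relabel[fitted]
    return LabelMap(labels, k)


def fit_cluster_centroids(image: CTImage, labels: LabelMap) -> np.ndarray:
    """Mean HU per tissue cluster, in label order."""
    return np.array([image.pixels[labels.labels == j].mean() if (labels.labels == j).any() else AIR_HU for j in range(labels.k)])


def _category_codes(k: int) -> list[int]:
    # tie-break order: tissue clusters by ascending index, then air, then metal
    return list(range(k)) + [AIR_LABEL, METAL_LABEL]


def apply_spatial_relationships(labels: LabelMap, spec: NeighborhoodSpec = NeighborhoodSpec()) -> LabelMap:
    """One synchronous majority-vote pass over a square neighbourhood.

    Every tissue pixel is reassigned to the category with the most
    members in the ``mask_size``×``mask_size`` window centred on it,
    counted on the *input* map. Air and metal pixels keep their codes but
    participate in the counts as their own categories. Ties keep the
    pixel's current label when it is among the maximizers, otherwise the
    first category in tie-break order (tissue 0..k−1, air, metal) wins.
    Windows are clipped at the image border (no padding).
    """
    lab = labels.labels
    codes = _category_codes(labels.k)
    size = spec.mask_size
    counts = np.empty((len(codes),) + lab.shape, dtype=np.int64)
    for idx, code in enumerate(codes):
        counts[idx] = ndi.uniform_filter((lab == code).astype(np.float64), size=size, mode="constant", cval=0.0) * size**2 + 0.5
    best = counts.max(axis=0)
    winner = np.argmax(counts, axis=0)  # first maximizer in tie-break order
    new = np.array(codes, dtype=np.int64)[winner]
    # a pixel whose current category ties the maximum keeps its label
    cur_idx = np.empty_like(lab)
    for idx, code in enumerate(codes):
        cur_idx[lab == code] = idx
    keeps = np.take_along_axis(counts, cur_idx[None], axis=0)[0] == best
    new = np.where(keeps, lab, new)
    tissue = lab >= 0
    out = np.where(tissue, new, lab)
    return LabelMap(out, labels.k)


def build_clustered_image(labels: LabelMap, priors: ClusterPriors, spacing: tuple[float, float] = (1.0, 1.0)) -> CTImage:
    """Paint each label with its representative HU value."""
    out = np.empty(labels.shape, dtype=np.float64)
    for code in np.unique(labels.labels):
        if int(code) not in priors:
            raise KeyError(f"no prior HU value configured for label code {code}")
        out[labels.labels == code] = priors[int(code)]
    return CTImage(out, spacing)


def combine_clustered(initial: CTImage, spatial: CTImage, rule: str = "add-absdiff") -> CTImage:
    """Merge the plain and spatial-relationship clustered scans.

    ``add-absdiff`` follows the literal combination rule
    ``initial + |spatial − initial|``: wherever the two clusterings
    disagree, the combined scan moves *up* from the initial value by the
    disagreement magnitude, which lifts dark streaks mislabelled as lung
    back toward soft tissue. ``replace-where-different`` instead takes
    the spatial scan's value at disagreeing pixels.
    """
    if initial.shape != spatial.shape:
        raise ValueError(f"shape mismatch: {initial.shape} vs {spatial.shape}")
    if rule == "add-absdiff":
        combined = initial.pixels + np.abs(spatial.pixels - initial.pixels)
    elif rule == "replace-where-different":
        combined = np.where(spatial.pixels != initial.pixels, spatial.pixels, initial.pixels)
    else:
        raise ValueError(f"unknown combine rule {rule!r}")
    return CTImage(combined, initial.spacing)
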