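"""Micrograph quantification: background removal, segmentation, counting.

The pipeline mirrors standard high-content practice for punctate
reporters: each channel is background-subtracted with a white top-hat
transform (removing the camera offset and the diffuse cytosolic Gal8
signal), binarized by a per-image Otsu threshold (or a fixed value),
split with a marker-based watershed so touching objects — e.g. two
side-by-side nuclei — count separately, size-filtered, and counted.
Counts from the punctate channels are normalized per cell by dividing by
the nucleus count of the same image, and the three images of a
biological replicate (one image per well, ~100 cells each) are averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import disk, white_tophat
from skimage.segmentation import watershed

from .synthetic import (
    CHANNEL_DID,
    CHANNEL_GAL8,
    CHANNEL_NBDPE,
    CHANNEL_NUCLEI,
)


@dataclass
class Treatment:
    compound: str = ""
    concentration_um: float = 0.0
    blocker: bool = False


@dataclass
class Micrograph:
    """One multi-channel 2D image with acquisition metadata."""

    channels: dict[str, np.ndarray]
    pixel_size: float = 1.0          # um per px
    well_id: str = ""
    treatment: Treatment = field(default_factory=Treatment)

    def __post_init__(self) -> None:
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channel rasters differ in shape: {shapes}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")


@dataclass
class ChannelConfig:
    """Per-channel segmentation parameters."""

    tophat_radius: int = 5
    threshold_method: str = "robust"  # "robust" | "otsu" | "fixed"
    threshold_value: float = 0.0      # used when threshold_method == "fixed"
    robust_k: float = 5.0             # noise-floor width, in robust SDs
    min_area: int = 3                # px^2
    max_area: float = np.inf         # px^2
    watershed_enabled: bool = True
    watershed_min_seed_separation: int = 5

    def __post_init__(self) -> None:
        if self.tophat_radius < 1:
            raise ValueError("tophat_radius must be >= 1")
        if self.min_area < 1:
            raise ValueError("min_area must be >= 1")
        if self.min_area >= self.max_area:
            raise ValueError("min_area must be < max_area")
        if self.threshold_method not in ("robust", "otsu", "fixed"):
            raise ValueError(
                "threshold_method must be 'robust', 'otsu' or 'fixed'"
            )


def default_quant_config() -> dict[str, ChannelConfig]:
    """Per-channel defaults for the simulated image scale.

    Top-hat radii are ~2x the expected object radius (nuclei ~12 px,
    diffraction-limited spots ~3 px); nuclei use a larger minimum area
    and a wider watershed seed separation matched to their size.
    """
    return {
        CHANNEL_NUCLEI: ChannelConfig(
            tophat_radius=15, min_area=50,
            watershed_min_seed_separation=10,
        ),
        CHANNEL_GAL8: ChannelConfig(tophat_radius=5),
        CHANNEL_DID: ChannelConfig(tophat_radius=5),
        CHANNEL_NBDPE: ChannelConfig(tophat_radius=5),
    }


@dataclass
class ImageCounts:
    """Object counts and per-cell ratios for one image.

    Ratios are ratios of image totals — (channel count)/(nuclei count) —
    matching quantification of stitched images of ~100 cells; they are
    ``nan`` (and ``ratios_defined`` False) when no nuclei were found.
    """

    nuclei: int
    foci: int
    puncta: int
    vesicles: int
    foci_per_cell: float
    puncta_per_cell: float
    vesicles_per_cell: float
    ratios_defined: bool


@dataclass
class ReplicateRecord:
    """Counts for the images of one biological replicate (nominally 3)."""

    well_id: str
    treatment: Treatment
    images: list[ImageCounts]
    foci_per_cell: float
    puncta_per_cell: float
    vesicles_per_cell: float


def tophat_filter(raster: np.ndarray, radius: int) -> np.ndarray:
    """White top-hat: the raster minus its morphological opening with a
    disk structuring element.

    Removes any background varying on scales wider than ~2x the radius
    (including a constant offset) while preserving compact bright
    features; the output is non-negative everywhere.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if radius >= min(raster.shape) / 2:
        raise ValueError(
            f"tophat radius {radius} too large for image {raster.shape}"
        )
    return white_tophat(np.asarray(raster, dtype=np.float64),
                        footprint=disk(radius))


def _binarize(raster: np.ndarray, config: ChannelConfig) -> np.ndarray:
    """Threshold a top-hat-filtered raster.

    The default ``robust`` method thresholds at
    ``median + robust_k * 1.4826 * MAD``, a noise floor that adapts to
    the image's own noise scale.  Otsu's method is available but splits
    the background noise rather than noise/foreground when bright
    objects cover a very small pixel fraction, as for sparse
    diffraction-limited puncta; the robust floor handles both sparse and
    dense channels.
    """
    if config.threshold_method == "fixed":
        return raster > config.threshold_value
    if np.ptp(raster) == 0:
        return np.zeros(raster.shape, dtype=bool)
    if config.threshold_method == "otsu":
        return raster > threshold_otsu(raster)
    med = np.median(raster)
    sigma = 1.4826 * np.median(np.abs(raster - med))
    return raster > med + config.robust_k * sigma


def segment(raster: np.ndarray, config: ChannelConfig) -> np.ndarray:
    """Binarize, watershed-split, and size-filter one filtered channel.

    Returns an integer label image (0 = background).  Watershed markers
    are local maxima of the Euclidean distance transform separated by at
    least ``watershed_min_seed_separation`` px; ties are broken by
    lexicographic pixel order, so the result is deterministic.
    """
    binary = _binarize(np.asarray(raster, dtype=np.float64), config)
    if not binary.any():
        return np.zeros(raster.shape, dtype=np.int32)

    if config.watershed_enabled:
        distance = ndi.distance_transform_edt(binary)
        coords = peak_local_max(
            distance,
            min_distance=config.watershed_min_seed_separation,
            labels=binary,
            exclude_border=False,
        )
        markers = np.zeros(binary.shape, dtype=np.int32)
        markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
        labels = watershed(-distance, markers, mask=binary)
    else:
        labels = cc_label(binary, connectivity=2)

    areas = np.bincount(labels.ravel())
    keep = np.flatnonzero(
        (areas >= config.min_area) & (areas <= config.max_area)
    )
    keep = keep[keep > 0]
    remap = np.zeros(areas.size, dtype=np.int32)
    remap[keep] = np.arange(1, keep.size + 1)
    return remap[labels]


def count_objects(labels: np.ndarray) -> int:
    """Number of distinct nonzero labels in a label image."""
    return int(len(np.unique(labels[labels > 0])))


def quantify_channel(raster: np.ndarray, config: ChannelConfig) -> int:
    return count_objects(segment(tophat_filter(raster, config.tophat_radius),
                                 config))


def quantify_image(
    m: Micrograph, config: dict[str, ChannelConfig] | None = None
) -> ImageCounts:
    """Count nuclei, Gal8 foci, DiD puncta, and phospholipidosis vesicles
    in one micrograph and form per-cell ratios.

    Channels absent from the micrograph count as 0.  If no nuclei are
    found the raw counts are still reported but the ratios are ``nan``.
    """
    config = config if config is not None else default_quant_config()
    counts = {}
    for role, attr in (
        (CHANNEL_NUCLEI, "nuclei"),
        (CHANNEL_GAL8, "foci"),
        (CHANNEL_DID, "puncta"),
        (CHANNEL_NBDPE, "vesicles"),
    ):
        if role in m.channels:
            counts[attr] = quantify_channel(m.channels[role], config[role])
        else:
            counts[attr] = 0
    n = counts["nuclei"]
    defined = n > 0
    ratio = (lambda c: c / n) if defined else (lambda c: float("nan"))
    return ImageCounts(
        **counts,
        foci_per_cell=ratio(counts["foci"]),
        puncta_per_cell=ratio(counts["puncta"]),
        vesicles_per_cell=ratio(counts["vesicles"]),
        ratios_defined=defined,
    )


def aggregate_replicate(
    images: list[ImageCounts],
    well_id: str = "",
    treatment: Treatment | None = None,
) -> ReplicateRecord:
    """Average per-cell ratios across the images of one replicate."""
    if not images:
        raise ValueError("aggregate_replicate requires at least one image")
    mean = lambda attr: float(
        np.mean([getattr(im, attr) for im in images])
    )
    return ReplicateRecord(
        well_id=well_id,
        treatment=treatment if treatment is not None else Treatment(),
        images=list(images),
        foci_per_cell=mean("foci_per_cell"),
        puncta_per_cell=mean("puncta_per_cell"),
        vesicles_per_cell=mean("vesicles_per_cell"),
    )


def colocalization_count(labels_a: np.ndarray, labels_b: np.ndarray) -> int:
    """Number of object pairs whose centroids fall inside each other's
    mask — a simple mutual-overlap measure of, e.g., Gal8 foci forming on
    colloid-containing (DiD-positive) vesicles.  Reported for inspection
    only; nothing downstream consumes it.
    """
    if labels_a.shape != labels_b.shape:
        raise ValueError("label images must share a shape")
    pairs = 0
    for la in np.unique(labels_a[labels_a > 0]):
        rr, cc = np.nonzero(labels_a == la)
        cr, ccol = int(round(rr.mean())), int(round(cc.mean()))
        lb = labels_b[cr, ccol]
        if lb > 0:
            rr2, cc2 = np.nonzero(labels_b == lb)
            cr2, ccol2 = int(round(rr2.mean())), int(round(cc2.mean()))
            if labels_a[cr2, ccol2] == la:
                pairs += 1
    return pairs
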