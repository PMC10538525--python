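"""Segmentation and background cleaning of pouch images.

Pipeline: LAB lightness thresholding -> connected-component labeling ->
area / center-distance filtering -> mask application. Small bright
particles (root debris, dust) become isolated components and are rejected
by the area filter; off-center objects such as rulers are rejected by the
center-distance filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.color import rgb2lab
from skimage.filters import threshold_otsu

from .records import PouchImage

__all__ = [
    "CleaningConfig",
    "BinaryMask",
    "ComponentRecord",
    "LabeledComponents",
    "segment_foreground",
    "label_components",
    "filter_components",
    "clean_image",
]


@dataclass
class CleaningConfig:
    """Free parameters of the cleaning pipeline.

    ``threshold`` is either an integer in [0, 255] applied to the
    percentile-stretched lightness channel, or the string ``"otsu"``.
    ``min_area_px`` defaults to 200 px, i.e. 0.02 mm^2-equivalent at
    100 px/cm. ``max_center_dist_frac`` is a fraction of the image
    half-diagonal.
    """

    stretch_percentiles: tuple = (1.0, 99.0)
    threshold: object = "otsu"
    connectivity: int = 8
    min_area_px: int = 200
    max_center_dist_frac: float = 0.95
    keep_largest_always: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.stretch_percentiles
        if not lo < hi:
            raise ValueError("stretch percentiles must satisfy low < high")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.min_area_px < 1:
            raise ValueError("min_area_px must be >= 1")
        if not 0.0 < self.max_center_dist_frac <= 1.0:
            raise ValueError("max_center_dist_frac must be in (0, 1]")
        if not (self.threshold == "otsu"
                or (isinstance(self.threshold, (int, float))
                    and 0 <= self.threshold <= 255)):
            raise ValueError("threshold must be 'otsu' or a number in [0, 255]")


@dataclass
class BinaryMask:
    """A boolean foreground mask with a provenance tag."""

    mask: np.ndarray
    provenance: str = "raw-threshold"  # "raw-threshold" | "cleaned"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def shape(self) -> tuple:
        return self.mask.shape


@dataclass
class ComponentRecord:
    label: int
    area_px: int
    centroid: tuple  # (row, col)


@dataclass
class LabeledComponents:
    labels: np.ndarray  # H x W int, 0 = background
    components: list = field(default_factory=list)


def _stretched_lightness(image: PouchImage, config: CleaningConfig) -> np.ndarray:
    """L channel of LAB (sRGB/D65), rescaled to 0-255 and percentile-stretched."""
    lab = rgb2lab(image.pixels.astype(np.float64) / 255.0)
    L = lab[..., 0] * (255.0 / 100.0)
    lo, hi = np.percentile(L, config.stretch_percentiles)
    if hi <= lo:
        # degenerate (near-constant) image: stretching undefined, pass through
        return L
    return np.clip((L - lo) / (hi - lo) * 255.0, 0.0, 255.0)


def segment_foreground(image: PouchImage, config: CleaningConfig | None = None) -> BinaryMask:
    """Global threshold on the stretched LAB lightness channel.

    With ``threshold="otsu"`` the cut is chosen by Otsu's method; a
    zero-variance image falls back to the fixed midpoint 127.5 with a
    warning.
    """
    config = config or CleaningConfig()
    L = _stretched_lightness(image, config)
    if config.threshold == "otsu":
        if np.ptp(L) == 0:
            warnings.warn("zero-variance image: Otsu undefined, using midpoint 127.5")
            thr = 127.5
        else:
            thr = threshold_otsu(L)
    else:
        thr = float(config.threshold)
    return BinaryMask(L > thr, provenance="raw-threshold")


_STRUCTS = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool),
    8: np.ones((3, 3), bool),
}


def label_components(mask: BinaryMask | np.ndarray, connectivity: int = 8) -> LabeledComponents:
    """Label maximal connected regions; record per-component area and centroid."""
    m = mask.mask if isinstance(mask, BinaryMask) else np.asarray(mask, bool)
    labels, n = ndimage.label(m, structure=_STRUCTS[connectivity])
    comps = []
    if n:
        idx = np.arange(1, n + 1)
        areas = ndimage.sum_labels(m, labels, idx).astype(int)
        cents = ndimage.center_of_mass(m, labels, idx)
        comps = [ComponentRecord(int(i), int(a), (float(r), float(c)))
                 for i, a, (r, c) in zip(idx, areas, cents)]
    return LabeledComponents(labels=labels, components=comps)


def filter_components(
    components: LabeledComponents,
    image_shape: tuple,
    config: CleaningConfig | None = None,
) -> BinaryMask:
    """Keep components that are large enough and close enough to the image center.

    A component survives iff area >= ``min_area_px`` and its centroid lies
    within ``max_center_dist_frac`` of the half-diagonal from the image
    center. The largest component is always kept when
    ``keep_largest_always`` is set, so the root system cannot reject itself.
    """
    config = config or CleaningConfig()
    h, w = image_shape[:2]
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    half_diag = float(np.hypot(h / 2.0, w / 2.0))
    keep = []
    largest = max(components.components, key=lambda c: c.area_px, default=None)
    for comp in components.components:
        dist = float(np.hypot(*(np.array(comp.centroid) - center)))
        ok = (comp.area_px >= config.min_area_px
              and dist <= config.max_center_dist_frac * half_diag)
        if ok or (config.keep_largest_always and comp is largest):
            keep.append(comp.label)
    if components.components and not keep:
        warnings.warn("all components rejected: cleaned mask is empty "
                      "(threshold or filters likely mis-set)")
    out = np.isin(components.labels, keep) if keep else np.zeros((h, w), bool)
    return BinaryMask(out, provenance="cleaned")


def clean_image(
    image: PouchImage, config: CleaningConfig | None = None
) -> tuple[PouchImage, BinaryMask]:
    """Full cleaning pipeline; the final mask is multiplied into the image."""
    config = config or CleaningConfig()
    raw = segment_foreground(image, config)
    comps = label_components(raw, config.connectivity)
    cleaned_mask = filter_components(comps, image.shape, config)
    px = image.pixels.copy()
    px[~cleaned_mask.mask] = 0
    cleaned = PouchImage(px, image.pixels_per_cm, id=image.id,
                         metadata={**image.metadata, "stage": "cleaned"})
    return cleaned, cleaned_mask
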