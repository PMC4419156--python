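"""Synthetic landscapes, assessment sites and confusion matrices.

The real study input — a 30-m land-cover clip of a river floodplain with
digitised assessment sites and an agency accuracy assessment — is emulated
here so that every downstream stage can be exercised and tested without
external data.

Landscapes are built by thresholding smoothed Gaussian white noise: blurring
with a kernel of width ``patch_scale`` induces spatial autocorrelation, and
mapping noise quantiles to classes at the requested proportions yields
spatially contiguous patches whose realised class shares are close to the
request.  Sites pair a floodplain mask (a rectangle or a sinuous band, a
schematic river corridor) with a surrounding buffer obtained by Chebyshev
dilation.  Confusion matrices are drawn row-wise from a multinomial with a
specified diagonal mass, giving the diagonally dominant structure typical of
accuracy assessments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .metrics import AssessmentSite
from .raster import CategoricalRaster
from .schemes import ConfusionMatrix

__all__ = [
    "SyntheticLandscapeConfig",
    "SyntheticConfusionConfig",
    "generate_landscape",
    "generate_site",
    "generate_confusion",
]


@dataclass(frozen=True)
class SyntheticLandscapeConfig:
    """Parameters of a synthetic categorical landscape.

    ``class_labels`` are the integer codes written into the raster, in the
    order matched to ``class_proportions``.  ``patch_scale`` is the Gaussian
    blur sigma in pixels: 0 gives spatially independent pixels, larger
    values larger contiguous patches.
    """

    grid_rows: int = 128
    grid_cols: int = 128
    class_labels: tuple[int, ...] = (0, 1, 2, 3, 4)
    class_proportions: tuple[float, ...] = (0.55, 0.20, 0.10, 0.10, 0.05)
    patch_scale: float = 6.0
    buffer_width: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows < 8 or self.grid_cols < 8:
            raise ValueError("grid dimensions must be >= 8")
        if len(self.class_labels) != len(self.class_proportions):
            raise ValueError("labels and proportions differ in length")
        props = np.asarray(self.class_proportions, dtype=float)
        if np.any(props < 0):
            raise ValueError("class proportions must be nonnegative")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError(f"class proportions must sum to 1, got {props.sum()}")
        if self.patch_scale < 0:
            raise ValueError("patch_scale must be >= 0")
        if self.buffer_width < 0:
            raise ValueError("buffer_width must be >= 0")


@dataclass(frozen=True)
class SyntheticConfusionConfig:
    """Parameters of a synthetic accuracy assessment."""

    n_classes: int = 5
    diagonal_mass: float = 0.9
    total_samples_per_class: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if not 0.0 < self.diagonal_mass <= 1.0:
            raise ValueError("diagonal_mass must lie in (0, 1]")
        if self.total_samples_per_class < 1:
            raise ValueError("total_samples_per_class must be positive")


def generate_landscape(config: SyntheticLandscapeConfig) -> CategoricalRaster:
    """Generate a patchy categorical raster.

    Deterministic for a fixed seed.  Realised proportions follow the
    requested ones exactly up to quantile ties (exactly at patch_scale 0 up
    to rounding; within a few percent for patch scales small relative to the
    grid).
    """
    rng = np.random.default_rng(config.seed)
    noise = rng.standard_normal((config.grid_rows, config.grid_cols))
    if config.patch_scale > 0:
        noise = ndimage.gaussian_filter(noise, sigma=config.patch_scale, mode="wrap")
    # Map noise quantiles to classes at the requested proportions: the
    # lowest p_0 fraction of values becomes class 0, and so on.
    order = np.argsort(noise, axis=None, kind="stable")
    n = order.size
    props = np.asarray(config.class_proportions, dtype=float)
    bounds = np.round(np.cumsum(props) * n).astype(int)
    flat = np.empty(n, dtype=np.int32)
    start = 0
    for label, stop in zip(config.class_labels, bounds):
        flat[order[start:stop]] = label
        start = stop
    if start < n:  # rounding slack goes to the last class
        flat[order[start:]] = config.class_labels[-1]
    return CategoricalRaster(flat.reshape(config.grid_rows, config.grid_cols))


def generate_site(
    raster_shape: tuple[int, int],
    floodplain_spec: dict,
    buffer_width: int,
    site_id: str = "site",
) -> AssessmentSite:
    """Build a floodplain mask and its surrounding buffer.

    ``floodplain_spec`` selects a geometry:

    * ``{"kind": "rectangle", "row0": .., "row1": .., "col0": .., "col1": ..}``
      — half-open pixel ranges;
    * ``{"kind": "band", "center_row": .., "amplitude": .., "period": ..,
      "width": ..}`` — a sinuous horizontal band, a schematic river corridor.

    The buffer is the Chebyshev dilation of the floodplain by
    ``buffer_width`` pixels minus the floodplain itself, so the two masks
    are disjoint by construction.
    """
    if buffer_width < 1:
        raise ValueError("buffer_width must be >= 1 (a zero-width buffer is empty)")
    rows, cols = raster_shape
    fp = np.zeros(raster_shape, dtype=bool)
    kind = floodplain_spec.get("kind", "rectangle")
    if kind == "rectangle":
        r0, r1 = int(floodplain_spec["row0"]), int(floodplain_spec["row1"])
        c0, c1 = int(floodplain_spec["col0"]), int(floodplain_spec["col1"])
        if not (0 <= r0 < r1 <= rows and 0 <= c0 < c1 <= cols):
            raise ValueError("rectangle does not lie within the grid")
        fp[r0:r1, c0:c1] = True
    elif kind == "band":
        center = float(floodplain_spec["center_row"])
        amplitude = float(floodplain_spec.get("amplitude", 0.0))
        period = float(floodplain_spec.get("period", cols))
        width = float(floodplain_spec["width"])
        cols_idx = np.arange(cols)
        center_rows = center + amplitude * np.sin(2.0 * np.pi * cols_idx / period)
        rows_idx = np.arange(rows)[:, None]
        fp = np.abs(rows_idx - center_rows[None, :]) <= width / 2.0
    else:
        raise ValueError(f"unknown floodplain geometry kind: {kind!r}")
    if not fp.any():
        raise ValueError("floodplain specification produced an empty mask")
    dilated = ndimage.binary_dilation(
        fp, structure=np.ones((3, 3), dtype=bool), iterations=buffer_width
    )
    buffer = dilated & ~fp
    if not buffer.any():
        raise ValueError("buffer mask is empty (floodplain fills the grid?)")
    return AssessmentSite(site_id=site_id, floodplain_mask=fp, buffer_mask=buffer)


def generate_confusion(config: SyntheticConfusionConfig) -> ConfusionMatrix:
    """Draw a diagonally dominant confusion matrix.

    Each mapped-class row is a multinomial sample of
    ``total_samples_per_class`` reference labels, with probability
    ``diagonal_mass`` on the correct class and the remainder spread evenly
    over the others.
    """
    rng = np.random.default_rng(config.seed)
    k = config.n_classes
    off = (1.0 - config.diagonal_mass) / (k - 1)
    counts = np.zeros((k, k), dtype=float)
    for i in range(k):
        p = np.full(k, off)
        p[i] = config.diagonal_mass
        counts[i] = rng.multinomial(config.total_samples_per_class, p)
    labels = tuple(f"class_{i}" for i in range(k))
    return ConfusionMatrix(counts=counts, labels=labels)
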