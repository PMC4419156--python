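"""Condition metrics and the multi-metric floodplain index.

Both the perturbation (land-use intensity) and fragmentation metrics are
area-weighted means of class sub-scores over an assessment mask:

.. math::

    Met = \\frac{\\sum_x C_{Lx} \\, w_{Lx}}{N}

with :math:`C_{Lx}` the pixel count of class :math:`x` inside the mask,
:math:`w_{Lx}` its weight in [0, 1], and :math:`N` the count of assessed
(non-nodata) pixels.  The four metrics — buffer/floodplain x
perturbation/fragmentation — combine into the condition index

.. math::

    Index = \\frac{(Met_{BP} + Met_{BF})/2 + Met_{FP} + Met_{FF}}{3}

where the buffer pair is averaged first because the buffer influences, but
does not constitute, the floodplain.  1.0 is an intact system, 0.0 a fully
disturbed one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mspa import STRUCTURAL_CLASS_NAMES
from .raster import CategoricalRaster

__all__ = [
    "AssessmentSite",
    "MetricSet",
    "weighted_cover_metric",
    "combine_index",
    "assess_site",
]


@dataclass(frozen=True)
class AssessmentSite:
    """A floodplain polygon and its surrounding buffer, rasterised as two
    disjoint boolean masks on the analysis grid."""

    site_id: str
    floodplain_mask: np.ndarray
    buffer_mask: np.ndarray

    def __post_init__(self) -> None:
        fp = np.asarray(self.floodplain_mask, dtype=bool)
        bf = np.asarray(self.buffer_mask, dtype=bool)
        if fp.shape != bf.shape:
            raise ValueError("floodplain and buffer masks must share a shape")
        if not fp.any():
            raise ValueError(f"site {self.site_id!r}: empty floodplain mask")
        if not bf.any():
            raise ValueError(f"site {self.site_id!r}: empty buffer mask")
        if (fp & bf).any():
            raise ValueError(f"site {self.site_id!r}: masks overlap")
        object.__setattr__(self, "floodplain_mask", fp)
        object.__setattr__(self, "buffer_mask", bf)


@dataclass(frozen=True)
class MetricSet:
    """The four metric scores and their combined index for one site."""

    site_id: str
    met_bp: float  # buffer perturbation
    met_fp: float  # floodplain perturbation
    met_bf: float  # buffer fragmentation
    met_ff: float  # floodplain fragmentation
    index: float

    def __post_init__(self) -> None:
        for name in ("met_bp", "met_fp", "met_bf", "met_ff", "index"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} outside [0, 1]: {v}")
        expected = combine_index(self.met_bp, self.met_bf, self.met_fp, self.met_ff)
        if abs(expected - self.index) > 1e-12:
            raise ValueError(
                f"index {self.index} inconsistent with metrics (expected {expected})"
            )


def weighted_cover_metric(
    raster: CategoricalRaster,
    mask: np.ndarray,
    weights: dict[int, float] | np.ndarray,
) -> float:
    """Area-weighted mean sub-score of the classes inside a mask.

    ``weights`` maps class code to weight; an array is read as weight per
    code index.  Nodata pixels are excluded from both the numerator and the
    assessed-area count N.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != raster.shape:
        raise ValueError("mask shape does not match raster")
    assessed = mask & raster.valid_mask
    n = int(assessed.sum())
    if n == 0:
        raise ValueError("mask covers no assessable (non-nodata) pixels")
    values = raster.data[assessed]
    if isinstance(weights, np.ndarray):
        weights = {i: float(w) for i, w in enumerate(weights)}
    codes, counts = np.unique(values, return_counts=True)
    total = 0.0
    for code, count in zip(codes, counts):
        try:
            w = weights[int(code)]
        except KeyError:
            raise KeyError(f"no weight for class code {int(code)}") from None
        total += count * w
    return total / n


def combine_index(met_bp: float, met_bf: float, met_fp: float, met_ff: float) -> float:
    """Combine the four metrics into the condition index.

    The two buffer metrics are averaged first, then averaged with the two
    floodplain metrics.
    """
    for name, v in (("met_bp", met_bp), ("met_bf", met_bf),
                    ("met_fp", met_fp), ("met_ff", met_ff)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} outside [0, 1]: {v}")
    return (((met_bp + met_bf) / 2.0) + met_fp + met_ff) / 3.0


def structural_weight_array(weights_by_name: dict[str, float]) -> dict[int, float]:
    """Translate structural-class-name weights to structural-code weights."""
    return {code: weights_by_name[name] for code, name in STRUCTURAL_CLASS_NAMES.items()}


def assess_site(
    perturbation_raster: CategoricalRaster,
    structural_raster: CategoricalRaster,
    site: AssessmentSite,
    landuse_weights: dict[int, float] | np.ndarray,
    structural_weights: dict[int, float] | np.ndarray,
) -> MetricSet:
    """Score one site: perturbation and fragmentation metrics over both
    masks, combined into the index.

    ``perturbation_raster`` carries land-use group codes, ``structural_raster``
    the structural-class codes; weights are per class code on the respective
    raster.
    """
    if perturbation_raster.shape != site.floodplain_mask.shape:
        raise ValueError("perturbation raster shape does not match site masks")
    if structural_raster.shape != site.floodplain_mask.shape:
        raise ValueError("structural raster shape does not match site masks")
    met_bp = weighted_cover_metric(perturbation_raster, site.buffer_mask, landuse_weights)
    met_fp = weighted_cover_metric(perturbation_raster, site.floodplain_mask, landuse_weights)
    met_bf = weighted_cover_metric(structural_raster, site.buffer_mask, structural_weights)
    met_ff = weighted_cover_metric(structural_raster, site.floodplain_mask, structural_weights)
    return MetricSet(
        site_id=site.site_id,
        met_bp=met_bp,
        met_fp=met_fp,
        met_bf=met_bf,
        met_ff=met_ff,
        index=combine_index(met_bp, met_bf, met_fp, met_ff),
    )
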