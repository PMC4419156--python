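"""Confusion-frequency simulation: stochastic map realizations from a UPM.

Each realization redraws every pixel's class from the user's-probability row
of its mapped class, independently per pixel, by inverse-CDF sampling of a
uniform(0, 1) draw over the row in the fixed class order.  Before sampling,
a spatial-autocorrelation filter nudges the retention probability (the
diagonal entry): interior pixels of a patch — those whose full 3x3
neighbourhood shares their class — keep their mapped class a little more
often, edge pixels a little less, reflecting that misclassification
concentrates at patch boundaries (mixed pixels, misregistration) rather
than as salt-and-pepper noise inside patches.

With a total gradient ``f`` (default 0.10), retention shifts by +f/2 on
interior pixels and -f/2 on edge pixels, a total interior-edge contrast of
``f``; off-diagonal mass is rescaled proportionally so each row remains a
distribution.  The interior/edge map is a property of the original patch
structure and is computed once on the input map, not per realization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import mspa as _mspa
from .metrics import AssessmentSite, MetricSet, assess_site
from .raster import CategoricalRaster
from .schemes import UserProbabilityMatrix
from .stats import ScoreDistribution, summarize

__all__ = [
    "AutocorrelationFilter",
    "RealizationRun",
    "interior_edge_map",
    "adjusted_row",
    "simulate_realization",
    "run_ensemble",
]

_ROW_TOL = 1e-9


@dataclass(frozen=True)
class AutocorrelationFilter:
    """Interior/edge adjustment of retention probabilities.

    ``total_gradient`` is the full interior-to-edge contrast f; each side
    moves by f/2.  ``mode`` selects how the shift is applied:

    * ``"additive"`` (default): retention gains/loses f/2 probability
      points;
    * ``"multiplicative"``: the misclassification mass is scaled by
      1 -/+ f/2 instead.
    """

    total_gradient: float = 0.10
    mode: str = "additive"

    def __post_init__(self) -> None:
        if not 0.0 <= self.total_gradient < 1.0:
            raise ValueError(f"total_gradient must lie in [0, 1), got {self.total_gradient}")
        if self.mode not in ("additive", "multiplicative"):
            raise ValueError(f"unknown filter mode: {self.mode!r}")

    @property
    def interior_shift(self) -> float:
        return self.total_gradient / 2.0

    @property
    def edge_shift(self) -> float:
        return -self.total_gradient / 2.0


@dataclass(frozen=True)
class RealizationRun:
    """Ensemble configuration: size, seed and filter."""

    n_realizations: int = 1000
    master_seed: int = 0
    filter: AutocorrelationFilter = field(default_factory=AutocorrelationFilter)

    def __post_init__(self) -> None:
        if self.n_realizations < 1:
            raise ValueError("n_realizations must be >= 1")

    def substream(self, realization_index: int, map_kind: int) -> np.random.Generator:
        """Independent, reproducible PRNG stream for one realization of one
        map kind (0 = perturbation, 1 = fragmentation)."""
        seq = np.random.SeedSequence(
            entropy=self.master_seed, spawn_key=(realization_index, map_kind)
        )
        return np.random.default_rng(seq)


def interior_edge_map(raster: CategoricalRaster) -> np.ndarray:
    """Boolean grid, True where the 3x3 window is single-class (interior).

    Off-grid neighbours are treated as sharing the pixel's class, so the map
    border does not count as patch edge by itself.
    """
    data = raster.data
    padded = np.pad(data, 1, mode="edge")
    interior = np.ones(data.shape, dtype=bool)
    rows, cols = data.shape
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            shifted = padded[1 + dr: 1 + dr + rows, 1 + dc: 1 + dc + cols]
            interior &= shifted == data
    return interior


def adjusted_row(
    upm_row: np.ndarray,
    mapped_class: int,
    is_interior: bool,
    filt: AutocorrelationFilter,
) -> np.ndarray:
    """Apply the autocorrelation filter to one UPM row.

    The diagonal (retention) entry shifts by +/- f/2 (clamped to [0, 1]) and
    the off-diagonal entries are rescaled proportionally so the row still
    sums to 1.  A row with zero misclassification mass has nothing to
    redistribute and is returned unchanged.
    """
    row = np.asarray(upm_row, dtype=float)
    if row.ndim != 1 or not 0 <= mapped_class < row.size:
        raise ValueError("mapped_class must index the row")
    if abs(row.sum() - 1.0) > 1e-6 or np.any(row < 0):
        raise ValueError("upm_row must be a probability distribution")
    f = filt.total_gradient
    if f == 0.0:
        return row.copy()
    p = row[mapped_class]
    off_mass = 1.0 - p
    if off_mass <= _ROW_TOL:
        return row.copy()
    if filt.mode == "additive":
        shift = filt.interior_shift if is_interior else filt.edge_shift
        p_new = float(np.clip(p + shift, 0.0, 1.0))
    else:  # multiplicative: scale the misclassification mass
        factor = (1.0 - f / 2.0) if is_interior else (1.0 + f / 2.0)
        p_new = float(np.clip(1.0 - off_mass * factor, 0.0, 1.0))
    out = row * ((1.0 - p_new) / off_mass)
    out[mapped_class] = p_new
    return out


def simulate_realization(
    raster: CategoricalRaster,
    upm: UserProbabilityMatrix,
    filt: AutocorrelationFilter | None = None,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    interior: np.ndarray | None = None,
) -> CategoricalRaster:
    """Draw one stochastic realization of a mapped raster.

    Raster codes must index the UPM rows (code k = row k, the fixed group
    order).  Every pixel is resampled independently: a uniform draw is
    placed on the inverse CDF of its (filter-adjusted) UPM row.  Nodata
    pixels are untouched.  Deterministic for a fixed seed.
    """
    if filt is None:
        filt = AutocorrelationFilter(total_gradient=0.0)
    data = raster.data
    valid = raster.valid_mask
    n_classes = upm.probs.shape[0]
    present = np.unique(data[valid])
    bad = [int(c) for c in present if not 0 <= int(c) < n_classes]
    if bad:
        raise ValueError(f"raster classes without a UPM row: {bad}")
    if interior is None:
        interior = interior_edge_map(raster)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # One uniform per grid cell, drawn in raster order for reproducibility.
    u = rng.random(data.shape)
    out = data.copy()
    for k in present:
        k = int(k)
        for is_int in (True, False):
            sel = valid & (data == k) & (interior == is_int)
            if not sel.any():
                continue
            row = adjusted_row(upm.probs[k], k, is_int, filt)
            cdf = np.cumsum(row)
            cdf[-1] = 1.0 + 1e-12  # guard against float shortfall
            out[sel] = np.searchsorted(cdf, u[sel], side="right").astype(out.dtype)
    return raster.with_data(out)


def run_ensemble(
    run: RealizationRun,
    perturbation_raster: CategoricalRaster,
    binary_raster: CategoricalRaster,
    sites: list[AssessmentSite],
    landuse_weights: dict[int, float] | np.ndarray,
    structural_weights: dict[int, float] | np.ndarray,
    perturbation_upm: UserProbabilityMatrix,
    fragmentation_upm: UserProbabilityMatrix,
    edge_width: int = 3,
    connectivity: int = 8,
) -> dict[str, dict[str, ScoreDistribution]]:
    """Full Monte Carlo ensemble over both input maps.

    Per realization: simulate the perturbation map and (independently) the
    binary map, rerun the structural classification on the simulated binary
    map, and score every site.  Returns, per site, a
    :class:`ScoreDistribution` for each of met_bp, met_fp, met_bf, met_ff
    and index, whose naive values come from the unperturbed inputs.
    """
    naive_structural = _mspa.classify_structure(
        binary_raster, edge_width=edge_width, connectivity=connectivity
    )
    naive: dict[str, MetricSet] = {
        s.site_id: assess_site(
            perturbation_raster, naive_structural, s, landuse_weights, structural_weights
        )
        for s in sites
    }

    # The interior/edge structure is a property of the original maps.
    pert_interior = interior_edge_map(perturbation_raster)
    frag_interior = interior_edge_map(binary_raster)

    metric_names = ("met_bp", "met_fp", "met_bf", "met_ff", "index")
    scores: dict[str, dict[str, list[float]]] = {
        s.site_id: {m: [] for m in metric_names} for s in sites
    }
    for i in range(run.n_realizations):
        sim_pert = simulate_realization(
            perturbation_raster, perturbation_upm, run.filter,
            seed=run.substream(i, 0), interior=pert_interior,
        )
        sim_binary = simulate_realization(
            binary_raster, fragmentation_upm, run.filter,
            seed=run.substream(i, 1), interior=frag_interior,
        )
        sim_structural = _mspa.classify_structure(
            sim_binary, edge_width=edge_width, connectivity=connectivity
        )
        for s in sites:
            ms = assess_site(
                sim_pert, sim_structural, s, landuse_weights, structural_weights
            )
            for m in metric_names:
                scores[s.site_id][m].append(getattr(ms, m))

    out: dict[str, dict[str, ScoreDistribution]] = {}
    for s in sites:
        out[s.site_id] = {
            m: summarize(
                getattr(naive[s.site_id], m),
                np.asarray(scores[s.site_id][m]),
                site_id=s.site_id,
                metric_name=m,
            )
            for m in metric_names
        }
    return out
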