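"""Land-cover reclassification schemes, confusion matrices and user's
probability matrices.

The assessment runs on two derived thematic maps: a five-group land-use map
(unmanaged / low-intensity agriculture / high-intensity agriculture /
low-intensity urban / high-intensity urban) feeding the perturbation metric,
and a binary unmanaged/managed map feeding the fragmentation metric.  Each
group carries a weight :math:`w_{Lx}` in [0, 1] expressing its position on the
disturbance (or habitat-quality) gradient.

Accuracy-assessment data travel as a :class:`ConfusionMatrix` (mapped class
rows x reference class columns).  Row-normalising a confusion matrix yields a
:class:`UserProbabilityMatrix` (UPM): for each mapped class, the probability
distribution of its true class, the engine of the misclassification
simulation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .raster import CategoricalRaster

__all__ = [
    "ReclassScheme",
    "ConfusionMatrix",
    "UserProbabilityMatrix",
    "reclassify",
    "aggregate_confusion",
    "overall_accuracy",
    "build_upm",
    "landuse_scheme",
    "binary_scheme",
    "structural_weights",
    "landuse_upm",
    "binary_upm",
    "LANDUSE_GROUPS",
    "BINARY_GROUPS",
]


@dataclass(frozen=True)
class ReclassScheme:
    """Mapping of raw class codes to named groups, each with a weight.

    ``group_order`` fixes the order used everywhere downstream (confusion
    matrix axes, UPM rows, inverse-CDF sampling), so results are reproducible
    regardless of dict iteration quirks.
    """

    mapping: dict[int, str]
    weights: dict[str, float]
    group_order: tuple[str, ...]

    def __post_init__(self) -> None:
        groups = set(self.group_order)
        if len(groups) != len(self.group_order):
            raise ValueError("group_order contains duplicates")
        if set(self.weights) != groups:
            raise ValueError("weights must cover exactly the groups in group_order")
        for g, w in self.weights.items():
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"weight for group {g!r} outside [0, 1]: {w}")
        unmapped = {g for g in self.mapping.values()} - groups
        if unmapped:
            raise ValueError(f"mapping targets unknown groups: {sorted(unmapped)}")

    @property
    def group_codes(self) -> dict[str, int]:
        """Integer code assigned to each group (its index in group_order)."""
        return {g: i for i, g in enumerate(self.group_order)}

    def group_of_code(self, code: int) -> str:
        try:
            return self.mapping[code]
        except KeyError:
            raise KeyError(f"class code {code} not covered by the scheme") from None

    def weight_array(self) -> np.ndarray:
        """Weights ordered by group code."""
        return np.array([self.weights[g] for g in self.group_order], dtype=float)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ReclassScheme":
        """Load a scheme from CSV with columns ``code,group,weight``.

        Group order follows first appearance in the file.
        """
        mapping: dict[int, str] = {}
        weights: dict[str, float] = {}
        order: list[str] = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                code = int(row["code"])
                group = row["group"].strip()
                mapping[code] = group
                if group not in weights:
                    weights[group] = float(row["weight"])
                    order.append(group)
        return cls(mapping=mapping, weights=weights, group_order=tuple(order))

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["code", "group", "weight"])
            for code in sorted(self.mapping):
                group = self.mapping[code]
                writer.writerow([code, group, self.weights[group]])


@dataclass(frozen=True)
class ConfusionMatrix:
    """Square matrix of accuracy-assessment counts.

    Rows are mapped classes, columns are ground-reference classes; the same
    label ordering applies to both axes.
    """

    counts: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError(f"confusion matrix must be square, got {counts.shape}")
        if counts.shape[0] != len(self.labels):
            raise ValueError("label count does not match matrix size")
        if np.any(counts < 0):
            raise ValueError("confusion matrix entries must be nonnegative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @classmethod
    def from_csv(cls, path: str | Path) -> "ConfusionMatrix":
        """Load a labeled confusion matrix (header row + label column)."""
        with open(path, newline="") as fh:
            rows = list(csv.reader(fh))
        if not rows:
            raise ValueError(f"{path}: empty confusion-matrix file")
        col_labels = [c.strip() for c in rows[0][1:]]
        row_labels: list[str] = []
        counts = []
        for row in rows[1:]:
            if not row:
                continue
            row_labels.append(row[0].strip())
            counts.append([float(v) for v in row[1:]])
        if row_labels != col_labels:
            raise ValueError("row and column labels differ or are misordered")
        return cls(counts=np.array(counts), labels=tuple(row_labels))

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow([""] + list(self.labels))
            for label, row in zip(self.labels, self.counts):
                writer.writerow([label] + [_fmt(v) for v in row])


@dataclass(frozen=True)
class UserProbabilityMatrix:
    """Row-stochastic misclassification probabilities per mapped class.

    ``probs[k, i]`` is the probability that a pixel mapped as class ``k`` is
    truly class ``i``.  Stored as proportions; accuracy reports often print
    them as percentages, and :meth:`from_csv` renormalises either form.
    """

    probs: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 2 or probs.shape[0] != probs.shape[1]:
            raise ValueError(f"UPM must be square, got {probs.shape}")
        if probs.shape[0] != len(self.labels):
            raise ValueError("label count does not match matrix size")
        if np.any(probs < 0) or np.any(probs > 1):
            raise ValueError("UPM entries must lie in [0, 1]")
        sums = probs.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError(f"UPM rows must sum to 1, got {sums}")
        object.__setattr__(self, "probs", probs)

    def row(self, label: str) -> np.ndarray:
        return self.probs[self.labels.index(label)]

    @classmethod
    def from_percent(
        cls, percent: np.ndarray, labels: tuple[str, ...]
    ) -> "UserProbabilityMatrix":
        """Build from a matrix printed in percent (rows summing to ~100)."""
        arr = np.asarray(percent, dtype=float)
        return cls(probs=arr / arr.sum(axis=1, keepdims=True), labels=labels)

    @classmethod
    def from_csv(cls, path: str | Path) -> "UserProbabilityMatrix":
        """Load a labeled UPM; percent and proportion forms both accepted.

        Rows are renormalised to sum to 1, so matrices printed to limited
        precision remain valid.
        """
        cm = ConfusionMatrix.from_csv(path)
        return cls.from_percent(cm.counts, cm.labels)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow([""] + list(self.labels))
            for label, row in zip(self.labels, self.probs):
                writer.writerow([label] + [f"{v:.6f}" for v in row])


def reclassify(raster: CategoricalRaster, scheme: ReclassScheme) -> CategoricalRaster:
    """Bin raw class codes into scheme groups.

    Output codes are the group indices in ``scheme.group_order``; nodata is
    preserved.  Raises ``KeyError`` naming the first code the scheme does not
    cover.
    """
    valid = raster.valid_mask
    present = np.unique(raster.data[valid])
    missing = [int(c) for c in present if int(c) not in scheme.mapping]
    if missing:
        raise KeyError(f"class codes not covered by the scheme: {missing}")
    codes = scheme.group_codes
    out = np.full(raster.shape, raster.nodata, dtype=np.int32)
    for raw in present:
        out[raster.data == raw] = codes[scheme.mapping[int(raw)]]
    return CategoricalRaster(out, nodata=raster.nodata)


def aggregate_confusion(cm: ConfusionMatrix, scheme: ReclassScheme) -> ConfusionMatrix:
    """Collapse a confusion matrix to the scheme's groups.

    Each output cell sums every input cell whose row label and column label
    map to that pair of groups; the grand total is conserved.  Labels may be
    raw codes (as strings) or already group names.
    """

    def to_group(label: str) -> str:
        if label in scheme.weights:
            return label
        try:
            code = int(label)
        except ValueError:
            raise KeyError(f"confusion-matrix label {label!r} not mapped by scheme") from None
        return scheme.group_of_code(code)

    groups = [to_group(lbl) for lbl in cm.labels]
    order = scheme.group_order
    idx = {g: i for i, g in enumerate(order)}
    n = len(order)
    out = np.zeros((n, n), dtype=float)
    for i, gi in enumerate(groups):
        for j, gj in enumerate(groups):
            out[idx[gi], idx[gj]] += cm.counts[i, j]
    return ConfusionMatrix(counts=out, labels=tuple(order))


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Trace over grand total: the fraction of assessed pixels mapped
    correctly."""
    total = cm.total
    if total <= 0:
        raise ValueError("confusion matrix has no observations")
    return float(np.trace(cm.counts) / total)


def build_upm(cm: ConfusionMatrix) -> UserProbabilityMatrix:
    """Row-normalise a confusion matrix into user's probabilities.

    A mapped class whose row sums to zero was never assessed and has no
    defined probability row; this raises.
    """
    row_sums = cm.counts.sum(axis=1)
    zero = np.nonzero(row_sums == 0)[0]
    if zero.size:
        bad = [cm.labels[i] for i in zero]
        raise ValueError(f"mapped classes never assessed (zero rows): {bad}")
    return UserProbabilityMatrix(
        probs=cm.counts / row_sums[:, None], labels=cm.labels
    )


def _fmt(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else f"{v:.6f}"


# ---------------------------------------------------------------------------
# Packaged defaults: the NLCD-style land-use binning, the binary
# unmanaged/managed binning, the structural-class weights, and the two
# user's probability matrices for the aggregated maps.
# ---------------------------------------------------------------------------

LANDUSE_GROUPS: tuple[str, ...] = (
    "unmanaged",
    "low_intensity_agriculture",
    "high_intensity_agriculture",
    "low_intensity_urban",
    "high_intensity_urban",
)

BINARY_GROUPS: tuple[str, ...] = ("unmanaged", "managed")

# NLCD code -> land-use group.  Open water, perennial ice/snow, forest,
# shrub, herbaceous and wetland classes all count as unmanaged floodplain
# cover; pasture/hay is low-intensity agriculture, row crops high-intensity;
# developed open space / low-intensity is low urban; medium/high development
# and barren are high urban.
_LANDUSE_MAPPING: dict[int, str] = {
    **{c: "unmanaged" for c in (11, 12, 41, 42, 43, 52, 71, 90, 95)},
    81: "low_intensity_agriculture",
    82: "high_intensity_agriculture",
    21: "low_intensity_urban",
    22: "low_intensity_urban",
    23: "high_intensity_urban",
    24: "high_intensity_urban",
    31: "high_intensity_urban",
}

_LANDUSE_WEIGHTS: dict[str, float] = {
    "unmanaged": 1.0,
    "low_intensity_agriculture": 0.8,
    "high_intensity_agriculture": 0.5,
    "low_intensity_urban": 0.2,
    "high_intensity_urban": 0.0,
}


def landuse_scheme() -> ReclassScheme:
    """Five-group land-use intensity scheme with its sub-score weights."""
    return ReclassScheme(
        mapping=dict(_LANDUSE_MAPPING),
        weights=dict(_LANDUSE_WEIGHTS),
        group_order=LANDUSE_GROUPS,
    )


def binary_scheme() -> ReclassScheme:
    """Binary unmanaged/managed scheme used by the fragmentation analysis.

    Maps NLCD codes directly; to binarise an already five-group map, reuse
    the group indices 0..4 as codes (see :func:`binary_from_landuse`).
    """
    mapping = {
        code: ("unmanaged" if group == "unmanaged" else "managed")
        for code, group in _LANDUSE_MAPPING.items()
    }
    return ReclassScheme(
        mapping=mapping,
        weights={"unmanaged": 1.0, "managed": 0.0},
        group_order=BINARY_GROUPS,
    )


def binary_from_landuse() -> ReclassScheme:
    """Binary scheme whose input codes are the five land-use group indices."""
    mapping = {i: ("unmanaged" if g == "unmanaged" else "managed")
               for i, g in enumerate(LANDUSE_GROUPS)}
    return ReclassScheme(
        mapping=mapping,
        weights={"unmanaged": 1.0, "managed": 0.0},
        group_order=BINARY_GROUPS,
    )


def structural_weights() -> dict[str, float]:
    """Habitat-quality weights for the seven structural classes."""
    return {
        "core": 1.0,
        "edge": 0.8,
        "loop": 0.6,
        "bridge": 0.6,
        "branch": 0.4,
        "islet": 0.2,
        "managed": 0.0,
    }


# User's probability matrices for the two aggregated maps, in percent.
_LANDUSE_UPM_PERCENT = np.array(
    [
        [93.10, 3.24, 1.68, 1.78, 0.20],
        [16.32, 77.29, 1.25, 4.88, 0.26],
        [4.02, 5.50, 88.05, 2.40, 0.03],
        [19.96, 5.10, 5.14, 65.40, 4.40],
        [18.32, 0.81, 0.27, 8.31, 72.29],
    ]
)

_BINARY_UPM_PERCENT = np.array(
    [
        [93.10, 6.90],
        [10.39, 89.61],
    ]
)


def landuse_upm() -> UserProbabilityMatrix:
    """UPM for the five-group land-use map (overall accuracy ~90 %)."""
    return UserProbabilityMatrix.from_percent(_LANDUSE_UPM_PERCENT, LANDUSE_GROUPS)


def binary_upm() -> UserProbabilityMatrix:
    """UPM for the binary unmanaged/managed map (overall accuracy ~92 %)."""
    return UserProbabilityMatrix.from_percent(_BINARY_UPM_PERCENT, BINARY_GROUPS)
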