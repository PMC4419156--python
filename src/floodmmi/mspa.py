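"""Morphological spatial pattern analysis on a binary unmanaged/managed map.

A simplified morphological decomposition in the MSPA family: the foreground
(unmanaged land) is partitioned into seven mutually exclusive structural
classes describing fragmentation —

* ``CORE``    interior pixels farther than ``edge_width`` (Chebyshev) from
              any background pixel;
* ``EDGE``    the rind of core patches, within ``edge_width`` of core
              (perforations, i.e. inner boundaries, are part of this rind);
* ``BRIDGE``  narrow connectors joining two or more distinct core patches;
* ``LOOP``    connectors that leave and re-enter the same core patch;
* ``BRANCH``  connectors attached to a core patch at one end only;
* ``ISLET``   foreground patches too small to contain any core;
* ``MANAGED`` the background.

Pixels beyond the map border are treated as foreground, so the analysis of a
map clipped to a study area does not manufacture artificial edge along the
clip line.  This partition is what the fragmentation metric weights; it does
not aim to reproduce the byte-level class codes of the JRC GUIDOS tool.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .raster import CategoricalRaster

__all__ = [
    "MANAGED",
    "CORE",
    "EDGE",
    "LOOP",
    "BRIDGE",
    "BRANCH",
    "ISLET",
    "STRUCTURAL_CLASS_NAMES",
    "GUIDOS_CODE_TABLE",
    "classify_structure",
]

MANAGED = 0
CORE = 1
EDGE = 2
LOOP = 3
BRIDGE = 4
BRANCH = 5
ISLET = 6

STRUCTURAL_CLASS_NAMES: dict[int, str] = {
    MANAGED: "managed",
    CORE: "core",
    EDGE: "edge",
    LOOP: "loop",
    BRIDGE: "bridge",
    BRANCH: "branch",
    ISLET: "islet",
}

#: Correspondence between this package's structural classes and the byte
#: codes emitted by the GUIDOS MSPA tool, for users comparing outputs.
#: The partition matches in intent, not byte-for-byte.
GUIDOS_CODE_TABLE: dict[str, tuple[int, ...]] = {
    "core": (17, 117),
    "edge": (3, 5, 35, 67, 103, 105, 135, 167),
    "loop": (65, 69, 165, 169),
    "bridge": (33, 37, 133, 137),
    "branch": (1, 101),
    "islet": (9, 109),
    "managed": (0, 100),
}

_STRUCT8 = np.ones((3, 3), dtype=bool)
_STRUCT4 = ndimage.generate_binary_structure(2, 1)


def classify_structure(
    binary: CategoricalRaster,
    edge_width: int = 3,
    connectivity: int = 8,
    foreground: int = 0,
    background: int = 1,
) -> CategoricalRaster:
    """Partition a binary map into the seven structural classes.

    Parameters
    ----------
    binary:
        Raster whose non-nodata pixels are all ``foreground`` or
        ``background``.
    edge_width:
        Width of the edge rind in pixels (Chebyshev distance).  At 30-m
        resolution the default of 3 corresponds to a 90-m rind.
    connectivity:
        4 or 8; patch connectivity for foreground components.  Chebyshev
        (8-neighbour) geometry is always used for the erosion and rind, so 8
        is the self-consistent choice.
    foreground, background:
        The two class codes of the binary map.

    Returns
    -------
    CategoricalRaster with the ``MANAGED`` .. ``ISLET`` codes above; nodata
    preserved.  Nodata pixels act as background for the morphology.
    """
    if edge_width < 1:
        raise ValueError(f"edge_width must be >= 1, got {edge_width}")
    if connectivity not in (4, 8):
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    data = binary.data
    valid = binary.valid_mask
    extra = np.unique(data[valid & (data != foreground) & (data != background)])
    if extra.size:
        raise ValueError(
            f"binary map contains classes other than {{{foreground}, {background}}}: "
            f"{[int(v) for v in extra]}"
        )

    fg = valid & (data == foreground)
    structure = _STRUCT8 if connectivity == 8 else _STRUCT4

    out = np.full(binary.shape, MANAGED, dtype=np.int32)

    # Core: Chebyshev distance to nearest background exceeds edge_width.
    # Pad with foreground so off-grid pixels never count as background.
    pad = edge_width + 1
    fg_padded = np.pad(fg, pad, mode="constant", constant_values=True)
    dist = ndimage.distance_transform_cdt(fg_padded, metric="chessboard")
    dist = dist[pad:-pad, pad:-pad]
    # cdt marks unreachable (background-free) pixels with -1: infinitely deep.
    core = fg & ((dist > edge_width) | (dist < 0))

    comp_labels, n_comp = ndimage.label(fg, structure=structure)
    core_labels, n_core = ndimage.label(core, structure=structure)

    out[fg] = ISLET  # components without core stay islet

    if n_core:
        # Rind of each core patch: non-core foreground of the same map
        # component within edge_width (ambient Chebyshev) of that patch.
        core_comp_of = {}  # core patch label -> map component label
        rinds: dict[int, np.ndarray] = {}
        edge = np.zeros_like(fg)
        for cl in range(1, n_core + 1):
            patch = core_labels == cl
            comp = comp_labels[patch][0]
            core_comp_of[cl] = comp
            halo = ndimage.binary_dilation(patch, _STRUCT8, iterations=edge_width)
            rind = halo & fg & ~core & (comp_labels == comp)
            rinds[cl] = rind
            edge |= rind
        out[edge] = EDGE
        out[core] = CORE

        # Connectors: what is left of core-containing components.
        has_core = np.zeros(n_comp + 1, dtype=bool)
        has_core[np.unique(comp_labels[core])] = True
        connector = fg & ~core & ~edge & has_core[comp_labels]
        conn_labels, n_conn = ndimage.label(connector, structure=structure)
        for ql in range(1, n_conn + 1):
            cc = conn_labels == ql
            halo = ndimage.binary_dilation(cc, structure)
            touched = [
                cl for cl, rind in rinds.items()
                if (halo & (rind | (core_labels == cl))).any()
            ]
            if len(touched) >= 2:
                out[cc] = BRIDGE
            elif len(touched) == 1:
                # Loop vs branch: count disjoint contact patches on the rind.
                contact = rinds[touched[0]] & halo
                _, n_contacts = ndimage.label(contact, structure=_STRUCT8)
                out[cc] = LOOP if n_contacts >= 2 else BRANCH
            else:
                out[cc] = BRANCH

    out[~valid] = binary.nodata
    return CategoricalRaster(out, nodata=binary.nodata)
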