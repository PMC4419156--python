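"""Brute-force reference implementation of the structural classification.

Written deliberately as plain nested loops and breadth-first searches, with
no code shared with the package, so it can serve as an independent oracle
for :func:`floodmmi.mspa.classify_structure`.

Rules implemented (identical reading as the package):

1. CORE: foreground pixel whose Chebyshev distance to the nearest in-grid
   background (or nodata) pixel exceeds ``edge_width``; off-grid pixels are
   foreground, so a map with no background at all is all core.
2. Foreground connected components (on-grid only) without any core pixel
   are ISLET.
3. In core-containing components, non-core pixels within ``edge_width``
   (ambient Chebyshev) of a core pixel of the *same* component are EDGE.
4. Remaining foreground pixels form connector components.  A connector
   adjacent (directly, or through a core patch's edge rind) to >= 2 distinct
   core patches is BRIDGE; to exactly one patch through >= 2 disjoint
   (8-connected) contact patches on the rind is LOOP; otherwise BRANCH.
5. Background is MANAGED; nodata stays nodata.
"""

from __future__ import annotations

from collections import deque

MANAGED, CORE, EDGE, LOOP, BRIDGE, BRANCH, ISLET = 0, 1, 2, 3, 4, 5, 6


def _neighbours(r, c, rows, cols, connectivity):
    if connectivity == 8:
        offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    for dr, dc in offsets:
        rr, cc = r + dr, c + dc
        if 0 <= rr < rows and 0 <= cc < cols:
            yield rr, cc


def _components(cells, rows, cols, connectivity):
    """Partition a set of (r, c) cells into connected components."""
    cells = set(cells)
    comps = []
    while cells:
        start = cells.pop()
        comp = {start}
        queue = deque([start])
        while queue:
            r, c = queue.popleft()
            for nb in _neighbours(r, c, rows, cols, connectivity):
                if nb in cells:
                    cells.remove(nb)
                    comp.add(nb)
                    queue.append(nb)
        comps.append(comp)
    return comps


def _chebyshev(a, b):
    return max(abs(a[0] - b[0]), abs(a[1] - b[1]))


def classify_structure_bruteforce(
    grid, edge_width=1, connectivity=8, foreground=0, background=1, nodata=-9999
):
    """Classify a list-of-lists binary grid; returns a list-of-lists of
    structural codes (nodata pixels keep the nodata value)."""
    rows, cols = len(grid), len(grid[0])
    fg, bg = set(), set()
    for r in range(rows):
        for c in range(cols):
            v = grid[r][c]
            if v == foreground:
                fg.add((r, c))
            elif v == background or v == nodata:
                bg.add((r, c))
            else:
                raise ValueError(f"unexpected class {v}")

    out = [[MANAGED] * cols for _ in range(rows)]

    # Rule 1: core by exhaustive distance scan (off-grid is foreground, so
    # only in-grid background pixels bound the distance).
    core = set()
    for p in fg:
        dist = min((_chebyshev(p, q) for q in bg), default=None)
        if dist is None or dist > edge_width:
            core.add(p)

    comps = _components(fg, rows, cols, connectivity)
    core_patches = _components(core, rows, cols, connectivity)

    edge = set()
    for comp in comps:
        comp_core = core & comp
        if not comp_core:
            for p in comp:
                out[p[0]][p[1]] = ISLET
            continue
        for p in comp - core:
            if min(_chebyshev(p, q) for q in comp_core) <= edge_width:
                edge.add(p)

    for p in core:
        out[p[0]][p[1]] = CORE
    for p in edge:
        out[p[0]][p[1]] = EDGE

    # Rind of each core patch: edge pixels of the same component within
    # edge_width of that patch.
    comp_of = {}
    for i, comp in enumerate(comps):
        for p in comp:
            comp_of[p] = i
    rinds = []
    for patch in core_patches:
        patch_comp = comp_of[next(iter(patch))]
        rind = {
            p for p in edge
            if comp_of[p] == patch_comp
            and min(_chebyshev(p, q) for q in patch) <= edge_width
        }
        rinds.append((patch, rind))

    # Rule 4: connectors.
    classified = core | edge | {p for p in fg if out[p[0]][p[1]] == ISLET}
    connectors = fg - classified
    for cc in _components(connectors, rows, cols, connectivity):
        halo = set()
        for p in cc:
            halo.update(_neighbours(p[0], p[1], rows, cols, connectivity))
        touched = [
            (patch, rind) for patch, rind in rinds
            if halo & (patch | rind)
        ]
        if len(touched) >= 2:
            label = BRIDGE
        elif len(touched) == 1:
            contact = touched[0][1] & halo
            n_patches = len(_components(contact, rows, cols, 8))
            label = LOOP if n_patches >= 2 else BRANCH
        else:
            label = BRANCH
        for p in cc:
            out[p[0]][p[1]] = label

    for r in range(rows):
        for c in range(cols):
            if grid[r][c] == nodata:
                out[r][c] = nodata
    return out
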