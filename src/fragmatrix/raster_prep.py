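"""Clean suitability rasters and binarize them into habitat / matrix.

Cleaning removes small contiguous groups of pixels (fewer than 4
8-connected pixels of the same suitability level) and replaces each with the
value of the largest and nearest group, judged over the eight-neighbour
topology.  Candidate replacement groups are ranked by Euclidean distance from
the removed group's centroid to the candidate's nearest pixel; distance ties
go to the larger group, then to the lower class code.  Each pass reassigns
all small groups against the pass's original labelling (so the pass is
order-independent), and passes repeat until no small group remains — the
result is a fixed point, which makes the operation idempotent.

Binarization collapses the three suitability levels to suitable / matrix
under two level combinations:

* ``main`` — suitable = {high, medium}, matrix = {unsuitable};
* ``sensitivity`` — suitable = {high}, matrix = {medium, unsuitable}.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

from .grids import (HIGH, MAIN, MATRIX, MEDIUM, NODATA, SCENARIOS, SUITABLE,
                    UNSUITABLE, BinaryHabitatMap, SuitabilityRaster)

logger = logging.getLogger(__name__)

MIN_GROUP_PIXELS = 4
_EIGHT = np.ones((3, 3), dtype=int)


def _label_components(grid: np.ndarray) -> tuple[np.ndarray, dict[int, dict]]:
    """Label 8-connected components of every suitability class.

    Returns a combined label grid (0 = NODATA) and per-component info:
    class code, pixel count, and the flat index of the first pixel
    (raster scan order).
    """
    comp = np.zeros(grid.shape, dtype=np.int32)
    info: dict[int, dict] = {}
    offset = 0
    for cls in (UNSUITABLE, MEDIUM, HIGH):
        lab, n = ndimage.label(grid == cls, structure=_EIGHT)
        if n == 0:
            continue
        mask = lab > 0
        comp[mask] = lab[mask] + offset
        counts = np.bincount(lab[mask])
        for k in range(1, n + 1):
            info[offset + k] = {"cls": cls, "size": int(counts[k])}
        offset += n
    flat = comp.ravel()
    order = np.flatnonzero(flat)
    first_seen: dict[int, int] = {}
    for idx in order:
        cid = int(flat[idx])
        if cid not in first_seen:
            first_seen[cid] = int(idx)
    for cid, pos in first_seen.items():
        info[cid]["first"] = pos
    return comp, info


def _candidates_for(info: dict[int, dict], cls: int) -> list[int]:
    """Replacement candidates for a small group of class ``cls``.

    A replacement must change the group's value, so only components of a
    different class qualify; groups of at least the size threshold are
    preferred, any different-class group is the fallback.
    """
    big = [cid for cid, d in info.items()
           if d["cls"] != cls and d["size"] >= MIN_GROUP_PIXELS]
    if big:
        return big
    return [cid for cid, d in info.items() if d["cls"] != cls]


def _clean_pass(grid: np.ndarray) -> tuple[np.ndarray, bool]:
    """One non-cascading cleaning pass; returns (new grid, changed?).

    All small groups are located against the pass's original labelling and
    reassigned together, so within-pass processing order cannot matter.
    """
    comp, info = _label_components(grid)
    small = [cid for cid, d in info.items() if d["size"] < MIN_GROUP_PIXELS]
    if not small:
        return grid, False

    rows, cols = np.indices(grid.shape)
    out = grid.copy()
    changed = False
    # deterministic order: by first pixel of each small group in scan order
    for cid in sorted(small, key=lambda c: info[c]["first"]):
        cands = _candidates_for(info, info[cid]["cls"])
        if not cands:
            continue
        pix = comp == cid
        cy, cx = rows[pix].mean(), cols[pix].mean()
        dist = np.hypot(rows - cy, cols - cx)
        cand_ids = np.array(sorted(cands))
        nearest = np.atleast_1d(
            ndimage.minimum(dist, labels=comp, index=cand_ids))
        keys = [(float(d), -info[int(c)]["size"], info[int(c)]["cls"])
                for d, c in zip(nearest, cand_ids)]
        best = int(cand_ids[min(range(len(keys)), key=keys.__getitem__)])
        out[pix] = info[best]["cls"]
        changed = True
    return out, changed


def clean_small_groups(raster: SuitabilityRaster,
                       max_passes: int = 50) -> SuitabilityRaster:
    """Remove sub-threshold suitability groups (see module docstring).

    A raster containing a single non-NODATA class (or a single component)
    is returned unchanged with a logged notice.
    """
    grid = raster.grid.copy()
    in_range = grid != NODATA
    classes = np.unique(grid[in_range])
    if classes.size <= 1:
        logger.info("%s: single-class raster, cleaning is a no-op",
                    raster.species_id)
        return SuitabilityRaster(grid, raster.pixel_size, raster.species_id,
                                 raster.degenerate)
    work = np.where(in_range, grid, NODATA)
    seen: dict[bytes, int] = {work.tobytes(): 0}
    trajectory = [work]
    for step in range(1, max_passes + 1):
        nxt, changed = _clean_pass(work)
        if not changed:
            break
        key = nxt.tobytes()
        if key in seen:
            # cycling between states (possible only for isolated groups with
            # no adjacent replacement); pick the canonical cycle state so the
            # operation stays deterministic and idempotent
            cycle = trajectory[seen[key]:]
            work = min(cycle, key=lambda g: g.tobytes())
            break
        seen[key] = step
        trajectory.append(nxt)
        work = nxt
    out = np.where(in_range, work, NODATA).astype(grid.dtype)
    return SuitabilityRaster(out, raster.pixel_size, raster.species_id,
                             raster.degenerate)


def binarize(raster: SuitabilityRaster, scenario: str = MAIN) -> BinaryHabitatMap:
    """Collapse suitability levels to suitable / matrix under a scenario."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    suitable_classes = (HIGH, MEDIUM) if scenario == MAIN else (HIGH,)
    grid = raster.grid
    out = np.full(grid.shape, MATRIX, dtype=np.uint8)
    out[np.isin(grid, suitable_classes)] = SUITABLE
    out[grid == NODATA] = NODATA
    return BinaryHabitatMap(out, scenario=scenario,
                            pixel_size=raster.pixel_size,
                            species_id=raster.species_id)
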