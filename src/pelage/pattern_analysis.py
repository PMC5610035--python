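"""Quantification of simulated spatiotemporal hair-growth patterns.

Works on :class:`~pelage.population.PatternRecord` objects: per-cycle anagen
onset maps, persistence of head-to-tail onset ordering (rank correlation),
bilateral mirror symmetry about a lateral midline, and arrival-time fronts
with a distortion measure for wave-breaker geometries.

Cycle indexing is per site: a site's cycle k onset is its k-th ~anagen entry
in the transition log, so sites that drift out of phase keep well-defined
cycles.  All metrics are invariant to site relabeling and to a global time
translation of the record.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._engine import ANAGEN_CODE
from .population import PatternRecord

__all__ = [
    "OnsetMap",
    "SymmetryScore",
    "WavefrontResult",
    "onset_map",
    "n_complete_cycles",
    "asynchrony_persistence",
    "bilateral_symmetry",
    "symmetry_score",
    "emergence_cycle",
    "wavefront_arrival",
]


@dataclasses.dataclass
class OnsetMap:
    """Per-site first ~anagen entry time of one (per-site) cycle.

    ``times`` is laid out on the lattice grid (rows, cols) with NaN at
    non-follicle sites and at sites that never reached this cycle; ``valid``
    is the companion mask.
    """

    cycle: int
    times: np.ndarray
    valid: np.ndarray

    def values(self) -> np.ndarray:
        return self.times[self.valid]


def onset_map(record: PatternRecord, cycle: int) -> OnsetMap:
    """Extract the cycle-``cycle`` anagen onset map (1-based cycle index)."""
    if cycle < 1:
        raise ValueError("cycle index is 1-based")
    tr = record.transitions
    ana = tr[tr["to_phase"] == ANAGEN_CODE]
    if cycle > (ana["cycle_index"].max() if len(ana) else 0):
        raise IndexError(f"cycle {cycle} beyond the record span")
    sel = ana[ana["cycle_index"] == cycle]
    times = np.full(record.lattice.shape, np.nan)
    times[sel["row"].to_numpy(), sel["col"].to_numpy()] = sel["time"].to_numpy()
    valid = ~np.isnan(times)
    return OnsetMap(cycle=cycle, times=times, valid=valid)


def n_complete_cycles(record: PatternRecord) -> int:
    """Largest k such that every follicle site has at least k anagen entries."""
    tr = record.transitions
    ana = tr[tr["to_phase"] == ANAGEN_CODE]
    counts = ana.groupby("site").size().reindex(range(record.n_sites), fill_value=0)
    return int(counts.min())


def asynchrony_persistence(
    record: PatternRecord,
    axis_coords: np.ndarray | None = None,
    threshold: float = 0.5,
    site_mask: np.ndarray | None = None,
    max_cycles: int | None = None,
) -> int:
    """Number of consecutive cycles the head-to-tail onset order persists.

    Returns the largest k such that for every cycle 1..k the Spearman rank
    correlation between per-site onset time and the head-to-tail coordinate
    (lattice row by default) exceeds ``threshold``.  ``site_mask`` (boolean
    over the lattice grid) restricts the statistic, e.g. to the domain that
    carries the imposed gradient.
    """
    shape = record.lattice.shape
    if axis_coords is None:
        axis_coords = np.broadcast_to(np.arange(shape[0])[:, None], shape)
    if site_mask is None:
        site_mask = np.ones(shape, dtype=bool)
    limit = max_cycles or n_complete_cycles(record)
    k = 0
    for cycle in range(1, limit + 1):
        om = onset_map(record, cycle)
        sel = om.valid & site_mask
        if sel.sum() < 3 or np.ptp(axis_coords[sel]) == 0:
            break
        rho = stats.spearmanr(axis_coords[sel], om.times[sel]).statistic
        if not (rho > threshold):
            break
        k = cycle
    return k


@dataclasses.dataclass
class SymmetryScore:
    cycle: int
    score: float


def _mirror_cols(shape: tuple[int, int], midline: float) -> np.ndarray:
    cols = np.arange(shape[1])
    return np.round(2 * midline - cols).astype(int)


def symmetry_score(om: OnsetMap, midline: float | None = None,
                   site_mask: np.ndarray | None = None) -> float:
    """Pearson correlation of the onset map with its lateral mirror image.

    The head-to-tail component (per-row mean) is removed first, so a pure
    head-to-tail gradient — which is trivially mirror-equal — scores by its
    lateral residual structure alone.  A map exactly equal to its mirror
    scores 1; a laterally antisymmetric map scores -1; random lateral
    structure scores near 0.  ``site_mask`` restricts the statistic to a
    focal region (e.g. the dorsal domain, whose pattern the flanking domains
    reorganize); the mask must itself be mirror-symmetric for the score to
    be meaningful.
    """
    rows, cols = om.times.shape
    if midline is None:
        midline = (cols - 1) / 2
    mcols = _mirror_cols(om.times.shape, midline)
    ok_col = (mcols >= 0) & (mcols < cols)
    t = om.times
    mt = np.full_like(t, np.nan)
    mt[:, ok_col] = t[:, mcols[ok_col]]
    both = om.valid & ~np.isnan(mt)
    if site_mask is not None:
        both &= site_mask
    # remove per-row means over the jointly valid sites
    a = np.where(both, t, np.nan)
    b = np.where(both, mt, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        row_mean = np.nanmean(np.where(both, t, np.nan), axis=1, keepdims=True)
    a = a - row_mean
    b = b - row_mean
    x, y = a[both], b[both]
    if x.size < 2:
        return float("nan")
    sx, sy = x.std(), y.std()
    if sx < 1e-12 or sy < 1e-12:
        # flat residual: symmetric iff the two sides agree exactly
        return 1.0 if np.allclose(x, y) else 0.0
    return float(np.corrcoef(x, y)[0, 1])


def bilateral_symmetry(
    record: PatternRecord,
    midline: float | None = None,
    cycles: Sequence[int] | None = None,
    site_mask: np.ndarray | None = None,
) -> list[SymmetryScore]:
    """Per-cycle mirror-symmetry scores of the anagen onset maps."""
    if record.lattice.shape[1] < 2:
        raise ValueError("bilateral symmetry needs a lattice at least 2 columns wide")
    if cycles is None:
        cycles = range(1, n_complete_cycles(record) + 1)
    return [
        SymmetryScore(cycle=c,
                      score=symmetry_score(onset_map(record, c), midline, site_mask))
        for c in cycles
    ]


def emergence_cycle(scores: Sequence[SymmetryScore], threshold: float = 0.7) -> int | None:
    """First cycle whose symmetry score exceeds ``threshold`` (None if never)."""
    for s in scores:
        if s.score > threshold:
            return s.cycle
    return None


@dataclasses.dataclass
class WavefrontResult:
    """Arrival-time field with iso-arrival contours.

    Contours are extracted column-wise: for each iso time level, the
    (fractional) row index where the arrival time crosses the level is
    interpolated within each column.  For a planar head-to-tail front the
    contour rows are constant; geometry features bend them.
    """

    arrival: np.ndarray                      # (rows, cols), NaN = no onset
    levels: np.ndarray
    contours: list[pd.DataFrame]             # per level: columns col, row

    def distortion(self, rows: slice | None = None) -> float:
        """Maximum front bowing, in site units.

        For each contour (restricted to ``rows`` if given), the perpendicular
        deviation is the spread max(row) - min(row) across columns; the
        distortion is the largest spread over all contours.  Zero up to
        discretization for an unobstructed planar front.
        """
        worst = 0.0
        lo = rows.start if rows and rows.start is not None else -np.inf
        hi = rows.stop if rows and rows.stop is not None else np.inf
        for c in self.contours:
            r = c["row"].to_numpy()
            r = r[(r >= lo) & (r < hi)]
            if r.size >= 2:
                worst = max(worst, float(r.max() - r.min()))
        return worst


def wavefront_arrival(
    record: PatternRecord,
    cycle: int,
    levels: np.ndarray | Sequence[float] | None = None,
    n_levels: int = 8,
) -> WavefrontResult:
    """Arrival-time field and iso-arrival contours for one cycle.

    Emits a warning and returns an empty contour set when the arrival field
    is flat (no propagating wave in the cycle).
    """
    om = onset_map(record, cycle)
    arr = om.times
    vals = om.values()
    if vals.size == 0 or np.ptp(vals) < 1e-9:
        warnings.warn("no propagating wave detected: flat arrival-time field",
                      stacklevel=2)
        return WavefrontResult(arrival=arr, levels=np.array([]), contours=[])
    if levels is None:
        levels = np.quantile(vals, np.linspace(0.15, 0.85, n_levels))
    levels = np.asarray(levels, dtype=float)
    contours = []
    rows, cols = arr.shape
    for lev in levels:
        pts = []
        for c in range(cols):
            col = arr[:, c]
            ok = ~np.isnan(col)
            idx = np.where(ok)[0]
            if idx.size < 2:
                continue
            r, t = idx.astype(float), col[idx]
            # first upward crossing of the level along the row direction
            for j in range(len(t) - 1):
                t0, t1 = t[j], t[j + 1]
                if (t0 - lev) * (t1 - lev) <= 0 and t0 != t1:
                    frac = (lev - t0) / (t1 - t0)
                    pts.append((c, r[j] + frac * (r[j + 1] - r[j])))
                    break
        contours.append(pd.DataFrame(pts, columns=["col", "row"]))
    return WavefrontResult(arrival=arr, levels=levels, contours=contours)
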