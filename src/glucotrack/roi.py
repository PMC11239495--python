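"""Cross-session ROI identity matching for volumetric imaging.

Manually drawn cell masks recorded in different sessions (or in
neighboring optical planes of the same volume) may be the same cell.
Two ROIs are joined when all of the following hold: they sit in the same
or adjacent planes, their 3-pixel-dilated masks overlap by more than 5%
(of the smaller mask by default), their activity traces correlate above
0.90 at some lag smaller than 2 s, and the correspondence is supported by
at least two independent sessions.  Joined pairs are merged by connected
components and merged traces are member means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

FRAME_SHAPE = (256, 256)   # 512x512 acquisition after 2x2 binning


@dataclass(frozen=True)
class ROIMask:
    roi_id: str
    session_id: str
    plane: int
    pixels: frozenset         # of (row, col)
    shape: tuple = FRAME_SHAPE

    def __post_init__(self):
        if not self.pixels:
            raise ValueError("empty ROI mask")
        for r, c in self.pixels:
            if not (0 <= r < self.shape[0] and 0 <= c < self.shape[1]):
                raise ValueError(f"pixel {(r, c)} outside frame {self.shape}")

    def to_array(self) -> np.ndarray:
        a = np.zeros(self.shape, dtype=bool)
        rows, cols = zip(*self.pixels)
        a[list(rows), list(cols)] = True
        return a


@dataclass
class MatchDecision:
    roi_a: str
    roi_b: str
    overlap_fraction: float
    trace_r: float
    best_lag: float           # seconds
    sessions_supporting: int
    joined: bool
    reason: str = ""


def disk_footprint(radius: int) -> np.ndarray:
    """Euclidean disk structuring element (radius 3 -> 29 pixels)."""
    r = np.arange(-radius, radius + 1)
    dr, dc = np.meshgrid(r, r, indexing="ij")
    return (dr**2 + dc**2) <= radius**2


def dilate_mask(mask: ROIMask, radius: int = 3) -> ROIMask:
    """Morphological dilation by a Euclidean disk, clipped at frame edges."""
    arr = ndimage.binary_dilation(mask.to_array(), structure=disk_footprint(radius))
    pix = frozenset(map(tuple, np.argwhere(arr)))
    return ROIMask(mask.roi_id, mask.session_id, mask.plane, pix, mask.shape)


def overlap_fraction(a: ROIMask, b: ROIMask, denominator: str = "min") -> float:
    """Pixel overlap of two (dilated) masks, |A & B| / min(|A|, |B|).

    ``denominator="union"`` switches to Jaccard normalization.
    """
    if a.shape != b.shape:
        raise ValueError("masks live on different frame grids")
    inter = len(a.pixels & b.pixels)
    if denominator == "min":
        denom = min(len(a.pixels), len(b.pixels))
    elif denominator == "union":
        denom = len(a.pixels | b.pixels)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return inter / denom


def best_lag_correlation(
    trace_a, trace_b, rate: float = 5.1, max_lag_s: float = 2.0
) -> tuple[float, float]:
    """Maximum Pearson r over integer-sample lags with |lag| < max_lag_s."""
    a = np.asarray(trace_a, dtype=float)
    b = np.asarray(trace_b, dtype=float)
    if a.size != b.size:
        raise ValueError("traces must have equal length")
    if np.std(a) <= 1e-12 or np.std(b) <= 1e-12:
        raise ValueError("constant trace")
    max_lag = int(np.ceil(max_lag_s * rate)) - 1
    n = a.size
    best_r, best_lag = -np.inf, 0
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            x, y = a[: n - lag], b[lag:]
        else:
            x, y = a[-lag:], b[: n + lag]
        if np.std(x) <= 1e-12 or np.std(y) <= 1e-12:
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        if r > best_r:
            best_r, best_lag = r, lag
    return best_r, best_lag / rate


def decide_join(
    a: ROIMask,
    b: ROIMask,
    trace_a,
    trace_b,
    sessions_supporting: int,
    rate: float = 5.1,
    dilation_radius: int = 3,
    overlap_min: float = 0.05,
    r_min: float = 0.90,
    max_lag_s: float = 2.0,
    denominator: str = "min",
) -> MatchDecision:
    """Full same-cell decision for one ROI pair; all evidence recorded."""
    plane_dist = abs(a.plane - b.plane)
    if plane_dist > 1:
        return MatchDecision(
            a.roi_id, b.roi_id, 0.0, float("nan"), float("nan"),
            sessions_supporting, False, reason="planes not adjacent",
        )
    ov = overlap_fraction(
        dilate_mask(a, dilation_radius), dilate_mask(b, dilation_radius), denominator
    )
    r, lag = best_lag_correlation(trace_a, trace_b, rate, max_lag_s)
    joined = (
        ov > overlap_min
        and r > r_min
        and abs(lag) < max_lag_s
        and sessions_supporting >= 2
    )
    reason = "" if joined else "criteria not met"
    return MatchDecision(a.roi_id, b.roi_id, ov, r, lag, sessions_supporting, joined, reason)


def merge_components(
    roi_ids, decisions: list[MatchDecision], traces: dict | None = None
):
    """Connected components over joined pairs; merged trace = member mean.

    Returns ``(groups, merged_traces)`` where groups is a list of sorted
    ROI-id lists (singletons included) and merged_traces maps the group's
    first member id to the mean trace (when traces are supplied).
    """
    parent = {rid: rid for rid in roi_ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for d in decisions:
        if d.joined:
            ra, rb = find(d.roi_a), find(d.roi_b)
            if ra != rb:
                parent[ra] = rb
    groups_map: dict[str, list] = {}
    for rid in roi_ids:
        groups_map.setdefault(find(rid), []).append(rid)
    groups = sorted([sorted(g) for g in groups_map.values()])
    merged = {}
    if traces is not None:
        for g in groups:
            merged[g[0]] = np.mean([np.asarray(traces[r], dtype=float) for r in g], axis=0)
    return groups, merged


def masks_from_labels(label_image, session_id: str, plane: int) -> list[ROIMask]:
    """ROI masks from an integer label image (0 = background)."""
    arr = np.asarray(label_image)
    out = []
    for lab in np.unique(arr):
        if lab == 0:
            continue
        pix = frozenset(map(tuple, np.argwhere(arr == lab)))
        out.append(ROIMask(f"roi_{int(lab)}", session_id, plane, pix, arr.shape))
    return out


def write_masks_csv(masks: list[ROIMask], path) -> None:
    """Run-length encoded mask table (text format)."""
    import pandas as pd

    rows = []
    for m in masks:
        by_row: dict[int, list[int]] = {}
        for r, c in sorted(m.pixels):
            by_row.setdefault(r, []).append(c)
        for r, cols in by_row.items():
            cols = sorted(cols)
            start = prev = cols[0]
            for c in cols[1:] + [None]:
                if c is None or c != prev + 1:
                    rows.append(
                        dict(
                            roi_id=m.roi_id, session_id=m.session_id, plane=m.plane,
                            row=r, col_start=start, col_end=prev,
                        )
                    )
                    if c is not None:
                        start = c
                prev = c if c is not None else prev
    pd.DataFrame(rows).to_csv(path, index=False)


def read_masks_csv(path, shape: tuple = FRAME_SHAPE) -> list[ROIMask]:
    import pandas as pd

    df = pd.read_csv(path)
    out = []
    for (rid, sid, plane), grp in df.groupby(["roi_id", "session_id", "plane"], sort=True):
        pix = set()
        for _, rec in grp.iterrows():
            for c in range(int(rec.col_start), int(rec.col_end) + 1):
                pix.add((int(rec.row), c))
        out.append(ROIMask(str(rid), str(sid), int(plane), frozenset(pix), shape))
    return out
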