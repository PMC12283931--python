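"""Filament skeleton tracing in fluorescence frames and cross-frame linking.

Replaces interactive snake-based tracing with a deterministic chain:
Gaussian smoothing, thresholding, morphological skeletonisation, extraction
of each skeleton's longest endpoint-to-endpoint path, sub-pixel extension of
the path ends to the intensity threshold crossing (skeletonisation retreats
from the rounded caps of a thresholded ridge by about its half-width, which
would otherwise clip the measured contour), coordinate smoothing, and
resampling at a fixed node spacing (1 px by default).  Traces are then
linked across frames by greedy nearest-centroid matching.

The tracker's geometry is validated against simulator ground truth; a
reader for externally tracked snake-style files lives in
:mod:`tubemech.traces` for pipelines that skip this module.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
from scipy import ndimage
from scipy.interpolate import splev, splprep
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import skeletonize

from .traces import FilamentTrace, TrackStack

__all__ = ["TrackingConfig", "to_8bit", "trace_filaments", "link_frames"]

logger = logging.getLogger(__name__)

_NEIGHBOURS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass(frozen=True)
class TrackingConfig:
    """Tracing and linking parameters (all lengths in pixels)."""

    smoothing_sigma: float = 1.0
    threshold_method: str = "global-otsu"  # or "fixed"
    fixed_threshold: float | None = None
    min_length_px: int = 10
    node_spacing_px: float = 1.0
    border_margin_px: int = 5
    end_extension_max_px: float = 5.0
    min_frames: int = 100
    max_link_displacement_px: float = 15.0

    def __post_init__(self) -> None:
        if self.node_spacing_px <= 0:
            raise ValueError("node_spacing_px must be > 0")
        if self.min_length_px < 3:
            raise ValueError("min_length_px must be >= 3")
        if self.threshold_method not in ("global-otsu", "fixed"):
            raise ValueError("threshold_method must be 'global-otsu' or 'fixed'")
        if self.threshold_method == "fixed" and self.fixed_threshold is None:
            raise ValueError("fixed threshold_method requires fixed_threshold")


def to_8bit(stack: np.ndarray) -> np.ndarray:
    """Linear min-max rescale of a whole image stack to uint8 [0, 255].

    The rescale uses the global minimum and maximum of the full stack (not
    per frame), so relative intensities across frames are preserved.
    Idempotent on full-range 8-bit input.  A constant stack maps to zeros
    with a warning.
    """
    stack = np.asarray(stack)
    lo, hi = float(stack.min()), float(stack.max())
    if hi == lo:
        warnings.warn("constant image: 8-bit conversion yields all zeros")
        return np.zeros(stack.shape, dtype=np.uint8)
    return np.rint((stack.astype(float) - lo) / (hi - lo) * 255.0).astype(np.uint8)


def _skeleton_graph(skel: np.ndarray) -> nx.Graph:
    g = nx.Graph()
    rows, cols = np.nonzero(skel)
    pixels = set(zip(rows.tolist(), cols.tolist()))
    for r, c in pixels:
        g.add_node((r, c))
        for dr, dc in _NEIGHBOURS:
            nb = (r + dr, c + dc)
            if nb in pixels:
                g.add_edge((r, c), nb, weight=float(np.hypot(dr, dc)))
    return g


def _longest_endpoint_path(
    g: nx.Graph, intensity: np.ndarray
) -> list[tuple[int, int]] | None:
    """Longest endpoint-to-endpoint geodesic through a skeleton component.

    Endpoint pairs are compared by path length; near-ties are broken by the
    summed image intensity along the path, then lexicographically.
    """
    endpoints = [n for n in g.nodes if g.degree[n] == 1]
    if len(endpoints) < 2:
        return None  # closed loop or single pixel: outside scope
    if len(endpoints) > 10:
        # double-sweep heuristic, exact on trees (skeletons are tree-like)
        start = endpoints[0]
        dist = nx.single_source_dijkstra_path_length(g, start, weight="weight")
        a = max(endpoints, key=lambda n: dist.get(n, -1.0))
        dist_a = nx.single_source_dijkstra_path_length(g, a, weight="weight")
        b = max(endpoints, key=lambda n: dist_a.get(n, -1.0))
        return nx.dijkstra_path(g, a, b, weight="weight")

    best = None
    for i, a in enumerate(endpoints):
        lengths, paths = nx.single_source_dijkstra(g, a, weight="weight")
        for b in endpoints[i + 1 :]:
            if b not in lengths:
                continue
            path = paths[b]
            length = lengths[b]
            brightness = float(sum(intensity[p] for p in path))
            key = (length, brightness, tuple(sorted((a, b))))
            if best is None or key > best[0]:
                best = (key, path)
    if best is None:
        return None
    if len(best[1]) > 1 and best[1][0] > best[1][-1]:
        best = (best[0], best[1][::-1])
    return best[1]


def _bilinear(img: np.ndarray, x: float, y: float) -> float:
    h, w = img.shape
    if not (0 <= x <= w - 1 and 0 <= y <= h - 1):
        return -np.inf
    x0, y0 = int(np.floor(x)), int(np.floor(y))
    x1, y1 = min(x0 + 1, w - 1), min(y0 + 1, h - 1)
    fx, fy = x - x0, y - y0
    return float(
        img[y0, x0] * (1 - fx) * (1 - fy)
        + img[y0, x1] * fx * (1 - fy)
        + img[y1, x0] * (1 - fx) * fy
        + img[y1, x1] * fx * fy
    )


def _extend_end(
    xy: np.ndarray, smooth: np.ndarray, thr: float, max_ext: float
) -> np.ndarray:
    """March from the last point of *xy* along the end tangent while the
    smoothed intensity stays above *thr*; returns appended points ending at
    the interpolated threshold crossing.

    With *thr* at half the ridge intensity this places the endpoint at the
    half-maximum crossing, which for a PSF-convolved line end coincides with
    the true filament tip."""
    k = min(4, len(xy) - 1)
    tangent = xy[-1] - xy[-1 - k]
    norm = np.linalg.norm(tangent)
    if norm == 0:
        return np.empty((0, 2))
    tangent = tangent / norm
    step = 0.1
    pts = []
    prev_val = _bilinear(smooth, xy[-1, 0], xy[-1, 1])
    for i in range(1, int(max_ext / step) + 1):
        p = xy[-1] + tangent * (i * step)
        val = _bilinear(smooth, p[0], p[1])
        if val < thr:
            if np.isfinite(val) and prev_val > thr:
                # sub-step interpolation of the threshold crossing
                frac = (prev_val - thr) / (prev_val - val)
                pts.append(xy[-1] + tangent * ((i - 1 + frac) * step))
            break
        pts.append(p)
        prev_val = val
    return np.asarray(pts).reshape(-1, 2)


def _smooth_resample(xy: np.ndarray, spacing: float) -> np.ndarray:
    """Smooth a pixel path's staircase and resample at uniform arc spacing."""
    if len(xy) >= 7:
        xy = np.column_stack(
            [
                ndimage.gaussian_filter1d(xy[:, 0], 1.5, mode="nearest"),
                ndimage.gaussian_filter1d(xy[:, 1], 1.5, mode="nearest"),
            ]
        )
    seg = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    keep = np.concatenate([[True], seg > 1e-9])
    xy = xy[keep]
    if len(xy) < 2:
        return xy
    arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(xy, axis=0), axis=1))])
    total = arc[-1]
    n = max(int(round(total / spacing)) + 1, 2)
    if len(xy) >= 4:
        try:
            tck, _ = splprep([xy[:, 0], xy[:, 1]], u=arc / total, s=len(xy) * 0.05, k=3)
            return np.column_stack(splev(np.linspace(0.0, 1.0, n), tck))
        except (ValueError, TypeError):  # degenerate geometry: fall through
            pass
    s = np.linspace(0.0, total, n)
    return np.column_stack(
        [np.interp(s, arc, xy[:, 0]), np.interp(s, arc, xy[:, 1])]
    )


def _refine_to_ridge(
    xy: np.ndarray, smooth: np.ndarray, half_window: float = 2.5
) -> np.ndarray:
    """Shift each node along its local normal to the intensity centroid of
    the perpendicular profile — sub-pixel lateral registration to the
    filament's ridge line."""
    if len(xy) < 3:
        return xy
    tangents = np.gradient(xy, axis=0)
    norms = np.linalg.norm(tangents, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    tangents /= norms
    normals = np.column_stack([-tangents[:, 1], tangents[:, 0]])
    offsets = np.arange(-half_window, half_window + 0.25, 0.5)
    out = xy.copy()
    for i, (p, n) in enumerate(zip(xy, normals)):
        vals = np.array([_bilinear(smooth, *(p + n * o)) for o in offsets])
        if not np.all(np.isfinite(vals)):
            continue
        w = vals - vals.min()
        total = w.sum()
        if total <= 0:
            continue
        out[i] = p + n * float((w * offsets).sum() / total)
    return out


def _uniform_resample(xy: np.ndarray, spacing: float) -> np.ndarray:
    """Resample an already-smooth polyline at uniform arc spacing."""
    seg = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    keep = np.concatenate([[True], seg > 1e-9])
    xy = xy[keep]
    if len(xy) < 2:
        return xy
    arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(xy, axis=0), axis=1))])
    n = max(int(round(arc[-1] / spacing)) + 1, 2)
    s = np.linspace(0.0, arc[-1], n)
    return np.column_stack([np.interp(s, arc, xy[:, 0]), np.interp(s, arc, xy[:, 1])])


def trace_filaments(
    frame: np.ndarray,
    cfg: TrackingConfig = TrackingConfig(),
    frame_index: int = 0,
) -> list[FilamentTrace]:
    """Trace every filament skeleton in a single 8-bit frame.

    Returns one trace (coordinates in px, node spacing ``node_spacing_px``)
    per connected filament, dropping objects shorter than ``min_length_px``
    or touching the border margin.  Node order runs from the
    lexicographically smaller endpoint.  A blank frame yields an empty list.
    """
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2:
        raise ValueError("trace_filaments expects a single 2-D frame")
    smooth = ndimage.gaussian_filter(img, cfg.smoothing_sigma)
    if cfg.threshold_method == "fixed":
        thr = float(cfg.fixed_threshold)
    else:
        if smooth.max() == smooth.min():
            return []
        thr = float(threshold_otsu(smooth))
    mask = smooth > thr
    if not mask.any():
        return []
    lab = label(mask, connectivity=2)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    mask = np.isin(lab, np.nonzero(sizes >= cfg.min_length_px)[0])
    skel = skeletonize(mask)
    labelled = label(skel, connectivity=2)

    traces: list[FilamentTrace] = []
    fid = 0
    for lab in range(1, labelled.max() + 1):
        component = labelled == lab
        g = _skeleton_graph(component)
        path = _longest_endpoint_path(g, smooth)
        if path is None:
            logger.info("skipping closed-loop or degenerate skeleton component")
            continue
        if len(path) < g.number_of_nodes():
            logger.info(
                "branched skeleton: kept longest path (%d of %d pixels)",
                len(path),
                g.number_of_nodes(),
            )
        xy = np.array([(c, r) for r, c in path], dtype=float)  # (x, y)
        if len(xy) < 3:
            continue
        # smooth the staircase first: end tangents for the tip extension are
        # then stable, and the tips land at the half-max intensity crossing
        fine = _smooth_resample(xy, 0.25)
        if len(fine) < 3:
            continue
        fine = _refine_to_ridge(fine, smooth)
        ridge = float(np.median([smooth[p] for p in path]))
        tip_thr = max(thr, 0.5 * ridge)
        head = _extend_end(fine[::-1], smooth, tip_thr, cfg.end_extension_max_px)
        tail = _extend_end(fine, smooth, tip_thr, cfg.end_extension_max_px)
        xy = np.vstack([head[::-1], fine, tail])
        nodes = _uniform_resample(xy, cfg.node_spacing_px)
        if len(nodes) < 2:
            continue
        length = float(np.sum(np.linalg.norm(np.diff(nodes, axis=0), axis=1)))
        if length < cfg.min_length_px:
            continue
        m = cfg.border_margin_px
        h, w = img.shape
        if (
            nodes[:, 0].min() < m
            or nodes[:, 1].min() < m
            or nodes[:, 0].max() > w - 1 - m
            or nodes[:, 1].max() > h - 1 - m
        ):
            continue
        if tuple(nodes[-1]) < tuple(nodes[0]):
            nodes = nodes[::-1]
        traces.append(
            FilamentTrace(filament_id=fid, frame=frame_index, nodes=nodes, unit="px")
        )
        fid += 1
    return traces


def link_frames(
    per_frame_traces: Sequence[Sequence[FilamentTrace]],
    cfg: TrackingConfig = TrackingConfig(),
) -> list[TrackStack]:
    """Link traces across frames into per-filament stacks.

    Greedy nearest-centroid assignment frame to frame, gated at
    ``max_link_displacement_px``; every trace joins at most one stack.
    Distance ties are broken deterministically towards the smaller track id.
    Stacks with fewer than ``min_frames`` traces are kept but logged.
    """
    tracks: list[list[FilamentTrace]] = []
    last_centroid: list[np.ndarray] = []
    last_frame: list[int] = []

    for traces in per_frame_traces:
        if not traces:
            continue
        frame = traces[0].frame
        centroids = [t.nodes.mean(axis=0) for t in traces]
        candidates = []
        for ti, c in enumerate(centroids):
            for tr in range(len(tracks)):
                d = float(np.linalg.norm(c - last_centroid[tr]))
                if d <= cfg.max_link_displacement_px:
                    candidates.append((d, tr, ti))
        used_tracks: set[int] = set()
        used_traces: set[int] = set()
        # sorting by (distance, track id) makes tie-breaks deterministic
        for d, tr, ti in sorted(candidates, key=lambda c: (c[0], c[1], c[2])):
            if tr in used_tracks or ti in used_traces:
                continue
            used_tracks.add(tr)
            used_traces.add(ti)
            tracks[tr].append(traces[ti])
            last_centroid[tr] = centroids[ti]
            last_frame[tr] = frame
        for ti, t in enumerate(traces):
            if ti not in used_traces:
                tracks.append([t])
                last_centroid.append(centroids[ti])
                last_frame.append(frame)

    stacks = []
    for tid, members in enumerate(tracks):
        import dataclasses

        relabelled = tuple(
            dataclasses.replace(t, filament_id=tid) for t in members
        )
        stack = TrackStack(filament_id=tid, traces=relabelled)
        if stack.n_frames < cfg.min_frames:
            logger.info(
                "track %d spans only %d frames (< %d)", tid, stack.n_frames, cfg.min_frames
            )
        if stack.n_gaps:
            logger.info("track %d has %d frame gap(s)", tid, stack.n_gaps)
        stacks.append(stack)
    return stacks
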