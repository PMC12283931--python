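"""Equilibrium 2D worm-like-chain ensembles and synthetic fluorescence rendering.

The generator draws independent equilibrium shapes of discretised 2D
worm-like chains (WLC) with a known ground-truth persistence length
:math:`L_p`.  A chain is built by integrating a tangent angle whose
increments over each arc step ``ds`` are i.i.d. zero-mean Gaussians with
variance ``ds / Lp``; for Gaussian increments this makes the ensemble
tangent autocorrelation *exactly* ``exp(-s / (2 Lp))``, the decay implied in
two dimensions by

.. math::

    \\langle R^2 \\rangle = 4 L_p^2\\,[\\,2 e^{-L/2L_p} - 2 + L/L_p\\,].

Frames are independent equilibrium draws rather than a temporally correlated
Brownian trajectory: the downstream estimator only assumes thermal
equilibrium shapes, so simulating relaxation dynamics would add parameters
without adding information.

The renderer turns traces into TIRFM-like movies: each filament deposits a
Gaussian point-spread function along its backbone at sub-pixel arc sampling,
on top of a constant background, with Poisson shot noise, Gaussian read
noise and quantisation to 8 or 16 bit, written as a multi-page TIFF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from scipy.ndimage import gaussian_filter

from .traces import FilamentTrace, TrackStack

__all__ = [
    "SyntheticConfig",
    "OpticsConfig",
    "sample_wlc_chain",
    "sample_ensemble",
    "render_frames",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of a synthetic WLC ensemble.

    Parameters
    ----------
    lp_true : float
        Ground-truth persistence length, µm.
    contour_lengths : sequence of float
        Contour lengths, µm.  If shorter than ``n_filaments`` the list is
        cycled; if longer, the first ``n_filaments`` entries are used.
    n_filaments, n_frames : int
        Number of filaments and of independent equilibrium frames each.
    ds : float or None
        Arc-length discretisation step, µm.  ``None`` selects, per filament,
        ``min(0.05, L/200)``, which keeps discretisation error well below the
        fitting tolerance.
    rng_seed : int
        Seed for the single documented random stream of the ensemble.
    field_size : (float, float)
        Width and height of the imaged field, µm; used for placement.
    placement : {"random", "grid"}
        Centroid placement in the field.  "grid" spreads filaments on a
        regular lattice, which keeps them from overlapping in rendered
        test movies.
    """

    lp_true: float
    contour_lengths: tuple[float, ...]
    n_filaments: int
    n_frames: int = 150
    ds: float | None = None
    rng_seed: int = 0
    field_size: tuple[float, float] = (40.0, 40.0)
    placement: str = "random"

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "contour_lengths", tuple(float(L) for L in self.contour_lengths)
        )
        if self.lp_true <= 0:
            raise ValueError("lp_true must be > 0")
        if not self.contour_lengths or any(L <= 0 for L in self.contour_lengths):
            raise ValueError("all contour_lengths must be > 0")
        if self.n_filaments < 1 or self.n_frames < 1:
            raise ValueError("n_filaments and n_frames must be >= 1")
        if self.ds is not None:
            if self.ds <= 0:
                raise ValueError("ds must be > 0")
            if self.ds > min(self.contour_lengths) / 10:
                raise ValueError("ds must be <= min(contour_lengths)/10")
        if self.placement not in ("random", "grid"):
            raise ValueError("placement must be 'random' or 'grid'")
        if len(self.field_size) != 2 or any(s <= 0 for s in self.field_size):
            raise ValueError("field_size must be two positive lengths")

    @classmethod
    def uniform_lengths(
        cls,
        lp_true: float,
        n_filaments: int,
        length_range: tuple[float, float],
        **kwargs,
    ) -> "SyntheticConfig":
        """Config with contour lengths drawn uniformly from *length_range*.

        The draw uses a stream derived from ``rng_seed`` so the ensemble is
        fully reproducible from the one seed.
        """
        seed = int(kwargs.get("rng_seed", 0))
        lo, hi = length_range
        if not 0 < lo <= hi:
            raise ValueError("length_range must satisfy 0 < lo <= hi")
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA11CE]))
        lengths = tuple(rng.uniform(lo, hi, size=n_filaments))
        return cls(
            lp_true=lp_true,
            contour_lengths=lengths,
            n_filaments=n_filaments,
            **kwargs,
        )

    def length_of(self, i: int) -> float:
        """Contour length assigned to filament *i* (cycling the list)."""
        return self.contour_lengths[i % len(self.contour_lengths)]

    def ds_of(self, i: int) -> float:
        if self.ds is not None:
            return self.ds
        return min(0.05, self.length_of(i) / 200.0)


@dataclass(frozen=True)
class OpticsConfig:
    """TIRFM-like rendering parameters.

    Defaults follow a 60x objective with a 16 µm camera pixel
    (0.267 µm/px) and 40 ms frame intervals; both are conventions of the
    synthetic renderer, configurable per dataset.
    """

    pixel_size: float = 0.267  # µm / px
    psf_sigma: float = 1.0  # px
    peak_intensity: float = 200.0  # photons at the ridge of a straight filament
    background: float = 20.0  # photons / px
    read_noise_sd: float = 2.0  # photons
    bit_depth: int = 16
    frame_interval: float = 0.040  # s
    shot_noise: bool = True

    def __post_init__(self) -> None:
        if self.pixel_size <= 0 or self.psf_sigma <= 0:
            raise ValueError("pixel_size and psf_sigma must be > 0")
        if min(self.peak_intensity, self.background, self.read_noise_sd) < 0:
            raise ValueError("intensities and noise levels must be >= 0")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")

    @property
    def dtype(self) -> np.dtype:
        return np.dtype(np.uint8 if self.bit_depth == 8 else np.uint16)

    @property
    def max_count(self) -> int:
        return 2**self.bit_depth - 1


def sample_wlc_chain(
    lp: float,
    contour_length: float,
    ds: float,
    rng: np.random.Generator,
    filament_id: int | str = 0,
    frame: int = 0,
) -> FilamentTrace:
    """Draw one equilibrium 2D worm-like chain shape.

    The chain has ``floor(contour_length/ds)`` segments of length *ds*
    (polyline contour within one *ds* of the request), a uniformly random
    initial tangent direction, Gaussian tangent-angle increments of variance
    ``ds/lp``, and is centred on its centroid.

    Returns a :class:`FilamentTrace` with coordinates in µm.
    """
    if lp <= 0 or contour_length <= 0 or ds <= 0:
        raise ValueError("lp, contour_length and ds must all be > 0")
    if ds >= contour_length:
        raise ValueError("ds must be smaller than contour_length")
    n_seg = int(np.floor(contour_length / ds))
    theta0 = rng.uniform(0.0, 2.0 * np.pi)
    dtheta = rng.normal(0.0, np.sqrt(ds / lp), size=n_seg - 1)
    theta = theta0 + np.concatenate([[0.0], np.cumsum(dtheta)])
    steps = ds * np.column_stack([np.cos(theta), np.sin(theta)])
    nodes = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    nodes -= nodes.mean(axis=0)
    return FilamentTrace(filament_id=filament_id, frame=frame, nodes=nodes, unit="um")


def _place_in_field(
    nodes: np.ndarray,
    field_size: tuple[float, float],
    rng: np.random.Generator,
    centre: np.ndarray | None = None,
    max_tries: int = 50,
) -> np.ndarray:
    """Translate a centred chain into the field, redrawing the position if
    more than 10% of nodes fall outside (shape preserved)."""
    w, h = field_size
    best = None
    for _ in range(max_tries):
        c = rng.uniform([0.0, 0.0], [w, h]) if centre is None else centre
        placed = nodes + c
        outside = np.mean(
            (placed[:, 0] < 0) | (placed[:, 0] > w) | (placed[:, 1] < 0) | (placed[:, 1] > h)
        )
        if best is None or outside < best[0]:
            best = (outside, placed)
        if outside <= 0.10:
            return placed
        if centre is not None:
            break  # fixed centre: nothing to redraw
    return best[1]


def sample_ensemble(config: SyntheticConfig) -> list[TrackStack]:
    """Sample the full filament ensemble described by *config*.

    Each filament gets ``n_frames`` independent equilibrium chains of its
    assigned contour length, placed in the field.  Fully reproducible from
    ``config.rng_seed``.
    """
    rng = np.random.default_rng(config.rng_seed)
    w, h = config.field_size
    if config.placement == "grid":
        n_side = int(np.ceil(np.sqrt(config.n_filaments)))
        xs = (np.arange(n_side) + 0.5) * (w / n_side)
        ys = (np.arange(n_side) + 0.5) * (h / n_side)
        centres = [
            np.array([xs[i % n_side], ys[i // n_side]])
            for i in range(config.n_filaments)
        ]
    else:
        centres = [None] * config.n_filaments

    stacks = []
    for i in range(config.n_filaments):
        L, ds = config.length_of(i), config.ds_of(i)
        traces = []
        for fr in range(config.n_frames):
            chain = sample_wlc_chain(
                config.lp_true, L, ds, rng, filament_id=i, frame=fr
            )
            placed = _place_in_field(chain.nodes, config.field_size, rng, centres[i])
            traces.append(chain.with_nodes(placed))
        stacks.append(TrackStack(filament_id=i, traces=tuple(traces)))
    return stacks


def _deposit_trace(
    canvas: np.ndarray, trace: FilamentTrace, pixel_size: float
) -> bool:
    """Accumulate unit line density along a trace polyline, bilinearly, at
    0.25 px arc sampling.  Returns True if any sample was clipped."""
    h, w = canvas.shape
    nodes_px = trace.nodes / pixel_size
    arc = trace.arc_positions / pixel_size
    step = 0.25
    n_samples = max(int(np.ceil(arc[-1] / step)), 2)
    s = np.linspace(0.0, arc[-1], n_samples)
    x = np.interp(s, arc, nodes_px[:, 0])
    y = np.interp(s, arc, nodes_px[:, 1])
    mass = arc[-1] / n_samples  # px of arc length carried by each sample

    inside = (x >= 0) & (x <= w - 1) & (y >= 0) & (y <= h - 1)
    clipped = not bool(inside.all())
    x, y = x[inside], y[inside]
    if x.size == 0:
        return clipped
    x0, y0 = np.floor(x).astype(int), np.floor(y).astype(int)
    fx, fy = x - x0, y - y0
    x1, y1 = np.minimum(x0 + 1, w - 1), np.minimum(y0 + 1, h - 1)
    np.add.at(canvas, (y0, x0), mass * (1 - fx) * (1 - fy))
    np.add.at(canvas, (y0, x1), mass * fx * (1 - fy))
    np.add.at(canvas, (y1, x0), mass * (1 - fx) * fy)
    np.add.at(canvas, (y1, x1), mass * fx * fy)
    return clipped


def render_frames(
    stacks: Sequence[TrackStack],
    optics: OpticsConfig,
    rng: np.random.Generator,
    field_size: tuple[float, float] | None = None,
    out: str | Path | None = None,
) -> np.ndarray:
    """Render TrackStacks into a noisy fluorescence image stack.

    Parameters
    ----------
    stacks : sequence of TrackStack
        Traces with coordinates in µm.
    optics : OpticsConfig
    rng : numpy Generator
        Noise stream.
    field_size : (width, height) in µm, optional
        Defaults to the bounding box of all traces plus a 2 µm margin.
    out : path, optional
        If given, the stack is also written as a multi-page TIFF.

    Returns
    -------
    ndarray, shape (n_frames, height, width)
        Quantised image stack (uint8 or uint16 per ``optics.bit_depth``).
    """
    all_traces = [t for s in stacks for t in s.traces]
    if not all_traces:
        raise ValueError("no traces to render")
    if any(t.unit != "um" for t in all_traces):
        raise ValueError("render_frames requires traces in µm")
    if field_size is None:
        pts = np.vstack([t.nodes for t in all_traces])
        field_size = (pts[:, 0].max() + 2.0, pts[:, 1].max() + 2.0)
    w_px = int(np.ceil(field_size[0] / optics.pixel_size))
    h_px = int(np.ceil(field_size[1] / optics.pixel_size))

    frames = sorted({t.frame for t in all_traces})
    by_frame: dict[int, list[FilamentTrace]] = {f: [] for f in frames}
    for t in all_traces:
        by_frame[t.frame].append(t)

    # unit line density smoothed by the PSF gives a straight-filament ridge
    # of 1/(sqrt(2*pi)*sigma); rescale so the ridge peaks at peak_intensity
    ridge_gain = optics.peak_intensity * np.sqrt(2.0 * np.pi) * optics.psf_sigma

    stack = np.empty((len(frames), h_px, w_px), dtype=optics.dtype)
    any_clipped = False
    for k, f in enumerate(frames):
        canvas = np.zeros((h_px, w_px), dtype=float)
        for t in by_frame[f]:
            any_clipped |= _deposit_trace(canvas, t, optics.pixel_size)
        signal = gaussian_filter(canvas, optics.psf_sigma) * ridge_gain
        photons = signal + optics.background
        if optics.shot_noise:
            photons = rng.poisson(photons).astype(float)
        if optics.read_noise_sd > 0:
            photons = photons + rng.normal(0.0, optics.read_noise_sd, photons.shape)
        stack[k] = np.clip(np.rint(photons), 0, optics.max_count).astype(optics.dtype)
    if any_clipped:
        warnings.warn("some filament nodes fell outside the field and were clipped")
    if out is not None:
        tifffile.imwrite(out, stack, photometric="minisblack")
    return stack
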