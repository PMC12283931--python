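"""Persistence-length estimation from thermal shape fluctuations.

A filament confined to two dimensions and fluctuating thermally behaves as a
worm-like chain: its contour length :math:`L` and mean-square end-to-end
distance :math:`\\langle R^2 \\rangle` are related through

.. math::

    \\langle R^2 \\rangle
        = 4 L_p^2 \\left[ 2 e^{-L/2L_p} - 2 + L/L_p \\right],

where :math:`L_p` is the persistence length — the arc length over which the
tangent direction decorrelates (in 2D the tangent autocorrelation is
``exp(-s/(2 Lp))``; the relation above is its double integral over the
contour).  Each filament contributes one ``(L, <R^2>)`` point, obtained by
averaging over 100–200 independent movie frames, and :math:`L_p` is
estimated by nonlinear least squares over the pooled points.

The module exposes the per-trace geometry (contour length, end-to-end
distance), the per-filament averaging, the closed-form model, a
statsmodels-style :class:`PersistenceLengthModel` whose ``fit`` returns a
:class:`WLCFit` results object, and an independent tangent-correlation
estimator used as a cross-check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .traces import FilamentTrace, TrackStack

__all__ = [
    "MechanicsPoint",
    "WLCFit",
    "TangentCorrelationFit",
    "PersistenceLengthModel",
    "contour_length",
    "end_to_end",
    "mean_square_R",
    "wlc_msR",
    "fit_persistence_length",
    "tangent_correlation_lp",
]


def contour_length(trace: FilamentTrace) -> float:
    """Contour length of a trace: summed node-to-node Euclidean distances.

    Returned in the trace's own unit.
    """
    return float(trace.arc_positions[-1])


def end_to_end(trace: FilamentTrace) -> float:
    """Straight-line distance between the first and last node."""
    return float(np.linalg.norm(trace.nodes[-1] - trace.nodes[0]))


@dataclass(frozen=True)
class MechanicsPoint:
    """One filament's datum for the worm-like-chain fit.

    ``L`` is the mean per-frame contour length (µm), ``msR`` the mean over
    frames of the squared end-to-end distance (µm²), ``sd_R2`` the sample SD
    of R² across frames.
    """

    filament_id: int | str
    L: float
    msR: float
    n_frames: int
    sd_R2: float = float("nan")

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ValueError("L must be > 0")
        if not 0.0 <= self.msR <= self.L**2 * (1 + 1e-9):
            raise ValueError("msR must lie in [0, L^2]")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


def mean_square_R(stack: TrackStack, pixel_size: float | None = None) -> MechanicsPoint:
    """Collapse a TrackStack to one (L, ⟨R²⟩) point.

    ``msR`` is the mean over frames of the squared end-to-end distance and
    ``L`` the mean over frames of the contour length.  Traces in pixels are
    converted to µm via *pixel_size*.  Warns when the frame count is outside
    the 100–200 range over which the averaging is designed to run.
    """
    if stack.n_frames < 1:
        raise ValueError("empty stack")
    scale = 1.0
    if stack.unit == "px":
        if pixel_size is None:
            raise ValueError("pixel_size required to convert px traces to µm")
        scale = pixel_size
    Ls = np.array([contour_length(t) for t in stack.traces]) * scale
    R2 = (np.array([end_to_end(t) for t in stack.traces]) * scale) ** 2
    n = stack.n_frames
    if n < 100 or n > 200:
        warnings.warn(
            f"filament {stack.filament_id!r}: <R^2> averaged over {n} frames "
            "(designed range is 100-200)"
        )
    sd = float(np.std(R2, ddof=1)) if n > 1 else float("nan")
    return MechanicsPoint(
        filament_id=stack.filament_id,
        L=float(Ls.mean()),
        msR=float(R2.mean()),
        n_frames=n,
        sd_R2=sd,
    )


def wlc_msR(L, lp: float):
    """Mean-square end-to-end distance of a 2D worm-like chain.

    ``4*lp**2 * (2*exp(-L/(2*lp)) - 2 + L/lp)``, evaluated stably: for
    ``L/lp < 1e-6`` the series ``L**2 - L**3/(6*lp)`` is used to avoid
    catastrophic cancellation.  Vectorised over ``L``.
    """
    if lp <= 0:
        raise ValueError("lp must be > 0")
    L = np.asarray(L, dtype=float)
    if np.any(L < 0):
        raise ValueError("L must be >= 0")
    x = L / (2.0 * lp)
    small = x < 5e-7
    # 8*lp^2*(expm1(-x) + x) == closed form; expm1 keeps mid-range x accurate
    out = 8.0 * lp**2 * (np.expm1(-x) + x)
    if np.any(small):
        Ls = L[small] if L.ndim else L
        series = Ls**2 - Ls**3 / (6.0 * lp)
        if L.ndim:
            out[small] = series
        else:
            out = series
    return out if L.ndim else float(out)


@dataclass
class WLCFit:
    """Persistence-length fit results.

    Attributes
    ----------
    lp_hat, lp_se : float
        Estimate and standard error of the persistence length, µm.
    n_points : int
        Number of (L, ⟨R²⟩) points fitted.
    residual_norm : float
        Euclidean norm of the fit residuals, µm².
    converged : bool
    beyond_support : bool
        True when ``lp_hat`` exceeds 10x the longest filament, i.e. the data
        barely bend over their length and the estimate is extrapolated.
    """

    lp_hat: float
    lp_se: float
    n_points: int
    residual_norm: float
    converged: bool
    beyond_support: bool = False
    model: "PersistenceLengthModel | None" = None

    def predict(self, L) -> np.ndarray:
        """Model ⟨R²⟩ at contour lengths *L* for the fitted Lp."""
        return wlc_msR(L, self.lp_hat)

    def summary(self) -> str:
        lines = [
            "Worm-like-chain persistence length fit",
            "=" * 42,
            f"  Lp estimate        {self.lp_hat:12.4f} µm",
            f"  Lp standard error  {self.lp_se:12.4f} µm",
            f"  n points           {self.n_points:12d}",
            f"  residual norm      {self.residual_norm:12.4g} µm²",
            f"  converged          {str(self.converged):>12s}",
        ]
        if self.beyond_support:
            lines.append("  warning: Lp exceeds 10x the longest filament; the")
            lines.append("  data provide only a lower bound at this stiffness")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Scatter of the fitted points with the model curve overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if self.model is not None:
            ax.plot(self.model.L, self.model.msR, "o", mfc="none", label="filaments")
            grid = np.linspace(0, self.model.L.max() * 1.05, 200)
            ax.plot(grid, self.predict(grid), "-", label=f"WLC fit, Lp={self.lp_hat:.1f} µm")
        ax.set_xlabel("contour length L (µm)")
        ax.set_ylabel(r"$\langle R^2 \rangle$ (µm$^2$)")
        ax.legend()
        return ax


class PersistenceLengthModel:
    """Worm-like-chain model for pooled per-filament (L, ⟨R²⟩) points.

    Parameters
    ----------
    L, msR : array-like
        Per-filament mean contour length (µm) and mean-square end-to-end
        distance (µm²).
    weights_sd : array-like, optional
        Per-point standard deviations used only when fitting with
        ``weighted=True`` (typically ``sd_R2/sqrt(n_frames)``).
    """

    def __init__(self, L, msR, weights_sd=None):
        L = np.asarray(L, dtype=float)
        msR = np.asarray(msR, dtype=float)
        if L.shape != msR.shape or L.ndim != 1:
            raise ValueError("L and msR must be 1-D arrays of equal length")
        if L.size < 2:
            raise ValueError("need at least 2 points to fit Lp")
        if np.unique(L).size < 2:
            raise ValueError("all contour lengths identical: Lp is not identifiable")
        bad = msR > L**2 * (1 + 1e-9)
        if np.any(bad):
            raise ValueError(
                f"{int(bad.sum())} point(s) with msR > L^2 rejected: the "
                "mean-square end-to-end distance cannot exceed the squared "
                "contour length"
            )
        self.L, self.msR = L, msR
        self.weights_sd = None if weights_sd is None else np.asarray(weights_sd, float)

    @classmethod
    def from_points(cls, points: Sequence[MechanicsPoint]) -> "PersistenceLengthModel":
        L = [p.L for p in points]
        msR = [p.msR for p in points]
        sd = [
            p.sd_R2 / np.sqrt(p.n_frames) if np.isfinite(p.sd_R2) else np.nan
            for p in points
        ]
        w = None if np.any(np.isnan(sd)) else sd
        return cls(L, msR, weights_sd=w)

    @classmethod
    def from_stacks(
        cls, stacks: Sequence[TrackStack], pixel_size: float | None = None
    ) -> "PersistenceLengthModel":
        return cls.from_points([mean_square_R(s, pixel_size) for s in stacks])

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, length_col: str = "L", msr_col: str = "msR"
    ) -> "PersistenceLengthModel":
        return cls(df[length_col].to_numpy(), df[msr_col].to_numpy())

    def fit(self, weighted: bool = False, p0: float | None = None) -> WLCFit:
        """Nonlinear least-squares estimate of the persistence length.

        Unweighted by default; ``weighted=True`` uses ``weights_sd`` as
        per-point sigmas.  The initial guess is the floppy-limit moment
        estimator ``median(msR / 4L)`` clamped positive.  Non-convergence is
        reported through ``converged=False`` rather than raised.
        """
        if p0 is None:
            p0 = float(np.median(self.msR / (4.0 * self.L)))
        p0 = max(p0, 1e-6)
        sigma = None
        if weighted:
            if self.weights_sd is None:
                raise ValueError("weighted fit requested but no weights available")
            sigma = np.maximum(self.weights_sd, 1e-12)
        try:
            popt, pcov = curve_fit(
                wlc_msR,
                self.L,
                self.msR,
                p0=[p0],
                sigma=sigma,
                bounds=(1e-12, np.inf),
                maxfev=20000,
            )
            lp_hat = float(popt[0])
            lp_se = float(np.sqrt(pcov[0, 0]))
            converged = bool(np.isfinite(lp_hat) and np.isfinite(lp_se))
        except RuntimeError:
            return WLCFit(
                lp_hat=float("nan"),
                lp_se=float("nan"),
                n_points=self.L.size,
                residual_norm=float("nan"),
                converged=False,
                model=self,
            )
        resid = self.msR - wlc_msR(self.L, lp_hat)
        return WLCFit(
            lp_hat=lp_hat,
            lp_se=lp_se,
            n_points=self.L.size,
            residual_norm=float(np.linalg.norm(resid)),
            converged=converged,
            beyond_support=lp_hat > 10.0 * float(self.L.max()),
            model=self,
        )


def fit_persistence_length(
    points: Sequence[MechanicsPoint], weighted: bool = False
) -> WLCFit:
    """Fit the 2D worm-like-chain relation to pooled per-filament points."""
    return PersistenceLengthModel.from_points(points).fit(weighted=weighted)


@dataclass(frozen=True)
class TangentCorrelationFit:
    """Persistence length from the tangent autocorrelation decay.

    ``decay_length`` is the fitted arc-length constant of
    ``<cos(theta(s+d)-theta(s))> = exp(-d/decay_length)``; in 2D the
    persistence length is half of it.  ``lower_bound`` is set when the
    correlation barely decays over the available arc lengths, in which case
    ``lp_hat`` is only a lower bound.
    """

    lp_hat: float
    decay_length: float
    n_pairs: int
    lower_bound: bool = False


def tangent_correlation_lp(
    stacks: Sequence[TrackStack],
    pixel_size: float | None = None,
    max_lags: int = 200,
) -> TangentCorrelationFit:
    """Estimate Lp from the pooled tangent autocorrelation.

    For every trace the segment tangent angles are computed; the mean cosine
    of the angle difference is pooled over all node pairs at each arc-length
    separation (across frames and filaments) and a single-exponential decay
    is fitted, returning half the decay length.  Serves as an estimator
    independent of the end-to-end-distance fit.
    """
    # group traces by (node count, spacing) so each group is a matrix and
    # every lag needs only one vectorised pass
    groups: dict[tuple[int, float], list[np.ndarray]] = {}
    for stack in stacks:
        scale = 1.0
        if stack.unit == "px":
            if pixel_size is None:
                raise ValueError("pixel_size required for px traces")
            scale = pixel_size
        for t in stack.traces:
            if t.n_nodes < 10:
                continue
            seg = np.diff(t.nodes, axis=0)
            theta = np.arctan2(seg[:, 1], seg[:, 0])
            ds = float(np.median(np.linalg.norm(seg, axis=1))) * scale
            groups.setdefault((theta.size, round(ds, 6)), []).append(theta)
    if not groups:
        raise ValueError("no traces with >= 10 nodes: insufficient pairs")
    corr_sums: dict[float, tuple[float, int]] = {}
    for (m, ds), thetas in groups.items():
        theta_mat = np.vstack(thetas)
        for k in range(1, min(m, max_lags + 1)):
            diff = theta_mat[:, k:] - theta_mat[:, :-k]
            c = float(np.cos(diff).sum())
            n = diff.size
            key = round(k * ds, 6)
            s0, n0 = corr_sums.get(key, (0.0, 0))
            corr_sums[key] = (s0 + c, n0 + n)
    lags = np.array(sorted(corr_sums))
    corr = np.array([corr_sums[k][0] / corr_sums[k][1] for k in lags])
    n_pairs = int(sum(n for _, n in corr_sums.values()))

    # log-linear fit over the initial decay only (correlation > 1/e):
    # large-separation points are few, noisy and log-biased
    usable = corr > np.exp(-1.0)
    if usable.sum() < 2:
        usable = corr > 0.05
    if usable.sum() < 2:
        raise ValueError("tangent correlation decays too fast for a fit")
    ll, cc = lags[usable], np.log(corr[usable])
    slope = float(np.sum(ll * cc) / np.sum(ll * ll))  # through the origin
    if slope >= -1e-12:
        return TangentCorrelationFit(
            lp_hat=float("inf"),
            decay_length=float("inf"),
            n_pairs=n_pairs,
            lower_bound=True,
        )
    decay = -1.0 / slope
    lower = decay > 10.0 * float(lags.max())
    return TangentCorrelationFit(
        lp_hat=decay / 2.0, decay_length=decay, n_pairs=n_pairs, lower_bound=lower
    )
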