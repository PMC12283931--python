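"""Tube-length morphometry and two-sample comparison.

Tube lengths are measured from manually traced closed outlines as half the
outline perimeter: a thin loop hugging both edges of a tube has perimeter
close to twice its length (the width contribution is not corrected).  Each
condition keeps its N longest tubes (N = 150 in the published procedure),
and conditions are compared with a two-sided Welch's t test on the raw
lengths — no multiple-testing correction is applied, matching how the
pairwise comparisons were reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import LineString

__all__ = [
    "TubeOutline",
    "LengthSample",
    "WelchResult",
    "half_perimeter_length",
    "select_longest",
    "welch_t_test",
    "read_outline_table",
]

OUTLINE_COLUMNS = ["outline_id", "vertex_index", "x", "y", "unit"]


@dataclass(frozen=True)
class TubeOutline:
    """Closed polygon traced around one tube.

    The polygon is implicitly closed: the edge from the last vertex back to
    the first is always included (a repeated first vertex is dropped).
    """

    outline_id: int | str
    vertices: np.ndarray
    unit: str = "um"

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array")
        if v.shape[0] >= 2 and np.allclose(v[0], v[-1]):
            v = v[:-1]
        if v.shape[0] < 3:
            raise ValueError("an outline needs at least 3 distinct vertices")
        object.__setattr__(self, "vertices", v)


@dataclass(frozen=True)
class LengthSample:
    """Lengths retained for one experimental condition, longest first."""

    condition_label: str
    lengths: np.ndarray
    n_selected: int

    def __post_init__(self) -> None:
        lengths = np.asarray(self.lengths, dtype=float)
        if self.n_selected > lengths.size:
            raise ValueError("n_selected cannot exceed the number of lengths")
        object.__setattr__(self, "lengths", lengths)


def half_perimeter_length(outline: TubeOutline) -> float:
    """Tube length as half the perimeter of its closed outline.

    A self-intersecting outline triggers a warning but still yields a value.
    """
    v = outline.vertices
    closed = np.vstack([v, v[:1]])
    if not LineString(closed).is_simple:
        warnings.warn(
            f"outline {outline.outline_id!r} is self-intersecting; "
            "half-perimeter may not reflect the tube length"
        )
    perimeter = float(np.sum(np.linalg.norm(np.diff(closed, axis=0), axis=1)))
    return perimeter / 2.0


def select_longest(
    lengths: Sequence[float], n: int = 150, condition_label: str = ""
) -> LengthSample:
    """Keep the *n* largest lengths (ties resolved by stable input order).

    When fewer than *n* lengths are supplied, all are kept with a warning —
    the selection is part of the published morphometry procedure, so a
    short sample is worth flagging.
    """
    lengths = np.asarray(list(lengths), dtype=float)
    if lengths.size == 0:
        raise ValueError("select_longest needs at least one length")
    if n < 1:
        raise ValueError("n must be >= 1")
    if n >= lengths.size:
        if n > lengths.size:
            warnings.warn(
                f"only {lengths.size} lengths available; keeping all (requested {n})"
            )
        n = lengths.size
    # stable sort on negated values keeps tied inputs in original order
    order = np.argsort(-lengths, kind="stable")[:n]
    return LengthSample(
        condition_label=condition_label, lengths=lengths[order], n_selected=n
    )


class WelchResult(NamedTuple):
    t: float
    df: float
    p: float


def welch_t_test(a: LengthSample, b: LengthSample) -> WelchResult:
    """Two-sided Welch's t test between two length samples.

    Returns the Welch statistic, Welch–Satterthwaite degrees of freedom and
    the two-sided p value.  When both samples have zero variance and equal
    means the comparison is vacuous and ``(t=0, df=nan, p=1)`` is returned
    with a warning; zero variance in any other configuration is an error.
    """
    xa, xb = np.asarray(a.lengths, float), np.asarray(b.lengths, float)
    if xa.size < 2 or xb.size < 2:
        raise ValueError("each sample needs at least 2 values")
    va, vb = xa.var(ddof=1), xb.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if xa.mean() == xb.mean():
            warnings.warn("both samples constant and equal; p = 1 by convention")
            return WelchResult(t=0.0, df=float("nan"), p=1.0)
        raise ValueError("zero variance in both samples with unequal means")
    if va == 0.0 or vb == 0.0:
        raise ValueError("zero variance in one sample: Welch's test undefined")
    res = stats.ttest_ind(xa, xb, equal_var=False)
    return WelchResult(t=float(res.statistic), df=float(res.df), p=float(res.pvalue))


def read_outline_table(path: str | Path) -> list[TubeOutline]:
    """Read a tab-separated polygon vertex table into TubeOutlines."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(OUTLINE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"outline table missing columns: {sorted(missing)}")
    outlines = []
    for oid, group in df.groupby("outline_id", sort=True):
        group = group.sort_values("vertex_index")
        outlines.append(
            TubeOutline(
                outline_id=oid,
                vertices=group[["x", "y"]].to_numpy(float),
                unit=str(group["unit"].iloc[0]),
            )
        )
    return outlines
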