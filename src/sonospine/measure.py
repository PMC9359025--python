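"""Spinous process angle (SPA) measurement and validation statistics.

The SPA is a scoliosis severity proxy read off the coronal spine image:
the spinous processes appear as a dark shadowed profile down the middle
of the image, and the angle between lines placed along the most-tilted
regions of that profile quantifies the curve.  Clinically the lines are
drawn by an observer; :func:`extract_spa_auto` automates the placement
(darkest-trough centerline, tangent-angle extrema) so that the whole
pipeline can be tested closed-loop against phantoms with known angles.

Validation statistics follow repeatability-study practice: intraclass
correlation (two-way random effects, absolute agreement, single measures
— ICC(2,1)) with Currier reliability bands, and a linear correlation
between measurement methods fitted through the origin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Literal, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sstats
from scipy.ndimage import uniform_filter1d

__all__ = [
    "SpaLine",
    "SpaMeasurement",
    "IccResult",
    "RegressionResult",
    "GeometryError",
    "DetectionError",
    "UndefinedIccError",
    "compute_spa",
    "extract_spa_auto",
    "icc",
    "regression_through_origin",
]


class GeometryError(ValueError):
    """Degenerate line geometry (zero-length line)."""


class DetectionError(RuntimeError):
    """No usable spinous-process centerline found in the image."""


class UndefinedIccError(ValueError):
    """ICC undefined (zero between-subject variance)."""


@dataclass(frozen=True)
class SpaLine:
    """A measurement line given by two distinct endpoints (x, y)."""

    x1: float
    y1: float
    x2: float
    y2: float

    def direction(self) -> np.ndarray:
        d = np.array([self.x2 - self.x1, self.y2 - self.y1], dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise GeometryError("SPA line endpoints coincide")
        return d / n


@dataclass(frozen=True)
class SpaMeasurement:
    """Two or three lines and the angle(s) between adjacent pairs."""

    lines: Tuple[SpaLine, ...]
    angles: Tuple[float, ...]  # degrees

    def __post_init__(self) -> None:
        if len(self.lines) not in (2, 3):
            raise ValueError("a SPA measurement uses 2 or 3 lines")
        if len(self.angles) != len(self.lines) - 1:
            raise ValueError("expected one angle per adjacent line pair")

    @property
    def spa(self) -> float:
        """The principal (largest) angle, degrees."""
        return max(self.angles)


def compute_spa(line_a: SpaLine, line_b: SpaLine) -> float:
    """Unsigned acute angle between two lines, degrees in [0, 90].

    Cobb-style convention: line direction sign is irrelevant, so the
    result is invariant under swapping endpoints, global rotation,
    translation, and uniform scaling.
    """
    da, db = line_a.direction(), line_b.direction()
    dot = float(np.dot(da, db))
    cross = float(da[0] * db[1] - da[1] * db[0])
    # atan2 form is numerically exact near 0 and 90 degrees
    return math.degrees(math.atan2(abs(cross), abs(dot)))


# ---------------------------------------------------------------------------
# Automatic SPA extraction
# ---------------------------------------------------------------------------

def _trough_centerline(
    image: np.ndarray,
    min_contrast: float,
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-row dark-trough position (darkness-weighted centroid), sub-pixel.

    Rows without a trough at least ``min_contrast`` grey levels below the
    row median, or with too few valid pixels, are skipped.
    """
    img = np.asarray(image, dtype=float)
    rows_out: List[int] = []
    cols_out: List[float] = []
    for r in range(img.shape[0]):
        row = img[r]
        valid = row > 0  # contrast-adjusted empties render as 0
        if valid.sum() < 8:
            continue
        vals = row[valid]
        med = np.median(vals)
        depth = med - vals  # darkness relative to local background
        if depth.max() < min_contrast:
            continue
        w = np.clip(depth - 0.5 * depth.max(), 0.0, None) ** 2
        if w.sum() == 0:
            continue
        cols = np.nonzero(valid)[0].astype(float)
        rows_out.append(r)
        cols_out.append(float(np.sum(cols * w) / np.sum(w)))
    return np.asarray(rows_out), np.asarray(cols_out)


def _local_slope(z: np.ndarray, x: np.ndarray, i: int, half: int) -> Tuple[float, float]:
    """Least-squares slope dx/dz and intercept over a window around i."""
    lo, hi = max(0, i - half), min(len(z), i + half + 1)
    p = np.polyfit(z[lo:hi], x[lo:hi], 1)
    return float(p[0]), float(p[1])


def _line_at(z: np.ndarray, x: np.ndarray, i: int, half: int) -> SpaLine:
    slope, icpt = _local_slope(z, x, i, half)
    lo, hi = max(0, i - half), min(len(z) - 1, i + half)
    return SpaLine(
        x1=slope * z[lo] + icpt, y1=float(z[lo]),
        x2=slope * z[hi] + icpt, y2=float(z[hi]),
    )


def extract_spa_auto(
    image: np.ndarray,
    spacing_x: float = 1.0,
    spacing_y: float = 1.0,
    curves: int = 1,
    smooth_window: int = 15,
    min_contrast: float = 8.0,
    fit_half_window: int = 8,
) -> SpaMeasurement:
    """Measure the SPA automatically from a rendered coronal image.

    The dark spinous-process profile is traced row by row (darkness-
    weighted trough centroid), smoothed (moving average over
    ``smooth_window`` rows), and its tangent angle computed from local
    line fits.  Lines are placed at the tangent-angle extrema: two lines
    for a single curve, three (one per alternating extremum) when
    ``curves=2``.

    ``spacing_x``/``spacing_y`` convert columns/rows to mm so angles are
    correct for anisotropic grids.  Raises :class:`DetectionError` when no
    contiguous dark centerline is found.
    """
    if curves not in (1, 2):
        raise ValueError("curves must be 1 or 2")
    rows, cols = _trough_centerline(image, min_contrast)
    if rows.size < max(4 * fit_half_window, 20):
        raise DetectionError("no usable spinous-process centerline detected")

    z = rows * spacing_y
    x = uniform_filter1d(cols * spacing_x, size=max(3, smooth_window), mode="nearest")

    n = len(z)
    half = fit_half_window
    idx = np.arange(half, n - half) if n > 2 * half else np.arange(n)
    theta = np.array(
        [math.degrees(math.atan(_local_slope(z, x, i, half)[0])) for i in idx]
    )
    theta_s = uniform_filter1d(theta, size=max(3, smooth_window // 2), mode="nearest")

    if curves == 1:
        i_max = idx[int(np.argmax(theta_s))]
        i_min = idx[int(np.argmin(theta_s))]
        first, second = sorted((i_max, i_min))
        lines = (_line_at(z, x, first, half), _line_at(z, x, second, half))
        return SpaMeasurement(lines=lines, angles=(compute_spa(*lines),))

    # two curves: three alternating tangent extrema ordered along the spine
    picks = _alternating_extrema(theta_s, idx)
    lines = tuple(_line_at(z, x, i, half) for i in picks)
    angles = tuple(
        compute_spa(lines[j], lines[j + 1]) for j in range(len(lines) - 1)
    )
    return SpaMeasurement(lines=lines, angles=angles)


def _alternating_extrema(theta: np.ndarray, idx: np.ndarray) -> List[int]:
    """Three alternating extremum indices for a double-curve profile."""
    n = len(theta)
    cand: List[Tuple[float, int]] = []
    for i in range(n):
        lo, hi = max(0, i - 5), min(n, i + 6)
        if theta[i] == theta[lo:hi].max() or theta[i] == theta[lo:hi].min():
            cand.append((theta[i], int(idx[i])))
    if len(cand) < 3:
        # fall back to the ends and the global opposite extremum
        mid = int(idx[int(np.argmin(theta))]) if theta[0] > np.median(theta) else int(
            idx[int(np.argmax(theta))]
        )
        return sorted({int(idx[0]), mid, int(idx[-1])})
    # strongest extremum, then the best opposite-sign ones before/after it
    cand.sort(key=lambda t: -abs(t[0]))
    base_val, base_i = cand[0]
    before = [c for c in cand if c[1] < base_i and np.sign(c[0]) != np.sign(base_val)]
    after = [c for c in cand if c[1] > base_i and np.sign(c[0]) != np.sign(base_val)]
    picks = [base_i]
    if before:
        picks.append(max(before, key=lambda t: abs(t[0]))[1])
    if after:
        picks.append(max(after, key=lambda t: abs(t[0]))[1])
    while len(picks) < 3:
        extra = [c[1] for c in cand if c[1] not in picks]
        if not extra:
            break
        picks.append(extra[0])
    return sorted(picks[:3])


# ---------------------------------------------------------------------------
# Repeatability and agreement statistics
# ---------------------------------------------------------------------------

RELIABILITY_BANDS = (
    (0.80, "very reliable"),
    (0.60, "moderately reliable"),
    (-np.inf, "questionably reliable"),
)


def reliability_label(icc_value: float) -> str:
    """Currier reliability band of an ICC value (0.80 / 0.60 cut points)."""
    for cut, label in RELIABILITY_BANDS:
        if icc_value >= cut:
            return label
    return RELIABILITY_BANDS[-1][1]  # pragma: no cover


@dataclass(frozen=True)
class IccResult:
    value: float
    label: str
    form: str
    ci95: Tuple[float, float]


def icc(table, form: str = "ICC2") -> IccResult:
    """Intraclass correlation of a subjects x raters table.

    Default form is ICC(2,1): two-way random effects, absolute agreement,
    single measures — the standard choice for method-repeatability
    studies.  Requires a complete table with >= 2 subjects and >= 2
    raters; zero between-subject variance makes the coefficient
    undefined and raises :class:`UndefinedIccError`.
    """
    import pingouin as pg

    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("rater table must be 2-D with >= 2 subjects and >= 2 raters")
    if np.isnan(arr).any():
        raise ValueError("rater table must have no missing cells")
    if np.ptp(arr.mean(axis=1)) == 0:
        raise UndefinedIccError("zero between-subject variance: ICC undefined")

    n_subj, n_raters = arr.shape
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n_subj), n_raters),
            "rater": np.tile(np.arange(n_raters), n_subj),
            "score": arr.ravel(),
        }
    )
    res = pg.intraclass_corr(
        data=long, targets="subject", raters="rater", ratings="score"
    )
    # pingouin labels the two-way-random absolute-agreement single-measure
    # form ICC(A,1) (a.k.a. ICC(2,1)); accept either spelling
    aliases = {
        "ICC1": "ICC(1,1)", "ICC2": "ICC(A,1)", "ICC3": "ICC(C,1)",
        "ICC(2,1)": "ICC(A,1)", "ICC(3,1)": "ICC(C,1)",
    }
    wanted = aliases.get(form, form)
    row = res[res["Type"] == wanted]
    if row.empty:
        raise ValueError(f"unknown ICC form {form!r}")
    value = float(row["ICC"].iloc[0])
    ci_col = "CI95%" if "CI95%" in row.columns else "CI95"
    ci = row[ci_col].iloc[0]
    if not np.isfinite(value):
        raise UndefinedIccError("ICC evaluation produced a non-finite value")
    return IccResult(
        value=value,
        label=reliability_label(value),
        form=form,
        ci95=(float(ci[0]), float(ci[1])),
    )


@dataclass(frozen=True)
class RegressionResult:
    slope: float  # through-origin slope sum(xy)/sum(x^2)
    r_squared: float  # uncentered R^2 of the through-origin model
    r_squared_centered: float
    pearson_r: float
    ols_slope: float  # ordinary least squares with intercept, for comparison
    ols_intercept: float
    n: int


def regression_through_origin(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Fit y = b·x (no intercept) between two measurement methods.

    slope = Σxy / Σx²; the model R² uses the uncentered total sum of
    squares Σy² (the centered version and Pearson r are also reported).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("x and y must have equal length >= 2")
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise ValueError("all x values are zero: through-origin slope undefined")
    slope = float(np.sum(x * y)) / sxx
    resid = y - slope * x
    ss_res = float(np.sum(resid**2))
    ss_tot_unc = float(np.sum(y**2))
    ss_tot_cen = float(np.sum((y - y.mean()) ** 2))
    r2_unc = 1.0 - ss_res / ss_tot_unc if ss_tot_unc > 0 else float("nan")
    r2_cen = 1.0 - ss_res / ss_tot_cen if ss_tot_cen > 0 else float("nan")
    if np.ptp(x) > 0 and np.ptp(y) > 0:
        pearson = float(sstats.pearsonr(x, y)[0])
    else:
        pearson = float("nan")
    ols = np.polyfit(x, y, 1) if np.ptp(x) > 0 else (float("nan"), float("nan"))
    return RegressionResult(
        slope=slope,
        r_squared=r2_unc,
        r_squared_centered=r2_cen,
        pearson_r=pearson,
        ols_slope=float(ols[0]),
        ols_intercept=float(ols[1]),
        n=int(x.size),
    )
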