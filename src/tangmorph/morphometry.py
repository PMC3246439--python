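"""Classical morphometric statistics for reduction analyses.

This module carries the statistics used to argue about resharpening
behavior from tool measurements and shape scores:

* tang/tip partition of an oriented outline (width-profile shoulder
  detection, or an explicit boundary hint);
* Welch's unequal-variance two-sample t test (retouched vs. unretouched
  tip and tang lengths);
* multiple regression of shape scores on overall length and tip length;
* major-axis (model II) regression of log tang length on log tip length,
  with a bootstrap isometry test — slope 1 on log-log scales is isometry,
  slope > 1 means the tang grows relatively larger as the tip shrinks;
* score spread by length quantile (the "more asymmetric when shorter"
  pattern) and cumulative typological curves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import ParameterError, ShoulderDetectionError
from .outline_io import Outline

__all__ = [
    "WelchResult",
    "AllometryResult",
    "RegressionResult",
    "QuantileSpread",
    "TangTipMeasurement",
    "measure_tang_tip",
    "welch_test",
    "regress_pc_on_size",
    "major_axis",
    "spread_by_length",
    "cumulative_type_curve",
    "aterian_inventory",
]


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float
    group_means: tuple[float, float]


@dataclass(frozen=True)
class AllometryResult:
    slope: float
    intercept: float
    ci: tuple[float, float]
    isometric: bool  # True when slope 1 lies inside the CI


@dataclass(frozen=True)
class RegressionResult:
    coefficients: dict
    adjusted_r2: float
    overall_p: float
    collinear_warning: bool = False


@dataclass(frozen=True)
class QuantileSpread:
    mode: str
    table: pd.DataFrame  # one row per bin: low, high, n, median, iqr, retouched_fraction


class TangTipMeasurement(NamedTuple):
    length: float
    tang_length: float
    tip_length: float
    boundary_x: float


# ---------------------------------------------------------------------------
# Tang/tip partition
# ---------------------------------------------------------------------------

def width_profile(outline: Outline, n_bins: int = 96) -> tuple[np.ndarray, np.ndarray]:
    """Binned y-extent of the outline as a function of x (tang-left oriented)."""
    pts = outline.points
    x = pts[:, 0]
    edges = np.linspace(x.min(), x.max(), n_bins + 1)
    idx = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)
    w = np.zeros(n_bins)
    for i in range(n_bins):
        ys = pts[idx == i, 1]
        if len(ys):
            w[i] = ys.max() - ys.min()
    centers = 0.5 * (edges[:-1] + edges[1:])
    # fill empty bins by interpolation, then light smoothing
    filled = w > 0
    if filled.sum() >= 2:
        w = np.interp(centers, centers[filled], w[filled])
    kernel = np.array([0.25, 0.5, 0.25])
    w = np.convolve(np.pad(w, 1, mode="edge"), kernel, mode="valid")
    return centers, w


def measure_tang_tip(
    outline: Outline,
    boundary_hint: Optional[float] = None,
    n_bins: int = 96,
    search_fraction: float = 0.6,
) -> TangTipMeasurement:
    """Split an oriented (tang-left) outline into tang and tip lengths.

    Without a hint, the tang/blade boundary is the largest positive jump of
    the smoothed width profile within the left ``search_fraction`` of the
    length — the shoulder where the narrow stem widens into the blade.  The
    jump must be an interior peak of the profile gradient: a smoothly
    swelling silhouette (e.g. an ellipse, steepest at its very end) has no
    shoulder and raises :class:`ShoulderDetectionError`.
    """
    pts = outline.points
    x_min, x_max = pts[:, 0].min(), pts[:, 0].max()
    length = float(x_max - x_min)
    if length <= 0:
        raise ParameterError(f"outline {outline.specimen_id!r} has zero x-extent")
    if boundary_hint is not None:
        boundary_x = float(boundary_hint)
    else:
        centers, w = width_profile(outline, n_bins=n_bins)
        grad = np.diff(w)
        limit = x_min + search_fraction * length
        window = np.flatnonzero(0.5 * (centers[:-1] + centers[1:]) <= limit)
        if len(window) < 3:
            raise ShoulderDetectionError(
                f"outline {outline.specimen_id!r}: search window too small"
            )
        g = grad[window]
        # a shoulder is a positive jump preceded by a plateau or notch
        # (near-zero or negative gradient); a smoothly swelling profile
        # (steepest at its very end, monotone thereafter) has none
        candidates = [
            j
            for j in range(1, len(g))
            if g[j] > 0 and np.min(g[:j]) < 0.3 * g[j]
        ]
        if not candidates:
            raise ShoulderDetectionError(
                f"outline {outline.specimen_id!r}: width profile has no "
                "detectable shoulder; pass boundary_hint"
            )
        j = max(candidates, key=lambda j: g[j])
        boundary_x = float(0.5 * (centers[window[j]] + centers[window[j] + 1]))
    tang = float(boundary_x - x_min)
    return TangTipMeasurement(
        length=length,
        tang_length=tang,
        tip_length=length - tang,
        boundary_x=boundary_x,
    )


# ---------------------------------------------------------------------------
# Two-sample comparison
# ---------------------------------------------------------------------------

def welch_test(x: Sequence[float], y: Sequence[float]) -> WelchResult:
    """Welch's unequal-variance two-sample t test (two-sided).

    The statistic's sign follows mean(x) − mean(y); degrees of freedom are
    Welch–Satterthwaite, so fractional values are expected.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ParameterError("each group needs at least 2 observations")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            return WelchResult(0.0, float(len(x) + len(y) - 2), 1.0,
                               (float(np.mean(x)), float(np.mean(y))))
        raise ParameterError("both groups have zero variance")
    res = stats.ttest_ind(x, y, equal_var=False)
    return WelchResult(
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        group_means=(float(np.mean(x)), float(np.mean(y))),
    )


# ---------------------------------------------------------------------------
# Size regressions
# ---------------------------------------------------------------------------

def regress_pc_on_size(
    scores: Sequence[float],
    length: Sequence[float],
    tip_length: Optional[Sequence[float]] = None,
) -> RegressionResult:
    """OLS of a shape score on length (and optionally tip length)."""
    y = np.asarray(scores, dtype=float)
    predictors = {"length": np.asarray(length, dtype=float)}
    if tip_length is not None:
        predictors["tip_length"] = np.asarray(tip_length, dtype=float)
    X = pd.DataFrame(predictors)
    if len(y) <= X.shape[1] + 1:
        raise ParameterError("too few observations for the regression")
    model = sm.OLS(y, sm.add_constant(X)).fit()
    coeffs = {k: float(v) for k, v in model.params.items()}
    return RegressionResult(
        coefficients=coeffs,
        adjusted_r2=float(model.rsquared_adj),
        overall_p=float(model.f_pvalue),
        collinear_warning=bool(model.condition_number > 1e10),
    )


# ---------------------------------------------------------------------------
# Major-axis allometry
# ---------------------------------------------------------------------------

def _ma_slope(x: np.ndarray, y: np.ndarray) -> float:
    sxx = x.var(ddof=1)
    syy = y.var(ddof=1)
    sxy = float(np.cov(x, y, ddof=1)[0, 1])
    if sxx == 0:
        raise ParameterError("zero variance in x; major-axis slope undefined")
    if sxy == 0:
        # principal axis aligned with a coordinate axis
        return 0.0 if sxx > syy else np.inf
    return (syy - sxx + np.sqrt((syy - sxx) ** 2 + 4 * sxy**2)) / (2 * sxy)


def major_axis(
    x: Sequence[float],
    y: Sequence[float],
    n_boot: int = 1000,
    seed: int = 0,
) -> AllometryResult:
    """Major-axis (model II) regression with a bootstrap isometry test.

    ``x`` and ``y`` are already-logged measurements.  The slope is that of
    the first principal axis of the 2×2 covariance; the CI is a seeded
    percentile bootstrap over specimens, and ``isometric`` records whether
    slope 1 lies inside it.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 10:
        raise ParameterError("need at least 10 paired observations")
    slope = _ma_slope(x, y)
    intercept = float(np.mean(y) - slope * np.mean(x))
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    n = len(x)
    for i in range(n_boot):
        while True:
            idx = rng.integers(0, n, n)
            if np.var(x[idx]) > 0:
                break
        boot[i] = _ma_slope(x[idx], y[idx])
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return AllometryResult(
        slope=float(slope),
        intercept=intercept,
        ci=(float(lo), float(hi)),
        isometric=bool(lo <= 1.0 <= hi),
    )


# ---------------------------------------------------------------------------
# Spread by length quantile
# ---------------------------------------------------------------------------

def spread_by_length(
    scores: Sequence[float],
    lengths: Sequence[float],
    mode: str = "equal_n",
    bins: int = 4,
    retouched: Optional[Sequence[bool]] = None,
) -> QuantileSpread:
    """Median, IQR and retouch fraction of a score, binned by length.

    ``equal_n`` bins by length quantile (roughly equal samples),
    ``equal_width`` splits the length range into equal segments (uneven
    samples) — the two conventional readings of size-dependent spread.
    """
    scores = np.asarray(scores, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if mode not in ("equal_n", "equal_width"):
        raise ParameterError(f"mode must be equal_n or equal_width, got {mode!r}")
    if bins < 2:
        raise ParameterError("bins must be >= 2")
    if len(scores) < 4 * bins:
        raise ParameterError(f"need at least {4 * bins} specimens for {bins} bins")
    if mode == "equal_n":
        try:
            cats = pd.qcut(lengths, q=bins, duplicates="raise")
        except ValueError as exc:
            raise ParameterError(
                f"tied lengths make a quantile bin empty: {exc}"
            ) from exc
    else:
        cats = pd.cut(lengths, bins=bins)
    df = pd.DataFrame({"score": scores, "length": lengths, "bin": cats})
    if retouched is not None:
        df["retouched"] = np.asarray(retouched, dtype=bool)
    rows = []
    for interval, grp in df.groupby("bin", observed=False, sort=True):
        if len(grp) == 0:
            raise ParameterError(f"bin {interval} is empty")
        q1, q3 = np.percentile(grp["score"], [25, 75])
        rows.append(
            {
                "low": float(interval.left),
                "high": float(interval.right),
                "n": int(len(grp)),
                "median": float(grp["score"].median()),
                "iqr": float(q3 - q1),
                "retouched_fraction": float(grp["retouched"].mean())
                if retouched is not None
                else float("nan"),
            }
        )
    return QuantileSpread(mode=mode, table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Cumulative typological curves
# ---------------------------------------------------------------------------

def cumulative_type_curve(
    type_codes: Sequence[int], reclassify_endscrapers: bool = False
) -> pd.Series:
    """Cumulative percentage of specimens by ascending type code.

    With ``reclassify_endscrapers`` the endscraper-tip codes 30/31 are
    re-counted as transverse scrapers 22/23 before accumulation (the
    orientation-convention correction for tanged pieces).
    """
    codes = np.asarray(type_codes, dtype=int)
    if len(codes) == 0:
        raise ParameterError("empty type code list")
    if reclassify_endscrapers:
        codes = codes.copy()
        codes[codes == 30] = 22
        codes[codes == 31] = 23
    counts = pd.Series(codes).value_counts().sort_index()
    return 100.0 * counts.cumsum() / counts.sum()


# ---------------------------------------------------------------------------
# Published assemblage inventory (input data)
# ---------------------------------------------------------------------------

_INVENTORY = [
    # site, n, country, collection_class
    ("Bir-Chaacha", 51, "Algeria", "excavated"),
    ("Bir-el-Ater", 19, "Algeria", "excavated"),
    ("Contrebandiers", 33, "Morocco", "excavated"),
    ("el-Mnasra", 20, "Algeria", "excavated"),
    ("el-Oubira", 97, "Algeria", "excavated"),
    ("Oued Djouf el Djemel", 140, "Algeria", "excavated"),
    ("Tit Mellil", 35, "Morocco", "excavated"),
    ("Beni-Abbes", 23, "Algeria", "surface"),
    ("Djouf Djoudder", 10, "Mali", "surface"),
    ("Erg Chech", 9, "Algeria", "surface"),
    ("Erg Jmeyha", 4, "Mali", "surface"),
    ("Koudiat Bou Gherara", 2, "Algeria", "surface"),
    ("Nord Azraza", 3, "Mali", "surface"),
    ("Polygone d'Eckmuhl", 16, "Algeria", "surface"),
    ("Oua-n-Torha", 3, "Algeria", "surface"),
    ("Oum-el-Ksi", 4, "Mali", "surface"),
    ("RDAC/REDA (Ouargla)", 20, "Algeria", "surface"),
    ("Unknown North Africa", 13, "", "surface"),
    ("Tebessa", 5, "Algeria", "surface"),
]


def aterian_inventory() -> pd.DataFrame:
    """Published specimen counts of the Aterian tanged-tool assemblages.

    One row per site with the number of complete tanged tools and whether
    the sample comes from an excavated assemblage or a surface collection.
    These counts are input data for sample-accounting summaries.
    """
    return pd.DataFrame(
        _INVENTORY, columns=["site", "n", "country", "collection_class"]
    )
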