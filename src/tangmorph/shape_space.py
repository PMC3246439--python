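"""PCA shape space over standardized elliptical Fourier coefficients.

The shape space is the eigendecomposition of the coefficient covariance
matrix (not the correlation matrix): the mean coefficient vector is the mean
shape, eigenvectors are directions of shape variation, and per-specimen
scores are the centered coefficients on those directions.  Extreme shapes
along a component are visualized by adding the extreme observed scores times
the eigenvector to the mean shape and running the inverse Fourier transform.
External samples are projected onto a fitted space without refitting, which
is how a comparison population (e.g. known arrowheads) is placed in a tool
assemblage's shape space.

Group scatter in a two-component plane is summarized by "data ellipses":
the 2×2 score covariance scaled by the chi-square quantile at the requested
level, centered on the group centroid.  A standard-error (mean-confidence)
variant is available via ``kind='mean'``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import Polygon
from sklearn.decomposition import PCA

from .efa import EFACoefficients, coefficient_columns, inverse_efa
from .errors import ParameterError
from .outline_io import Outline


@dataclass(frozen=True)
class ShapeSpace:
    """A fitted PCA over a specimen × coefficient matrix.

    ``eigenvectors`` has one component per row (k × p, orthonormal rows);
    ``scores`` is the specimen × component table, columns ``pc1..pck``.
    """

    mean_coeffs: pd.Series
    eigenvectors: np.ndarray
    eigenvalues: np.ndarray
    scores: pd.DataFrame
    variance_fraction: np.ndarray

    @property
    def columns(self) -> list[str]:
        return list(self.mean_coeffs.index)

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


@dataclass(frozen=True)
class GroupEllipse:
    group: str
    center: tuple[float, float]
    axes: tuple[float, float]
    angle: float
    level: float

    def polygon(self, n_vertices: int = 256) -> np.ndarray:
        """Polygonal approximation, ``(n_vertices, 2)``."""
        t = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
        ca, sa = np.cos(self.angle), np.sin(self.angle)
        x = self.axes[0] * np.cos(t)
        y = self.axes[1] * np.sin(t)
        return np.column_stack(
            [self.center[0] + ca * x - sa * y, self.center[1] + sa * x + ca * y]
        )


# ---------------------------------------------------------------------------
# Fitting and reconstruction
# ---------------------------------------------------------------------------

def fit_pca(matrix: pd.DataFrame) -> ShapeSpace:
    """Fit the covariance-matrix PCA of a specimen × coefficient table."""
    if len(matrix) < 3:
        raise ParameterError(f"need at least 3 specimens, got {len(matrix)}")
    X = matrix.to_numpy(dtype=float)
    if np.allclose(X.var(axis=0), 0.0):
        raise ParameterError("zero-variance coefficient matrix; no shape space")
    k = min(len(matrix) - 1, X.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    components = pca.components_.copy()
    # sign convention: largest-magnitude loading of each component positive
    for i in range(k):
        j = int(np.argmax(np.abs(components[i])))
        if components[i, j] < 0:
            components[i] *= -1.0
            scores[:, i] *= -1.0
    eigenvalues = pca.explained_variance_.copy()
    total = pca.explained_variance_.sum() / pca.explained_variance_ratio_.sum()
    return ShapeSpace(
        mean_coeffs=pd.Series(pca.mean_, index=matrix.columns),
        eigenvectors=components,
        eigenvalues=eigenvalues,
        scores=pd.DataFrame(
            scores,
            index=matrix.index,
            columns=[f"pc{i + 1}" for i in range(k)],
        ),
        variance_fraction=eigenvalues / total,
    )


def _coeffs_from_vector(vector: np.ndarray, columns: Sequence[str], specimen_id: str) -> EFACoefficients:
    H = len(columns) // 4
    if list(columns) != coefficient_columns(H):
        raise ParameterError("coefficient columns are not in canonical a1..dH order")
    return EFACoefficients(
        specimen_id=specimen_id,
        A0=0.0,
        C0=0.0,
        harmonics=np.asarray(vector, dtype=float).reshape(H, 4),
        normalization_state=frozenset(),
    )


def mean_shape(space: ShapeSpace, n_points: int = 512) -> Outline:
    """The mean coefficient vector rendered as an outline."""
    return inverse_efa(
        _coeffs_from_vector(space.mean_coeffs.to_numpy(), space.columns, "mean_shape"),
        n_points=n_points,
    )


def extreme_shape(
    space: ShapeSpace, component: int, n_points: int = 512
) -> tuple[Outline, Outline]:
    """Outlines at the minimum and maximum observed score of one component."""
    if not 0 <= component < space.n_components:
        raise ParameterError(
            f"component must be in [0, {space.n_components}), got {component}"
        )
    s = space.scores.iloc[:, component].to_numpy()
    mean = space.mean_coeffs.to_numpy()
    vec = space.eigenvectors[component]
    shapes = []
    for tag, extreme in (("min", s.min()), ("max", s.max())):
        coeffs = _coeffs_from_vector(
            mean + extreme * vec, space.columns, f"pc{component + 1}_{tag}"
        )
        shapes.append(inverse_efa(coeffs, n_points=n_points))
    return shapes[0], shapes[1]


def project(space: ShapeSpace, external: pd.DataFrame) -> pd.DataFrame:
    """Score an external coefficient matrix in an already-fitted space."""
    if list(external.columns) != space.columns:
        raise ParameterError(
            "external matrix columns do not match the fitted space"
        )
    centered = external.to_numpy(dtype=float) - space.mean_coeffs.to_numpy()
    scores = centered @ space.eigenvectors.T
    return pd.DataFrame(scores, index=external.index, columns=space.scores.columns)


def component_asymmetry_mass(space: ShapeSpace) -> np.ndarray:
    """Per-component fraction of squared loading on the b/c coefficients.

    b_n and c_n vanish for outlines mirror-symmetric about the long axis, so
    a component whose loading mass concentrates there is an asymmetry axis;
    components loading on a_n/d_n describe symmetric variation (elongation,
    tapering, relative tang length).
    """
    is_bc = np.array([c[0] in "bc" for c in space.columns])
    sq = space.eigenvectors**2
    return sq[:, is_bc].sum(axis=1) / sq.sum(axis=1)


# ---------------------------------------------------------------------------
# Group ellipses
# ---------------------------------------------------------------------------

def confidence_ellipse(
    scores: np.ndarray,
    level: float = 0.95,
    group: str = "",
    kind: str = "data",
) -> GroupEllipse:
    """Chi-square-scaled ellipse of a 2-D score cloud.

    ``kind='data'`` scales the score covariance itself (the region holding
    roughly ``level`` of the population under normality); ``kind='mean'``
    divides the covariance by n first, giving a confidence region for the
    group centroid.
    """
    pts = np.asarray(scores, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ParameterError("scores must be an (n, 2) array")
    if len(pts) < 3:
        raise ParameterError("need at least 3 points for an ellipse")
    if not 0 < level < 1:
        raise ParameterError(f"level must be in (0, 1), got {level}")
    if kind not in ("data", "mean"):
        raise ParameterError(f"kind must be 'data' or 'mean', got {kind!r}")
    cov = np.cov(pts, rowvar=False)
    if kind == "mean":
        cov = cov / len(pts)
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] <= 1e-12 * max(evals[1], 1e-300):
        raise ParameterError("degenerate score covariance (points collinear)")
    q = stats.chi2.ppf(level, df=2)
    # eigh returns ascending order; major axis last
    axes = (float(np.sqrt(evals[1] * q)), float(np.sqrt(evals[0] * q)))
    angle = float(np.arctan2(evecs[1, 1], evecs[0, 1]))
    center = pts.mean(axis=0)
    return GroupEllipse(
        group=group,
        center=(float(center[0]), float(center[1])),
        axes=axes,
        angle=angle,
        level=level,
    )


def overlap_summary(e1: GroupEllipse, e2: GroupEllipse, n_vertices: int = 256) -> str:
    """Categorical relation of two ellipses: 'disjoint', 'overlapping' or 'nested'."""
    p1 = Polygon(e1.polygon(n_vertices))
    p2 = Polygon(e2.polygon(n_vertices))
    if p1.covers(p2) or p2.covers(p1):
        return "nested"
    if p1.intersects(p2):
        return "overlapping"
    return "disjoint"
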