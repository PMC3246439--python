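"""Elliptical Fourier analysis of closed outlines.

A closed contour traversed at constant speed decomposes into harmonics

    x(t) = A0 + sum_n  a_n cos(n t) + b_n sin(n t)
    y(t) = C0 + sum_n  c_n cos(n t) + d_n sin(n t),      t in [0, 2*pi),

four real coefficients per harmonic.  The forward transform here evaluates
the Kuhl–Giardina per-segment integrals of the piecewise-linear contour
exactly (no FFT of sampled points), so the coefficients are exact for a
polygon and independent of sampling phase.

The standardization dialect is the one used in outline studies of tool
reduction: translate the centroid to the origin, divide by the square root
of outline area (so every standardized shape has unit area), and rotate the
first-harmonic "best-fitting" ellipse onto the x-axis *without* rescaling
its semi-major axis — elongation stays in the coefficients, because shape
change along the long axis is exactly what a reduction analysis is about.
Start-point phase is additionally normalized (parametric start at the
larger-x end of the major axis) so that coefficients are comparable across
specimens; the residual 180° axis ambiguity is broken by requiring the
narrower lobe (the tang) at smaller x.

Harmonic power is power_n = (a_n² + b_n² + c_n² + d_n²)/2; truncation keeps
the smallest harmonic count whose cumulative power fraction reaches a
threshold (0.99 by default) for every specimen — with the conventional
default of 11 harmonics, i.e. 44 coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, NormalizationError, ParameterError
from .outline_io import Outline, measure_geometry

DEFAULT_HARMONICS = 11
DEFAULT_POWER_THRESHOLD = 0.99

FULL_NORMALIZATION = frozenset(
    {"translated", "area_scaled", "rotation_standardized", "start_normalized"}
)


@dataclass(frozen=True)
class EFACoefficients:
    """Elliptical Fourier descriptor of one specimen.

    ``harmonics`` is an ``(H, 4)`` array of (a_n, b_n, c_n, d_n) rows;
    ``A0``/``C0`` are the offset (centroid) terms.  ``normalization_state``
    records which standardizations have been applied.
    """

    specimen_id: str
    A0: float
    C0: float
    harmonics: np.ndarray
    normalization_state: frozenset = frozenset()

    def __post_init__(self) -> None:
        h = np.asarray(self.harmonics, dtype=float)
        if h.ndim != 2 or h.shape[1] != 4 or h.shape[0] < 1:
            raise ParameterError("harmonics must be an (H, 4) array with H >= 1")
        object.__setattr__(self, "harmonics", h)
        object.__setattr__(
            self, "normalization_state", frozenset(self.normalization_state)
        )

    @property
    def H(self) -> int:
        return self.harmonics.shape[0]

    def as_vector(self) -> np.ndarray:
        """Flatten to (a1, b1, c1, d1, ..., aH, bH, cH, dH)."""
        return self.harmonics.ravel().copy()


@dataclass(frozen=True)
class HarmonicSpectrum:
    power: np.ndarray
    cumulative_fraction: np.ndarray


def coefficient_columns(H: int) -> list[str]:
    """Fixed column order of the specimen × coefficient matrix."""
    return [f"{letter}{n}" for n in range(1, H + 1) for letter in "abcd"]


# ---------------------------------------------------------------------------
# Forward transform (exact per-segment Kuhl–Giardina integrals)
# ---------------------------------------------------------------------------

def efa_forward(outline: Outline, H: int = DEFAULT_HARMONICS) -> EFACoefficients:
    """Elliptical Fourier coefficients of a closed polygonal outline."""
    n_pts = outline.n_points
    if H < 1 or H > n_pts // 2 - 1:
        raise ParameterError(
            f"H must satisfy 1 <= H <= n_points//2 - 1 = {n_pts // 2 - 1}, got {H}"
        )
    pts = np.vstack([outline.points, outline.points[:1]])
    d = np.diff(pts, axis=0)
    dt = np.hypot(d[:, 0], d[:, 1])
    if np.any(dt == 0):
        raise ParameterError(
            f"outline {outline.specimen_id!r} contains zero-length segments"
        )
    t = np.concatenate([[0.0], np.cumsum(dt)])
    T = t[-1]

    n = np.arange(1, H + 1)[:, None]
    phi1 = 2 * np.pi * n * t[1:] / T
    phi0 = 2 * np.pi * n * t[:-1] / T
    dcos = np.cos(phi1) - np.cos(phi0)
    dsin = np.sin(phi1) - np.sin(phi0)
    k = T / (2.0 * (n * np.pi) ** 2)
    vx = d[:, 0] / dt
    vy = d[:, 1] / dt
    a = (k * vx * dcos).sum(axis=1)
    b = (k * vx * dsin).sum(axis=1)
    c = (k * vy * dcos).sum(axis=1)
    dd = (k * vy * dsin).sum(axis=1)

    # offsets: mean of the piecewise-linear x(t), y(t) over one period
    # (per-segment trapezoid is exact for linear segments)
    mid = 0.5 * (pts[:-1] + pts[1:])
    A0 = float((mid[:, 0] * dt).sum() / T)
    C0 = float((mid[:, 1] * dt).sum() / T)

    return EFACoefficients(
        specimen_id=outline.specimen_id,
        A0=A0,
        C0=C0,
        harmonics=np.column_stack([a, b, c, dd]),
        normalization_state=frozenset(),
    )


# ---------------------------------------------------------------------------
# Inverse transform
# ---------------------------------------------------------------------------

def inverse_efa(coeffs: EFACoefficients, n_points: int = 512) -> Outline:
    """Synthesize the outline at ``n_points`` equal parameter increments."""
    t = np.linspace(0.0, 2 * np.pi, n_points, endpoint=False)
    n = np.arange(1, coeffs.H + 1)[:, None]
    cos_nt = np.cos(n * t)
    sin_nt = np.sin(n * t)
    a, b, c, d = coeffs.harmonics.T
    x = coeffs.A0 + a @ cos_nt + b @ sin_nt
    y = coeffs.C0 + c @ cos_nt + d @ sin_nt
    return Outline(coeffs.specimen_id, np.column_stack([x, y]))


# ---------------------------------------------------------------------------
# Standardization (all performed in coefficient space)
# ---------------------------------------------------------------------------

def _start_shift(harm: np.ndarray, theta: float) -> np.ndarray:
    """Shift the parametric start point by ``theta`` (t -> t + theta)."""
    out = np.empty_like(harm)
    for i in range(harm.shape[0]):
        nth = (i + 1) * theta
        rot = np.array(
            [[np.cos(nth), -np.sin(nth)], [np.sin(nth), np.cos(nth)]]
        )
        m = harm[i].reshape(2, 2) @ rot
        out[i] = m.ravel()
    return out


def _spatial_rotate(harm: np.ndarray, psi: float) -> np.ndarray:
    """Rotate the outline by ``psi`` about the origin, in coefficient space."""
    rot = np.array([[np.cos(psi), -np.sin(psi)], [np.sin(psi), np.cos(psi)]])
    out = np.empty_like(harm)
    for i in range(harm.shape[0]):
        out[i] = (rot @ harm[i].reshape(2, 2)).ravel()
    return out


def _first_harmonic_axes(harm: np.ndarray) -> tuple[float, float]:
    """Semi-axis lengths of the first-harmonic (best-fitting) ellipse."""
    a, b, c, d = harm[0]
    # singular values of [[a, b], [c, d]]
    m = np.array([[a, b], [c, d]])
    s = np.linalg.svd(m, compute_uv=False)
    return float(s[0]), float(s[1])


def standardize(coeffs: EFACoefficients, outline_area: float) -> EFACoefficients:
    """Translate, area-scale and rotation/start-standardize coefficients.

    The returned coefficients are invariant under translation, uniform
    scaling and rotation of the source outline.  The first-harmonic
    ellipse's major axis ends parallel to +x with the parametric start at
    its larger-x end; semi-axes are *not* rescaled, so elongation survives.
    """
    if outline_area <= 0:
        raise ParameterError(f"outline_area must be positive, got {outline_area}")
    state = set(coeffs.normalization_state)

    harm = coeffs.harmonics.copy()

    # 1. translation: centroid at the origin
    A0 = C0 = 0.0
    state.add("translated")

    # 2. size: divide coordinates (hence all coefficients) by sqrt(area)
    if "area_scaled" not in state:
        harm = harm / np.sqrt(outline_area)
        state.add("area_scaled")

    # 3. rotation + start point, from the first-harmonic ellipse
    if "rotation_standardized" not in state:
        major, minor = _first_harmonic_axes(harm)
        if major - minor < 1e-9 * max(major, 1e-30):
            warnings.warn(
                f"specimen {coeffs.specimen_id!r}: first-harmonic ellipse is "
                "a circle; rotation standardization skipped",
                stacklevel=2,
            )
        else:
            a1, b1, c1, d1 = harm[0]
            theta = 0.5 * np.arctan2(
                2.0 * (a1 * b1 + c1 * d1),
                a1 * a1 + c1 * c1 - b1 * b1 - d1 * d1,
            )
            harm = _start_shift(harm, theta)
            # make sure the start phase points along the MAJOR semi-axis
            a1, b1, c1, d1 = harm[0]
            if np.hypot(a1, c1) < np.hypot(b1, d1):
                harm = _start_shift(harm, np.pi / 2)
            a1, b1, c1, d1 = harm[0]
            psi = np.arctan2(c1, a1)
            harm = _spatial_rotate(harm, -psi)
            # after rotating by -psi the start sits at the larger-x end
            # (a1 = |(a1, c1)| > 0).  The remaining 180° axis ambiguity is
            # broken toward the input's own orientation: inputs follow the
            # tang-left convention, so the alignment rotation must not
            # exceed a quarter turn.  The joint spatial+start half-turn
            # keeps harmonic 1 fixed and negates even harmonics only.
            if np.cos(psi) < 0:
                harm[1::2] *= -1.0
        state.update({"rotation_standardized", "start_normalized"})

    return EFACoefficients(
        specimen_id=coeffs.specimen_id,
        A0=A0,
        C0=C0,
        harmonics=harm,
        normalization_state=frozenset(state),
    )


# ---------------------------------------------------------------------------
# Harmonic power and truncation
# ---------------------------------------------------------------------------

def spectrum(coeffs: EFACoefficients) -> HarmonicSpectrum:
    """Per-harmonic power (half the squared coefficient sum) and cumulative fraction."""
    power = 0.5 * (coeffs.harmonics**2).sum(axis=1)
    total = power.sum()
    if total <= 0:
        raise ParameterError(
            f"specimen {coeffs.specimen_id!r}: all coefficients are zero; "
            "power fractions undefined"
        )
    return HarmonicSpectrum(power=power, cumulative_fraction=np.cumsum(power) / total)


def choose_harmonics(
    spectra: Iterable[HarmonicSpectrum],
    threshold: float = DEFAULT_POWER_THRESHOLD,
    max_h: Optional[int] = None,
) -> int:
    """Smallest H whose cumulative power fraction reaches ``threshold`` for every specimen.

    ``max_h`` caps the usable harmonic count (for example when downstream
    tables are fixed at 11 harmonics); spectra should then be computed at a
    higher H so the cap is a real constraint rather than the normalization
    endpoint.
    """
    if not 0 < threshold < 1:
        raise ParameterError(f"threshold must be in (0, 1), got {threshold}")
    spectra = list(spectra)
    if not spectra:
        raise ParameterError("no spectra supplied")
    h_needed = []
    for i, sp in enumerate(spectra):
        limit = len(sp.power) if max_h is None else min(max_h, len(sp.power))
        ok = np.flatnonzero(sp.cumulative_fraction[:limit] >= threshold)
        if len(ok) == 0:
            raise ParameterError(
                f"threshold {threshold} unreachable at H={limit} "
                f"(worst specimen index {i}, fraction there "
                f"{sp.cumulative_fraction[limit - 1]:.12f})"
            )
        h_needed.append(int(ok[0]) + 1)
    return max(h_needed)


# ---------------------------------------------------------------------------
# Coefficient matrices and their plain-text round trip
# ---------------------------------------------------------------------------

def coefficient_matrix(coeff_set: Sequence[EFACoefficients]) -> pd.DataFrame:
    """Stack coefficient vectors into a specimen × coefficient table.

    Rows are specimens (index ``specimen_id``), columns follow
    :func:`coefficient_columns`.  All specimens must share the harmonic
    count and the normalization state.
    """
    coeff_set = list(coeff_set)
    if not coeff_set:
        raise ParameterError("empty coefficient set")
    H = coeff_set[0].H
    state = coeff_set[0].normalization_state
    for c in coeff_set[1:]:
        if c.H != H:
            raise NormalizationError(
                f"mixed harmonic counts: {H} vs {c.H} ({c.specimen_id!r})"
            )
        if c.normalization_state != state:
            raise NormalizationError(
                f"mixed normalization states: {sorted(state)} vs "
                f"{sorted(c.normalization_state)} ({c.specimen_id!r})"
            )
    data = np.vstack([c.as_vector() for c in coeff_set])
    return pd.DataFrame(
        data,
        index=pd.Index([c.specimen_id for c in coeff_set], name="specimen_id"),
        columns=coefficient_columns(H),
    )


def write_coefficients(coeff_set: Sequence[EFACoefficients], path) -> None:
    """Write a delimited coefficient table that round-trips bit-exactly."""
    rows = []
    for c in coeff_set:
        row = {"specimen_id": c.specimen_id, "A0": c.A0, "C0": c.C0}
        for col, v in zip(coefficient_columns(c.H), c.as_vector()):
            row[col] = v
        row["normalization_state"] = "|".join(sorted(c.normalization_state)) or "raw"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_coefficients(path) -> list[EFACoefficients]:
    table = pd.read_csv(path, float_precision="round_trip")
    needed = {"specimen_id", "A0", "C0", "normalization_state"}
    if not needed <= set(table.columns):
        raise FormatError(
            f"coefficient table {path}: missing {sorted(needed - set(table.columns))}"
        )
    coeff_cols = [c for c in table.columns if c not in needed]
    if len(coeff_cols) % 4 != 0:
        raise FormatError(f"coefficient table {path}: column count not a multiple of 4")
    H = len(coeff_cols) // 4
    expected = coefficient_columns(H)
    if coeff_cols != expected:
        raise FormatError(f"coefficient table {path}: unexpected column order")
    out = []
    for _, row in table.iterrows():
        state = row["normalization_state"]
        state = frozenset() if state == "raw" else frozenset(str(state).split("|"))
        out.append(
            EFACoefficients(
                specimen_id=str(row["specimen_id"]),
                A0=float(row["A0"]),
                C0=float(row["C0"]),
                harmonics=row[expected].to_numpy(dtype=float).reshape(H, 4),
                normalization_state=state,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Convenience: full per-outline pipeline step
# ---------------------------------------------------------------------------

def standardized_coefficients(
    outline: Outline, H: int = DEFAULT_HARMONICS
) -> EFACoefficients:
    """Forward transform + full standardization of one oriented outline."""
    geom = measure_geometry(outline)
    return standardize(efa_forward(outline, H=H), geom.area)
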