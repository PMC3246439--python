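"""Reading, tracing, orienting and resampling closed specimen outlines.

An :class:`Outline` is an ordered, implicitly closed polygon (the first point
is *not* repeated at the end) describing one tool silhouette in the plane,
with y increasing upward ("dorsal side up").  The analysis convention is that
after :func:`orient` the traversal is counterclockwise (positive signed area)
and the tang — the narrow hafting stem — sits at smaller x than the tip
("tang facing the left").

Specimen metadata travels alongside the outlines as :class:`SpecimenRecord`
rows; `collection_class` distinguishes excavated assemblages from surface
collections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage import measure as skmeasure

from .errors import (
    AmbiguousOrientationError,
    DegenerateOutlineError,
    FormatError,
)

MIN_OUTLINE_POINTS = 8
DEFAULT_N_POINTS = 512  # supports >=11 harmonics with negligible discretization error

COLLECTION_CLASSES = ("excavated", "surface")

METADATA_COLUMNS = [
    "specimen_id",
    "assemblage",
    "collection_class",
    "retouched",
    "type_code",
    "length",
    "tip_length",
    "tang_length",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Outline:
    """A closed planar polygon for one specimen.

    Parameters
    ----------
    specimen_id:
        Identifier, unique within a sample.
    points:
        ``(n, 2)`` float array of vertices; closure is implicit (the last
        vertex connects back to the first, which is not repeated).
    """

    specimen_id: str
    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise FormatError(
                f"outline {self.specimen_id!r}: points must be an (n, 2) array"
            )
        # a repeated closing vertex is the expected explicit-closure form
        if len(pts) > 1 and np.all(pts[-1] == pts[0]):
            pts = pts[:-1]
        # drop duplicated consecutive interior vertices (digitization artifact)
        keep = np.ones(len(pts), dtype=bool)
        keep[1:] = np.any(pts[1:] != pts[:-1], axis=1)
        if not keep.all():
            warnings.warn(
                f"outline {self.specimen_id!r}: dropped "
                f"{int((~keep).sum())} duplicate consecutive point(s)",
                stacklevel=2,
            )
            pts = pts[keep]
        if len(pts) < MIN_OUTLINE_POINTS:
            raise DegenerateOutlineError(
                f"outline {self.specimen_id!r} has {len(pts)} distinct points; "
                f"at least {MIN_OUTLINE_POINTS} required"
            )
        object.__setattr__(self, "points", pts)

    @property
    def n_points(self) -> int:
        return len(self.points)

    def signed_area(self) -> float:
        """Shoelace signed area (positive for counterclockwise traversal)."""
        x, y = self.points[:, 0], self.points[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    def perimeter(self) -> float:
        d = np.diff(np.vstack([self.points, self.points[:1]]), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())


@dataclass(frozen=True)
class SpecimenRecord:
    """Classical measurements and labels for one specimen.

    ``retouched`` follows the typological convention that Bordes types 6 and
    above are retouched pieces; ``type_code`` is an input label, never
    derived from shape here.
    """

    specimen_id: str
    assemblage: str = ""
    collection_class: str = "excavated"
    retouched: bool = False
    type_code: Optional[int] = None
    length: float = float("nan")
    tip_length: float = float("nan")
    tang_length: float = float("nan")

    def __post_init__(self) -> None:
        if self.collection_class not in COLLECTION_CLASSES:
            raise FormatError(
                f"specimen {self.specimen_id!r}: collection_class must be one "
                f"of {COLLECTION_CLASSES}, got {self.collection_class!r}"
            )
        for name in ("tip_length", "tang_length"):
            v = getattr(self, name)
            if np.isfinite(v) and v < 0:
                raise FormatError(
                    f"specimen {self.specimen_id!r}: {name} must be >= 0"
                )


class Geometry(NamedTuple):
    area: float
    centroid: tuple[float, float]
    length: float
    max_width: float


# ---------------------------------------------------------------------------
# Outline and metadata tables
# ---------------------------------------------------------------------------

def read_outlines(path) -> list[Outline]:
    """Read an outline table (columns specimen_id, point_index, x, y).

    Points are grouped by specimen and ordered by ``point_index``; one
    :class:`Outline` is returned per specimen in order of first appearance.
    """
    table = pd.read_csv(path)
    required = {"specimen_id", "point_index", "x", "y"}
    missing = required - set(table.columns)
    if missing:
        raise FormatError(
            f"outline table {path}: missing column(s) {sorted(missing)}"
        )
    outlines: list[Outline] = []
    too_small: list[str] = []
    for sid, grp in table.groupby("specimen_id", sort=False):
        grp = grp.sort_values("point_index")
        pts = grp[["x", "y"]].to_numpy(dtype=float)
        try:
            outlines.append(Outline(str(sid), pts))
        except DegenerateOutlineError:
            too_small.append(str(sid))
    if too_small:
        raise DegenerateOutlineError(
            f"outline table {path}: specimen(s) {too_small} have fewer than "
            f"{MIN_OUTLINE_POINTS} distinct points"
        )
    return outlines


def write_outlines(outlines: Iterable[Outline], path) -> None:
    """Write outlines in the same delimited layout :func:`read_outlines` reads."""
    frames = []
    for o in outlines:
        frames.append(
            pd.DataFrame(
                {
                    "specimen_id": o.specimen_id,
                    "point_index": np.arange(o.n_points),
                    "x": o.points[:, 0],
                    "y": o.points[:, 1],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def read_metadata(path) -> list[SpecimenRecord]:
    """Read the specimen metadata table (see :data:`METADATA_COLUMNS`)."""
    table = pd.read_csv(path)
    if "specimen_id" not in table.columns:
        raise FormatError(f"metadata table {path}: missing column specimen_id")
    records = []
    for _, row in table.iterrows():
        kwargs = {}
        for col in METADATA_COLUMNS:
            if col not in table.columns or pd.isna(row.get(col)):
                continue
            kwargs[col] = row[col]
        if "retouched" in kwargs:
            kwargs["retouched"] = _parse_bool(kwargs["retouched"])
        if "type_code" in kwargs:
            kwargs["type_code"] = int(kwargs["type_code"])
        kwargs["specimen_id"] = str(kwargs["specimen_id"])
        records.append(SpecimenRecord(**kwargs))
    return records


def _parse_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise FormatError(f"cannot interpret {v!r} as a boolean retouch flag")


def records_to_frame(records: Sequence[SpecimenRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records], columns=METADATA_COLUMNS)


def write_metadata(records: Sequence[SpecimenRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Mask tracing
# ---------------------------------------------------------------------------

def trace_mask(image, min_area: int = 50) -> list[Outline]:
    """Trace outer boundaries of foreground components in a binary mask.

    ``image`` is either a path to a single-channel PNG (foreground > 0) or a
    2-D array.  Components with at least ``min_area`` pixels become outlines,
    traced at sub-pixel precision with marching squares; interior holes are
    ignored (specimens are silhouettes).  Raster row order is flipped so that
    y increases upward.
    """
    if not isinstance(image, np.ndarray):
        image = iio.imread(image)
    image = np.asarray(image)
    if image.ndim == 3:  # collapse any color/alpha channels
        image = image[..., 0]
    values = np.unique(image)
    if len(values) > 2 or (len(values) == 2 and values[0] != 0):
        raise FormatError(
            f"mask is not binary: found pixel values {values[:8].tolist()}"
        )
    fg = (image > 0).astype(np.uint8)
    labels = skmeasure.label(fg)
    outlines: list[Outline] = []
    n_rows = fg.shape[0]
    for region in skmeasure.regionprops(labels):
        if region.area < min_area:
            continue
        # pad so components touching the raster border still close
        component = np.pad((labels == region.label).astype(float), 1)
        contours = skmeasure.find_contours(component, 0.5)
        if not contours:
            continue
        boundary = max(contours, key=lambda c: len(c)) - 1.0  # outer contour only
        # (row, col) -> (x, y) with y up
        pts = np.column_stack([boundary[:, 1], (n_rows - 1) - boundary[:, 0]])
        o = Outline(f"component_{region.label}", pts)
        if o.signed_area() < 0:
            o = Outline(o.specimen_id, o.points[::-1])
        outlines.append(o)
    if not outlines:
        warnings.warn(
            f"no connected component with >= {min_area} pixels found in mask",
            stacklevel=2,
        )
    return outlines


# ---------------------------------------------------------------------------
# Resampling and orientation
# ---------------------------------------------------------------------------

def resample(outline: Outline, n_points: int = DEFAULT_N_POINTS) -> Outline:
    """Resample to ``n_points`` vertices equally spaced by arc length."""
    if n_points < 32:
        raise FormatError(f"n_points must be >= 32, got {n_points}")
    pts = np.vstack([outline.points, outline.points[:1]])
    seg = np.hypot(*np.diff(pts, axis=0).T)
    t = np.concatenate([[0.0], np.cumsum(seg)])
    perimeter = t[-1]
    if perimeter <= 0:
        raise DegenerateOutlineError(
            f"outline {outline.specimen_id!r} has zero perimeter"
        )
    ti = np.linspace(0.0, perimeter, n_points, endpoint=False)
    x = np.interp(ti, t, pts[:, 0])
    y = np.interp(ti, t, pts[:, 1])
    return Outline(outline.specimen_id, np.column_stack([x, y]))


def _end_halfwidth(pts: np.ndarray, left: bool, frac: float = 0.25) -> float:
    """Mean half-width of the outer ``frac`` of the x-extent on one side."""
    x = pts[:, 0]
    x0, x1 = x.min(), x.max()
    cut = x0 + frac * (x1 - x0) if left else x1 - frac * (x1 - x0)
    sel = x <= cut if left else x >= cut
    ymid = 0.5 * (pts[:, 1].min() + pts[:, 1].max())
    return float(np.mean(np.abs(pts[sel, 1] - ymid)))


def orient(outline: Outline, tang_side_hint: str = "auto") -> Outline:
    """Normalize traversal to counterclockwise and put the tang at smaller x.

    With ``tang_side_hint='auto'`` the narrower end (smaller mean half-width
    over the outer 25% of the x-extent) is taken to be the tang; ``'left'``
    (``'right'``) asserts the tang currently sits on that side.  A tool found
    tang-right is rotated 180° about its centroid.
    """
    if tang_side_hint not in ("left", "right", "auto"):
        raise FormatError(f"unknown tang_side_hint {tang_side_hint!r}")
    o = outline
    if o.signed_area() < 0:
        o = Outline(o.specimen_id, o.points[::-1])
    if tang_side_hint == "auto":
        wl = _end_halfwidth(o.points, left=True)
        wr = _end_halfwidth(o.points, left=False)
        scale = max(wl, wr)
        if scale <= 0 or abs(wl - wr) <= 0.01 * scale:
            raise AmbiguousOrientationError(
                f"outline {o.specimen_id!r}: both ends equally wide; "
                "supply tang_side_hint='left' or 'right'"
            )
        tang_side = "left" if wl < wr else "right"
    else:
        tang_side = tang_side_hint
    if tang_side == "right":
        centroid = np.array(_polygon_centroid(o.points))
        o = Outline(o.specimen_id, 2 * centroid - o.points)
        # point-wise negation reverses traversal sense; restore CCW
        if o.signed_area() < 0:
            o = Outline(o.specimen_id, o.points[::-1])
    return o


# ---------------------------------------------------------------------------
# Measurement
# ---------------------------------------------------------------------------

def _polygon_centroid(pts: np.ndarray) -> tuple[float, float]:
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * cross.sum()
    if abs(a) < 1e-300:
        raise DegenerateOutlineError("polygon has zero area; centroid undefined")
    cx = ((x + xn) * cross).sum() / (6 * a)
    cy = ((y + yn) * cross).sum() / (6 * a)
    return float(cx), float(cy)


def measure_geometry(outline: Outline) -> Geometry:
    """Area (|shoelace|), polygon centroid, x-extent length, y-extent width."""
    pts = outline.points
    area = abs(outline.signed_area())
    if area <= 0:
        raise DegenerateOutlineError(
            f"outline {outline.specimen_id!r} has zero area"
        )
    return Geometry(
        area=area,
        centroid=_polygon_centroid(pts),
        length=float(pts[:, 0].max() - pts[:, 0].min()),
        max_width=float(pts[:, 1].max() - pts[:, 1].min()),
    )
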