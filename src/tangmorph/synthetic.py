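"""Synthetic tanged-tool outlines with known ground truth.

Real tanged-tool outlines come from museum photographs that cannot be
redistributed, so every pipeline test runs on silhouettes generated here
with fully known parameters.  A tool is a half-width profile over its long
axis: a rounded-trapezoid tang (with the paired notches that define the
stem) joined at a shoulder to a blade whose half-width tapers to the tip as
a superellipse of exponent q (small q → pointed, large q → blunt and
rounded).  Side-to-side asymmetry s scales the upper half-widths by (1+s)
and the lower by (1−s).  Edge jitter is a shared seeded perturbation of the
half-width profile applied to both edges, so that asymmetry is controlled
by s alone and a tool generated with −s is the exact mirror image of its +s
twin.

Staged resharpening shortens the tip by a fixed fraction per step while the
tang — parked in the haft — keeps its absolute length.  Trajectories:
``edge_left``/``edge_right`` drift the asymmetry one way per step
(maintaining one lateral edge), ``symmetric_point`` keeps a pointed tip,
``rounding`` blunts the tip into an endscraper-like arc, ``mixed`` draws a
trajectory per lineage.  A separate generator emits an elongated,
low-asymmetry arrowhead-like population for projection comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import ParameterError
from .outline_io import Outline, SpecimenRecord, resample

REDUCTION_MODES = ("none", "symmetric_point", "edge_left", "edge_right", "rounding", "mixed")

NOTCH_DEPTH_FRACTION = 0.25  # of tang half-width; fixed, not a free parameter
ASYMMETRY_BOUND = 0.6
TANG_FRACTION_BOUNDS = (0.1, 0.5)


@dataclass(frozen=True)
class ToolTruth:
    """Ground-truth parameters of one generated tool."""

    specimen_id: str
    length: float = 60.0
    tang_fraction: float = 0.3
    tang_halfwidth: float = 5.0
    blade_halfwidth: float = 10.0
    pointedness: float = 1.5
    asymmetry: float = 0.0
    reduction_step: int = 0
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = TANG_FRACTION_BOUNDS
        # the draw bound applies to fresh lineages; resharpening shortens the
        # tip only, so reduced pieces legitimately carry relatively larger tangs
        hi_eff = hi if self.reduction_step == 0 else 0.9
        if not lo < self.tang_fraction < hi_eff:
            raise ParameterError(
                f"tang_fraction must be in ({lo}, {hi_eff}) at reduction step "
                f"{self.reduction_step}, got {self.tang_fraction}"
            )
        if not -ASYMMETRY_BOUND < self.asymmetry < ASYMMETRY_BOUND:
            raise ParameterError(
                f"asymmetry must be in (-{ASYMMETRY_BOUND}, {ASYMMETRY_BOUND}), "
                f"got {self.asymmetry}"
            )
        if self.length <= 0 or self.pointedness <= 0 or self.noise_sd < 0:
            raise ParameterError("length and pointedness must be positive, noise_sd >= 0")
        if not 0 < self.tang_halfwidth < self.blade_halfwidth:
            raise ParameterError("require 0 < tang_halfwidth < blade_halfwidth")
        if self.reduction_step < 0:
            raise ParameterError("reduction_step must be >= 0")

    @property
    def retouched(self) -> bool:
        return self.reduction_step > 0

    @property
    def tang_length(self) -> float:
        return self.tang_fraction * self.length

    @property
    def tip_length(self) -> float:
        return self.length - self.tang_length

    @property
    def elongation(self) -> float:
        return self.length / (2.0 * self.blade_halfwidth)


@dataclass(frozen=True)
class AssemblageSpec:
    """Distributional recipe for a synthetic assemblage.

    Defaults emulate a mixed tanged-tool sample: lengths around 60 mm,
    moderate blade widths, mild initial asymmetry, and lineages discarded
    after 0–5 resharpening steps along a per-lineage trajectory.
    """

    n: int = 400
    seed: int = 0
    length_mean: float = 60.0
    length_sd: float = 10.0
    tang_fraction_range: tuple[float, float] = (0.22, 0.35)
    blade_halfwidth_fraction_range: tuple[float, float] = (0.12, 0.22)
    tang_halfwidth_fraction_range: tuple[float, float] = (0.45, 0.65)
    pointedness_range: tuple[float, float] = (1.0, 2.2)
    asymmetry_sd: float = 0.10
    noise_sd: float = 0.01
    reduction: str = "mixed"
    max_steps: int = 5
    step_fraction: float = 0.10
    drift: float = 0.08
    n_points: int = 512

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ParameterError("n must be >= 1")
        if self.reduction not in REDUCTION_MODES:
            raise ParameterError(
                f"reduction must be one of {REDUCTION_MODES}, got {self.reduction!r}"
            )
        if not 0 < self.step_fraction < 0.3:
            raise ParameterError("step_fraction must be in (0, 0.3)")


# ---------------------------------------------------------------------------
# Single-tool construction
# ---------------------------------------------------------------------------

def _halfwidth_profile(u: np.ndarray, truth: ToolTruth) -> np.ndarray:
    """Symmetric half-width at relative positions u in [0, 1] (tang at u=0)."""
    f = truth.tang_fraction
    wt, wb = truth.tang_halfwidth, truth.blade_halfwidth
    q = truth.pointedness
    h = np.zeros_like(u)

    butt_end = 0.10 * f      # rounded butt cap
    notch_start = 0.75 * f   # paired notches just below the shoulder
    blend = 0.05 * (1.0 - f)  # shoulder blend width (blade-relative)

    # tang: cap, body, notch dip
    in_cap = u < butt_end
    h[in_cap] = wt * np.sqrt(np.clip(1.0 - ((butt_end - u[in_cap]) / butt_end) ** 2, 0, 1))
    in_body = (u >= butt_end) & (u < notch_start)
    h[in_body] = wt
    in_notch = (u >= notch_start) & (u < f)
    phase = (u[in_notch] - notch_start) / (f - notch_start)
    h[in_notch] = wt * (1.0 - NOTCH_DEPTH_FRACTION * np.sin(np.pi * phase) ** 2)

    # blade: superelliptic taper, smooth-stepped up from the tang at the shoulder
    in_blade = u >= f
    v = (u[in_blade] - f) / (1.0 - f)
    h_blade = wb * np.clip(1.0 - v**q, 0.0, 1.0) ** (1.0 / q)
    ramp = np.clip(v / blend, 0.0, 1.0)
    smooth = ramp * ramp * (3.0 - 2.0 * ramp)
    h[in_blade] = wt + (h_blade - wt) * smooth
    return h


def generate_tool(truth: ToolTruth, n_points: int = 512) -> Outline:
    """Closed, oriented (tang-left, counterclockwise) outline of one tool."""
    n_side = 400
    # open grid: butt vertex and tip vertex added explicitly
    u = np.linspace(0.0, 1.0, n_side + 2)[1:-1]
    h = _halfwidth_profile(u, truth)

    rng = np.random.default_rng(truth.seed)
    jitter = rng.normal(0.0, truth.noise_sd * truth.blade_halfwidth, size=n_side)
    h_j = np.maximum(h + jitter, 0.05 * truth.tang_halfwidth)

    x = u * truth.length
    top = np.column_stack([x, h_j * (1.0 + truth.asymmetry)])
    bottom = np.column_stack([x, -h_j * (1.0 - truth.asymmetry)])
    butt = np.array([[0.0, 0.0]])
    tip = np.array([[truth.length, 0.0]])
    # counterclockwise: butt -> along the bottom edge -> tip -> back along the top
    poly = np.vstack([butt, bottom, tip, top[::-1]])
    outline = Outline(truth.specimen_id, poly)
    return resample(outline, n_points)


# ---------------------------------------------------------------------------
# Staged resharpening
# ---------------------------------------------------------------------------

def _reduced_truth(
    truth: ToolTruth,
    step: int,
    mode: str,
    step_fraction: float,
    drift: float,
    step_seed: int,
) -> ToolTruth:
    """Truth parameters after ``step`` resharpening events (tang length fixed)."""
    tang_abs = truth.tang_length
    tip = truth.tip_length * (1.0 - step_fraction) ** step
    length = tang_abs + tip
    s = truth.asymmetry
    q = truth.pointedness
    if mode == "edge_left":
        s = s - drift * step
    elif mode == "edge_right":
        s = s + drift * step
    elif mode == "rounding":
        q = q * (1.0 + step_fraction) ** step
    elif mode not in ("symmetric_point", "none"):
        raise ParameterError(f"unknown reduction mode {mode!r}")
    s = float(np.clip(s, -0.58, 0.58))
    return replace(
        truth,
        length=length,
        tang_fraction=tang_abs / length,
        asymmetry=s,
        pointedness=q,
        reduction_step=step,
        seed=step_seed,
    )


def simulate_reduction(
    truth: ToolTruth,
    steps: int,
    mode: str = "symmetric_point",
    step_fraction: float = 0.10,
    drift: float = 0.05,
    n_points: int = 512,
) -> list[tuple[ToolTruth, Outline]]:
    """Resharpening trajectory: one (truth, outline) pair per step 0..steps.

    Each step multiplies the tip length by (1 − step_fraction) while the
    tang keeps its absolute length; edge modes drift the asymmetry by
    ±drift per step, ``rounding`` blunts the taper exponent.  Edge jitter is
    redrawn per step from seeds derived from the lineage seed.
    """
    if steps < 1:
        raise ParameterError("steps must be >= 1")
    if not 0 < step_fraction < 0.3:
        raise ParameterError("step_fraction must be in (0, 0.3)")
    rng = np.random.default_rng(truth.seed)
    step_seeds = rng.integers(0, 2**31 - 1, size=steps + 1)
    out = []
    for k in range(steps + 1):
        tk = _reduced_truth(truth, k, mode, step_fraction, drift, int(step_seeds[k]))
        tk = replace(tk, specimen_id=f"{truth.specimen_id}_step{k}")
        out.append((tk, generate_tool(tk, n_points=n_points)))
    return out


# ---------------------------------------------------------------------------
# Assemblages
# ---------------------------------------------------------------------------

def _type_code(truth: ToolTruth, mode: str) -> int:
    """A coarse typological label consistent with the tool's final shape."""
    if not truth.retouched:
        return 1  # unretouched blank
    if truth.pointedness >= 2.8:
        return 30  # endscraper-like rounded tip
    if truth.pointedness <= 1.4 and abs(truth.asymmetry) < 0.15:
        return 6  # retouched point
    return 10 + (truth.seed % 15)  # sidescraper range 10..24


def generate_assemblage(
    spec: AssemblageSpec,
) -> tuple[list[Outline], list[SpecimenRecord], list[ToolTruth]]:
    """Draw ``spec.n`` lineages, each discarded at a random reduction step."""
    rng = np.random.default_rng(spec.seed)
    outlines: list[Outline] = []
    records: list[SpecimenRecord] = []
    truths: list[ToolTruth] = []
    for i in range(spec.n):
        length = float(np.clip(rng.normal(spec.length_mean, spec.length_sd),
                               0.4 * spec.length_mean, 2.0 * spec.length_mean))
        f = float(rng.uniform(*spec.tang_fraction_range))
        wb = float(rng.uniform(*spec.blade_halfwidth_fraction_range)) * length
        wt = float(rng.uniform(*spec.tang_halfwidth_fraction_range)) * wb
        q = float(np.exp(rng.uniform(np.log(spec.pointedness_range[0]),
                                     np.log(spec.pointedness_range[1]))))
        s = float(np.clip(rng.normal(0.0, spec.asymmetry_sd), -0.3, 0.3))
        base_seed = int(rng.integers(0, 2**31 - 1))
        truth0 = ToolTruth(
            specimen_id=f"syn{i:04d}",
            length=length,
            tang_fraction=f,
            tang_halfwidth=wt,
            blade_halfwidth=wb,
            pointedness=q,
            asymmetry=s,
            reduction_step=0,
            noise_sd=spec.noise_sd,
            seed=base_seed,
        )
        if spec.reduction == "none":
            step, mode = 0, "none"
        else:
            step = int(rng.integers(0, spec.max_steps + 1))
            if spec.reduction == "mixed":
                mode = str(rng.choice(
                    ["symmetric_point", "edge_left", "edge_right", "rounding"]
                ))
            else:
                mode = spec.reduction
        step_seed = int(np.random.default_rng(base_seed).integers(0, 2**31 - 1))
        truth = _reduced_truth(
            truth0, step, mode if step > 0 else "none",
            spec.step_fraction, spec.drift, step_seed,
        )
        outline = generate_tool(truth, n_points=spec.n_points)
        outlines.append(outline)
        truths.append(truth)
        records.append(
            SpecimenRecord(
                specimen_id=truth.specimen_id,
                assemblage="synthetic",
                collection_class="excavated",
                retouched=truth.retouched,
                type_code=_type_code(truth, mode),
                length=truth.length,
                tip_length=truth.tip_length,
                tang_length=truth.tang_length,
            )
        )
    return outlines, records, truths


def generate_allometric_sample(
    n: int,
    slope: float,
    seed: int = 0,
    spread_major: float = 0.30,
    spread_minor: float = 0.10,
    center: tuple[float, float] = (3.3, 2.9),
) -> tuple[np.ndarray, np.ndarray]:
    """Bivariate normal (x, y) whose population major axis has the given slope.

    Used for recovery studies of the model-II regression: points are drawn
    with standard deviation ``spread_major`` along the axis of slope
    ``slope`` through ``center`` and ``spread_minor`` perpendicular to it —
    log-scale measurement pairs with a known allometric axis.
    """
    if n < 10:
        raise ParameterError("n must be >= 10")
    if spread_minor >= spread_major:
        raise ParameterError("spread_minor must be < spread_major")
    rng = np.random.default_rng(seed)
    u = np.array([1.0, slope]) / math.hypot(1.0, slope)
    v = np.array([-u[1], u[0]])
    z = rng.normal(size=(n, 2)) * np.array([spread_major, spread_minor])
    xy = np.asarray(center) + z[:, :1] * u + z[:, 1:] * v
    return xy[:, 0], xy[:, 1]


def generate_projectile_population(
    n: int, seed: int = 0, n_points: int = 512
) -> tuple[list[Outline], list[SpecimenRecord]]:
    """An elongated, low-asymmetry, unreduced arrowhead-like population.

    Emulates a sample of true projectile points: high length/width ratio and
    a tight side-to-side symmetry, with no resharpening stages — the
    comparison standard projected into a tool assemblage's shape space.
    """
    if n < 3:
        raise ParameterError("n must be >= 3")
    rng = np.random.default_rng(seed)
    outlines, records = [], []
    for i in range(n):
        length = float(np.clip(rng.normal(55.0, 6.0), 35.0, 80.0))
        wb = float(rng.uniform(0.075, 0.105)) * length
        truth = ToolTruth(
            specimen_id=f"proj{i:03d}",
            length=length,
            tang_fraction=float(rng.uniform(0.20, 0.30)),
            tang_halfwidth=float(rng.uniform(0.50, 0.62)) * wb,
            blade_halfwidth=wb,
            pointedness=float(rng.uniform(0.9, 1.4)),
            asymmetry=float(np.clip(rng.normal(0.0, 0.015), -0.05, 0.05)),
            reduction_step=0,
            noise_sd=0.01,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        outlines.append(generate_tool(truth, n_points=n_points))
        records.append(
            SpecimenRecord(
                specimen_id=truth.specimen_id,
                assemblage="projectile_reference",
                collection_class="excavated",
                retouched=False,
                type_code=None,
                length=truth.length,
                tip_length=truth.tip_length,
                tang_length=truth.tang_length,
            )
        )
    return outlines, records
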