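"""End-to-end orchestration: outlines → EFA → shape space → statistics.

Two analyses are wired here.  The *reduction* analysis asks whether
resharpening happened in the haft: tip lengths of retouched pieces should
be shorter than those of unretouched pieces (Welch test) while tang lengths
stay indistinguishable.  The *shape* analysis characterizes how tools were
resharpened: PCA of the standardized Fourier coefficients, extreme-shape
reconstructions, regressions of shape scores on size, major-axis allometry
of log tang on log tip length, score spread by length quantile, and an
optional projection of an external (e.g. arrowhead) sample into the fitted
space with group data ellipses.

Every intermediate artifact is written as delimited text so each stage can
be re-loaded independently, and all randomness flows from the single
``seed`` in :class:`RunConfig`.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import efa, morphometry, outline_io, shape_space, synthetic
from .errors import ParameterError

log = logging.getLogger("tangmorph")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)


@dataclass(frozen=True)
class RunConfig:
    """Flat configuration of one pipeline run.

    Exactly one input source must be set: ``outlines_path`` (+ optional
    ``metadata_path``), ``masks_path``, or ``simulate`` (a synthetic
    assemblage recipe).
    """

    outlines_path: Optional[str] = None
    masks_path: Optional[str] = None
    metadata_path: Optional[str] = None
    simulate: Optional[synthetic.AssemblageSpec] = None
    harmonics: int = efa.DEFAULT_HARMONICS
    power_threshold: float = efa.DEFAULT_POWER_THRESHOLD
    n_points: int = outline_io.DEFAULT_N_POINTS
    seed: int = 0
    tang_side: str = "left"  # current tang side of file inputs; 'auto' to detect
    welch: bool = True
    regressions: bool = True
    allometry: bool = True
    quantile_spread: bool = True
    projection_reference: Optional[str] = None  # path, or "projectile:<n>"
    out_dir: str = "tangmorph_out"

    def __post_init__(self) -> None:
        sources = [
            self.outlines_path is not None,
            self.masks_path is not None,
            self.simulate is not None,
        ]
        if sum(sources) != 1:
            raise ParameterError(
                "exactly one of outlines_path, masks_path or simulate must be set"
            )
        if self.harmonics < 1:
            raise ParameterError("harmonics must be >= 1")


_CONFIG_KEYS = {
    "outlines_path": str, "masks_path": str, "metadata_path": str,
    "harmonics": int, "power_threshold": float, "n_points": int, "seed": int,
    "tang_side": str,
    "welch": bool, "regressions": bool, "allometry": bool,
    "quantile_spread": bool, "projection_reference": str, "out_dir": str,
}


def read_config(path) -> RunConfig:
    """Parse a flat key=value config file; ``simulate.n=...`` keys build a spec."""
    kwargs: dict = {}
    sim_kwargs: dict = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ParameterError(f"config line without '=': {raw!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        if key.startswith("simulate."):
            sim_kwargs[key[len("simulate."):]] = value
            continue
        if key not in _CONFIG_KEYS:
            raise ParameterError(f"unknown config key {key!r}")
        typ = _CONFIG_KEYS[key]
        kwargs[key] = value.lower() in ("true", "1", "yes") if typ is bool else typ(value)
    if sim_kwargs:
        spec_kwargs = {}
        for f in fields(synthetic.AssemblageSpec):
            if f.name in sim_kwargs:
                v = sim_kwargs.pop(f.name)
                if f.name == "reduction":
                    spec_kwargs[f.name] = v
                elif f.name in ("n", "seed", "max_steps", "n_points"):
                    spec_kwargs[f.name] = int(v)
                elif "range" in f.name:
                    lo, hi = v.split(",")
                    spec_kwargs[f.name] = (float(lo), float(hi))
                else:
                    spec_kwargs[f.name] = float(v)
        if sim_kwargs:
            raise ParameterError(f"unknown simulate.* keys: {sorted(sim_kwargs)}")
        kwargs["simulate"] = synthetic.AssemblageSpec(**spec_kwargs)
    return RunConfig(**kwargs)


# ---------------------------------------------------------------------------
# Input loading
# ---------------------------------------------------------------------------

def _load_inputs(config: RunConfig):
    """Outlines + metadata records (possibly None) for the configured source."""
    if config.simulate is not None:
        spec = replace(config.simulate, seed=config.seed, n_points=config.n_points)
        log.info("simulating assemblage: n=%d seed=%d", spec.n, spec.seed)
        outlines, records, truths = synthetic.generate_assemblage(spec)
        return outlines, records, truths
    if config.outlines_path is not None:
        outlines = outline_io.read_outlines(config.outlines_path)
    else:
        outlines = outline_io.trace_mask(config.masks_path)
    outlines = [
        outline_io.resample(outline_io.orient(o, config.tang_side), config.n_points)
        for o in outlines
    ]
    records = (
        outline_io.read_metadata(config.metadata_path)
        if config.metadata_path
        else None
    )
    return outlines, records, None


def _coefficient_table(outlines, harmonics: int) -> tuple[pd.DataFrame, list]:
    coeffs = []
    for o in outlines:
        geom = outline_io.measure_geometry(o)
        c = efa.standardize(efa.efa_forward(o, H=harmonics), geom.area)
        log.debug("specimen %s standardized: %s", o.specimen_id,
                  sorted(c.normalization_state))
        coeffs.append(c)
    return efa.coefficient_matrix(coeffs), coeffs


# ---------------------------------------------------------------------------
# Analyses
# ---------------------------------------------------------------------------

def run_reduction_analysis(config: RunConfig) -> dict:
    """Welch comparison of tip and tang lengths, retouched vs. unretouched."""
    outlines, records, _ = _load_inputs(config)
    if records is None:
        raise ParameterError("reduction analysis needs metadata with retouch flags")
    meta = outline_io.records_to_frame(records)
    if meta["retouched"].isna().any():
        raise ParameterError("metadata is missing retouch flags")
    retouched = meta[meta["retouched"].astype(bool)]
    unretouched = meta[~meta["retouched"].astype(bool)]
    if len(retouched) < 2:
        raise ParameterError("no retouched group: cannot run the reduction analysis")
    if len(unretouched) < 2:
        raise ParameterError("no unretouched group: cannot run the reduction analysis")
    report: dict = {
        "n_total": int(len(meta)),
        "n_retouched": int(len(retouched)),
        "n_unretouched": int(len(unretouched)),
        "per_assemblage": meta.groupby("assemblage")["specimen_id"].count().to_dict(),
    }
    for part in ("tip_length", "tang_length"):
        res = morphometry.welch_test(
            unretouched[part].to_numpy(float), retouched[part].to_numpy(float)
        )
        report[f"welch_{part}"] = {
            "t": res.t, "df": res.df, "p": res.p,
            "mean_unretouched": res.group_means[0],
            "mean_retouched": res.group_means[1],
        }
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta.to_csv(out / "measurements.csv", index=False)
    _write_report(report, out / "reduction_report")
    return report


def run_shape_analysis(config: RunConfig) -> dict:
    """PCA shape space, size regressions, allometry, spread, optional projection."""
    outlines, records, truths = _load_inputs(config)
    matrix, _ = _coefficient_table(outlines, config.harmonics)
    space = shape_space.fit_pca(matrix)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    n_show = min(3, space.n_components)
    report: dict = {
        "n_specimens": int(len(matrix)),
        "harmonics": int(config.harmonics),
        "n_coefficients": int(matrix.shape[1]),
        "variance_fraction": [float(v) for v in space.variance_fraction[:n_show]],
        "asymmetry_mass": [
            float(v) for v in shape_space.component_asymmetry_mass(space)[:n_show]
        ],
    }
    space.scores.to_csv(out / "scores.csv", float_format="%.17g")
    matrix.to_csv(out / "coefficients.csv", float_format="%.17g")
    extreme_outlines = []
    for comp in range(n_show):
        lo, hi = shape_space.extreme_shape(space, comp, n_points=config.n_points)
        extreme_outlines.extend([lo, hi])
    outline_io.write_outlines(extreme_outlines, out / "extreme_shapes.csv")

    meta = outline_io.records_to_frame(records) if records is not None else None
    if meta is not None:
        meta = meta.set_index("specimen_id").loc[space.scores.index]

    if meta is not None and config.regressions and n_show >= 3:
        asym_mass = shape_space.component_asymmetry_mass(space)[:n_show]
        symmetric_pcs = [i for i in range(n_show) if asym_mass[i] < 0.5] or [1, 2]
        report["regressions"] = {}
        for comp in symmetric_pcs[:2]:
            res = morphometry.regress_pc_on_size(
                space.scores.iloc[:, comp].to_numpy(),
                meta["length"].to_numpy(float),
                meta["tip_length"].to_numpy(float),
            )
            report["regressions"][f"pc{comp + 1}"] = {
                "coefficients": res.coefficients,
                "adjusted_r2": res.adjusted_r2,
                "overall_p": res.overall_p,
            }

    if meta is not None and config.allometry:
        ok = (meta["tang_length"] > 0) & (meta["tip_length"] > 0)
        res = morphometry.major_axis(
            np.log(meta.loc[ok, "tip_length"].to_numpy(float)),
            np.log(meta.loc[ok, "tang_length"].to_numpy(float)),
            seed=config.seed,
        )
        report["allometry"] = {
            "slope": res.slope, "intercept": res.intercept,
            "ci": list(res.ci), "isometric": res.isometric,
        }

    if meta is not None and config.quantile_spread:
        asym_mass = shape_space.component_asymmetry_mass(space)
        asym_pc = int(np.argmax(asym_mass[:n_show]))
        spread = morphometry.spread_by_length(
            space.scores.iloc[:, asym_pc].to_numpy(),
            meta["length"].to_numpy(float),
            mode="equal_n",
            bins=4,
            retouched=meta["retouched"].to_numpy(bool),
        )
        spread.table.to_csv(out / "quantile_spread.csv", index=False)
        report["quantile_spread"] = {
            "asymmetry_pc": f"pc{asym_pc + 1}",
            "iqr": [float(v) for v in spread.table["iqr"]],
        }

    if config.projection_reference:
        ref_outlines = _load_reference(config)
        ref_matrix, _ = _coefficient_table(ref_outlines, config.harmonics)
        ref_scores = shape_space.project(space, ref_matrix)
        ref_scores.to_csv(out / "projection_scores.csv", float_format="%.17g")
        e_main = shape_space.confidence_ellipse(
            space.scores.iloc[:, :2].to_numpy(), group="sample"
        )
        e_ref = shape_space.confidence_ellipse(
            ref_scores.iloc[:, :2].to_numpy(), group="reference"
        )
        asym_mass = shape_space.component_asymmetry_mass(space)
        asym_pc = int(np.argmax(asym_mass[:n_show]))
        report["projection"] = {
            "n_reference": int(len(ref_matrix)),
            "overlap_pc1_pc2": shape_space.overlap_summary(e_main, e_ref),
            "asymmetry_pc": f"pc{asym_pc + 1}",
            "asymmetry_score_var_sample": float(
                space.scores.iloc[:, asym_pc].var()
            ),
            "asymmetry_score_var_reference": float(
                ref_scores.iloc[:, asym_pc].var()
            ),
        }

    _write_report(report, out / "shape_report")
    return report


def _load_reference(config: RunConfig):
    ref = config.projection_reference
    if ref.startswith("projectile:"):
        n = int(ref.split(":", 1)[1])
        outlines, _ = synthetic.generate_projectile_population(
            n, seed=config.seed + 1, n_points=config.n_points
        )
        return outlines
    outlines = outline_io.read_outlines(ref)
    return [
        outline_io.resample(outline_io.orient(o, config.tang_side), config.n_points)
        for o in outlines
    ]


def _write_report(report: dict, stem: Path) -> None:
    stem.with_suffix(".json").write_text(json.dumps(report, indent=2, sort_keys=True))
    lines = [_format_report(report)]
    stem.with_suffix(".txt").write_text("\n".join(lines) + "\n")
    log.info("wrote %s and %s", stem.with_suffix(".json"), stem.with_suffix(".txt"))


def _format_report(d: dict, indent: int = 0) -> str:
    out = []
    pad = "  " * indent
    for k, v in d.items():
        if isinstance(v, dict):
            out.append(f"{pad}{k}:")
            out.append(_format_report(v, indent + 1))
        else:
            out.append(f"{pad}{k}: {v}")
    return "\n".join(out)


def run(config: RunConfig) -> dict:
    """Run every requested analysis; returns the merged report."""
    report: dict = {}
    if config.welch and (config.metadata_path or config.simulate is not None):
        report["reduction"] = run_reduction_analysis(config)
    report["shape"] = run_shape_analysis(config)
    return report
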