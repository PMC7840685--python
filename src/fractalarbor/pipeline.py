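"""End-to-end measurement pipeline: arbors → records → fits → peaks.

``measure_arbor`` takes one centerline arbor through the full chain:
tube mesh synthesis, surface area with interior-face exclusion, convex
hull, box-counted fractal dimension, spine-dilated orientation-averaged
profile, and branch volume.  ``run_pipeline`` drives ensembles described
by a config mapping (or YAML file), assembles a record table, fits the
metric-vs-D cubics and locates the R_PA / R_PV peaks.

Problem sizes (voxel resolutions, viewpoint counts, ensemble sizes) are
all in the config so studies can be scaled to the available compute.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import angles as _angles
from . import arbor as _arbor
from . import boxcount as _boxcount
from . import morphometry as _morph
from . import optimization as _opt
from . import profile as _profile
from . import synthetic as _synth
from .errors import FractalArborError, ParameterError

log = logging.getLogger("fractalarbor")

__all__ = ["MeasureSettings", "measure_arbor", "run_pipeline", "htree_ensemble",
           "neuron_population_check"]


@dataclass
class MeasureSettings:
    """Per-arbor measurement knobs (resolutions in voxels/µm)."""

    boxcount_resolution: float = 4.0
    boxcount_source: str = "centerline"   #: "centerline" (width-free D) or "mesh"
    min_box_um: float | None = None       #: override; see resolved_min_box
    profile_resolution: float = 1.0
    vm_resolution: float = 4.0
    viewpoints: int = 201
    spine_radius: float = 2.0
    slide_step: float = 0.25
    max_offsets: int = 64

    def resolved_min_box(self, arbor=None) -> float:
        """Fine end of the admissible fit window.

        For tube meshes this is the 2 µm branch-diameter scale below
        which counts probe the tube surface.  For the width-free
        centerline the structure ends at the shortest branch instead, so
        the cutoff is that length (clipped between two voxels and 2 µm);
        without it the best-R² search can lock onto the exact power law
        of the sub-branch straight-line regime (slope 1, R² ≈ 1).
        """
        if self.min_box_um is not None:
            return self.min_box_um
        if self.boxcount_source != "centerline":
            return _boxcount.FINE_CUTOFF_UM
        lo = 2.0 / self.boxcount_resolution
        if arbor is None:
            return max(lo, 0.5)
        l_min = min(b.length for b in arbor.branches)
        return float(np.clip(l_min, lo, _boxcount.FINE_CUTOFF_UM))


def measure_dimension_of(arbor: _arbor.CenterlineArbor,
                         settings: MeasureSettings,
                         mesh: _arbor.TriangleMesh | None = None) -> _boxcount.DimensionFit:
    if settings.boxcount_source == "centerline":
        grid = _arbor.voxelize_centerline(arbor, settings.boxcount_resolution)
    else:
        if mesh is None:
            mesh = _arbor.mesh_from_centerline(arbor)
        grid = _arbor.voxelize(mesh, settings.boxcount_resolution)
    curve = _boxcount.box_count(grid, slide_step=settings.slide_step,
                                max_offsets=settings.max_offsets)
    return _boxcount.fit_dimension(curve, min_box_um=settings.resolved_min_box(arbor))


def measure_arbor(arbor: _arbor.CenterlineArbor, arbor_id: str = "arbor",
                  manipulation: str = "none", alpha: float = 1.0,
                  settings: MeasureSettings | None = None) -> _opt.MorphRecord:
    """Full measurement chain producing one :class:`MorphRecord`."""
    s = settings or MeasureSettings()
    t0 = time.perf_counter()
    mesh = _arbor.mesh_from_centerline(arbor)
    hull = _morph.hull_metrics(mesh.vertices)
    if hull.degenerate:
        raise ParameterError(f"{arbor_id}: degenerate (coplanar) hull")
    A_s = _morph.surface_area(mesh, arbor)
    fit = measure_dimension_of(arbor, s, mesh=mesh)
    grid_p = _arbor.voxelize(mesh, s.profile_resolution)
    dilated = _profile.dilate_grid(grid_p, s.spine_radius)
    prof = _profile.mean_profile(dilated, _profile.fibonacci_directions(s.viewpoints))
    V_m = _morph.model_volume(mesh, s.vm_resolution, arbor=arbor)
    log.info("measured %s (D=%.3f) in %.1fs", arbor_id, fit.D, time.perf_counter() - t0)
    return _opt.MorphRecord(
        arbor_id=arbor_id, manipulation=manipulation, alpha=alpha,
        D=fit.D, P=prof.mean_P, A_s=A_s, A_b=hull.area,
        V_b=hull.volume, V_m=V_m,
    )


def htree_ensemble(
    D_targets: list[float],
    weave_sigmas: list[float],
    levels: int = 12,
    total_length: float = 4000.0,
    width: float = 1.0,
    seed: int = 0,
    hurst: float = 0.75,
) -> list[tuple[str, str, float, _arbor.CenterlineArbor]]:
    """Straight + weaving H-trees across scaling exponents.

    Returns (arbor_id, manipulation, parameter, arbor) tuples; total wire
    length is constant across the whole family.
    """
    out = []
    for i, Dt in enumerate(D_targets):
        for j, sig in enumerate(weave_sigmas):
            spec = _synth.HTreeSpec(
                D_target=Dt, levels=levels, total_length=total_length,
                width=width, weave_sigma=sig, hurst=hurst,
                seed=int(seed) + 1000 * i + j,
            )
            arb = _synth.generate_weaving_htree(spec)
            out.append((f"htree_D{Dt:g}_s{sig:g}", "weave_sigma", float(sig), arb))
    return out


def neuron_population_check(data_dir, settings: MeasureSettings | None = None) -> dict:
    """Population statistics on real reconstructions (external data).

    Expects a directory of SWC centerline reconstructions (for example
    the deposited CA1 dataset) and reports the median box-counted D and
    the median D after branch-length equalization.  The data are not
    shipped with the package; without them this raises FileNotFoundError.
    """
    p = Path(data_dir)
    files = sorted(p.glob("*.swc")) if p.is_dir() else []
    if not files:
        raise FileNotFoundError(
            f"no SWC reconstructions found under {data_dir!r}; download the "
            "deposited dataset to run the neuron-population comparison"
        )
    s = settings or MeasureSettings(boxcount_source="mesh")
    import numpy as _np

    from . import morphometry as _m

    Ds, Ds_eq = [], []
    for f in files:
        arb = _arbor.read_swc(f)
        Ds.append(measure_dimension_of(arb, s).D)
        Ds_eq.append(measure_dimension_of(_m.equalize_branch_lengths(arb), s).D)
    return {
        "n_arbors": len(files),
        "median_D": float(_np.median(Ds)),
        "median_D_equalized": float(_np.median(Ds_eq)),
    }


def _build_arbors(config: dict) -> list[tuple[str, str, float, _arbor.CenterlineArbor]]:
    seed = int(config.get("seed", 0))
    entries: list[tuple[str, str, float, _arbor.CenterlineArbor]] = []
    for gen in config.get("generators", []):
        kind = gen["kind"]
        if kind == "htree":
            entries.extend(
                htree_ensemble(
                    gen["D_targets"], gen.get("weave_sigmas", [0.0]),
                    levels=gen.get("levels", 12),
                    total_length=gen.get("total_length", 4000.0),
                    width=gen.get("width", 1.0),
                    seed=gen.get("seed", seed),
                    hurst=gen.get("hurst", 0.75),
                )
            )
        elif kind == "equal_htree":
            arb = _synth.generate_equal_length_htree(
                gen.get("phi", 90.0), gen.get("levels", 12),
                branch_length=gen.get("branch_length"),
                total_length=gen.get("total_length"),
                width=gen.get("width", 1.0),
            )
            entries.append((f"equal_htree_phi{gen.get('phi', 90.0):g}", "none", 1.0, arb))
        elif kind == "toy":
            spec = _synth.ToyArborSpec(
                n_levels=gen.get("n_levels", 7),
                seed=gen.get("seed", seed),
            )
            entries.append((f"toy_{gen.get('seed', seed)}", "none", 1.0,
                            _synth.generate_toy_arbor(spec)))
        else:
            raise ParameterError(f"unknown generator kind: {kind}")
    for path in config.get("inputs", []):
        entries.append((Path(path).stem, "none", 1.0, _arbor.read_swc(path)))
    # α-variants apply to toy/SWC arbors (angle manipulation of neurons)
    alphas = config.get("alphas", [])
    targets = config.get("targets", ["weave"])
    if alphas:
        variants = []
        for name, manip, a, arb in entries:
            if manip != "none":
                continue
            for target in targets:
                for alpha in alphas:
                    spec = _angles.ManipulationSpec(alpha=alpha, target=target)
                    variants.append(
                        (f"{name}_a{alpha:g}_{target}", target, float(alpha),
                         _angles.scale_angles(arb, spec))
                    )
        entries = variants
    return entries


def run_pipeline(config: dict | str | Path, output_dir: str | Path | None = None) -> dict:
    """Run the full study described by ``config`` (mapping or YAML path).

    Writes ``records.csv``, ``curves.json`` and ``peaks.json`` into the
    output directory and returns the results as a dict.  Per-arbor
    failures are logged into a failure manifest; the pipeline continues.
    """
    if not isinstance(config, dict):
        import yaml

        with open(config) as fh:
            config = yaml.safe_load(fh)
    out_dir = Path(output_dir or config.get("output_dir", "fractalarbor_out"))
    out_dir.mkdir(parents=True, exist_ok=True)

    settings = MeasureSettings(**config.get("measure", {}))
    entries = _build_arbors(config)
    records: list[_opt.MorphRecord] = []
    failures: list[dict] = []
    for name, manip, alpha, arb in entries:
        try:
            records.append(measure_arbor(arb, name, manip, alpha, settings))
        except (FractalArborError, ValueError) as exc:
            log.warning("arbor %s failed: %s", name, exc)
            failures.append({"arbor_id": name, "error": f"{type(exc).__name__}: {exc}"})

    df = _opt.records_frame(records)
    df.to_csv(out_dir / "records.csv", index=False)

    result: dict = {"n_records": len(records), "failures": failures,
                    "records": df.to_dict(orient="list")}
    fit_cfg = config.get("fits", {})
    grid_step = fit_cfg.get("grid_step", 0.001)
    if len(df) >= 5 and df.D.nunique() >= 4:
        curves = _opt.fit_optimization_curves(df, n_bins=fit_cfg.get("n_bins", 15))
        lo, hi = curves.D_range
        grid = np.arange(lo, hi + grid_step, grid_step)
        peaks = {}
        r_values = {}
        for which in ("R_PA", "R_PV"):
            R = _opt.compute_R(curves, which, grid)
            pk = _opt.find_peak(R, grid, data_range=curves.D_range)
            peaks[which] = asdict(pk)
            r_values[which] = R.tolist()
        curves_json = {
            "coefficients": {k: list(map(float, v)) for k, v in curves.coeffs.items()},
            "D_range": list(curves.D_range),
            "grid_step": grid_step,
        }
        with open(out_dir / "curves.json", "w") as fh:
            json.dump(curves_json, fh, indent=1)
        with open(out_dir / "peaks.json", "w") as fh:
            json.dump(peaks, fh, indent=1)
        result.update({"curves": curves_json, "peaks": peaks})
    else:
        log.warning("too few records (%d) or D values for cubic fits; skipping",
                    len(df))
        result["warning"] = "too few records for fits"
    with open(out_dir / "failures.json", "w") as fh:
        json.dump(failures, fh, indent=1)
    return result
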