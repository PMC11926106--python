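"""Config-driven orchestration: simulate -> analyze -> report.

A :class:`RunConfig` (YAML/JSON on disk, pydantic-validated in memory)
selects the stages to run and their parameters.  ``simulate`` writes
synthetic inputs in the same formats the analysis stages read (spectral
TIFFs + metadata sidecars, contour CSV, track CSV) plus a ``truth.json``;
``phasor``/``wetting``/``zeta`` write per-object result CSVs; ``report``
aggregates per condition (mean +/- SD) and joins the ground truth when one
is available.  Every run writes a structured log with package versions and
the master seed, and is bit-reproducible for a fixed (config, seed).
"""

from __future__ import annotations

import json
import platform
import time
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import __version__, electrokinetics, io, phasor, synthetic, wetting

__all__ = [
    "RunConfig",
    "PipelineError",
    "run_pipeline",
    "analyze_stack",
    "analyze_contours",
    "analyze_track",
    "default_axis",
]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


# ---------------------------------------------------------------------------
# configuration


class HsiSimConfig(BaseModel):
    fractions: list[float] = [0.0, 0.25, 0.5, 0.75, 1.0]
    n_images: int = Field(3, ge=1)
    photons_per_pixel: float = Field(1.0e4, gt=0)
    shape: tuple[int, int] = (64, 64)
    ring_radius_px: float = Field(20.0, gt=0)
    ring_width_px: float = Field(2.0, gt=0)


class WettingSimConfig(BaseModel):
    sigma_ce: float = Field(15.7, gt=0)  # uN/m, protein condensate scale
    affinity_contrasts: list[float] = [-12.0, -6.0, 0.0, 6.0, 12.0]  # uN/m
    sigma_mean: float = Field(20.0, gt=0)  # uN/m
    n_images: int = Field(3, ge=1)
    vesicle_radius: float = Field(10.0, gt=0)  # um
    pixel_size: float = Field(0.1, gt=0)  # um/pixel
    noise_sigma_px: float = Field(0.5, ge=0)
    n_points_per_arc: int = Field(200, ge=10)


class MediumConfig(BaseModel):
    eta_c: float = Field(3.0, gt=0)  # Pa s
    eta_e: float = Field(1.0e-3, gt=0)  # Pa s
    kappa: float = Field(1.27e9, gt=0)  # 1/m (150 mM 1:1 electrolyte)
    R: float = Field(5.0e-6, gt=0)  # m
    eps_r: float = Field(78.4, gt=0)

    def to_params(self) -> electrokinetics.MediumParams:
        return electrokinetics.MediumParams(eta_c=self.eta_c, eta_e=self.eta_e,
                                            kappa=self.kappa, R=self.R, eps_r=self.eps_r)


class ZetaSimConfig(BaseModel):
    zeta_mV: list[float] = [0.0, 5.0, 10.0, 13.0]  # low-|zeta| condensate range
    n_tracks: int = Field(3, ge=1)
    E: float = Field(1.0e3, gt=0)  # V/m
    D: float = Field(0.05, ge=0)  # um^2/s
    duration: float = Field(1000.0, gt=0)  # s
    dt: float = Field(1.0, gt=0)
    medium: MediumConfig = MediumConfig()


class SimulateConfig(BaseModel):
    kinds: list[Literal["hsi", "wetting", "zeta"]] = ["hsi", "wetting", "zeta"]
    hsi: HsiSimConfig = HsiSimConfig()
    wetting: WettingSimConfig = WettingSimConfig()
    zeta: ZetaSimConfig = ZetaSimConfig()


class PhasorStageConfig(BaseModel):
    stacks: list[str] = []  # TIFF paths; empty -> simulated inputs
    axis: tuple[float, float, float, float] | None = None  # g0, s0, g1, s1
    n_bins: int = Field(100, ge=1)
    harmonic: int = Field(1, ge=1)
    intensity_threshold: float | None = None  # None -> Otsu


class WettingStageConfig(BaseModel):
    contours: str | None = None  # CSV path; None -> simulated inputs
    sigma_ce: float = Field(15.7, gt=0)
    pixel_size: float = Field(0.1, gt=0)


class ZetaStageConfig(BaseModel):
    tracks: str | None = None  # CSV path; None -> simulated inputs
    E: float = Field(1.0e3, gt=0)
    field_axis: tuple[float, float] = (1.0, 0.0)
    medium: MediumConfig = MediumConfig()


class RunConfig(BaseModel):
    """Full pipeline configuration; defaults run every stage end to end."""

    stages: list[Literal["simulate", "phasor", "wetting", "zeta", "report"]]
    seed: int = 0
    out_dir: str = "memwet_out"
    simulate: SimulateConfig = SimulateConfig()
    phasor: PhasorStageConfig = PhasorStageConfig()
    wetting: WettingStageConfig = WettingStageConfig()
    zeta: ZetaStageConfig = ZetaStageConfig()

    @field_validator("stages")
    @classmethod
    def _non_empty(cls, v: list[str]) -> list[str]:
        if not v:
            raise ValueError("stages must name at least one stage")
        return v

    @classmethod
    def default(cls) -> "RunConfig":
        return cls(stages=["simulate", "phasor", "wetting", "zeta", "report"])

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(io.load_config(path))


# ---------------------------------------------------------------------------
# single-object analyses (library surface used by the CLI)


def default_axis() -> phasor.TrajectoryAxis:
    """Gel-to-fluid trajectory anchored at the default reference phasors."""
    wl = synthetic.default_wavelengths()
    spec_gel, spec_fluid = synthetic.make_reference_spectra(
        synthetic.GEL_COMPONENT, synthetic.FLUID_COMPONENT, wl)
    e0 = phasor.spectrum_phasor(spec_gel, wl, synthetic.LAMBDA_MIN, synthetic.LAMBDA_MAX)
    e1 = phasor.spectrum_phasor(spec_fluid, wl, synthetic.LAMBDA_MIN, synthetic.LAMBDA_MAX)
    return phasor.TrajectoryAxis(endpoint_0=e0, endpoint_1=e1)


def analyze_stack(stack: phasor.SpectrumStack, axis: phasor.TrajectoryAxis | None = None,
                  n_bins: int = 100, harmonic: int = 1,
                  intensity_threshold: float | None = None,
                  ) -> tuple[dict, phasor.FractionHistogram]:
    """Fluidity-fraction summary of one hyperspectral stack."""
    if axis is None:
        axis = default_axis()
    field = phasor.compute_phasor(stack, phasor.PhasorConfig(
        harmonic=harmonic, intensity_threshold=intensity_threshold))
    fractions = phasor.project_fraction(field, axis)
    hist = phasor.histogram_fractions(fractions[field.mask], n_bins=n_bins)
    cm = phasor.center_of_mass(hist)
    return {"center_of_mass": cm, "n_pixels": hist.n_pixels,
            "mean_fraction": float(np.nanmean(fractions[field.mask]))}, hist


def analyze_contours(cs: wetting.ContourSet, sigma_ce: float) -> dict:
    """Angles and fluid-elastic parameters of one contour set."""
    circles = {name: wetting.fit_circle(getattr(cs, f"arc_{name}"))
               for name in ("ie", "ic", "ce")}
    angles = wetting.apparent_angles(circles["ie"], circles["ic"], circles["ce"])
    params = wetting.wetting_parameters(angles, sigma_ce)
    report = wetting.validate_geometry(angles, sigma_ce)
    return {
        "image_id": cs.image_id,
        "theta_i": angles.theta_i, "theta_e": angles.theta_e, "theta_c": angles.theta_c,
        "asymmetry_deg": angles.asymmetry_deg,
        "phi": params.phi, "theta_e_in": params.theta_e_in,
        "W": params.affinity_contrast,
        "sigma_ie": params.sigma_ie, "sigma_ic": params.sigma_ic,
        "rms_residual_ie": circles["ie"].rms_residual,
        "rms_residual_ic": circles["ic"].rms_residual,
        "rms_residual_ce": circles["ce"].rms_residual,
        "ic_is_line": circles["ic"].is_line,
        "validation_flags": "; ".join(report.flags),
    }


def analyze_track(track: electrokinetics.DriftTrack,
                  medium: electrokinetics.MediumParams, E: float | None = None) -> dict:
    """Drift velocity and zeta-potential of one condensate trajectory."""
    if E is None:
        E = track.field_magnitude
    fit = electrokinetics.fit_drift(track)
    zeta = electrokinetics.zeta_potential(fit.velocity, medium, E)
    return {"track_id": track.track_id, "nu_m_per_s": fit.velocity,
            "nu_stderr_m_per_s": fit.stderr, "r_squared": fit.r_squared,
            "zeta_mV": zeta * 1e3}


# ---------------------------------------------------------------------------
# stages


def _simulate_stage(cfg: RunConfig, out: Path, log: list[str]) -> None:
    sim_dir = out / "simulated"
    sim_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    truth: dict[str, dict] = {}

    if "hsi" in cfg.simulate.kinds:
        h = cfg.simulate.hsi
        for f in h.fractions:
            for rep in range(h.n_images):
                image_id = f"hsi_f{f:g}_r{rep}"
                stack, tr = synthetic.simulate_hsi_vesicle(
                    f=f, shape=h.shape, ring_radius_px=h.ring_radius_px,
                    ring_width_px=h.ring_width_px,
                    photons_per_pixel=h.photons_per_pixel,
                    seed=int(rng.integers(2**31)))
                io.write_stack(stack, sim_dir / f"{image_id}.tiff")
                truth[image_id] = {"kind": "hsi", "condition": f"f={f:g}", **tr.params}
        log.append(f"simulate: wrote {len(h.fractions) * h.n_images} hyperspectral stacks")

    if "wetting" in cfg.simulate.kinds:
        w = cfg.simulate.wetting
        contour_sets = []
        for W in w.affinity_contrasts:
            for rep in range(w.n_images):
                image_id = f"wet_W{W:g}_r{rep}"
                cs, tr = synthetic.simulate_wetting_geometry(
                    sigma_ce=w.sigma_ce, W=W, sigma_mean=w.sigma_mean,
                    vesicle_radius=w.vesicle_radius, pixel_size=w.pixel_size,
                    noise_sigma=w.noise_sigma_px, n_points_per_arc=w.n_points_per_arc,
                    seed=int(rng.integers(2**31)), image_id=image_id)
                contour_sets.append(cs)
                truth[image_id] = {"kind": "wetting", "condition": f"W={W:g}", **tr.params}
        io.write_contours(contour_sets, sim_dir / "contours.csv")
        log.append(f"simulate: wrote {len(contour_sets)} contour sets")

    if "zeta" in cfg.simulate.kinds:
        z = cfg.simulate.zeta
        tracks = []
        for zv in z.zeta_mV:
            for rep in range(z.n_tracks):
                track_id = f"zeta_{zv:g}mV_r{rep}"
                track, tr = synthetic.simulate_drift_track(
                    zeta=zv * 1e-3, params=z.medium.to_params(), E=z.E, D=z.D,
                    duration=z.duration, dt=z.dt,
                    seed=int(rng.integers(2**31)), track_id=track_id)
                tracks.append(track)
                truth[track_id] = {"kind": "zeta", "condition": f"zeta={zv:g}mV", **tr.params}
        io.write_tracks(tracks, sim_dir / "tracks.csv")
        log.append(f"simulate: wrote {len(tracks)} drift tracks")

    (sim_dir / "truth.json").write_text(json.dumps(truth, indent=1))


def _phasor_stage(cfg: RunConfig, out: Path, log: list[str]) -> None:
    paths = [Path(p) for p in cfg.phasor.stacks]
    if not paths:
        paths = sorted((out / "simulated").glob("hsi_*.tiff"))
    if not paths:
        raise PipelineError("phasor: no input stacks (configure phasor.stacks or run simulate)")
    axis = (phasor.TrajectoryAxis(cfg.phasor.axis[:2], cfg.phasor.axis[2:])
            if cfg.phasor.axis is not None else default_axis())
    rows, hists = [], []
    for path in paths:
        stack = io.read_stack(path)
        res, hist = analyze_stack(stack, axis=axis, n_bins=cfg.phasor.n_bins,
                                  harmonic=cfg.phasor.harmonic,
                                  intensity_threshold=cfg.phasor.intensity_threshold)
        image_id = path.stem
        rows.append({"image_id": image_id, **res})
        hists.append(pd.DataFrame({"image_id": image_id,
                                   "bin_position": hist.bin_positions,
                                   "frequency": hist.frequencies}))
    pd.DataFrame(rows).to_csv(out / "phasor_results.csv", index=False)
    pd.concat(hists, ignore_index=True).to_csv(out / "phasor_histograms.csv", index=False)
    log.append(f"phasor: analyzed {len(rows)} stacks")


def _wetting_stage(cfg: RunConfig, out: Path, log: list[str]) -> None:
    path = cfg.wetting.contours or out / "simulated" / "contours.csv"
    if not Path(path).exists():
        raise PipelineError("wetting: no contour CSV (configure wetting.contours or run simulate)")
    contour_sets = io.read_contours(path, pixel_size=cfg.wetting.pixel_size)
    rows = [analyze_contours(cs, cfg.wetting.sigma_ce) for cs in contour_sets.values()]
    pd.DataFrame(rows).to_csv(out / "wetting_results.csv", index=False)
    log.append(f"wetting: analyzed {len(rows)} contour sets")


def _zeta_stage(cfg: RunConfig, out: Path, log: list[str]) -> None:
    path = cfg.zeta.tracks or out / "simulated" / "tracks.csv"
    if not Path(path).exists():
        raise PipelineError("zeta: no track CSV (configure zeta.tracks or run simulate)")
    tracks = io.read_tracks(path, field_magnitude=cfg.zeta.E, field_axis=cfg.zeta.field_axis)
    medium = cfg.zeta.medium.to_params()
    rows = [analyze_track(t, medium) for t in tracks]
    pd.DataFrame(rows).to_csv(out / "zeta_results.csv", index=False)
    log.append(f"zeta: analyzed {len(rows)} tracks")


_REPORT_METRICS = {
    "phasor": ("phasor_results.csv", "image_id", "center_of_mass", "f"),
    "wetting": ("wetting_results.csv", "image_id", "phi", "phi"),
    "zeta": ("zeta_results.csv", "track_id", "zeta_mV", "zeta_mV"),
}


def _report_stage(cfg: RunConfig, out: Path, log: list[str]) -> None:
    truth_path = out / "simulated" / "truth.json"
    truth = json.loads(truth_path.read_text()) if truth_path.exists() else {}
    blocks = []
    for stage, (fname, id_col, metric, truth_key) in _REPORT_METRICS.items():
        fpath = out / fname
        if not fpath.exists():
            continue
        df = pd.read_csv(fpath)
        df["condition"] = [truth.get(i, {}).get("condition", "all") for i in df[id_col]]
        df["truth"] = [truth.get(i, {}).get(truth_key, np.nan) for i in df[id_col]]
        grp = df.groupby("condition", sort=False)[metric].agg(["mean", "std", "count"])
        tr = df.groupby("condition", sort=False)["truth"].mean()
        blocks.append(pd.DataFrame({
            "stage": stage, "metric": metric, "condition": grp.index,
            "truth": tr.values, "estimate_mean": grp["mean"].values,
            "estimate_sd": grp["std"].values, "n": grp["count"].values,
        }))
    if not blocks:
        raise PipelineError("report: no result tables to aggregate")
    pd.concat(blocks, ignore_index=True).to_csv(out / "summary.csv", index=False)
    log.append(f"report: wrote summary for {len(blocks)} stages")


_STAGES = {
    "simulate": _simulate_stage,
    "phasor": _phasor_stage,
    "wetting": _wetting_stage,
    "zeta": _zeta_stage,
    "report": _report_stage,
}


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages in order; returns the output directory.

    Each stage reads/writes files under ``config.out_dir``.  A structured
    run log (versions, seed, per-stage messages) is written alongside the
    result tables.  Stage failures raise :class:`PipelineError` naming the
    stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    t0 = time.time()
    for stage in config.stages:
        try:
            _STAGES[stage](config, out, log)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise PipelineError(f"stage '{stage}' failed: {exc}") from exc
    (out / "run_log.json").write_text(json.dumps({
        "memwet_version": __version__,
        "numpy_version": np.__version__,
        "python_version": platform.python_version(),
        "seed": config.seed,
        "stages": list(config.stages),
        "messages": log,
        "elapsed_s": round(time.time() - t0, 3),
        "config": config.model_dump(),
    }, indent=1, default=str))
    return out
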