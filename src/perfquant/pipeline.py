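"""Workflow orchestration: phantom-mode and volunteer-mode pipelines.

Phantom mode simulates the dual-bolus / dual-tracer protocol at each flow of
the grid, quantifies each run with both arms (Fermi-constrained
deconvolution of the MR curves; decay correction + 1TC fit of the PET TACs)
and compares the arms with the agreement statistics.  Volunteer mode
consumes user-provided ROI curve files instead of the simulator.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
from pydantic import BaseModel, Field

from .agreement import AgreementReport, PairedMeasurements, agreement_report
from .cmr import FermiFit, FermiFitOptions, baseline_correct, exponential_tail, fit_fermi
from .io import config_hash, read_curve_csv, write_curve_csv, write_tac_csv
from .mr_signal import (
    assemble_dual_bolus_aif,
    build_lut,
    detect_bolus_foot,
    MRProtocol,
    normalize_aif_integral,
    signal_to_concentration,
)
from .pet import N13_HALF_LIFE_MIN, OneTCFit, OneTCFitOptions, decay_correct, fit_1tc
from .phantom import PhantomConfig, PhantomDataset, simulate_protocol

__all__ = [
    "PipelineConfig",
    "StageError",
    "quantify_cmr_phantom",
    "quantify_pet_phantom",
    "run_phantom_study",
    "run_pipeline",
    "PhantomStudyResult",
]

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; names the stage and region."""

    def __init__(self, stage: str, region: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for {region!r}: {cause}")
        self.stage = stage
        self.region = region
        self.cause = cause


# ---------------------------------------------------------------------------
# phantom-mode quantification
# ---------------------------------------------------------------------------

#: seconds of AIF window retained after the detected bolus foot; the
#: gamma-variate first pass has decayed below 2% of peak well inside this
AIF_SUPPORT_S = 50.0
#: myocardial analysis window starts this many seconds before the neat bolus
PRE_NEAT_MARGIN_S = 5.0


def _phantom_mr_curves(ds: PhantomDataset):
    """Baseline-corrected dilute-AIF surrogate and myocardial curve.

    Returns the surrogate AIF (dose-ratio-scaled, foot-aligned to the neat
    arrival, cropped to its bolus support) and the myocardial curve over the
    neat-bolus window, re-baselined on the samples immediately preceding the
    neat arrival so residual dilute-bolus washout does not leak in.
    """
    cfg = ds.config
    sig_aif = baseline_correct(ds.mr_signal_aif, cfg.n_baseline)
    sig_myo = baseline_correct(ds.mr_signal_myo, cfg.n_baseline)

    guard = cfg.neat_arrival - 3.0 * cfg.dynamic_interval
    dilute = sig_aif.crop(t_max=guard)
    surrogate = assemble_dual_bolus_aif(dilute, cfg.dose_ratio, cfg.neat_arrival)

    t0 = cfg.neat_arrival - PRE_NEAT_MARGIN_S
    myo_w = sig_myo.crop(t_min=t0)
    pre = sig_myo.crop(t_min=t0 - 3.0 * cfg.dynamic_interval, t_max=t0 - 1e-9)
    myo_w = myo_w.with_values(myo_w.values - pre.values.mean())

    aif_vals = surrogate.sample(myo_w.times)
    support = (myo_w.times >= cfg.neat_arrival - 2.0) & (
        myo_w.times <= cfg.neat_arrival + AIF_SUPPORT_S
    )
    aif_vals = np.where(support, np.maximum(aif_vals, 0.0), 0.0)
    aif_w = myo_w.with_values(aif_vals)
    return aif_w, myo_w


def quantify_cmr_phantom(ds: PhantomDataset, opts: FermiFitOptions | None = None) -> FermiFit:
    """CMR arm on a phantom dataset.

    Baseline correction, dual-bolus AIF assembly, integral normalization of
    the AIF to the myocardial curve (with analytic exponential completion of
    the truncated washout tail, so the conservation identity
    int C_m = int C_a holds on the finite acquisition window), then
    Fermi-constrained deconvolution.  MBF is calibrated by the phantom's
    known dispersion volume per mass.
    """
    cfg = ds.config
    aif_w, myo_w = _phantom_mr_curves(ds)
    i_myo = myo_w.integral()
    tail = exponential_tail(myo_w)
    if tail is not None:
        i_myo += tail[3]
    aif_n = normalize_aif_integral(aif_w, myo_w)
    aif_n = aif_n.with_values(aif_n.values * (i_myo / myo_w.integral()))
    if opts is None:
        opts = FermiFitOptions(vd_per_mass=cfg.vd_per_mass)
    return fit_fermi(aif_n, myo_w, opts)


def quantify_pet_phantom(ds: PhantomDataset, window_s: float = 240.0,
                         opts: OneTCFitOptions | None = None) -> OneTCFit:
    """PET arm on a phantom dataset: decay-correct, 1TC fit with Vb = 0.

    The phantom compartment has no arterial spillover geometry, so the
    blood-volume fraction is fixed at zero.
    """
    cfg = ds.config
    aif_c = decay_correct(ds.pet_tac_aif, cfg.half_life_min)
    myo_c = decay_correct(ds.pet_tac_myo, cfg.half_life_min)
    if opts is None:
        opts = OneTCFitOptions(fit_vb=False, vd_per_mass=cfg.vd_per_mass)
    return fit_1tc(aif_c, myo_c, window_s=window_s, opts=opts)


# ---------------------------------------------------------------------------
# phantom study sweep
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomStudyResult:
    """Both-arm MBF estimates over a flow grid plus their agreement."""

    flows: tuple[float, ...]
    cmr_mbf: tuple[float, ...]
    pet_mbf: tuple[float, ...]
    agreement: AgreementReport

    def to_dict(self) -> dict:
        return {
            "flows": list(self.flows),
            "cmr_mbf": list(self.cmr_mbf),
            "pet_mbf": list(self.pet_mbf),
            "agreement": self.agreement.to_dict(),
        }


def run_phantom_study(flows=(1.0, 2.0, 3.0, 4.0, 5.0), seed: int = 0,
                      window_s: float = 240.0, **config_overrides) -> PhantomStudyResult:
    """Simulate and quantify one pass over the flow grid with both arms."""
    cmr_vals, pet_vals = [], []
    for i, flow in enumerate(flows):
        cfg = PhantomConfig(flow=float(flow), seed=seed + 7919 * i, **config_overrides)
        ds = simulate_protocol(cfg)
        cmr_vals.append(quantify_cmr_phantom(ds).mbf)
        pet_vals.append(quantify_pet_phantom(ds, window_s=window_s).mbf)
    pairs = PairedMeasurements(tuple(f"flow_{f:g}" for f in flows),
                               np.array(cmr_vals), np.array(pet_vals))
    return PhantomStudyResult(tuple(float(f) for f in flows),
                              tuple(cmr_vals), tuple(pet_vals),
                              agreement_report(pairs))


# ---------------------------------------------------------------------------
# configuration and the orchestrated pipelines
# ---------------------------------------------------------------------------

class MRBlock(BaseModel):
    ti_ms: float = 100.0
    tr_ms: float = 1.9
    flip_deg: float = 10.0
    n_dynamics: int = 240
    n_baseline: int = 8
    dynamic_interval_s: float = 1.0
    r1_relaxivity: float = 5.0
    t10_ms: float = 3000.0
    m0: float = 1000.0

    def protocol(self) -> MRProtocol:
        return MRProtocol(**self.model_dump())


class PETBlock(BaseModel):
    half_life_min: float = N13_HALF_LIFE_MIN
    window_s: float = 240.0
    vb_mode: Literal["fixed_zero", "fitted"] = "fixed_zero"


class DualBolusBlock(BaseModel):
    dose_ratio: float = 10.0
    delay_s: float = 120.0
    foot_threshold: float = 0.05


class PhantomBlock(BaseModel):
    flows: list[float] = Field(default_factory=lambda: [1.0, 2.0, 3.0, 4.0, 5.0])
    noise_mr_sigma: float = 0.1
    noise_pet_cv: float = 0.03
    dispersion_volume: float = 45.0
    tissue_mass: float = 45.0
    heart_rate: float = 60.0


class VolunteerBlock(BaseModel):
    aif_signal_csv: str | None = None
    myo_signal_csvs: dict[str, str] = Field(default_factory=dict)
    pet_aif_tac_csv: str | None = None
    pet_myo_tac_csvs: dict[str, str] = Field(default_factory=dict)
    neat_arrival_s: float | None = None
    lut_conc_max: float = 10.0
    lut_points: int = 4096
    density_g_per_ml: float = 1.05


class PipelineConfig(BaseModel):
    """Schema-validated configuration for the `run` workflow."""

    mode: Literal["phantom", "volunteer"] = "phantom"
    seed: int = 0
    output_dir: str = "perfquant_out"
    mr: MRBlock = Field(default_factory=MRBlock)
    pet: PETBlock = Field(default_factory=PETBlock)
    dual_bolus: DualBolusBlock = Field(default_factory=DualBolusBlock)
    phantom: PhantomBlock = Field(default_factory=PhantomBlock)
    volunteer: VolunteerBlock = Field(default_factory=VolunteerBlock)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured workflow end to end, writing all artifacts.

    Every output carries the config hash and seed, so the run is fully
    regenerable from configuration alone.  Returns the machine-readable run
    report (also written as ``report.json``).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    # hash the scientific configuration only; where it is written is not
    # part of its identity
    chash = config_hash(config.model_dump(exclude={"output_dir"}))
    meta = {"config_hash": chash, "seed": str(config.seed)}
    report: dict = {"mode": config.mode, "config_hash": chash, "seed": config.seed,
                    "stages": [], "_timings": []}
    t_start = time.time()

    if config.mode == "phantom":
        _run_phantom_mode(config, out, meta, report)
    else:
        _run_volunteer_mode(config, out, meta, report)

    # wall times go to the log only, keeping report.json byte-reproducible
    # for identical config + seed
    timings = report.pop("_timings")
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default, sort_keys=True)
    with open(out / "run.log", "w") as fh:
        fh.write(f"config_hash={chash} seed={config.seed} "
                 f"total={time.time() - t_start:.3f} s\n")
        for st, dt in zip(report["stages"], timings):
            fh.write(f"{st['stage']}: {st.get('detail', '')} [{dt:.3f} s]\n")
    return report


def _stage(report: dict, name: str, detail: str, t0: float) -> None:
    report["stages"].append({"stage": name, "detail": detail})
    report["_timings"].append(time.time() - t0)


def _run_phantom_mode(config: PipelineConfig, out: Path, meta: dict, report: dict) -> None:
    pb = config.phantom
    overrides = dict(
        noise_mr_sigma=pb.noise_mr_sigma, noise_pet_cv=pb.noise_pet_cv,
        dispersion_volume=pb.dispersion_volume, tissue_mass=pb.tissue_mass,
        heart_rate=pb.heart_rate, dose_ratio=config.dual_bolus.dose_ratio,
        interbolus_delay=config.dual_bolus.delay_s,
        n_dynamics=config.mr.n_dynamics, n_baseline=config.mr.n_baseline,
        half_life_min=config.pet.half_life_min, mr_protocol=config.mr.protocol(),
    )
    rows = []
    for i, flow in enumerate(pb.flows):
        t0 = time.time()
        cfg = PhantomConfig(flow=float(flow), seed=config.seed + 7919 * i, **overrides)
        try:
            ds = simulate_protocol(cfg)
        except Exception as exc:
            raise StageError("simulate", f"flow_{flow:g}", exc) from exc
        tag = f"flow{flow:g}"
        write_curve_csv(out / f"{tag}_aif_conc.csv", ds.aif_conc, meta)
        write_curve_csv(out / f"{tag}_myo_conc.csv", ds.myo_conc, meta)
        write_curve_csv(out / f"{tag}_mr_signal_aif.csv", ds.mr_signal_aif, meta)
        write_curve_csv(out / f"{tag}_mr_signal_myo.csv", ds.mr_signal_myo, meta)
        write_tac_csv(out / f"{tag}_pet_tac_aif.csv", ds.pet_tac_aif, meta)
        write_tac_csv(out / f"{tag}_pet_tac_myo.csv", ds.pet_tac_myo, meta)
        with open(out / f"{tag}_truth.json", "w") as fh:
            json.dump({"truth_flow": flow, "config_hash": meta["config_hash"],
                       "seed": cfg.seed}, fh)
        try:
            cfit = quantify_cmr_phantom(ds)
        except Exception as exc:
            raise StageError("quant-cmr", f"flow_{flow:g}", exc) from exc
        try:
            pfit = quantify_pet_phantom(ds, window_s=config.pet.window_s)
        except Exception as exc:
            raise StageError("quant-pet", f"flow_{flow:g}", exc) from exc
        rows.append({"flow": flow, "cmr_mbf": cfit.mbf, "pet_mbf": pfit.mbf,
                     "cmr_converged": cfit.converged, "pet_converged": pfit.converged})
        _stage(report, "quantify", f"flow {flow:g}: cmr={cfit.mbf:.3f} "
               f"pet={pfit.mbf:.3f} mL/g/min", t0)
    report["per_flow"] = rows
    if len(rows) >= 2:
        pairs = PairedMeasurements(tuple(f"flow_{r['flow']:g}" for r in rows),
                                   np.array([r["cmr_mbf"] for r in rows]),
                                   np.array([r["pet_mbf"] for r in rows]))
        report["agreement"] = agreement_report(pairs).to_dict()


def _run_volunteer_mode(config: PipelineConfig, out: Path, meta: dict, report: dict) -> None:
    vb = config.volunteer
    protocol = config.mr.protocol()
    rows: dict = {}

    if vb.aif_signal_csv and vb.myo_signal_csvs:
        t0 = time.time()
        try:
            aif_sig = read_curve_csv(vb.aif_signal_csv)
        except FileNotFoundError as exc:
            raise StageError("read-curves", vb.aif_signal_csv, exc) from exc
        lut = build_lut(protocol, vb.lut_conc_max, vb.lut_points)
        aif_bc = baseline_correct(aif_sig, protocol.n_baseline)
        baseline = float(aif_sig.values[: protocol.n_baseline].mean())
        aif_conc = signal_to_concentration(aif_sig, lut, baseline).curve
        aif_conc = baseline_correct(aif_conc, protocol.n_baseline)
        neat = vb.neat_arrival_s
        if neat is None:
            neat = detect_bolus_foot(aif_bc) + config.dual_bolus.delay_s
        aif_surr = assemble_dual_bolus_aif(
            aif_conc, config.dual_bolus.dose_ratio, neat,
            threshold_frac=config.dual_bolus.foot_threshold)
        _stage(report, "aif", f"surrogate AIF foot at {neat:.1f} s", t0)
        for region, path in vb.myo_signal_csvs.items():
            t0 = time.time()
            try:
                myo_sig = read_curve_csv(path)
            except FileNotFoundError as exc:
                raise StageError("read-curves", path, exc) from exc
            myo_base = float(myo_sig.values[: protocol.n_baseline].mean())
            myo_conc = signal_to_concentration(
                myo_sig, build_lut(
                    MRProtocol(**{**protocol.__dict__, "t10_ms": 1200.0}),
                    vb.lut_conc_max, vb.lut_points),
                myo_base).curve
            myo_conc = baseline_correct(myo_conc, protocol.n_baseline)
            opts = FermiFitOptions(vd_per_mass=1.0 / vb.density_g_per_ml)
            fit = fit_fermi(aif_surr.with_values(aif_surr.sample(myo_conc.times)),
                            myo_conc, opts)
            rows.setdefault("cmr", {})[region] = {
                "mbf": fit.mbf, "rss": fit.rss, "converged": fit.converged}
            _stage(report, "quant-cmr", f"{region}: mbf={fit.mbf:.3f}", t0)

    if vb.pet_aif_tac_csv and vb.pet_myo_tac_csvs:
        t0 = time.time()
        try:
            aif_tac = read_curve_csv(vb.pet_aif_tac_csv)
        except FileNotFoundError as exc:
            raise StageError("read-tacs", vb.pet_aif_tac_csv, exc) from exc
        if not aif_tac.decay_corrected:
            aif_tac = decay_correct(aif_tac, config.pet.half_life_min)
        _stage(report, "pet-aif", "input TAC decay-corrected", t0)
        for region, path in vb.pet_myo_tac_csvs.items():
            t0 = time.time()
            try:
                myo_tac = read_curve_csv(path)
            except FileNotFoundError as exc:
                raise StageError("read-tacs", path, exc) from exc
            if not myo_tac.decay_corrected:
                myo_tac = decay_correct(myo_tac, config.pet.half_life_min)
            opts = OneTCFitOptions(fit_vb=config.pet.vb_mode == "fitted",
                                   vd_per_mass=1.0 / vb.density_g_per_ml)
            fit = fit_1tc(aif_tac, myo_tac, window_s=config.pet.window_s, opts=opts)
            rows.setdefault("pet", {})[region] = {
                "mbf": fit.mbf, "K1": fit.params.K1, "k2": fit.params.k2,
                "Vb": fit.params.Vb, "converged": fit.converged}
            _stage(report, "quant-pet", f"{region}: mbf={fit.mbf:.3f}", t0)

    report["fits"] = rows
    both = set(rows.get("cmr", {})) & set(rows.get("pet", {}))
    if len(both) >= 2:
        labels = sorted(both)
        pairs = PairedMeasurements(
            tuple(labels),
            np.array([rows["cmr"][r]["mbf"] for r in labels]),
            np.array([rows["pet"][r]["mbf"] for r in labels]))
        report["agreement"] = agreement_report(pairs).to_dict()
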