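"""Digital twin of the physical perfusion phantom.

A well-mixed "myocardial" compartment of known dispersion volume V_d is fed
by a bolus-shaped arterial input; the compartment obeys

    dC_m/dt = (Q / V_d) (C_a - C_m),      Q = flow * tissue_mass  [mL/min],

so knowledge of V_d and the mass equivalent calibrates recovered rate
constants to mL/g/min, exactly as in the bench phantom.  One protocol run
reproduces the dual-bolus / dual-tracer injection scheme: a dilute
gadolinium bolus, an interbolus-delay-later neat bolus (1:10 dose ratio)
co-injected with the 13N-ammonia tracer, MR dynamics at one sample per
heartbeat and PET activity binned into the acquisition frame scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .curves import FramedTAC, InvalidInputError, SampledCurve
from .mr_signal import MRProtocol, PHANTOM_PROTOCOL, srflash_signal
from .pet import N13_HALF_LIFE_MIN, bin_frames, default_frame_scheme

__all__ = [
    "BolusSpec",
    "PhantomConfig",
    "PhantomDataset",
    "generate_aif",
    "simulate_tissue_curve",
    "simulate_protocol",
]


@dataclass(frozen=True)
class BolusSpec:
    """A gamma-variate bolus: relative dose (neat == 1), arrival and shape.

    The curve is peak-normalized so a unit-dose bolus has maximum 1; its
    mode sits at ``arrival_time + shape_alpha * shape_beta``.
    """

    dose: float
    arrival_time: float
    shape_alpha: float = 3.0
    shape_beta: float = 4.0

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise InvalidInputError("dose must be non-negative")
        if self.shape_alpha <= 0 or self.shape_beta <= 0:
            raise InvalidInputError("gamma-variate shape parameters must be positive")


@dataclass(frozen=True)
class PhantomConfig:
    """One phantom run.

    ``flow`` is the ground-truth perfusion rate (mL/g/min);
    ``dispersion_volume`` (mL) and ``tissue_mass`` (g) define the sampled
    compartment — the default unit ratio maps mL/min 1:1 onto mL/g/min.
    Noise parameters of zero give a bit-reproducible noise-free dataset.
    """

    flow: float
    dispersion_volume: float = 45.0
    tissue_mass: float = 45.0
    heart_rate: float = 60.0
    interbolus_delay: float = 120.0
    n_dynamics: int = 240
    n_baseline: int = 8
    pet_duration: float = 300.0
    noise_mr_sigma: float = 0.1
    noise_pet_cv: float = 0.03
    seed: int = 0
    dose_ratio: float = 10.0
    neat_peak_conc: float = 0.5  # mmol/L, arterial peak of the neat bolus
    tracer_peak_activity: float = 100.0  # kBq/mL, arterial peak
    bolus_alpha: float = 3.0
    bolus_beta: float = 4.0
    half_life_min: float = N13_HALF_LIFE_MIN
    mr_protocol: MRProtocol = field(default_factory=lambda: PHANTOM_PROTOCOL)
    fine_dt: float = 0.1

    def __post_init__(self) -> None:
        if self.flow <= 0 or self.dispersion_volume <= 0 or self.tissue_mass <= 0:
            raise InvalidInputError("flow, dispersion_volume and tissue_mass must be positive")
        if self.heart_rate <= 0:
            raise InvalidInputError("heart_rate must be positive")
        if self.interbolus_delay < 0:
            raise InvalidInputError("interbolus_delay must be non-negative")

    @property
    def dynamic_interval(self) -> float:
        """MR dynamic spacing: one dynamic per heartbeat, s."""
        return 60.0 / self.heart_rate

    @property
    def dilute_arrival(self) -> float:
        """Dilute bolus foot: just after the baseline dynamics."""
        return self.n_baseline * self.dynamic_interval + 2.0

    @property
    def neat_arrival(self) -> float:
        return self.dilute_arrival + self.interbolus_delay

    @property
    def washout_rate(self) -> float:
        """Compartment washout rate Q / V_d in s^-1."""
        return self.flow * self.tissue_mass / self.dispersion_volume / 60.0

    @property
    def vd_per_mass(self) -> float:
        """Calibration factor V_d / mass (mL/g) converting min^-1 to mL/g/min."""
        return self.dispersion_volume / self.tissue_mass


@dataclass(frozen=True)
class PhantomDataset:
    """Everything one simulated protocol run produces, on one protocol clock."""

    truth_flow: float
    aif_conc: SampledCurve  # gadolinium, fine grid, mmol/L
    myo_conc: SampledCurve
    mr_signal_aif: SampledCurve  # a.u., one sample per heartbeat
    mr_signal_myo: SampledCurve
    pet_tac_aif: FramedTAC  # frame-binned, decay applied, not corrected
    pet_tac_myo: FramedTAC
    config: PhantomConfig


def generate_aif(boluses: list[BolusSpec], time_grid: np.ndarray,
                 unit: str = "1") -> SampledCurve:
    """Sum of dose-scaled, peak-normalized gamma-variate boluses.

    g(t) = dose * ((t - t_a) / (alpha beta))^alpha * exp(alpha - (t - t_a)/beta)
    for t > t_a, zero before; linear in dose, so an empty bolus list yields
    the all-zero curve.
    """
    t = np.asarray(time_grid, dtype=float)
    if t.ndim != 1 or len(t) < 2 or np.any(np.diff(t) <= 0):
        raise InvalidInputError("time_grid must be 1-D and strictly increasing")
    total = np.zeros_like(t)
    for b in boluses:
        if b.arrival_time > t[-1]:
            raise InvalidInputError(
                f"bolus arrival {b.arrival_time} s lies beyond the grid span {t[-1]} s"
            )
        s = t - b.arrival_time
        pos = s > 0
        g = np.zeros_like(t)
        sp = s[pos]
        g[pos] = (sp / (b.shape_alpha * b.shape_beta)) ** b.shape_alpha * np.exp(
            b.shape_alpha - sp / b.shape_beta
        )
        total += b.dose * g
    return SampledCurve(t, total, unit=unit)


def simulate_tissue_curve(aif: SampledCurve, flow: float, dispersion_volume: float,
                          tissue_mass: float) -> SampledCurve:
    """Concentration in the well-mixed compartment driven by ``aif``.

    C_m(t) = (Q/V_d) int_0^t C_a(u) exp(-(Q/V_d)(t - u)) du with
    Q = flow * tissue_mass; evaluated by exact integration of the exponential
    kernel against the piecewise-linear interpolant of C_a.
    """
    if flow <= 0 or dispersion_volume <= 0 or tissue_mass <= 0:
        raise InvalidInputError("flow, dispersion_volume and tissue_mass must be positive")
    if aif.unit == "a.u.":
        raise InvalidInputError(
            "tissue simulation operates on concentration/activity curves, not raw signal"
        )
    from .curves import exp_convolve

    kw = flow * tissue_mass / dispersion_volume / 60.0  # s^-1
    cm = kw * exp_convolve(aif.times, aif.values, kw)
    return aif.with_values(cm)


def simulate_protocol(config: PhantomConfig) -> PhantomDataset:
    """One full dual-bolus / dual-tracer phantom run.

    Produces gadolinium concentration curves, SR-FLASH signal dynamics
    sampled once per heartbeat, and decay-affected, frame-binned PET TACs;
    optional additive Gaussian noise on the MR signal and multiplicative
    Gaussian noise on the PET frame means (sd scaled by 1/sqrt(duration) to
    mimic count statistics), all drawn from ``config.seed``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    t_end = cfg.neat_arrival + cfg.pet_duration
    tg = np.arange(0.0, t_end + cfg.fine_dt / 2, cfg.fine_dt)

    gd_boluses = [
        BolusSpec(1.0 / cfg.dose_ratio, cfg.dilute_arrival, cfg.bolus_alpha, cfg.bolus_beta),
        BolusSpec(1.0, cfg.neat_arrival, cfg.bolus_alpha, cfg.bolus_beta),
    ]
    aif_gd = generate_aif(gd_boluses, tg, unit="mmol/L")
    aif_gd = aif_gd.with_values(aif_gd.values * cfg.neat_peak_conc)
    myo_gd = simulate_tissue_curve(aif_gd, cfg.flow, cfg.dispersion_volume, cfg.tissue_mass)

    # MR dynamics: one sample per heartbeat
    t_mr = np.arange(cfg.n_dynamics) * cfg.dynamic_interval
    sig_aif = srflash_signal(aif_gd.sample(t_mr), cfg.mr_protocol)
    sig_myo = srflash_signal(myo_gd.sample(t_mr), cfg.mr_protocol)
    if cfg.noise_mr_sigma > 0:
        sig_aif = sig_aif + rng.normal(0.0, cfg.noise_mr_sigma, cfg.n_dynamics)
        sig_myo = sig_myo + rng.normal(0.0, cfg.noise_mr_sigma, cfg.n_dynamics)
    mr_aif = SampledCurve(t_mr, sig_aif, unit="a.u.")
    mr_myo = SampledCurve(t_mr, sig_myo, unit="a.u.")

    # PET: tracer co-injected with the neat bolus, physical decay, frame binning
    tracer_bolus = [BolusSpec(1.0, cfg.neat_arrival, cfg.bolus_alpha, cfg.bolus_beta)]
    aif_pet = generate_aif(tracer_bolus, tg, unit="kBq/mL")
    aif_pet = aif_pet.with_values(aif_pet.values * cfg.tracer_peak_activity)
    myo_pet = simulate_tissue_curve(aif_pet, cfg.flow, cfg.dispersion_volume, cfg.tissue_mass)
    lam = np.log(2.0) / (cfg.half_life_min * 60.0)
    decay = np.exp(-lam * np.maximum(tg - cfg.neat_arrival, 0.0))

    scheme = default_frame_scheme(t0=cfg.neat_arrival)
    if scheme.ends[-1] - cfg.neat_arrival > cfg.pet_duration + 1e-9:
        keep = scheme.ends - cfg.neat_arrival <= cfg.pet_duration + 1e-9
        from .curves import FrameScheme

        scheme = FrameScheme(scheme.starts[keep], scheme.durations[keep])
    tac_aif = bin_frames(aif_pet.with_values(aif_pet.values * decay), scheme)
    tac_myo = bin_frames(myo_pet.with_values(myo_pet.values * decay), scheme)
    if cfg.noise_pet_cv > 0:
        sd = cfg.noise_pet_cv / np.sqrt(scheme.durations)
        tac_aif = tac_aif.with_activity(tac_aif.mean_activity * (1.0 + rng.normal(0, sd)))
        tac_myo = tac_myo.with_activity(tac_myo.mean_activity * (1.0 + rng.normal(0, sd)))

    return PhantomDataset(
        truth_flow=cfg.flow,
        aif_conc=aif_gd,
        myo_conc=myo_gd,
        mr_signal_aif=mr_aif,
        mr_signal_myo=mr_myo,
        pet_tac_aif=tac_aif,
        pet_tac_myo=tac_myo,
        config=cfg,
    )
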