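"""Synthetic raw data with the statistical structure the pipeline assumes.

Every generator is a pure function of its parameters and seed, and its
noiseless output agrees with the corresponding forward model (Eyring,
two-state unfolding, one-phase association) to machine precision — so the
downstream fitters can be validated by round trip, from raw traces all the
way to recovered thermodynamic parameters.

What is emulated:

* zero-order NADPH-depletion absorbance traces under saturating substrate,
  floored once the limiting species is exhausted;
* kcat panels drawn from the Eyring law with multiplicative lognormal
  replicate scatter (rates are positive and kinetic replicate error scales
  with the rate);
* CD thermal melts with sloping folded/unfolded baselines, duplicate
  222/222.1 nm reads, transient HT dips at LED-pulse times mapped onto the
  temperature ramp, and (optionally) a high-temperature aggregation
  signature — linear CD surge plus exponential HT collapse above an onset;
* single-exponential chromophore-recovery traces.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np

from .constants import C_TO_K, R_CAL, celsius_to_kelvin
from .kinetics import eyring_kcat
from .melt import two_state_model
from .types import (
    AggregationArtifact,
    KineticTrace,
    MeltCurve,
    PulseSchedule,
    RateMeasurement,
    TrueParams,
)

__all__ = [
    "simulate_absorbance_trace",
    "simulate_kcat_dataset",
    "simulate_melt_curve",
    "simulate_relaxation_trace",
    "pulse_hit_indices",
    "DEFAULT_TEMPS_C",
]

#: Assay temperatures for a transition-state analysis (°C); the instrument
#: also records 40 °C but that point is excluded downstream because the
#: marginally stable fusion begins to denature there.
DEFAULT_TEMPS_C: Tuple[float, ...] = (5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 35.0)


def simulate_absorbance_trace(
    kcat_true: float,
    enzyme_conc: float = 100e-9,
    epsilon: float = 13.2,
    pathlength: float = 1.0,
    duration: float = 60.0,
    dt: float = 0.2,
    noise_sd: float = 0.0,
    substrate_conc: float = 25e-6,
    cofactor_conc: float = 90e-6,
    temperature: float = 25.0,
    condition: str = "dark",
    a0: Optional[float] = None,
    seed: int = 0,
) -> KineticTrace:
    """Zero-order NADPH-depletion trace at 340 nm.

    A(t) = A0 − ε·l·[E]·kcat·t + N(0, noise_sd), with the depletion floored
    once the limiting species (substrate or cofactor) is exhausted — the
    assay is run saturating, so there is no Michaelis–Menten rollover, just
    a hard stop.  A0 defaults to the cofactor's full absorbance.
    """
    if dt <= 0 or duration <= 0:
        raise ValueError("dt and duration must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if kcat_true < 0:
        raise ValueError("kcat_true must be non-negative")
    if min(enzyme_conc, substrate_conc, cofactor_conc) <= 0:
        raise ValueError("concentrations must be positive")

    time = np.arange(0.0, duration + dt / 2, dt)
    limit = min(substrate_conc, cofactor_conc)  # M of product formable
    if a0 is None:
        a0 = epsilon * 1000.0 * pathlength * cofactor_conc
    depleted = np.minimum(enzyme_conc * kcat_true * time, limit)
    absorbance = a0 - epsilon * 1000.0 * pathlength * depleted
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        absorbance = absorbance + rng.normal(0.0, noise_sd, size=time.size)
    return KineticTrace(
        time=time,
        absorbance=absorbance,
        temperature=temperature,
        condition=condition,
        enzyme_conc=enzyme_conc,
        epsilon=epsilon,
        pathlength=pathlength,
    )


def simulate_kcat_dataset(
    params: TrueParams,
    temps: Sequence[float] = DEFAULT_TEMPS_C,
    reps: int = 3,
    condition: str = "dark",
    variant: str = "DL121",
    seed: Optional[int] = None,
) -> list[RateMeasurement]:
    """Replicate kcat panel drawn from the Eyring law.

    Each replicate is eyring_kcat(ΔH‡, ΔS‡, T) · exp(N(0, σ)) with
    σ = ln(1 + cv): multiplicative lognormal scatter keeps rates positive
    and makes the replicate spread proportional to the rate, as kinetic
    replicates behave.  cv = 0 returns the closed-form values exactly.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if len(temps) == 0:
        raise ValueError("temps must be non-empty")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    sigma = np.log1p(params.kcat_cv)
    out = []
    for t_c in temps:
        base = eyring_kcat(params.dh_act, params.ds_act, celsius_to_kelvin(t_c))
        for rep in range(reps):
            noise = np.exp(rng.normal(0.0, sigma)) if sigma > 0 else 1.0
            out.append(
                RateMeasurement(
                    temperature=float(t_c),
                    kcat=float(base * noise),
                    condition=condition,
                    replicate=rep,
                    variant=variant,
                )
            )
    return out


def pulse_hit_indices(
    n_rows: int,
    schedule: PulseSchedule,
    meas_interval_s: float = 61.3,
    intra_pair_gap_s: float = 2.6,
    integration_s: float = 1.0,
    dual_wavelength: bool = True,
    phase_s: float = 0.0,
) -> np.ndarray:
    """Row indices whose integration window overlaps an LED pulse.

    Row times follow the ramp: each temperature step takes
    ``meas_interval_s`` and the second wavelength read of a pair lags the
    first by ``intra_pair_gap_s``.  A row is hit when any pulse (start times
    ``phase_s + k·period``) overlaps its ``integration_s``-long window.
    """
    hits = []
    per_temp = 2 if dual_wavelength else 1
    for row in range(n_rows):
        step, sub = divmod(row, per_temp)
        t = step * meas_interval_s + sub * intra_pair_gap_s
        # pulse start s must satisfy s in (t - duration, t + integration)
        lo = t - schedule.pulse_duration_s - phase_s
        hi = t + integration_s - phase_s
        k_min = np.ceil(lo / schedule.period_s + 1e-12)
        if k_min * schedule.period_s < hi - 1e-12 and k_min >= 0:
            hits.append(row)
    return np.array(hits, dtype=np.intp)


def simulate_melt_curve(
    params: TrueParams,
    temps: Optional[Sequence[float]] = None,
    noise_sd: float = 0.2,
    pulses: Optional[PulseSchedule] = None,
    aggregation: Optional[AggregationArtifact] = None,
    condition: str = "dark",
    variant: str = "DL121",
    seed: Optional[int] = None,
    dual_wavelength: bool = True,
    meas_interval_s: float = 61.3,
    intra_pair_gap_s: float = 2.6,
    integration_s: float = 1.0,
    phase_s: float = 0.0,
    ht_base: float = 300.0,
    ht_rise: float = 60.0,
    ht_noise_sd: float = 0.05,
    cd_pulse_artifact: float = -12.0,
) -> MeltCurve:
    """CD melt with dual-wavelength rows, pulse artifacts and aggregation.

    The CD channel is the two-state model plus Gaussian noise; the HT
    channel rises smoothly with the unfolded fraction (scattering grows as
    the protein unfolds).  Above the aggregation onset the CD signal surges
    linearly and the HT voltage decays exponentially.  Rows coinciding with
    an LED pulse get a square HT dip of ``ht_drop`` volts and a corrupted
    CD value (offset by ``cd_pulse_artifact``).
    """
    if temps is None:
        temps = np.arange(5.0, 80.0 + 1e-9, 0.5)
    temps = np.asarray(temps, dtype=float)
    if temps.size >= 2 and not np.all(np.diff(temps) > 0):
        raise ValueError("temperature grid must be strictly increasing")
    if noise_sd < 0 or ht_noise_sd < 0:
        raise ValueError("noise levels must be non-negative")

    rng = np.random.default_rng(params.seed if seed is None else seed)
    wavelengths = (222.0, 222.1) if dual_wavelength else (222.0,)
    n_rows = temps.size * len(wavelengths)

    row_temp = np.repeat(temps, len(wavelengths))
    row_wl = np.tile(np.array(wavelengths), temps.size)

    cd_true = two_state_model(
        row_temp, params.dh_fold, params.tm_true, params.f, params.cf, params.u, params.cu
    )
    # HT baseline tracks the unfolded population
    t_k = row_temp + C_TO_K
    tm_k = params.tm_true + C_TO_K
    expo = np.clip((params.dh_fold / (R_CAL * t_k)) * (t_k / tm_k - 1.0), -700, 700)
    frac_folded = np.exp(expo) / (1.0 + np.exp(expo))
    ht_true = ht_base + ht_rise * (1.0 - frac_folded)

    if aggregation is not None:
        above = row_temp > aggregation.t_onset
        excess = row_temp - aggregation.t_onset
        spike = (
            aggregation.cd_surge_rate
            * excess
            * np.exp(-excess / aggregation.cd_decay_width)
        )
        cd_true = cd_true + np.where(above, spike, 0.0)
        ht_true = ht_true * np.where(
            above,
            np.exp(-aggregation.ht_decay_rate * (row_temp - aggregation.t_onset)),
            1.0,
        )

    cd = cd_true + (rng.normal(0.0, noise_sd, n_rows) if noise_sd > 0 else 0.0)
    ht = ht_true + (rng.normal(0.0, ht_noise_sd, n_rows) if ht_noise_sd > 0 else 0.0)

    if pulses is not None:
        hits = pulse_hit_indices(
            n_rows,
            pulses,
            meas_interval_s=meas_interval_s,
            intra_pair_gap_s=intra_pair_gap_s,
            integration_s=integration_s,
            dual_wavelength=dual_wavelength,
            phase_s=phase_s,
        )
        ht[hits] -= pulses.ht_drop
        cd[hits] += cd_pulse_artifact

    return MeltCurve(
        temperature=row_temp,
        wavelength=row_wl,
        cd=cd,
        ht=ht,
        condition=condition,
        variant=variant,
    )


def simulate_relaxation_trace(
    k_rel: float,
    a0: float = 0.012,
    plateau: float = 0.048,
    duration: float = 300.0,
    dt: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    temperature: float = 25.0,
    condition: str = "dark",
) -> KineticTrace:
    """Chromophore dark-recovery trace: A(t) = P + (A0 − P)·e^(−k·t) + noise."""
    if k_rel <= 0:
        raise ValueError("k_rel must be positive")
    if dt <= 0 or duration <= 0:
        raise ValueError("dt and duration must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    time = np.arange(0.0, duration + dt / 2, dt)
    absorbance = plateau + (a0 - plateau) * np.exp(-k_rel * time)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        absorbance = absorbance + rng.normal(0.0, noise_sd, size=time.size)
    return KineticTrace(
        time=time,
        absorbance=absorbance,
        temperature=temperature,
        condition=condition,
        enzyme_conc=20e-6,
        epsilon=13.2,
        pathlength=1.0,
        wavelength_nm=447.0,
    )
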