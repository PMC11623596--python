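"""Catalytic rates and transition-state thermodynamics.

The chain implemented here mirrors a standard steady-state workflow for a
light-regulated enzyme assayed by NADPH depletion at 340 nm:

1. ``initial_velocity`` — linear regression of the first seconds of an
   absorbance trace, converted to molar units with Beer-Lambert.
2. ``kcat_from_velocity`` — turnover number under saturating substrate.
3. ``fit_eyring`` / ``bootstrap_eyring`` — transition-state enthalpy and
   entropy (ΔH‡, ΔS‡) from kcat(T) via the linearized Eyring equation
   ln(kcat/T) = ln(kB/h) + ΔS‡/R − ΔH‡/(R·T), with case-resampling
   bootstrap for standard errors and percentile confidence intervals.
4. ``allostery_energetics`` — lit-minus-dark ΔΔH‡, ΔΔS‡ and the derived
   ΔΔG‡(T_ref) and catalytic fold change, with paired-bootstrap CIs.
5. ``fit_one_phase_association`` — single-exponential recovery of the
   photoreceptor chromophore in the dark.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit

from .constants import C_TO_K, KB_OVER_H, R_CAL, celsius_to_kelvin
from .types import (
    AllosteryEnergetics,
    DegenerateDataError,
    EyringFit,
    KineticTrace,
    RateMeasurement,
    RelaxationFit,
    TooFewPointsError,
)

__all__ = [
    "initial_velocity",
    "kcat_from_velocity",
    "kcat_from_trace",
    "eyring_kcat",
    "fit_eyring",
    "bootstrap_eyring",
    "allostery_energetics",
    "predicted_fold_change",
    "fold_change_ci",
    "fit_one_phase_association",
]


def initial_velocity(trace: KineticTrace, window: float = 15.0) -> float:
    """Initial reaction velocity (M/s) from the first ``window`` seconds.

    The slope of absorbance vs time over [0, window] is estimated by ordinary
    linear regression and converted to molar units via the extinction
    coefficient (mM^-1 cm^-1) and path length.  A negative velocity (rising
    absorbance) is returned as-is so pathological traces stay visible.
    """
    if trace.epsilon <= 0 or trace.pathlength <= 0:
        raise ValueError("epsilon and pathlength must be positive")
    mask = (trace.time >= 0) & (trace.time <= window)
    if int(mask.sum()) < 5:
        raise TooFewPointsError(
            f"need >= 5 samples in [0, {window}] s, got {int(mask.sum())}"
        )
    slope, _ = np.polyfit(trace.time[mask], trace.absorbance[mask], 1)
    # AU/s -> mM/s -> M/s
    return float(-slope / (trace.epsilon * trace.pathlength) / 1000.0)


def kcat_from_velocity(v0: float, enzyme_conc: float) -> float:
    """Turnover number (1/s) from an initial velocity under saturation."""
    if enzyme_conc <= 0:
        raise ValueError("enzyme_conc must be positive")
    return float(v0 / enzyme_conc)


def kcat_from_trace(trace: KineticTrace, window: float = 15.0) -> float:
    """Convenience composition: trace -> initial velocity -> kcat."""
    return kcat_from_velocity(initial_velocity(trace, window), trace.enzyme_conc)


def eyring_kcat(dh_act: float, ds_act: float, temperature_k) -> float:
    """Transition-state-theory rate: (kB·T/h)·exp(−ΔH‡/RT)·exp(ΔS‡/R)."""
    t_k = np.asarray(temperature_k, dtype=float)
    if np.any(t_k <= 0):
        raise ValueError("temperature must be positive kelvin")
    out = KB_OVER_H * t_k * np.exp(-dh_act / (R_CAL * t_k)) * np.exp(ds_act / R_CAL)
    return out if out.ndim else float(out)


def _filtered_arrays(
    measurements: Sequence[RateMeasurement],
    t_max: Optional[float],
    t_min: Optional[float],
) -> Tuple[np.ndarray, np.ndarray, int]:
    temps = np.array([m.temperature for m in measurements], dtype=float)
    kcats = np.array([m.kcat for m in measurements], dtype=float)
    if np.any(kcats <= 0):
        raise ValueError("all kcat values must be positive")
    keep = np.ones(temps.size, dtype=bool)
    if t_max is not None:
        keep &= temps <= t_max + 1e-9
    if t_min is not None:
        keep &= temps >= t_min - 1e-9
    n_excluded = int(temps.size - keep.sum())
    return temps[keep], kcats[keep], n_excluded


def _linear_eyring(x: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    """Closed-form OLS of y = a + b·x, returned as (dH‡, ΔS‡)."""
    xc = x - x.mean()
    slope = float(np.dot(xc, y) / np.dot(xc, xc))
    intercept = float(y.mean() - slope * x.mean())
    dh = -slope * R_CAL
    ds = (intercept - np.log(KB_OVER_H)) * R_CAL
    return dh, ds


def fit_eyring(
    measurements: Sequence[RateMeasurement],
    t_max: Optional[float] = 35.0,
    t_min: Optional[float] = None,
) -> EyringFit:
    """Point-estimate Eyring fit on the linearized form.

    Measurements above ``t_max`` (°C) are excluded before fitting — high
    temperatures where the protein begins to denature break the linearity
    of ln(kcat/T) vs 1/T and must not enter the regression.
    """
    temps_c, kcats, n_excluded = _filtered_arrays(measurements, t_max, t_min)
    if np.unique(temps_c).size < 2:
        raise DegenerateDataError(
            "need at least 2 distinct temperatures after filtering"
        )
    t_k = celsius_to_kelvin(temps_c)
    dh, ds = _linear_eyring(1.0 / t_k, np.log(kcats / t_k))
    return EyringFit(dh_act=dh, ds_act=ds, n_points=int(t_k.size), n_excluded=n_excluded)


def bootstrap_eyring(
    measurements: Sequence[RateMeasurement],
    n_boot: int = 5000,
    seed: int = 0,
    t_max: Optional[float] = 35.0,
    t_min: Optional[float] = None,
    stratified: bool = False,
) -> EyringFit:
    """Eyring fit with case-resampling bootstrap errors.

    Each iteration draws ``n_points`` (T, kcat) pairs with replacement from
    the pooled filtered dataset and refits; draws with fewer than two
    distinct temperatures cannot identify a slope and are redrawn (counted
    in ``n_redrawn``).  ``stratified=True`` resamples replicates within each
    temperature instead of pooling.  The point estimate always comes from
    the full dataset, never from the bootstrap mean.
    """
    point = fit_eyring(measurements, t_max=t_max, t_min=t_min)
    temps_c, kcats, _ = _filtered_arrays(measurements, t_max, t_min)
    t_k = celsius_to_kelvin(temps_c)
    x = 1.0 / t_k
    y = np.log(kcats / t_k)
    n = x.size

    rng = np.random.default_rng(seed)
    if stratified:
        idx = np.empty((n_boot, n), dtype=np.intp)
        col = 0
        for temp in np.unique(temps_c):
            members = np.flatnonzero(temps_c == temp)
            draw = rng.integers(0, members.size, size=(n_boot, members.size))
            idx[:, col : col + members.size] = members[draw]
            col += members.size
        n_redrawn = 0
    else:
        idx = rng.integers(0, n, size=(n_boot, n))
        n_redrawn = 0
        while True:
            xs = np.sort(x[idx], axis=1)
            distinct = (np.diff(xs, axis=1) > 0).sum(axis=1) + 1
            bad = np.flatnonzero(distinct < 2)
            if bad.size == 0:
                break
            n_redrawn += int(bad.size)
            idx[bad] = rng.integers(0, n, size=(bad.size, n))

    xs, ys = x[idx], y[idx]
    xm = xs.mean(axis=1, keepdims=True)
    ym = ys.mean(axis=1, keepdims=True)
    xc = xs - xm
    slope = (xc * ys).sum(axis=1) / (xc * xc).sum(axis=1)
    intercept = ym[:, 0] - slope * xm[:, 0]
    boot_dh = -slope * R_CAL
    boot_ds = (intercept - np.log(KB_OVER_H)) * R_CAL

    ci = lambda v: tuple(np.percentile(v, [2.5, 97.5]))
    return EyringFit(
        dh_act=point.dh_act,
        ds_act=point.ds_act,
        n_points=point.n_points,
        n_excluded=point.n_excluded,
        boot_dh=boot_dh,
        boot_ds=boot_ds,
        se_dh=float(np.std(boot_dh, ddof=1)),
        se_ds=float(np.std(boot_ds, ddof=1)),
        ci95_dh=ci(boot_dh),
        ci95_ds=ci(boot_ds),
        seed=seed,
        n_boot=n_boot,
        n_redrawn=n_redrawn,
    )


def allostery_energetics(
    lit: EyringFit, dark: EyringFit, t_ref: float = 303.15
) -> AllosteryEnergetics:
    """Lit-minus-dark transition-state energetics at ``t_ref`` (K).

    ΔΔG‡ = ΔΔH‡ − T·ΔΔS‡ and fold = exp(−ΔΔG‡/RT) hold exactly by
    construction.  Confidence intervals pair iteration i of the lit
    bootstrap stream with iteration i of the (independent) dark stream.
    """
    if not (lit.has_bootstrap and dark.has_bootstrap):
        raise ValueError("both fits must carry bootstrap distributions")
    if lit.n_boot != dark.n_boot:
        raise ValueError("lit and dark fits must have equal n_boot")

    ddh = lit.dh_act - dark.dh_act
    dds = lit.ds_act - dark.ds_act
    ddg = ddh - t_ref * dds
    fold = float(np.exp(-ddg / (R_CAL * t_ref)))

    boot_ddh = lit.boot_dh - dark.boot_dh
    boot_dds = lit.boot_ds - dark.boot_ds
    boot_ddg = boot_ddh - t_ref * boot_dds
    boot_fold = np.exp(-boot_ddg / (R_CAL * t_ref))

    ci = lambda v: tuple(np.percentile(v, [2.5, 97.5]))
    return AllosteryEnergetics(
        ddh=ddh,
        dds=dds,
        t_dds_at_ref=t_ref * dds,
        ddg_at_ref=ddg,
        t_ref=t_ref,
        fold_change_at_ref=fold,
        ci95_ddh=ci(boot_ddh),
        ci95_dds=ci(boot_dds),
        ci95_t_dds=ci(t_ref * boot_dds),
        ci95_ddg=ci(boot_ddg),
        ci95_fold=ci(boot_fold),
        boot_ddh=boot_ddh,
        boot_dds=boot_dds,
        boot_ddg=boot_ddg,
        boot_fold=boot_fold,
    )


def predicted_fold_change(energetics: AllosteryEnergetics, temperature_k):
    """Lit/dark rate ratio predicted at any temperature (K).

    ratio(T) = exp(−(ΔΔH‡ − T·ΔΔS‡)/(R·T)); strictly decreasing in T when
    ΔΔH‡ < 0, which is the signature of enthalpy-driven allostery.
    """
    t_k = np.asarray(temperature_k, dtype=float)
    if np.any(t_k <= 0):
        raise ValueError("temperature must be positive kelvin")
    out = np.exp(-(energetics.ddh - t_k * energetics.dds) / (R_CAL * t_k))
    return out if out.ndim else float(out)


def fold_change_ci(
    energetics: AllosteryEnergetics, temperature_k: float
) -> Tuple[float, float, float]:
    """(point, lo95, hi95) of the predicted fold change at any temperature."""
    boot = np.exp(
        -(energetics.boot_ddh - temperature_k * energetics.boot_dds)
        / (R_CAL * temperature_k)
    )
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return float(predicted_fold_change(energetics, temperature_k)), float(lo), float(hi)


def _one_phase(t, k, a0, plateau):
    return plateau + (a0 - plateau) * np.exp(-k * t)


def fit_one_phase_association(trace: KineticTrace) -> RelaxationFit:
    """Single-exponential approach to a plateau, A(t) = P + (A0−P)e^(−kt).

    Initialization takes A0 and the plateau from the trace endpoints and the
    rate from the half-recovery time; k is constrained positive.  A constant
    trace leaves k unidentifiable and raises ``DegenerateDataError``.
    """
    t, y = trace.time, trace.absorbance
    if t.size < 4:
        raise TooFewPointsError("need at least 4 samples")
    span = float(y[-1] - y[0])
    scale = max(float(np.max(np.abs(y))), 1e-12)
    if np.ptp(y) < 1e-9 * scale or abs(span) < 1e-9 * scale:
        raise DegenerateDataError("constant trace: A0 = plateau, k unidentifiable")

    half = y[0] + 0.5 * span
    crossed = np.flatnonzero(
        (y - half) * np.sign(span) >= 0
    )
    t_half = float(t[crossed[0]]) if crossed.size and t[crossed[0]] > 0 else float(
        t[-1] / 2
    )
    k0 = np.log(2.0) / max(t_half, float(t[-1]) * 1e-3)
    try:
        popt, _ = curve_fit(
            _one_phase,
            t,
            y,
            p0=[k0, float(y[0]), float(y[-1])],
            bounds=([1e-12, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as err:  # pragma: no cover - hard to hit with valid input
        raise DegenerateDataError(f"one-phase fit did not converge: {err}") from err
    k, a0, plateau = (float(v) for v in popt)
    resid = y - _one_phase(t, k, a0, plateau)
    return RelaxationFit(
        k_rel=k, a0=a0, plateau=plateau, rms=float(np.sqrt(np.mean(resid**2)))
    )
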