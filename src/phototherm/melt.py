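"""CD thermal-melt cleaning and two-state unfolding fits.

Raw melts from a pulsed-LED CD experiment need three cleaning steps before a
melting temperature can be trusted:

1. ``detect_light_pulses`` — measurements taken while the excitation LED
   fired show a transient dip in the photomultiplier HT voltage; those rows
   are artifacts and are dropped.
2. ``clean_melt`` — the instrument records duplicate reads at 222 and
   222.1 nm precisely so that a pulse-corrupted read has a surviving twin;
   the channels are averaged onto one temperature grid.
3. ``fit_window`` — in the dark state the protein aggregates at high
   temperature (CD surges while HT collapses), so the two-state fit endpoint
   is set halfway between the temperature of maximum CD and the temperature
   of maximum HT, keeping the fit on the two-state part of the curve.

``fit_two_state`` then fits the observed ellipticity with a folded/unfolded
equilibrium whose baselines drift linearly with temperature:

    K(T) = exp[(ΔH/(R·T_K))·(T_K/Tm_K − 1)]
    θ(T) = K/(1+K) · ((F + Cf·T) − (U + CU·T)) + (U + CU·T)

with T_K = T + 273.15 and R = 1.987 cal/(mol K).  ΔH here is the folding
enthalpy (negative) and is a fit-internal shape parameter; a free energy of
unfolding is deliberately not derived because thermal unfolding of this
fusion is not reversible.
"""

from __future__ import annotations

import logging
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import curve_fit

from .constants import C_TO_K, R_CAL
from .types import MeltCurve, MeltFit, TooFewPointsError

__all__ = [
    "detect_light_pulses",
    "clean_melt",
    "merge_melt_scans",
    "mdeg_to_mre",
    "mre_to_mdeg",
    "fit_window",
    "two_state_model",
    "fit_two_state",
    "fraction_folded",
]

logger = logging.getLogger(__name__)


def detect_light_pulses(ht: Sequence[float], k_mad: float = 5.0) -> np.ndarray:
    """Indices of HT samples corrupted by an LED pulse.

    A pulse appears as a transient dip: a steep drop in the HT first
    difference (beyond ``k_mad`` times the MAD of successive differences)
    followed by an immediate recovery.  Requiring the recovery distinguishes
    single-sample pulse dips from the sustained HT decay that accompanies
    aggregation, which must never be flagged.  Dips in the first or last
    sample, where only one flank is observable, are flagged from that flank
    alone.
    """
    ht = np.asarray(ht, dtype=float)
    if ht.size < 5:
        raise TooFewPointsError("need at least 5 samples")
    d = np.diff(ht)
    med = float(np.median(d))
    mad = float(np.median(np.abs(d - med)))
    scale = max(mad, 1e-9 * max(1.0, float(np.median(np.abs(ht)))))
    thr = k_mad * scale

    flagged: List[int] = []
    n = ht.size
    for i in range(1, n):
        drop = med - d[i - 1]
        if drop <= thr:
            continue
        if i == n - 1:
            flagged.append(i)  # terminal drop: no recovery observable
        elif (d[i] - med) > 0.5 * thr:
            flagged.append(i)
    # leading-edge dip: the first sample sits below a steep recovery
    if (d[0] - med) > thr and 1 not in flagged:
        flagged.insert(0, 0)
    return np.array(sorted(set(flagged)), dtype=np.intp)


def _average_channels(
    curve: MeltCurve, keep: np.ndarray, pair_tol: float
) -> MeltCurve:
    temps = curve.temperature[keep]
    wls = curve.wavelength[keep]
    cds = curve.cd[keep]
    hts = curve.ht[keep]
    unique_wl = np.unique(wls)
    if unique_wl.size == 1:
        return MeltCurve(temps, wls, cds, hts, curve.condition, curve.variant)

    a = np.flatnonzero(wls == unique_wl[0])
    b = np.flatnonzero(wls == unique_wl[1])
    rows: List[Tuple[float, float, float, float]] = []
    i = j = 0
    unpaired = 0
    while i < a.size and j < b.size:
        ta, tb = temps[a[i]], temps[b[j]]
        if abs(ta - tb) <= pair_tol:
            rows.append(
                (
                    0.5 * (ta + tb),
                    0.5 * (wls[a[i]] + wls[b[j]]),
                    0.5 * (cds[a[i]] + cds[b[j]]),
                    0.5 * (hts[a[i]] + hts[b[j]]),
                )
            )
            i += 1
            j += 1
        elif ta < tb:
            rows.append((ta, wls[a[i]], cds[a[i]], hts[a[i]]))
            unpaired += 1
            i += 1
        else:
            rows.append((tb, wls[b[j]], cds[b[j]], hts[b[j]]))
            unpaired += 1
            j += 1
    for k in range(i, a.size):
        rows.append((temps[a[k]], wls[a[k]], cds[a[k]], hts[a[k]]))
        unpaired += 1
    for k in range(j, b.size):
        rows.append((temps[b[k]], wls[b[k]], cds[b[k]], hts[b[k]]))
        unpaired += 1
    if unpaired:
        logger.info("clean_melt: %d rows had no partner within %.3g degC", unpaired, pair_tol)
    rows.sort(key=lambda r: r[0])
    arr = np.array(rows, dtype=float)
    return MeltCurve(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3], curve.condition, curve.variant)


def clean_melt(
    curve: MeltCurve, k_mad: float = 5.0, pair_tol: Optional[float] = None
) -> MeltCurve:
    """Drop pulse-corrupted rows, then average the dual-wavelength reads.

    Channels are paired by nearest temperature within half a ramp step
    (``pair_tol`` overrides); rows whose partner was removed by the pulse
    filter survive as singles, which is the point of the duplicate reads.
    """
    n_wl = np.unique(curve.wavelength).size
    if n_wl > 2:
        raise ValueError(f"expected one or two wavelength channels, got {n_wl}")
    flagged = detect_light_pulses(curve.ht, k_mad=k_mad)
    keep = np.ones(len(curve), dtype=bool)
    keep[flagged] = False
    if pair_tol is None:
        steps = np.diff(np.unique(curve.temperature))
        pair_tol = float(np.median(steps)) / 2.0 if steps.size else 0.25
    return _average_channels(curve, keep, pair_tol)


def merge_melt_scans(curves: Sequence[MeltCurve]) -> MeltCurve:
    """Pool replicate melt scans into one curve (rows sorted by temperature).

    Thermal melts are commonly acquired as triplicate scans and fit jointly;
    each scan should be pulse-cleaned before merging.
    """
    if not curves:
        raise ValueError("need at least one scan")
    conditions = {c.condition for c in curves}
    variants = {c.variant for c in curves}
    if len(conditions) != 1 or len(variants) != 1:
        raise ValueError("scans must share condition and variant")
    temps = np.concatenate([c.temperature for c in curves])
    order = np.argsort(temps, kind="stable")
    return MeltCurve(
        temperature=temps[order],
        wavelength=np.concatenate([c.wavelength for c in curves])[order],
        cd=np.concatenate([c.cd for c in curves])[order],
        ht=np.concatenate([c.ht for c in curves])[order],
        condition=curves[0].condition,
        variant=curves[0].variant,
    )


def mdeg_to_mre(
    theta_mdeg, molar_conc: float, pathlength_cm: float, n_residues: int
):
    """Mean residue ellipticity (deg·cm²/dmol) from raw ellipticity (mdeg).

    Convention: MRE = θ_mdeg / (10 · l_cm · c_M · n_residues).  This is the
    single convention used throughout the package; the inverse is
    ``mre_to_mdeg``.
    """
    if molar_conc <= 0 or pathlength_cm <= 0 or n_residues <= 0:
        raise ValueError("concentration, path length and residue count must be positive")
    return np.asarray(theta_mdeg, dtype=float) / (
        10.0 * pathlength_cm * molar_conc * n_residues
    )


def mre_to_mdeg(mre, molar_conc: float, pathlength_cm: float, n_residues: int):
    """Inverse of ``mdeg_to_mre``."""
    if molar_conc <= 0 or pathlength_cm <= 0 or n_residues <= 0:
        raise ValueError("concentration, path length and residue count must be positive")
    return np.asarray(mre, dtype=float) * (
        10.0 * pathlength_cm * molar_conc * n_residues
    )


def fit_window(curve: MeltCurve, min_span: float = 10.0) -> Tuple[float, float]:
    """Aggregation-aware fit window from the HT channel.

    The start is the lowest measured temperature.  When aggregation is
    present the HT voltage peaks and then collapses while CD keeps rising;
    the endpoint is then the midpoint between the temperature of maximum CD
    and the temperature of maximum HT.  If HT is still rising at the end of
    the ramp (no aggregation signature) or the midpoint would leave less
    than ``min_span`` °C of data, the full range is used.
    """
    temps = curve.temperature
    t_start = float(temps.min())
    t_max = float(temps.max())
    steps = np.diff(np.unique(temps))
    step = float(np.median(steps)) if steps.size else 0.5

    # Aggregation signature = a substantial HT collapse after the HT peak;
    # an HT channel that merely rises and plateaus with unfolding is clean.
    ht_tail = float(np.median(curve.ht[-5:]))
    decline = float(curve.ht.max()) - ht_tail
    if decline <= 0.25 * float(np.ptp(curve.ht)):
        return (t_start, t_max)  # no aggregation signature

    ht_s = _moving_average(curve.ht, 9)
    cd_s = _moving_average(curve.cd, 5)
    # The HT channel plateaus once unfolding completes, so under noise the
    # literal argmax wanders over the plateau; the temperature of maximum HT
    # is estimated as the first attainment of the peak level, to within half
    # a percent of the channel's dynamic range.
    tol = max(0.005 * float(np.ptp(ht_s)), 1e-12)
    t_at_ht_max = float(temps[np.argmax(ht_s >= ht_s.max() - tol)])
    t_at_cd_max = float(temps[np.argmax(cd_s)])
    t_end = 0.5 * (t_at_cd_max + t_at_ht_max)
    if t_end <= t_start + min_span:
        logger.info(
            "fit_window: midpoint endpoint %.1f too close to start, using full range",
            t_end,
        )
        return (t_start, t_max)
    return (t_start, t_end)


def two_state_model(temperature_c, dh_fold, tm, f, cf, u, cu):
    """Observed ellipticity for a two-state unfolding with sloping baselines."""
    t_c = np.asarray(temperature_c, dtype=float)
    t_k = t_c + C_TO_K
    tm_k = tm + C_TO_K
    expo = np.clip((dh_fold / (R_CAL * t_k)) * (t_k / tm_k - 1.0), -700.0, 700.0)
    k_eq = np.exp(expo)
    frac = k_eq / (1.0 + k_eq)
    folded = f + cf * t_c
    unfolded = u + cu * t_c
    out = frac * (folded - unfolded) + unfolded
    return out if out.ndim else float(out)


def _moving_average(y: np.ndarray, width: int) -> np.ndarray:
    if width <= 1 or y.size < width:
        return y
    kernel = np.ones(width) / width
    pad = width // 2
    padded = np.pad(y, pad, mode="edge")
    return np.convolve(padded, kernel, mode="valid")[: y.size]


def fit_two_state(
    curve: MeltCurve,
    window: Optional[Tuple[float, float]] = None,
    dh_init: float = -50000.0,
    init_smooth: int = 5,
) -> MeltFit:
    """Nonlinear least-squares two-state fit over (ΔH, Tm, F, Cf, U, CU).

    Tm is initialized from the extremum of a smoothed dCD/dT, baselines from
    linear fits to the outer 20% temperature segments, and ΔH from
    ``dh_init``; ΔH is constrained negative.  A fit whose Tm falls outside
    the window or whose transition amplitude is indistinguishable from the
    baselines is returned with ``converged=False`` and diagnostics, never as
    a silent number.
    """
    if window is None:
        window = fit_window(curve)
    t0, t1 = window
    mask = (curve.temperature >= t0 - 1e-9) & (curve.temperature <= t1 + 1e-9)
    temps = curve.temperature[mask]
    y = curve.cd[mask]
    if temps.size < 10:
        raise TooFewPointsError("need at least 10 points inside the fit window")

    # initialize Tm from the steepest point of the per-temperature mean
    # (replicate scans share grid points, so deduplicate before gradient)
    uniq, inv = np.unique(temps, return_inverse=True)
    y_mean = np.bincount(inv, weights=y) / np.bincount(inv)
    smoothed = _moving_average(y_mean, init_smooth)
    grad = np.gradient(smoothed, uniq)
    tm0 = float(uniq[np.argmax(np.abs(grad))])
    span = float(np.ptp(temps))
    low = temps <= temps.min() + 0.2 * span
    high = temps >= temps.max() - 0.2 * span
    cf0, f0 = np.polyfit(temps[low], y[low], 1) if low.sum() >= 2 else (0.0, y[0])
    cu0, u0 = np.polyfit(temps[high], y[high], 1) if high.sum() >= 2 else (0.0, y[-1])

    p0 = [dh_init, tm0, f0, cf0, u0, cu0]
    lower = [-1e7, temps.min() - 10.0, -np.inf, -np.inf, -np.inf, -np.inf]
    upper = [-1.0, temps.max() + 10.0, np.inf, np.inf, np.inf, np.inf]
    diagnostics = {"window": window, "tm_init": tm0, "n_points": int(temps.size)}
    try:
        popt, _ = curve_fit(
            two_state_model, temps, y, p0=p0, bounds=(lower, upper), maxfev=40000
        )
    except RuntimeError as err:
        diagnostics["reason"] = f"optimizer failure: {err}"
        return MeltFit(
            tm=float("nan"),
            dh_fold=float("nan"),
            f=float("nan"),
            cf=float("nan"),
            u=float("nan"),
            cu=float("nan"),
            fit_window=window,
            rms=float("nan"),
            converged=False,
            diagnostics=diagnostics,
        )

    dh, tm, f, cf, u, cu = (float(v) for v in popt)
    resid = y - two_state_model(temps, *popt)
    rms = float(np.sqrt(np.mean(resid**2)))
    amplitude = abs((f + cf * tm) - (u + cu * tm))
    converged = True
    if not (t0 < tm < t1):
        converged = False
        diagnostics["reason"] = f"Tm {tm:.2f} outside fit window {window}"
    elif amplitude < max(5.0 * rms, 1e-3 * max(float(np.ptp(y)), 1e-12)):
        converged = False
        diagnostics["reason"] = (
            f"transition amplitude {amplitude:.3g} indistinguishable from baselines"
        )
    return MeltFit(
        tm=tm,
        dh_fold=dh,
        f=f,
        cf=cf,
        u=u,
        cu=cu,
        fit_window=window,
        rms=rms,
        converged=converged,
        diagnostics=diagnostics,
    )


def fraction_folded(fit: MeltFit, temperature_c):
    """Folded population K/(1+K) at a temperature; 0.5 exactly at Tm."""
    if not fit.converged:
        raise ValueError(f"fit not accepted: {fit.diagnostics.get('reason', 'flagged')}")
    t_k = np.asarray(temperature_c, dtype=float) + C_TO_K
    tm_k = fit.tm + C_TO_K
    expo = np.clip((fit.dh_fold / (R_CAL * t_k)) * (t_k / tm_k - 1.0), -700.0, 700.0)
    k_eq = np.exp(expo)
    out = k_eq / (1.0 + k_eq)
    return out if out.ndim else float(out)
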