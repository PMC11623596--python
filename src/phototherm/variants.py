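"""Cross-variant aggregation: tradeoff coordinates and stability-activity trends.

This stage never refits anything — it joins accepted kinetic and melt
results per variant into records, places each variant on the
enthalpy-entropy tradeoff plane (x = T·ΔΔS‡, y = ΔΔH‡, where the x=y
diagonal marks exact compensation and vertical distance above it is the
allosteric free-energy gain −ΔΔG‡), and quantifies the correlation between
light-induced stability change (ΔTm) and light-induced transition-state
free-energy change (ΔΔG‡), with an explicit, parameterized exclusion set.
"""

from __future__ import annotations

from typing import Dict, Iterable, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .constants import R_CAL
from .kinetics import allostery_energetics, predicted_fold_change
from .types import (
    AllosteryEnergetics,
    CorrelationResult,
    EyringFit,
    MeltFit,
    VariantRecord,
)

__all__ = [
    "build_variant_record",
    "classify_allostery",
    "tradeoff_coordinates",
    "temperature_profile",
    "stability_activity_correlation",
    "records_to_frame",
]


def classify_allostery(
    energetics: AllosteryEnergetics,
    reference: Optional[AllosteryEnergetics] = None,
) -> str:
    """Classify a variant's allosteric effect from its fold-change CI.

    A record with exactly zero effect (ΔΔG‡ = 0) is always neutral,
    regardless of CI width.  Otherwise, without a reference the CI is
    compared against 1 (no allostery); with a reference construct the two
    95% CIs are compared: overlapping CIs are neutral (effect size similar
    to the reference), a CI entirely above is enhancing, entirely below
    disrupting.
    """
    if energetics.ddg_at_ref == 0.0:
        return "neutral"
    lo, hi = energetics.ci95_fold
    if reference is None:
        if lo > 1.0:
            return "enhancing"
        if hi < 1.0:
            return "disrupting"
        return "neutral"
    ref_lo, ref_hi = reference.ci95_fold
    if lo > ref_hi:
        return "enhancing"
    if hi < ref_lo:
        return "disrupting"
    return "neutral"


def build_variant_record(
    lit_fit: Optional[EyringFit],
    dark_fit: Optional[EyringFit],
    lit_melt: Optional[MeltFit],
    dark_melt: Optional[MeltFit],
    t_ref: float = 303.15,
    variant: str = "DL121",
    reference: Optional[AllosteryEnergetics] = None,
) -> VariantRecord:
    """Join lit/dark kinetics and melt results into one variant record.

    Missing or flagged inputs do not abort the join: the affected fields are
    None and listed in ``missing``, and the record is classified
    ``incomplete`` if the energetics cannot be formed.
    """
    missing = []

    energetics = None
    if lit_fit is None or not getattr(lit_fit, "has_bootstrap", False):
        missing.append("lit_fit")
    if dark_fit is None or not getattr(dark_fit, "has_bootstrap", False):
        missing.append("dark_fit")
    if not missing:
        energetics = allostery_energetics(lit_fit, dark_fit, t_ref=t_ref)

    tm_lit = tm_dark = dtm = None
    if lit_melt is None or not lit_melt.converged:
        missing.append("lit_melt")
    else:
        tm_lit = float(lit_melt.tm)
    if dark_melt is None or not dark_melt.converged:
        missing.append("dark_melt")
    else:
        tm_dark = float(dark_melt.tm)
    if tm_lit is not None and tm_dark is not None:
        dtm = tm_lit - tm_dark

    if energetics is not None:
        classification = classify_allostery(energetics, reference)
        fold = energetics.fold_change_at_ref
        fold_ci = energetics.ci95_fold
    else:
        classification = "incomplete"
        fold = fold_ci = None

    return VariantRecord(
        variant=variant,
        energetics=energetics,
        tm_lit=tm_lit,
        tm_dark=tm_dark,
        dtm=dtm,
        fold_change_at_ref=fold,
        fold_ci95=fold_ci,
        classification=classification,
        missing=tuple(missing),
    )


def tradeoff_coordinates(
    records: Sequence[VariantRecord], t_ref: float = 303.15
) -> pd.DataFrame:
    """Enthalpy-entropy tradeoff plane coordinates per variant.

    Returns one row per record with x = T_ref·ΔΔS‡ and y = ΔΔH‡ (cal/mol),
    the signed vertical distance above the x=y diagonal
    (``gain = x − y = −ΔΔG‡(T_ref)``, the allosteric free-energy gain), the
    fold change at T_ref and propagated 95% CIs.  Distances are invariant
    under translation along the diagonal.
    """
    rows = []
    for rec in records:
        e = rec.energetics
        if e is None:
            raise ValueError(f"record {rec.variant} has no energetics")
        x = t_ref * e.dds
        y = e.ddh
        boot_gain = t_ref * e.boot_dds - e.boot_ddh
        lo_g, hi_g = np.percentile(boot_gain, [2.5, 97.5])
        lo_x, hi_x = np.percentile(t_ref * e.boot_dds, [2.5, 97.5])
        lo_y, hi_y = np.percentile(e.boot_ddh, [2.5, 97.5])
        rows.append(
            {
                "variant": rec.variant,
                "t_dds": x,
                "ddh": y,
                "gain": x - y,
                "fold_change": float(np.exp((x - y) / (R_CAL * t_ref))),
                "t_dds_ci_lo": lo_x,
                "t_dds_ci_hi": hi_x,
                "ddh_ci_lo": lo_y,
                "ddh_ci_hi": hi_y,
                "gain_ci_lo": lo_g,
                "gain_ci_hi": hi_g,
            }
        )
    return pd.DataFrame(rows)


def temperature_profile(
    record: VariantRecord, temps_k: Sequence[float]
) -> np.ndarray:
    """Predicted lit/dark fold change across temperatures (K)."""
    if record.energetics is None:
        raise ValueError(f"record {record.variant} has no energetics")
    return np.asarray(
        [predicted_fold_change(record.energetics, t) for t in temps_k], dtype=float
    )


def stability_activity_correlation(
    records: Sequence[VariantRecord],
    exclusions: Iterable[str] = (),
) -> CorrelationResult:
    """OLS of ΔTm (lit−dark, °C) on ΔΔG‡ (cal/mol) with Pearson r.

    ``exclusions`` names records omitted from the line of best fit (an
    explicit analysis choice, never hard-coded); excluding an unknown label
    is an error.  The reverse regression (ΔΔG‡ on ΔTm) is reported alongside
    because the fitting direction for such tradeoff plots is a convention.
    """
    labels = {r.variant for r in records}
    excluded = frozenset(exclusions)
    unknown = excluded - labels
    if unknown:
        raise ValueError(f"exclusions not in record set: {sorted(unknown)}")
    used = [r for r in records if r.variant not in excluded]
    if len(used) < 3:
        raise ValueError("need at least 3 records after exclusion")
    for r in used:
        if r.energetics is None or r.dtm is None:
            raise ValueError(f"record {r.variant} is incomplete")
    x = np.array([r.energetics.ddg_at_ref for r in used])
    y = np.array([r.dtm for r in used])
    fwd = stats.linregress(x, y)
    rev = stats.linregress(y, x)
    return CorrelationResult(
        slope=float(fwd.slope),
        intercept=float(fwd.intercept),
        pearson_r=float(fwd.rvalue),
        n_used=len(used),
        excluded=excluded,
        slope_reverse=float(rev.slope),
        intercept_reverse=float(rev.intercept),
    )


def records_to_frame(records: Sequence[VariantRecord]) -> pd.DataFrame:
    """Variant-panel table: one row per construct with the derived quantities."""
    rows = []
    for r in records:
        e = r.energetics
        rows.append(
            {
                "variant": r.variant,
                "ddh": None if e is None else e.ddh,
                "dds": None if e is None else e.dds,
                "t_dds": None if e is None else e.t_dds_at_ref,
                "ddg": None if e is None else e.ddg_at_ref,
                "fold_change": r.fold_change_at_ref,
                "tm_lit": r.tm_lit,
                "tm_dark": r.tm_dark,
                "dtm": r.dtm,
                "classification": r.classification,
            }
        )
    return pd.DataFrame(rows)
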