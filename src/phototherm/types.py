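"""Domain containers for kinetic, thermodynamic and melt data.

All containers are plain dataclasses with light validation in
``__post_init__``; fitted results additionally carry the diagnostic
information needed to decide whether a number should be trusted
(bootstrap vectors, convergence flags, fit windows).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np


class TooFewPointsError(ValueError):
    """Raised when a fit or filter receives fewer samples than it needs."""


class DegenerateDataError(ValueError):
    """Raised when the data cannot identify the model (e.g. a constant trace)."""


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return arr


@dataclass
class KineticTrace:
    """A single absorbance-vs-time record at one temperature and condition.

    ``epsilon`` is the extinction coefficient in mM^-1 cm^-1 at the stated
    wavelength (13.2 for NADPH at 340 nm), ``enzyme_conc`` is molar.
    """

    time: np.ndarray                # s, strictly increasing
    absorbance: np.ndarray          # AU
    temperature: float = 25.0       # °C
    condition: str = "dark"
    enzyme_conc: float = 100e-9     # M
    epsilon: float = 13.2           # mM^-1 cm^-1
    pathlength: float = 1.0         # cm
    wavelength_nm: float = 340.0

    def __post_init__(self):
        self.time = _as_float_array(self.time, "time")
        self.absorbance = _as_float_array(self.absorbance, "absorbance")
        if self.time.size != self.absorbance.size:
            raise ValueError("time and absorbance must have equal length")
        if self.time.size >= 2 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        if self.enzyme_conc <= 0:
            raise ValueError("enzyme_conc must be positive")
        if self.epsilon <= 0 or self.pathlength <= 0:
            raise ValueError("epsilon and pathlength must be positive")

    def __len__(self) -> int:
        return self.time.size


@dataclass(frozen=True)
class RateMeasurement:
    """One catalytic turnover observation: (temperature, kcat) for a condition."""

    temperature: float              # °C
    kcat: float                     # 1/s
    condition: str = "dark"         # {"lit", "dark"}
    replicate: int = 0
    variant: str = "DL121"

    def __post_init__(self):
        if self.kcat <= 0:
            raise ValueError("kcat must be positive")


@dataclass
class EyringFit:
    """Transition-state parameters from a linearized Eyring fit.

    Point estimates always come from the full filtered dataset; the bootstrap
    vectors (when present) quantify their sampling error.  ``n_excluded``
    counts measurements dropped by the temperature filter and ``n_redrawn``
    counts degenerate bootstrap draws (fewer than two distinct temperatures)
    that were redrawn.
    """

    dh_act: float                   # ΔH‡, cal/mol
    ds_act: float                   # ΔS‡, cal/(mol K)
    n_points: int
    n_excluded: int = 0
    boot_dh: Optional[np.ndarray] = None
    boot_ds: Optional[np.ndarray] = None
    se_dh: Optional[float] = None
    se_ds: Optional[float] = None
    ci95_dh: Optional[Tuple[float, float]] = None
    ci95_ds: Optional[Tuple[float, float]] = None
    seed: Optional[int] = None
    n_boot: int = 0
    n_redrawn: int = 0

    def __post_init__(self):
        if self.boot_dh is not None:
            self.boot_dh = _as_float_array(self.boot_dh, "boot_dh")
            self.boot_ds = _as_float_array(self.boot_ds, "boot_ds")
            if len(self.boot_dh) != self.n_boot or len(self.boot_ds) != self.n_boot:
                raise ValueError("bootstrap vectors must have length n_boot")

    @property
    def has_bootstrap(self) -> bool:
        return self.boot_dh is not None and self.n_boot > 0


@dataclass
class AllosteryEnergetics:
    """Lit-minus-dark transition-state energetics at a reference temperature.

    Identities ``ddg_at_ref = ddh - t_ref * dds`` and
    ``fold_change_at_ref = exp(-ddg_at_ref / (R * t_ref))`` hold exactly;
    confidence intervals come from pairing iteration i of the lit bootstrap
    stream with iteration i of the dark stream.
    """

    ddh: float                      # ΔΔH‡, cal/mol
    dds: float                      # ΔΔS‡, cal/(mol K)
    t_dds_at_ref: float             # T_ref·ΔΔS‡, cal/mol
    ddg_at_ref: float               # ΔΔG‡(T_ref), cal/mol
    t_ref: float                    # K
    fold_change_at_ref: float
    ci95_ddh: Tuple[float, float]
    ci95_dds: Tuple[float, float]
    ci95_t_dds: Tuple[float, float]
    ci95_ddg: Tuple[float, float]
    ci95_fold: Tuple[float, float]
    boot_ddh: np.ndarray = field(repr=False, default=None)
    boot_dds: np.ndarray = field(repr=False, default=None)
    boot_ddg: np.ndarray = field(repr=False, default=None)
    boot_fold: np.ndarray = field(repr=False, default=None)


@dataclass
class RelaxationFit:
    """One-phase association fit A(t) = plateau + (A0 - plateau) e^(-k t)."""

    k_rel: float                    # 1/s
    a0: float
    plateau: float
    rms: float

    def __post_init__(self):
        if self.k_rel <= 0:
            raise ValueError("k_rel must be positive")


@dataclass
class MeltCurve:
    """Temperature-resolved CD ellipticity plus the photomultiplier HT channel.

    Rows are stored in instrument (measurement) order: temperature
    non-decreasing, with the dual 222/222.1 nm reads interleaved.
    """

    temperature: np.ndarray         # °C
    wavelength: np.ndarray          # nm, per row
    cd: np.ndarray                  # mdeg (or MRE after conversion)
    ht: np.ndarray                  # V
    condition: str = "dark"
    variant: str = "DL121"

    def __post_init__(self):
        self.temperature = _as_float_array(self.temperature, "temperature")
        self.wavelength = _as_float_array(self.wavelength, "wavelength")
        self.cd = _as_float_array(self.cd, "cd")
        self.ht = _as_float_array(self.ht, "ht")
        n = self.temperature.size
        if not (self.wavelength.size == self.cd.size == self.ht.size == n):
            raise ValueError("all channels must have equal length")
        if n >= 2 and np.any(np.diff(self.temperature) < 0):
            raise ValueError("temperature must be non-decreasing")

    def __len__(self) -> int:
        return self.temperature.size


@dataclass
class MeltFit:
    """Two-state unfolding fit: Tm, folding enthalpy and sloping baselines.

    ``converged`` is False when the optimizer failed, Tm fell outside the fit
    window, or the fitted transition amplitude is indistinguishable from the
    baselines; flagged fits never report a silent number (``diagnostics``
    says why).
    """

    tm: float                       # °C
    dh_fold: float                  # cal/mol, negative
    f: float                        # folded baseline intercept, signal units
    cf: float                       # folded baseline slope, per °C
    u: float                        # unfolded baseline intercept
    cu: float                       # unfolded baseline slope, per °C
    fit_window: Tuple[float, float]
    rms: float
    converged: bool
    diagnostics: dict = field(default_factory=dict)


@dataclass(frozen=True)
class TrueParams:
    """Generating parameters for the synthetic-data module.

    One object carries the generative side of every fitted symbol: the
    transition-state pair (dh_act, ds_act), the melt parameters
    (tm_true, dh_fold, baselines) and the replicate noise level for rates.
    """

    dh_act: float = 14000.0         # cal/mol
    ds_act: float = -12.667         # cal/(mol K)
    tm_true: float = 33.9           # °C
    dh_fold: float = -60000.0       # cal/mol, < 0 (exothermic folding)
    f: float = -20.5                # folded baseline intercept, mdeg
    cf: float = 0.05                # folded baseline slope, mdeg/°C
    u: float = -6.0                 # unfolded baseline intercept, mdeg
    cu: float = 0.02                # unfolded baseline slope, mdeg/°C
    kcat_cv: float = 0.05           # replicate coefficient of variation
    seed: int = 0

    def __post_init__(self):
        if self.dh_fold >= 0:
            raise ValueError("dh_fold must be negative (folding is exothermic)")
        if self.kcat_cv < 0:
            raise ValueError("kcat_cv must be non-negative")


@dataclass(frozen=True)
class PulseSchedule:
    """Periodic LED illumination pulses as seen by the CD instrument."""

    period_s: float = 10.0
    pulse_duration_s: float = 0.25
    ht_drop: float = 30.0           # V, magnitude of the HT dip during a pulse

    def __post_init__(self):
        if not (self.period_s > self.pulse_duration_s > 0):
            raise ValueError("require period_s > pulse_duration_s > 0")
        if self.ht_drop <= 0:
            raise ValueError("ht_drop must be positive")


@dataclass(frozen=True)
class AggregationArtifact:
    """High-temperature aggregation signature above an onset temperature.

    The CD channel surges linearly at ``cd_surge_rate`` just above onset but
    the surge is damped with scale ``cd_decay_width`` as aggregating
    material precipitates out of the beam, so the excess CD signal is a
    transient spike peaking ``cd_decay_width`` °C above onset.  The HT
    voltage decays exponentially above onset.
    """

    t_onset: float = 50.0           # °C
    cd_surge_rate: float = 6.0      # mdeg per °C initial rise above onset
    cd_decay_width: float = 3.0     # °C, precipitation damping scale
    ht_decay_rate: float = 0.03     # 1/°C exponential HT decay above onset

    def __post_init__(self):
        if self.cd_surge_rate < 0 or self.ht_decay_rate < 0:
            raise ValueError("surge and decay rates must be non-negative")
        if self.cd_decay_width <= 0:
            raise ValueError("cd_decay_width must be positive")


@dataclass
class VariantRecord:
    """Per-variant lit/dark summary joining kinetics and melt results."""

    variant: str
    energetics: Optional[AllosteryEnergetics]
    tm_lit: Optional[float]
    tm_dark: Optional[float]
    dtm: Optional[float]            # Tm_lit - Tm_dark, °C
    fold_change_at_ref: Optional[float]
    fold_ci95: Optional[Tuple[float, float]]
    classification: str             # {"enhancing", "disrupting", "neutral", "incomplete"}
    missing: Tuple[str, ...] = ()


@dataclass
class CorrelationResult:
    """Line of best fit between light-induced stability and activity changes."""

    slope: float                    # dTm per cal/mol of ΔΔG‡
    intercept: float                # °C
    pearson_r: float
    n_used: int
    excluded: frozenset
    slope_reverse: float = float("nan")     # ΔΔG‡ per °C, reverse regression
    intercept_reverse: float = float("nan")
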