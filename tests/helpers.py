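"""Small factories for fitted-result objects used across test modules."""

import numpy as np

from phototherm import EyringFit, MeltFit, allostery_energetics


def make_eyring_fit(dh, ds, n_boot=400, spread_dh=0.0, spread_ds=0.0, seed=0):
    """EyringFit with a bootstrap cloud of given spread around (dh, ds)."""
    rng = np.random.default_rng(seed)
    boot_dh = dh + (rng.normal(0.0, spread_dh, n_boot) if spread_dh else np.zeros(n_boot))
    boot_ds = ds + (rng.normal(0.0, spread_ds, n_boot) if spread_ds else np.zeros(n_boot))
    ci = lambda v: tuple(np.percentile(v, [2.5, 97.5]))
    return EyringFit(
        dh_act=float(dh),
        ds_act=float(ds),
        n_points=21,
        boot_dh=boot_dh,
        boot_ds=boot_ds,
        se_dh=float(np.std(boot_dh, ddof=1)),
        se_ds=float(np.std(boot_ds, ddof=1)),
        ci95_dh=ci(boot_dh),
        ci95_ds=ci(boot_ds),
        seed=seed,
        n_boot=n_boot,
    )


def make_energetics(ddh, ddg, t_ref=303.15, spread=0.0, seed=0, n_boot=400):
    """Energetics with exact (ddh, ddg) point values at t_ref."""
    dds = (ddh - ddg) / t_ref
    lit = make_eyring_fit(ddh, dds, n_boot, spread, spread / t_ref, seed)
    dark = make_eyring_fit(0.0, 0.0, n_boot, spread, spread / t_ref, seed + 1)
    return allostery_energetics(lit, dark, t_ref=t_ref)


def make_melt_fit(tm, dh_fold=-60000.0, converged=True):
    return MeltFit(
        tm=float(tm),
        dh_fold=dh_fold,
        f=-20.5,
        cf=0.05,
        u=-6.0,
        cu=0.02,
        fit_window=(5.0, 80.0),
        rms=0.1,
        converged=converged,
        diagnostics={} if converged else {"reason": "synthetic flagged fit"},
    )
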