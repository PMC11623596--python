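"""Independent brute-force oracles, kept free of the implementation paths.

These deliberately avoid the package's fitting routines: the Eyring oracle
is a zooming grid search over (ΔH‡, ΔS‡) minimizing the sum of squared
errors in ln(kcat), and the one-phase oracle is a profile scan over the
rate constant with an analytic linear sub-fit of the amplitude parameters.
"""

import numpy as np

R = 1.987
KB_OVER_H = 1.380649e-23 / 6.62607015e-34


def grid_search_eyring(
    temps_k,
    kcats,
    dh_center=15000.0,
    dh_halfwidth=12000.0,
    ds_center=-15.0,
    ds_halfwidth=30.0,
    levels=6,
    n=41,
):
    """(ΔH‡, ΔS‡) minimizing SSE of ln(kcat) by iterative grid refinement."""
    temps_k = np.asarray(temps_k, float)
    log_obs = np.log(np.asarray(kcats, float))
    dh_c, dh_w, ds_c, ds_w = dh_center, dh_halfwidth, ds_center, ds_halfwidth
    for _ in range(levels):
        dh_grid = np.linspace(dh_c - dh_w, dh_c + dh_w, n)
        ds_grid = np.linspace(ds_c - ds_w, ds_c + ds_w, n)
        pred = (
            np.log(KB_OVER_H * temps_k)[None, None, :]
            - dh_grid[:, None, None] / (R * temps_k)[None, None, :]
            + ds_grid[None, :, None] / R
        )
        sse = ((pred - log_obs) ** 2).sum(axis=2)
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        dh_c, ds_c = dh_grid[i], ds_grid[j]
        dh_w = 3.0 * (dh_grid[1] - dh_grid[0])
        ds_w = 3.0 * (ds_grid[1] - ds_grid[0])
    return float(dh_c), float(ds_c)


def profile_scan_one_phase(time, values, k_lo=1e-4, k_hi=10.0, n_coarse=400, n_fine=400):
    """Best-fit rate of A(t)=P+(A0-P)e^(-kt) by 1-D scan with linear sub-fit."""
    time = np.asarray(time, float)
    values = np.asarray(values, float)

    def sse_at(k):
        design = np.column_stack([np.ones_like(time), np.exp(-k * time)])
        coef, *_ = np.linalg.lstsq(design, values, rcond=None)
        resid = values - design @ coef
        return float(resid @ resid)

    coarse = np.logspace(np.log10(k_lo), np.log10(k_hi), n_coarse)
    best = min(coarse, key=sse_at)
    idx = int(np.argmin(np.abs(coarse - best)))
    lo = coarse[max(idx - 1, 0)]
    hi = coarse[min(idx + 1, n_coarse - 1)]
    fine = np.linspace(lo, hi, n_fine)
    return float(min(fine, key=sse_at))
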