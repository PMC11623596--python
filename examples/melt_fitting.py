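"""Melting temperatures from pulse-corrupted, aggregating CD melts.

Simulates triplicate dark-state thermal melts (with LED-pulse HT dips and
the high-temperature aggregation signature) and lit-state melts (no
aggregation), then runs the cleaning chain: pulse removal, dual-wavelength
averaging, HT-informed fit window, and the two-state fit with sloping
baselines.
"""

from phototherm import (
    AggregationArtifact,
    PulseSchedule,
    TrueParams,
    clean_melt,
    fit_two_state,
    fit_window,
    simulate_melt_curve,
)
from phototherm.melt import merge_melt_scans

for condition, tm_true, artifact in [
    ("dark", 33.9, AggregationArtifact(t_onset=50.0)),
    ("lit", 31.3, None),
]:
    params = TrueParams(tm_true=tm_true)
    scans = [
        clean_melt(
            simulate_melt_curve(
                params,
                noise_sd=0.2,
                pulses=PulseSchedule(),
                aggregation=artifact,
                condition=condition,
                seed=500 + scan,
            )
        )
        for scan in range(3)
    ]
    merged = merge_melt_scans(scans)
    window = fit_window(merged)
    fit = fit_two_state(merged, window=window)
    print(f"{condition:>4}: Tm = {fit.tm:6.2f} C (true {tm_true}), "
          f"fit window {window[0]:.1f}-{window[1]:.1f} C, "
          f"rms {fit.rms:.2f} mdeg, converged={fit.converged}")

print()
print("The dark-state window stops below the ~50 C aggregation onset (the")
print("HT voltage collapses there), so the second CD transition caused by")
print("precipitation never contaminates the two-state fit; the lit melt")
print("shows no aggregation and is fit over the full ramp.")
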