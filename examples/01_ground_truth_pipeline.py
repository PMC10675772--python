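"""Ground-truth balance variables from laboratory-rate signals.

Builds one synthetic trial at force-plate/marker/IMU rates, detects the
gait events from the vertical ground reaction forces, computes the COP from
plate forces and moments, recombines the whole-body COM from the 13
segmental COMs, derives the sagittal/frontal COM-COP inclination angles and
their GCV-spline rates of change, and normalizes everything to the
101-point gait cycle.
"""

import numpy as np

from gaitbalance import balance, synth

raw = synth.make_raw_trial(synth.SubjectParams(cycle_duration_s=1.1), seed=1)

events = balance.detect_events(raw.forces[:, :, 2], rate_hz=synth.GRF_RATE)
print(f"gait events (% cycle): CTO {events.cto_pct:.1f}, "
      f"CHS {events.chs_pct:.1f}, TO {events.to_pct:.1f} "
      f"(cycle {events.cycle_duration_s:.2f} s)")

cops = [balance.compute_cop(raw.forces[p], raw.moments[p]) for p in range(2)]
cop = balance.combine_cop(cops, raw.forces[:, :, 2])
com = balance.compute_com(raw.segment_coms, raw.mass_fractions)

# resample the 1200 Hz COP onto the 200 Hz marker clock before the angle
t_grf = np.arange(raw.forces.shape[1]) / synth.GRF_RATE
t_mk = np.arange(com.shape[0]) / synth.MARKER_RATE
cop_mk = np.column_stack([np.interp(t_mk, t_grf, np.asarray(cop[:, i]))
                          for i in range(3)])
sag, fro = balance.compute_ia(com, cop_mk)

k = round(synth.GRF_RATE / synth.MARKER_RATE)
ev_mk = balance.GaitEvents(hs=raw.events.hs // k, cto=raw.events.cto // k,
                           chs=raw.events.chs // k, to=raw.events.to // k,
                           next_hs=raw.events.next_hs // k,
                           rate_hz=synth.MARKER_RATE)
sag_n = balance.normalize_cycle(sag, ev_mk)
rcia = balance.differentiate_gcv(sag[ev_mk.hs:ev_mk.next_hs + 1],
                                 t_mk[ev_mk.hs:ev_mk.next_hs + 1])

print(f"sagittal IA at HS {sag_n[0]:+.2f} deg, at TO "
      f"{sag_n[round(events.to_pct)]:+.2f} deg "
      "(positive = COM anterior to COP)")
print(f"sagittal RCIA range {rcia.min():+.0f} .. {rcia.max():+.0f} deg/s")
print(f"round-trip error vs the generating template: "
      f"{np.abs(sag_n - raw.ia_template[0]).max():.2e} deg")
# The round-trip error shows the pipeline (events -> COP -> COM -> IA ->
# normalization) reproduces the curves the trial was generated from.
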