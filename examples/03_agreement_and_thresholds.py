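"""Bland-Altman device agreement and specificity-constrained thresholds.

Pairs the device's 5-minute HR/RR values with the coincident hourly manual
readings across a small cohort, then shows how an alarm threshold is chosen
at maximum sensitivity subject to specificity > 0.9.
"""

import numpy as np

from shockwatch import (CohortConfig, bland_altman, build_device_fragments,
                        build_manual_fragments, filter_patient, iter_cohort,
                        select_threshold, time_to_first_alarm)
from shockwatch.models import RiskTrajectory

pairs_hr, pairs_rr = [], []
for patient in iter_cohort(CohortConfig(n_patients=15, seed=21)):
    res = filter_patient(patient.ecg, patient.resp)
    device = build_device_fragments(patient, res.hr, res.rr)
    by_t = {f.t: f for f in device.fragments}
    for mv in patient.manual_vitals:
        if mv.t in by_t:
            pairs_hr.append((by_t[mv.t].values["hr"], mv.hr))
            pairs_rr.append((by_t[mv.t].values["rr"], mv.rr))

for name, pairs in (("HR", pairs_hr), ("RR", pairs_rr)):
    res = bland_altman([a for a, _ in pairs], [b for _, b in pairs])
    print(f"{name}: mean difference {res.mean_diff:+.3f}, 95% limits of "
          f"agreement ({res.loa_low:.2f}, {res.loa_high:.2f}), n={res.n_pairs}")
# A mean difference near zero with narrow limits means the device tracks the
# manual readings; the limits widen with manual observation noise.

# threshold selection on toy validation scores
rng = np.random.default_rng(0)
labels = np.r_[np.zeros(40), np.ones(10)]
scores = np.r_[rng.beta(2, 5, 40), rng.beta(5, 2, 10)]
thr = select_threshold(scores, labels, min_specificity=0.9)
print(f"\nthreshold at max sensitivity with specificity > 0.9: {thr:.3f}")

traj = RiskTrajectory(patient_id="demo", t=np.arange(0, 361, 5.0),
                      risk=np.linspace(0.1, 0.95, 73))
alarm = time_to_first_alarm(traj, thr)
print(f"first alarm for a steadily rising risk: t={alarm.first_alarm_t:.0f} min "
      f"(censored={alarm.censored})")
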