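"""Compare two groups of morphometry reports the way bone studies do.

Each parameter gets a Shapiro-Wilk normality gate per group, then Welch's
t-test (both normal) or Mann-Whitney U; differences are expressed as a
percentage of the control mean.  Here the flight group is simulated with a
planted 13% cortical-fraction deficit.
"""

import numpy as np

from osteomorph import RunConfig, run_study, percent_difference

rng = np.random.default_rng(0)
control = [{"sample_id": f"c{i}",
            "Dia.Ct.BV/TV": rng.normal(0.690, 0.028),
            "BV/TV": rng.normal(0.563, 0.021)} for i in range(15)]
flight = [{"sample_id": f"f{i}",
           "Dia.Ct.BV/TV": rng.normal(0.690 * 0.87, 0.026),  # planted -13%
           "BV/TV": rng.normal(0.512, 0.021)} for i in range(12)]

table = run_study(RunConfig(), control, flight)
print(table[["Index", "Control mean", "Flight mean", "Difference (%)",
             "Test", "p-value", "Significant"]].to_string(index=False))
print()
print("Difference (%) is 100*(flight-control)/control; e.g. group means "
      f"0.563 vs 0.512 give {percent_difference(0.563, 0.512):+.1f}%.")
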