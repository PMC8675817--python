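"""Tracking under a sinusoidal pressure disturbance.

A 10 mmHg drug-induced oscillation (0.25 in normalized units, period 100 s)
is added at the measured output; the error criteria are compared with the
clean run.
"""

from mapmpc import Scenario, disturbance_test

table = disturbance_test(Scenario(seed=1))
print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print("All three criteria grow with the disturbance: with a 60 s dead time "
      "the loop cannot phase-align its correction to a 100 s period, so a "
      "residual oscillation remains on the output.")
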