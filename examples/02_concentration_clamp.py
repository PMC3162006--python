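"""Tracing a steady-state relationship with a concentration clamp.

Holds A fixed at each of 25 sweep values, relaxes the rest of the toy
pathway to steady state, records B, and fits candidate algebraic forms.
For this linear chain the exact relation is B = (k2/k3)·A = 0.1·A, and the
linear form wins the least-rmse selection.
"""

import phasereduce as pr

toy = pr.make_toy_model()
tc = pr.simulate_transient(toy, pr.StimulusProtocol(
    parameter="k1", on_value=100.0, t_off=10.0, t_end=20.0))

sweep = pr.default_sweep(tc, "A")          # 0 to 1.5x the observed maximum
curve = pr.concentration_clamp(toy, "A", sweep, "B", context={"k1": 100.0})
fit = pr.fit_relation(curve)

print(f"swept A over [{sweep[0]:g}, {sweep[-1]:g}] µM at {len(sweep)} points")
print(f"best form: {fit.form}")
for name, value in fit.parameters.items():
    print(f"  {name} = {value:.6g}")
print(f"  rmse = {fit.rmse:.3g} µM")
print("\nThe fitted slope recovers the rate-constant ratio k2/k3 = 0.1: the "
      "clamp reads the steady-state law directly off the network, without "
      "algebra on the rate equations.")
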