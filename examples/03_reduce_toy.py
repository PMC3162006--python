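"""The full reduction workflow on the toy pathway.

Classifies the direct species pairs by loop area, replaces the tightly
equilibrated B equation with its fitted clamp relation, and scores the
2-ODE reduced model against the 3-ODE original.  Reduced species are still
predicted — just algebraically.
"""

import phasereduce as pr

toy = pr.make_toy_model()
protocol = pr.StimulusProtocol(parameter="k1", on_value=100.0,
                               t_off=10.0, t_end=20.0, n_out=2000)
tc = pr.simulate_transient(toy, protocol)
am = pr.pairwise_area_matrix(pr.normalize(tc))
_, direct = pr.classify_pairs(am, direct_pairs=toy.direct_pairs())

# the A-B loop area is ~0.091, so a 0.1 threshold reduces exactly that pair
plan = pr.propose_plan(am, direct, toy, threshold=0.1)
print("reduction plan:")
for a in plan.actions:
    extra = f" ({a.driver}, area {a.area:.3f})" if a.area is not None else ""
    print(f"  {a.target}: {a.action}{extra}")

curve = pr.concentration_clamp(toy, "A", pr.default_sweep(tc, "A"), "B",
                               context={"k1": 100.0})
fits = {"B": pr.fit_relation(curve)}
reduced = pr.apply_plan(toy, plan, fits)
print(f"\nODE states: {toy.ode_states} -> {reduced.ode_states} "
      f"(B now explicit: {fits['B'].form})")

report = pr.score_reduction(toy, reduced, protocol)
print("\nmean error vs original (% of each state's dynamic range):")
for s, e in report.per_state.items():
    print(f"  {s}: {e:.3f}%")
print(f"  overall: {report.overall:.3f}%")
print("\nA is untouched (0%); B and C inherit ~1% error from replacing the "
      "B dynamics by the steady-state relation.")
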