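"""Phase-loop hysteresis on the three-species toy pathway.

Simulates source → A → B → C → sink under a 10 s input pulse, normalizes
the trajectories, and prints the pairwise loop areas.  A small area means
the pair equilibrates together (a quasi-steady relationship); a large one
means the downstream species lags.
"""

import phasereduce as pr

toy = pr.make_toy_model()
protocol = pr.StimulusProtocol(parameter="k1", on_value=100.0,
                               t_off=10.0, t_end=20.0, n_out=2000)
tc = pr.simulate_transient(toy, protocol)
ntc = pr.normalize(tc)
am = pr.pairwise_area_matrix(ntc)

print("pairwise hysteresis areas (0 = no timescale separation, 1 = complete):")
for (a, b), area in sorted(am.pairs().items()):
    print(f"  {a}-{b}: {area:.4f}  [{pr.classify_area(area)}]")
print("\nThe A-B pair has the smallest area: B tracks its steady-state "
      "relation B = 0.1*A almost perfectly, so its differential equation "
      "is a candidate for algebraic replacement. B-C shows ~5x more "
      "hysteresis because C relaxes ten times more slowly than B.")
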