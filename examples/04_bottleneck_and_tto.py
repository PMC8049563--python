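"""Ancestral bottlenecks bias TT split times; TTo removes most of the bias.

A severe bottleneck just before the split shortens the early ancestral
coalescent stages, which the constant-ancestor model misreads as a more
recent split.  Supplying externally obtained drift values (here: the true
ones, as an outgroup-ascertainment stand-in) to the TTo equations replaces
the constant-size assumption with a ratio approximation for tau4 and
recovers most of the split time.
"""

from twotwo import Bottleneck, DemographyConfig, estimate_tt, estimate_tto, simulate_counts

print(f"{'bottleneck':>12} {'TT t-hat':>10} {'TTo t-hat':>10}   (true split: 10,000)")
for tau_b in (100, 500, 1000):
    cfg = DemographyConfig(
        N1=17_000, N2=17_000, NA=17_000, t_split=10_000,
        bottleneck=Bottleneck(lam=1500 / 17_000, tau_b=tau_b, phi=0),
        mu=1.25e-8, m_tot=1e9, R=500_000, seed=7, mode="expected",
    )
    res = simulate_counts(cfg)
    tt = estimate_tt(res.counts)
    tto = estimate_tto(res.counts, res.truth.alpha1, res.truth.alpha2)
    print(f"{tau_b:>9} g {tt.t1_generations:>10,.0f} {tto.t1_generations:>10,.0f}")
print()
print("The TT underestimate grows with bottleneck duration (the ancestral "
      "population of 1,500 diploids absorbs the early coalescences), "
      "collapsing to ~2,700 generations at 1,000 g; the TTo estimates stay "
      "within ~20% of the truth throughout.")
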