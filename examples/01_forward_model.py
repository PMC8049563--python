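"""Forward model: from divergence parameters to the 2+2 spectrum.

Two chromosomes per population; each site shows (i, j) derived-allele
counts.  Under the constant-ancestor model the seven polymorphic
configuration probabilities are closed forms in the drift probabilities
(alpha), the mutation-scaled split times (T = mu*t), conditional
within-branch coalescence times (V = mu*nu) and the ancestral size
(theta = mu*N_A, N_A in chromosomes).
"""

from twotwo import POLYMORPHIC_CONFIGS, TTParams, tt_forward_probs

params = TTParams(
    alpha1=0.8,      # 20% chance the pop-1 pair coalesces before the split
    alpha2=0.5,      # strong drift on branch 2
    T1=1.25e-4,      # mu*t: 10,000 generations at mu = 1.25e-8
    T2=1.25e-4,
    V1=2.5e-5, V2=5e-5,
    theta=4.25e-4,   # mu*N_A: 34,000 chromosomes = 17,000 diploids
)

probs = tt_forward_probs(params)
print("configuration  probability")
for i, j in POLYMORPHIC_CONFIGS:
    print(f"  p{i},{j}        {probs[i, j]:.3e}")
print(f"  p0,0+p2,2    {probs.lump:.6f}   (monomorphic lump)")
print()
print(f"Polymorphic fraction: {probs.polymorphic_sum:.3e} — about "
      f"{probs.polymorphic_sum * 1e9 / 1e6:.1f} of every 1,000 million sites "
      "segregate in this sample.")
print("p1,1 (a shared intermediate-frequency variant) requires both pairs to "
      "enter the ancestral population, so it scales with alpha1*alpha2.")
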