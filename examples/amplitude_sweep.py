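"""Stationary cooperation versus the link-weight amplitude ratio.

Sweeps Delta/delta over a coarse grid at b=1.34, delta=0.4 (50x50, 5000
MCS, 2 replicates per point for speed) and prints the mean stationary
cooperation fraction per ratio.  The response is non-monotone: an
intermediate amplitude sustains the most cooperation.
"""

import coevopd as cp

ratios = [0.0, 0.1, 0.2, 0.3, 0.5, 0.7, 1.0]
res = cp.sweep_amplitude(1.34, 0.4, ratios, protocol="desk", seed=0)
agg = res.aggregate().sort_values("ratio")

print("Delta/delta   mean rho_C   sem")
for _, row in agg.iterrows():
    print(f"   {row['ratio']:4.1f}       {row['mean']:6.3f}    {row['sem']:.3f}")
best = agg.loc[agg["mean"].idxmax()]
print()
print(f"optimal amplitude ratio: {best['ratio']:.1f} (rho_C = {best['mean']:.3f})")
print("ratio 0 is the frozen-weight game (extinction at this temptation);")
print("large ratios overshoot the weight bounds in single steps and erode")
print("the cooperators' advantage back toward a lower mixed level.")
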