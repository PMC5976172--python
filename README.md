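# dendricap

Quantitative analysis of Purkinje-neuron dendritic excitability from
patch-clamp recordings — for cellular electrophysiologists studying
dendritic degeneration in cerebellar ataxia models, and for anyone who
needs tested implementations of the underlying estimators.

The package implements five analysis stages plus seeded synthetic-data
generators so every stage is testable end to end without recordings:

1. **Two-compartment capacitance** — the capacitative transient after a
   voltage step ΔV decays as I(t) = A₁e^(−t/τ₁) + A₂e^(−t/τ₂); the
   fitted coefficients map to the equivalent circuit of a soma/proximal
   compartment and a distal dendritic compartment:

       C₁ = τ₁(A₁+A₂)²/(A₁ΔV)   C₂ = A₂τ₂/ΔV
       R₁ = ΔV/(A₁+A₂)          R₂ = ΔV/A₂ − ΔV/(A₁+A₂)

   C₂ tracks the surface area of the distal dendritic arbor, so its
   decline over age quantifies dendritic degeneration.
2. **Spike features** — threshold (5% of maximal dV/dt), peak-to-anti-peak
   amplitude, and half-width with sub-sample interpolation, after liquid
   junction potential correction.
3. **bAP attenuation** — back-propagating action-potential amplitude
   versus soma-to-patch distance x fit with y = A·e^(−bx) (half-width
   with y = A·e^(bx)); length constant λ = 1/b; wild-type versus mutant
   compared with the extra sum-of-squares F test for nested curves.
4. **Dendritic calcium-spike threshold** — smallest somatic current step
   eliciting the all-or-none dendritic calcium spike, windowed input
   resistance (steady states between −80 and −75 mV only), and the
   non-firing-cell usability rules.
5. **Channel-gene screen** — subset an expression table to the 145-gene
   IUPHAR voltage-gated channel superfamily, flag q ≤ 0.05, build the
   log₂ fold-change heat-map matrix, and intersect the significant sets
   at two ages.

See `docs/methods.md` for models, defaults and limitations.

## Worked example

Simulate a two-group bAP dataset planted at rates b = 0.0376 (wild-type)
and 0.0215 (mutant), then fit both groups and test whether one curve
suffices:

```python
import pandas as pd
from dendricap import (AttenuationDataset, SimBapSpec, extra_ss_f_test,
                       length_constant, simulate_bap_dataset)

wt  = simulate_bap_dataset(SimBapSpec(a0=72.86, b_amp=0.0376, seed=3),
                           group="wild_type")
mut = simulate_bap_dataset(SimBapSpec(a0=75.40, b_amp=0.0215, seed=4),
                           group="mutant")
data = AttenuationDataset(records=pd.concat([wt.records, mut.records],
                                            ignore_index=True))
res = extra_ss_f_test(data, response="amplitude")
for group, fit in res.per_group.items():
    print(f"{group:10s} b = {fit.b:.4f}  lambda = {length_constant(fit):.1f} um"
          f"  R2 = {fit.r2:.3f}")
print(f"F({res.df_num},{res.df_den}) = {res.f_stat:.1f}, p = {res.p_value:.2e}")
```

Output:

```
mutant     b = 0.0215  lambda = 46.4 um  R2 = 0.986
wild_type  b = 0.0423  lambda = 23.6 um  R2 = 0.966
F(2,20) = 62.7, p = 2.43e-09
```

The mutant group attenuates over roughly twice the distance of the
wild-type group (λ ≈ 46 vs 24 μm here), and the F test rejects the
single-curve null: back-propagating spikes invade the mutant dendrite
far more effectively. With the noise set to zero the fits return the
planted rates exactly, i.e. λ = 46.5 and 26.6 μm.

The same workflow is available from the shell:

```sh
dendricap simulate --what bap --seed 3 --out run/
dendricap atten --table run/bap_dataset.csv --out run/atten.json
dendricap study --seed 1 --out run/study/   # all five stages at once
```

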