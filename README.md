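# synaptica

Associative memory, structural synaptic plasticity, and effectual
connectivity: analyses and simulators for networks that store Hebbian cell
assemblies by rewiring.

## The problem

Cortical networks are sparsely connected — within a macrocolumn of
*n* ≈ 10⁵ neurons only about *P* = 0.1 of neuron pairs share a synapse,
while about *P*_pot = 0.5 of pairs are close enough that a synapse *could*
grow (a "potential synapse").  Storage capacity of associative networks
scales with connectivity, so at *P* = 0.1 only few memories fit.  Structural
plasticity — the ongoing elimination of unstable synapses and homeostatic
regrowth at potential locations — lets the network move its scarce synapses
to where a memory set needs them.  The quantity that tracks this process is
the **effectual connectivity**

    P_eff = #(required synapses realized) / #(required synapses),

the fraction of the consolidation-tagged neuron pairs *S* that carry an
actual potentiated synapse.  Retrieval behaves as if the memories were
stored in a static network with connectivity *P*_eff, which may far exceed
the anatomical *P*.

The package implements, as tested library code plus a `synaptica` CLI:

- **Binary associative networks.**  Willshaw storage
  `W_ij = 1 ⇔ Σ_μ u_i^μ v_j^μ ≥ 1` and zip nets, whose homeostatic synaptic
  thresholds fix the fraction *p*₁ of potentiated synapses; one-step
  retrieval `v̂_j = 1 ⇔ Σ_i ũ_i W_ij + N_j ≥ Θ_j` with fixed, ℓ-winner, or
  pattern-part thresholds, and output noise ε̂ = q₁₀ + (1/q − 1) q₀₁.
- **Connectivity measures.**  *P*, *P*_pot, *P*_eff and the consolidation
  load *P*₁ₛ = 1 − (1 − kl/mn)^M of a random memory set.
- **Structural-plasticity dynamics.**  A three-state Markov model of a
  potential synapse (potential π, silent 0, consolidated 1) with
  tag-dependent rates p_c|s, p_e|s, p_d|s and homeostatic synaptogenesis;
  both a stochastic per-synapse simulator and an exact group-level solver.
- **Capacity theory.**  Exact finite-size error rates of the diluted
  Willshaw net (binomial analysis conditioned on unit usage), pattern
  capacity M_ε, weight capacity C^wp and per-1-synapse capacity C^tot; the
  Gaussian signal-to-noise theory of covariance ("Bayesian") networks and
  the zip factor ζ(p₁) = φ(Φ⁻¹(1−p₁))²/(p₁(1−p₁)) for binarized weights.
- **Information flow.**  Transfer-entropy bounds CN ≤ TE ≤ OE relating
  storage capacity to functional-connectivity measures.
- **The spacing effect.**  A closed form for P_eff after a study gap Δt,
  and the optimal-gap criterion solved in x = (1 − p_d|0)^Δt — why spaced
  rehearsal beats massed rehearsal, and when to restudy.

## Worked example

How many cell assemblies of size *k* = 50 fit into a macrocolumn
(*m* = *n* = 10⁵, output noise ε ≤ 0.01) once structural plasticity has
raised effectual connectivity to the potential level 0.5?

```python
from synaptica import pattern_capacity, zipnet_capacity, optimal_gap, SpacingParams

r = pattern_capacity(k=50, l=50, m=100_000, n=100_000, P_eff=0.5, eps=0.01)
print(r.M_eps, round(r.C_tot, 2), round(r.P_1, 3))
# 799686 0.54 0.091

z = zipnet_capacity(k=50, l=50, m=100_000, n=100_000, P1=0.1, P_pot=0.5, eps=0.01)
print(z.M_eps, round(z.C_tot, 2))
# 965681 0.59

og = optimal_gap(SpacingParams(p_e0=0.01, p_d0=0.0001))
print(round(og.dt, 1))
# 425.3
```

The Willshaw macrocolumn stores ≈ 8·10⁵ memories — at *P*_eff = *P* = 0.1
it would store essentially none — at 0.54 bit per non-silent synapse and a
residual anatomical connectivity *P*₁ ≈ 0.09, consistent with physiology.
The zip net, which decouples *p*₁ from *k* and *M*, stores ≈ 9.7·10⁵
memories at 0.59 bit per synapse with *P*₁ fixed at 0.1.  With synaptic
turnover p_e|0 = 0.01 and deconsolidation p_d|0 = 10⁻⁴ per step, the best
moment to restudy is ≈ 425 steps after the first session, independent of
the retention interval.

The same analyses are available from the shell:

```bash
synaptica capacity willshaw --n 100000 --k 50 --peff 0.5 --eps 0.01
synaptica spacing optimize
synaptica simulate --config spaced.json --out trajectory.csv  # after: synaptica fixture --kind spaced-rehearsal --out spaced.json
```

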