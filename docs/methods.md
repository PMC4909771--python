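# Methods

This note documents the models, the numerical choices, and the limits of
what the test suite demonstrates.

## Memory model

Memories are M pairs of sparse binary patterns (u^μ, v^μ) over populations
of m address and n content neurons with mean activities k = pm and l = qn.
Two generators are provided: `fixed-size` (exactly k resp. l active units,
drawn uniformly without replacement) and `bernoulli` (each unit active
independently with probability p resp. q).  All capacity theory assumes the
i.i.d. Bernoulli component model, which makes the conditional-independence
steps of the exact analysis exact; simulations may use either.  Patterns
are stored as sorted active-index lists; dense matrices are materialized
for the network sizes the simulations actually touch (m·n ≤ ~10⁷).

**Willshaw storage** clips the Hebbian synaptic potential
ω_ij = Σ_μ u_i^μ v_j^μ at a synaptic threshold of 1.  **Zip-net storage**
computes covariance (Σ_μ (u_i−p)(v_j−q)) or homosynaptic (Σ_μ u_i(v_j−q))
potentials on the potential-connectivity mask and sets per-neuron synaptic
thresholds at the quantile that realizes exactly the target fraction of
1-synapses; ties break by (potential descending, presynaptic index
ascending), fixed so runs are bit-reproducible.  Self-connections are
permitted in auto-association (nothing in the model forbids them).

**Retrieval** is one-step: dendritic potentials x_j = Σ_i ũ_i W_ij plus
optional intrinsic noise N_j ~ Uniform[0, N_max].  Threshold strategies:
scalar Θ; ℓ-winner (the maximal integer Θ that activates at least ℓ
units — ties above threshold stay active, so the output can exceed ℓ); and
pattern-part (per-unit Θ_j equal to the count of anatomically connected
active inputs), which provably produces no miss errors for noiseless
queries.  An empty ℓ-winner query returns an empty output with a warning
flag rather than the degenerate everything-at-zero answer.

## Connectivity measures

P (anatomical), P_pot (potential), the consolidation load P_1S (fraction of
pairs the memory set tags), and P_eff (fraction of tagged pairs carrying a
potentiated synapse).  The nonzero test on a real-valued consolidation
signal is exact (Heaviside of S²) — callers quantize; an all-zero signal
raises rather than returning a silent NaN.  Tagged pairs that lack a
potential synapse can never be realized but remain in the P_eff
denominator; saturation therefore tops out at P_eff = P_pot.

## Structural-plasticity dynamics

A potential synapse is a three-state Markov chain: π (potential, not
realized), 0 (realized, silent, unstable), 1 (potentiated and
consolidated).  Per step and per synapse, with tag s ∈ {0, 1}:
consolidation 0→1 w.p. p_c|s, elimination 0→π w.p. p_e|s, deconsolidation
w.p. p_d|s (model A: 1→0; model B: 1→π), synaptogenesis π→0 w.p. p_g.
Outside rehearsal the tags are inert: every synapse uses the s = 0 rates
with p_c = 0.  Consolidated tagged synapses default to p_e|1 = p_d|1 = 0.
Updates are synchronous — all transitions are drawn from the start-of-step
snapshot — matching the recursion the group solver integrates.

Homeostasis keeps anatomical connectivity constant.  The micro simulator's
default regrows exactly as many synapses as were eliminated in the step,
uniformly among the snapshot's π locations (exact-count mode; connectivity
is constant to the synapse until the π pool depletes, which sets a warning
flag).  A probabilistic mode applies p_g = expected-elimination-flux / #π
instead.  The macro solver always balances in expectation:
p_g = [Σ_s p_e|s P_0^(s) (+ Σ_s p_d|s P_1^(s) for model B)] / Σ_s P_π^(s),
computed from the pre-step state (explicit scheme) and clipped to [0, 1].

The group-level ("macro") solver partitions potential synapses by their
signal value, iterates the three-term recursions per group, and converts
per-synapse probabilities to pair-level connectivities through the
potential-synapse-count distribution p(n) (default: one potential synapse
per pair; a pair is consolidated iff at least one of its n synapses is).
Its cost is per-group, not per-synapse, which is what makes protocol-level
and behavioral-timescale simulations cheap.

Micro-vs-macro agreement is tested on the spaced-rehearsal configuration
(m = n = 1000, M = 20 memories of 50 units, P = 0.1, P_pot = 1,
p_e|0 = 0.01, four 5-step sessions 100 steps apart, 20 seeds).  The initial
level of P_eff carries a hypergeometric placement fluctuation of the
~10⁵ actual synapses over the ~4.8·10⁴ tagged pairs that the deterministic
solver cannot know, so the test checks the initial level against its
sampling error and the subsequent *increments* against the solver — both
within 3 SE.  Model time is abstract; one step per hour is the convention
used when mapping retention intervals in days onto steps (RI_steps = 24·RI_days).

## Exact Willshaw capacity

For noiseless queries of a stored memory in a net whose required synapses
are present independently with probability P_eff: a member ("high") output
unit receives X_hi ~ Binomial(k, P_eff) inputs, so q10(Θ) = Pr[X_hi < Θ].
A non-member ("low") unit is conditioned on its usage B ~ Binomial(M−1, q),
the number of other memories containing it; given B each active address
unit is potentiated onto it independently with probability
π₁(B) = 1 − (1 − k/m)^B, so X_lo | B ~ Binomial(k, P_eff·π₁(B)) and q01 is
the B-mixture of upper tails.  The usage sum is truncated where the
cumulative tail mass of B falls below 10⁻¹⁴.  The output noise
ε̂ = q10 + (1/q − 1) q01 is minimized over the integer threshold Θ ∈ 0..k
(ties to the smaller Θ).

Pattern capacity M_ε is found by exponential bracketing plus integer
bisection on M; monotonicity of the threshold-optimized noise in M is
asserted at every probe rather than assumed.  At M_ε the module reports
p₁ = 1 − (1 − kl/mn)^M (evaluated via log1p/expm1 so 10⁶-memory loads stay
accurate), P₁ = p₁·P_eff, C_abs = M·n·T(q, q01, q10) with T the
binary-channel transinformation, C^wp = C_abs/(P_eff·m·n), and
C^tot = C_abs/(P₁·m·n).  The asymptotic weight capacity uses the closed
curve C(p₁) = ln(p₁)·ln(1−p₁)/ln 2, symmetric with maximum ln 2 at
p₁ = 1/2; the per-1-synapse curve C(p₁)/p₁ diverges like −ld p₁ for sparse
potentiation, which is the structural-plasticity advantage.

The analysis is validated against Monte-Carlo retrieval over ensembles of
m = n = 500 diluted nets (3 binomial SE).  Note the MC uses fixed-size
address patterns — the within-memory sampling-without-replacement
correlation they introduce is negligible at k/m = 0.02.

## Gaussian (zip / Bayesian) capacity

For the covariance rule the high/low dendritic-potential distributions are
approximated as Gaussians with squared SNR r² = mP(1−p)/((M−1) q(1−q)).  A
firing threshold at fraction γ of the separation gives q10 = Φ(−(1−γ)r),
q01 = Φ(−γr); γ is optimized by bounded scalar minimization.  Binarizing
optimally learned weights at the p₁-quantile retains
ζ(p₁) = φ(Φ⁻¹(1−p₁))²/(p₁(1−p₁)) of the squared SNR (2/π at the median),
so the zip net reaches ζ(P₁/P_pot) times the Gaussian pattern capacity at
connectivity P_pot, with error rates re-evaluated at r√ζ and capacity per
1-synapse C^tot = C_abs/(P₁ m n).

The Gaussian tail is an asymptotic approximation: for discrete dendritic
sums (k active inputs) it underestimates error probabilities, so at small
sizes the predicted capacity is optimistic — at m = n = 2000, k = 40 the
empirically bracketed capacity is about half the prediction, and the test
asserts exactly that factor-two bracket rather than a sharper claim.  At
macrocolumn scale (n = 10⁵, k ≥ 50) the theory is consistent with the exact
Willshaw analysis and is the intended operating regime.

## Transfer-entropy bounds

Treating retrieval as a binary memory channel with i.i.d. memory bits, the
normalized transfer entropy is bounded by the normalized capacity
CN = T(q, q01, q10) from below and the output entropy OE = H_b(q̂) from
above; deterministic retrieval attains OE, retrieval with independent
intrinsic noise attains CN.  The estimator is plug-in: empirical component
error rates from Monte-Carlo retrievals, OE from the empirical output
marginal in the deterministic regime.  No raw histogram estimation over 2ⁿ
output states is attempted — the i.i.d.-bit reduction *is* the model.
Reports in this context use the symmetric noise convention
ε̂ = q·q10 + (1−q)·q01.

## Spacing effect

With p_c|s = s, p_e|1 = p_d|1 = 0 (model B), the performance reached by a
brief second study after a gap Δt admits a closed form in
x_d = (1−p_d|0)^Δt and x_e = (1−p_e|0)^Δt, given the first-session
performance P_eff^(1) and the consolidated fraction
P₁(t₁) = P₁(t₀)(1−P_1S)(1−p_d|0)^{t₁} + P_1S·P_eff^(1).  The form is an
approximation to the full group recursion (the silent-pool bookkeeping is
linearized); against the macro engine it is accurate to ~1–2% over the
tested protocols, and the zero-gap identity P_eff^(2)(0) = P_eff^(1) is
exact.  After the second session performance decays by (1−p_d|0) per step,
so the optimal gap is independent of the retention interval — the model's
known limitation (behaviorally the optimal gap grows with RI; capturing
that needs at least two synapse populations with different rates, which is
out of scope here).

The stationarity criterion in x = (1−p_d|0)^Δt with
α = ln(1−p_e|0)/ln(1−p_d|0) is solved by Brent's method on (0, 1) to
10⁻¹²; α > 1 (turnover faster than deconsolidation) is required for an
interior optimum, otherwise a boundary diagnosis is returned.  Both the
continuous optimum and its best integer neighbor are reported.  Near the
optimum the objective is extremely flat (fractions of a percent over
hundreds of steps), so argmax positions are ill-conditioned; validations
therefore require the criterion's gap to realize ≥ 99.9% of the maximal
simulated performance rather than comparing argmax indices.

Default protocol parameters are the cortical set P_pot = 0.4, P = 0.1,
P₁(t₀) = 0.02 (≈ 20% of synapses in the "up" state), consolidation load
P_1S = 0.001 (a small set of new facts against a large old repertoire),
first session t₁ = 10 steps, second session 1 step.

## What the synthetic data does and does not show

The fixture generator produces i.i.d. random sparse patterns, Bernoulli
potential-connectivity masks, and consolidation signals derived from the
stored set itself.  Real cortical data differ in known ways: pattern
statistics are neither i.i.d. nor homogeneous, potential connectivity has
geometric structure (distance-dependent, with multi-synapse contacts whose
count distribution p(n) is only generically supported here), and
consolidation signals are noisy rather than exact Willshaw tags.  Passing
tests therefore demonstrate internal consistency of the theory and
correctness of the implementations under the stated stochastic model, not
quantitative predictions for any particular cortical area.

## Numerical conventions

- All probabilities of rare events are computed with log1p/expm1 or
  scipy's tail functions; binomial tails via `binom.sf/cdf`.
- Randomness flows from one master seed through named, CRC-keyed
  substreams, so multi-stage runs are reproducible component by component.
- 0-based indexing everywhere, including the text file formats.
- Degenerate inputs raise `ParameterError` with the offending quantity in
  the message (all-zero signal, zero consolidation load, infeasible
  zip-net target, vanishing gap-formula denominator).
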