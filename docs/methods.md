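# Methods

## Model and procedures

We test `k` one-sided elementary null hypotheses `H_j: δ_j = 0` against
`δ_j > 0` with strong FWER control at level `α` over two stages.  All
procedures are closed tests: every nonempty intersection `H_J`, `J ⊆ I₁`,
receives a local level-`α` two-stage test, and `H_j` is rejected when every
intersection containing it is rejected.  Coherence of the elementary
decisions is therefore structural, not an additional assumption.

### Graph weighting

A weighting strategy is a graph `({w_{j,I}}, G)` with nonnegative nodal
weights summing to at most one and rows of the transition matrix summing to
at most one with zero diagonal.  Removing node `i` updates

    w_j ← w_j + w_i g_ij,
    g_jk ← (g_jk + g_ji g_ik) / (1 − g_ji g_ij),

with the new edge set to zero when the denominator vanishes (two nodes
passing all weight to each other while both are removed: there is no weight
left to route through them).  Removing all nodes of `I ∖ J` yields
`{w_{j,J}}`; the result is independent of removal order, which the test
suite verifies by exhaustive permutation on small random graphs.  The table
is built by dynamic programming down the subset lattice, so each of the
`2^k − 1` subsets costs one node removal.  For exhaustive graphs (all sums
equal one) the extracted weights of every subset sum to one; weights are
monotone (`w_{j,J'} ≥ w_{j,J}` for `J' ⊆ J`).

### Local tests

With marginal p values `p_j` and weights `w = {w_{j,J}}`, zero-weight
components dropped:

- nonparametric: `p_J = min(1, min_j p_j / w_j)`;
- parametric (correlations known): `p_J = P_{H_J}(min_j P_j/w_j ≤ q)` with
  `q` the observed minimum — a multivariate-normal union probability on the
  z scale;
- mixed: partition the positive-weight labels into blocks of known
  correlation; each block contributes its parametric exceedance probability
  (block-local minimum) divided by the block weight sum; the adjusted p is
  the minimum over blocks, capped at one.  Singleton blocks reduce to
  `p_j / w_j`; one block reduces to the parametric case (exactly so for
  exhaustive graphs, whose weights sum to one).

Correlation knowledge is a partition of the labels into blocks carrying a
one-factor representation `corr(Z_i, Z_j) = a_i a_j`.  This covers the two
structures that occur in multiarm trials — comparisons sharing a control
arm (`a_i = √(n_i/(n_i+n_0))`, hence 0.5 pairwise under balanced
randomization) and equicorrelated blocks with `ρ ≥ 0` — and no numeric
value is ever imputed for cross-block correlations.

### The combination method

`ν = (√t, √(1−t))` at the planned information fraction `t`, fixed for good:
under the null the stage-wise adjusted p values are independent and
(super)uniform, so `C_J` keeps its null distribution regardless of interim
adaptations.  `α_{J,1} = 2 − 2Φ(z_{α/2}/√t)` (Lan–DeMets O'Brien–Fleming
spending) and `α_{J,2}` solves
`P(P₁ ≤ α₁) + P(P₁ > α₁, C(P₁,P₂) ≤ α₂) = α`, a bivariate normal orthant
equation in `(Z₁, ν₁Z₁ + ν₂Z₂)` with correlation `ν₁`.  After the interim
the open intersections split into `J_A` (subsets of the selected set `I₂`,
tested with the possibly adapted weights), `J_B` (no stage-two data,
`p_{J,(2)} = 1`), and `J_C` (partial data, `p_{J,(2)} = p_{J∩I₂,(2)}`
inherited from the selected part, including its weights).

### The CER method

Per intersection, `c_{J,1}` spends `α_{J,1}` and `c_{J,2}` exhausts `α`
through the two-look group-sequential equations — sums of per-component
bivariate probabilities (nonparametric), a joint MVN union over stage-one
and cumulative z statistics (parametric; stage correlation `√t` within a
hypothesis, shared-control correlation across), or block sums (mixed).
Cumulative p values follow the inverse-normal rule
`p_{j,2} = 1 − Φ(√t_j z_{p_{j,1}} + √(1−t_j) z_{p_{j,(2)}})` with the
per-hypothesis (possibly adapted) information fraction `t_j`, computed from
the actual stage allocations as a ratio of informations.  Given stage-one
data, the cumulative statistic crosses its boundary iff the incremental z
exceeds `(z_{w c₂} − √t z_{p₁})/√(1−t)`; `B_J` is the resulting conditional
rejection probability (union within blocks, summed across blocks).  The
adapted constant solves `conditional level(c̃) = B_J` with the adapted
weights, fractions and incremental correlations.  Partially dropped subsets
are tested through `J ∩ I₂` with the weight-table entry of `J ∩ I₂` (zero
weight on dropped labels, surviving weights summing to one).  When the PCER
sum reaches one the intersection is rejected outright — no stage-two
outcome could violate the conditional constraint.

Two deliberate choices where the construction was open:

- *Unreachable equality.* If even full spending (`c̃ = 1`) leaves the
  adapted conditional level below `B_J`, the constant is capped at one
  rather than raising an error: the CER/PCER requirement is an inequality,
  so the capped test is the least conservative valid test.  This arises
  when an adaptation sharply increases stage-two information.
- *Parametric `J ∈ J_C`.* The conditional union is computed over
  `J ∩ I₂` only, conditioning on the stage-one p values of those same
  components; the conditional constraint `≤ B_J` (computed on full `J`)
  is what guarantees the level, so the restriction is conservative-safe.

### Numerical layer

All probabilities reduce to normal orthants evaluated by fixed quadrature:
a Gauss–Legendre correlation-integral bivariate CDF (absolute error below
1e-12 for |ρ| ≤ 0.95), a Gauss–Hermite one-factor reduction (96 nodes; 32
inside the simulator, where Monte-Carlo error dominates), and a two-factor
tensor grid (40×40) for the two-look joint probabilities.  scipy's MVN
integrator handles general correlation matrices and serves as the
independent oracle in tests.  Every routine is deterministic, which the
boundary root-solving (Brent, argument tolerance 1e-12, brackets
`[1e-12, 1−1e-12]` on the p-value scale) relies on.  Marginal p values of
exactly 0 or 1 are clamped to `[1e-15, 1−1e-15]` before `Φ⁻¹`.  All
boundary comparisons are non-strict (`≤`).

## The simulator

The generator emulates a four-arm, two-endpoint, two-stage trial: 100
subjects per arm planned (50 per stage; the interim at 50% of enrollment),
subject-level bivariate normal outcomes with common σ = 1 and endpoint
correlation ρ (0.5 in power runs; 0 and 0.8 additionally for error-rate
runs), active arms defined by effect size δ = 0.4 on both endpoints of the
arm, one-sided pooled-variance t tests per stage.  The weighting graph
gives each primary 1/4; a rejected primary passes 3/4 of its weight to its
own secondary and 1/12 to each other primary; a rejected secondary returns
its weight in thirds to the other primaries.  Dropping rules act on the
marginal stage-one primary p values (drop at p ≥ 0.75 / 0.5 / 0.25, or keep
only the smallest).  Dropped arms' stage-two subjects are reassigned in
equal integer shares to the continuing arms including control, the
remainder to control — the same convention that turns 35 dropped subjects
into a 52/53 split over two arms.  Stage-one rejections count toward power
and FWER regardless of later dropping; conjunctive power is reported as
undefined for the keep-one rule, under which rejecting all false nulls is
impossible by construction.

The combination method is simulated by plain replication; the CER method by
the two-phase scheme (m₁ stage-one draws, m₂ stage-two completions each,
cluster-robust standard errors over stage-one draws), because the expensive
step — solving the adapted boundary of every open intersection — depends on
stage one only.  When no arm is dropped the adapted constants equal the
preplanned ones and the solve is skipped.  Problem sizes: the packaged
acceptance run uses 10,000 combination-method replicates for the null error
rate; the test suite uses 2,000–2,500 combination replicates and
250–400 × 8–10 CER draws, sized so that the method ordering it checks is
separated by more than three Monte-Carlo standard errors.  A single PCG64
stream (child streams per interim-selection group) makes every estimate
exactly reproducible from the seed.

What passing simulations do and do not show: the generator matches the
assumptions of the analysis (normal outcomes, common known-to-be-equal
variances estimated by pooling, independent stages, exactly attained
allocation).  It does not emulate overdispersion, missing data, staggered
enrollment or delayed endpoints, so the estimated operating characteristics
certify the implementation under its stated model, not robustness to
violations of it.

## Known limitations

- Two stages only; no futility boundaries; no estimation or confidence
  intervals after adaptation.
- Parametric blocks require a one-factor correlation structure for the
  fast path; general PSD matrices fall back to scipy's integrator (slower,
  and in more than two dimensions accurate to ~1e-7 rather than 1e-12).
- Negative within-block correlations have no one-factor representation and
  are supported only through the fallback path.
- The closed tests are not consonance-improved: rejecting an intersection
  need not entail an elementary rejection, which is one reason the
  combination method is markedly conservative under aggressive designs.
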