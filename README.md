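# gamcp — graph-based adaptive two-stage closed testing

`gamcp` implements multiple testing for confirmatory clinical trials that
compare several treatment arms against a shared control on several
endpoints, over two stages with an unblinded interim analysis.  It is aimed
at trial statisticians who need strong familywise error rate (FWER) control
while keeping the freedom to drop arms, reweight hypotheses, or change
stage-two sample sizes after looking at interim data.

## The methodology

Testing priorities are encoded as a directed graph: nodal weights
`w_{j,I}` say how the one-sided level `α` is split across the elementary
hypotheses `H_j`, and a transition matrix `G = (g_ij)` says where a removed
node's weight flows.  Iterated node removal extracts the weights
`{w_{j,J}, j ∈ J}` of every intersection hypothesis `H_J` in the closure,
and `H_j` is rejected only when every `H_J ∋ j` is rejected by a local
level-`α` test (closed testing).  Each intersection is tested with a
weighted Bonferroni test, a weighted parametric (Dunnett-type) test when
the z-statistic correlations are known, or a mixed test when they are known
only within blocks.

Two adaptive two-stage procedures are provided:

- **p-value combination** — stage-wise adjusted p values `p_{J,1}`,
  `p_{J,(2)}` are merged through the inverse-normal rule
  `C_J = 1 − Φ{ν₁ Φ⁻¹(1−p_{J,1}) + ν₂ Φ⁻¹(1−p_{J,(2)})}` with prespecified
  `ν₁² + ν₂² = 1`; `H_J` is rejected early when `p_{J,1} ≤ α_{J,1}` (an
  O'Brien–Fleming-type spending level) or finally when `C_J ≤ α_{J,2}`,
  with `α_{J,2}` solved from the two-stage level condition.
- **conditional error rate (CER/PCER)** — a two-look group-sequential test
  with constants `c_{J,1}, c_{J,2}` is prespecified per intersection; at
  the interim the conditional probability `B_J(χ₁)` that the preplanned
  test would still reject is computed, and the adapted stage-two constant
  `c̃_{J,2}` is solved so the adapted test's conditional rejection
  probability equals `B_J`, which preserves the level under arbitrary
  data-dependent adaptations.

A vectorized Monte-Carlo simulator estimates disjunctive power, conjunctive
power and FWER for a four-arm two-endpoint trial with interim drop-the-loser
rules and reallocation of the dropped arms' subjects.

## Worked example

A trial compares two doses against placebo on a primary and a key secondary
endpoint (`H1`/`H2`: high/low dose primary, `H3`/`H4`: the matching
secondaries), with an interim at half the information:

```sh
gamcp fixtures schizophrenia_combo --out fx
gamcp combo plan    --config fx/design.yaml --out out
gamcp combo interim --config fx/design.yaml --out out
gamcp combo final   --config fx/design.yaml --interim out/interim.json \
                    --adaptation fx/adaptation.yaml --out out
```

prints

```
{"alpha": 0.025, "alpha1": 0.0015253227579889112, "alpha2": 0.024499771789662797, ...}
{"early_rejected": ["H1"], "continuing": ["H2", "H3", "H4"]}
{"H1": "stage1", "H2": "retained", "H3": "stage2", "H4": "retained"}
```

meaning: the interim spends `α_{J,1} = 0.00153` of the one-sided 0.025, the
final combination tests run at `α_{J,2} = 0.0245`; the high-dose primary
hypothesis `H1` is rejected already at the interim, and after stage two the
high-dose secondary `H3` is also rejected, while the low-dose hypotheses
are retained.  The same design analysed with the CER method
(`gamcp fixtures schizophrenia_cer`, then `gamcp cer plan / interim /
adapt / final`) drops `H3` at the interim, treats the low-dose endpoints as
co-primaries, and rejects `H2` and `H4` — illustrating that the CER route
can convert the same evidence into more rejections.

The same machinery is available as a library:

```python
from gamcp import DesignSpec, GraphSpec, CorrBlock, CorrelationModel, interim_test
```

Simulator (four arms, two endpoints, conservative dropping):

```sh
gamcp simulate --scenario S1 --rule conservative --method cer --reps 2000 --m2 8 --seed 7
```

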