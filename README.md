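# chromlink

Linking chromatin-conformation change to transcription regulation: a tested,
reusable pipeline for differential promoter–enhancer Hi-C interaction
analysis.

Chromosome-conformation (Hi-C) experiments that compare two cellular states —
for example a leukemia cell line before and after a differentiation stimulus —
usually find that TAD boundaries and A/B compartments barely move, while the
contact intensity *within* specific TADs, and between specific promoter and
enhancer bins, changes substantially and tracks gene expression.  `chromlink`
implements the computational framework for that style of analysis:

- **Bridge-linker pair processing** — trimming reads at the biotinylated
  bridge-linker junction (`CGCGATATCTTATCTGACT` / reverse complement),
  duplicate removal, strand-orientation-based span-threshold estimation
  (~3 kb for a 4-cutter), and classification of pairs into full segments,
  self-ligations, intra- and inter-chromosomal ligations.
- **Contact matrices** — 40-kb binned symmetric count matrices, iterative
  correction (ICE) balancing, observed/expected transforms, and
  megabase-scale replicate reproducibility.
- **A/B compartments** — per-chromosome first principal component of the
  O/E-correlation matrix, marker-oriented signs, and compartment-switch
  calling that requires agreement of every replicate in both conditions.
- **TAD dynamics** — per-TAD internal/external counts, an empirical-null
  fold-change test built from within-condition replicate ratios, seven
  σ-deviation categories, and boundary-stability comparison.
- **Differential gene-regulatory interactions** — the MA-plot binomial
  random-sampling test (below) on within-TAD promoter-bin × enhancer-bin
  contact counts, with Benjamini–Hochberg-adjusted p < 0.001 Gain/Loss calls.
- **Enrichment statistics** — Fisher exact tests of DEG enrichment, Mann–
  Whitney comparisons, region signal fold changes, open-chromatin peak
  enrichment in Gain/Loss regions, and TF-network hub-degree ranking.
- **Synthetic data with planted truth** — a toy genome (2 × 20 Mb, 40-kb
  bins) with TADs, a compartment checkerboard, distance-decaying Poisson
  contacts, planted interaction changes coupled to planted expression
  changes, and linker-bearing read pairs, so the whole pipeline is testable
  end to end without external data.

## The differential-interaction statistic

Contacts of one gene-regulatory bin pair are modelled as binomial sampling
from each condition's library: C_i ~ Binomial(n_i, p_i), with n_i the total
intra-chromosomal Hi-C count of condition i.  With X = log2 C2, Y = log2 C1,

    M = X − Y,     A = (X + Y) / 2,

the null hypothesis H0: p1 = p2 is tested through the conditional normal
law of M given A = a.  The common proportion is estimated as
p̂ = 2^a / √(n1·n2), giving delta-method variances
V_i = (1 − p̂) / (n_i · p̂ · ln²2), and

    E[M | A = a] = log2(n2 / n1),
    Var[M | A = a] = 4·V1·V2 / (V1 + V2),
    z = (m − E[M|a]) / √Var[M|a]  ~  N(0, 1) under H0.

M is oriented condition 2 − condition 1, so interactions enhanced after
treatment (Gain) have M > 0.  Calls use Benjamini–Hochberg-adjusted
p < 0.001.

## Worked example

Run the full differential-interaction pipeline on the default planted
synthetic system, and one hand-sized call of the statistic:

```python
from chromlink.synthetic_data import TruthConfig
from chromlink.workflows import differential_interaction_recovery
from chromlink.reg_interactions import MarsInput, mars_test

result = differential_interaction_recovery(TruthConfig(seed=1))
calls = result["calls"]
called = calls[calls["call"] != "NS"]
print(f"candidate pairs tested: {len(calls)}")
print(f"Gain calls: {(called['call'] == 'Gain').sum()}, "
      f"Loss calls: {(called['call'] == 'Loss').sum()}")
print(f"recall on planted pairs: {result['recall']:.3f}")
print(f"precision vs generator truth: {result['precision']:.3f}")

single = mars_test(MarsInput(0, 1, c1=100, c2=200, n1=1_000_000, n2=1_000_000))
print(f"M = {single.m:.2f}, A = {single.a:.2f}, "
      f"z = {single.z:.2f}, p = {single.p:.2e}")
```

prints

```
candidate pairs tested: 1129
Gain calls: 46, Loss calls: 49
recall on planted pairs: 0.988
precision vs generator truth: 1.000
M = 1.00, A = 7.14, z = 5.83, p = 5.57e-09
```

The toy system plants 40 Gain and 40 Loss promoter–enhancer pairs with a
twofold contact change; 1,129 within-TAD gene-bin × regulatory-bin pairs
pass the count filter, 95 are called at adjusted p < 0.001, 79 of the 80
planted pairs are recovered with the correct direction, and every call sits
on a cell whose generating model truly changed.  The single-pair example
shows that a count doubling at matched library depth (C1 = 100 → C2 = 200 at
n = 10⁶) yields z ≈ 5.8.

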