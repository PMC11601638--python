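# hdselect

Hyperdimensional-computing classification and backward variable
elimination for case/control microbial profiles.

Shotgun-metagenomic studies routinely ask which microbial species
separate diseased from healthy individuals — for example which gut
bacteria distinguish colorectal-cancer stool samples from controls.
`hdselect` answers that question with a brain-inspired vector-symbolic
architecture (VSA): instead of fitting coefficients, it encodes every
sample into a high-dimensional integer vector and classifies by cosine
similarity against per-class associative memories, then strips away
uninformative species by wrapper-style backward elimination. It is aimed
at computational microbiologists working with MetaPhlAn-style
relative-abundance tables, but the classifier and selector are
domain-agnostic.

## The model

**Encoding.** A value range `[v_min, v_max]` is quantised into `L` *level
vectors*: bipolar hypervectors (`±1` entries, dimensionality `d`, default
10,000) built from one random base vector by flipping `N = ⌊d / 2 / L⌋`
fresh coordinates per step. Flip sets are disjoint, so similarity decays
linearly with level distance,

    cos(ℓ_i, ℓ_j) = 1 − 2·N·|i − j| / d ,

making nearby values similar and distant values quasi-orthogonal. A
sample with F feature values is encoded as

    enc(x) = Σ_{n=0}^{F−1} ρ^n( ℓ(x_n) ) ,

where `ρ` is a one-position circular shift tagging the feature position
(the first feature is unrotated). Binary presence/absence data uses
`L = 2`.

**Classification.** Each class vector is the element-wise sum of its
training samples' encodings; a sample is predicted as the class with the
highest cosine similarity. Bundling noise is mitigated by *retraining*:
up to `R` passes (default 10) over the training set in which every
misclassified encoding is subtracted from the wrong class vector and
added to the true one, stopping when the training error count stops
changing.

**Feature selection.** Backward variable elimination: starting from all
species `S`, each iteration cross-validates one model per candidate set
`S∖{f}`. Candidates below the accuracy threshold `T` (default 60%) are
discarded; every feature whose candidate accuracy lies within the
*accuracy uncertainty percentage* `u` (default 1%) of the iteration best
`ACC*` is removed together. The loop stops when no candidate reaches
`T`, when an iteration's best falls below the previous iteration's best,
or when `S` empties. The survivors are reported together with the
globally best subset and the *sub-optimal* model: the evaluated subset
with the fewest features whose accuracy still exceeds 70%.

**Statistics.** Selected species are characterised by class prevalence,
log2 fold change of mean relative abundance, and a two-sided Wilcoxon
rank-sum test with Benjamini–Hochberg correction (significant when
`p ≤ 0.05` and `FDR ≤ 0.2`).

## Worked example

```python
from hdselect import (SelectionConfig, SyntheticSpec, backward_eliminate,
                      binarize, generate, wilcoxon_bh)

dataset, informative = generate(SyntheticSpec(seed=42))   # 60 CRC / 60 control
binary = binarize(dataset)                                # presence/absence
config = SelectionConfig(dimensionality=1024, levels=2, seed=42)
result = backward_eliminate(binary, config)

print(f"full-model accuracy: {result.history[0].mean_accuracy:.3f}")
print(f"selected features:   {len(result.selected_features)}")
print(f"best accuracy:       {result.best_accuracy:.3f}")
print(f"models evaluated:    {result.models_evaluated}")
```

prints

```
full-model accuracy: 0.875
selected features:   11
best accuracy:       0.925
models evaluated:    455
```

The synthetic cohort plants three discriminative species (present in 80%
of cases vs 10% of controls); all three survive elimination here, the
full 30-species model reaches 87.5% 5-fold accuracy, and the best
evaluated subset reaches 92.5%. The follow-up statistics recover the
plant cleanly:

```python
stats = wilcoxon_bh(dataset, case_label="CRC", control_label="control")
print(stats.loc[informative, ["prevalence_case", "prevalence_control", "log2fc", "fdr"]])
```

```
                prevalence_case  prevalence_control  log2fc  fdr
s__Species_002          86.6667             13.3333  2.1162  0.0
s__Species_019          73.3333              8.3333  5.4254  0.0
s__Species_022          71.6667              6.6667  3.8483  0.0
```

Each planted species is far more prevalent in cases, more abundant on
the log2 scale, and significant after BH correction.

The same pipeline is available from the shell:

```sh
hdselect simulate --outdir cohort --seed 42
hdselect select cohort/profiles.tsv -m cohort/metadata.tsv \
    --binary -d 1024 --outdir run --seed 42
hdselect stats cohort/profiles.tsv -m cohort/metadata.tsv --outdir run
```

which writes a per-candidate ledger TSV, a summary JSON and the
differential-abundance TSV. Real MetaPhlAn tables are read the same way
(multiple tables are harmonised: species not detected in every study are
folded into the `unclassified` remainder, then the <1% max-abundance and
<5% prevalence filters apply).

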