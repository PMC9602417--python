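# tdfe — tensor-decomposition-based unsupervised feature extraction

`tdfe` identifies genes whose expression follows an interpretable
pattern — stable across biological replicates, monotone over postnatal
development, and contrasting an exposed against a control group — from
time-course expression experiments with a factorial layout. It was built
for studies of the developmental liver transcriptome of mouse offspring
after maternal cadmium exposure (three postnatal days, three replicates,
exposed vs control dams), but applies to any gene × replicate ×
timepoint × condition design.

## Method

Per-timepoint expression tables are assembled into a fourth-order tensor

    x[i, j, k, l],   i = gene, j = replicate, k = timepoint, l = exposure group

of shape (N, M, K, L) (default non-gene extents M = 3 replicates,
K = 3 postnatal days, L = 2 groups). The tensor is factored by
higher-order singular value decomposition (HOSVD), a Tucker
decomposition

    x[i,j,k,l] = Σ G(l1,l2,l3,l4) · u_{l1,i} · u_{l2,j} · u_{l3,k} · u_{l4,l}

whose factor matrices hold the left singular vectors of each mode's
unfolding and whose core G weights every combination of components.
One component per non-gene mode is then chosen by interpretability:

* **replicate** — the component with the least variation across
  replicates (score: sd / max |entry|; replicates are exchangeable, so a
  flat profile is the meaningful one),
* **time** — a strictly monotone component (tested in both sign
  orientations; the most pronounced trend wins),
* **exposure** — the component whose two entries have opposite signs,
  i.e. an exposed-vs-control contrast.

Fixing that triple (l2′, l3′, l4′) turns the core into a vector
G(l1, l2′, l3′, l4′) over gene components; at most M·K·L = 18 of its
entries can be non-zero, and the top components by |G| (default three)
are kept. Genes are scored on those components under a normal
assumption:

    p_i = P[ χ²_df  >  Σ_{l1′} ( u_{l1′,i} / σ_{l1′} )² ],   df = #components

with σ the component's standard deviation over genes (about zero, no
centring), adjusted by Benjamini–Hochberg, and selected at adjusted
p < 0.05. A per-gene multiple-regression baseline
(v = a + b·PND + c·exposure, Wald χ²₁ tests on b and c, both p < 0.05,
no correction) is fitted alongside for comparison; it characteristically
selects a far larger, far less specific gene list.

A synthetic-data generator produces per-timepoint tables with a planted
gene set whose exposure-group difference decays monotonically over the
postnatal days, so the whole pipeline is testable end-to-end with known
ground truth.

## Worked example

Run the full pipeline on the standard benchmark simulation (1000 genes,
50 planted, seed 5):

```
$ tdfe -v run --simulate --seed 5 --out demo_run
INFO tdfe: tensor dims (N, M, K, L) = (1000, 3, 3, 2)
INFO tdfe: components: replicate=1 time=2 exposure=2 genes=[2, 6, 14]
INFO tdfe: selected 34 / 1000 genes at alpha=0.05
INFO tdfe: regression baseline selected 51 genes
```

Reading the output: the automatic criteria picked replicate component 1
(flat across replicates), time component 2 (monotone decreasing over
PND 1 → 21 → 42) and exposure component 2 (opposite signs for exposed
vs control); gene components 2, 6 and 14 had the largest core weights at
that triple. Chi-square scoring with BH correction then called 34 of
1000 genes significant at α = 0.05 — these are the genes carrying a
replicate-stable, decaying exposure response — while the uncorrected
two-coefficient regression baseline flagged 51. `demo_run/` contains
the tensor bundle, the Tucker factors, `selection.json` (per-column
criterion scores and the full core slice), `gene_scores.tsv` (loadings,
statistic, raw/adjusted p per gene), `selected_genes.txt` (one gene per
line, ready for enrichment-tool upload) and `run_record.json` (every
analysis choice actually used).

The same stages are available as library functions
(`tdfe.generate_dataset`, `tdfe.build_tensor`, `tdfe.hosvd`,
`tdfe.select_components`, `tdfe.score_genes`, `tdfe.fit_genes`) and as
stagewise CLI subcommands (`simulate`, `build`, `decompose`, `select`,
`score`, `regress`).

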