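# Methods

## Problem and model

The package infers repressive miRNA→mRNA interactions from a paired
two-condition time-course design: each feature (miRNA or transcript) is
measured as a log2 intensity in control and UVB-treated cultures at
timepoints d1, d4, d7, d9 with `n` replicates per condition×timepoint.
Treatment response is modelled additively on the log2 scale: a responsive
miRNA *i* has UVB mean `c_i + s_i · E · g(t)` (control mean `c_i`, sign
`s_i = ±1`, maximal effect `E`, monotone time profile `g`), and a target *j*
of that miRNA is shifted by `−β` times the miRNA's shift. Inference combines
three ingredients, each a separate decision with its own parameters:

1. a differential-expression call per feature,
2. a sequence/tool-based candidate set of (miRNA, gene) pairs, and
3. a Pearson anti-correlation test of each candidate over the time course.

Only pairs passing all three — DE miRNA, enough prediction-tool votes, and
`r ≤ −r_min` — become high-confidence edges of the exported bipartite
network.

## Differential expression

Per feature, a two-sided Welch (unequal-variance) *t*-test of UVB vs control
at the chosen scope (one timepoint, default the last, or all timepoints
pooled), with Welch–Satterthwaite degrees of freedom, followed by
Benjamini–Hochberg step-up adjustment across all tested features
(delegated to `statsmodels.multipletests(method="fdr_bh")`). The call is
conjunctive: `2**|log2fc| ≥ fold_cutoff` (default 1.5) **and** adjusted
p < α (default 0.05; `use_adjusted=False` switches to the raw p).

Welch rather than a pooled-variance or moderated (empirical-Bayes) *t* is a
deliberate choice: with triplicates per group Welch is the robust default,
and variance-shrinkage machinery would add a modelling layer this package
does not aim to reproduce. The consequence is somewhat lower power at n = 3
than a moderated test would give; the recovery results below are measured
under exactly this choice.

Degenerate features — zero variance in both groups — arise in the σ = 0
simulations. The scalar `welch_t` refuses them when the means are also
equal (there is literally no information), and returns t = ±inf, p = 0 when
the means differ (a noise-free shift). The matrix-level caller instead
records the all-equal case as t = 0, p = 1, "not DE", so that noise-free
pipelines run end to end; this convention is visible in the results table
(df is NaN for such rows).

## Candidate pairs

The built-in "seedscan" predictor implements canonical seed matching only.
With the seed defined as miRNA nucleotides 2–8, a site on the UTR sense
strand is: 6mer = reverse complement of nt 2–7; 7mer-m8 = reverse complement
of nt 2–8; 7mer-A1 = the 6mer followed by an A; 8mer = the 7mer-m8 followed
by an A (the A is required as a literal adenosine regardless of the miRNA's
first base). Each occurrence of the 6-nt core is reported once with the most
specific type it supports, so a 7mer inside an 8mer at the same core is
never double-counted. Coordinates are 0-based half-open; UTRs are taken in
sense orientation; `N` never matches. A pair is emitted when a site of at
least `min_site_type` (default 7mer-A1) exists; multiple sites still give
one pair. Conservation, site accessibility and pairing thermodynamics are
deliberately absent — those signals enter only through imported external
tool tables.

Consensus voting unions the per-tool pair lists (external TSV tables plus,
optionally, seedscan) and keeps pairs supported by at least `min_tools`
tools (default 3). Three was chosen from the error rates of the simulated
tools: with 10 tools at sensitivity 0.7 and false-positive rate 0.01, a true
edge reaches 3 votes with probability P(Bin(10, 0.7) ≥ 3) ≈ 0.998 while a
non-edge does so with P(Bin(10, 0.01) ≥ 3) ≈ 1.1×10⁻⁴. The threshold is a
flag, not a constant.

## Correlation scoring and the network

Each candidate is scored by the sample Pearson correlation of the miRNA and
gene profiles. The default profile is the **ratio** mode: per-(timepoint,
replicate) log2(UVB/control), pairing replicate k of UVB with replicate k of
control, n = timepoints × replicates (12 under the defaults). Ratios remove
baseline differences between features and make an unresponsive gene a
zero-variance vector, whose correlation is reported as undefined (NaN) and
classified `none`. The **intensity** mode (all samples' log2 intensities) is
retained for sensitivity analysis.

Sign classification uses a symmetric threshold `r_min` (default 0.5):
negative if `r ≤ −r_min`, positive if `r ≥ +r_min`, else none. No p-value is
attached to r — at n = 12 the threshold is the decision rule. Positive edges
are kept and labelled (they flag indirect or co-regulated relationships) but
are never high-confidence; only negative edges are.

`pearson_r` uses the two-pass definitional formula (centred dot product over
the product of norms). A result within 4 machine epsilons of ±1 is rounded
to exactly ±1: for exactly (anti-)proportional inputs the deviation of the
true correlation from ±1 is quadratic in the rounding noise of the inputs,
i.e. far below double precision, so the residual is roundoff of the dot
products themselves.

The network is a bipartite graph: miRNA nodes on one side, gene nodes
(role `target`, or `transcription_factor` when the gene appears in a
user-supplied TF list) on the other, annotated with each feature's DE
direction and fold. Unclassified edges are excluded by default. Exports are
byte-stable (nodes and edges sorted lexicographically): SIF
(`mirna <sign> gene`), GraphML, and node/edge attribute TSVs in which
negative edges are coloured green and positive red, matching the usual
display convention for repression networks. Structural invariants —
bipartiteness, |r| ≤ 1, high-confidence ⇒ negative — are asserted on every
constructed graph.

The pipeline restricts correlation scoring to candidates whose miRNA was
called DE (`all_mirnas=True` overrides): the screen asks which *responsive*
miRNAs drive which transcripts.

## Synthetic data

The generator emulates the study design, not the measurement platform: it
writes log2 intensities directly (no probe-level effects, normalisation,
batch structure or missing values), with baselines uniform on [6, 12] —
a typical mid-range for log2 microarray intensities — and i.i.d. Gaussian
noise (sd 0.25 by default, a plausible replicate-level scatter for arrays)
added to every sample. The time profile `g` is a linear ramp over the
timepoint index (0, 1/3, 2/3, 1): the minimal monotone choice, since real
miRNA kinetics vary but are not specified by any single functional form.
Defaults: 40 miRNAs, 20 regulated with |effect| = 2 log2 units at the last
timepoint; 400 genes of which 100 (5 per regulated miRNA, disjoint) are
planted targets with β = 1; triplicates; 10 simulated tools at
sensitivity 0.7 / false-positive rate 0.01.

Sequences: mature miRNAs are random 21-nt RNA with pairwise-distinct seeds;
UTRs are random 600-nt DNA. Every planted edge gets one 8mer site (reverse
complement of the miRNA's nt 2–8 plus A) spliced at a recorded position, and
rejection sampling regenerates any UTR that accidentally contains a
7mer-m8-or-stronger site for a planted miRNA that does not target it.
Weaker accidental sites (6mer, 7mer-A1) are allowed — they exist in real
UTRs too and are handled by consensus voting, not by construction.

The bundle is a pure function of its configuration object including the
seed; three independent RNG streams (expression, tool tables, sequences)
keep each sub-generator individually reproducible.

What passing tests therefore show: the pipeline recovers planted repressive
structure under additive Gaussian noise at realistic amplitude, with
calibrated tool errors. What they do not show: robustness to platform
artefacts, non-monotone kinetics, overlapping target sets, expression-
dependent site efficacy, or indirect-regulation confounding — all absent
from the generator by design.

## Measured behaviour (computed by the test suite and acceptance script)

* Noise-free limit (σ = 0): every planted pair has r = −1 exactly and the
  pipeline's precision and recall on planted edges are both 1.0.
* Default noise (σ = 0.25): precision ≥ 0.9 and recall ≥ 0.8 at the tested
  seeds (in practice both are at or near 1.0; the mean planted-pair r is
  about −0.84).
* Global null (200 features, 3 vs 3, σ = 0.25): the conjunctive DE rule
  with BH at α = 0.05 calls nothing in ≥ 95 of 100 seeded runs.

Problem sizes in the tests are the generator defaults above; the
false-discovery check uses 100 replicate null simulations of 200 features.

## Numerical and degenerate-input conventions

* BH on an empty vector returns an empty vector; ties are handled by stable
  sorting, so adjustment is permutation-invariant.
* `fold_change` reports linear fold ≥ 1 plus a direction flag
  (`up`/`down`/`none` at exactly zero mean).
* Irradiation-time rounding is half-away-from-zero (timer convention),
  not banker's rounding.
* cPDL divides by the printed lab constant 0.301 rather than
  log10(2) ≈ 0.30103 — a deliberate, documented ≈0.01% deviation that keeps
  outputs on the lab's own scale.
* `consensus` with `min_tools` larger than the number of supplied tools
  warns and returns an (often empty) result rather than raising; a pipeline
  configured that way completes with an empty network and a manifest that
  records zero edges.
* Matrix TSVs are parsed with round-trip float precision, so
  write→read→analyse gives bit-identical results to the in-memory path.

## Known limitations

* No moderated-variance testing; power at n = 3 is below a limma-style
  analysis of the same data.
* No multiple-site dose effects: one site suffices and site count does not
  enter scoring.
* Anti-correlation cannot distinguish direct repression from shared
  upstream regulation; with correlated trajectories (two like-signed
  regulated miRNAs), a target of one correlates perfectly with the other,
  and only the candidate-set stage separates them.
* The TF role annotation is user-supplied; the package does not call
  transcription factors itself.
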