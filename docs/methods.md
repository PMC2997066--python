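# Methods

## Activity calling

Each gene's background level is estimated from a **reference sample set**
(by default the healthy samples; activity is then called on all tissues).
The sliding-window label-entropy procedure assumes that in the expression
range occupied by background noise, samples from *many* tissue classes mix,
whereas ranges occupied by genuinely active expression contain only the few
expressing tissues.  The midpoint of the maximum-entropy window is therefore
an estimate of the center of the background mass; adding twice the sample SD
of the values below it yields the activity cutoff.  A gene is active in a
tissue when its *median* there strictly exceeds the cutoff — the median is
what makes the procedure robust: even a cutoff that sits only ~1 SD above
the background center is crossed by a background tissue-median with
negligible probability at realistic replicate counts.

Numerical choices:

* **Window geometry.**  Width 5% of the gene's maximum; the stride is a
  fixed fraction of the maximum (default 1%), giving a deterministic,
  scale-equivariant grid of half-open windows `[lo, lo + w)` from 0 to the
  maximum.  Empty windows carry no entropy entry.
* **Entropy.**  Plug-in Shannon entropy of the tissue-label proportions,
  base 2 (the argmax is base-invariant).
* **Tie rule.**  Among windows with exactly equal maximal entropy the one
  with the highest midpoint wins — the most conservative choice (highest
  cutoff, fewest calls).
* **SD.**  Sample SD (n−1) of the non-missing values strictly below the
  midpoint.  With fewer than two such values the SD is undefined; the
  cutoff falls back to the midpoint and the gene is flagged
  (`sd_undefined`).  Genes with no usable reference data (all missing, or
  maximum 0) are flagged `no_data` and called inactive everywhere.
* **Missing data** are excluded pairwise from windows, SDs and medians; a
  tissue with no non-missing values for a gene is called 0 and logged.

### Calibration caveat (documented, deliberate)

The per-**sample** false-activation rate of the literal cutoff formula is
substantially larger than the nominal 2.5% suggested by "midpoint + 2 SD":
when all background tissues share one expression distribution, the
max-entropy window sits at the background *mode* (the plug-in entropy of
every bulk window estimates the same log₂ k, so the densest window wins),
and the values below the midpoint form roughly a half-normal whose sample SD
is ≈ 0.60 σ.  The cutoff then lands near μ + 1.2 σ and ~11–15% of
individual background samples exceed it (`analysis/02` and
`scripts/acceptance.py` measure ≈ 0.14).  Two further rare failure modes
follow from the same geometry: in a few percent of genes the midpoint
drifts ~1 σ low and the cutoff falls at or below the background mean
(systematic false actives), or — for genes active in many reference
tissues — the max-entropy window lands in the *active* mass (systematic
false inactives).  Because the activity call thresholds the tissue median,
aggregate sensitivity and specificity stay ≥ 0.9 regardless (measured
≈ 1.00 / 0.96 at the default study conditions), but *set-exact* recovery
of gain/loss gene lists over a whole panel is not a robust property of the
procedure.  The test suite asserts the idealized per-sample bound and the
exact gain/loss recovery faithfully and documents their failure rather than
weakening them.

## Taxonomy

Asymmetric-binary (Jaccard) distance: mismatched positions over positions
where at least one vector is 1; joint inactivity is uninformative and
ignored; two all-zero vectors get distance 0 so identical profiles always
co-cluster.  Agglomeration uses scipy's `linkage` (complete for the main
taxonomy, Ward for gain/loss panels); merge heights are verified against a
brute-force Lance–Williams oracle in the tests.  With tied distances the
tree topology depends on the input order, so order-invariance is only
asserted on tie-free fixtures.  The number of groups read off a dendrogram
is a presentation choice; `cut_groups(k)` exposes it (defaults: 4 tissue
groups, 6 gene groups).

## Co-expression walks

Pearson correlation over pairwise-complete observations for all unordered
pairs; pairs with fewer than `min_overlap` shared non-missing samples (or a
zero-variance gene on the shared support) carry no correlation.
`min_overlap` defaults to 30 at desk scale.  The per-gene link gate uses the
nearest-rank empirical quantile of the gene's own **signed** correlations at
0.999; everything at or above the threshold is a valid outgoing link, so at
least one link survives whenever any correlation exists and validity is
directed (u→v can be valid while v→u is not).  Walks (500 per seed, 5
steps) choose uniformly among the current node's valid links excluding the
immediately previous node; dead-end walks terminate early and are counted.
Visits are counted with multiplicity and the seed is excluded from its own
profile; the neighborhood keeps genes visited ≥ 2 times.

## Enrichment and term ordering

One-sided hypergeometric over-representation with the correlation-graph
gene set as universe; raw p < 0.01 accepted by default (an optional
Benjamini–Hochberg switch uses `scipy.stats.false_discovery_control`).
Terms accepted for ≥ 15 seed genes are retained for presentation.
Information content is computed from the ontology's own annotation
frequencies, IC(t) = −ln(|genes(t)|/|genes(root)|), after closing
annotations under ancestor propagation; Lin similarity uses the common
ancestor with maximal IC (ties → smallest term id), and the presentation
order is the leaf order of a Ward tree on 1 − similarity.

## The synthetic generator

`simulate_expression` emulates the features of a large curated multi-tissue
expression corpus that this analysis depends on: per-gene bimodal
expression — a clipped-Gaussian background Normal(μ_g, σ_g) with μ_g ~
U(3, 6), σ_g ~ U(0.3, 0.8), plus an active component shifted
+`active_shift_sd`·σ_g (default 8) in a random subset of tissues
(default fraction 1/6, or an exact per-gene count) — replicate samples in
each of `n_tissues` classes split into paired healthy/malignant halves,
completely-at-random missing values (default 5%), and gene modules whose
members share a per-sample latent factor scaled by `module_factor_sd`·σ_g.
`simulate_ontology` plants one designated term per module (annotating
exactly the module's genes) under a single root, with filler terms chained
below the module terms, each annotating the first half of its parent's
genes.  Marker genes are the first gene of each module.

What the generator does **not** emulate: platform or batch effects,
tissue-specific background shifts, informative missingness, heavy-tailed
expression noise, and correlation structure beyond the planted modules.
Passing tests therefore demonstrate that the procedures recover the
structure they assume, not that the assumptions hold in any real corpus.

**Study scales.**  The activity studies use 30 tissues × 20 samples
(40–200 genes) — enough replicates for stable tissue medians.  The
co-expression study uses 1500 genes × 99 tissue classes × 6 samples with
five 20-gene modules at `module_factor_sd = 3`.  The tissue count matters:
the 8-SD activity shifts induce *coincidence* correlations between
unrelated genes that happen to be active in overlapping tissue subsets,
with magnitude ∝ 1/√n_tissues; at the corpus-scale 99 classes they stay
safely below the module-factor correlations, so each gene's
top-99.9-percentile links (2 per gene at n = 1500 under the nearest-rank
gate) point to module mates and walk neighborhoods are module-pure.  At a
few dozen tissues this ordering inverts — a real limitation of percentile
gating on strongly bimodal data, and the reason tissue-rich compendia are
the method's natural substrate.

## Pipeline and reproducibility

One master seed deterministically derives per-stage seeds (SeedSequence of
`[master, crc32(stage)]`); per-seed-gene walk seeds derive from the walk
stage seed and the gene's position.  Every stage reads and writes the
declared plain-text artifacts (TSV/GMT/OBO/Newick), so `run-all` and the
chained subcommands are byte-identical for a fixed seed; the manifest
records the effective config, stage row counts and SHA-256 checksums.
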