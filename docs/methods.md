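# Methods

This note documents the statistical model, the defaults and the design
choices behind `mircnet`, in the spirit of a package vignette. Everything
quantitative stated here is computed by the test suite or by
`scripts/acceptance.py`; nothing is asserted from memory.

## Data model and preprocessing

Expression values are treated as **linear-scale normalized intensities**;
the fold-change FC = mean(case)/mean(control) is a ratio of linear means,
so log2-stored matrices must be declared with `log2_input: true`, which
exponentiates on read. Public series mix both conventions, and the ratio
definition only makes sense on the linear scale.

Preprocessing policies (`io_formats`):

- **Technical replicates** are collapsed to the arithmetic mean of their
  member columns (`collapse_replicates`); a replicate group spanning case
  and control labels is a hard error.
- **miRNA identifier mapping** keeps only assay identifiers in a
  one-to-one relationship with a canonical miRNA name *in both
  directions*: if two assay ids map to one name (or one id is ambiguous),
  all of them are dropped rather than guessed.
- **Gene identifier mapping** drops unmapped probes, renames the rest to
  uppercase gene symbols, then averages rows sharing a symbol per sample.
  This preserves per-sample total intensity up to the averaging factor (a
  property test checks the weighted-sum identity).
- **Longitudinal designs** (two samples per patient) are handled by an
  explicit `include_samples` list in the config rather than a hard-coded
  choice of time point, since no principled default exists.
- Gene symbols are uppercased throughout; miRNA names are kept
  case-sensitive ("miR-"/"let-" prefixes are meaningful).

Duplicated feature row names in an input matrix are rejected at read time:
resolving them is the identifier-mapping step's job, and silent collapsing
would hide mapping errors.

## Per-dataset differential expression

Each feature gets a two-sided two-sample t-test between cases and
controls. The default is the **Welch** (unequal-variance) form, exposed as
`test: student|welch`: with four independent datasets from different
platforms and cohort sizes from 8 to 99 per group, assuming equal
variances is the riskier choice. Degenerate features (zero variance in
both groups) get p = 1 when the means are equal, p = 0 otherwise; features
with a zero control mean have no defined fold-change and are excluded with
a logged warning. No per-dataset multiple-testing correction is applied —
the raw p ≤ α threshold (α = 0.05) is deliberate, because error control
comes from the cross-dataset consensus and its permutation test, not from
any single dataset.

## Consensus call

A feature passes the **overlap criterion** when it is DE (p ≤ α) in at
least `k_min` datasets (default 3 of 4) and the **directional criterion**
when, additionally, its fold-change direction is identical in every
supporting dataset (and not "unchanged"). Features absent from a platform
simply lack that dataset's vote; nothing is imputed, so a feature measured
on fewer than `k_min` platforms can never pass. The directional criterion
implies the overlap criterion by construction, and the caller is invariant
to dataset ordering (both are property-tested).

Reported per-feature fold-changes across datasets are summarized as the
**arithmetic mean of per-dataset fold-changes** and labelled as such
(`mean_fold_change`); geometric averaging would be defensible too, but the
arithmetic mean is what practitioners typically quote for this statistic.

## Permutation tests

Two permutation tests assess whether the consensus could arise from random
per-dataset selections. Per replicate, for each dataset *d*, a uniform
random subset of that dataset's platform universe of size |DE_d| is drawn;
the statistic T is the number of features selected in ≥ `k_min` datasets.
The second (directional) test additionally requires the supporting
selections to agree in direction. Two design points:

- **Direction in the null.** A sampled feature inherits the dataset's
  *observed* direction label for it — directions form a fixed per-dataset
  labelling and only membership is randomized. This preserves each
  dataset's empirical up/down imbalance, which an i.i.d. ±1 assignment
  (available as `direction_mode="random_sign"`) would erase.
- **Reporting convention.** p_report = r/B with r = #{T_b ≥ T_obs};
  when r = 0 the value reported is the bound 1/B (flagged `is_bound`,
  read "p < 1/B"). With the default B = 5000 this yields the bounds 0.0002
  (and 0.002 at B = 500). The conservative estimator (r+1)/(B+1) is
  available via `p_convention="plus_one"`.

The implementation is vectorized (per-dataset subset draws via
`argpartition` over uniform variates; selection and direction counts
accumulated in B × features integer matrices), so B = 5000 over realistic
universes runs in well under a second. The replicate mean is verified
against an exhaustive enumeration over all C(6,3)⁴ subset combinations on
a six-feature toy problem.

**Calibration.** The reported r/B value is discrete and conservative, so
its distribution under the null is not literally Uniform(0,1) — no valid
discrete p-value's is. Calibration is therefore checked on the randomized
probability-integral-transform value (r' + V·ties)/B with V ~ U(0,1)
(`PermutationResult.uniformized_p`), which is exactly uniform when the
observed statistic is exchangeable with the null replicates; the test
suite confirms uniformity (Kolmogorov–Smirnov) across 200 simulated null
studies. The PIT value is a diagnostic only; inference always uses
p_report.

## Target-database integration

Filters follow strict, **inclusive** cutoffs:

- TarBase-style validated records are kept iff the assay method is
  exactly "reporter gene assay" (case-insensitive); correlation-based
  evidence (microarray, sequencing) is discarded because it shows
  co-expression, not causal binding.
- miRTarBase-style records are kept unless support is "weak"
  (case-insensitive; any other value, including NA, counts as non-weak).
- Predicted records pass per-database filters — TargetScan context score
  ≤ −0.19, microT-CDS miTG ≥ 0.993, miRDB ≥ 84 — and the final predicted
  set is the **three-way intersection** of per-database passing pairs.

Pairs are keyed on (canonical miRNA name, uppercase gene symbol); the
union of validated and predicted pairs becomes repression edges with
evidence `validated`, `predicted` or `both`. TF–miRNA regulation records
carrying a feedback flag contribute the reciprocal miRNA→TF repression as
an extra miRNA-target edge (deduplicated against pairs already present).
Records arrive as normalized TSVs rather than live database exports: the
databases are versioned and unavailable offline, so the fixture schema
defines the contract.

## Promoter motif scanning

Promoter windows span **1.5 kb upstream to 0.5 kb downstream of the TSS**
(2 kb), strand-oriented: on the minus strand the interval
[tss−500, tss+1500) is reverse-complemented so that window position 0 is
always −1500 in transcript orientation. Coordinates are 0-based,
half-open; windows running off a sequence end are N-padded with a logged
warning.

Motifs are scored as log2 odds against a 0-order background (from the
MEME file, or uniform), with pseudocount 10⁻³ added to motif probabilities
(then renormalized) before the log. Scores are discretized to an integer
grid with step (score range)/1000, and the **exact null distribution** of
a background string's score is computed by positionwise convolution of the
per-position 4-point score distributions; the match p-value is the tail
P(score ≥ s). Both the table and the window scores use the *same* integer
grid, so lookups are exact — there is no float-to-bin mismatch, and the DP
is verified against exhaustive enumeration over all 4^L strings for
L ≤ 6. A granularity coarser than 100 bins across the score range triggers
a warning.

Scanning slides over every offset on both strands (the reverse-complement
motif is scanned over the forward window and gets its own tail table,
which matters for asymmetric backgrounds). Footprints containing N or
lowercase (repeat-masked) bases are skipped entirely. Matches with
p ≤ 0.05 are kept — this threshold is the pipeline's stated operating
point, not the much stricter default of common scanners, because the
subsequent top-1% truncation does the real selection. Hits are then
reduced to the best (smallest-p) hit per (TF, target) pair, sorted by p
with lexicographic tie-breaks, and truncated to ceil(0.01 × unique pairs),
**separately for TF→miRNA and TF→gene** predictions (the two categories
have very different candidate-set sizes, and a joint cut would let the
larger swamp the smaller). Deduplication before truncation was a genuinely
open choice; dedup-first is implemented because duplicated hits otherwise
consume top-1% slots with redundant information.

## Network assembly and loop motifs

Sign conventions: miRNA→target edges are repressions (−1), TF→target
edges activations (+1), unless a curated regulation record overrides the
sign. Overrides are applied before duplicate merging, so a curated
repression and a default-sign prediction of the same edge merge cleanly
(to evidence `both`) instead of conflicting; genuinely contradictory
explicit signs raise an error naming the pair. One edge per ordered
(src, dst) pair; self-loops are excluded; node roles (mirna / tf / target)
derive from incident edge categories, and a node may hold several roles
(TFs that are themselves miRNA targets are counted once in node totals,
separately in the role breakdown).

**Feedback loops** are simple directed cycles, enumerated with a bounded
simple-cycle search; the default bound is length 2 (mutual TF↔miRNA
regulation, the biologically typical case), with longer cycles available
via `max_len`. A loop is positive iff its repression-edge count is even.
**Feed-forward loops** are ordered triples X→Y, Y→Z, X→Z over distinct
nodes, coherent iff sign(X→Z) = sign(X→Y)·sign(Y→Z), with a flag for
miRNA participation. Both enumerations are validated against brute-force
oracles on random signed digraphs.

## Enrichment and subnetworks

Over-representation uses the upper hypergeometric tail P(X ≥ k) with
query and term sets intersected with the background first; terms with
zero overlap are skipped. The background defaults to the union of the
gene-set collection's genes and the network's gene nodes — the honest
choice when the query derives from a network rather than from a measured
expression universe. Adjustment is Benjamini–Hochberg (step-up), and
terms with q ≤ 0.05 are called enriched. miRNA nodes never count toward
the overlap k (gene-set annotations describe genes); miRNAs enter the
picture only through subnetwork adjacency.

A term's **subnetwork** is its genes present in the network (the seed),
plus all first neighbours, plus the seed-incident edges. Edges running
between two non-seed neighbours are excluded by default — the narrower
reading of "edges between the genes and their first neighbours" — but
`include_neighbor_edges=True` switches to the full induced-edge variant,
since either reading is defensible. The term × miRNA presence matrix marks
a cell iff the miRNA sits in that term's subnetwork node set.

## Synthetic data: what it emulates and what it does not

`synthetic_data` generates the study conditions end to end. Defaults per
molecule type: 4 datasets with (case, control) counts (20, 21), (59, 37),
(23, 70), (8, 8) — the unbalanced designs typical of public blood
microarray series; 850 features per platform (mature-miRNA panels carry
fewer than 900 identifiers) of which a 60% shared core is measured by all
platforms and the rest is platform-private, reproducing the
cross-platform overlap problem the consensus addresses; 18 planted
consensus features plus 10 inconsistent (conflicting directions) and 20
sporadic (≤ 2 datasets) decoys.

Intensities are **lognormal**: a per-feature baseline exp(N(6, 1)) times
exp(N(0, noise_sd²)) per sample, with the case mean of a planted feature
multiplied (up) or divided (down) by the effect size δ. Multiplicative
effects make the ratio-of-means fold-change target δ in expectation.
Defaults δ = 2.0 and noise_sd = 0.5 (natural-log scale) are typical
magnitudes for moderately dysregulated transcripts on microarrays; the
high-power regime used in the recovery test (δ = 4, noise_sd = 0.2,
20 per group, 30 planted features, ≥ 90% recovery) is a separate, fixed
configuration. All outputs are pure functions of (spec, seed).

Interaction fixtures are built **by scenario, not by running the
filters**: each record's retention flag follows from the construction
(e.g. a TarBase record is emitted *with* a microarray method and flagged
must-drop), including records exactly at each score cutoff to pin the
inclusive boundaries, and membership patterns covering 1-of-3, 2-of-3 and
3-of-3 database presence. Promoter fixtures are i.i.d. background
sequences with maximal-probability motif consensus strings inserted at
recorded offsets on either strand, plus occasional N-runs.

Deliberately **not** modelled: inter-feature correlation, batch and
platform effects, array-specific noise, realistic miRNA naming or
annotation structure. Passing tests therefore demonstrate that the
machinery is correct under its stated model, not that the statistical
power figures transfer to real arrays, where correlated noise makes
consensus both harder and more necessary.

## Pipeline determinism and problem sizes

The pipeline fans a single global seed out to stages by fixed offsets, so
stages can be rerun in isolation; every output file is SHA-256-recorded in
`manifest.json`, and identical (config, seed, inputs) reproduce identical
hashes (tested). Everything is single-threaded by contract.

Problem sizes in the shipped tests are scaled to what the checks need:
consensus/permutation tests run on universes of 40–200 features with
B = 300–5000 replicates; the null-calibration study uses 200 simulated
studies at B = 300; loop oracles use 12-node graphs; motif enumeration
stops at L = 6 (4⁶ strings). These sizes make every oracle exhaustive or
tight while keeping the full suite fast.

## Known limitations

- No moderated (empirical-Bayes) test statistics; small-cohort datasets
  rely entirely on the consensus for stability.
- No q-values for motif hits and no input-learned background; the scanner
  is a faithful exact-p reimplementation, not a full FIMO replacement.
- The enrichment engine is a generic gene-set ORA; it does not reproduce
  any specific annotation service's term content, clustering or GO-DAG
  propagation.
- Feedback-loop search defaults to length 2; longer cycles must be
  requested explicitly and can be numerous in dense networks.
- miRNA alias histories are not resolved; identifier maps are taken as
  given.
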