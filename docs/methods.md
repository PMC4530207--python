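# Methods

## The model

`larma` treats a differential-expression (DE) meta-analysis as a
market-basket problem. Each tumour-vs-normal comparison is a
*transaction* whose *items* are the lncRNA gene symbols called
differentially expressed in it (|log2 fold change| ≥ 1, FDR-adjusted
p ≤ 0.05, closed thresholds on both sides). An itemset S has

    supp(S)  = #{transactions containing all of S} / n
    conf(X⇒Y) = supp(X ∪ Y) / supp(X)

A rule X⇒Y with confidence 1 therefore means: in every comparison where
all genes of X were modulated, all genes of Y were modulated too. With
few transactions (n = 34 at the study scale) confidence 1 is the
conservative choice; support ≥ 0.15 requires at least
⌈0.15·34⌉ = 6 carrier comparisons.

Redundancy is defined over the *union* gene set of a rule: a family of
rules spanning the same gene set, or a subset of it at the same
support, carries one finding, and only the largest gene set is kept.
This is exactly a closed-itemset filter restricted to rule-bearing
itemsets; the survivors form an antichain under (⊆ with equal support).

## Transactions and filtering

* lncRNA status comes from a biotype whitelist
  (3prime_overlapping_ncrna, antisense, lincRNA, processed_transcript,
  sense_intronic, sense_overlapping), looked up in a two-column TSV or
  a Gencode-dialect GTF. In GTF mode a gene qualifies if *any* of its
  transcripts carries a whitelisted biotype.
* Multi-probe genes are collapsed to the passing probe with maximum
  |LFC| (ties by input order). The gene-level sign derives from that
  representative. This is one of several defensible summaries; the
  chosen rule is deterministic and monotone in the thresholds.
* Comparisons whose basket is empty are dropped by default (the meta-
  analysis keeps only gene lists with at least one modulated lncRNA);
  `drop_empty=False` retains them.
* Basket files (`comparison_id<TAB>item1,item2,...`) round-trip items
  and signs (signed dialect `GENE:+1`); representative magnitudes are
  deliberately not serialized.

## Mining

Levelwise Apriori with bitset counting: each item maps to an integer
bitmask over transactions, so support counting is AND + popcount and
all counts are exact integers. Candidate (k)-sets join two frequent
(k−1)-sets sharing a (k−2)-prefix and are pruned by anti-monotonicity.
The default rule dialect emits single-item consequents (C one item of
S, X = S∖C), matching common Apriori implementations; a full
bipartition mode exists behind `all_consequents=True`. Redundant-rule
*counts* (e.g. in the null simulation) always use the default dialect.

`min_support_count` guards the ceiling against binary-float round-up
with a 1e−9 relative tolerance (0.15·40 must give 6, not 7).

Output ordering everywhere is (descending size, descending support,
lexicographic items), which also resolves ties deterministically.

## Null simulation

Two seeded nulls assess whether the mined structure exceeds chance:

* `sample` — draw `n_draw` transactions without replacement from a
  pool and re-mine with the same thresholds. The pool is the user's
  choice (e.g. non-cancer comparisons); the method does not guess it.
* `shuffle` — before drawing, destroy item co-occurrence by swap
  randomization: 10 × (number of incidences) attempted pairwise swaps
  of (transaction, item) incidences, rejecting swaps that would
  duplicate an item. Transaction sizes are preserved exactly, item
  marginals approximately; signs travel with items.

Each run records the redundant-rule count and the largest rule
itemset's size; the summary reports exceedance counts over strict
thresholds and empirical quantiles. Identical seeds give identical run
lists.

## Validation codification

The cross-dataset assessment of a signature is narrative in origin;
`validate` codifies it into three tiers applied mechanically per gene,
with the RNA-seq matrix as arbiter of failure:

1. **not_validated** — no evidence at all; or every RNA-seq entry is
   NS/NA; or the finite RNA-seq entries disagree in sign with each
   other or with the discovery consensus.
2. **confirmed** — in *every* evidence matrix the gene is assessable in
   all comparisons, every entry agrees with the consensus sign, and
   every entry has |LFC| ≥ `strong_lfc` (default 1).
3. **consistent_attenuated** — otherwise (sign-consistent but
   sub-threshold somewhere, or not assessable everywhere).

"Validated" for headline counting means confirmed ∪
consistent_attenuated. This codification was reverse-engineered to
reproduce the packaged 13-gene worked example exactly (6 confirmed, 4
attenuated, 3 not validated); printed small values such as −0.3 are
treated as finite significant LFCs, since the source tables print
"n.s." where a call was not significant. Whether sub-threshold printed
values were formally significant in the original RNA-seq analysis is
not knowable from the tables; the codification takes them at face
value.

## Comodulation

The pairwise engine constrains one gene to a user-chosen target with a
required sign (+1 up, −1 down) and scores every other gene over the
comparisons where both are measurable (copresence). On that universe,
with n11/n10/n01/n00 the 2×2 of (target-with-sign, candidate-any-sign)
presence:

    support    = n11 / N
    confidence = n11 / (n11 + n10)
    lift       = n11·N / ((n11 + n10)(n11 + n01))
    phi        = (n11·n00 − n10·n01) / √(row and column margin product)
    chi²       = N·phi²   (1 df, no continuity correction)

phi equals the Pearson correlation of the two 0/1 presence indicators
(oracle-tested). Defaults: copresence ≥ 10, phi > 0.3, lift ≥ 0,
chi² p ≤ 1 (permissive). Earlier pairwise-comodulation services
computed related indexes over a proprietary comparison corpus; the set
above is this package's own reconstruction over the copresence
universe. The
candidate's sign is unconstrained; each result carries the candidate's
majority sign among co-modulated comparisons so up/down lists can be
split downstream. Zero-margin tables have undefined phi and are
filtered.

## PCA and separation

Exact SVD of the centred (optionally scaled) samples × probes table;
samples are observations, probes variables; scaling is off by default
so the analysis runs on log2 intensities as-is. Component signs are
fixed (largest-magnitude loading positive) for reproducible score
files. Keeping all components, scores·loadingsᵀ + means reconstructs
the input to 1e−8. Group separation is quantified as the mean
silhouette over samples in the first-k (default 2) component space;
singleton classes contribute 0.

## Enrichment

Flat gene-set over-representation: one-sided Fisher exact
(hypergeometric upper tail) per set against an explicit universe,
Benjamini-Hochberg across all tested sets, significance at adjusted
p strictly below 0.05. Ontology-graph traversal and most-specific-term
selection are deliberately out of scope; users supply flat GMT sets.

## Synthetic studies

`synth.generate_study` emits probe-level DE tables whose transaction
encoding is known by construction: planted patterns (gene set, carrier
comparisons, sign vector) plus independent Bernoulli background
modulation (default rate 0.05 per measurable gene and comparison), a
300-gene lncRNA universe with 50 protein-coding decoys the biotype
filter must remove, 34 comparisons by default, and optional
per-comparison universe dropout to emulate platform heterogeneity.
DE probes draw |LFC| ~ 1 + Exp(mean 1) and adj_p ~ U(0, 0.05); null
probes draw LFC ~ Normal(0, 0.3) clipped to (−1, 1) and adj_p ~
U(0.05, 1], so they can never pass the thresholds and the generated
tables reproduce the ground-truth transactions exactly at (1, 0.05).
`thirteen_gene_study_spec` mirrors the discovery setting: one 13-gene
pattern (8 down, 5 up) carried by 6 of 34 comparisons.

What the generator does **not** emulate: correlated background biology
across datasets (background items are independent Bernoulli draws),
probe-level intensity noise, or realistic platform annotation drift.
Passing tests therefore demonstrate algorithmic correctness and
recovery under idealized noise, not performance on real GEO corpora.

## Problem sizes and determinism

The bundled worked example mines 6 transactions over 13 genes
(8 191 frequent itemsets, 53 235 rules) in well under a second. The
property suite checks the miner against exhaustive enumeration on 200
random instances (≤ 60 transactions, ≤ 20 items, baskets ≤ 7), planted-
pattern recovery over 50 seeded studies at 5% background, and the
oracle identities for phi/chi², BH and PCA reconstruction. All
randomness flows through explicit integer seeds
(`numpy.random.default_rng`).

## Known limitations

* Full-corpus analyses (dozens of GEO datasets, genome-wide
  comodulation lists) require external downloads and are outside what
  the packaged fixtures can reproduce; the property suite above stands
  in for them.
* Redundant-rule counts depend on the rule-generation dialect and are
  comparable only within one dialect.
* The validation tiers encode one reading of a narrative assessment;
  alternative readings (e.g. treating printed sub-threshold values as
  non-significant) would reclassify individual genes.
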