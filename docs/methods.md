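# Methods

This note documents the models and procedures implemented in `litpath`,
the defaults they run under, and what the synthetic-data tests do and do
not demonstrate about real corpora.

## Corpus model and filter cascade

A publication record is a (title, abstract, year, keywords, journal, DOI)
tuple; the abstract is treated as a faithful summary of the study. The
filter cascade applies, in a fixed order: (1) abstract present; (2) a
disease term — by default any token starting with `alzheimer` or
`dementia` — anywhere in title, abstract or keywords; (3) deduplication
keyed on lowercased DOI when present, else normalized title + year (DOIs
are the only stable identifier in open academic-graph dumps);
(4) negative-finding phrase match; (5) removal of records whose disease
mentions all lie inside matched exclusion-criterion phrases (span-based:
a record survives if any disease token falls outside every exclusion
span); (6) abstract length within 250–4,000 characters (configurable; the
bounds exclude title-only stubs and concatenated full texts); (7) keyword
lists longer than 30 entries are cleared, the record kept. Stages only
remove or shrink records, so the cascade is monotone and idempotent;
every stage logs (records in, records removed) and the report arithmetic
is checked to balance.

## Text normalization and matching

All matching runs on a single normalized token representation: NFKC,
lowercase, Greek letters transliterated in place (β→beta, so "Aβ42"
becomes the token `abeta42`), tokens split on non-alphanumerics with
internal hyphens kept. Dictionary phrases of 1–6 tokens are matched as
contiguous token runs, greedily longest-first, and a token run consumed
by a longer phrase is not re-counted for its sub-phrases ("mild cognitive
impairment" does not also count "cognitive impairment"). Phrases never
span field boundaries. Matching is literal (no stemming): dictionary
semantics stay exactly what the curator wrote.

## Classification rules

**Pathway association.** Each pathway dictionary splits its terms into
*full* (diagnostic for the pathway) and *partial* classes. A record gets a
full association when at least `full_min` (default 1) distinct full terms
match, else a partial association when any partial term matches, else
none. The level is monotone in the matched terms.

**Dementia class.** Four disjoint vocabularies — AD-specific (e.g.
*alzheimer*, *APP*, *presenilin*), general dementia (*memory*, *aging*),
related dementias (*parkinson*, *frontotemporal*, *ALS*), unrelated
dementias (*creutzfeldt*, *prion*, AIDS-dementia terms) — are counted per
record. The rule, in order: (a) if the unrelated share of all class hits
exceeds `unrelated_frac` (default 0.5) and no suggestive term
(*neurodegeneration*, *misfolding*, …) is present → `unrelated`; (b) if
total hits fall below `min_hits` (default 2) → `dementia` (too little
evidence for a specific call); (c) strict dominance of AD-specific over
related → `AD`, and vice versa → `related`; (d) ties → `dementia`.
Dominance uses raw hit counts, not length-weighted proportions: count
comparison is reproducible and insensitive to abstract length. The
per-record count of AD-specific hits is kept as the *AD word score*; its
pathway mean colors network nodes.

**Evidence type.** Three independent axes (genetic vs model, animal vs
human, in vitro vs in vivo) each carry two competing term sides plus a
shared review vocabulary. Review hits preempt every axis (reviews are not
original research). Otherwise a side wins with ≥ `side_min` (default 1)
hits and zero opposing hits; hits on both sides → `both`; none →
`neither`. Dictionaries can be benchmarked against records with known
labels (in practice, topic-specific journals); precision/recall with an
empty denominator is reported as undefined, never as zero.

## Ranking

A pathway's study count in a stratum is its number of distinct associated
records at the configured levels (default: full associations only; a
switch includes partial). Rank 1 is the most-studied pathway; ties take
average ranks, which makes Σrank = n(n+1)/2 an invariant and Spearman
comparisons well defined. Strata: all records, AD-labeled records,
impact-factor thresholds (records from journals missing in the impact
table are excluded from impact strata only), and single years from 1990
(earlier literature is too sparse to rank meaningfully). Yearly rank
matrices mask pathways that stay below `min_per_year` (default 20)
studies in every year — alternatively on the mean — while keeping them in
full tables. Rank trajectories are clustered with average-linkage
agglomeration on 1 − Spearman distance; distance and linkage are recorded
in the result and configurable.

## Networks

**Gene overlap.** For gene sets with ≥ 10 genes over a universe (default:
union of the loaded collection, overridable), each pair is tested with a
one-sided Fisher exact test for enrichment of the overlap k in the 2×2
table (k, |A|−k; |B|−k, N−|A|−|B|+k); depleted overlap is not evidence of
relatedness, hence one-sided (a two-sided switch exists). P-values are
BH-adjusted — by default over every eligible pair in the collection, not
just the displayed top-k sub-network, so the q-values do not depend on
the display cut — and edges with q < α (default 0.05) are weighted by
−log₁₀ q. `bh_fdr` is implemented directly from the step-up definition
(q(i) = min over p(j) ≥ p(i) of min(1, m·p(j)/j)) so that its output is
bit-for-bit the definitional value. The same machinery scores external
gene lists against the collection, and a Wilcoxon rank-sum test (exact
for combined n ≤ 20 without ties, normal approximation with tie
correction otherwise; the regime used is reported) compares literature
ranks of enriched versus non-enriched pathways.

**Co-expression.** A pathway's expression summary is the mean of
gene-wise z-scores (ddof = 1) of its member genes per sample, a
deliberately simplified re-implementation of the pathway co-expression
(PCxN) proxy statistic — the package computes its own edge statistic and
does not reproduce the published multi-tissue resource. Disjoint
pathways: Pearson correlation of the summaries. Overlapping pathways: the
first-order partial correlation between the summaries of A∖B and B∖A
given the summary of A∩B, with the p-value from t = r√((n−3)/(1−r²)) on
n−3 df. One shared gene is conditioned on directly via its z-score. This
corrects co-expression that exists only because the same measurements
enter both summaries.

*Known caveat (collider conditioning).* When shared genes are genuinely
co-regulated by both pathways' activities, the shared summary is a common
*effect* of the two activities, and conditioning on it induces a negative
bias in the corrected correlation (in the limit of two independent
activities and a noiseless shared sum, the partial correlation is −1).
The correction is therefore interpreted as removing membership-overlap
artifacts, not as a causal adjustment; the null simulations in the test
suite use the mechanical-overlap construction, where the statistic is
unbiased, and the package makes no claim about the collider regime.

## Drug targeting

Trial intervention names are resolved case-insensitively against a
synonym table; non-specific names (e.g. "calcium channel blocker") are
blocklisted; unresolved names are reported, and resolved + blocked +
unresolved always equals the input count. Indication aim (symptomatic vs
disease-modifying) is a required curated input, never inferred — that
judgment needs literature context a join cannot supply — as are gene
targets. Per class, each pathway counts the distinct drugs with at least
one target gene in its set (a drug with three targets in one pathway
counts once); counting is order-invariant and drugs with empty target
sets are flagged and counted nowhere.

## Synthetic data: what it shows and what it does not

The generators produce template-based token sequences, not natural
language. Every record embeds exactly the lexicon terms implied by its
planted labels, separated by decoy vocabulary screened at generation time
against every loaded lexicon; planted terms are additionally screened so
that a term planted for one dictionary family cannot be matched by
another family (records planted as negative-finding or exclusion-only are
exempt — the cascade removes them before annotation). This makes expected
classifier output an exact function of the truth file, which is what the
correctness tests rely on.

Default study conditions: 1990–2019, abstracts of 400–1,500 characters,
dementia-class mixture 64/16/12/8% (AD/dementia/related/unrelated,
mirroring a corpus where roughly two thirds of studies are AD-specific),
5% negative-finding and 2% exclusion-only records, an eight-journal
roster spanning impact factors 2–17 with one journal absent from the
impact table, and full-association mention rates for ten pathways spanning
0.02–0.16. Expression data follow a latent-activity factor model: each
pathway has a latent activity drawn from a configured correlation matrix
(checked PSD), each gene is the mean of its owning pathways' activities
plus N(0, σ²) noise. Observed summary correlations are attenuated below
the planted latent correlation by the factor 1/(1 + σ²/m) for m member
genes — tests account for this rather than expecting the raw planted
value.

Passing on synthetic data demonstrates algorithmic correctness —
filtering, matching, counting, ranking and the network statistics do what
their definitions say — and calibration of the statistical machinery. It
does not demonstrate dictionary quality on real abstracts: real language
has negation scope, synonymy, polysemy and section structure that
template text deliberately lacks. Dictionary quality on a real corpus
must be established the way it is in practice: manual scoring of sampled
abstracts (supported by `sample_for_review`/`aggregate_review`) and
journal-based benchmarking of the evidence axes.

## Numerical and design choices

* Problem sizes in the shipped tests and acceptance script (corpora of
  300–5,000 records, 2,000-gene universes, 300-sample expression
  matrices, 100-replicate null simulations) were chosen as the smallest
  sizes at which the planted effects are statistically unambiguous
  (binomial 99% intervals, Fisher p ≪ α for planted overlaps).
* Network fixtures keep decoy gene sets small relative to planted blocks
  so that chance overlaps are essentially never significant; recovery
  claims involving FDR thresholds are stated over replicates, because a
  BH pass at α admits a false edge with probability of a few times α per
  dataset even when everything is implemented correctly.
* Spearman, Fisher, Mann–Whitney and hierarchical clustering are
  delegated to scipy; BH and the partial-correlation edge are implemented
  in-package (definitional contracts) and cross-checked in tests against
  statsmodels and pingouin respectively.
* Ties are broken deterministically everywhere (mergesort-stable sorts,
  alphabetical tie-breaks in reports); repeated runs with the same seed
  are byte-identical, which the end-to-end test asserts.

## Limitations

Abstract-only mining misses pathways discussed only in full text;
dictionary matching yields false positives that only manual scoring can
quantify; the shipped dictionaries are small illustrative defaults, not
the curated instruments a production analysis needs; the co-expression
statistic is a simplified single-matrix proxy for a multi-tissue
consensus method; and drug-target joins inherit the coverage and biases
of their input tables.
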