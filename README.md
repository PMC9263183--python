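# litpath

Dictionary-based literature mining of pathway associations with
Alzheimer's disease (AD) and dementia.

Systematic reviews of AD mechanisms usually cover a handful of pathways;
the dementia literature as a whole touches hundreds. `litpath` implements
a reusable pipeline for quantifying, across a publication corpus, how
strongly each biological pathway is associated with AD/dementia, what kind
of evidence drives each association, and how the top-ranked pathways
relate to each other through shared genes, co-expression and drug targets.
It is aimed at researchers who want to place their pathway of interest in
the context of the wider dementia literature, and at methodologists who
want a fully testable, download-free re-implementation of this style of
text-mining analysis.

## What it computes

Given a corpus of publication records (JSON-lines: title, abstract, year,
keywords, journal, DOI) and four curated dictionary families (pathway
terms, dementia classes, evidence types, negative/exclusion phrases):

1. **Filter cascade** — keep records with an abstract mentioning
   *alzheimer*/*dementia*; drop duplicates, negative findings, abstracts
   where dementia is only an exclusion criterion, and out-of-bounds
   lengths; clear oversized keyword lists. Every stage is logged.
2. **Annotation** — per record: a pathway association level per dictionary
   (*full* if enough full-class terms hit, else *partial*/*none*); a
   dementia class (AD / dementia / related / unrelated) from the relative
   proportions of the four class vocabularies; an evidence label per axis
   (genetic vs model, animal vs human, in vitro vs in vivo; reviews
   preempt all axes).
3. **Ranking** — pathways ranked by distinct-study counts (rank 1 = most
   studied, average ranks on ties, so that Σrank = n(n+1)/2), overall, per
   dementia stratum, per journal-impact stratum and per year since 1990;
   strata compared with tie-corrected Spearman ρ; yearly rank trajectories
   hierarchically clustered (1 − Spearman distance, average linkage).
4. **Networks** — for the top-k literature-ranked pathways: a gene-overlap
   network (one-sided Fisher exact test per pair on a 2×2 table over the
   gene universe, Benjamini–Hochberg q < 0.05, edge weight −log₁₀ q) and a
   co-expression network (PCxN-style: correlation between pathway summary
   statistics — the mean of gene-wise z-scores — with the overlap between
   two pathways partialled out via the first-order partial correlation
   r_xy·z = (r_xy − r_xz r_yz)/√((1−r_xz²)(1−r_yz²)), t-test on n−3 df).
   The same Fisher machinery scores enrichment of external AD gene lists,
   and a Wilcoxon rank-sum test compares literature ranks of enriched vs
   non-enriched pathways.
5. **Drug targeting** — trial intervention names resolved through a
   synonym table (blocklisting non-specific names), joined with curated
   indications (symptomatic vs disease-modifying) and gene targets, and
   counted as distinct drugs per pathway per class.

A synthetic-data module generates corpora, gene sets, expression matrices
and drug tables with exact ground truth, so the full pipeline is testable
without downloading anything.

## Worked example

```python
from litpath import (annotate_corpus, attach_impact, compare_ranks,
                     default_lexicons, filter_corpus, rank_pathways)
from litpath.synth import CorpusConfig, gen_corpus, impact_table_from_config

lexicons = default_lexicons()
cfg = CorpusConfig(n=3000)                      # synthetic study conditions
records, truth = gen_corpus(cfg, seed=2)
survivors, report = filter_corpus(records, lexicons.negative)
survivors = attach_impact(survivors, impact_table_from_config(cfg))
result = annotate_corpus(survivors, lexicons)

all_ranks = rank_pathways(result.associations)
print(all_ranks.head(3).to_string(index=False))
for stratum in ("ad", "impact:5"):
    rho = compare_ranks(all_ranks, rank_pathways(result.associations, stratum)).rho
    print(f"Spearman(all, {stratum}) = {rho:.3f}")
```

prints

```
  pathway_id  study_count  rank
R-HSA-168256          426   1.0
    hsa01100          401   2.0
    hsa04210          314   3.0
Spearman(all, ad) = 1.000
Spearman(all, impact:5) = 1.000
```

The study counts recover the planted mention rates (0.16/0.13/0.11 of
2,797 surviving records), and the rank order is unchanged when restricted
to AD-labeled records or high-impact journals — the planted rates are
stratum-independent, so ρ near 1 is the expected behavior.

The `examples/` directory has one short script per capability (filtering
and annotation, ranking and stratification, overlap networks,
co-expression, drug targeting). A thin CLI mirrors the library:
`litpath simulate|filter|annotate|rank|network|coexpress|drugs`.

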