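"""Dictionary annotation of filtered records.

For each record the annotators produce:

* a per-pathway association level (none / partial / full) from the pathway
  lexicons — *full* when enough full-class terms are matched, *partial*
  when only partial-class terms hit;
* a dementia class label (AD / dementia / related / unrelated) from the
  relative proportions of the four dementia term classes, with suggestive
  terms rescuing borderline abstracts from the unrelated class and
  uncertain AD-vs-related abstracts labeled "dementia";
* an evidence label per axis (side_a / side_b / both / neither / review),
  with review terms preempting every axis.

All annotators are pure functions of (record, lexicons, config).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .config import DEFAULT_CONFIG, PipelineConfig
from .corpus import PublicationRecord
from .lexicons import (
    DEMENTIA_CLASSES,
    DementiaLexicon,
    EvidenceLexicon,
    LexiconSet,
    PathwayLexicon,
)
from .text import PhraseMatcher, match_terms, normalize_phrase, normalize_text

__all__ = [
    "normalize_text",
    "match_terms",
    "PathwayAssociation",
    "DementiaAnnotation",
    "EvidenceAnnotation",
    "pathway_association",
    "classify_dementia",
    "classify_evidence",
    "classify_evidence_all",
    "benchmark_evidence",
    "annotate_corpus",
    "AnnotationResult",
]


def _record_token_fields(
    record: PublicationRecord, fields: Sequence[str]
) -> list[list[str]]:
    """Tokenize each searched field separately (phrases never span fields)."""
    return [normalize_text(text) for text in record.field_texts(fields)]


def _match_fields(token_fields, matcher: PhraseMatcher):
    from collections import Counter

    counts: Counter = Counter()
    for tokens in token_fields:
        counts.update(matcher.match(tokens))
    return counts


# ---------------------------------------------------------------------------
# Pathway association
# ---------------------------------------------------------------------------

@dataclass
class PathwayAssociation:
    record_id: str
    pathway_id: str
    level: str  # none | partial | full
    matched_terms: list[str]
    match_count: int


def pathway_association(
    record: PublicationRecord,
    lexicon: PathwayLexicon,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> PathwayAssociation:
    """Associate a record with one pathway.

    Level is *full* when at least ``config.full_min`` distinct full-class
    terms match, else *partial* when any partial-class term matches, else
    *none*.  Full and partial terms are matched jointly longest-first so a
    token run consumed by a longer phrase is not re-counted.
    """
    token_fields = _record_token_fields(record, config.search_fields)
    matcher = PhraseMatcher(lexicon.all_terms)
    counts = _match_fields(token_fields, matcher)

    full_norm = {normalize_phrase(t) for t in lexicon.full_terms}
    distinct_full = sum(1 for tup in counts if tup in full_norm)
    n_partial_hits = sum(c for tup, c in counts.items() if tup not in full_norm)

    if distinct_full >= config.full_min:
        level = "full"
    elif n_partial_hits >= 1:
        level = "partial"
    else:
        level = "none"
    return PathwayAssociation(
        record_id=record.record_id,
        pathway_id=lexicon.pathway_id,
        level=level,
        matched_terms=sorted(" ".join(tup) for tup in counts),
        match_count=sum(counts.values()),
    )


# ---------------------------------------------------------------------------
# Dementia stratification
# ---------------------------------------------------------------------------

@dataclass
class DementiaAnnotation:
    record_id: str
    class_counts: dict[str, int]
    suggestive_count: int
    label: str  # AD | dementia | related | unrelated
    ad_word_score: int


def classify_dementia(
    record: PublicationRecord,
    lexicon: DementiaLexicon,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> DementiaAnnotation:
    """Assign a record to one of the four dementia classes.

    Rule, applied to the per-class hit counts:

    a. unrelated-class hits exceed ``unrelated_frac`` of all class hits and
       no suggestive term is present → ``unrelated``;
    b. fewer than ``min_hits`` total class hits → ``dementia`` (too little
       evidence for a specific call);
    c. AD-specific strictly dominates related → ``AD``; related strictly
       dominates AD-specific → ``related``;
    d. AD/related tie → ``dementia``.
    """
    token_fields = _record_token_fields(record, config.search_fields)

    phrase_class: dict[tuple[str, ...], str] = {}
    for cls, terms in lexicon.class_terms().items():
        for term in terms:
            phrase_class[normalize_phrase(term)] = cls
    matcher = PhraseMatcher(phrase_class.keys())
    counts = _match_fields(token_fields, matcher)

    class_counts = {c: 0 for c in DEMENTIA_CLASSES}
    for tup, c in counts.items():
        class_counts[phrase_class[tup]] += c

    sugg_matcher = PhraseMatcher(lexicon.suggestive_terms)
    suggestive = sum(_match_fields(token_fields, sugg_matcher).values())

    total = sum(class_counts.values())
    ad = class_counts["ad_specific"]
    related = class_counts["related"]

    if (
        total > 0
        and class_counts["unrelated"] / total > config.unrelated_frac
        and suggestive == 0
    ):
        label = "unrelated"
    elif total < config.min_hits:
        label = "dementia"
    elif ad > related:
        label = "AD"
    elif related > ad:
        label = "related"
    else:
        label = "dementia"

    return DementiaAnnotation(
        record_id=record.record_id,
        class_counts=class_counts,
        suggestive_count=suggestive,
        label=label,
        ad_word_score=ad,
    )


# ---------------------------------------------------------------------------
# Evidence classification
# ---------------------------------------------------------------------------

@dataclass
class EvidenceAnnotation:
    record_id: str
    axis: str
    label: str  # side_a | side_b | both | neither | review


def classify_evidence(
    record: PublicationRecord,
    lexicon: EvidenceLexicon,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> EvidenceAnnotation:
    """Assign a record to one side of an evidence axis.

    Review terms preempt the axis entirely (reviews are not original
    research).  A side wins when it reaches ``side_min`` hits and the
    opposing side has none; hits on both sides → ``both``; none → ``neither``.
    """
    token_fields = _record_token_fields(record, config.search_fields)

    review_hits = sum(
        _match_fields(token_fields, PhraseMatcher(lexicon.review_terms)).values()
    )
    if review_hits:
        label = "review"
    else:
        a = sum(
            _match_fields(token_fields, PhraseMatcher(lexicon.side_a_terms)).values()
        )
        b = sum(
            _match_fields(token_fields, PhraseMatcher(lexicon.side_b_terms)).values()
        )
        if a >= config.side_min and b == 0:
            label = "side_a"
        elif b >= config.side_min and a == 0:
            label = "side_b"
        elif a >= 1 and b >= 1:
            label = "both"
        else:
            label = "neither"
    return EvidenceAnnotation(record.record_id, lexicon.axis, label)


def classify_evidence_all(
    record: PublicationRecord,
    lexicons: dict[str, EvidenceLexicon],
    config: PipelineConfig = DEFAULT_CONFIG,
) -> dict[str, EvidenceAnnotation]:
    return {
        axis: classify_evidence(record, lx, config) for axis, lx in lexicons.items()
    }


@dataclass
class BenchmarkResult:
    axis: str
    confusion: pd.DataFrame  # true labels x predicted labels
    precision: dict[str, float | None]
    recall: dict[str, float | None]


def benchmark_evidence(
    records: Sequence[PublicationRecord],
    true_labels: Sequence[str],
    lexicon: EvidenceLexicon,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> BenchmarkResult:
    """Benchmark one evidence axis on records with known labels.

    Mirrors dictionary benchmarking against topic-specific journals: records
    sourced from a journal dedicated to one evidence type carry that type as
    their true label.  Precision/recall are reported per label and left as
    ``None`` (undefined), not zero, when a denominator is empty.
    """
    if len(records) != len(true_labels):
        raise ValueError("records and true_labels must align")
    preds = [classify_evidence(rec, lexicon, config).label for rec in records]
    labels = sorted(set(true_labels) | set(preds))
    confusion = pd.DataFrame(0, index=labels, columns=labels)
    for truth, pred in zip(true_labels, preds):
        confusion.loc[truth, pred] += 1
    precision: dict[str, float | None] = {}
    recall: dict[str, float | None] = {}
    for lab in labels:
        pred_n = int(confusion[lab].sum())
        true_n = int(confusion.loc[lab].sum())
        tp = int(confusion.loc[lab, lab])
        precision[lab] = tp / pred_n if pred_n else None
        recall[lab] = tp / true_n if true_n else None
    return BenchmarkResult(lexicon.axis, confusion, precision, recall)


# ---------------------------------------------------------------------------
# Whole-corpus annotation
# ---------------------------------------------------------------------------

@dataclass
class AnnotationResult:
    """Corpus-level annotation output.

    ``associations`` holds one row per (record, pathway) pair with a
    non-none association level, joined with the record's dementia and
    evidence labels; ``records`` holds one row per record.
    """

    associations: pd.DataFrame
    records: pd.DataFrame
    config: PipelineConfig

    def to_tsv(self, path) -> None:
        self.associations.to_csv(path, sep="\t", index=False)


class _CorpusAnnotator:
    """Prebuilt matchers for annotating many records with one lexicon set."""

    def __init__(self, lexicons: LexiconSet, config: PipelineConfig):
        self.config = config
        self.lexicons = lexicons
        self.pathway_matchers = {}
        for pid, lx in lexicons.pathways.items():
            self.pathway_matchers[pid] = (
                PhraseMatcher(lx.all_terms),
                {normalize_phrase(t) for t in lx.full_terms},
            )
        self.phrase_class = {}
        for cls, terms in lexicons.dementia.class_terms().items():
            for term in terms:
                self.phrase_class[normalize_phrase(term)] = cls
        self.dementia_matcher = PhraseMatcher(self.phrase_class.keys())
        self.suggestive_matcher = PhraseMatcher(lexicons.dementia.suggestive_terms)
        self.evidence_matchers = {
            axis: (
                PhraseMatcher(lx.review_terms),
                PhraseMatcher(lx.side_a_terms),
                PhraseMatcher(lx.side_b_terms),
            )
            for axis, lx in lexicons.evidence.items()
        }

    def dementia(self, token_fields) -> tuple[str, int]:
        cfg = self.config
        counts = _match_fields(token_fields, self.dementia_matcher)
        class_counts = {c: 0 for c in DEMENTIA_CLASSES}
        for tup, c in counts.items():
            class_counts[self.phrase_class[tup]] += c
        suggestive = sum(_match_fields(token_fields, self.suggestive_matcher).values())
        total = sum(class_counts.values())
        ad = class_counts["ad_specific"]
        related = class_counts["related"]
        if (
            total > 0
            and class_counts["unrelated"] / total > cfg.unrelated_frac
            and suggestive == 0
        ):
            label = "unrelated"
        elif total < cfg.min_hits:
            label = "dementia"
        elif ad > related:
            label = "AD"
        elif related > ad:
            label = "related"
        else:
            label = "dementia"
        return label, ad

    def evidence(self, token_fields, axis: str) -> str:
        cfg = self.config
        review_m, a_m, b_m = self.evidence_matchers[axis]
        if sum(_match_fields(token_fields, review_m).values()):
            return "review"
        a = sum(_match_fields(token_fields, a_m).values())
        b = sum(_match_fields(token_fields, b_m).values())
        if a >= cfg.side_min and b == 0:
            return "side_a"
        if b >= cfg.side_min and a == 0:
            return "side_b"
        if a >= 1 and b >= 1:
            return "both"
        return "neither"

    def pathway(self, token_fields, pid: str) -> tuple[str, int]:
        matcher, full_norm = self.pathway_matchers[pid]
        counts = _match_fields(token_fields, matcher)
        distinct_full = sum(1 for tup in counts if tup in full_norm)
        n_partial = sum(c for tup, c in counts.items() if tup not in full_norm)
        if distinct_full >= self.config.full_min:
            level = "full"
        elif n_partial >= 1:
            level = "partial"
        else:
            level = "none"
        return level, sum(counts.values())


def annotate_corpus(
    records: Sequence[PublicationRecord],
    lexicons: LexiconSet,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> AnnotationResult:
    """Annotate a filtered corpus with all dictionary families."""
    rec_rows = []
    assoc_rows = []
    axes = sorted(lexicons.evidence)
    ann = _CorpusAnnotator(lexicons, config)
    for rec in records:
        token_fields = _record_token_fields(rec, config.search_fields)
        dem_label, ad_score = ann.dementia(token_fields)
        ev = {axis: ann.evidence(token_fields, axis) for axis in axes}
        rec_rows.append(
            {
                "record_id": rec.record_id,
                "dementia_label": dem_label,
                "ad_word_score": ad_score,
                **{f"ev_{axis}": ev[axis] for axis in axes},
                "year": rec.year,
                "journal": rec.journal,
                "impact": rec.impact,
            }
        )
        for pid in sorted(lexicons.pathways):
            level, match_count = ann.pathway(token_fields, pid)
            if level == "none":
                continue
            assoc_rows.append(
                {
                    "record_id": rec.record_id,
                    "pathway_id": pid,
                    "level": level,
                    "match_count": match_count,
                    "dementia_label": dem_label,
                    "ad_word_score": ad_score,
                    **{f"ev_{axis}": ev[axis] for axis in axes},
                    "year": rec.year,
                    "journal": rec.journal,
                    "impact": rec.impact,
                }
            )
    assoc_cols = [
        "record_id",
        "pathway_id",
        "level",
        "match_count",
        "dementia_label",
        "ad_word_score",
        *[f"ev_{axis}" for axis in axes],
        "year",
        "journal",
        "impact",
    ]
    associations = pd.DataFrame(assoc_rows, columns=assoc_cols)
    rec_cols = [c for c in assoc_cols if c not in ("pathway_id", "level", "match_count")]
    records_df = pd.DataFrame(rec_rows, columns=rec_cols)
    return AnnotationResult(associations, records_df, config)
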