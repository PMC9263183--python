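"""Publication records: reading, the filter cascade, impact factors, sampling.

The corpus is a JSON-lines file, one publication per line, in the style of
open academic graph dumps (id / title / abstract / year / keywords / venue /
doi).  Before any dictionary annotation the corpus is pushed through a fixed
seven-stage filter cascade:

1. keep only records with a non-empty abstract;
2. keep only records mentioning a disease term (default: "alzheimer" or
   "dementia") in title, abstract or keywords;
3. remove duplicates (DOI when present, else normalized title + year);
4. remove abstracts matching the negative-findings phrase list;
5. remove abstracts where the disease terms occur only inside
   exclusion-criterion phrases ("patients with dementia were excluded");
6. remove abstracts outside the configured length bounds;
7. clear (not remove) the keyword list of records with too many keywords.

Each stage logs its input and removal counts into a :class:`FilterReport`
whose arithmetic always balances.
"""

from __future__ import annotations

import json
import random
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .config import DEFAULT_CONFIG, PipelineConfig
from .lexicons import NegativeLexicon
from .text import PhraseMatcher, normalize_text

DEFAULT_FIELD_MAP = {
    "record_id": "id",
    "title": "title",
    "abstract": "abstract",
    "year": "year",
    "keywords": "keywords",
    "journal": "venue",
    "doi": "doi",
}


@dataclass
class PublicationRecord:
    """One title/abstract unit flowing through the pipeline."""

    record_id: str
    title: str = ""
    abstract: str = ""
    year: int | None = None
    keywords: list[str] = field(default_factory=list)
    journal: str = ""
    doi: str | None = None
    #: journal impact factor; None marks "impact unknown" and excludes the
    #: record from impact-stratified rankings only
    impact: float | None = None

    def field_texts(self, fields: Sequence[str]) -> list[str]:
        out = []
        for f in fields:
            if f == "keywords":
                out.extend(self.keywords)
            else:
                out.append(getattr(self, f))
        return out

    def to_json_obj(self, field_map: dict | None = None) -> dict:
        fm = field_map or DEFAULT_FIELD_MAP
        obj = {
            fm["record_id"]: self.record_id,
            fm["title"]: self.title,
            fm["abstract"]: self.abstract,
            fm["year"]: self.year,
            fm["keywords"]: list(self.keywords),
            fm["journal"]: self.journal,
        }
        if self.doi is not None:
            obj[fm["doi"]] = self.doi
        return obj


def record_from_json_obj(obj: dict, field_map: dict | None = None) -> PublicationRecord:
    """Build a record from one JSON object, mapping missing fields to empties."""
    fm = field_map or DEFAULT_FIELD_MAP
    rid = obj.get(fm["record_id"])
    if rid is None:
        raise ValueError("record is missing its id field")
    year = obj.get(fm["year"])
    year = int(year) if year is not None else None
    keywords = obj.get(fm["keywords"]) or []
    if not isinstance(keywords, list):
        keywords = [str(keywords)]
    doi = obj.get(fm["doi"])
    return PublicationRecord(
        record_id=str(rid),
        title=str(obj.get(fm["title"]) or ""),
        abstract=str(obj.get(fm["abstract"]) or ""),
        year=year,
        keywords=[str(k) for k in keywords],
        journal=str(obj.get(fm["journal"]) or ""),
        doi=str(doi) if doi else None,
    )


def read_corpus(
    path: str | Path, field_map: dict | None = None
) -> tuple[list[PublicationRecord], int]:
    """Read a JSON-lines corpus.

    Returns ``(records, n_malformed)``.  Malformed lines are counted and
    skipped with a warning, never silently dropped; an unreadable file is a
    fatal error.
    """
    records: list[PublicationRecord] = []
    malformed = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
                records.append(record_from_json_obj(obj, field_map))
            except (json.JSONDecodeError, ValueError, TypeError):
                malformed += 1
    if malformed:
        warnings.warn(f"{path}: skipped {malformed} malformed line(s)")
    return records, malformed


def write_corpus(
    records: Iterable[PublicationRecord],
    path: str | Path,
    field_map: dict | None = None,
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(rec.to_json_obj(field_map), sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# Filter cascade
# ---------------------------------------------------------------------------

@dataclass
class FilterStage:
    name: str
    records_in: int
    records_removed: int


@dataclass
class FilterReport:
    stages: list[FilterStage] = field(default_factory=list)
    n_keywords_cleared: int = 0

    @property
    def total_in(self) -> int:
        return self.stages[0].records_in if self.stages else 0

    @property
    def total_out(self) -> int:
        return self.total_in - sum(s.records_removed for s in self.stages)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.name, s.records_in, s.records_removed) for s in self.stages],
            columns=["stage", "records_in", "records_removed"],
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _normalized_title_key(title: str) -> str:
    return " ".join(normalize_text(title))


def _disease_hit(token: str, disease_terms: Sequence[str]) -> bool:
    # word-boundary prefix semantics: "dementias" and "alzheimer's" count
    return any(token.startswith(term) for term in disease_terms)


def filter_corpus(
    records: Sequence[PublicationRecord],
    negative: NegativeLexicon,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> tuple[list[PublicationRecord], FilterReport]:
    """Apply the seven-stage filter cascade.

    Returns the surviving records (keyword lists possibly cleared in stage 7)
    and a balanced per-stage :class:`FilterReport`.  Stages never add
    records, so the cascade is monotone non-increasing and idempotent.
    """
    report = FilterReport()
    current = list(records)

    def log(name: str, survivors: list[PublicationRecord]) -> list[PublicationRecord]:
        report.stages.append(
            FilterStage(name, len(current), len(current) - len(survivors))
        )
        return survivors

    # 1. abstract present
    current = log("has_abstract", [r for r in current if r.abstract.strip()])

    # 2. disease terms anywhere in the configured fields
    survivors = []
    for rec in current:
        tokens = [
            t
            for text in rec.field_texts(config.search_fields)
            for t in normalize_text(text)
        ]
        if any(_disease_hit(t, config.disease_terms) for t in tokens):
            survivors.append(rec)
    current = log("disease_terms", survivors)

    # 3. deduplicate (DOI, else normalized title + year); first wins
    seen: set = set()
    survivors = []
    for rec in current:
        key = (
            ("doi", rec.doi.strip().lower())
            if rec.doi
            else ("title", _normalized_title_key(rec.title), rec.year)
        )
        if key in seen:
            continue
        seen.add(key)
        survivors.append(rec)
    current = log("deduplicate", survivors)

    # 4. negative findings
    neg_matcher = PhraseMatcher(negative.negative_phrases)
    survivors = []
    for rec in current:
        hit = any(
            neg_matcher.match(normalize_text(text))
            for text in rec.field_texts(config.search_fields)
        )
        if not hit:
            survivors.append(rec)
    current = log("negative_findings", survivors)

    # 5. dementia only as exclusion criterion: remove the record when every
    # disease-term token lies inside a matched exclusion phrase
    exc_matcher = PhraseMatcher(negative.exclusion_phrases)
    survivors = []
    for rec in current:
        free_hit = False  # a disease token outside any exclusion span
        for text in rec.field_texts(config.search_fields):
            tokens = normalize_text(text)
            spans = exc_matcher.match_spans(tokens)
            covered = set()
            for start, end, _ in spans:
                covered.update(range(start, end))
            for i, tok in enumerate(tokens):
                if i not in covered and _disease_hit(tok, config.disease_terms):
                    free_hit = True
                    break
            if free_hit:
                break
        if free_hit:
            survivors.append(rec)
    current = log("exclusion_criterion", survivors)

    # 6. abstract length bounds
    survivors = [
        r
        for r in current
        if config.abstract_min_chars <= len(r.abstract) <= config.abstract_max_chars
    ]
    current = log("length_bounds", survivors)

    # 7. clear oversized keyword lists (records retained)
    cleared = 0
    survivors = []
    for rec in current:
        if len(rec.keywords) > config.max_keywords:
            rec = replace(rec, keywords=[])
            cleared += 1
        survivors.append(rec)
    current = log("keyword_reset", survivors)
    report.n_keywords_cleared = cleared

    return current, report


# ---------------------------------------------------------------------------
# Impact factors
# ---------------------------------------------------------------------------

class ImpactTable:
    """Journal name → impact factor, with normalized case-insensitive lookup."""

    def __init__(self, mapping: dict[str, float]):
        self._table: dict[str, float] = {}
        for journal, impact in mapping.items():
            impact = float(impact)
            if impact < 0:
                raise ValueError(f"negative impact factor for {journal!r}")
            self._table[self._key(journal)] = impact

    @staticmethod
    def _key(journal: str) -> str:
        return " ".join(normalize_text(journal))

    def get(self, journal: str) -> float | None:
        return self._table.get(self._key(journal))

    def __len__(self) -> int:
        return len(self._table)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ImpactTable":
        mapping: dict[str, float] = {}
        with open(path, encoding="utf-8") as fh:
            for raw in fh:
                line = raw.rstrip("\n")
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                journal, impact = line.split("\t")
                mapping[journal] = float(impact)
        return cls(mapping)


def attach_impact(
    records: Sequence[PublicationRecord], impact: ImpactTable
) -> list[PublicationRecord]:
    """Annotate records with journal impact (None when the journal is unknown)."""
    return [replace(rec, impact=impact.get(rec.journal)) for rec in records]


# ---------------------------------------------------------------------------
# Manual-review sampling
# ---------------------------------------------------------------------------

@dataclass
class ReviewSample:
    records: list[PublicationRecord]
    requested: int
    undersized: bool


@dataclass
class ReviewScore:
    fraction: float
    n_positive: int
    n_scored: int


def sample_for_review(
    records: Sequence[PublicationRecord], n: int, seed: int
) -> ReviewSample:
    """Draw a reproducible random sample of a pathway's records for manual
    scoring.  If fewer than ``n`` records exist, all are returned and the
    sample is flagged undersized."""
    if n < 1:
        raise ValueError("sample size must be >= 1")
    rng = random.Random(seed)
    pool = list(records)
    if len(pool) <= n:
        return ReviewSample(pool, n, undersized=len(pool) < n)
    return ReviewSample(rng.sample(pool, n), n, undersized=False)


def aggregate_review(annotations: Sequence[bool]) -> ReviewScore:
    """Aggregate human yes/no annotations into the fraction positive."""
    if not annotations:
        raise ValueError("no annotations to aggregate")
    n_pos = sum(bool(a) for a in annotations)
    return ReviewScore(n_pos / len(annotations), n_pos, len(annotations))
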