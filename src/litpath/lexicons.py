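"""Dictionary (lexicon) families driving all classification.

Four families are used by the pipeline:

* pathway lexicons — per-pathway term lists split into *full* terms (a hit
  is sufficient for a full association) and *partial* terms;
* the dementia lexicon — four disjoint term classes (AD-specific, general
  dementia, related dementias, unrelated dementias) plus suggestive terms
  used to rescue borderline abstracts from the unrelated class;
* evidence lexicons — per axis (genetic vs model, animal vs human,
  in vitro vs in vivo) two competing term sides plus shared review terms;
* the negative lexicon — negative-finding phrases and phrases marking
  dementia as an exclusion criterion.

All lexicons are data (TSV files), not code.  '#' lines are comments.
A small illustrative default set ships with the package; real analyses are
expected to supply curated dictionaries of their own.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

from .text import normalize_phrase

DEMENTIA_CLASSES = ("ad_specific", "dementia_general", "related", "unrelated")
EVIDENCE_AXES = ("genetic_vs_model", "animal_vs_human", "invitro_vs_invivo")


class LexiconError(ValueError):
    """Raised when a lexicon file violates a structural invariant."""


def _norm_set(terms: Iterable[str]) -> frozenset[tuple[str, ...]]:
    return frozenset(t for t in (normalize_phrase(x) for x in terms) if t)


@dataclass(frozen=True)
class PathwayLexicon:
    pathway_id: str
    name: str
    source: str  # KEGG | Reactome | custom
    full_terms: frozenset[str]
    partial_terms: frozenset[str]

    def __post_init__(self):
        if not self.full_terms:
            raise LexiconError(f"pathway {self.pathway_id!r} has no full terms")
        overlap = _norm_set(self.full_terms) & _norm_set(self.partial_terms)
        if overlap:
            shared = ", ".join(" ".join(t) for t in sorted(overlap))
            raise LexiconError(
                f"pathway {self.pathway_id!r}: terms listed as both full and "
                f"partial: {shared}"
            )

    @property
    def all_terms(self) -> frozenset[str]:
        return self.full_terms | self.partial_terms


@dataclass(frozen=True)
class DementiaLexicon:
    ad_specific: frozenset[str]
    dementia_general: frozenset[str]
    related: frozenset[str]
    unrelated: frozenset[str]
    suggestive_terms: frozenset[str]

    def __post_init__(self):
        norm = {c: _norm_set(getattr(self, c)) for c in DEMENTIA_CLASSES}
        for i, a in enumerate(DEMENTIA_CLASSES):
            for b in DEMENTIA_CLASSES[i + 1 :]:
                shared = norm[a] & norm[b]
                if shared:
                    terms = ", ".join(" ".join(t) for t in sorted(shared))
                    raise LexiconError(
                        f"dementia classes {a!r} and {b!r} share terms: {terms}"
                    )

    def class_terms(self) -> dict[str, frozenset[str]]:
        return {c: getattr(self, c) for c in DEMENTIA_CLASSES}


@dataclass(frozen=True)
class EvidenceLexicon:
    axis: str
    side_a: str  # human-readable side names, e.g. "genetic"
    side_b: str
    side_a_terms: frozenset[str]
    side_b_terms: frozenset[str]
    review_terms: frozenset[str]

    def __post_init__(self):
        shared = _norm_set(self.side_a_terms) & _norm_set(self.side_b_terms)
        if shared:
            terms = ", ".join(" ".join(t) for t in sorted(shared))
            raise LexiconError(
                f"evidence axis {self.axis!r}: sides share terms: {terms}"
            )


@dataclass(frozen=True)
class NegativeLexicon:
    negative_phrases: frozenset[str]
    exclusion_phrases: frozenset[str]

    def __post_init__(self):
        if not self.negative_phrases or not self.exclusion_phrases:
            raise LexiconError("negative lexicon requires phrases of both kinds")


@dataclass
class LexiconSet:
    """The full dictionary bundle consumed by the pipeline."""

    pathways: dict[str, PathwayLexicon]
    dementia: DementiaLexicon
    evidence: dict[str, EvidenceLexicon]
    negative: NegativeLexicon


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

_SIDE_NAMES = {
    "genetic_vs_model": ("genetic", "model"),
    "animal_vs_human": ("animal", "human"),
    "invitro_vs_invivo": ("in_vitro", "in_vivo"),
}


def _read_rows(path: str | Path, n_cols: int, kind: str):
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != n_cols:
                raise LexiconError(
                    f"{path}: line {lineno}: expected {n_cols} tab-separated "
                    f"columns for a {kind} lexicon, got {len(parts)}"
                )
            rows.append((lineno, [p.strip() for p in parts]))
    seen = set()
    unique = []
    dups = 0
    for lineno, parts in rows:
        key = tuple(parts)
        if key in seen:
            dups += 1
            continue
        seen.add(key)
        unique.append((lineno, parts))
    if dups:
        warnings.warn(f"{path}: {dups} duplicated row(s) collapsed")
    return unique


def load_lexicon(path: str | Path, kind: str):
    """Load a validated lexicon from a TSV file.

    ``kind`` is one of ``pathway`` (columns: pathway_id, name, source, term,
    match_class), ``dementia`` (class, term), ``evidence`` (axis, side,
    term) or ``negative`` (kind, phrase).  Pathway files return a dict of
    :class:`PathwayLexicon` keyed by pathway_id; evidence files return a
    dict of :class:`EvidenceLexicon` keyed by axis.
    """
    if kind == "pathway":
        rows = _read_rows(path, 5, kind)
        meta: dict[str, tuple[str, str]] = {}
        terms: dict[str, dict[str, set[str]]] = {}
        for lineno, (pid, name, source, term, mclass) in rows:
            if mclass not in ("full", "partial"):
                raise LexiconError(
                    f"{path}: line {lineno}: match_class must be full|partial"
                )
            if pid in meta and meta[pid] != (name, source):
                raise LexiconError(
                    f"{path}: line {lineno}: pathway {pid!r} redefined with a "
                    f"different name/source"
                )
            meta[pid] = (name, source)
            terms.setdefault(pid, {"full": set(), "partial": set()})[mclass].add(term)
        out = {}
        for pid, (name, source) in meta.items():
            out[pid] = PathwayLexicon(
                pathway_id=pid,
                name=name,
                source=source,
                full_terms=frozenset(terms[pid]["full"]),
                partial_terms=frozenset(terms[pid]["partial"]),
            )
        return out

    if kind == "dementia":
        rows = _read_rows(path, 2, kind)
        classes: dict[str, set[str]] = {c: set() for c in DEMENTIA_CLASSES}
        classes["suggestive"] = set()
        for lineno, (cls, term) in rows:
            if cls not in classes:
                raise LexiconError(
                    f"{path}: line {lineno}: unknown dementia class {cls!r}"
                )
            classes[cls].add(term)
        return DementiaLexicon(
            ad_specific=frozenset(classes["ad_specific"]),
            dementia_general=frozenset(classes["dementia_general"]),
            related=frozenset(classes["related"]),
            unrelated=frozenset(classes["unrelated"]),
            suggestive_terms=frozenset(classes["suggestive"]),
        )

    if kind == "evidence":
        rows = _read_rows(path, 3, kind)
        sides: dict[str, dict[str, set[str]]] = {}
        review: set[str] = set()
        for lineno, (axis, side, term) in rows:
            if side == "review":
                review.add(term)
                continue
            if axis not in EVIDENCE_AXES:
                raise LexiconError(
                    f"{path}: line {lineno}: unknown evidence axis {axis!r}"
                )
            if side not in ("side_a", "side_b"):
                raise LexiconError(
                    f"{path}: line {lineno}: side must be side_a|side_b|review"
                )
            sides.setdefault(axis, {"side_a": set(), "side_b": set()})[side].add(term)
        out = {}
        for axis, d in sides.items():
            a_name, b_name = _SIDE_NAMES[axis]
            out[axis] = EvidenceLexicon(
                axis=axis,
                side_a=a_name,
                side_b=b_name,
                side_a_terms=frozenset(d["side_a"]),
                side_b_terms=frozenset(d["side_b"]),
                review_terms=frozenset(review),
            )
        return out

    if kind == "negative":
        rows = _read_rows(path, 2, kind)
        neg: set[str] = set()
        exc: set[str] = set()
        for lineno, (rkind, phrase) in rows:
            if rkind == "negative":
                neg.add(phrase)
            elif rkind == "exclusion":
                exc.add(phrase)
            else:
                raise LexiconError(
                    f"{path}: line {lineno}: kind must be negative|exclusion"
                )
        return NegativeLexicon(frozenset(neg), frozenset(exc))

    raise ValueError(f"unknown lexicon kind {kind!r}")


def save_lexicon(lexicon, path: str | Path) -> None:
    """Write a lexicon back to its TSV dialect (inverse of load_lexicon)."""
    lines = []
    if isinstance(lexicon, dict) and lexicon and isinstance(
        next(iter(lexicon.values())), PathwayLexicon
    ):
        for pid in sorted(lexicon):
            lx = lexicon[pid]
            for term in sorted(lx.full_terms):
                lines.append(f"{pid}\t{lx.name}\t{lx.source}\t{term}\tfull")
            for term in sorted(lx.partial_terms):
                lines.append(f"{pid}\t{lx.name}\t{lx.source}\t{term}\tpartial")
    elif isinstance(lexicon, DementiaLexicon):
        for cls in DEMENTIA_CLASSES:
            for term in sorted(getattr(lexicon, cls)):
                lines.append(f"{cls}\t{term}")
        for term in sorted(lexicon.suggestive_terms):
            lines.append(f"suggestive\t{term}")
    elif isinstance(lexicon, dict) and lexicon and isinstance(
        next(iter(lexicon.values())), EvidenceLexicon
    ):
        review: set[str] = set()
        for axis in sorted(lexicon):
            lx = lexicon[axis]
            for term in sorted(lx.side_a_terms):
                lines.append(f"{axis}\tside_a\t{term}")
            for term in sorted(lx.side_b_terms):
                lines.append(f"{axis}\tside_b\t{term}")
            review |= lx.review_terms
        for term in sorted(review):
            lines.append(f"shared\treview\t{term}")
    elif isinstance(lexicon, NegativeLexicon):
        for phrase in sorted(lexicon.negative_phrases):
            lines.append(f"negative\t{phrase}")
        for phrase in sorted(lexicon.exclusion_phrases):
            lines.append(f"exclusion\t{phrase}")
    else:
        raise ValueError(f"cannot serialize lexicon of type {type(lexicon)!r}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def validate_collection(pathway_lexicons: dict[str, PathwayLexicon]):
    """Report terms shared by two or more pathway lexicons.

    Sharing is permitted — pathways legitimately share vocabulary — but is
    surfaced so that dictionary curators can iterate.  Returns a sorted list
    of ``(term, [pathway_ids])`` with ids sorted, deterministic for any
    input order.
    """
    if not pathway_lexicons:
        raise ValueError("at least one pathway lexicon is required")
    owners: dict[tuple[str, ...], set[str]] = {}
    surface: dict[tuple[str, ...], str] = {}
    for pid, lx in pathway_lexicons.items():
        for term in lx.all_terms:
            tup = normalize_phrase(term)
            owners.setdefault(tup, set()).add(pid)
            surface.setdefault(tup, term)
    report = [
        (surface[tup], sorted(pids))
        for tup, pids in owners.items()
        if len(pids) >= 2
    ]
    report.sort(key=lambda item: item[0])
    return report


# ---------------------------------------------------------------------------
# Shipped defaults
# ---------------------------------------------------------------------------

def _data_path(name: str) -> Path:
    return Path(str(resources.files("litpath") / "data")) / name


def load_lexicon_dir(directory: str | Path) -> LexiconSet:
    """Load a lexicon bundle from a directory.

    Expects ``pathways.tsv``, ``dementia.tsv``, ``evidence.tsv`` and
    ``negative.tsv`` in the TSV dialects of :func:`load_lexicon`.
    """
    d = Path(directory)
    return LexiconSet(
        pathways=load_lexicon(d / "pathways.tsv", "pathway"),
        dementia=load_lexicon(d / "dementia.tsv", "dementia"),
        evidence=load_lexicon(d / "evidence.tsv", "evidence"),
        negative=load_lexicon(d / "negative.tsv", "negative"),
    )


def default_lexicons() -> LexiconSet:
    """The small illustrative dictionary set shipped with the package."""
    return load_lexicon_dir(_data_path(""))
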