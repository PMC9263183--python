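"""Drug-trial interventions → canonical drugs → targeted pathways.

Trial intervention names are resolved against a synonym table (built, in
practice, from several drug databases), non-specific names ("calcium
channel blocker") are removed via a blocklist, and each resolved drug
carries a human-curated indication aim — *symptomatic* or
*disease-modifying* — plus a set of gene targets.  Pathways are then ranked
per indication class by the number of distinct drugs with at least one
target gene in the pathway's gene set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .networks import GeneSetCollection

INDICATION_CLASSES = ("symptomatic", "disease_modifying")


@dataclass(frozen=True)
class DrugRecord:
    canonical: str
    synonyms: frozenset[str]
    indication: str  # symptomatic | disease_modifying | excluded
    targets: frozenset[str]
    exclusion_reason: str | None = None

    def __post_init__(self):
        if self.canonical not in self.synonyms:
            object.__setattr__(self, "synonyms", self.synonyms | {self.canonical})
        if self.indication == "excluded" and not self.exclusion_reason:
            object.__setattr__(self, "exclusion_reason", "unspecified")


def _norm_name(name: str) -> str:
    return " ".join(name.lower().split())


# ---------------------------------------------------------------------------
# TSV inputs
# ---------------------------------------------------------------------------

def _read_tsv_pairs(path: str | Path) -> list[tuple[str, str]]:
    pairs = []
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            a, b = line.split("\t")
            pairs.append((a.strip(), b.strip()))
    return pairs


def load_synonyms(path: str | Path) -> dict[str, str]:
    """TSV (canonical, synonym) → normalized synonym → canonical map."""
    table: dict[str, str] = {}
    for canonical, synonym in _read_tsv_pairs(path):
        for name in (canonical, synonym):
            key = _norm_name(name)
            if key in table and table[key] != canonical:
                raise ValueError(
                    f"synonym {name!r} maps to both {table[key]!r} and {canonical!r}"
                )
            table[key] = canonical
    return table


def load_targets(path: str | Path) -> dict[str, frozenset[str]]:
    """TSV (canonical, gene) → canonical → target gene set."""
    out: dict[str, set[str]] = {}
    for canonical, gene in _read_tsv_pairs(path):
        out.setdefault(canonical, set()).add(gene)
    return {k: frozenset(v) for k, v in out.items()}


def load_indications(path: str | Path) -> dict[str, str]:
    """TSV (canonical, class) → canonical → indication class."""
    out: dict[str, str] = {}
    for canonical, cls in _read_tsv_pairs(path):
        if cls not in INDICATION_CLASSES + ("excluded",):
            raise ValueError(f"unknown indication class {cls!r} for {canonical!r}")
        out[canonical] = cls
    return out


def load_trials(path: str | Path) -> list[tuple[str, str]]:
    """TSV (trial_id, intervention_name) rows."""
    return _read_tsv_pairs(path)


def load_blocklist(path: str | Path) -> frozenset[str]:
    """One non-specific intervention name per line."""
    names = set()
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if line and not line.startswith("#"):
                names.add(_norm_name(line))
    return frozenset(names)


# ---------------------------------------------------------------------------
# Resolution
# ---------------------------------------------------------------------------

@dataclass
class ResolutionReport:
    """Every input name is accounted for: resolved + blocked + unresolved."""

    resolved: dict[str, str]  # input name -> canonical
    blocked: list[str]
    unresolved: list[str]
    n_input: int

    @property
    def canonicals(self) -> list[str]:
        return sorted(set(self.resolved.values()))


def resolve_drugs(
    intervention_names: Iterable[str],
    synonym_table: Mapping[str, str],
    blocklist: Iterable[str] = (),
) -> ResolutionReport:
    """Resolve trial intervention names to canonical drugs.

    Matching is case-insensitive on whitespace-normalized names.  Blocked
    (non-specific) names are removed; unknown names are reported, never
    silently dropped.
    """
    block = {_norm_name(b) for b in blocklist}
    resolved: dict[str, str] = {}
    blocked: list[str] = []
    unresolved: list[str] = []
    names = list(intervention_names)
    for name in names:
        key = _norm_name(name)
        if key in block:
            blocked.append(name)
        elif key in synonym_table:
            resolved[name] = synonym_table[key]
        else:
            unresolved.append(name)
    return ResolutionReport(resolved, blocked, unresolved, n_input=len(names))


def build_drug_records(
    resolution: ResolutionReport,
    targets: Mapping[str, frozenset[str]],
    indications: Mapping[str, str],
) -> list[DrugRecord]:
    """Join resolved drugs with curated indications and gene targets.

    Drugs without a curated indication are kept as ``excluded`` records
    with a reason, matching the rule that uncuratable drugs leave the
    analysis but stay accounted for.
    """
    syn_by_canonical: dict[str, set[str]] = {}
    for name, canonical in resolution.resolved.items():
        syn_by_canonical.setdefault(canonical, set()).add(name)
    records = []
    for canonical in sorted(syn_by_canonical):
        indication = indications.get(canonical)
        if indication is None:
            indication, reason = "excluded", "no curated indication"
        elif indication == "excluded":
            reason = "curated as excluded"
        else:
            reason = None
        records.append(
            DrugRecord(
                canonical=canonical,
                synonyms=frozenset(syn_by_canonical[canonical]),
                indication=indication,
                targets=targets.get(canonical, frozenset()),
                exclusion_reason=reason,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Pathway targeting
# ---------------------------------------------------------------------------

@dataclass
class TargetingResult:
    """Per-indication-class pathway targeting counts and ranks."""

    tables: dict[str, pd.DataFrame]  # class -> pathway_id/n_drugs/rank
    drugs_without_targets: list[str]
    shared_top: list[str]  # pathways top-ranked in both classes

    def table(self, indication: str) -> pd.DataFrame:
        return self.tables[indication]


def drug_pathway_targeting(
    drugs: Sequence[DrugRecord],
    gene_sets: GeneSetCollection,
    top_n: int = 10,
) -> TargetingResult:
    """Count, per indication class, the distinct drugs targeting each pathway.

    A drug with several target genes inside one pathway counts once for it;
    a drug targeting genes in several pathways counts once for each.  The
    result is invariant to drug input order.  Drugs with empty target sets
    are flagged and counted nowhere.
    """
    no_targets = sorted(
        d.canonical for d in drugs if d.indication in INDICATION_CLASSES and not d.targets
    )
    if no_targets:
        warnings.warn(f"drugs without targets: {no_targets}")
    tables = {}
    for cls in INDICATION_CLASSES:
        class_drugs = [d for d in drugs if d.indication == cls and d.targets]
        counts = {pid: 0 for pid in sorted(gene_sets.sets)}
        for drug in class_drugs:
            for pid in counts:
                if drug.targets & gene_sets[pid]:
                    counts[pid] += 1
        table = pd.DataFrame(
            {"pathway_id": list(counts), "n_drugs": list(counts.values())}
        )
        table["rank"] = table["n_drugs"].rank(ascending=False, method="average")
        table = table.sort_values(
            ["rank", "pathway_id"], kind="mergesort"
        ).reset_index(drop=True)
        tables[cls] = table
    shared = set.intersection(
        *[
            set(t[t["n_drugs"] > 0].head(top_n)["pathway_id"])
            for t in tables.values()
        ]
    ) if tables else set()
    return TargetingResult(
        tables=tables, drugs_without_targets=no_targets, shared_top=sorted(shared)
    )
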