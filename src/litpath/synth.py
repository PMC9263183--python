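"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate, at desk scale, the inputs the pipeline consumes in
a real analysis: a publication corpus in JSON-lines form, pathway gene sets
in GMT form, a gene × sample expression matrix, and drug/trial tables.

Abstracts are template-based token sequences, not natural language: each
record embeds the lexicon terms implied by its planted labels, separated by
decoy vocabulary that is screened at generation time against every loaded
lexicon.  Planted terms are additionally screened so that a term planted
for one dictionary family can never be matched by another family.  This
makes the expected classifier output an exact function of the truth file —
which free text would break — at the cost of all linguistic realism.

Every generator is a pure function of (config, seed): the same seed yields
byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG, PipelineConfig
from .corpus import PublicationRecord
from .lexicons import LexiconSet, default_lexicons
from .networks import GeneSetCollection
from .text import normalize_phrase

# Candidate decoy vocabulary; words colliding with any loaded lexicon token
# (or with a disease term) are removed at generation time.
_DECOY_CANDIDATES = (
    "analysis approach assay baseline biomarker channel cortex dataset "
    "density detection dynamics effect enzyme evaluation examination "
    "experiment factor fraction framework function gradient imaging "
    "intervention kinetics laboratory magnitude measurement mechanism "
    "membrane method modulation molecule network neuron observation "
    "parameter pattern peptide perfusate pilot population procedure "
    "profile protein protocol quantification ratio receptor region "
    "regulation relationship report resolution response result sample "
    "secretion sequence signal spectrum stimulation structure synthesis "
    "technique threshold tissue transport uptake validation velocity "
    "matrix cascade module circuit domain vector substrate reagent "
    "buffer gradient filtration absorbance luminescence microscopy "
    "fluorescence centrifugation titration calibration replicate"
).split()

#: default planted mention rates (full associations) for the shipped
#: pathway dictionaries whose terms are independent of the dementia classes
DEFAULT_PATHWAY_RATES: dict[str, float] = {
    "R-HSA-168256": 0.16,
    "hsa01100": 0.13,
    "hsa04210": 0.11,
    "hsa04725": 0.09,
    "hsa04730": 0.07,
    "hsa03050": 0.06,
    "custom-diabetes": 0.05,
    "hsa04062": 0.04,
    "hsa04140": 0.03,
    "hsa04721": 0.02,
}

#: journals sampled for synthetic records; None marks a journal absent from
#: the impact table (excluded from impact-stratified rankings)
DEFAULT_JOURNALS: tuple[tuple[str, float | None], ...] = (
    ("Journal of Synthetic Neurology", 2.1),
    ("Annals of Simulated Medicine", 3.4),
    ("Synthetic Brain Research", 4.8),
    ("Journal of Generated Neuroscience", 5.6),
    ("Simulated Aging Reports", 7.3),
    ("Synthetic Lancet Neurology", 11.2),
    ("Generated Nature Dementia", 16.5),
    ("Obscure Regional Bulletin", None),
)


def _contains(seq: tuple[str, ...], sub: tuple[str, ...]) -> bool:
    n, m = len(seq), len(sub)
    if m == 0 or m > n:
        return False
    return any(seq[i : i + m] == sub for i in range(n - m + 1))


def _lexicon_subsets(lexicons: LexiconSet) -> dict[tuple, frozenset]:
    """All separately-matched phrase sets, keyed so that cross-set
    containment can be forbidden while within-set nesting stays allowed."""
    subsets: dict[tuple, frozenset] = {}
    for pid, lx in lexicons.pathways.items():
        subsets[("pathway", pid)] = frozenset(
            normalize_phrase(t) for t in lx.all_terms
        )
    dem = lexicons.dementia
    subsets[("dementia", "classes")] = frozenset(
        normalize_phrase(t) for terms in dem.class_terms().values() for t in terms
    )
    subsets[("dementia", "suggestive")] = frozenset(
        normalize_phrase(t) for t in dem.suggestive_terms
    )
    review: set = set()
    for axis, lx in lexicons.evidence.items():
        subsets[("evidence", axis, "side_a")] = frozenset(
            normalize_phrase(t) for t in lx.side_a_terms
        )
        subsets[("evidence", axis, "side_b")] = frozenset(
            normalize_phrase(t) for t in lx.side_b_terms
        )
        review |= {normalize_phrase(t) for t in lx.review_terms}
    subsets[("evidence", "review")] = frozenset(review)
    subsets[("negative",)] = frozenset(
        normalize_phrase(t) for t in lexicons.negative.negative_phrases
    )
    subsets[("exclusion",)] = frozenset(
        normalize_phrase(t) for t in lexicons.negative.exclusion_phrases
    )
    return subsets


def _safe_phrases(
    own_key: tuple, subsets: dict[tuple, frozenset], candidates
) -> list[tuple[str, ...]]:
    """Phrases from ``candidates`` containing no phrase of any other subset."""
    others = [ps for key, ps in subsets.items() if key != own_key]
    safe = []
    for cand in sorted(candidates):
        tup = normalize_phrase(cand)
        if any(_contains(tup, other) for ps in others for other in ps):
            continue
        safe.append(tup)
    return safe


def _screen_decoys(lexicons: LexiconSet, config: PipelineConfig) -> list[str]:
    lex_tokens = {
        tok for ps in _lexicon_subsets(lexicons).values() for p in ps for tok in p
    }
    decoys = [
        w
        for w in _DECOY_CANDIDATES
        if w not in lex_tokens
        and not any(w.startswith(t) for t in config.disease_terms)
    ]
    if len(decoys) < 20:
        raise ValueError("too few decoy words survive lexicon screening")
    return decoys


# ---------------------------------------------------------------------------
# Corpus generator
# ---------------------------------------------------------------------------

@dataclass
class CorpusConfig:
    """Study conditions for the synthetic corpus.

    Defaults mimic a dementia-literature slice: years 1990–2019, roughly
    two thirds of abstracts AD-specific, a twentieth reporting negative
    findings, pathway mention rates spanning an order of magnitude.
    """

    n: int = 1000
    pathway_rates: Mapping[str, float] | None = None
    dementia_mixture: Mapping[str, float] = field(
        default_factory=lambda: {
            "AD": 0.64,
            "dementia": 0.16,
            "related": 0.12,
            "unrelated": 0.08,
        }
    )
    evidence_mixture: Mapping[str, float] = field(
        default_factory=lambda: {
            "side_a": 0.25,
            "side_b": 0.30,
            "both": 0.10,
            "neither": 0.30,
            "review": 0.05,
        }
    )
    negative_fraction: float = 0.05
    exclusion_fraction: float = 0.02
    duplicate_fraction: float = 0.0
    year_range: tuple[int, int] = (1990, 2019)
    length_range: tuple[int, int] = (400, 1500)
    journals: tuple[tuple[str, float | None], ...] = DEFAULT_JOURNALS

    def validate(self) -> None:
        for name, mix in (
            ("dementia_mixture", self.dementia_mixture),
            ("evidence_mixture", self.evidence_mixture),
        ):
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {total})")
            if any(v < 0 for v in mix.values()):
                raise ValueError(f"{name} has negative weights")
        rates = self.pathway_rates or DEFAULT_PATHWAY_RATES
        if any(not (0.0 <= r <= 1.0) for r in rates.values()):
            raise ValueError("pathway rates must lie in [0, 1]")
        for frac in (self.negative_fraction, self.exclusion_fraction,
                     self.duplicate_fraction):
            if not (0.0 <= frac <= 1.0):
                raise ValueError("fractions must lie in [0, 1]")


@dataclass
class SyntheticTruth:
    """Ground truth serialized alongside every generated corpus."""

    records: dict[str, dict]
    config: dict

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"config": self.config, "records": self.records},
                       sort_keys=True, indent=1),
            encoding="utf-8",
        )


def _surface(tup: tuple[str, ...]) -> str:
    return " ".join(tup)


def gen_corpus(
    config: CorpusConfig | None = None,
    seed: int = 0,
    lexicons: LexiconSet | None = None,
) -> tuple[list[PublicationRecord], SyntheticTruth]:
    """Generate a synthetic publication corpus with exact ground truth.

    Each record embeds the lexicon terms implied by its planted dementia
    class, evidence labels and pathway mentions, padded with screened decoy
    vocabulary to the sampled abstract length.  Records flagged negative or
    exclusion-only are constructed to be removed by the corresponding
    filter stage.
    """
    config = config or CorpusConfig()
    config.validate()
    lexicons = lexicons or default_lexicons()
    pipeline_cfg = DEFAULT_CONFIG
    rng = np.random.default_rng(seed)

    subsets = _lexicon_subsets(lexicons)
    decoys = _screen_decoys(lexicons, pipeline_cfg)
    rates = dict(config.pathway_rates or DEFAULT_PATHWAY_RATES)

    # safe planted-term pools
    dem = lexicons.dementia
    class_pool = {
        cls: _safe_phrases(("dementia", "classes"), subsets, terms)
        for cls, terms in dem.class_terms().items()
    }
    for cls, pool in class_pool.items():
        if len(pool) < 3:
            raise ValueError(f"dementia class {cls!r} has too few safe terms")
    pathway_pool = {}
    for pid in rates:
        lx = lexicons.pathways[pid]
        full_safe = _safe_phrases(("pathway", pid), subsets, lx.full_terms)
        if not full_safe:
            raise ValueError(
                f"pathway {pid!r} has no full terms safe for planting "
                f"(terms collide with another dictionary family)"
            )
        partial_safe = _safe_phrases(("pathway", pid), subsets, lx.partial_terms)
        pathway_pool[pid] = (full_safe, partial_safe)
    axes = sorted(lexicons.evidence)
    side_pool = {
        (axis, side): _safe_phrases(("evidence", axis, side), subsets,
                                    getattr(lexicons.evidence[axis], f"{side}_terms"))
        for axis in axes
        for side in ("side_a", "side_b")
    }
    review_pool = _safe_phrases(
        ("evidence", "review"), subsets,
        {t for lx in lexicons.evidence.values() for t in lx.review_terms},
    )
    # negative/exclusion-planted records are removed by their filter stage
    # before annotation, so these pools need no cross-family screening; an
    # exclusion phrase must only survive the (earlier) negative stage and
    # carry a disease token.
    negative_pool = sorted(
        normalize_phrase(t) for t in lexicons.negative.negative_phrases
    )
    neg_set = subsets[("negative",)]
    exclusion_pool = [
        p
        for p in sorted(
            normalize_phrase(t) for t in lexicons.negative.exclusion_phrases
        )
        if not any(_contains(p, neg) for neg in neg_set)
        and any(tok.startswith(t) for tok in p for t in pipeline_cfg.disease_terms)
    ]
    for name, pool in (
        ("review", review_pool),
        ("negative", negative_pool),
        ("exclusion", exclusion_pool),
    ):
        if not pool:
            raise ValueError(f"no safe {name} phrases available for planting")

    def pick(pool, k):
        idx = rng.choice(len(pool), size=min(k, len(pool)), replace=False)
        return [pool[i] for i in sorted(idx)]

    dem_classes = list(config.dementia_mixture)
    dem_probs = np.array([config.dementia_mixture[c] for c in dem_classes])
    ev_labels = [l for l in config.evidence_mixture if l != "review"]
    ev_probs = np.array([config.evidence_mixture[l] for l in ev_labels])
    ev_probs = ev_probs / ev_probs.sum() if ev_probs.sum() > 0 else ev_probs
    review_frac = config.evidence_mixture.get("review", 0.0)

    records: list[PublicationRecord] = []
    truth_records: dict[str, dict] = {}
    journal_idx = rng.integers(0, len(config.journals), size=config.n)

    for i in range(config.n):
        rid = f"S{i:06d}"
        year = int(rng.integers(config.year_range[0], config.year_range[1] + 1))
        journal, impact = config.journals[journal_idx[i]]
        is_negative = bool(rng.random() < config.negative_fraction)
        is_exclusion = (not is_negative) and bool(
            rng.random() < config.exclusion_fraction
        )

        items: list[tuple[str, ...]] = []
        truth: dict = {
            "year": year,
            "journal": journal,
            "impact": impact,
            "negative": is_negative,
            "exclusion_only": is_exclusion,
            "pathways": {},
            "dementia_class": None,
            "evidence": {},
        }

        if is_exclusion:
            # the only disease mention sits inside an exclusion phrase
            items.append(exclusion_pool[int(rng.integers(len(exclusion_pool)))])
        else:
            # disease anchor guaranteeing the disease-term filter passes
            items.append(("dementia",))
            dem_class = dem_classes[int(rng.choice(len(dem_classes), p=dem_probs))]
            truth["dementia_class"] = dem_class
            if dem_class == "AD":
                items.extend(pick(class_pool["ad_specific"], int(rng.integers(2, 4))))
            elif dem_class == "related":
                items.extend(pick(class_pool["related"], int(rng.integers(2, 4))))
            elif dem_class == "unrelated":
                items.extend(pick(class_pool["unrelated"], 3))
            else:  # "dementia": generic terms only, AD/related both absent
                items.extend(pick(class_pool["dementia_general"], int(rng.integers(1, 3))))

            is_review = bool(rng.random() < review_frac)
            if is_review:
                items.append(review_pool[int(rng.integers(len(review_pool)))])
                truth["evidence"] = {axis: "review" for axis in axes}
            else:
                for axis in axes:
                    label = ev_labels[int(rng.choice(len(ev_labels), p=ev_probs))]
                    truth["evidence"][axis] = label
                    if label in ("side_a", "side_b"):
                        items.extend(pick(side_pool[(axis, label)],
                                          int(rng.integers(1, 3))))
                    elif label == "both":
                        items.extend(pick(side_pool[(axis, "side_a")], 1))
                        items.extend(pick(side_pool[(axis, "side_b")], 1))

            for pid in sorted(rates):
                if rng.random() < rates[pid]:
                    full_safe, _ = pathway_pool[pid]
                    items.extend(pick(full_safe, 1))
                    truth["pathways"][pid] = "full"

            if is_negative:
                items.append(negative_pool[int(rng.integers(len(negative_pool)))])

        # assemble: shuffle planted items, separate with decoys, pad to length
        order = rng.permutation(len(items))
        tokens: list[str] = []
        for j in order:
            tokens.extend(items[j])
            tokens.append(decoys[int(rng.integers(len(decoys)))])
        target_len = int(rng.integers(config.length_range[0],
                                      config.length_range[1] + 1))
        while sum(len(t) + 1 for t in tokens) < target_len:
            tokens.append(decoys[int(rng.integers(len(decoys)))])
        abstract = " ".join(tokens).capitalize() + "."

        title_words = [decoys[int(rng.integers(len(decoys)))]
                       for _ in range(int(rng.integers(4, 9)))]
        keywords = [decoys[int(rng.integers(len(decoys)))]
                    for _ in range(int(rng.integers(3, 6)))]
        rec = PublicationRecord(
            record_id=rid,
            title=" ".join(title_words).capitalize(),
            abstract=abstract,
            year=year,
            keywords=keywords,
            journal=journal,
            doi=f"10.5555/synth.{i:06d}",
            impact=impact,
        )
        records.append(rec)
        truth_records[rid] = truth

    # optional exact duplicates (same DOI, new id) for the dedup stage
    if config.duplicate_fraction > 0 and records:
        n_dup = int(round(config.duplicate_fraction * config.n))
        dup_sources = rng.integers(0, len(records), size=n_dup)
        for j, src in enumerate(dup_sources):
            base = records[int(src)]
            rid = f"D{j:06d}"
            rec = PublicationRecord(
                record_id=rid,
                title=base.title,
                abstract=base.abstract,
                year=base.year,
                keywords=list(base.keywords),
                journal=base.journal,
                doi=base.doi,
                impact=base.impact,
            )
            records.append(rec)
            truth_records[rid] = {
                **truth_records[base.record_id],
                "duplicate_of": base.record_id,
            }

    cfg_echo = asdict(config)
    cfg_echo["pathway_rates"] = dict(config.pathway_rates or DEFAULT_PATHWAY_RATES)
    cfg_echo["seed"] = seed
    return records, SyntheticTruth(records=truth_records, config=cfg_echo)


def impact_table_from_config(config: CorpusConfig):
    """The impact table matching a synthetic corpus' journal roster."""
    from .corpus import ImpactTable

    return ImpactTable(
        {name: imp for name, imp in config.journals if imp is not None}
    )


# ---------------------------------------------------------------------------
# Filter-cascade fixture
# ---------------------------------------------------------------------------

def filter_cascade_fixture() -> tuple[list[PublicationRecord], list[str]]:
    """Twelve handcrafted records, one violating each filter stage.

    Returns (records, expected surviving record ids).  Five records survive:
    four clean ones plus one whose 35-entry keyword list is cleared.
    """
    filler = ("measurement of baseline parameters across the sample followed "
              "standard laboratory procedure with replicate calibration and "
              "careful documentation of the protocol at every stage of the "
              "experiment to ensure a stable analysis framework ")

    def abstract(core: str) -> str:
        text = core + " " + filler
        while len(text) < 300:
            text += filler
        return text[:1200]

    good = abstract("We studied dementia progression and memory decline.")
    records = [
        PublicationRecord("F01", "A study", good, 2001, ["alpha"], "Journal A",
                          doi="10.1/a"),
        PublicationRecord("F02", "Keyword flood", good, 2002,
                          [f"kw{i}" for i in range(35)], "Journal B",
                          doi="10.1/b"),
        PublicationRecord("F03", "Original", good, 2003, ["beta"], "Journal C",
                          doi="10.1/c"),
        PublicationRecord("F04", "Duplicate", good, 2003, ["beta"], "Journal C",
                          doi="10.1/c"),  # removed: duplicate DOI of F03
        PublicationRecord("F05", "Another study", abstract(
            "Alzheimer pathology was assessed with imaging."), 2004, [],
            "Journal D", doi="10.1/d"),
        PublicationRecord("F06", "Fifth survivor", abstract(
            "Dementia incidence was tracked in the cohort."), 2005, [],
            "Journal E", doi="10.1/e"),
        PublicationRecord("F07", "No abstract", "", 2006, [], "Journal F",
                          doi="10.1/f"),  # removed: stage 1
        PublicationRecord("F08", "Cardiology only", abstract(
            "We measured cardiac output in athletes."), 2007, [], "Journal G",
            doi="10.1/g"),  # removed: stage 2, no disease term
        PublicationRecord("F09", "Negative finding", abstract(
            "There was no significant association between the marker and "
            "dementia."), 2008, [], "Journal H",
            doi="10.1/h"),  # removed: stage 4
        PublicationRecord("F10", "Exclusion criterion", abstract(
            "Patients with dementia were excluded from this cardiology "
            "cohort."), 2009, [], "Journal I",
            doi="10.1/i"),  # removed: stage 5
        PublicationRecord("F11", "Too short",
                          "Dementia was mentioned briefly.", 2010, [],
                          "Journal J", doi="10.1/j"),  # removed: stage 6
        PublicationRecord("F12", "Too long", ("dementia " + filler * 40)[:5000],
                          2011, [], "Journal K",
                          doi="10.1/k"),  # removed: stage 6
    ]
    return records, ["F01", "F02", "F03", "F05", "F06"]


# ---------------------------------------------------------------------------
# Gene-set generator
# ---------------------------------------------------------------------------

@dataclass
class GeneSetConfig:
    n_pathways: int = 10
    universe_size: int = 2000
    size_range: tuple[int, int] = (20, 60)
    #: overlap blocks: dicts with n_members, size, overlap (shared fraction)
    blocks: tuple[dict, ...] = ()

    def validate(self) -> None:
        if self.size_range[0] < 10:
            raise ValueError("gene sets must have at least 10 genes")
        n_block = sum(b["n_members"] for b in self.blocks)
        if n_block > self.n_pathways:
            raise ValueError("blocks request more pathways than n_pathways")
        need = max(
            [self.size_range[1]] + [b["size"] for b in self.blocks], default=0
        )
        if need > self.universe_size:
            raise ValueError("universe too small for requested set sizes")


def gen_gene_sets(
    config: GeneSetConfig | None = None, seed: int = 0
) -> tuple[GeneSetCollection, dict]:
    """Generate gene sets with planted overlap blocks.

    Within a block every member shares a common core of ``overlap × size``
    genes; the remaining genes of each member are drawn independently from
    the universe, so cross-block overlap stays hypergeometric-random.
    """
    config = config or GeneSetConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    universe = [f"G{i:05d}" for i in range(config.universe_size)]
    uni_arr = np.array(universe)

    sets: dict[str, frozenset[str]] = {}
    truth_blocks = []
    idx = 0
    for block in config.blocks:
        size = block["size"]
        core_n = int(round(block["overlap"] * size))
        core = uni_arr[rng.choice(config.universe_size, size=core_n, replace=False)]
        members = []
        rest_pool = np.array(sorted(set(universe) - set(core)))
        for _ in range(block["n_members"]):
            pid = f"P{idx:03d}"
            idx += 1
            extra = rest_pool[
                rng.choice(len(rest_pool), size=size - core_n, replace=False)
            ]
            if block.get("disjoint"):
                # strictly disjoint allocation beyond the shared core
                rest_pool = np.array(sorted(set(rest_pool) - set(extra)))
            sets[pid] = frozenset(core) | frozenset(extra)
            members.append(pid)
        truth_blocks.append(
            {
                "members": members,
                "core": sorted(core.tolist()),
                "overlap": block["overlap"],
                "size": size,
            }
        )
    while idx < config.n_pathways:
        pid = f"P{idx:03d}"
        idx += 1
        size = int(rng.integers(config.size_range[0], config.size_range[1] + 1))
        genes = uni_arr[rng.choice(config.universe_size, size=size, replace=False)]
        sets[pid] = frozenset(genes)

    truth = {
        "blocks": truth_blocks,
        "sizes": {pid: len(g) for pid, g in sets.items()},
        "universe_size": config.universe_size,
        "seed": seed,
    }
    return GeneSetCollection(sets, universe=universe), truth


# ---------------------------------------------------------------------------
# Expression generator
# ---------------------------------------------------------------------------

def gen_expression(
    gene_sets: GeneSetCollection,
    latent_corr: pd.DataFrame,
    noise_sd: float = 1.0,
    n_samples: int = 100,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Generate a gene × sample matrix from latent pathway activities.

    ``latent_corr`` is the pathway-activity correlation matrix (rows and
    columns indexed by pathway id; must be positive semi-definite).  Each
    gene's value is the mean of the latent activities of the pathways that
    own it, plus independent Gaussian noise; genes shared between pathways
    therefore load on every owning pathway.
    """
    if n_samples < 10:
        raise ValueError("need at least 10 samples")
    pids = list(latent_corr.index)
    if list(latent_corr.columns) != pids:
        raise ValueError("latent_corr must be square with matching index/columns")
    cov = latent_corr.to_numpy(dtype=float)
    eig = np.linalg.eigvalsh((cov + cov.T) / 2)
    if eig.min() < -1e-8:
        raise ValueError("latent correlation matrix is not positive semi-definite")
    missing = [p for p in pids if p not in gene_sets.sets]
    if missing:
        raise ValueError(f"latent_corr references unknown pathways: {missing}")

    rng = np.random.default_rng(seed)
    latents = rng.multivariate_normal(
        np.zeros(len(pids)), cov, size=n_samples, method="svd"
    )  # samples x pathways

    genes = sorted(set().union(*(gene_sets[p] for p in pids)))
    owners = {
        g: [j for j, p in enumerate(pids) if g in gene_sets[p]] for g in genes
    }
    signal = np.stack(
        [latents[:, owners[g]].mean(axis=1) for g in genes]
    )  # genes x samples
    noise = rng.normal(0.0, noise_sd, size=signal.shape)
    expr = pd.DataFrame(
        signal + noise,
        index=genes,
        columns=[f"S{j:04d}" for j in range(n_samples)],
    )
    truth = {
        "pathways": pids,
        "latent_corr": latent_corr.to_numpy().tolist(),
        "noise_sd": noise_sd,
        "n_samples": n_samples,
        "seed": seed,
    }
    return expr, truth


# ---------------------------------------------------------------------------
# Drug-table generator
# ---------------------------------------------------------------------------

@dataclass
class DrugTableConfig:
    n_symptomatic: int = 4
    n_disease_modifying: int = 6
    pathways_per_drug: tuple[int, int] = (1, 3)
    synonyms_per_drug: tuple[int, int] = (1, 3)
    trials_per_drug: tuple[int, int] = (1, 3)
    n_blocked_names: int = 2
    n_unresolved_names: int = 1


@dataclass
class DrugTables:
    trials: list[tuple[str, str]]
    synonyms: list[tuple[str, str]]
    targets: list[tuple[str, str]]
    indications: list[tuple[str, str]]
    blocklist: list[str]

    def write(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for name, rows in (
            ("trials", self.trials),
            ("synonyms", self.synonyms),
            ("targets", self.targets),
            ("indications", self.indications),
        ):
            with open(d / f"{name}.tsv", "w", encoding="utf-8") as fh:
                for a, b in rows:
                    fh.write(f"{a}\t{b}\n")
        (d / "blocklist.txt").write_text(
            "\n".join(self.blocklist) + "\n", encoding="utf-8"
        )


_BLOCK_NAMES = ("calcium channel blocker", "vitamin supplement",
                "herbal extract", "dietary intervention")


def gen_drug_table(
    gene_sets: GeneSetCollection,
    config: DrugTableConfig | None = None,
    seed: int = 0,
) -> tuple[DrugTables, dict]:
    """Generate trial/synonym/target/indication tables with exact truth.

    Each drug targets one member gene in each of 1–3 planted pathways and
    appears in trials under randomly chosen synonyms; the planted per-class
    pathway-targeting counts are recomputed exactly by the targeting join.
    """
    config = config or DrugTableConfig()
    rng = np.random.default_rng(seed)
    pids = sorted(gene_sets.sets)
    if not pids:
        raise ValueError("gene set collection is empty")

    drugs = []
    for cls, count in (
        ("symptomatic", config.n_symptomatic),
        ("disease_modifying", config.n_disease_modifying),
    ):
        for j in range(count):
            name = f"{cls.replace('_', '')}drug{j:02d}"
            n_path = int(rng.integers(config.pathways_per_drug[0],
                                      config.pathways_per_drug[1] + 1))
            chosen = [pids[k] for k in
                      rng.choice(len(pids), size=min(n_path, len(pids)),
                                 replace=False)]
            targets = []
            for pid in chosen:
                members = sorted(gene_sets[pid])
                targets.append(members[int(rng.integers(len(members)))])
            n_syn = int(rng.integers(config.synonyms_per_drug[0],
                                     config.synonyms_per_drug[1] + 1))
            synonyms = [f"{name}-alias{s}" for s in range(n_syn)]
            drugs.append((name, cls, sorted(set(targets)), synonyms))

    trials: list[tuple[str, str]] = []
    syn_rows: list[tuple[str, str]] = []
    target_rows: list[tuple[str, str]] = []
    ind_rows: list[tuple[str, str]] = []
    trial_no = 0
    for name, cls, targets, synonyms in drugs:
        ind_rows.append((name, cls))
        for syn in synonyms:
            syn_rows.append((name, syn))
        for gene in targets:
            target_rows.append((name, gene))
        all_names = [name] + synonyms
        n_trials = int(rng.integers(config.trials_per_drug[0],
                                    config.trials_per_drug[1] + 1))
        for _ in range(n_trials):
            label = all_names[int(rng.integers(len(all_names)))]
            # mixed-case trial entries exercise case-insensitive resolution
            shown = label.upper() if rng.random() < 0.3 else label
            trials.append((f"NCT{trial_no:07d}", shown))
            trial_no += 1
    blocklist = list(_BLOCK_NAMES[: config.n_blocked_names])
    for b in blocklist:
        trials.append((f"NCT{trial_no:07d}", b))
        trial_no += 1
    for u in range(config.n_unresolved_names):
        trials.append((f"NCT{trial_no:07d}", f"unknown compound {u}"))
        trial_no += 1

    # truth: distinct-drug counts per class per pathway from planted targets
    counts = {
        cls: {pid: 0 for pid in pids}
        for cls in ("symptomatic", "disease_modifying")
    }
    for name, cls, targets, _ in drugs:
        tset = set(targets)
        for pid in pids:
            if tset & gene_sets[pid]:
                counts[cls][pid] += 1
    truth = {
        "targeting": counts,
        "drugs": {
            name: {"class": cls, "targets": targets, "synonyms": synonyms}
            for name, cls, targets, synonyms in drugs
        },
        "blocked": blocklist,
        "n_unresolved": config.n_unresolved_names,
        "seed": seed,
    }
    tables = DrugTables(
        trials=trials,
        synonyms=syn_rows,
        targets=target_rows,
        indications=ind_rows,
        blocklist=blocklist,
    )
    return tables, truth
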