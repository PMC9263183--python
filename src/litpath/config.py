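"""Pipeline configuration.

Every tunable cutoff used by the filter cascade, the annotators and the
ranking stages lives here so that result artifacts can embed the exact
configuration they were produced under.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field, replace


@dataclass(frozen=True)
class PipelineConfig:
    # --- corpus filtering ---
    abstract_min_chars: int = 250
    abstract_max_chars: int = 4000
    max_keywords: int = 30
    disease_terms: tuple[str, ...] = ("alzheimer", "dementia")
    #: record fields searched for disease terms and pathway/dictionary terms
    search_fields: tuple[str, ...] = ("title", "abstract", "keywords")

    # --- pathway association ---
    #: distinct full-class terms required for a full association
    full_min: int = 1

    # --- dementia stratification ---
    #: minimum total dementia-class hits before an AD/related call is made
    min_hits: int = 2
    #: fraction of class hits that must be unrelated-class to call "unrelated"
    unrelated_frac: float = 0.5

    # --- evidence classification ---
    #: hits required on one side (with zero on the other) for a side call
    side_min: int = 1

    # --- ranking ---
    #: association levels counted as a "study" of a pathway
    count_levels: tuple[str, ...] = ("full",)
    min_per_year: int = 20
    #: "every_year": mask pathways below min_per_year in every year;
    #: "mean": mask pathways whose mean yearly count is below min_per_year
    yearly_rule: str = "every_year"

    # --- networks ---
    fisher_alternative: str = "greater"
    #: "all": BH-adjust over every eligible pathway pair in the collection;
    #: "selected": adjust only over the pairs among the selected top-k nodes
    fdr_scope: str = "all"

    def to_dict(self) -> dict:
        return asdict(self)

    def with_(self, **kwargs) -> "PipelineConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


DEFAULT_CONFIG = PipelineConfig()
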