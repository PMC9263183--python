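"""Resolve trial interventions to drugs and rank the pathways they target.

Generates synthetic trial/synonym/target/indication tables, resolves the
intervention names (case-insensitively, removing non-specific names), and
counts distinct drugs per pathway for each indication class.
"""

from litpath import build_drug_records, drug_pathway_targeting, resolve_drugs
from litpath.synth import gen_drug_table, gen_gene_sets

gene_sets, _ = gen_gene_sets(seed=5)
tables, truth = gen_drug_table(gene_sets, seed=5)

synonym_table = {}
for canonical, syn in tables.synonyms:
    synonym_table[syn.lower()] = canonical
    synonym_table[canonical.lower()] = canonical

names = [name for _, name in tables.trials]
report = resolve_drugs(names, synonym_table, blocklist=tables.blocklist)
print(f"{report.n_input} trial interventions: {len(report.resolved)} resolved "
      f"to {len(report.canonicals)} drugs, {len(report.blocked)} blocked "
      f"(non-specific), {len(report.unresolved)} unresolved")

targets = {}
for canonical, gene in tables.targets:
    targets.setdefault(canonical, set()).add(gene)
records = build_drug_records(report,
                             {k: frozenset(v) for k, v in targets.items()},
                             dict(tables.indications))
result = drug_pathway_targeting(records, gene_sets)
for cls, table in result.tables.items():
    hit = table[table.n_drugs > 0]
    print(f"\nMost-targeted pathways ({cls}):")
    print(hit.head(5).to_string(index=False))
# n_drugs counts distinct drugs with at least one target gene in the
# pathway; a drug hitting three genes of one pathway still counts once.
print(f"\nPathways top-ranked in both classes: {result.shared_top}")
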