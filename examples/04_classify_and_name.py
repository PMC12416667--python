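"""CYP nomenclature assignment: thresholds, novelty, and name allocation.

Queries sharing >55% identity with a named P450 join its subfamily, >40%
its family (with a new subfamily letter), and anything at or below 40% to
everything named founds a new family numbered from a private base (9001+)
so locally coined names never collide with committee-assigned ones.
"""

from cypminer import classify_all
from cypminer.synthetic import SyntheticConfig, generate

config = SyntheticConfig(seed=7, n_families=2, subfamilies_per_family=2,
                         ref_length=(150, 200), n_known_subfamily=2,
                         n_new_subfamily=2, n_new_family=2, n_decoy=0,
                         n_incomplete=0, n_duplicate=0)
dataset = generate(config)

results, registry, summary = classify_all(dataset.records, dataset.panel)

print(f"{'query':<14}{'best hit':<16}{'identity':>8}  {'novelty':<16}{'name'}")
for r in sorted(results, key=lambda r: r.record_id):
    print(f"{r.record_id:<14}{r.best_hit_id:<16}{r.identity_pct:>7.1f}%  "
          f"{r.novelty:<16}{r.name}")

print(f"\n{summary.n_classified} classified into {summary.n_families} families / "
      f"{summary.n_subfamilies} subfamilies "
      f"({summary.n_new_families} new families, {summary.n_new_subfamilies} new subfamilies)")

# Queries above 55% inherit an existing subfamily (next allele number);
# those in the 40-55 band inherit only the family and open a new subfamily
# letter; remote homologs below 40% receive fresh CYP9001+, CYP9002+ ...
# family numbers.
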