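"""Pairwise alignment and blastp-style screening against a reference panel.

Builds a tiny synthetic reference panel, then screens one genuine query and
one random decoy. The screen passes a candidate only if its best local hit
satisfies E-value <= 1e-5, both coverages >= 50%, and identity >= 15%.
"""

import numpy as np

from cypminer import ProteinRecord, global_align, local_align, screen_candidates
from cypminer.synthetic import SyntheticConfig, generate

dataset = generate(SyntheticConfig(seed=11, n_families=2, subfamilies_per_family=2,
                                   ref_length=(150, 200), n_known_subfamily=1,
                                   n_new_subfamily=0, n_new_family=0, n_decoy=0,
                                   n_incomplete=0, n_duplicate=0))
panel = dataset.panel
query = dataset.records[0]  # a known-subfamily mutant of one reference

res = global_align(query.sequence, panel.entries[0].sequence)
print(f"semi-global identity to {panel.entries[0].ref_id}: {res.identity_pct:.1f}% "
      f"(score {res.score:.0f}, {res.n_columns} aligned columns)")

rng = np.random.default_rng(0)
decoy = ProteinRecord(
    record_id="decoy",
    sequence="M" + "".join("ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, 180)),
)

for hit in screen_candidates([query, decoy], panel):
    verdict = "PASS" if hit.passed else f"FAIL ({','.join(hit.failed_criteria)})"
    ident = f"{hit.identity_pct:.1f}%" if hit.identity_pct else "-"
    print(f"{hit.record_id}: best hit {hit.ref_id}, identity {ident}, "
          f"E={hit.evalue:.2e} -> {verdict}")

# The derived query aligns strongly (tiny E-value) and passes; the random
# decoy's best local alignment is weak and fails the E-value criterion.
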