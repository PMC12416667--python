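"""The full discovery funnel on the default synthetic preset.

Runs dereplication -> reference screen -> filter cascade -> classification
-> per-site summary on a generated dataset with known composition, then
prints the funnel and the site summary table the pipeline wrote.
"""

from pathlib import Path

import pandas as pd

from cypminer import RunConfig, run
from cypminer.synthetic import SyntheticConfig

out = Path("scratch/example_run")
result = run(RunConfig(out_dir=str(out), synthetic=SyntheticConfig(), seed=17))

print("discovery funnel (stage -> surviving records):")
for stage, count in result.manifest["counts"].items():
    print(f"  {stage:<18} {count}")

print("\nper-site summary (from", out / "site_summary.tsv", "):")
print(pd.read_csv(out / "site_summary.tsv", sep="\t").to_string(index=False))

# 42 synthetic queries shrink to 36 unique sequences (duplicates merged),
# 30 pass the screen (decoys fail), 26 are complete motif-bearing P450s, and
# all 26 are classified -- matching the generator's truth table exactly.
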