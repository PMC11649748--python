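"""Generate a synthetic family exome dataset by gene dropping.

Builds the default 8-member two-generation family (father and three of six
offspring affected), plants one causal missense variant heterozygous in
exactly the affected members, and adds ten decoys per class, each
engineered to fail one specific funnel stage. Prints the output files and
the truth-label census.
"""

import tempfile
from collections import Counter
from pathlib import Path

from pedsieve import SimConfig, generate_dataset

outdir = Path(tempfile.mkdtemp(prefix="pedsieve_sim_"))
cfg = SimConfig(seed=42, n_decoys_per_class=10)
paths = generate_dataset(cfg, outdir)

print(f"wrote dataset to {outdir}:")
for name, path in paths.items():
    print(f"  {name:14s} {path.name}")

labels = Counter(
    line.split("\t")[-1]
    for line in paths["truth"].read_text().strip().splitlines()[1:]
)
print("\nrecord classes (1 causal + 10 decoys per class):")
for cls, n in labels.most_common():
    print(f"  {cls:22s} {n}")
# Decoy classes map one-to-one onto funnel stages: e.g. 'common_maf' decoys
# have population allele frequency above the 1% rarity threshold and are
# removed by the MAF stage and nothing else.
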