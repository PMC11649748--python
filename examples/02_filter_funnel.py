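"""Run the variant-filtering funnel and read the per-stage counts.

The funnel applies, in order: known-variant exclusion, autosomal-dominant
segregation (het in all affected, absent in all unaffected), consequence
class, population rarity (<1%), local-database rarity, and the 2-of-3
pathogenicity consensus. Each count pair shows how many variants entered
and left a stage; only the planted causal variant survives all six.
"""

import tempfile
from pathlib import Path

from pedsieve import (
    SimConfig,
    generate_dataset,
    read_annotated_vcf,
    read_local_frequency_table,
    read_panel,
    run_funnel,
)

outdir = Path(tempfile.mkdtemp(prefix="pedsieve_funnel_"))
cfg = SimConfig(
    seed=7,
    n_decoys_per_class=10,
    decoy_classes=(
        "non_segregating",
        "common_maf",
        "excluded_consequence",
        "benign_consensus",
        "known_panel_variant",
    ),
)
paths = generate_dataset(cfg, outdir)

variants = read_annotated_vcf(paths["vcf"])
panel = read_panel(paths["panel_genes"], paths["panel_variants"])
local = read_local_frequency_table(paths["local_af"])
survivors, report = run_funnel(variants, cfg.pedigree, panel, local)

print(f"{len(variants)} variants in")
for stage, n_in, n_out in report.stages:
    print(f"  {stage:16s} {n_in:3d} -> {n_out:3d}   (-{n_in - n_out})")
print(f"survivors: {[f'{v.gene} {v.key_str}' for v in survivors]}")
# With 5 classes x 10 decoys, each stage removes exactly its 10 designated
# decoys and the single survivor is the planted causal variant.
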