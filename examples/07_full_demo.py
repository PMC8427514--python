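"""Run the complete synthetic pipeline end to end.

Equivalent to `epiatlas demo --outdir demo_out --seed 1`: simulate ->
binarize -> segment -> methylome -> expression -> enhancer atlas -> GWAS,
writing BED/TSV outputs plus a JSON manifest of the key numbers.
"""

import json

from epiatlas.pipeline import PipelineConfig, run_demo

manifest = run_demo("demo_out", PipelineConfig(seed=1))
print(json.dumps(manifest, indent=2, default=str))
print("\noutputs in demo_out/: segmentation.bed, umr_lmr.bed, gene_classes.tsv,")
print("tissue_specificity.tsv, specific_enhancers.bed, gwas_enrichment.tsv, manifest.json")
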