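#!/usr/bin/env bash
# Full file-driven run: simulate a gene-level scenario (ontology,
# annotations, per-entity two-class expression), then run
# DE-call -> enrichment -> similarity -> threshold -> network -> ROC.
set -euo pipefail

workdir=$(mktemp -d)
mirlink simulate --out-dir "$workdir/inputs" --seed 7
mirlink run-all \
  --obo "$workdir/inputs/ontology.obo" \
  --annotations "$workdir/inputs/annotations.tsv" \
  --manifest "$workdir/inputs/manifest.tsv" \
  --gold-pairs "$workdir/inputs/gold_pairs.tsv" \
  --out-dir "$workdir/run" \
  --seed 7

echo "--- summary ---"
cat "$workdir/run/summary.json"
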