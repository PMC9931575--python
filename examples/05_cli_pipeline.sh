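#!/usr/bin/env bash
# Full command-line walkthrough: validate a design config, emit an oligo
# library, simulate a competitive growth experiment, and run the fitness
# pipeline on the simulated FASTQs. Run from the repository root:
#   bash examples/05_cli_pipeline.sh
set -euo pipefail

CONFIG=examples/demo_config.yaml
WORK=$(mktemp -d)
trap 'rm -rf "$WORK"' EXIT

cge validate --config "$CONFIG"

# 1. Oligo library: FASTA of 100-nt templates plus a TSV of tags.
cge design --config "$CONFIG" --locus EBOX_DEMO --n-oligos 200 --seed 1 \
    --out "$WORK/library"
head -4 "$WORK/library.fasta"

# 2. Ground-truth simulation: mutant allele grows 0.231/day slower.
cge simulate --config "$CONFIG" --locus EBOX_DEMO --seed 5 \
    --n-cells 30000 --depth 1000000 --fitness-effect -0.231 \
    --outdir "$WORK/sim"

# 3. Editing-outcome decomposition of the baseline sample.
cge efficiency --config "$CONFIG" --fastq "$WORK/sim/baseline.fastq" \
    --out "$WORK/efficiency.tsv"
cat "$WORK/efficiency.tsv"

# 4. Paired-lineage fitness analysis (counts, pairs, summary, manifest).
cge fitness --config "$CONFIG" \
    --baseline "$WORK/sim/baseline.fastq" --endpoint "$WORK/sim/endpoint.fastq" \
    --outdir "$WORK/run"
cat "$WORK/run/summary.tsv"
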