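#!/usr/bin/env bash
# End-to-end shell workflow: simulate -> build -> classify -> eval -> shrink.
set -euo pipefail
out=$(mktemp -d)

kmerlca simulate --out "$out/bench" --n-phyla 3 --genome-length 20000 \
    --reads-per-genome 100 --seed 11

kmerlca build "$out/bench/genomes.fna" \
    --taxonomy "$out/bench/taxonomy.tsv" --map "$out/bench/seqid2taxid.tsv" \
    --db "$out/bench.db" -k 31 -m 9

kmerlca classify "$out/bench/reads.fastq" --db "$out/bench.db" \
    --taxonomy "$out/bench/taxonomy.tsv" --output "$out/hits.tsv"

kmerlca eval --hits "$out/hits.tsv" --truth "$out/bench/truth.tsv" \
    --taxonomy "$out/bench/taxonomy.tsv" --ranks species,genus,phylum \
    --output "$out/report.tsv"

kmerlca shrink --db "$out/bench.db" --output "$out/mini.db" --factor 19

cat "$out/report.tsv"
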