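"""Build a k-mer→LCA database from a small simulated library and classify reads.

Generates three 20 kb genomes in three genera, builds the database, and
classifies a handful of error-bearing reads, printing each read's label and
its per-position hit list (runs of "taxid:count"; 0 = k-mer not in the
database, A = window with an ambiguous base).
"""

from kmerlca import (
    BenchmarkConfig,
    MinimizerParams,
    build,
    classify,
    make_benchmark,
)
from kmerlca.classify import hit_list_runs

bench = make_benchmark(
    BenchmarkConfig(n_phyla=3, genome_length=20_000, reads_per_genome=3, seed=7)
)
db = build(bench.library, bench.tree, k=31, params=MinimizerParams(m=9))
print(f"database: {len(db)} records over {bench.config.n_genomes} genomes\n")

for read_id, seq in bench.reads:
    res = classify(db, bench.tree, seq, read_id=read_id)
    truth = bench.truth[read_id]
    name = bench.tree.name(res.label) if res.classified else "-"
    print(f"{read_id}: label={res.label} ({name}) truth={truth} "
          f"score={res.path_score}")
    print(f"  hits: {hit_list_runs(res.hit_list)}")

# Each read's label should be its source species (or an ancestor when
# sequencing errors leave too few intact 31-mers); the path score counts
# the k-mer windows supporting the winning root-to-leaf path.
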