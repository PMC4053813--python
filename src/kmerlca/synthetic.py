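"""Synthetic taxonomies, genomes and error-bearing reads for benchmarking.

The read simulator emulates short-read sequencing with a position-dependent
substitution rate rising from the start of the read to its end (as in real
Illumina data) plus uniform insertion/deletion errors.  The positional
curve is an exponential ramp between the begin and end rates, calibrated
deterministically so its average equals a target mean rate; the defaults
(1% at read start, 6% at the end, 2% mean, 0.5% insertion + 0.5% deletion)
reproduce the summary statistics of the high-error simulated metagenome
used to stress-test exact-match classifiers.

Genome divergence is modelled in two steps, mirroring how simulated
metagenomes are built from reference libraries: species genomes diverge
from a genus ancestor, and reads are drawn from a *strain* genome that
differs from the database species genome by the simulator's default 0.1%
SNP and 0.1% indel rates — so even "error-free" reads may mismatch the
database unless strain divergence is also zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .db import GenomeLibrary
from .taxonomy import TaxonomyTree

__all__ = [
    "ErrorProfile",
    "BenchmarkConfig",
    "Benchmark",
    "make_taxonomy",
    "make_genome",
    "mutate_genome",
    "simulate_reads",
    "make_benchmark",
    "write_benchmark",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i
    _LUT[_b + 32] = _i


def _to_array(s: str) -> np.ndarray:
    b = _LUT[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]
    if (b == 255).any():
        raise ValueError("sequence contains non-ACGT characters")
    return b


def _to_string(b: np.ndarray) -> str:
    return _BASES[b].tobytes().decode("ascii")


@dataclass(frozen=True)
class ErrorProfile:
    """Positional substitution ramp plus uniform indel rates.

    ``begin_mismatch``/``end_mismatch`` bound the per-position substitution
    probability; the exponential interpolation between them is calibrated
    so the positional average equals ``mean_mismatch`` exactly.
    """

    begin_mismatch: float = 0.01
    end_mismatch: float = 0.06
    mean_mismatch: float = 0.02
    insertion: float = 0.005
    deletion: float = 0.005

    def __post_init__(self):
        for p in (
            self.begin_mismatch,
            self.end_mismatch,
            self.mean_mismatch,
            self.insertion,
            self.deletion,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("error probabilities must lie in [0, 1]")
        if self.begin_mismatch > self.end_mismatch:
            raise ValueError("begin_mismatch must not exceed end_mismatch")
        if not self.begin_mismatch <= self.mean_mismatch <= self.end_mismatch:
            raise ValueError("mean_mismatch must lie within [begin, end]")

    @classmethod
    def zero(cls) -> "ErrorProfile":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0)

    def positional_rates(self, read_len: int) -> np.ndarray:
        """Per-position substitution probabilities for a read of given length.

        Exponential ramp p(t) = begin + (end-begin) * (e^{at}-1)/(e^a-1)
        with the shape parameter ``a`` solved so that the mean over the
        read's positions equals ``mean_mismatch`` (to ~1e-12).
        """
        if read_len < 1:
            raise ValueError("read_len must be >= 1")
        lo, hi, mean = self.begin_mismatch, self.end_mismatch, self.mean_mismatch
        if read_len == 1 or hi == lo:
            return np.full(read_len, mean)
        t = np.linspace(0.0, 1.0, read_len)
        target = (mean - lo) / (hi - lo)  # mean of the unit ramp

        def ramp(a: float) -> np.ndarray:
            if abs(a) < 1e-9:
                return t
            if a > 0:  # overflow-safe form of (e^{at}-1)/(e^a-1)
                return (np.exp(a * (t - 1.0)) - np.exp(-a)) / -np.expm1(-a)
            return np.expm1(a * t) / np.expm1(a)

        if abs(target - 0.5) < 1e-12:
            return lo + (hi - lo) * t
        a = brentq(lambda a: ramp(a).mean() - target, -700.0, 700.0, xtol=1e-12)
        return lo + (hi - lo) * ramp(a)


def make_taxonomy(
    n_phyla: int,
    n_genera_per_family: int,
    n_species_per_genus: int,
    seed: int = 0,
) -> TaxonomyTree:
    """Toy taxonomy with complete seven-rank lineages.

    One kingdom; each phylum carries a single class/order/family chain
    holding ``n_genera_per_family`` genera of ``n_species_per_genus``
    species each.  Node IDs are assigned deterministically (the seed is
    accepted for interface symmetry; the construction is fully
    deterministic).
    """
    if min(n_phyla, n_genera_per_family, n_species_per_genus) < 1:
        raise ValueError("all counts must be >= 1")
    nodes: dict[int, tuple[int, str, str]] = {1: (1, "no rank", "root")}
    next_id = 2

    def add(parent: int, rank: str, name: str) -> int:
        nonlocal next_id
        nodes[next_id] = (parent, rank, name)
        next_id += 1
        return next_id - 1

    kingdom = add(1, "kingdom", "Kingdom_1")
    for p in range(1, n_phyla + 1):
        phylum = add(kingdom, "phylum", f"Phylum_{p}")
        cls = add(phylum, "class", f"Class_{p}")
        order = add(cls, "order", f"Order_{p}")
        family = add(order, "family", f"Family_{p}")
        for g in range(1, n_genera_per_family + 1):
            genus = add(family, "genus", f"Genus_{p}_{g}")
            for s in range(1, n_species_per_genus + 1):
                add(genus, "species", f"Species_{p}_{g}_{s}")
    return TaxonomyTree(nodes)


def make_genome(length: int, gc: float = 0.5, seed: int = 0) -> str:
    """Random i.i.d. genome with the requested GC fraction."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return _to_string(rng.choice(4, size=length, p=probs).astype(np.uint8))


def mutate_genome(
    g: str, snp_rate: float = 0.001, indel_rate: float = 0.001, seed: int = 0
) -> str:
    """Diverged copy of a genome: substitutions plus insertions/deletions.

    Each position substitutes to a uniformly random *different* base with
    probability ``snp_rate``; insertion and deletion events each occur at
    ``indel_rate / 2`` per base.  The defaults match common read-simulator
    strain-divergence settings (0.1% SNPs, 0.1% indels).
    """
    for r in (snp_rate, indel_rate):
        if not 0.0 <= r < 1.0:
            raise ValueError("rates must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    b = _to_array(g).copy()
    n = len(b)
    sub = rng.random(n) < snp_rate
    b[sub] = (b[sub] + rng.integers(1, 4, size=int(sub.sum()))) % 4
    ins = rng.random(n) < indel_rate / 2
    dele = rng.random(n) < indel_rate / 2
    counts = ins.astype(np.int64) + (~dele).astype(np.int64)
    out = np.repeat(b, counts)
    starts = np.cumsum(counts) - counts
    ins_slots = starts[ins]  # the inserted base precedes the original one
    out[ins_slots] = rng.integers(0, 4, size=len(ins_slots))
    return _to_string(out.astype(np.uint8))


_DEL_BUFFER = 24  # extra template bases to absorb deletions


def simulate_reads(
    g: str,
    n: int,
    read_len: int,
    profile: ErrorProfile,
    seed: int = 0,
    id_prefix: str = "read",
) -> list[tuple[str, str, int]]:
    """Simulate reads with positional substitution and indel errors.

    Start positions are uniform, strands random; indels are applied to the
    template and the read is then truncated/padded to ``read_len`` before
    position-dependent substitutions are imposed along the read as
    synthesized.  Returns (read-ID, sequence, forward-strand origin
    position) triples, deterministic for a given seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    L = len(g)
    if read_len > L:
        raise ValueError(f"read_len {read_len} exceeds genome length {L}")
    rng = np.random.default_rng(seed)
    fwd = _to_array(g)
    rev = (3 - fwd)[::-1]
    rates = profile.positional_rates(read_len)
    buf = read_len + _DEL_BUFFER
    out: list[tuple[str, str, int]] = []
    starts = rng.integers(0, L - read_len + 1, size=n)
    strands = rng.integers(0, 2, size=n)
    for i in range(n):
        start = int(starts[i])
        strand_seq = rev if strands[i] else fwd
        template = strand_seq[start : start + buf]
        dele = rng.random(len(template)) < profile.deletion
        kept = template[~dele]
        ins = rng.random(len(kept)) < profile.insertion
        if ins.any():
            kept = np.insert(kept, np.flatnonzero(ins), rng.integers(0, 4, int(ins.sum())).astype(np.uint8))
        if len(kept) < read_len:  # template exhausted at the genome end
            pad = rng.integers(0, 4, read_len - len(kept)).astype(np.uint8)
            kept = np.concatenate([kept, pad])
        read = kept[:read_len].copy()
        sub = rng.random(read_len) < rates
        nsub = int(sub.sum())
        if nsub:
            read[sub] = (read[sub] + rng.integers(1, 4, nsub)) % 4
        origin = start if not strands[i] else L - start - read_len
        out.append((f"{id_prefix}_{i}", _to_string(read), origin))
    return out


@dataclass(frozen=True)
class BenchmarkConfig:
    """Study conditions for a self-contained simulated metagenome.

    The defaults describe the headline desk-scale benchmark: ten 100 kb
    genomes in ten distinct genera, 1,000 100-bp reads per genome at the
    high-error profile, with reads drawn from strain genomes diverged
    0.1%/0.1% from the database genomes.
    """

    n_phyla: int = 10
    n_genera_per_family: int = 1
    n_species_per_genus: int = 1
    genome_length: int = 100_000
    gc: float = 0.5
    reads_per_genome: int = 1_000
    read_len: int = 100
    profile: ErrorProfile = field(default_factory=ErrorProfile)
    species_snp: float = 0.02  # divergence between congeneric species
    species_indel: float = 0.002
    strain_snp: float = 0.001  # read-source strain vs database genome
    strain_indel: float = 0.001
    seed: int = 0

    @property
    def n_genomes(self) -> int:
        return self.n_phyla * self.n_genera_per_family * self.n_species_per_genus

    def zero_error(self) -> "BenchmarkConfig":
        """Same genomes, but error-free reads drawn from the database genomes."""
        return replace(
            self, profile=ErrorProfile.zero(), strain_snp=0.0, strain_indel=0.0
        )


@dataclass
class Benchmark:
    """A cross-consistent (library, taxonomy, reads, truth) quadruple."""

    config: BenchmarkConfig
    library: GenomeLibrary
    tree: TaxonomyTree
    reads: list[tuple[str, str]]  # (read-ID, sequence)
    truth: dict[str, int]  # read-ID -> origin species taxid

    def genus_exclusive_kmers(self, k: int) -> bool:
        """True iff no canonical k-mer is shared between genera."""
        from . import codec

        per_genus: dict[int, list[np.ndarray]] = {}
        for seqid, seq in self.library.sequences:
            taxid = self.library.taxon_map[seqid]
            genus = self.tree.ancestor_at_rank(taxid, "genus")
            codes, valid = codec.sequence_codes(seq, k)
            per_genus.setdefault(genus, []).append(codes[valid])
        all_codes = []
        owners = []
        for gi, chunks in enumerate(per_genus.values()):
            u = np.unique(np.concatenate(chunks))
            all_codes.append(u)
            owners.append(np.full(len(u), gi))
        codes = np.concatenate(all_codes)
        owners = np.concatenate(owners)
        order = np.argsort(codes, kind="stable")
        codes, owners = codes[order], owners[order]
        dup = codes[1:] == codes[:-1]
        return not bool((dup & (owners[1:] != owners[:-1])).any())


def make_benchmark(config: BenchmarkConfig | None = None) -> Benchmark:
    """Generate a taxonomy, genome library, simulated reads and truth set.

    Genus ancestor genomes are independent random sequences; species
    genomes diverge from the genus ancestor, and reads come from a strain
    genome further diverged from the species genome.  Every genome
    contributes the same number of reads (equal abundance).
    """
    cfg = config or BenchmarkConfig()
    tree = make_taxonomy(
        cfg.n_phyla, cfg.n_genera_per_family, cfg.n_species_per_genus, cfg.seed
    )
    rng = np.random.default_rng(cfg.seed)
    seeds = iter(rng.integers(0, 2**31 - 1, size=cfg.n_genomes * 4 + 64))

    species_ids = sorted(t for t in tree if tree.rank(t) == "species")
    genus_of = {s: tree.ancestor_at_rank(s, "genus") for s in species_ids}
    genus_genomes: dict[int, str] = {}
    sequences: list[tuple[str, str]] = []
    taxon_map: dict[str, int] = {}
    reads: list[tuple[str, str]] = []
    truth: dict[str, int] = {}
    for sp in species_ids:
        genus = genus_of[sp]
        # one seed per role per species, drawn unconditionally so that the
        # same base seed yields the same genomes across config variants
        genus_seed, species_seed, strain_seed = (int(next(seeds)) for _ in range(3))
        if genus not in genus_genomes:
            genus_genomes[genus] = make_genome(cfg.genome_length, cfg.gc, genus_seed)
        if cfg.species_snp == 0 and cfg.species_indel == 0:
            genome = genus_genomes[genus]
        else:
            genome = mutate_genome(
                genus_genomes[genus], cfg.species_snp, cfg.species_indel, species_seed
            )
        seqid = f"taxon{sp}"
        sequences.append((seqid, genome))
        taxon_map[seqid] = sp
        if cfg.strain_snp == 0 and cfg.strain_indel == 0:
            strain = genome
        else:
            strain = mutate_genome(genome, cfg.strain_snp, cfg.strain_indel, strain_seed)
        for read_id, seq, _pos in simulate_reads(
            strain,
            cfg.reads_per_genome,
            cfg.read_len,
            cfg.profile,
            int(next(seeds)),
            id_prefix=seqid,
        ):
            reads.append((read_id, seq))
            truth[read_id] = sp
    library = GenomeLibrary(sequences=sequences, taxon_map=taxon_map)
    return Benchmark(cfg, library, tree, reads, truth)


def write_benchmark(bench: Benchmark, outdir) -> dict[str, Path]:
    """Write a benchmark to disk in standard formats.

    Produces genomes.fna (FASTA), reads.fastq (constant placeholder
    qualities — the classifier ignores them), truth.tsv, seqid2taxid.tsv
    and taxonomy.tsv; returns the path of each artifact.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genomes": outdir / "genomes.fna",
        "reads": outdir / "reads.fastq",
        "truth": outdir / "truth.tsv",
        "seqid2taxid": outdir / "seqid2taxid.tsv",
        "taxonomy": outdir / "taxonomy.tsv",
    }
    with open(paths["genomes"], "w") as fh:
        for seqid, seq in bench.library.sequences:
            fh.write(f">{seqid}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    with open(paths["reads"], "w") as fh:
        for read_id, seq in bench.reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")
    with open(paths["truth"], "w") as fh:
        for read_id, taxid in bench.truth.items():
            fh.write(f"{read_id}\t{taxid}\n")
    with open(paths["seqid2taxid"], "w") as fh:
        for seqid, taxid in bench.library.taxon_map.items():
            fh.write(f"{seqid}\t{taxid}\n")
    with open(paths["taxonomy"], "w") as fh:
        for taxid in sorted(bench.tree):
            fh.write(
                f"{taxid}\t{bench.tree.parent(taxid)}\t{bench.tree.rank(taxid)}"
                f"\t{bench.tree.name(taxid)}\n"
            )
    return paths
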