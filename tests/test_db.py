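import numpy as np
import pytest

from kmerlca import codec, db as dbm
from kmerlca.codec import MinimizerParams, canonical, encode
from kmerlca.db import (
    ContaminationFilter,
    GenomeLibrary,
    KrakenDB,
    QueryCursor,
    build,
    enumerate_distinct_kmers,
    load,
    save,
    shrink,
)
from kmerlca.taxonomy import TaxonomyTree


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture
def params():
    return MinimizerParams(m=5)


@pytest.fixture
def library(small_tree):
    rng = np.random.default_rng(1)
    shared = _random_seq(rng, 80)
    return GenomeLibrary(
        sequences=[
            ("s4", _random_seq(rng, 200) + shared),
            ("s5", _random_seq(rng, 200) + shared),
            ("s3", _random_seq(rng, 200)),
        ],
        taxon_map={"s4": 4, "s5": 5, "s3": 3},
    )


class TestEnumerate:
    def test_homopolymer(self):
        lib = GenomeLibrary([("a", "AAAA")], {"a": 1})
        assert enumerate_distinct_kmers(lib, 3) == {encode("AAA")}

    def test_hand_enumeration(self):
        lib = GenomeLibrary([("a", "ACGTA")], {"a": 1})
        assert enumerate_distinct_kmers(lib, 4) == {
            encode("ACGT"),
            encode(canonical("CGTA")),
        }

    def test_random_sequence_count_matches_bruteforce(self):
        rng = np.random.default_rng(2)
        s = _random_seq(rng, 200)
        lib = GenomeLibrary([("a", s)], {"a": 1})
        brute = {encode(canonical(s[i : i + 31])) for i in range(len(s) - 30)}
        got = enumerate_distinct_kmers(lib, 31)
        assert got == brute
        assert len(brute) == 170  # all 31-mers of this sequence are distinct

    def test_ambiguous_windows_excluded(self):
        lib = GenomeLibrary([("a", "ACGTNACGT")], {"a": 1})
        assert enumerate_distinct_kmers(lib, 5) == set()

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            enumerate_distinct_kmers(GenomeLibrary([], {}), 5)


class TestBuild:
    def test_single_genome_kmers_store_its_taxon(self, small_tree, params):
        lib = GenomeLibrary([("s3", "ACGTACGTACGT")], {"s3": 3})
        db = build(lib, small_tree, k=7, params=params)
        for code in enumerate_distinct_kmers(lib, 7):
            assert db.query(code) == 3

    def test_shared_kmer_stores_lca_of_siblings(self, small_tree, library, params):
        db = build(library, small_tree, k=31, params=params)
        shared = enumerate_distinct_kmers(
            GenomeLibrary([library.sequences[0]], library.taxon_map), 31
        ) & enumerate_distinct_kmers(
            GenomeLibrary([library.sequences[1]], library.taxon_map), 31
        )
        assert shared  # the fixture embeds an 80 bp shared block
        for code in shared:
            assert db.query(code) == 2  # lca(4, 5)

    def test_order_independence_byte_identical(self, small_tree, library, params, tmp_path):
        db1 = build(library, small_tree, k=31, params=params)
        flipped = GenomeLibrary(library.sequences[::-1], library.taxon_map)
        db2 = build(flipped, small_tree, k=31, params=params)
        p1, p2 = tmp_path / "a.db", tmp_path / "b.db"
        save(db1, p1)
        save(db2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_missing_taxon_names_sequence(self, small_tree, params):
        lib = GenomeLibrary([("sX", "ACGTACGTACGT")], {"sX": 99})
        with pytest.raises(ValueError, match="sX"):
            build(lib, small_tree, k=7, params=params)

    def test_stored_lca_is_ancestor_of_each_contributor(self, small_tree, library, params):
        db = build(library, small_tree, k=31, params=params)
        for seqid, seq in library.sequences:
            taxid = library.taxon_map[seqid]
            codes, valid = codec.sequence_codes(seq, 31)
            for code in codes[valid][::13]:
                lca = db.query(int(code))
                assert lca is not None
                assert small_tree.is_in_clade(taxid, lca)

    def test_invariants_on_records(self, small_tree, library, params):
        db = build(library, small_tree, k=31, params=params)
        codes = db.records["code"]
        assert len(np.unique(codes)) == len(codes)  # k-mer codes unique
        offs = db.offsets
        assert offs[0] == 0 and offs[-1] == len(db)
        assert (np.diff(offs.astype(np.int64)) >= 0).all()
        for b in np.flatnonzero(np.diff(offs.astype(np.int64)) > 0)[:50]:
            lo, hi = int(offs[b]), int(offs[b + 1])
            assert (np.diff(codes[lo:hi].astype(object)) > 0).all()
            for code in codes[lo:hi]:
                assert codec.minimizer_bucket(int(code), db.k, db.params) == b


class TestContaminationFilter:
    def test_adapter_kmers_removed(self, small_tree, params):
        rng = np.random.default_rng(5)
        adapter = _random_seq(rng, 40)
        clean = _random_seq(rng, 120)
        lib = GenomeLibrary([("s3", clean + adapter)], {"s3": 3})
        filt = ContaminationFilter(adapters=[adapter])
        db = build(lib, small_tree, k=31, params=params, filters=filt)
        for code in enumerate_distinct_kmers(GenomeLibrary([("a", adapter)], {"a": 1}), 31):
            assert db.query(code) is None
        assert db.query(encode(canonical(clean[:31]))) == 3

    def test_adapter_equal_to_contig_removes_everything(self, small_tree, params):
        seq = _random_seq(np.random.default_rng(6), 100)
        lib = GenomeLibrary([("s3", seq)], {"s3": 3})
        filt = ContaminationFilter(adapters=[seq])
        with pytest.raises(ValueError, match="empty"):
            build(lib, small_tree, k=31, params=params, filters=filt)

    def test_draft_edge_trim_window_arithmetic(self, small_tree, params):
        """100 bp draft contig, k=31: windows 0-19 and 50-69 are trimmed,
        20-49 kept."""
        seq = _random_seq(np.random.default_rng(7), 100)
        lib = GenomeLibrary([("s3", seq)], {"s3": 3}, draft_ids={"s3"})
        db = build(lib, small_tree, k=31, params=params, filters=ContaminationFilter())
        kept = {encode(canonical(seq[i : i + 31])) for i in range(20, 50)}
        trimmed = {
            encode(canonical(seq[i : i + 31]))
            for i in list(range(0, 20)) + list(range(50, 70))
        } - kept
        assert len(db) == len(kept)
        for code in kept:
            assert db.query(code) == 3
        for code in trimmed:
            assert db.query(code) is None

    def test_non_draft_sequence_unaffected(self, small_tree, params):
        seq = _random_seq(np.random.default_rng(8), 100)
        lib = GenomeLibrary([("s3", seq)], {"s3": 3})
        with_filt = build(lib, small_tree, k=31, params=params, filters=ContaminationFilter())
        without = build(lib, small_tree, k=31, params=params)
        assert with_filt == without


class TestQuery:
    def test_present_and_absent(self, small_tree, library, params):
        db = build(library, small_tree, k=31, params=params)
        stored = int(db.records["code"][0])
        assert db.query(stored) is not None
        absent = 0
        codes = set(int(c) for c in db.records["code"])
        while absent in codes:
            absent += 1
        assert db.query(absent) is None

    def test_cursor_never_changes_answers(self, small_tree, library, params):
        """Streaming overlapping k-mers with a shared cursor returns exactly
        what independent cursor-less queries return, in any stream order."""
        db = build(library, small_tree, k=31, params=params)
        seq = library.sequences[0][1]
        codes, valid = codec.sequence_codes(seq, 31)
        codes = [int(c) for c in codes[valid]]
        plain = [db.query(c) for c in codes]
        cursor = QueryCursor()
        assert [db.query(c, cursor) for c in codes] == plain
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(codes))
        cursor = QueryCursor()
        shuffled = [db.query(codes[i], cursor) for i in perm]
        assert shuffled == [plain[i] for i in perm]

    def test_wrong_k_detected_via_bucket_range(self, small_tree, library, params):
        db = build(library, small_tree, k=31, params=params)
        with pytest.raises(Exception):
            codec.minimizer_bucket(5, 0, params)  # degenerate k


class TestShrink:
    def _db_with_n_records(self, n, params=MinimizerParams(m=5)):
        rng = np.random.default_rng(n)
        tree = TaxonomyTree({1: (1, "no rank", "r"), 2: (1, "genus", "g")})
        while True:
            lib = GenomeLibrary([("a", _random_seq(rng, n + 60))], {"a": 2})
            db = build(lib, tree, k=21, params=params)
            if len(db) >= n:
                db.records = db.records[:n]
                # recompute offsets for the truncated record set
                buckets = [
                    codec.minimizer_bucket(int(c), db.k, db.params)
                    for c in db.records["code"]
                ]
                offsets = np.zeros(params.n_buckets + 1, dtype=np.uint64)
                counts = np.bincount(buckets, minlength=params.n_buckets)
                offsets[1:] = np.cumsum(counts, dtype=np.uint64)
                db.offsets = offsets
                return db

    def test_single_block_keeps_last_record(self):
        db = self._db_with_n_records(19)
        small = shrink(db, 19)
        assert len(small) == 1
        assert small.records[0] == db.records[18]

    def test_complete_blocks(self):
        db = self._db_with_n_records(190)
        assert len(shrink(db, 19)) == 10

    @pytest.mark.parametrize("n, factor", [(20, 19), (199, 19), (57, 7)])
    def test_floor_count_and_subset(self, n, factor):
        db = self._db_with_n_records(n)
        small = shrink(db, factor)
        assert len(small) == n // factor
        original = {(int(r["code"]), int(r["taxon"])) for r in db.records}
        for r in small.records:
            assert (int(r["code"]), int(r["taxon"])) in original

    def test_shrunk_db_answers_match_original_for_retained(self):
        db = self._db_with_n_records(100)
        small = shrink(db, 7)
        for r in small.records:
            assert small.query(int(r["code"])) == db.query(int(r["code"]))

    def test_bad_factor_and_empty_result(self):
        db = self._db_with_n_records(10)
        with pytest.raises(ValueError):
            shrink(db, 1)
        with pytest.raises(ValueError, match="empty"):
            shrink(db, 11)


class TestSerialization:
    def test_round_trip(self, small_tree, library, params, tmp_path):
        db = build(library, small_tree, k=31, params=params)
        p = tmp_path / "x.db"
        save(db, p)
        assert load(p) == db

    def test_record_section_is_12_bytes_per_kmer(self, small_tree, library, tmp_path):
        params = MinimizerParams(m=2)
        db = build(library, small_tree, k=31, params=params)
        p = tmp_path / "x.db"
        save(db, p)
        header, offsets = 20, (4**2 + 1) * 8
        record_bytes = p.stat().st_size - header - offsets
        assert record_bytes / len(db) == 12

    def test_offset_section_size_formula(self, small_tree, library, tmp_path):
        params = MinimizerParams(m=2)
        db = build(library, small_tree, k=31, params=params)
        p = tmp_path / "x.db"
        save(db, p)
        assert p.stat().st_size == 20 + 12 * len(db) + (4**2 + 1) * 8  # 136-byte index

    def test_bad_magic_and_truncation(self, small_tree, library, params, tmp_path):
        db = build(library, small_tree, k=31, params=params)
        p = tmp_path / "x.db"
        save(db, p)
        data = p.read_bytes()
        (tmp_path / "bad.db").write_bytes(b"XXXX" + data[4:])
        with pytest.raises(ValueError, match="magic"):
            load(tmp_path / "bad.db")
        (tmp_path / "trunc.db").write_bytes(data[: len(data) // 2])
        with pytest.raises(ValueError, match="truncated"):
            load(tmp_path / "trunc.db")
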