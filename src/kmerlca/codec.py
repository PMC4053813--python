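"""2-bit DNA k-mer encoding, canonicalization and minimizer selection.

A k-mer (k <= 31) is packed into an unsigned 64-bit integer, two bits per
base (A=00, C=01, G=10, T=11), first base in the most significant position.
With this layout integer comparison of equal-length codes coincides with
lexicographic comparison of the strings, so the *canonical* form of a k-mer
(the lexicographically smaller of the k-mer and its reverse complement) can
be computed entirely on integers.

The minimizer of a k-mer is the canonical M-mer of the k-mer whose
XOR-scrambled code is smallest.  Scrambling (toggling half of the bits with
a fixed constant before comparison) breaks the heavy bias of plain
lexicographic ordering toward low-complexity M-mers such as poly-A, which
would otherwise concentrate a large share of k-mers into a few buckets.
Because the canonical M-mer set of a k-mer equals that of its reverse
complement, the minimizer is strand-invariant and can be computed on either
strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AMBIGUOUS",
    "MinimizerParams",
    "reverse_complement",
    "canonical",
    "encode",
    "decode",
    "revcomp_code",
    "canonical_code",
    "minimizer",
    "minimizer_bucket",
    "kmers_of",
    "sequence_kmers",
    "default_scramble",
]

_BASES = "ACGT"
_BASE_TO_BITS = {"A": 0, "C": 1, "G": 2, "T": 3}

# byte -> 2-bit value; 255 flags a non-ACGT (ambiguous) character
_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class _Ambiguous:
    """Singleton marker for k-mer windows containing non-ACGT characters."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "AMBIGUOUS"


AMBIGUOUS = _Ambiguous()


def default_scramble(m: int) -> int:
    """Alternating ``0101...01`` pattern over 2*m bits (toggles half the bits)."""
    return int("01" * m, 2)


@dataclass(frozen=True)
class MinimizerParams:
    """Minimizer length M and the XOR constant used to scramble the ordering.

    ``scramble=0`` disables scrambling (plain lexicographic minimizers).
    """

    m: int = 15
    scramble: int = field(default=-1)

    def __post_init__(self):
        if not 1 <= self.m <= 31:
            raise ValueError(f"minimizer length must be in [1, 31], got {self.m}")
        if self.scramble == -1:
            object.__setattr__(self, "scramble", default_scramble(self.m))
        if not 0 <= self.scramble < 4**self.m:
            raise ValueError("scramble constant must fit in 2*M bits")

    @property
    def n_buckets(self) -> int:
        return 4**self.m


def _check_dna(s: str, allow_n: bool = False) -> None:
    allowed = set("ACGTNacgtn") if allow_n else set("ACGTacgt")
    bad = set(s) - allowed
    if bad:
        raise ValueError(f"non-DNA characters in sequence: {sorted(bad)!r}")


def reverse_complement(s: str) -> str:
    """Reverse complement of a DNA string; N maps to N."""
    _check_dna(s, allow_n=True)
    return s.translate(_COMPLEMENT)[::-1]


def canonical(s: str) -> str:
    """The lexicographically smaller of ``s`` and its reverse complement."""
    _check_dna(s, allow_n=False)
    rc = s.translate(_COMPLEMENT)[::-1]
    return min(s.upper(), rc.upper())


def encode(s: str) -> int:
    """Pack an ACGT string (length <= 31) into a 2-bit-per-base integer."""
    if len(s) > 31:
        raise ValueError(f"k-mer length {len(s)} exceeds 31")
    if not s:
        raise ValueError("cannot encode an empty k-mer")
    code = 0
    for ch in s.upper():
        try:
            code = (code << 2) | _BASE_TO_BITS[ch]
        except KeyError:
            raise ValueError(f"ambiguous base {ch!r} cannot be encoded") from None
    return code


def decode(code: int, k: int) -> str:
    """Inverse of :func:`encode` for a k-mer of known length."""
    if not 1 <= k <= 31:
        raise ValueError(f"k must be in [1, 31], got {k}")
    if not 0 <= code < 4**k:
        raise ValueError(f"code {code} out of range for k={k}")
    out = []
    for shift in range(2 * (k - 1), -2, -2):
        out.append(_BASES[(code >> shift) & 3])
    return "".join(out)


def revcomp_code(code: int, k: int) -> int:
    """Reverse complement acting directly on a 2-bit code."""
    comp = code ^ (4**k - 1)
    out = 0
    for _ in range(k):
        out = (out << 2) | (comp & 3)
        comp >>= 2
    return out


def canonical_code(code: int, k: int) -> int:
    """min(code, revcomp_code) — the canonical form on integers."""
    return min(code, revcomp_code(code, k))


def minimizer(kmer: str, params: MinimizerParams) -> int:
    """Canonical M-mer of ``kmer`` whose scrambled code is smallest.

    The caller passes the k-mer in canonical form; because canonical M-mers
    are strand-invariant the result is the same either way.  Ties on the
    scrambled value are broken toward the leftmost occurrence, which cannot
    change the value itself.
    """
    k = len(kmer)
    if params.m > k:
        raise ValueError(f"minimizer length {params.m} exceeds k-mer length {k}")
    code = encode(kmer)
    best = None
    mask = 4**params.m - 1
    for i in range(k - params.m + 1):
        sub = (code >> 2 * (k - params.m - i)) & mask
        canon = canonical_code(sub, params.m)
        if best is None or (canon ^ params.scramble) < (best ^ params.scramble):
            best = canon
    return best


def minimizer_bucket(kmer_code: int, k: int, params: MinimizerParams) -> int:
    """Scrambled value of the minimizer — the database bucket index."""
    if k < params.m:
        raise ValueError(f"k ({k}) is smaller than the minimizer length {params.m}")
    mask = 4**params.m - 1
    best = None
    for i in range(k - params.m + 1):
        sub = (kmer_code >> 2 * (k - params.m - i)) & mask
        scrambled = canonical_code(sub, params.m) ^ params.scramble
        if best is None or scrambled < best:
            best = scrambled
    return best


def kmers_of(s: str, k: int) -> list[tuple[int, object]]:
    """All k-mer windows of ``s`` as (position, canonical code | AMBIGUOUS).

    Windows containing any non-ACGT character are reported as AMBIGUOUS
    rather than silently dropped, so downstream consumers can account for
    every position.  A sequence shorter than k yields an empty list.
    """
    if not 1 <= k <= 31:
        raise ValueError(f"k must be in [1, 31], got {k}")
    codes, valid = sequence_codes(s, k)
    out: list[tuple[int, object]] = []
    for i in range(codes.shape[0]):
        out.append((i, int(codes[i])) if valid[i] else (i, AMBIGUOUS))
    return out


# ---------------------------------------------------------------------------
# Vectorized internals (shared by the database builder and the classifier)
# ---------------------------------------------------------------------------


def _base_array(s: str) -> np.ndarray:
    return _LUT[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]


def _window_codes_strand(b: np.ndarray, k: int) -> np.ndarray:
    """Codes of all k-windows of a 2-bit base array (ambiguous bases as 0)."""
    vals = np.where(b == 255, 0, b).astype(np.uint64)
    n = len(vals) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    # rolling: code[i+1] = ((code[i] << 2) | base) & mask — vectorized via
    # weighted sliding windows in chunks to bound memory
    powers = (np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    windows = np.lib.stride_tricks.sliding_window_view(vals, k)
    out = np.empty(n, dtype=np.uint64)
    chunk = 1 << 18
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        out[lo:hi] = (windows[lo:hi] * powers).sum(axis=1, dtype=np.uint64)
    return out


def sequence_codes(s: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical codes for every k-window of ``s`` plus a validity mask.

    Returns ``(codes, valid)`` of length ``len(s) - k + 1`` (empty when the
    sequence is shorter than k); ``valid[i]`` is False for windows covering
    a non-ACGT character, and the corresponding code is undefined.
    """
    b = _base_array(s)
    n = len(b) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    ambig = (b == 255).astype(np.uint8)
    # window valid iff no ambiguous base inside
    csum = np.concatenate([[0], np.cumsum(ambig)])
    valid = (csum[k:] - csum[:-k]) == 0

    fwd = _window_codes_strand(b, k)
    # reverse-complement codes: forward codes of rc(s), reversed
    rc_b = np.where(b == 255, np.uint8(255), (3 - b).astype(np.uint8))[::-1]
    rev = _window_codes_strand(rc_b, k)[::-1]
    return np.minimum(fwd, rev), valid


def sequence_minimizers(
    s: str, k: int, params: MinimizerParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Canonical codes, bucket indices and validity for every k-window.

    The bucket index of a window is the scrambled value of its minimizer.
    Minimizers are computed on the raw strand, which is equivalent to
    computing them on the canonical k-mer (the canonical M-mer candidate
    set is strand-invariant).
    """
    if params.m > k:
        raise ValueError(f"minimizer length {params.m} exceeds k {k}")
    codes, valid = sequence_codes(s, k)
    n = codes.shape[0]
    if n == 0:
        return codes, np.empty(0, dtype=np.uint64), valid
    mcodes, _ = sequence_codes(s, params.m)  # canonical M-mer codes, all positions
    scrambled = mcodes ^ np.uint64(params.scramble)
    w = k - params.m + 1
    windows = np.lib.stride_tricks.sliding_window_view(scrambled, w)
    buckets = windows.min(axis=1)
    return codes, buckets, valid
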