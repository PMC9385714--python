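"""Genotype representation, mutant enumeration, naming, and encodings.

A genotype is a fixed-length RNA sequence over {A, C, G, U}; by default the
35-nt catalytic core of the ligase ribozyme. Positions are 1-based within
the core (core position 1 corresponds to absolute position 45 of the full
ribozyme; ``CORE_OFFSET`` converts). A combinatorial library over N chosen
loci is projected onto bitvectors (wild allele = 0, mutant allele = 1,
locus 0 = least significant bit); that bit order also fixes the "binary
order" used by the Walsh--Hadamard decomposition in :mod:`ribonet.epistasis`.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

ALPHABET = "ACGU"
CORE_LENGTH = 35
#: offset from 1-based core position to absolute position in the full ribozyme
CORE_OFFSET = 44

Genotype = str

_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_VARIANT_TOKEN = re.compile(r"^(\d+)([ACGU])$")


def validate_sequence(seq: str, length: int | None = None) -> str:
    """Check that ``seq`` is over {A,C,G,U} (and of the given length)."""
    if length is not None and len(seq) != length:
        raise ValueError(f"expected length {length}, got {len(seq)}")
    for ch in seq:
        if ch not in _BASE_INDEX:
            raise ValueError(f"invalid base {ch!r}; alphabet is {ALPHABET}")
    return seq


class Mutation(NamedTuple):
    """A single substitution: 1-based core position and target base."""

    position: int
    base: str


MutationSet = tuple[Mutation, ...]


def hamming(a: Genotype, b: Genotype) -> int:
    """Number of positions at which two equal-length sequences differ."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def enumerate_single_mutants(seq: Genotype) -> list[Genotype]:
    """All 3L sequences at Hamming distance 1, position-major then A<C<G<U."""
    out = []
    for i, ref in enumerate(seq):
        for base in ALPHABET:
            if base != ref:
                out.append(seq[:i] + base + seq[i + 1 :])
    return out


def enumerate_double_mutants(seq: Genotype) -> list[Genotype]:
    """All 9*C(L,2) sequences at Hamming distance 2, deterministic order."""
    L = len(seq)
    if L < 2:
        raise ValueError("need at least two positions for double mutants")
    out = []
    for i in range(L):
        alts_i = [b for b in ALPHABET if b != seq[i]]
        for j in range(i + 1, L):
            alts_j = [b for b in ALPHABET if b != seq[j]]
            for bi in alts_i:
                for bj in alts_j:
                    out.append(seq[:i] + bi + seq[i + 1 : j] + bj + seq[j + 1 :])
    return out


def n_k_mutants(L: int, k: int) -> int:
    """Number of distinct sequences at exactly Hamming distance k."""
    return math.comb(L, k) * 3**k


def sample_k_mutants(
    seq: Genotype, k: int, n: int, rng: np.random.Generator
) -> list[Genotype]:
    """Sample ``n`` unique genotypes at exactly Hamming distance ``k``.

    Uniform without replacement over the full k-mutant set. Sampling is by
    rejection (draw position set + bases, dedupe) which is efficient as long
    as ``n`` is not close to the total count; if ``n`` exceeds half the
    space, the full set is enumerated and subsampled instead.
    """
    L = len(seq)
    total = n_k_mutants(L, k)
    if n > total:
        raise ValueError(f"requested {n} mutants but only {total} exist")

    if n * 2 >= total:
        pool = _enumerate_k_mutants(seq, k)
        idx = rng.choice(total, size=n, replace=False)
        return [pool[i] for i in sorted(idx)]

    seen: set[str] = set()
    out: list[Genotype] = []
    while len(out) < n:
        pos = rng.choice(L, size=k, replace=False)
        chars = list(seq)
        for p in pos:
            alts = [b for b in ALPHABET if b != seq[p]]
            chars[p] = alts[rng.integers(3)]
        cand = "".join(chars)
        if cand not in seen:
            seen.add(cand)
            out.append(cand)
    return out


def _enumerate_k_mutants(seq: Genotype, k: int) -> list[Genotype]:
    out = []
    for pos in itertools.combinations(range(len(seq)), k):
        alts = [[b for b in ALPHABET if b != seq[p]] for p in pos]
        for bases in itertools.product(*alts):
            chars = list(seq)
            for p, b in zip(pos, bases):
                chars[p] = b
            out.append("".join(chars))
    return out


# ---------------------------------------------------------------------------
# variant naming: "7G/8C/19U" tokens, "WT" for the empty set
# ---------------------------------------------------------------------------

def name_variant(mutations: Iterable[Mutation]) -> str:
    """Canonical variant name: ``posBASE`` tokens joined by ``/``; ``WT`` if empty."""
    muts = sorted(mutations)
    if not muts:
        return "WT"
    return "/".join(f"{p}{b}" for p, b in muts)


def parse_variant(name: str) -> MutationSet:
    """Inverse of :func:`name_variant`."""
    if name == "WT":
        return ()
    muts = []
    last_pos = 0
    for token in name.split("/"):
        m = _VARIANT_TOKEN.match(token)
        if m is None:
            raise ValueError(f"malformed variant token {token!r}")
        pos = int(m.group(1))
        if pos <= last_pos:
            raise ValueError(f"positions not strictly increasing in {name!r}")
        last_pos = pos
        muts.append(Mutation(pos, m.group(2)))
    return tuple(muts)


def mutations_between(reference: Genotype, seq: Genotype) -> MutationSet:
    """Mutation set carried by ``seq`` relative to ``reference``."""
    if len(reference) != len(seq):
        raise ValueError("length mismatch")
    return tuple(
        Mutation(i + 1, b) for i, (r, b) in enumerate(zip(reference, seq)) if r != b
    )


def apply_mutations(reference: Genotype, mutations: Iterable[Mutation]) -> Genotype:
    """Apply a mutation set to a reference sequence."""
    chars = list(reference)
    for pos, base in mutations:
        if not 1 <= pos <= len(chars):
            raise ValueError(f"position {pos} out of range 1..{len(chars)}")
        if chars[pos - 1] == base:
            raise ValueError(f"target base equals reference at position {pos}")
        chars[pos - 1] = base
    return "".join(chars)


# ---------------------------------------------------------------------------
# biallelic projection of a combinatorial library
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocusMap:
    """Biallelic projection of a combinatorial library onto N loci.

    ``positions`` are 1-based core positions (unique, increasing); at locus
    ``i`` the wild sequence carries ``wild[i]`` and the fully mutated anchor
    carries ``mutant[i]``. ``wild_sequence`` is the full core of the wild
    type; the all-ones anchor is obtained by substituting every mutant
    allele.
    """

    wild_sequence: Genotype
    positions: tuple[int, ...]
    mutant: tuple[str, ...]
    wild: tuple[str, ...] = field(default=())

    def __post_init__(self):
        wild = tuple(self.wild_sequence[p - 1] for p in self.positions)
        object.__setattr__(self, "wild", wild)
        if len(self.positions) != len(self.mutant):
            raise ValueError("positions and mutant alleles differ in length")
        if list(self.positions) != sorted(set(self.positions)):
            raise ValueError("positions must be unique and increasing")
        for p, w, m in zip(self.positions, wild, self.mutant):
            if not 1 <= p <= len(self.wild_sequence):
                raise ValueError(f"position {p} outside the core")
            if w == m:
                raise ValueError(f"wild and mutant allele identical at position {p}")

    @property
    def n_loci(self) -> int:
        return len(self.positions)

    @property
    def mutant_sequence(self) -> Genotype:
        """The all-mutant anchor genotype (every locus set to 1)."""
        return decode_binary((1 << self.n_loci) - 1, self)

    @classmethod
    def from_pair(cls, wild: Genotype, mutant: Genotype) -> "LocusMap":
        """Build the map from the two anchor sequences."""
        muts = mutations_between(wild, mutant)
        return cls(
            wild_sequence=wild,
            positions=tuple(m.position for m in muts),
            mutant=tuple(m.base for m in muts),
        )


def encode_binary(seq: Genotype, locus_map: LocusMap) -> int:
    """Encode a genotype inside the combinatorial subspace as a bit index.

    Bit ``i`` is 1 iff the sequence carries the mutant allele at locus ``i``
    (locus 0 = lowest core position = least significant bit). Raises if the
    sequence carries a third allele at a mapped locus or differs from the
    wild sequence outside the map.
    """
    if len(seq) != len(locus_map.wild_sequence):
        raise ValueError("length mismatch with the locus map's wild sequence")
    mapped = set(locus_map.positions)
    for i, (w, s) in enumerate(zip(locus_map.wild_sequence, seq), start=1):
        if i not in mapped and w != s:
            raise ValueError(f"mismatch outside the locus map at position {i}")
    index = 0
    for bit, (pos, w, m) in enumerate(
        zip(locus_map.positions, locus_map.wild, locus_map.mutant)
    ):
        base = seq[pos - 1]
        if base == m:
            index |= 1 << bit
        elif base != w:
            raise ValueError(
                f"base {base!r} at position {pos} is neither allele ({w}/{m})"
            )
    return index


def decode_binary(index: int, locus_map: LocusMap) -> Genotype:
    """Inverse of :func:`encode_binary`."""
    if not 0 <= index < (1 << locus_map.n_loci):
        raise ValueError("index outside the combinatorial space")
    chars = list(locus_map.wild_sequence)
    for bit, (pos, m) in enumerate(zip(locus_map.positions, locus_map.mutant)):
        if index >> bit & 1:
            chars[pos - 1] = m
    return "".join(chars)


def one_hot(seq: Genotype) -> np.ndarray:
    """Flattened one-hot encoding, position-major, base order A,C,G,U.

    A 35-nt core maps to a 1x140 binary vector with exactly L ones.
    """
    vec = np.zeros(4 * len(seq), dtype=np.float64)
    for i, ch in enumerate(seq):
        vec[4 * i + _BASE_INDEX[ch]] = 1.0
    return vec


def one_hot_matrix(seqs: Sequence[Genotype]) -> np.ndarray:
    """Stack :func:`one_hot` encodings of many sequences into a matrix."""
    if not seqs:
        return np.zeros((0, 0))
    X = np.zeros((len(seqs), 4 * len(seqs[0])), dtype=np.float64)
    for r, s in enumerate(seqs):
        for i, ch in enumerate(s):
            X[r, 4 * i + _BASE_INDEX[ch]] = 1.0
    return X
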