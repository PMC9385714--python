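"""Genotype -> relative-activity maps, sparse and combinatorially complete."""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ribonet.sequence_core import (
    Genotype,
    LocusMap,
    decode_binary,
    encode_binary,
    hamming,
)

#: floor applied to RA before taking logarithms (configurable per call)
DEFAULT_LN_RA_FLOOR = 1e-3


class Landscape:
    """A map from genotype sequences to relative activity (RA).

    RA is the fitness proxy: fraction-ligated of a variant divided by that
    of the wild type, so the wild type has RA 1 by construction.
    """

    def __init__(self, activities: Mapping[Genotype, float], wild_type: Genotype):
        self._ra = dict(activities)
        self.wild_type = wild_type
        for seq, ra in self._ra.items():
            if ra < 0:
                raise ValueError(f"negative RA for {seq!r}")

    def __len__(self) -> int:
        return len(self._ra)

    def __contains__(self, seq: Genotype) -> bool:
        return seq in self._ra

    def __iter__(self):
        return iter(self._ra)

    def ra(self, seq: Genotype) -> float:
        return self._ra[seq]

    def items(self):
        return self._ra.items()

    def sequences(self) -> list[Genotype]:
        return list(self._ra)

    def distances_to(self, reference: Genotype | None = None) -> dict[Genotype, int]:
        ref = self.wild_type if reference is None else reference
        return {s: hamming(s, ref) for s in self._ra}

    # -- plain-text I/O ------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sequence": list(self._ra), "RA": list(self._ra.values())}
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, wild_type: Genotype) -> "Landscape":
        df = pd.read_csv(path, sep="\t")
        return cls(dict(zip(df["sequence"], df["RA"])), wild_type)


class CombinatorialLandscape(Landscape):
    """A combinatorially complete biallelic landscape over N loci.

    Holds the RA of all 2^N genotypes as a vector in binary order (index =
    bitvector of the genotype, locus 0 = LSB), the ordering assumed by the
    Walsh--Hadamard decomposition.
    """

    def __init__(self, ra_vector: Iterable[float], locus_map: LocusMap):
        ra = np.asarray(list(ra_vector), dtype=np.float64)
        n = locus_map.n_loci
        if ra.shape != (1 << n,):
            raise ValueError(f"expected 2^{n} activities, got {ra.shape}")
        self.locus_map = locus_map
        self.ra_vector = ra
        seqs = [decode_binary(i, locus_map) for i in range(1 << n)]
        super().__init__(dict(zip(seqs, ra)), locus_map.wild_sequence)
        self._index = {s: i for i, s in enumerate(seqs)}

    @property
    def n_loci(self) -> int:
        return self.locus_map.n_loci

    def index_of(self, seq: Genotype) -> int:
        return encode_binary(seq, self.locus_map)

    def ln_ra_vector(self, floor: float = DEFAULT_LN_RA_FLOOR) -> np.ndarray:
        """ln(RA) in binary order, with RA clamped below at ``floor``.

        Exact zeros in RA are artifacts of finite sequencing depth; the
        clamp keeps the log-space vector finite.
        """
        return np.log(np.maximum(self.ra_vector, floor))

    @classmethod
    def from_landscape(
        cls, landscape: Landscape, locus_map: LocusMap
    ) -> "CombinatorialLandscape":
        n = locus_map.n_loci
        ra = np.empty(1 << n)
        for i in range(1 << n):
            ra[i] = landscape.ra(decode_binary(i, locus_map))
        return cls(ra, locus_map)
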