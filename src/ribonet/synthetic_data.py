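"""Generators for every input the pipeline consumes.

Everything the analysis assumes can be synthesized here with known ground
truth: combinatorially complete landscapes with a controllable epistasis
spectrum (draw sparse background-averaged coefficients, invert the
Walsh--Hadamard map), two-anchor neutral networks with a tunable ridge of
neutral intermediates, per-variant ligated/unligated read counts whose
fraction-ligated encodes relative activity, and FASTQ fixtures exercising
the barcode/flank/quality filters. All generators are deterministic under
a fixed seed.

The wild-type core used by the generators is a synthetic 35-nt stand-in
for a ligase catalytic core (the generators only need a fixed reference
sequence; no result depends on its identity).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ribonet.activity_quant import AssaySpec
from ribonet.epistasis import interaction_orders, wh_compose_avg
from ribonet.landscape import CombinatorialLandscape
from ribonet.sequence_core import ALPHABET, Genotype, LocusMap, validate_sequence

#: synthetic 35-nt reference core (fixed, arbitrary; see module docstring)
DEFAULT_WT = validate_sequence("GGAUCGUCAGUGCAUUGAGCCUAGCAAGGCAUCGU", 35)


def default_locus_map(n_loci: int, wild_sequence: Genotype = DEFAULT_WT) -> LocusMap:
    """A biallelic map over the first ``n_loci`` core positions.

    The mutant allele at each locus is the alphabetically next base, which
    keeps the map deterministic.
    """
    if n_loci > len(wild_sequence):
        raise ValueError("more loci than core positions")
    positions = tuple(range(1, n_loci + 1))
    mutant = tuple(
        ALPHABET[(ALPHABET.index(wild_sequence[p - 1]) + 1) % 4] for p in positions
    )
    return LocusMap(wild_sequence=wild_sequence, positions=positions, mutant=mutant)


# ---------------------------------------------------------------------------
# landscapes from a prescribed epistasis spectrum
# ---------------------------------------------------------------------------

@dataclass
class SpectrumSpec:
    """Sparse background-averaged spectrum for a synthetic landscape.

    ``terms_per_order`` maps interaction order k (1..N) to the number of
    nonzero coefficients drawn at that order; ``scale_per_order`` to their
    Gaussian magnitude scale. ``order0`` fixes the order-0 (global mean)
    term. ``noise_sd`` adds Gaussian measurement noise on ln(RA).
    """

    n_loci: int
    terms_per_order: Mapping[int, int]
    scale_per_order: Mapping[int, float] | float = 1.0
    order0: float = 0.0
    noise_sd: float = 0.0

    def scale(self, order: int) -> float:
        if isinstance(self.scale_per_order, Mapping):
            return float(self.scale_per_order.get(order, 1.0))
        return float(self.scale_per_order)

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_loci > 16:
            raise ValueError("full enumeration capped at 16 loci")
        for k, count in self.terms_per_order.items():
            if not 1 <= k <= self.n_loci:
                raise ValueError(f"order {k} outside 1..N")
            if count > math.comb(self.n_loci, k):
                raise ValueError(f"more order-{k} terms than C(N,{k})")


def simulate_landscape_from_spectrum(
    spec: SpectrumSpec,
    rng: np.random.Generator,
    locus_map: LocusMap | None = None,
) -> tuple[CombinatorialLandscape, np.ndarray]:
    """Draw a complete landscape with known background-averaged coefficients.

    Coefficients at each requested order are placed at uniformly chosen
    index positions of that order with N(0, scale) values; the inverse
    weighted Walsh--Hadamard transform produces ln(RA) for all 2^N
    genotypes, to which i.i.d. Gaussian noise is added. Returns the
    landscape and the ground-truth ``e_avg`` vector.
    """
    lmap = locus_map or default_locus_map(spec.n_loci)
    if lmap.n_loci != spec.n_loci:
        raise ValueError("locus map does not match the spectrum's N")
    n = spec.n_loci
    orders = interaction_orders(n)
    e_avg = np.zeros(1 << n)
    e_avg[0] = spec.order0
    for k, count in sorted(spec.terms_per_order.items()):
        candidates = np.flatnonzero(orders == k)
        picks = rng.choice(candidates, size=count, replace=False)
        e_avg[picks] = rng.normal(0.0, spec.scale(k), size=count)
    ln_ra = wh_compose_avg(e_avg, n)
    if spec.noise_sd > 0:
        ln_ra = ln_ra + rng.normal(0.0, spec.noise_sd, size=ln_ra.size)
    return CombinatorialLandscape(np.exp(ln_ra), lmap), e_avg


def simulate_additive_landscape(
    n_loci: int,
    rng: np.random.Generator,
    effect_sd: float = 0.5,
    locus_map: LocusMap | None = None,
) -> CombinatorialLandscape:
    """Purely additive landscape: ln(RA) is a sum of per-locus effects."""
    lmap = locus_map or default_locus_map(n_loci)
    effects = rng.normal(0.0, effect_sd, size=n_loci)
    idx = np.arange(1 << n_loci)
    bits = (idx[:, None] >> np.arange(n_loci)) & 1
    ln_ra = bits @ effects
    return CombinatorialLandscape(np.exp(ln_ra), lmap)


# ---------------------------------------------------------------------------
# two-anchor neutral networks
# ---------------------------------------------------------------------------

def _ridge_mask(n_loci: int, ridge_width: int) -> np.ndarray:
    """Neutral mask of the window-constrained ridge.

    A genotype with k mutations is neutral iff all its mutations fall
    within the first min(k + w - 1, N) loci of the canonical (locus-index)
    order, or it lies within Hamming distance w - 1 of the all-mutant
    anchor (the distant anchor carries a mutationally robust neutral
    neighborhood, as the band alone thins out at the top). Width 1 leaves
    a single neutral chain (mutations accumulate in strict canonical
    order); width N makes every genotype neutral.
    """
    if not 1 <= ridge_width <= n_loci:
        raise ValueError("ridge_width outside 1..N")
    idx = np.arange(1 << n_loci)
    pc = interaction_orders(n_loci)
    window = np.minimum(pc + ridge_width - 1, n_loci)
    on_band = (idx >> window) == 0  # no bits above the allowed window
    near_anchor = (n_loci - pc) <= ridge_width - 1
    return on_band | near_anchor


def simulate_two_anchor_network(
    n_loci: int,
    ridge_width: int,
    rng: np.random.Generator,
    threshold: float = 0.2,
    locus_map: LocusMap | None = None,
) -> tuple[CombinatorialLandscape, dict]:
    """A landscape whose neutral set is a tunable ridge between two anchors.

    Both anchors (all-wild and all-mutant) are neutral: the wild anchor has
    RA exactly 1 (it is the normalization reference) and the mutant anchor
    draws a high neutral RA. Other ridge genotypes draw RA uniformly from
    [threshold, 1]; off-ridge genotypes draw from [0, threshold/2], a
    safety margin below the neutrality boundary.

    Returns the landscape and an info dict with the neutral mask and, for
    N <= 6, the exact accessible-path fraction by exhaustive enumeration.
    """
    lmap = locus_map or default_locus_map(n_loci)
    neutral = _ridge_mask(n_loci, ridge_width)
    n_total = 1 << n_loci
    ra = np.where(
        neutral,
        rng.uniform(threshold, 1.0, size=n_total),
        rng.uniform(0.0, threshold / 2.0, size=n_total),
    )
    ra[0] = 1.0
    landscape = CombinatorialLandscape(ra, lmap)

    info: dict = {"neutral_mask": neutral, "ridge_width": ridge_width}
    if n_loci <= 6:
        n_accessible = 0
        total = 0
        for perm in itertools.permutations(range(n_loci)):
            acc, ok = 0, True
            for locus in perm[:-1]:  # strict intermediates only
                acc |= 1 << locus
                if not neutral[acc]:
                    ok = False
                    break
            n_accessible += ok
            total += 1
        info["accessible_path_fraction"] = n_accessible / total
    return landscape, info


# ---------------------------------------------------------------------------
# sequencing-read simulation
# ---------------------------------------------------------------------------

@dataclass
class ReadSimSpec:
    """Parameters of the simulated ligation assay.

    ``fl_wt`` is the wild type's true fraction ligated; a variant's true FL
    is RA * fl_wt (clipped at 1). Depth per variant per replicate is
    Poisson around ``mean_depth`` (negative-binomial if ``dispersion`` is
    set); ligated counts are binomial in the true FL.
    """

    fl_wt: float = 0.5
    mean_depth: float = 1000.0
    dispersion: float | None = None
    n_replicates: int = 2
    ligated_barcode: str = "ACGU"
    unligated_barcode: str = "UGCA"
    core_flank_5p: str = "GGAAGG"
    core_flank_3p: str = "CCUUCC"

    def __post_init__(self):
        if not 0 < self.fl_wt <= 1:
            raise ValueError("fl_wt must be in (0, 1]")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")

    def assay_spec(self, core_length: int, **kwargs) -> AssaySpec:
        return AssaySpec(
            ligated_barcode=self.ligated_barcode,
            unligated_barcode=self.unligated_barcode,
            core_flank_5p=self.core_flank_5p,
            core_flank_3p=self.core_flank_3p,
            core_length=core_length,
            **kwargs,
        )


def simulate_reads(
    landscape,
    spec: ReadSimSpec,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-variant, per-replicate ligated/unligated counts from true RAs.

    Returns a tidy count table (variant, replicate, N_ligated,
    N_unligated) in the format ``activity_quant.read_count_table`` loads.
    """
    rows = []
    for seq, ra in landscape.items():
        fl = min(ra * spec.fl_wt, 1.0)
        for rep in range(1, spec.n_replicates + 1):
            if spec.dispersion is None:
                depth = int(rng.poisson(spec.mean_depth))
            else:
                # negative binomial parameterized by mean and dispersion r
                r = spec.dispersion
                p = r / (r + spec.mean_depth)
                depth = int(rng.negative_binomial(r, p))
            n_lig = int(rng.binomial(depth, fl)) if depth > 0 else 0
            rows.append(
                {
                    "variant": seq,
                    "replicate": rep,
                    "N_ligated": n_lig,
                    "N_unligated": depth - n_lig,
                }
            )
    return pd.DataFrame(rows)


def counts_to_nested(count_table: pd.DataFrame) -> dict:
    """Tidy count table -> {seq: ((lig1, unlig1), (lig2, unlig2))}."""
    out: dict = {}
    for seq, grp in count_table.groupby("variant", sort=False):
        reps = {
            int(r.replicate): (int(r.N_ligated), int(r.N_unligated))
            for r in grp.itertuples()
        }
        out[seq] = (reps[1], reps[2])
    return out


def write_fastq_pair(
    count_table: pd.DataFrame,
    spec: ReadSimSpec,
    rep1_path,
    rep2_path,
    rng: np.random.Generator,
    quality: int = 30,
    low_quality_fraction: float = 0.0,
    low_quality: int = 10,
) -> None:
    """Emit one FASTQ per replicate with barcode + flanks + core reads.

    Each counted read becomes a 4-line Phred+33 record; a configurable
    fraction of reads carries one low-quality base call inside the
    variable region, to exercise the quality filter.
    """
    paths = {1: rep1_path, 2: rep2_path}
    handles = {rep: open(path, "w") for rep, path in paths.items()}
    try:
        read_no = 0
        for row in count_table.itertuples():
            core = row.variant
            for barcode, count in (
                (spec.ligated_barcode, row.N_ligated),
                (spec.unligated_barcode, row.N_unligated),
            ):
                seq = barcode + spec.core_flank_5p + core + spec.core_flank_3p
                core_start = len(barcode) + len(spec.core_flank_5p)
                for _ in range(count):
                    read_no += 1
                    quals = [quality] * len(seq)
                    if low_quality_fraction and rng.random() < low_quality_fraction:
                        pos = core_start + int(rng.integers(len(core)))
                        quals[pos] = low_quality
                    qline = "".join(chr(q + 33) for q in quals)
                    handles[row.replicate].write(
                        f"@read{read_no}\n{seq}\n+\n{qline}\n"
                    )
    finally:
        for h in handles.values():
            h.close()
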