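"""In-silico genetic operators and the two generation designers.

Each experimental generation of ribozyme variants was designed in silico
from the assayed activities of the previous one: tournament selection picks
parents (highest RA wins each tournament), one-point crossover recombines
them, and a per-position point-mutation operator (probability 1/35 per
position, so one substitution per sequence on average) adds diversity.

Two designers are provided. The first (used for early generations) mutates
every recombinant immediately after crossover. The second (later
generations) emits a set of *pure* recombinants plus a smaller set of point
mutants drawn from parents and recombinants — the change that dramatically
raised the fraction of neutral offspring. Both designers deduplicate
against all previously assayed genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from ribonet.sequence_core import ALPHABET, Genotype

#: attempts per requested offspring before novelty search gives up
NOVELTY_CAP_FACTOR = 100


@dataclass
class Individual:
    genotype: Genotype
    ra: float
    origin: str = "parent"  # parent | recombinant | point_mutant | control

    def __post_init__(self):
        if self.ra < 0:
            raise ValueError("RA must be non-negative")


@dataclass
class GAConfig:
    tournament_size: int = 10
    n_parents: int = 100
    n_recombinants: int = 800
    n_mutants: int = 200
    population_size: int = 1000
    per_position_mutation_prob: float = 1.0 / 35.0
    n_controls: int = 0

    def __post_init__(self):
        if self.tournament_size < 1:
            raise ValueError("tournament_size must be >= 1")
        if self.population_size < self.n_recombinants + self.n_mutants:
            raise ValueError("population smaller than recombinants + mutants")


class NoveltyExhausted(RuntimeError):
    """Raised when novel offspring cannot be found within the iteration cap."""


def tournament_select(
    population: Sequence[Individual], cfg: GAConfig, rng: np.random.Generator
) -> list[Individual]:
    """Select ``cfg.n_parents`` parents by repeated tournaments.

    Each tournament samples ``tournament_size`` contestants without
    replacement from the variants not yet chosen as parents; the contestant
    with the highest RA wins (ties broken uniformly at random) and the
    losers are returned to the pool.
    """
    if not population:
        raise ValueError("empty population")
    if cfg.n_parents > len(population):
        raise ValueError("n_parents exceeds population size")
    available = list(range(len(population)))
    parents: list[Individual] = []
    for _ in range(cfg.n_parents):
        k = min(cfg.tournament_size, len(available))
        contestants = rng.choice(len(available), size=k, replace=False)
        ras = np.array([population[available[i]].ra for i in contestants])
        best = np.flatnonzero(ras == ras.max())
        winner_slot = int(contestants[best[rng.integers(len(best))]])
        parents.append(population[available[winner_slot]])
        available.pop(winner_slot)
    return parents


def one_point_crossover(
    p1: Genotype, p2: Genotype, rng: np.random.Generator
) -> Genotype:
    """Recombine two parents at a uniform cut in 1..L-1, return one child.

    End cuts are excluded so both children are true recombinants; which of
    the two children is returned is itself a fair coin flip.
    """
    if len(p1) != len(p2):
        raise ValueError("parents differ in length")
    cut = int(rng.integers(1, len(p1)))
    children = (p1[:cut] + p2[cut:], p2[:cut] + p1[cut:])
    return children[int(rng.integers(2))]


def mutate(
    g: Genotype, cfg: GAConfig, rng: np.random.Generator
) -> Genotype:
    """Point-mutate: each position substitutes with prob 1/35 (uniform alt base).

    May return the input unchanged when zero substitutions are drawn;
    novelty is enforced by the designers' dedup step, not here.
    """
    p = cfg.per_position_mutation_prob
    if p <= 0:
        return g
    hits = np.flatnonzero(rng.random(len(g)) < p)
    if hits.size == 0:
        return g
    chars = list(g)
    for i in hits:
        alts = [b for b in ALPHABET if b != chars[i]]
        chars[i] = alts[int(rng.integers(3))]
    return "".join(chars)


def _fill_novel(
    make, n: int, history: set[Genotype], taken: set[Genotype]
) -> list[Genotype]:
    """Draw from ``make()`` until ``n`` offspring novel w.r.t. history+generation."""
    out: list[Genotype] = []
    attempts = 0
    cap = NOVELTY_CAP_FACTOR * max(n, 1)
    while len(out) < n:
        if attempts >= cap:
            raise NoveltyExhausted(
                f"could not find {n} novel offspring within {cap} attempts"
            )
        attempts += 1
        cand = make()
        if cand in history or cand in taken:
            continue
        taken.add(cand)
        out.append(cand)
    return out


def _insert_controls(
    offspring: list[Individual],
    controls: Sequence[Genotype],
    n_controls: int,
    rng: np.random.Generator,
) -> list[Individual]:
    """Overwrite ``n_controls`` random slots with control genotypes.

    Controls are inserted after dedup and may duplicate history by design
    (the wild type is carried in every generation as the RA reference).
    """
    if n_controls == 0 or not controls:
        return offspring
    n = min(n_controls, len(offspring), len(controls))
    slots = rng.choice(len(offspring), size=n, replace=False)
    picks = rng.choice(len(controls), size=n, replace=False if n <= len(controls) else True)
    for slot, pick in zip(slots, picks):
        offspring[slot] = Individual(controls[pick], ra=0.0, origin="control")
    return offspring


def design_generation_v1(
    population: Sequence[Individual],
    cfg: GAConfig,
    history: Iterable[Genotype],
    rng: np.random.Generator,
    controls: Sequence[Genotype] = (),
) -> list[Individual]:
    """Early-generation designer: every recombinant is immediately mutated.

    Repeat {pick two random parents -> one-point crossover -> point
    mutation} until ``population_size`` novel offspring are collected, then
    replace random slots with the controls.
    """
    parents = tournament_select(population, cfg, rng)
    hist = set(history)
    taken: set[Genotype] = set()

    def make() -> Genotype:
        i, j = rng.choice(len(parents), size=2, replace=False)
        child = one_point_crossover(parents[i].genotype, parents[j].genotype, rng)
        return mutate(child, cfg, rng)

    seqs = _fill_novel(make, cfg.population_size, hist, taken)
    offspring = [Individual(s, ra=0.0, origin="point_mutant") for s in seqs]
    return _insert_controls(offspring, controls, cfg.n_controls, rng)


def design_generation_v2(
    population: Sequence[Individual],
    cfg: GAConfig,
    history: Iterable[Genotype],
    rng: np.random.Generator,
    controls: Sequence[Genotype] = (),
) -> list[Individual]:
    """Later-generation designer: pure recombinants plus separate point mutants.

    ``n_recombinants`` novel pure recombinants (no substitution) are
    generated from the parents; ``n_mutants`` further offspring are made by
    point-mutating random picks from the pool of parents and recombinants.
    """
    parents = tournament_select(population, cfg, rng)
    hist = set(history)
    taken: set[Genotype] = set()

    def make_recombinant() -> Genotype:
        i, j = rng.choice(len(parents), size=2, replace=False)
        return one_point_crossover(parents[i].genotype, parents[j].genotype, rng)

    rec_seqs = _fill_novel(make_recombinant, cfg.n_recombinants, hist, taken)

    pool = [p.genotype for p in parents] + rec_seqs

    def make_mutant() -> Genotype:
        return mutate(pool[int(rng.integers(len(pool)))], cfg, rng)

    mut_seqs = _fill_novel(make_mutant, cfg.n_mutants, hist, taken)

    offspring = [Individual(s, ra=0.0, origin="recombinant") for s in rec_seqs] + [
        Individual(s, ra=0.0, origin="point_mutant") for s in mut_seqs
    ]
    return _insert_controls(offspring, controls, cfg.n_controls, rng)


def generation_manifest(offspring: Sequence[Individual], generation_index: int):
    """Tabulate a designed generation (TSV-ready)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "sequence": [o.genotype for o in offspring],
            "origin": [o.origin for o in offspring],
            "generation_index": generation_index,
        }
    )
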