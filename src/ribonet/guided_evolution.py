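"""Classifier-guided, fully in-silico evolutionary loop.

The final generation of variants is designed without any intermediate
experiments: starting from the last assayed population, 100 rounds of
selection, recombination (80% of offspring), point mutation (the rest) and
classifier screening are run, tracking the mean Hamming distance from the
wild type each round. Selection here is guided by the classifier rather
than by measured RA: within a tournament, if at least one contestant is
predicted neutral, a random predicted-neutral contestant wins; otherwise a
random contestant wins.

Every round's population retains only predicted-neutral offspring (a flag
defers that filter to the final round), and offspring novelty is enforced
against the loop's own running history, which is what pushes the
population outward instead of letting it drift in place.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
import pandas as pd

from ribonet.evolution_engine import GAConfig, mutate, one_point_crossover
from ribonet.sequence_core import Genotype, hamming


class SequenceClassifier(Protocol):
    """Anything that predicts neutrality for a batch of sequences."""

    def predict_neutral(self, sequences: Sequence[Genotype]) -> np.ndarray: ...


class OracleClassifier:
    """Ground-truth classifier backed by a landscape (for simulation studies).

    A sequence is predicted neutral iff it is present in the landscape with
    RA at or above the threshold; sequences outside the landscape are
    deleterious.
    """

    def __init__(self, landscape, threshold: float = 0.2):
        self.landscape = landscape
        self.threshold = threshold

    def predict_neutral(self, sequences: Sequence[Genotype]) -> np.ndarray:
        return np.array(
            [
                s in self.landscape and self.landscape.ra(s) >= self.threshold
                for s in sequences
            ],
            dtype=bool,
        )


@dataclass
class GuidedConfig:
    n_rounds: int = 100
    recombinant_fraction: float = 0.8
    final_population: int = 12000
    ga: GAConfig = field(default_factory=GAConfig)
    filter_every_round: bool = True
    enforce_novelty: bool = True
    keep_parents: bool = False

    def __post_init__(self):
        if not 0 < self.recombinant_fraction < 1:
            raise ValueError("recombinant_fraction must be in (0, 1)")


@dataclass
class GuidedResult:
    final_population: list[Genotype]
    mean_hamming: list[float]  # per round, from the reference sequence
    fraction_neutral: list[float]  # predicted-neutral fraction per round
    population_sizes: list[int]
    extinct_at_round: int | None = None

    @property
    def extinct(self) -> bool:
        return self.extinct_at_round is not None

    def trajectory_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "round": np.arange(1, len(self.mean_hamming) + 1),
                "population_size": self.population_sizes,
                "mean_hamming": self.mean_hamming,
                "fraction_predicted_neutral": self.fraction_neutral,
            }
        )


def guided_tournament_select(
    population: Sequence[Genotype],
    classifier: SequenceClassifier,
    cfg: GAConfig,
    rng: np.random.Generator,
    neutral_mask: np.ndarray | None = None,
) -> list[Genotype]:
    """Tournament selection on predicted neutrality instead of measured RA.

    Within each tournament the winner is a uniform pick among the
    predicted-neutral contestants, or among all contestants if none is
    predicted neutral. Selection is with replacement across tournaments
    (the same variant may parent several offspring) but without replacement
    within a tournament.
    """
    if len(population) == 0:
        raise ValueError("empty population")
    if neutral_mask is None:
        neutral_mask = classifier.predict_neutral(population)
    n_parents = min(cfg.n_parents, len(population))
    parents: list[Genotype] = []
    for _ in range(n_parents):
        k = min(cfg.tournament_size, len(population))
        contestants = rng.choice(len(population), size=k, replace=False)
        neutral = contestants[neutral_mask[contestants]]
        pool = neutral if neutral.size else contestants
        parents.append(population[int(pool[rng.integers(pool.size)])])
    return parents


def _make_offspring(
    parents: Sequence[Genotype],
    n_offspring: int,
    cfg: GuidedConfig,
    rng: np.random.Generator,
    history: set[Genotype],
) -> list[Genotype]:
    """Generate offspring: recombinant_fraction by crossover, rest by mutation."""
    out: list[Genotype] = []
    attempts, cap = 0, 100 * max(n_offspring, 1)
    while len(out) < n_offspring and attempts < cap:
        attempts += 1
        if rng.random() < cfg.recombinant_fraction and len(parents) >= 2:
            i, j = rng.choice(len(parents), size=2, replace=False)
            child = one_point_crossover(parents[i], parents[j], rng)
        else:
            child = mutate(parents[int(rng.integers(len(parents)))], cfg.ga, rng)
        if cfg.enforce_novelty and child in history:
            continue
        history.add(child)
        out.append(child)
    return out


def run_guided_evolution(
    start_population: Sequence[Genotype],
    classifier: SequenceClassifier,
    cfg: GuidedConfig,
    rng: np.random.Generator,
    reference: Genotype | None = None,
) -> GuidedResult:
    """Run the guided loop and track mean Hamming distance per round.

    Each round: guided tournament selection -> offspring generation ->
    classification; predicted-neutral offspring form the next round's
    population. The final round generates ``final_population`` candidates
    and returns only those predicted neutral. If a round yields no
    predicted-neutral offspring the loop reports extinction and stops.
    """
    if not start_population:
        raise ValueError("empty starting population")
    reference = reference or start_population[0]
    population = list(start_population)
    history: set[Genotype] = set(population)

    mean_h: list[float] = []
    frac_neutral: list[float] = []
    sizes: list[int] = []
    extinct_at = None

    for rnd in range(1, cfg.n_rounds + 1):
        parents = guided_tournament_select(population, classifier, cfg.ga, rng)
        last = rnd == cfg.n_rounds
        n_offspring = cfg.final_population if last else cfg.ga.population_size
        offspring = _make_offspring(parents, n_offspring, cfg, rng, history)
        if not offspring:
            extinct_at = rnd
            break
        neutral = classifier.predict_neutral(offspring)
        frac_neutral.append(float(neutral.mean()))
        keep = cfg.filter_every_round or last
        survivors = (
            [s for s, ok in zip(offspring, neutral) if ok] if keep else offspring
        )
        if cfg.keep_parents and not last:
            # elitism: selected parents persist so a lean round cannot wipe
            # out the population
            survivors = survivors + [p for p in parents if p not in set(survivors)]
        if not survivors:
            mean_h.append(float(np.mean([hamming(s, reference) for s in offspring])))
            sizes.append(0)
            extinct_at = rnd
            break
        population = survivors
        mean_h.append(float(np.mean([hamming(s, reference) for s in population])))
        sizes.append(len(population))

    return GuidedResult(
        final_population=population,
        mean_hamming=mean_h,
        fraction_neutral=frac_neutral,
        population_sizes=sizes,
        extinct_at_round=extinct_at,
    )
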