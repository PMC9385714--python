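"""Mutational-path accessibility over a combinatorially complete landscape.

A direct mutational path from the all-wild to the all-mutant anchor is an
ordering (permutation) of the N loci; it visits N+1 genotypes, each one
substitution from the previous, with no backtracking. A path is neutral at
threshold t when none of its N-1 strict intermediates falls below t (the
anchors are the known-active endpoints and are excluded by default).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ribonet.landscape import CombinatorialLandscape

MutationalPath = tuple[int, ...]  # permutation of the loci 0..N-1


def sample_unique_paths(
    n_loci: int, n_paths: int, rng: np.random.Generator
) -> list[MutationalPath]:
    """Sample ``n_paths`` unique random locus orderings.

    Uniform permutations, deduplicated until the requested number of unique
    paths is reached. For small N where ``n_paths`` approaches N!, the
    permutations are enumerated exhaustively and subsampled instead.
    """
    total = math.factorial(n_loci)
    if n_paths > total:
        raise ValueError(f"requested {n_paths} paths but only {total} exist")
    if n_paths * 2 >= total:
        pool = list(itertools.permutations(range(n_loci)))
        idx = rng.choice(total, size=n_paths, replace=False)
        return [pool[i] for i in sorted(idx)]
    seen: set[MutationalPath] = set()
    out: list[MutationalPath] = []
    while len(out) < n_paths:
        p = tuple(int(x) for x in rng.permutation(n_loci))
        if p not in seen:
            seen.add(p)
            out.append(p)
    return out


def path_genotype_indices(path: MutationalPath) -> list[int]:
    """Bit indices of the N+1 genotypes visited by a path."""
    idx = [0]
    acc = 0
    for locus in path:
        acc |= 1 << locus
        idx.append(acc)
    return idx


def path_min_activity(
    path: MutationalPath,
    landscape: CombinatorialLandscape,
    include_endpoints: bool = False,
) -> float:
    """Minimum RA along the path's chain of intermediates.

    By default only the N-1 strict intermediates are evaluated; the path is
    neutral at threshold t iff this minimum is >= t.
    """
    idx = path_genotype_indices(path)
    if not include_endpoints:
        idx = idx[1:-1]
    return float(landscape.ra_vector[idx].min())


def path_min_activities(
    paths: Sequence[MutationalPath],
    landscape: CombinatorialLandscape,
    include_endpoints: bool = False,
) -> np.ndarray:
    """Vectorized minimum-RA per path for large path samples."""
    if not paths:
        return np.zeros(0)
    n = landscape.n_loci
    perm = np.asarray(paths, dtype=np.int64)
    bits = np.left_shift(np.int64(1), perm)
    chain = np.bitwise_or.accumulate(bits, axis=1)  # indices after each step
    if not include_endpoints:
        chain = chain[:, : n - 1]
    else:
        chain = np.concatenate(
            [np.zeros((len(paths), 1), dtype=np.int64), chain], axis=1
        )
    return landscape.ra_vector[chain].min(axis=1)


def enumerate_all_paths(n_loci: int) -> list[MutationalPath]:
    """All N! direct paths (exhaustive oracle, small N only)."""
    return list(itertools.permutations(range(n_loci)))


@dataclass
class PathReport:
    table: pd.DataFrame  # threshold, n_evaluable, n_neutral, fraction


def accessibility_curve(
    paths: Sequence[MutationalPath],
    landscape: CombinatorialLandscape,
    thresholds: Sequence[float],
    include_endpoints: bool = False,
) -> PathReport:
    """Fraction of paths neutral at each threshold (non-increasing in t).

    Variants discarded upstream (read-count filters) may be marked NaN in
    the landscape's RA vector; a path through such a genotype is
    non-evaluable and is excluded from both numerator and denominator,
    counted in ``n_non_evaluable``.
    """
    mins = path_min_activities(paths, landscape, include_endpoints)
    evaluable = mins[~np.isnan(mins)]
    n_non_evaluable = int(np.isnan(mins).sum())
    rows = []
    for t in thresholds:
        neutral = int((evaluable >= t).sum())
        rows.append(
            {
                "threshold": t,
                "n_evaluable": evaluable.size,
                "n_non_evaluable": n_non_evaluable,
                "n_neutral": neutral,
                "fraction": neutral / evaluable.size if evaluable.size else float("nan"),
            }
        )
    return PathReport(table=pd.DataFrame(rows))
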