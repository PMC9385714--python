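"""Epistasis analysis: log-additive expectations, directional epistasis,
reciprocal-sign census, and the Walsh--Hadamard decomposition.

Log-additive model
    The expected ln(RA) of a multi-mutant is the sum of the ln(RA) values
    of its constituent single mutants; deviations from this expectation are
    epistasis.

Directional epistasis
    The decay of the neutral fraction with mutation count is fitted to
    ``omega(n) = exp(-alpha * n**beta)``; ``alpha`` is the robustness decay
    (lower = more robust) and ``beta`` the directionality of epistasis
    (beta > 1: excess negative epistasis; beta < 1: excess positive;
    beta = 1: balanced or none).

Reciprocal sign epistasis
    For a pair of genotypes two substitutions apart (ab, AB) with both
    single-mutant intermediates (Ab, aB) present, reciprocal sign epistasis
    holds when both endpoints are fitter than both intermediates or both
    are less fit — the severest form of ruggedness, blocking the direct
    paths between the endpoints.

Walsh--Hadamard decomposition
    On a combinatorially complete biallelic landscape the ln(RA) vector
    ``w`` (in binary genotype order, locus 0 = LSB) maps linearly onto
    epistatic coefficients: relative to the wild type as ``e_rel = G w``
    and background-averaged as ``e_avg = V H w``, where G, H and V follow
    the 2x2 block recursions

        G_{n+1} = [[G_n, 0], [-G_n, G_n]],      G_0 = 1
        H_{n+1} = [[H_n, H_n], [H_n, -H_n]],    H_0 = 1  (Hadamard)
        V_{n+1} = [[V_n / 2, 0], [0, -V_n]],    V_0 = 1  (weighting)

    The order of a coefficient is the popcount of its index (the loci it
    involves). Both maps are invertible, so ``w`` can be reconstructed from
    a truncated coefficient vector to ask how much of the landscape
    low-order interactions explain. The transforms are computed by fast
    in-place butterflies; the dense matrices serve as a brute-force oracle
    for modest N.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.metrics import r2_score

from ribonet.landscape import (
    DEFAULT_LN_RA_FLOOR,
    CombinatorialLandscape,
    Landscape,
)
from ribonet.sequence_core import (
    Genotype,
    Mutation,
    apply_mutations,
    hamming,
    mutations_between,
)

DENSE_MATRIX_CAP = 12


# ---------------------------------------------------------------------------
# log-additive expectation
# ---------------------------------------------------------------------------

class LogAdditiveModel:
    """Epistasis-free expectation from single-mutant activities.

    Holds the RA of every assayed single mutant of a reference sequence
    (at most 3L entries, 105 for the 35-nt core). The expected RA of any
    multi-mutant is the product of its constituent single-mutant RAs
    (a sum in log space); the reference itself maps to 1.
    """

    def __init__(
        self,
        reference: Genotype,
        single_ra: Mapping[Mutation, float],
        ln_floor: float = DEFAULT_LN_RA_FLOOR,
    ):
        self.reference = reference
        self.ln_floor = ln_floor
        self._ln_single = {
            m: float(np.log(max(ra, ln_floor))) for m, ra in single_ra.items()
        }

    @classmethod
    def from_landscape(
        cls, landscape: Landscape, reference: Genotype | None = None, **kwargs
    ) -> "LogAdditiveModel":
        ref = reference or landscape.wild_type
        singles = {}
        for seq, ra in landscape.items():
            muts = mutations_between(ref, seq)
            if len(muts) == 1:
                singles[muts[0]] = ra
        return cls(ref, singles, **kwargs)

    def expected_ra(self, variant: Genotype) -> float:
        """Product of constituent single-mutant RAs; errors if one is missing."""
        total = 0.0
        for m in mutations_between(self.reference, variant):
            if m not in self._ln_single:
                raise KeyError(f"single mutant {m.position}{m.base} not in the model")
            total += self._ln_single[m]
        return float(np.exp(total))

    def expected_ln_ra(self, variant: Genotype) -> float:
        return float(np.log(self.expected_ra(variant)))


def expected_ra_log_additive(variant: Genotype, model: LogAdditiveModel) -> float:
    return model.expected_ra(variant)


def r_squared(observed: Sequence[float], expected: Sequence[float]) -> float:
    """Coefficient of determination, 1 - SS_res/SS_tot; may be negative."""
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if observed.shape != expected.shape or observed.size < 2:
        raise ValueError("need two equal-length vectors of size >= 2")
    if np.allclose(observed, observed[0]):
        raise ValueError("observed vector is constant; R^2 undefined")
    return float(r2_score(observed, expected))


# ---------------------------------------------------------------------------
# neutral fraction by distance and the directional-epistasis fit
# ---------------------------------------------------------------------------

def neutral_fraction_by_distance(
    landscape: Landscape,
    reference: Genotype | None = None,
    threshold: float = 0.2,
    distances: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Fraction of assayed variants neutral at each Hamming distance.

    Returns a table with columns (n, n_total, n_neutral, omega); empty
    distance classes raise if explicitly requested.
    """
    ref = reference or landscape.wild_type
    by_n: dict[int, list[float]] = {}
    for seq, ra in landscape.items():
        by_n.setdefault(hamming(seq, ref), []).append(ra)
    wanted = sorted(by_n) if distances is None else list(distances)
    rows = []
    for n in wanted:
        if n not in by_n:
            raise ValueError(f"no variants at distance {n}")
        ras = np.asarray(by_n[n])
        rows.append(
            {
                "n": n,
                "n_total": ras.size,
                "n_neutral": int((ras >= threshold).sum()),
                "omega": float((ras >= threshold).mean()),
            }
        )
    return pd.DataFrame(rows)


def directional_model(n, alpha, beta):
    """omega(n) = exp(-alpha * n**beta)."""
    return np.exp(-alpha * np.power(np.asarray(n, dtype=float), beta))


@dataclass
class DirectionalFit:
    alpha: float
    beta: float
    alpha_se: float
    beta_se: float
    residuals: np.ndarray

    def omega(self, n):
        return directional_model(n, self.alpha, self.beta)


def fit_directional_epistasis(
    n: Sequence[float],
    omega: Sequence[float],
    sigma: Sequence[float] | None = None,
) -> DirectionalFit:
    """Nonlinear least-squares fit of the directional-epistasis model.

    Initial values alpha=0.5, beta=1.0 with positivity bounds. If
    per-point uncertainties ``sigma`` are supplied they are used as
    absolute weights, so the reported standard errors are calibrated.
    """
    n = np.asarray(n, dtype=float)
    omega = np.asarray(omega, dtype=float)
    if n.size < 2:
        raise ValueError("need at least two distance classes")
    if np.any(omega <= 0) or np.any(omega > 1):
        raise ValueError("omega values must lie in (0, 1]")
    popt, pcov = curve_fit(
        directional_model,
        n,
        omega,
        p0=(0.5, 1.0),
        bounds=([1e-12, 1e-12], [np.inf, np.inf]),
        sigma=None if sigma is None else np.asarray(sigma, dtype=float),
        absolute_sigma=sigma is not None,
        maxfev=10000,
    )
    se = np.sqrt(np.diag(pcov))
    return DirectionalFit(
        alpha=float(popt[0]),
        beta=float(popt[1]),
        alpha_se=float(se[0]),
        beta_se=float(se[1]),
        residuals=omega - directional_model(n, *popt),
    )


# ---------------------------------------------------------------------------
# reciprocal sign epistasis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SquarePair:
    """A distance-2 genotype pair with both single-mutant intermediates."""

    ab: Genotype
    AB: Genotype
    intermediates: tuple[Genotype, Genotype]
    reference_distance: int  # Hamming distance of the closer endpoint to WT


def classify_reciprocal_sign(
    ra_ab: float, ra_AB: float, ra_Ab: float, ra_aB: float
) -> bool:
    """True iff both endpoints beat, or both trail, both intermediates.

    Strict inequalities; the call is symmetric in the endpoints and in the
    intermediates, so it does not depend on which endpoint is the
    reference.
    """
    lo, hi = min(ra_ab, ra_AB), max(ra_ab, ra_AB)
    ilo, ihi = min(ra_Ab, ra_aB), max(ra_Ab, ra_aB)
    return lo > ihi or hi < ilo


def _intermediates(a: Genotype, b: Genotype) -> tuple[Genotype, Genotype]:
    diff = [i for i, (x, y) in enumerate(zip(a, b)) if x != y]
    i, j = diff
    ab1 = a[:i] + b[i] + a[i + 1 :]
    ab2 = a[:j] + b[j] + a[j + 1 :]
    return ab1, ab2


def enumerate_square_pairs(
    landscape: Landscape, wt: Genotype | None = None
) -> list[SquarePair]:
    """All unordered distance-2 pairs whose two intermediates are assayed.

    The endpoint closer to the wild type is designated the reference
    (``ab``); ``reference_distance`` bins the pair by its distance from the
    wild type. Quadratic in the number of assayed genotypes; intended for
    sparse datasets — use :func:`reciprocal_sign_census_complete` for a
    full 2^N landscape.
    """
    wt = wt or landscape.wild_type
    seqs = landscape.sequences()
    dist = {s: hamming(s, wt) for s in seqs}
    pairs: list[SquarePair] = []
    for i in range(len(seqs)):
        a = seqs[i]
        for j in range(i + 1, len(seqs)):
            b = seqs[j]
            if len(a) != len(b) or hamming(a, b) != 2:
                continue
            m1, m2 = _intermediates(a, b)
            if m1 not in landscape or m2 not in landscape:
                continue
            ab, AB = (a, b) if dist[a] <= dist[b] else (b, a)
            pairs.append(
                SquarePair(
                    ab=ab,
                    AB=AB,
                    intermediates=(m1, m2),
                    reference_distance=dist[ab],
                )
            )
    return pairs


def reciprocal_sign_fraction(
    landscape: Landscape, wt: Genotype | None = None
) -> pd.DataFrame:
    """Reciprocal-sign census binned by the reference's distance from WT."""
    pairs = enumerate_square_pairs(landscape, wt)
    rows: dict[int, list[int]] = {}
    for sq in pairs:
        flag = classify_reciprocal_sign(
            landscape.ra(sq.ab),
            landscape.ra(sq.AB),
            landscape.ra(sq.intermediates[0]),
            landscape.ra(sq.intermediates[1]),
        )
        rows.setdefault(sq.reference_distance, []).append(int(flag))
    return pd.DataFrame(
        [
            {
                "reference_distance": d,
                "n_pairs": len(flags),
                "n_reciprocal_sign": int(np.sum(flags)),
                "fraction": float(np.mean(flags)),
            }
            for d, flags in sorted(rows.items())
        ]
    )


def count_square_pairs_complete(n_loci: int) -> int:
    """Distance-2 pair count on a complete biallelic landscape: 2^N C(N,2)/2."""
    from math import comb

    return (1 << n_loci) * comb(n_loci, 2) // 2


def reciprocal_sign_census_complete(
    landscape: CombinatorialLandscape,
) -> pd.DataFrame:
    """Vectorized census over all distance-2 pairs of a complete landscape.

    Every square of the hypercube (choice of two loci plus a background on
    the rest) contributes its two diagonals as distance-2 pairs: {00, 11}
    and {01, 10} at the chosen loci. Binned by the closer endpoint's
    popcount (= Hamming distance from the all-wild anchor).
    """
    N = landscape.n_loci
    ra = landscape.ra_vector
    all_idx = np.arange(1 << N, dtype=np.int64)
    popcount = np.array([bin(i).count("1") for i in range(1 << N)], dtype=np.int64)

    n_pairs = np.zeros(N + 1, dtype=np.int64)
    n_rse = np.zeros(N + 1, dtype=np.int64)
    for i in range(N):
        bi = 1 << i
        for j in range(i + 1, N):
            bj = 1 << j
            bg = all_idx[(all_idx & bi == 0) & (all_idx & bj == 0)]
            g00, g01, g10, g11 = bg, bg | bi, bg | bj, bg | bi | bj
            r00, r01, r10, r11 = ra[g00], ra[g01], ra[g10], ra[g11]
            # diagonal {00, 11}: intermediates 01, 10
            flag = _rse_flags(r00, r11, r01, r10)
            refd = np.minimum(popcount[g00], popcount[g11])
            np.add.at(n_pairs, refd, 1)
            np.add.at(n_rse, refd, flag)
            # diagonal {01, 10}: intermediates 00, 11
            flag = _rse_flags(r01, r10, r00, r11)
            refd = np.minimum(popcount[g01], popcount[g10])
            np.add.at(n_pairs, refd, 1)
            np.add.at(n_rse, refd, flag)

    rows = [
        {
            "reference_distance": d,
            "n_pairs": int(n_pairs[d]),
            "n_reciprocal_sign": int(n_rse[d]),
            "fraction": float(n_rse[d] / n_pairs[d]) if n_pairs[d] else float("nan"),
        }
        for d in range(N + 1)
        if n_pairs[d]
    ]
    return pd.DataFrame(rows)


def _rse_flags(e1, e2, m1, m2):
    lo, hi = np.minimum(e1, e2), np.maximum(e1, e2)
    ilo, ihi = np.minimum(m1, m2), np.maximum(m1, m2)
    return ((lo > ihi) | (hi < ilo)).astype(np.int64)


# ---------------------------------------------------------------------------
# Walsh--Hadamard decomposition
# ---------------------------------------------------------------------------

def build_epistasis_matrices(n_loci: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Dense G, H, V matrices from their 2x2 block recursions (oracle only)."""
    if n_loci > DENSE_MATRIX_CAP:
        raise ValueError(
            f"dense construction capped at N={DENSE_MATRIX_CAP}; use the fast transforms"
        )
    G = np.array([[1.0]])
    H = np.array([[1.0]])
    V = np.array([[1.0]])
    g1 = np.array([[1.0, 0.0], [-1.0, 1.0]])
    h1 = np.array([[1.0, 1.0], [1.0, -1.0]])
    v1 = np.array([[0.5, 0.0], [0.0, -1.0]])
    for _ in range(n_loci):
        G = np.kron(g1, G)
        H = np.kron(h1, H)
        V = np.kron(v1, V)
    return G, H, V


def _butterfly(w: np.ndarray, combine) -> np.ndarray:
    """Apply a 2x2 block transform over every bit level, in place on a copy."""
    x = np.array(w, dtype=np.float64)
    n = x.size
    h = 1
    while h < n:
        x = x.reshape(-1, 2, h)
        lo = x[:, 0, :].copy()
        hi = x[:, 1, :].copy()
        x[:, 0, :], x[:, 1, :] = combine(lo, hi)
        x = x.reshape(n)
        h *= 2
    return x


def fwht(w: np.ndarray) -> np.ndarray:
    """Fast Walsh--Hadamard transform: H w (unnormalized)."""
    return _butterfly(w, lambda lo, hi: (lo + hi, lo - hi))


def g_transform(w: np.ndarray) -> np.ndarray:
    """Fast relative transform: G w."""
    return _butterfly(w, lambda lo, hi: (lo, hi - lo))


def g_inverse_transform(e: np.ndarray) -> np.ndarray:
    """Fast inverse of G (its inverse has the same structure with +G_n)."""
    return _butterfly(e, lambda lo, hi: (lo, hi + lo))


def v_weights(n_loci: int) -> np.ndarray:
    """Diagonal of the weighting matrix V: (1/2)^(N-|i|) * (-1)^|i|."""
    pc = np.array([bin(i).count("1") for i in range(1 << n_loci)])
    return (0.5 ** (n_loci - pc)) * ((-1.0) ** pc)


def interaction_orders(n_loci: int) -> np.ndarray:
    """Order of each coefficient: popcount of its index."""
    return np.array([bin(i).count("1") for i in range(1 << n_loci)], dtype=np.int64)


@dataclass
class WHDecomposition:
    """ln(RA) in binary order with its two epistatic coefficient vectors."""

    n_loci: int
    w: np.ndarray
    e_rel: np.ndarray
    e_avg: np.ndarray
    order: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        idx = np.arange(1 << self.n_loci)
        loci = [
            "+".join(str(b) for b in range(self.n_loci) if i >> b & 1) or "-"
            for i in idx
        ]
        return pd.DataFrame(
            {
                "term_index": idx,
                "order": self.order,
                "loci": loci,
                "e_avg": self.e_avg,
                "e_rel": self.e_rel,
            }
        )


def wh_decompose(w: Sequence[float], n_loci: int | None = None) -> WHDecomposition:
    """Decompose a complete landscape's ln(RA) vector into epistatic terms.

    ``w`` must have length 2^N and be sorted in binary genotype order.
    Computed with fast butterflies; agrees with the dense-matrix oracle.
    """
    w = np.asarray(w, dtype=np.float64)
    n = w.size
    if n_loci is None:
        n_loci = int(n).bit_length() - 1
    if n != 1 << n_loci or not np.all(np.isfinite(w)):
        raise ValueError("w must have finite entries and length 2^N")
    e_rel = g_transform(w)
    e_avg = v_weights(n_loci) * fwht(w)
    return WHDecomposition(
        n_loci=n_loci,
        w=w,
        e_rel=e_rel,
        e_avg=e_avg,
        order=interaction_orders(n_loci),
    )


def wh_compose_avg(e_avg: np.ndarray, n_loci: int) -> np.ndarray:
    """Invert the background-averaged map: w = H^{-1} V^{-1} e_avg."""
    e_avg = np.asarray(e_avg, dtype=np.float64)
    return fwht(e_avg / v_weights(n_loci)) / (1 << n_loci)


def reconstruct_truncated(
    dec: WHDecomposition, max_order: int, basis: str = "averaged"
) -> np.ndarray:
    """Reconstruct ln(RA) keeping only coefficients up to ``max_order``.

    ``basis`` selects the background-averaged (``averaged``) or
    WT-relative (``relative``) coefficients; at ``max_order == N`` the
    original vector is recovered exactly.
    """
    if not 0 <= max_order <= dec.n_loci:
        raise ValueError("max_order outside 0..N")
    keep = dec.order <= max_order
    if basis == "averaged":
        return wh_compose_avg(np.where(keep, dec.e_avg, 0.0), dec.n_loci)
    if basis == "relative":
        return g_inverse_transform(np.where(keep, dec.e_rel, 0.0))
    raise ValueError("basis must be 'averaged' or 'relative'")


def term_fraction(n_loci: int, max_order: int) -> float:
    """Fraction of all 2^N terms with order <= max_order."""
    from math import comb

    if not 0 <= max_order <= n_loci:
        raise ValueError("max_order outside 0..N")
    return sum(comb(n_loci, j) for j in range(max_order + 1)) / (1 << n_loci)


def reconstruction_report(
    dec: WHDecomposition,
    basis: str = "averaged",
    min_distance_excess: bool = False,
) -> pd.DataFrame:
    """R^2 between observed and truncated-reconstruction ln(RA) per order.

    With ``min_distance_excess`` the R^2 at order k is computed only on
    variants whose Hamming distance from the all-wild anchor exceeds k (a
    robustness check: the result should be qualitatively unchanged).
    """
    rows = []
    pc = interaction_orders(dec.n_loci)  # popcount doubles as genotype distance
    for k in range(dec.n_loci + 1):
        rec = reconstruct_truncated(dec, k, basis)
        if min_distance_excess:
            mask = pc > k
            r2 = (
                r_squared(dec.w[mask], rec[mask])
                if mask.sum() >= 2 and not np.allclose(dec.w[mask], dec.w[mask][0])
                else float("nan")
            )
        else:
            r2 = r_squared(dec.w, rec)
        rows.append(
            {
                "max_order": k,
                "r2": r2,
                "term_fraction": term_fraction(dec.n_loci, k),
            }
        )
    return pd.DataFrame(rows)
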