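"""Log-additive model, directional fit, reciprocal-sign census, WH transform."""

import itertools
import math

import numpy as np
import pytest

from ribonet import epistasis as ep
from ribonet.landscape import CombinatorialLandscape, Landscape
from ribonet.sequence_core import decode_binary, enumerate_single_mutants, hamming
from ribonet.synthetic_data import (
    SpectrumSpec,
    default_locus_map,
    simulate_additive_landscape,
    simulate_landscape_from_spectrum,
)


class TestLogAdditiveModel:
    def test_wild_type_maps_to_one(self, wt):
        singles = {m: 0.5 for s in [wt] for m in []}
        land = Landscape({wt: 1.0, **{s: 0.5 for s in enumerate_single_mutants(wt)[:5]}}, wt)
        model = ep.LogAdditiveModel.from_landscape(land)
        assert model.expected_ra(wt) == pytest.approx(1.0)

    def test_double_mutant_product(self, wt):
        s1, s2 = enumerate_single_mutants(wt)[0], enumerate_single_mutants(wt)[4]
        double = s2[:0] + s1[0] + s2[1:]
        assert hamming(double, wt) == 2
        land = Landscape({wt: 1.0, s1: 0.5, s2: 0.4}, wt)
        model = ep.LogAdditiveModel.from_landscape(land)
        assert model.expected_ra(double) == pytest.approx(0.2)

    def test_missing_single_raises(self, wt):
        land = Landscape({wt: 1.0}, wt)
        model = ep.LogAdditiveModel.from_landscape(land)
        with pytest.raises(KeyError):
            model.expected_ra(enumerate_single_mutants(wt)[0])

    def test_perfect_on_additive_landscape(self):
        land = simulate_additive_landscape(6, np.random.default_rng(0))
        model = ep.LogAdditiveModel.from_landscape(land)
        obs, exp = [], []
        for seq, ra in land.items():
            if hamming(seq, land.wild_type) >= 2:
                obs.append(np.log(ra))
                exp.append(model.expected_ln_ra(seq))
        assert ep.r_squared(obs, exp) == pytest.approx(1.0, abs=1e-9)


class TestRSquared:
    def test_reference_cases(self):
        assert ep.r_squared([1, 2, 3], [1, 2, 3]) == 1.0
        assert ep.r_squared([1, 2, 3], [2, 2, 2]) == 0.0
        assert ep.r_squared([1, 2, 3], [1, 2, 4]) == pytest.approx(0.5)

    def test_constant_observed_raises(self):
        with pytest.raises(ValueError):
            ep.r_squared([1, 1, 1], [1, 2, 3])


class TestNeutralFraction:
    def test_known_fractions_recovered(self, rng):
        lmap = default_locus_map(4)
        # construct per-distance neutral fractions by hand
        ra = np.zeros(16)
        pc = ep.interaction_orders(4)
        for k in range(5):
            idx = np.flatnonzero(pc == k)
            n_neutral = {0: 1, 1: 2, 2: 3, 3: 1, 4: 1}[k]
            ra[idx] = 0.05
            ra[idx[:n_neutral]] = 0.9
        land = CombinatorialLandscape(ra, lmap)
        tab = ep.neutral_fraction_by_distance(land, threshold=0.2)
        assert list(tab["n_neutral"]) == [1, 2, 3, 1, 1]
        assert tab["omega"].iloc[0] == 1.0

    def test_all_neutral(self):
        lmap = default_locus_map(3)
        land = CombinatorialLandscape(np.ones(8), lmap)
        tab = ep.neutral_fraction_by_distance(land, threshold=0.2)
        assert (tab["omega"] == 1.0).all()


class TestDirectionalFit:
    def test_noise_free_recovery(self):
        n = np.array([1, 2, 3])
        omega = ep.directional_model(n, 0.5, 1.2)
        fit = ep.fit_directional_epistasis(n, omega)
        assert fit.alpha == pytest.approx(0.5, abs=1e-4)
        assert fit.beta == pytest.approx(1.2, abs=1e-4)

    def test_additive_landscape_beta_near_one(self):
        """Without epistasis the decay of the neutral fraction has beta ~ 1."""
        rng = np.random.default_rng(2)
        # additive per-locus survival: omega(n) = p^n exactly -> beta = 1
        p = 0.7
        n = np.array([1, 2, 3])
        fit = ep.fit_directional_epistasis(n, p**n)
        assert fit.beta == pytest.approx(1.0, abs=1e-6)
        assert fit.alpha == pytest.approx(-np.log(p), abs=1e-6)

    def test_recovery_under_binomial_noise(self):
        """alpha, beta within 3 calibrated SEs under sampling noise."""
        alpha, beta, m = 0.5, 1.2, 1000
        n = np.array([1, 2, 3])
        truth = ep.directional_model(n, alpha, beta)
        ok = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            omega = rng.binomial(m, truth) / m
            sigma = np.sqrt(truth * (1 - truth) / m)
            fit = ep.fit_directional_epistasis(n, omega, sigma=sigma)
            ok += (
                abs(fit.alpha - alpha) < 3 * fit.alpha_se
                and abs(fit.beta - beta) < 3 * fit.beta_se
            )
        assert ok >= n_seeds - 1


class TestReciprocalSign:
    def test_classification_rules(self):
        assert ep.classify_reciprocal_sign(1.0, 1.0, 0.1, 0.1)
        assert ep.classify_reciprocal_sign(0.1, 0.1, 1.0, 1.0)
        assert not ep.classify_reciprocal_sign(1.0, 0.1, 0.5, 0.5)
        # reference-choice symmetry
        assert ep.classify_reciprocal_sign(1.0, 0.9, 0.1, 0.2) == \
            ep.classify_reciprocal_sign(0.9, 1.0, 0.2, 0.1)

    def test_pair_count_complete_n2(self):
        lmap = default_locus_map(2)
        land = CombinatorialLandscape([1.0, 0.5, 0.5, 1.0], lmap)
        pairs = ep.enumerate_square_pairs(land)
        assert len(pairs) == 2 == ep.count_square_pairs_complete(2)

    @pytest.mark.parametrize("n", [3, 4, 5])
    def test_closed_form_counts(self, n):
        lmap = default_locus_map(n)
        land = CombinatorialLandscape(np.ones(1 << n), lmap)
        assert len(ep.enumerate_square_pairs(land)) == ep.count_square_pairs_complete(n)

    def test_sparse_missing_intermediate_excluded(self, wt):
        lmap = default_locus_map(2)
        # drop one intermediate (index 1): only the {01,10} diagonal's pair
        # with intact intermediates survives... both pairs need both
        # intermediates, so none survive for {00,11}; {01,10} needs 00 and 11
        seqs = {decode_binary(i, lmap): 1.0 for i in (0, 2, 3)}
        land = Landscape(seqs, lmap.wild_sequence)
        assert ep.enumerate_square_pairs(land) == []

    def test_additive_landscape_has_none(self):
        land = simulate_additive_landscape(5, np.random.default_rng(3))
        census = ep.reciprocal_sign_census_complete(land)
        assert census["n_reciprocal_sign"].sum() == 0

    @pytest.mark.parametrize("n,seed", [(4, 0), (6, 1)])
    def test_vectorized_census_matches_brute_force(self, n, seed):
        """Independent O(4^N) pairwise oracle vs the vectorized census."""
        rng = np.random.default_rng(seed)
        lmap = default_locus_map(n)
        land = CombinatorialLandscape(rng.uniform(0, 1, size=1 << n), lmap)
        census = ep.reciprocal_sign_census_complete(land)
        # oracle: enumerate index pairs, classify naively
        brute = {}
        for i, j in itertools.combinations(range(1 << n), 2):
            if bin(i ^ j).count("1") != 2:
                continue
            bits = [1 << b for b in range(n) if (i ^ j) >> b & 1]
            m1, m2 = i ^ bits[0], i ^ bits[1]
            d = min(bin(i).count("1"), bin(j).count("1"))
            flag = ep.classify_reciprocal_sign(
                land.ra_vector[i], land.ra_vector[j],
                land.ra_vector[m1], land.ra_vector[m2],
            )
            tot, rse = brute.get(d, (0, 0))
            brute[d] = (tot + 1, rse + flag)
        for row in census.itertuples():
            assert brute[row.reference_distance] == (row.n_pairs, row.n_reciprocal_sign)


class TestWalshHadamard:
    def test_base_case_matrices(self):
        G, H, V = ep.build_epistasis_matrices(1)
        assert np.array_equal(H, [[1, 1], [1, -1]])
        assert np.array_equal(G, [[1, 0], [-1, 1]])
        assert np.array_equal(V, [[0.5, 0], [0, -1]])

    def test_dense_cap(self):
        with pytest.raises(ValueError):
            ep.build_epistasis_matrices(13)

    @pytest.mark.parametrize("n", [2, 4, 8])
    def test_fast_matches_dense_oracle(self, n):
        rng = np.random.default_rng(n)
        w = rng.normal(size=1 << n)
        G, H, V = ep.build_epistasis_matrices(n)
        dec = ep.wh_decompose(w)
        assert np.abs(dec.e_rel - G @ w).max() < 1e-9
        assert np.abs(dec.e_avg - V @ H @ w).max() < 1e-9

    @pytest.mark.parametrize("n", [4, 10, 16])
    def test_round_trip_inversion(self, n):
        rng = np.random.default_rng(n)
        w = rng.normal(size=1 << n)
        dec = ep.wh_decompose(w)
        assert np.abs(ep.wh_compose_avg(dec.e_avg, n) - w).max() < 1e-9
        assert np.abs(ep.g_inverse_transform(dec.e_rel) - w).max() < 1e-9

    def test_constant_vector_is_pure_order_zero(self):
        dec = ep.wh_decompose(np.full(32, 2.5))
        nz = np.flatnonzero(np.abs(dec.e_avg) > 1e-12)
        assert list(nz) == [0]
        assert dec.e_avg[0] == pytest.approx(2.5)

    def test_additive_vector_has_no_higher_orders(self):
        n = 6
        rng = np.random.default_rng(4)
        effects = rng.normal(size=n)
        idx = np.arange(1 << n)
        bits = (idx[:, None] >> np.arange(n)) & 1
        w = bits @ effects + 0.3
        dec = ep.wh_decompose(w)
        assert np.abs(dec.e_avg[dec.order >= 2]).max() < 1e-10
        assert np.abs(dec.e_rel[dec.order >= 2]).max() < 1e-10

    def test_term_counts_per_order(self):
        dec = ep.wh_decompose(np.zeros(1 << 6))
        for k in range(7):
            assert int((dec.order == k).sum()) == math.comb(6, k)


class TestTruncatedReconstruction:
    def test_full_order_recovers_exactly(self):
        rng = np.random.default_rng(8)
        w = rng.normal(size=256)
        dec = ep.wh_decompose(w)
        for basis in ("averaged", "relative"):
            rec = ep.reconstruct_truncated(dec, 8, basis)
            assert np.abs(rec - w).max() < 1e-9
            assert ep.r_squared(w, rec) == pytest.approx(1.0)

    def test_order_zero_is_mean_only(self):
        rng = np.random.default_rng(9)
        w = rng.normal(size=64)
        dec = ep.wh_decompose(w)
        rec = ep.reconstruct_truncated(dec, 0, "averaged")
        # averaged order-0 reconstruction is the landscape mean everywhere
        assert np.allclose(rec, w.mean())
        assert ep.r_squared(w, rec) == pytest.approx(0.0, abs=1e-9)

    def test_low_order_spectrum_exact_at_its_order(self):
        spec = SpectrumSpec(n_loci=8, terms_per_order={1: 6, 2: 8, 3: 5})
        land, e_true = simulate_landscape_from_spectrum(
            spec, np.random.default_rng(10)
        )
        dec = ep.wh_decompose(land.ln_ra_vector(floor=1e-12))
        r3 = ep.r_squared(dec.w, ep.reconstruct_truncated(dec, 3))
        r2 = ep.r_squared(dec.w, ep.reconstruct_truncated(dec, 2))
        assert r3 == pytest.approx(1.0, abs=1e-6)
        assert r2 < 1.0 - 1e-4

    def test_relative_order1_equals_log_additive(self):
        """Truncating the WT-relative basis at order 1 IS the log-additive
        model, inside the combinatorial subspace."""
        rng = np.random.default_rng(11)
        lmap = default_locus_map(5)
        land = CombinatorialLandscape(np.exp(rng.normal(0, 0.5, size=32)), lmap)
        # normalize so the wild type has RA exactly 1
        ra = land.ra_vector / land.ra_vector[0]
        land = CombinatorialLandscape(ra, lmap)
        dec = ep.wh_decompose(land.ln_ra_vector(floor=1e-12))
        rec1 = ep.reconstruct_truncated(dec, 1, "relative")
        model = ep.LogAdditiveModel.from_landscape(land, ln_floor=1e-12)
        for i in range(32):
            seq = decode_binary(i, lmap)
            assert rec1[i] == pytest.approx(model.expected_ln_ra(seq), abs=1e-9)

    def test_report_monotone_tail_and_term_fraction(self):
        spec = SpectrumSpec(n_loci=6, terms_per_order={1: 4, 2: 4})
        land, _ = simulate_landscape_from_spectrum(spec, np.random.default_rng(12))
        dec = ep.wh_decompose(land.ln_ra_vector(floor=1e-12))
        report = ep.reconstruction_report(dec)
        assert report["r2"].iloc[-1] == pytest.approx(1.0)
        assert report["term_fraction"].iloc[-1] == 1.0


class TestTermFraction:
    def test_sixteen_locus_low_order_share(self):
        frac = ep.term_fraction(16, 2)
        assert frac == pytest.approx(137 / 65536)
        assert f"{100 * frac:.1f}%" == "0.2%"

    @pytest.mark.parametrize("n,k,expected", [(3, 1, 0.5), (5, 5, 1.0), (4, 0, 1 / 16)])
    def test_small_cases(self, n, k, expected):
        assert ep.term_fraction(n, k) == pytest.approx(expected)
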