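import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lhdnet as lhd

from conftest import random_network


def replicate_heats(lap, net, gene, seed_size, t, rng_seed, n_perm):
    """Independent re-derivation of the permutation replicate heats at a node."""
    rng = np.random.default_rng(rng_seed)
    idx = net.index[gene]
    heats = []
    for _ in range(n_perm):
        picked = rng.choice(net.n_nodes, size=seed_size, replace=False)
        h0 = np.zeros(net.n_nodes)
        h0[picked] = 1.0 / seed_size
        heats.append(float(lap.apply_exp_neg(h0, t)[idx]))
    return heats


@pytest.fixture(scope="module")
def setup():
    rng = np.random.default_rng(42)
    net = random_network(rng, 60, p=0.1)
    lap = lhd.build_laplacian(net)
    return net, lap


@pytest.fixture(scope="module")
def screen_inputs(planted):
    spec, net, membership, catalog, seeds = planted
    lap = lhd.build_laplacian(net)
    h0 = lhd.initial_heat(net, seeds)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        heat, t, _ = lhd.propagate_until_stable(
            lap, h0, lhd.DiffusionConfig(), net=net
        )
        cands = lhd.select_candidates(net, heat, seeds, lhd.DiffusionConfig())
    return net, lap, seeds, catalog, cands, t, membership


class TestPermutationPvalues:
    def test_pvalue_is_exceed_count_over_n(self, setup):
        """p(g) = Heat_> / n: planting the actual heat at the k-th largest
        replicate heat must give exactly (k-1)/n, e.g. 25/500 -> 0.05."""
        net, lap = setup
        gene, t, n_perm = net.nodes[7], 2.0, 500
        heats = sorted(
            replicate_heats(lap, net, gene, 5, t, rng_seed=9, n_perm=n_perm),
            reverse=True,
        )
        # actual heat strictly between the 25th and 26th largest replicates
        actual = (heats[24] + heats[25]) / 2
        cfg = lhd.ScreenConfig(n_permutations=n_perm, rng_seed=9)
        pv = lhd.permutation_pvalues(lap, net, [(gene, actual)], 5, t, cfg)
        assert pv[gene] == 25 / 500 == 0.05

    def test_top_candidate_gets_zero(self, setup):
        net, lap = setup
        gene, t = net.nodes[3], 2.0
        heats = replicate_heats(lap, net, gene, 5, t, rng_seed=11, n_perm=200)
        cfg = lhd.ScreenConfig(n_permutations=200, rng_seed=11)
        pv = lhd.permutation_pvalues(
            lap, net, [(gene, max(heats) + 1e-9)], 5, t, cfg
        )
        assert pv[gene] == 0.0

    def test_exact_tie_not_counted(self, setup):
        """A replicate heat exactly equal to the actual heat is not an
        exceedance (strict inequality)."""
        net, lap = setup
        gene, t = net.nodes[3], 2.0
        heats = replicate_heats(lap, net, gene, 5, t, rng_seed=13, n_perm=100)
        top = max(heats)
        cfg = lhd.ScreenConfig(n_permutations=100, rng_seed=13)
        pv = lhd.permutation_pvalues(lap, net, [(gene, top)], 5, t, cfg)
        below = pv[gene]
        pv2 = lhd.permutation_pvalues(
            lap, net, [(gene, np.nextafter(top, 0.0))], 5, t, cfg
        )
        assert below == 0.0
        assert pv2[gene] == 1 / 100

    def test_plus_one_estimator(self, setup):
        net, lap = setup
        gene, t = net.nodes[3], 2.0
        heats = replicate_heats(lap, net, gene, 5, t, rng_seed=13, n_perm=100)
        cfg = lhd.ScreenConfig(n_permutations=100, rng_seed=13, plus_one_pvalues=True)
        pv = lhd.permutation_pvalues(
            lap, net, [(gene, max(heats) + 1e-9)], 5, t, cfg
        )
        assert pv[gene] == 1 / 101

    def test_reproducible_and_order_invariant(self, setup):
        net, lap = setup
        cands = [(net.nodes[i], 0.01 + 0.001 * i) for i in range(6)]
        cfg = lhd.ScreenConfig(n_permutations=50, rng_seed=5)
        pv1 = lhd.permutation_pvalues(lap, net, cands, 4, 1.0, cfg)
        pv2 = lhd.permutation_pvalues(lap, net, list(reversed(cands)), 4, 1.0, cfg)
        assert pv1 == pv2

    def test_multiples_of_one_over_n(self, setup):
        net, lap = setup
        cands = [(g, 0.016) for g in net.nodes[:10]]
        cfg = lhd.ScreenConfig(n_permutations=40, rng_seed=2)
        pv = lhd.permutation_pvalues(lap, net, cands, 4, 1.0, cfg)
        for p in pv.values():
            assert 0.0 <= p <= 1.0
            assert (p * 40) == int(round(p * 40))

    def test_replicates_reuse_operator(self, setup):
        """500 replicates cost 500 heat-kernel applications on the one
        existing operator; no per-replicate Laplacian rebuilds."""
        net, lap = setup
        before = lap.n_apply_calls
        cfg = lhd.ScreenConfig(n_permutations=37, rng_seed=1)
        lhd.permutation_pvalues(lap, net, [(net.nodes[0], 0.5)], 3, 1.0, cfg)
        assert lap.n_apply_calls - before == 37

    def test_oversized_seed_set_rejected(self, setup):
        net, lap = setup
        cfg = lhd.ScreenConfig(n_permutations=10, rng_seed=1)
        with pytest.raises(ValueError, match="seed_size"):
            lhd.permutation_pvalues(
                lap, net, [(net.nodes[0], 0.5)], net.n_nodes + 1, 1.0, cfg
            )


class TestMaxAssociationScore:
    def test_max_over_reference_edges(self, star_net):
        seeds = lhd.SeedSet("x", ["n1", "n2"])
        assert lhd.max_association_score(star_net, "g", seeds) == 950

    def test_no_reference_edge_gives_zero(self, star_net):
        seeds = lhd.SeedSet("x", ["iso"])
        assert lhd.max_association_score(star_net, "g", seeds) == 0

    def test_self_excluded_from_reference(self, star_net):
        seeds = lhd.SeedSet("x", ["n1", "n2"])
        # n1 is itself a reference gene; only its edges to other refs count
        assert lhd.max_association_score(star_net, "n1", seeds) == 450

    def test_adjacent_seed_lower_bound(self, planted):
        _, net, _, _, seeds = planted
        for gene in net.nodes[:30]:
            if gene in seeds.genes:
                continue
            confs = [
                c for nb, c in net.neighbors(gene).items() if nb in seeds.genes
            ]
            if confs:
                assert lhd.max_association_score(net, gene, seeds) == max(confs)


class TestLinkage:
    def test_identical_vectors(self):
        v = np.array([1.0, 2.0, 3.0])
        assert lhd.linkage(v, v) == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        assert lhd.linkage(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 0.0

    def test_worked_cosine(self):
        assert lhd.linkage(np.array([3.0, 4.0]), np.array([4.0, 3.0])) == pytest.approx(
            24 / 25
        )

    def test_zero_vector_defined_as_zero(self):
        assert lhd.linkage(np.zeros(3), np.array([1.0, 0.0, 0.0])) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            lhd.linkage(np.ones(2), np.ones(3))

    @pytest.mark.parametrize("seed", range(3))
    def test_symmetric_kernel(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.random(8), rng.random(8)
        assert abs(lhd.linkage(a, b) - lhd.linkage(b, a)) <= 1e-12

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        vals=st.lists(
            st.floats(min_value=0.0, max_value=300.0), min_size=2, max_size=12
        ),
        scale=st.floats(min_value=0.1, max_value=10.0),
    )
    def test_bounded_symmetric_and_scale_invariant(self, vals, scale):
        """Enrichment profiles are nonnegative, so their cosine lies in
        [0, 1], is symmetric, and ignores overall profile magnitude."""
        rng = np.random.default_rng(len(vals))
        a = np.asarray(vals)
        b = rng.random(len(vals)) * 300
        psi = lhd.linkage(a, b)
        assert 0.0 <= psi <= 1.0 + 1e-12
        assert psi == pytest.approx(lhd.linkage(b, a), abs=1e-12)
        assert psi == pytest.approx(lhd.linkage(a * scale, b), rel=1e-9)


class TestMaxFunctionScore:
    def test_identical_profile_reference(self):
        profiles = {"g": np.array([1.0, 2.0]), "r": np.array([1.0, 2.0])}
        seeds = lhd.SeedSet("x", ["r"])
        assert lhd.max_function_score("g", seeds, profiles) == pytest.approx(1.0)

    def test_orthogonal_references(self):
        profiles = {
            "g": np.array([1.0, 0.0]),
            "r1": np.array([0.0, 1.0]),
            "r2": np.array([0.0, 2.0]),
        }
        seeds = lhd.SeedSet("x", ["r1", "r2"])
        assert lhd.max_function_score("g", seeds, profiles) == 0.0

    def test_takes_maximum(self):
        profiles = {
            "g": np.array([3.0, 4.0]),
            "r1": np.array([-4.0, 3.0]),
            "r2": np.array([4.0, 3.0]),
        }
        seeds = lhd.SeedSet("x", ["r1", "r2"])
        assert lhd.max_function_score("g", seeds, profiles) == pytest.approx(0.96)

    def test_no_usable_reference_is_error(self):
        profiles = {"g": np.ones(2)}
        seeds = lhd.SeedSet("x", ["g"])
        with pytest.raises(ValueError):
            lhd.max_function_score("g", seeds, profiles)


class TestRunScreen:
    def test_vacuous_thresholds_keep_everyone(self, screen_inputs):
        net, lap, seeds, catalog, cands, t, _ = screen_inputs
        cfg = lhd.ScreenConfig(
            n_permutations=20, p_cutoff=1.1, mas_cutoff=0, mfs_cutoff=0.0, rng_seed=0
        )
        tab = lhd.run_screen(
            cands, lap, net, seeds, [catalog], lhd.EnrichmentContext(), cfg, t
        )
        counts = tab.stage_counts
        assert (
            counts["candidate"]
            == counts["permutation"]
            == counts["association"]
            == counts["function"]
            == len(cands)
        )

    def test_zero_p_cutoff_eliminates_everyone(self, screen_inputs):
        net, lap, seeds, catalog, cands, t, _ = screen_inputs
        cfg = lhd.ScreenConfig(n_permutations=20, p_cutoff=0.0, rng_seed=0)
        tab = lhd.run_screen(
            cands, lap, net, seeds, [catalog], lhd.EnrichmentContext(), cfg, t
        )
        assert tab.stage_counts["permutation"] == 0
        assert tab.survivors() == []

    def test_planted_fixture_counts_and_enrichment(self, screen_inputs):
        net, lap, seeds, catalog, cands, t, membership = screen_inputs
        cfg = lhd.ScreenConfig(rng_seed=0)
        tab = lhd.run_screen(
            cands, lap, net, seeds, [catalog], lhd.EnrichmentContext(), cfg, t
        )
        c = tab.stage_counts
        assert (
            c["candidate"] > c["permutation"] >= c["association"] >= c["function"] > 0
        )
        # survivor overlap with the planted module is hypergeometrically
        # extreme: brute-force tail P(X >= k) among candidate genes
        survivors = tab.survivors()
        module = {g for g, m in membership.items() if m == 0}
        cand_genes = [g for g, _ in cands]
        N, M = len(cand_genes), sum(1 for g in cand_genes if g in module)
        n, k = len(survivors), sum(1 for g in survivors if g in module)
        tail = sum(
            math.comb(M, j) * math.comb(N - M, n - j) / math.comb(N, n)
            for j in range(k, min(n, M) + 1)
        )
        assert tail < 1e-4

    def test_pvalues_are_grid_multiples(self, screen_inputs):
        net, lap, seeds, catalog, cands, t, _ = screen_inputs
        cfg = lhd.ScreenConfig(n_permutations=50, rng_seed=3)
        tab = lhd.run_screen(
            cands, lap, net, seeds, [catalog], lhd.EnrichmentContext(), cfg, t
        )
        scaled = tab.table["p_value"] * 50
        assert np.allclose(scaled, np.round(scaled))
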