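import itertools
import warnings

import numpy as np
import pytest

from ssrkit import admixture
from ssrkit.admixture import (
    align_runs_greedy,
    assign_memberships,
    evanno,
    hierarchical_rounds,
    mixture_loglik,
    run_admixture,
    run_k_scan,
)
from ssrkit.genotypes import GenotypeError, GenotypeMatrix


def two_pop_gm(n_per_pop=30, n_loci=10, hybrids=0, seed=0):
    """Two populations fixed for different alleles at every locus, plus
    optional F1 hybrids (one allele from each)."""
    ids, calls, truth = [], [], []
    for i in range(n_per_pop):
        ids.append(f"P1_{i:02d}")
        calls.append([(100, 100)] * n_loci)
        truth.append((1.0, 0.0))
    for i in range(n_per_pop):
        ids.append(f"P2_{i:02d}")
        calls.append([(120, 120)] * n_loci)
        truth.append((0.0, 1.0))
    for i in range(hybrids):
        ids.append(f"F1_{i:02d}")
        calls.append([(100, 120)] * n_loci)
        truth.append((0.5, 0.5))
    gm = GenotypeMatrix.from_calls(
        ids, [f"L{j}" for j in range(n_loci)], calls
    )
    return gm, np.array(truth)


def best_perm_mae(q, truth):
    k = q.shape[1]
    return min(
        float(np.abs(q[:, list(p)] - truth).mean())
        for p in itertools.permutations(range(k))
    )


class TestSampler:
    def test_k1_exact_ones(self):
        gm, _ = two_pop_gm(5, 4)
        run = run_admixture(gm, 1, burnin=50, iters=200, seed=0)
        assert np.array_equal(run.q, np.ones((gm.n_accessions, 1)))

    def test_q_rows_sum_to_one(self):
        gm, _ = two_pop_gm(10, 6)
        run = run_admixture(gm, 3, burnin=100, iters=500, seed=1)
        assert np.allclose(run.q.sum(axis=1), 1.0, atol=1e-9)
        assert (run.q >= 0).all() and (run.p >= 0).all()
        assert np.isfinite(run.ln_pd)

    @pytest.mark.parametrize("seed", range(5))
    def test_two_pop_recovery(self, seed):
        gm, truth = two_pop_gm(30, 10)
        run = run_admixture(gm, 2, burnin=300, iters=1500, seed=seed)
        assert float(run.q.max(axis=1).mean()) >= 0.95
        # exact label agreement after permutation
        hard_truth = truth.argmax(axis=1)
        best = min(
            (
                sum(
                    int(a != b)
                    for a, b in zip(run.q[:, list(p)].argmax(axis=1), hard_truth)
                )
                for p in itertools.permutations(range(2))
            )
        )
        assert best == 0

    def test_f1_hybrids_near_half(self):
        maes = []
        for seed in range(3):
            gm, truth = two_pop_gm(25, 10, hybrids=10, seed=seed)
            run = run_admixture(gm, 2, burnin=300, iters=1500, seed=seed)
            hyb = truth[:, 0] == 0.5
            maes.append(best_perm_mae(run.q[hyb], truth[hyb]))
        assert float(np.mean(maes)) < 0.15

    def test_seed_mandatory(self):
        gm, _ = two_pop_gm(4, 3)
        with pytest.raises(GenotypeError, match="seed"):
            run_admixture(gm, 2, burnin=10, iters=50)

    def test_bad_k(self):
        gm, _ = two_pop_gm(4, 3)
        with pytest.raises(GenotypeError):
            run_admixture(gm, 0, burnin=10, iters=50, seed=0)

    def test_no_recording_window(self):
        gm, _ = two_pop_gm(4, 3)
        with pytest.raises(GenotypeError):
            run_admixture(gm, 2, burnin=100, iters=5, seed=0, thin=10)

    def test_reproducible(self):
        gm, _ = two_pop_gm(8, 5)
        r1 = run_admixture(gm, 2, burnin=100, iters=400, seed=9)
        r2 = run_admixture(gm, 2, burnin=100, iters=400, seed=9)
        assert np.array_equal(r1.q, r2.q)
        assert r1.ln_pd == r2.ln_pd

    def test_label_switch_invariance_of_likelihood(self):
        gm, _ = two_pop_gm(10, 6)
        run = run_admixture(gm, 3, burnin=100, iters=400, seed=2)
        from ssrkit.admixture import _copies

        ind, loc, al, _ = _copies(gm)
        base = mixture_loglik(run.q, run.p, ind, loc, al)
        perm = [2, 0, 1]
        permuted = mixture_loglik(run.q[:, perm], run.p[perm], ind, loc, al)
        assert permuted == pytest.approx(base, abs=1e-9)

    def test_missing_copies_skipped(self):
        calls = [[(100, 100), None], [(120, 120), (100, 120)]]
        gm = GenotypeMatrix.from_calls(["A", "B"], ["L1", "L2"], calls)
        run = run_admixture(gm, 2, burnin=50, iters=200, seed=0)
        assert np.isfinite(run.ln_pd)


class TestEvanno:
    def test_hand_computed(self):
        # mean lnPD (-1000, -800, -790, -789) for K=1..4, sd at K=2 exactly 5
        runs = {
            1: [-1001.0, -999.0],
            2: [-805.0, -800.0, -795.0],
            3: [-791.0, -789.0],
            4: [-790.0, -788.0],
        }
        tab = evanno(runs)
        assert tab.l_prime[2] == pytest.approx(200.0, abs=1e-9)
        assert tab.l_second[2] == pytest.approx(190.0, abs=1e-9)
        assert tab.delta_k[2] == pytest.approx(38.0, abs=1e-9)
        assert tab.best_k == 2

    def test_linear_lnpd_gives_zero(self):
        runs = {k: [-1000.0 + 10 * k + e for e in (-1.0, 1.0)] for k in range(1, 6)}
        tab = evanno(runs)
        assert all(v == pytest.approx(0.0, abs=1e-9) for v in tab.delta_k.values())

    def test_undefined_at_ends(self):
        runs = {k: [float(-k), float(-k) + 1] for k in (1, 2, 3)}
        tab = evanno(runs)
        assert 1 not in tab.delta_k and 3 not in tab.delta_k
        assert set(tab.delta_k) == {2}

    def test_zero_sd_inf_with_warning(self):
        runs = {1: [-10.0, -10.0], 2: [-5.0, -5.0], 3: [-4.0, -4.0]}
        with pytest.warns(UserWarning, match="zero sd"):
            tab = evanno(runs)
        assert tab.delta_k[2] == float("inf")

    def test_requires_three_ks(self):
        with pytest.raises(GenotypeError):
            evanno({1: [-1.0, -2.0], 2: [-1.0, -2.0]})


class TestAlignment:
    def test_permuted_copy_recovered(self):
        rng = np.random.default_rng(0)
        q = rng.dirichlet(np.ones(4), size=30)
        perm = (2, 0, 3, 1)
        res = align_runs_greedy([q, q[:, perm]])
        assert np.allclose(res.aligned_q[1], q)
        assert res.mean_similarity == pytest.approx(1.0, abs=1e-12)

    def test_noise_runs_low_similarity(self):
        rng = np.random.default_rng(1)
        runs = [rng.dirichlet(np.ones(3), size=40) for _ in range(4)]
        res = align_runs_greedy(runs)
        assert res.mean_similarity < 1.0

    def test_k2_swapped_half(self):
        rng = np.random.default_rng(2)
        q = rng.dirichlet(np.ones(2), size=25)
        runs = [q if i % 2 == 0 else q[:, ::-1] for i in range(10)]
        res = align_runs_greedy(runs)
        for aligned in res.aligned_q:
            assert np.allclose(aligned, q)

    def test_mismatched_shapes_error(self):
        rng = np.random.default_rng(3)
        with pytest.raises(GenotypeError):
            align_runs_greedy(
                [rng.dirichlet(np.ones(2), size=5), rng.dirichlet(np.ones(3), size=5)]
            )

    def test_large_k_assignment_path(self):
        rng = np.random.default_rng(4)
        q = rng.dirichlet(np.ones(9), size=40)
        perm = tuple(rng.permutation(9))
        res = align_runs_greedy([q, q[:, perm]])
        assert np.allclose(res.aligned_q[1], q)


class TestAssignment:
    def test_clear_member(self):
        assert assign_memberships(np.array([[0.8, 0.1, 0.1]])) == [0]

    def test_admixed(self):
        assert assign_memberships(np.array([[0.55, 0.45]])) == ["admixed"]

    def test_boundary_inclusive(self):
        assert assign_memberships(np.array([[0.70, 0.30]])) == [0]

    def test_threshold_validated(self):
        with pytest.raises(GenotypeError):
            assign_memberships(np.array([[0.5, 0.5]]), threshold=0.4)
        with pytest.raises(GenotypeError):
            assign_memberships(np.array([[0.5, 0.5]]), threshold=1.2)


class TestBarplot:
    def test_writes_png(self, tmp_path):
        rng = np.random.default_rng(0)
        q = rng.dirichlet(np.ones(3), size=20)
        out = tmp_path / "bars.png"
        admixture.membership_barplot(q, out)
        assert out.stat().st_size > 0


class TestHierarchical:
    def test_nested_structure_found(self):
        # one "pool" that itself contains two fixed subpools
        ids, calls, labels = [], [], {}
        for i in range(15):
            ids.append(f"S1_{i}")
            calls.append([(100, 100)] * 8)
            labels[f"S1_{i}"] = "c0"
        for i in range(15):
            ids.append(f"S2_{i}")
            calls.append([(120, 120)] * 8)
            labels[f"S2_{i}"] = "c0"
        gm = GenotypeMatrix.from_calls(ids, [f"L{j}" for j in range(8)], calls)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = hierarchical_rounds(
                gm, labels, k_min=1, k_max=3, runs_per_k=2,
                burnin=200, iters=1000, seed=5,
            )
        assert out["c0"].evanno.best_k == 2

    def test_partition_preserved(self):
        gm, truth = two_pop_gm(12, 5)
        labels = {a: ("g1" if a.startswith("P1") else "g2")
                  for a in gm.accession_ids}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = hierarchical_rounds(
                gm, labels, k_min=1, k_max=3, runs_per_k=2,
                burnin=100, iters=500, seed=6,
            )
        for group, sr in out.items():
            members = [a for a, l in labels.items() if l == group]
            assert sorted(sr.labels) == sorted(members)

    def test_small_subset_skipped(self):
        gm, _ = two_pop_gm(3, 4)
        labels = {a: "only" for a in gm.accession_ids}
        with pytest.warns(UserWarning, match="skipped"):
            out = hierarchical_rounds(
                gm, labels, k_max=5, runs_per_k=2,
                burnin=50, iters=200, seed=7,
            )
        assert out["only"].evanno is None
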