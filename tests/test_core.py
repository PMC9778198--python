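import itertools

import numpy as np
import pytest

from ssrcore import (
    CoreSet,
    PhenotypeTable,
    combine_cores,
    compare_core_original,
    diversity_core_search,
    evaluate_phenotype_core,
    locus_stats,
    m_strategy_core,
    phenotype_core,
)
from ssrcore.core import _search_objective
from ssrcore.simulate import SimulationConfig, simulate_dataset

from conftest import make_gm


# ---------------------------------------------------------------------------
# phenotypic core
# ---------------------------------------------------------------------------

def _pheno(values, traits=None):
    values = np.asarray(values, dtype=float)
    traits = traits or [f"t{j + 1}" for j in range(values.shape[1])]
    ids = [f"E{i + 1}" for i in range(values.shape[0])]
    return PhenotypeTable(ids, traits, values)


class TestPhenotypeCore:
    def test_ratio_one_keeps_all(self, study_dataset):
        _, _, pt = study_dataset
        cs = phenotype_core(pt, ratio=1.0)
        assert cs.entry_ids == pt.entry_ids

    @pytest.mark.parametrize("linkage", ["upgma", "ward", "median"])
    def test_separated_pairs_yield_one_per_pair(self, linkage):
        """8 entries in 4 tight, well-separated pairs at ratio 0.5."""
        centers = np.array([[0, 0], [10, 0], [0, 10], [10, 10]], float)
        vals = np.repeat(centers, 2, axis=0)
        vals[1::2] += 0.01
        pt = _pheno(vals)
        cs = phenotype_core(pt, linkage=linkage, sampling="random", ratio=0.5, seed=0)
        assert cs.size == 4
        picked = {pt.entry_ids.index(e) // 2 for e in cs.entry_ids}
        assert picked == {0, 1, 2, 3}

    def test_preferred_beats_deviation_on_range(self):
        """Clusters with one extreme member: preferred sampling keeps ranges."""
        rng = np.random.default_rng(0)
        blocks = []
        for c in range(5):
            base = rng.normal(scale=0.1, size=(5, 3)) + 10 * c
            base[0] += 4.0  # one extreme member per cluster
            blocks.append(base)
        pt = _pheno(np.vstack(blocks))
        cr = {}
        for samp in ("preferred", "deviation"):
            cs = phenotype_core(pt, sampling=samp, ratio=0.2, seed=1)
            cr[samp] = evaluate_phenotype_core(pt, cs).CR
        assert cr["preferred"] >= cr["deviation"]

    def test_small_ratio_rejected(self):
        pt = _pheno(np.random.default_rng(0).normal(size=(10, 2)))
        with pytest.raises(ValueError):
            phenotype_core(pt, ratio=0.05)

    def test_mahalanobis_with_singular_covariance_warns(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(12, 1))
        vals = np.hstack([x, 2 * x, x + 1])  # rank-1 trait block
        pt = _pheno(vals)
        with pytest.warns(UserWarning, match="singular"):
            cs = phenotype_core(pt, distance="mahalanobis", ratio=0.5, seed=0)
        assert cs.size == 6


class TestEvaluatePhenotypeCore:
    def test_identity_core(self, study_dataset):
        """core == original -> MD=0, VD=0, CR=100, VR=100."""
        _, _, pt = study_dataset
        ev = evaluate_phenotype_core(pt, CoreSet(list(pt.entry_ids), "all"))
        assert ev.MD == 0.0 and ev.VD == 0.0
        assert ev.CR == pytest.approx(100.0)
        assert ev.VR == pytest.approx(100.0)
        assert ev.passes

    def test_cr_hand_arithmetic(self):
        """Core missing both extremes of one of five traits: CR = (100/5)(4+0.5)."""
        rng = np.random.default_rng(1)
        vals = rng.uniform(10, 20, size=(12, 5))
        # trait 0: linear spread so trimming the 2 extremes halves the range
        vals[:, 0] = np.concatenate([[0.0, 100.0], np.linspace(25, 75, 10)])
        # make sure every other trait keeps its extremes inside the core rows
        core_rows = list(range(2, 12))
        for j in range(1, 5):
            cols = vals[:, j]
            imax, imin = np.argmax(cols), np.argmin(cols)
            vals[2, j] = cols[imax]
            vals[3, j] = cols[imin]
        pt = _pheno(vals)
        core = CoreSet([pt.entry_ids[i] for i in core_rows], "trimmed")
        ev = evaluate_phenotype_core(pt, core)
        assert ev.CR == pytest.approx((100.0 / 5) * (4 + 0.5), abs=1e-9)

    def test_vd_counts_significant_variance_tests(self):
        """10 of 15 traits with collapsed variance in the core -> VD = 66.67."""
        rng = np.random.default_rng(2)
        n = 60
        vals = rng.normal(50, 10, size=(n, 15))
        core_rows = list(range(0, n, 2))
        for j in range(10):  # crush core variance for the first ten traits
            vals[core_rows, j] = 50 + 0.01 * rng.normal(size=len(core_rows))
        pt = _pheno(vals)
        ev = evaluate_phenotype_core(pt, CoreSet([pt.entry_ids[i] for i in core_rows], "c"))
        assert ev.VD == pytest.approx(100 * 10 / 15, abs=1e-9)

    def test_affine_rescaling_invariance(self, study_dataset):
        """Positive rescaling leaves MD/VD/CR/VR unchanged; shifts leave MD/VD/CR."""
        _, _, pt = study_dataset
        core = CoreSet(pt.entry_ids[::4], "stride")
        base = evaluate_phenotype_core(pt, core)
        scaled = PhenotypeTable(pt.entry_ids, pt.trait_ids, pt.values * 3.7)
        ev_s = evaluate_phenotype_core(scaled, core)
        for attr in ("MD", "VD", "CR", "VR"):
            assert getattr(ev_s, attr) == pytest.approx(getattr(base, attr), abs=1e-9)
        shifted = PhenotypeTable(pt.entry_ids, pt.trait_ids, pt.values + 13.0)
        ev_t = evaluate_phenotype_core(shifted, core)
        for attr in ("MD", "VD", "CR"):
            assert getattr(ev_t, attr) == pytest.approx(getattr(base, attr), abs=1e-9)

    def test_zero_range_trait_excluded(self):
        vals = np.column_stack([np.ones(8), np.arange(8, dtype=float)])
        pt = _pheno(vals)
        ev = evaluate_phenotype_core(pt, CoreSet(pt.entry_ids[:4], "c"))
        assert any("zero original range" in w for w in ev.warnings)


# ---------------------------------------------------------------------------
# molecular cores
# ---------------------------------------------------------------------------

class TestMStrategy:
    def test_identical_homozygotes_core_of_one(self):
        gm = make_gm([[("A", "A"), ("B", "B")]] * 5)
        assert m_strategy_core(gm).size == 1

    def test_two_entry_cover_verified_by_brute_force(self):
        """Entries 1 and 4 jointly carry every allele; no single entry does."""
        geno = [
            [("A", "B"), ("E", "E")],
            [("A", "A"), ("E", "F")],
            [("B", "B"), ("E", "E")],
            [("C", "D"), ("F", "G")],
            [("A", "C"), ("E", "G")],
        ]
        gm = make_gm(geno)
        core = m_strategy_core(gm)
        counts, _, _ = gm.allele_count_blocks()
        B = counts > 0
        full = B.any(axis=0)
        # brute force: smallest covering subset over all 2^5 candidates
        best = None
        for r in range(1, 6):
            for combo in itertools.combinations(range(5), r):
                if (B[list(combo)].any(axis=0) == full).all():
                    best = combo
                    break
            if best:
                break
        assert len(core.entry_ids) == len(best) == 2
        assert set(core.entry_ids) == {"E1", "E4"}

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_full_allele_retention_on_simulations(self, seed):
        cfg = SimulationConfig(pop_sizes=(30, 30, 30), n_loci=12, fst_target=0.1, seed=seed)
        gm, _, _ = simulate_dataset(cfg)
        core = m_strategy_core(gm)
        orig_na = locus_stats(gm)["Na"]
        core_na = locus_stats(gm.subset(core.entry_ids))["Na"]
        assert (core_na == orig_na).all()

    def test_not_larger_than_random_covering_subsets(self, study_dataset):
        """Greedy core is no larger than the best of 1000 random covering subsets."""
        gm, _, _ = study_dataset
        core = m_strategy_core(gm)
        counts, _, _ = gm.allele_count_blocks()
        B = counts > 0
        full = B.any(axis=0)
        rng = np.random.default_rng(0)
        best_random = gm.n_entries
        for _ in range(1000):
            order = rng.permutation(gm.n_entries)
            covered = np.zeros_like(full)
            size = 0
            for i in order:
                if (covered | B[i] != covered).any():
                    covered |= B[i]
                    size += 1
                if covered.all():
                    break
            best_random = min(best_random, size)
        assert core.size <= best_random


class TestDiversityCoreSearch:
    def test_size_rule(self, study_dataset):
        gm, _, _ = study_dataset
        cs = diversity_core_search(gm, 0.10, seed=0, n_iter=300)
        assert cs.size == 23  # round(0.10 * 232)

    def test_objective_beats_random_subsets(self):
        cfg = SimulationConfig(pop_sizes=(20, 20, 20), n_loci=10, fst_target=0.1, seed=4)
        gm, _, _ = simulate_dataset(cfg)
        from ssrcore.structure import shared_allele_distance

        _, D = shared_allele_distance(gm)
        counts, _, _ = gm.allele_count_blocks()
        cover = counts > 0
        A = cover.shape[1]
        rng = np.random.default_rng(0)
        for trial in range(5):
            cs = diversity_core_search(gm, 0.3, seed=trial, n_iter=3000)
            idx = np.asarray([gm.entry_ids.index(e) for e in cs.entry_ids])
            obj = _search_objective(D, cover, idx, A)
            rand_best = max(
                _search_objective(
                    D, cover, rng.choice(gm.n_entries, size=cs.size, replace=False), A
                )
                for _ in range(100)
            )
            assert obj >= rand_best

    def test_deterministic_for_seed(self, study_dataset):
        gm, _, _ = study_dataset
        a = diversity_core_search(gm, 0.1, seed=9, n_iter=200)
        b = diversity_core_search(gm, 0.1, seed=9, n_iter=200)
        assert a.entry_ids == b.entry_ids

    def test_tiny_size_rejected(self):
        gm = make_gm([[("A", "B")], [("A", "A")], [("B", "B")]])
        with pytest.raises(ValueError):
            diversity_core_search(gm, 0.3)


class TestCompareCoreOriginal:
    def test_identity_core(self, study_dataset):
        gm, _, _ = study_dataset
        ev = compare_core_original(gm, CoreSet(list(gm.entry_ids), "all"))
        np.testing.assert_allclose(ev.table["retention_pct"], 100.0)
        assert (ev.table["t"] == 0).all()
        assert ev.sample_retention == pytest.approx(100.0)

    def test_sample_retention_percentage(self, study_dataset):
        gm, _, _ = study_dataset
        core = CoreSet(list(gm.entry_ids)[:158], "slice")
        ev = compare_core_original(gm, core)
        assert round(ev.sample_retention, 1) == 68.1

    def test_rare_allele_removal_depresses_na(self):
        """Dropping all carriers of singleton alleles lowers Na significantly."""
        rng = np.random.default_rng(8)
        n, L = 80, 20
        calls = np.empty((n, L, 2), dtype=object)
        for l in range(L):
            # common background alleles + singleton rare carriers among first 30
            for i in range(n):
                calls[i, l, 0] = str(rng.integers(2))
                calls[i, l, 1] = str(rng.integers(2))
            carrier = rng.integers(0, 30)
            calls[carrier, l, 1] = f"rare{l}"
        from ssrcore import GenotypeMatrix

        gm = GenotypeMatrix([f"E{i}" for i in range(n)], [f"L{l}" for l in range(L)], calls)
        core = CoreSet([f"E{i}" for i in range(30, n)], "no-rare", source_ids=gm.entry_ids)
        ev = compare_core_original(gm, core)
        assert ev.table.loc["Na", "core"] < ev.table.loc["Na", "original"]
        assert ev.table.loc["Na", "p"] < 0.05


class TestCombineCores:
    def test_union_and_idempotence(self):
        src = [f"E{i}" for i in range(5)]
        a = CoreSet(["E1", "E2"], "a", source_ids=src)
        b = CoreSet(["E2", "E3"], "b", source_ids=src)
        u = combine_cores(a, b)
        assert set(u.entry_ids) == {"E1", "E2", "E3"}
        assert "a" in u.method and "b" in u.method
        aa = combine_cores(a, a)
        assert set(aa.entry_ids) == set(a.entry_ids)
        assert u.size >= max(a.size, b.size)

    def test_disjoint_sources_rejected(self):
        a = CoreSet(["E1"], "a", source_ids=["E1", "E2"])
        b = CoreSet(["X1"], "b", source_ids=["X1", "X2"])
        with pytest.raises(ValueError):
            combine_cores(a, b)
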