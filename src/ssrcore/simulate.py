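"""Synthetic SSR genotype and phenotype datasets with tunable differentiation.

Genotypes follow the Balding–Nichols model: ancestral allele frequencies per
locus are drawn from a symmetric Dirichlet, each population's frequencies
are drawn from ``Dirichlet(p * (1 - F) / F)`` around the ancestral vector
(so the expected fixation index equals ``F``), and individual genotypes are
two independent draws from the population frequencies (Hardy–Weinberg within
populations).  Calls are masked missing at a configurable rate.

Traits are multivariate normal: a per-(population, trait) mean shift drawn
with standard deviation ``trait_group_effect`` (a standardized
between-population effect size) plus unit-variance noise with a
compound-symmetric correlation among traits.

The default configuration reproduces the design of a 232-accession,
17-provenance *Castanopsis hystrix* germplasm survey: the published
provenance sample sizes, 32 SSR loci with 8–15 alleles each, overall
differentiation F = 0.042 and 15 correlated traits.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import GenotypeMatrix, MISSING, PhenotypeTable, PopulationMap
from .refdata import POPULATION_SIZES


@dataclass
class SimulationConfig:
    """Study-design parameters for :func:`simulate_dataset`."""

    pop_sizes: tuple[int, ...] = tuple(POPULATION_SIZES)
    n_loci: int = 32
    alleles_per_locus: tuple[int, int] = (8, 15)
    fst_target: float = 0.042
    missing_rate: float = 0.02
    n_traits: int = 15
    trait_group_effect: float = 0.5
    trait_correlation: float = 0.3
    dirichlet_concentration: float = 1.0
    seed: int = 0

    @property
    def n_pops(self) -> int:
        return len(self.pop_sizes)

    @property
    def n_entries(self) -> int:
        return int(sum(self.pop_sizes))

    def __post_init__(self) -> None:
        self.pop_sizes = tuple(int(s) for s in self.pop_sizes)
        self.alleles_per_locus = tuple(int(a) for a in self.alleles_per_locus)
        if any(s < 1 for s in self.pop_sizes):
            raise ValueError("population sizes must be >= 1")
        if not 0.0 <= self.fst_target <= 0.5:
            raise ValueError("fst_target must be in [0, 0.5]")
        if not 0.0 <= self.missing_rate <= 0.3:
            raise ValueError("missing_rate must be in [0, 0.3]")
        if self.alleles_per_locus[0] < 2:
            raise ValueError("need at least 2 alleles per locus")


def simulate_dataset(
    cfg: SimulationConfig,
) -> tuple[GenotypeMatrix, PopulationMap, PhenotypeTable]:
    """Draw one dataset; byte-identical for identical configs (seed included)."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_entries
    lo, hi = cfg.alleles_per_locus
    F = cfg.fst_target

    pop_labels = [f"P{g + 1}" for g in range(cfg.n_pops)]
    entry_ids: list[str] = []
    entry_pop: list[int] = []
    for g, size in enumerate(cfg.pop_sizes):
        for i in range(size):
            entry_ids.append(f"{pop_labels[g]}-{i + 1:02d}")
            entry_pop.append(g)
    entry_pop_arr = np.asarray(entry_pop)

    locus_ids = [f"SSR{l + 1:02d}" for l in range(cfg.n_loci)]
    calls = np.empty((n, cfg.n_loci, 2), dtype=object)
    for l in range(cfg.n_loci):
        J = int(rng.integers(lo, hi + 1))
        # SSR-style fragment-size labels
        base = int(rng.integers(100, 300))
        labels = [str(base + 2 * j) for j in range(J)]
        # Condition each locus on observing all J alleles after masking: an SSR
        # survey's allele set is by definition the set actually detected, so a
        # locus advertised as J-allelic must show J alleles.  Rejection keeps
        # the within-population genotype distribution Hardy-Weinberg.
        for _attempt in range(1000):
            p_anc = rng.dirichlet(np.full(J, cfg.dirichlet_concentration))
            p_anc = np.maximum(p_anc, 1e-6)
            p_anc /= p_anc.sum()
            draws = np.empty((n, 2), dtype=np.int64)
            for g in range(cfg.n_pops):
                if F > 0:
                    p_g = rng.dirichlet(p_anc * (1.0 - F) / F)
                else:
                    p_g = p_anc
                rows = np.nonzero(entry_pop_arr == g)[0]
                draws[rows] = rng.choice(J, size=(rows.size, 2), p=p_g)
            miss = (
                rng.random(n) < cfg.missing_rate
                if cfg.missing_rate > 0
                else np.zeros(n, dtype=bool)
            )
            if miss.all():
                miss[rng.integers(n)] = False
            if np.unique(draws[~miss]).size == J:
                break
        for r in range(n):
            if miss[r]:
                calls[r, l, 0] = MISSING
                calls[r, l, 1] = MISSING
            else:
                calls[r, l, 0] = labels[draws[r, 0]]
                calls[r, l, 1] = labels[draws[r, 1]]

    gm = GenotypeMatrix(entry_ids, locus_ids, calls)
    pm = PopulationMap({e: pop_labels[g] for e, g in zip(entry_ids, entry_pop)})

    shifts = rng.normal(0.0, cfg.trait_group_effect, size=(cfg.n_pops, cfg.n_traits))
    rho = cfg.trait_correlation
    cov = np.full((cfg.n_traits, cfg.n_traits), rho)
    np.fill_diagonal(cov, 1.0)
    noise = rng.multivariate_normal(np.zeros(cfg.n_traits), cov, size=n, method="cholesky")
    z = shifts[entry_pop_arr] + noise
    # trait-like units: positive means with ~10% coefficient of variation, so
    # CV-based evaluation metrics behave as they do on real growth/wood traits
    offset = rng.uniform(10.0, 100.0, size=cfg.n_traits)
    values = offset + 0.1 * offset * z
    pt = PhenotypeTable(entry_ids, [f"trait{t + 1:02d}" for t in range(cfg.n_traits)], values)
    return gm, pm, pt


def study_scale_dataset(
    seed: int = 0, **overrides
) -> tuple[GenotypeMatrix, PopulationMap, PhenotypeTable]:
    """Dataset at the default study scale: 232 entries, 17 provenances with the
    published sample sizes, 32 loci with 8–15 alleles, F = 0.042, 15 traits."""
    cfg = replace(SimulationConfig(seed=seed), **overrides)
    return simulate_dataset(cfg)
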