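"""Core-collection construction and evaluation.

Two routes to a core subset are provided, mirroring germplasm practice:

* **Phenotypic** (stepwise clustering): standardize traits, build a
  hierarchical tree (UPGMA / Ward / median linkage on Euclidean or
  Mahalanobis distances), cut it into ``round(ratio * N)`` clusters and keep
  one representative per cluster — drawn at random, the entry nearest the
  cluster centroid ("deviation sampling") or the most extreme entry
  ("preferred sampling", maximizing range retention).
* **Molecular**: the M-strategy greedy allele maximization (full allele
  coverage with a pruning pass), and a diversity-maximizing stochastic
  subset search at a fixed sampling ratio in the Core Hunter spirit
  (allele coverage + mean nearest-entry distance objective).

Evaluation follows the standard germplasm metrics: MD/VD are the
percentages of traits whose core-vs-original mean (Welch t) or variance
(F) difference is significant; CR is the mean core/original range ratio
(x100) and VR the mean coefficient-of-variation ratio (x100).  A phenotypic
core is conventionally acceptable when MD <= 20% and CR > 80%.  Molecular
cores are compared through per-locus diversity parameters (Na, Ne, Ho, He,
I, PIC), their retention percentages, and per-parameter Welch t-tests.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage as _scipy_linkage
from scipy.spatial.distance import pdist

from .diversity import locus_stats
from .io import GenotypeMatrix, PhenotypeTable

_LINKAGE = {"upgma": "average", "ward": "ward", "median": "median"}
_SAMPLING = {"random", "deviation", "preferred"}


@dataclass
class CoreSet:
    """A selected subset of the collection, with provenance metadata."""

    entry_ids: list[str]
    method: str
    ratio: float | None = None
    seed: int | None = None
    source_ids: list[str] | None = None

    def __post_init__(self) -> None:
        if len(set(self.entry_ids)) != len(self.entry_ids):
            raise ValueError("core set contains duplicate entries")
        if not self.entry_ids:
            raise ValueError("core set is empty")
        if self.source_ids is not None:
            extra = set(self.entry_ids) - set(self.source_ids)
            if extra:
                raise ValueError(f"core entries outside the original collection: {sorted(extra)}")

    @property
    def size(self) -> int:
        return len(self.entry_ids)


@dataclass
class PhenoEvaluation:
    """MD/VD/CR/VR summary of a phenotypic core against the original collection."""

    MD: float
    VD: float
    CR: float
    VR: float
    per_trait: pd.DataFrame
    alpha: float
    passes: bool
    warnings: list[str] = field(default_factory=list)


@dataclass
class MolecularEvaluation:
    """Per-parameter core-vs-original comparison over per-locus diversity values."""

    table: pd.DataFrame
    sample_retention: float
    core_size: int
    original_size: int


# ---------------------------------------------------------------------------
# phenotypic core
# ---------------------------------------------------------------------------

def _standardize(pt: PhenotypeTable) -> np.ndarray:
    X = pt.values.astype(float)
    mu = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (X - mu) / sd
    return np.where(np.isfinite(Z), Z, 0.0)  # mean-impute missing cells after scaling


def _pairwise(Z: np.ndarray, distance: str) -> np.ndarray:
    if distance == "euclidean":
        return pdist(Z)
    if distance == "mahalanobis":
        cov = np.cov(Z, rowvar=False)
        p = cov.shape[0]
        if np.linalg.matrix_rank(cov) < p:
            _warnings.warn("singular trait covariance; ridge-regularizing", stacklevel=3)
            cov = cov + (1e-6 * np.trace(cov) / p) * np.eye(p)
        return pdist(Z, metric="mahalanobis", VI=np.linalg.inv(cov))
    raise ValueError(f"unknown distance {distance!r}")


def phenotype_core(
    pt: PhenotypeTable,
    distance: str = "euclidean",
    linkage: str = "upgma",
    sampling: str = "preferred",
    ratio: float = 0.15,
    seed: int | None = 0,
) -> CoreSet:
    """Stepwise-clustering phenotypic core at a sampling ratio.

    The tree is cut into ``m = round(ratio * N)`` clusters and one entry is
    kept per cluster according to ``sampling``; singleton clusters contribute
    their sole member.
    """
    if linkage not in _LINKAGE:
        raise ValueError(f"unknown linkage {linkage!r}")
    if sampling not in _SAMPLING:
        raise ValueError(f"unknown sampling {sampling!r}")
    if not 0 < ratio <= 1:
        raise ValueError("ratio must be in (0, 1]")
    N = len(pt.entry_ids)
    m = int(round(ratio * N))
    if ratio == 1.0 or m >= N:
        return CoreSet(list(pt.entry_ids), f"{distance}-{linkage}-{sampling}-{int(ratio * 100)}",
                       ratio, seed, list(pt.entry_ids))
    if m < 2:
        raise ValueError(f"ratio {ratio} yields fewer than 2 clusters for N={N}")
    Z = _standardize(pt)
    cond = _pairwise(Z, distance)
    tree = _scipy_linkage(cond, method=_LINKAGE[linkage])
    labels = fcluster(tree, t=m, criterion="maxclust")
    rng = np.random.default_rng(seed)
    picked: list[int] = []
    for c in np.unique(labels):
        members = np.nonzero(labels == c)[0]
        if members.size == 1:
            picked.append(int(members[0]))
            continue
        if sampling == "random":
            picked.append(int(rng.choice(members)))
        elif sampling == "preferred":
            norms = np.linalg.norm(Z[members], axis=1)
            picked.append(int(members[np.argmax(norms)]))
        else:  # deviation: closest to the cluster centroid
            centroid = Z[members].mean(axis=0)
            dd = np.linalg.norm(Z[members] - centroid, axis=1)
            picked.append(int(members[np.argmin(dd)]))
    picked = sorted(picked)
    return CoreSet(
        [pt.entry_ids[i] for i in picked],
        f"{distance}-{linkage}-{sampling}-{int(round(ratio * 100))}",
        ratio,
        seed,
        list(pt.entry_ids),
    )


def evaluate_phenotype_core(
    pt: PhenotypeTable, core: CoreSet, alpha: float = 0.05
) -> PhenoEvaluation:
    """MD/VD/CR/VR evaluation of a core subset against the full table.

    Per trait: Welch two-sample t-test of means and an F-test of variances,
    core vs original; MD and VD are the percentages of significant traits.
    CR averages core/original range ratios, VR core/original coefficient-of-
    variation ratios (both x100).  Traits with zero original range are
    excluded from CR with a warning.
    """
    core_pt = pt.subset(core.entry_ids)
    notes: list[str] = []
    rows = []
    for j, trait in enumerate(pt.trait_ids):
        x_all = pt.values[:, j]
        x_core = core_pt.values[:, j]
        x_all = x_all[np.isfinite(x_all)]
        x_core = x_core[np.isfinite(x_core)]
        t_stat, t_p = stats.ttest_ind(x_core, x_all, equal_var=False)
        v_core = np.var(x_core, ddof=1)
        v_all = np.var(x_all, ddof=1)
        if v_all > 0 and v_core > 0:
            F = v_core / v_all
            df1, df2 = x_core.size - 1, x_all.size - 1
            f_p = 2 * min(stats.f.sf(F, df1, df2), stats.f.cdf(F, df1, df2))
        else:
            F, f_p = np.nan, np.nan
        rng_all = np.ptp(x_all)
        rng_core = np.ptp(x_core)
        cr = rng_core / rng_all if rng_all > 0 else np.nan
        if rng_all == 0:
            notes.append(f"trait {trait!r} has zero original range; excluded from CR")
        cv_all = np.std(x_all, ddof=1) / abs(np.mean(x_all)) if np.mean(x_all) != 0 else np.nan
        cv_core = np.std(x_core, ddof=1) / abs(np.mean(x_core)) if np.mean(x_core) != 0 else np.nan
        vr = cv_core / cv_all if cv_all and np.isfinite(cv_all) and cv_all > 0 else np.nan
        rows.append(
            {
                "trait": trait,
                "t": t_stat,
                "t_p": t_p,
                "F": F,
                "F_p": f_p,
                "range_ratio": cr,
                "cv_ratio": vr,
            }
        )
    det = pd.DataFrame(rows).set_index("trait")
    identical = core.size == len(pt.entry_ids) and set(core.entry_ids) == set(pt.entry_ids)
    if identical:
        # core == original: degenerate tests; no trait differs
        md = vd = 0.0
    else:
        md = 100.0 * float((det["t_p"] < alpha).sum()) / len(det)
        vd = 100.0 * float((det["F_p"] < alpha).sum()) / len(det)
    cr_vals = det["range_ratio"].dropna()
    vr_vals = det["cv_ratio"].dropna()
    CR = 100.0 * float(cr_vals.mean()) if len(cr_vals) else np.nan
    VR = 100.0 * float(vr_vals.mean()) if len(vr_vals) else np.nan
    return PhenoEvaluation(
        MD=md, VD=vd, CR=CR, VR=VR, per_trait=det, alpha=alpha,
        passes=bool(md <= 20.0 and CR > 80.0), warnings=notes,
    )


# ---------------------------------------------------------------------------
# molecular cores
# ---------------------------------------------------------------------------

def m_strategy_core(gm: GenotypeMatrix) -> CoreSet:
    """Greedy maximization of allele coverage (M strategy) with pruning.

    Entries are added by largest count of not-yet-covered alleles (ties:
    fewest total distinct alleles carried, then lowest position in the entry
    order) until every allele of the collection is covered; a backward pass
    then drops entries whose alleles are all covered by the rest.  The
    returned core always retains 100% of the distinct alleles.
    """
    counts, _, _ = gm.allele_count_blocks()
    B = counts > 0  # entry x allele incidence
    n, A = B.shape
    totals = B.sum(axis=1)
    uncovered = np.ones(A, dtype=bool)
    order = []
    selected = np.zeros(n, dtype=bool)
    while uncovered.any():
        gains = B[:, uncovered].sum(axis=1)
        gains[selected] = -1
        best_gain = gains.max()
        cands = np.nonzero(gains == best_gain)[0]
        if len(cands) > 1:
            cands = cands[totals[cands] == totals[cands].min()]
        pick = int(cands[0])
        selected[pick] = True
        order.append(pick)
        uncovered &= ~B[pick]
    # pruning pass: most recently added first
    for pick in reversed(order):
        rest = selected.copy()
        rest[pick] = False
        if rest.any() and not (B[pick] & ~B[rest].any(axis=0)).any():
            selected[pick] = False
    idx = np.nonzero(selected)[0]
    return CoreSet(
        [gm.entry_ids[i] for i in idx], "M-strategy", None, None, list(gm.entry_ids)
    )


def _search_objective(D: np.ndarray, cover: np.ndarray, idx: np.ndarray, n_alleles: int) -> float:
    """0.5 * allele-coverage fraction + 0.5 * mean nearest-entry distance."""
    cov = float((cover[idx].any(axis=0)).sum()) / n_alleles
    sub = D[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub, np.inf)
    en = float(sub.min(axis=1).mean())
    return 0.5 * cov + 0.5 * en


def diversity_core_search(
    gm: GenotypeMatrix,
    ratio: float,
    seed: int = 0,
    n_iter: int = 10_000,
) -> CoreSet:
    """Diversity-maximizing core at a fixed sampling ratio by local search.

    Size is ``round(ratio * N)``.  Starting from a random subset, improving
    swaps are applied: each pass scans members in random order, evaluates
    every single-entry swap for that member and applies the best improving
    one (steepest ascent within the member's swap neighborhood).  The budget
    ``n_iter`` caps the number of candidate-swap evaluations; the objective
    is non-decreasing throughout.
    """
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    N = gm.n_entries
    size = int(round(ratio * N))
    if size < 2:
        raise ValueError(f"ratio {ratio} yields a core smaller than 2 (N={N})")
    from .structure import shared_allele_distance

    _, D = shared_allele_distance(gm)
    counts, _, _ = gm.allele_count_blocks()
    cover = counts > 0
    n_alleles = cover.shape[1]
    rng = np.random.default_rng(seed)
    current = rng.choice(N, size=size, replace=False)
    in_set = np.zeros(N, dtype=bool)
    in_set[current] = True
    obj = _search_objective(D, cover, current, n_alleles)
    evals = 0
    improved = True
    while improved and evals < n_iter:
        improved = False
        for pos in rng.permutation(size):
            out_entry = current[pos]
            candidates = np.nonzero(~in_set)[0]
            best_obj, best_cand = obj, -1
            for cand in candidates:
                trial = current.copy()
                trial[pos] = cand
                val = _search_objective(D, cover, trial, n_alleles)
                evals += 1
                if val > best_obj + 1e-12:
                    best_obj, best_cand = val, cand
                if evals >= n_iter:
                    break
            if best_cand >= 0:
                in_set[out_entry] = False
                in_set[best_cand] = True
                current[pos] = best_cand
                obj = best_obj
                improved = True
            if evals >= n_iter:
                break
    idx = np.sort(current)
    return CoreSet(
        [gm.entry_ids[i] for i in idx],
        f"H-{int(round(ratio * 100))}",
        ratio,
        seed,
        list(gm.entry_ids),
    )


PARAMS = ["Na", "Ne", "Ho", "He", "I", "PIC"]


def compare_core_original(gm: GenotypeMatrix, core: CoreSet) -> MolecularEvaluation:
    """Retention percentages and Welch t-tests of per-locus diversity parameters.

    For each parameter, the core and original per-locus values (one per
    locus) are compared by an independent two-sample t-test, and retention is
    ``100 * mean_core / mean_original``.
    """
    orig = locus_stats(gm)
    sub = locus_stats(gm.subset(core.entry_ids))
    identical = set(core.entry_ids) == set(gm.entry_ids)
    rows = []
    for p in PARAMS:
        a, b = sub[p].to_numpy(float), orig[p].to_numpy(float)
        if identical:
            t_stat, p_val = 0.0, 1.0
        else:
            t_stat, p_val = stats.ttest_ind(a, b, equal_var=False)
        rows.append(
            {
                "parameter": p,
                "core": float(np.nanmean(a)),
                "original": float(np.nanmean(b)),
                "retention_pct": 100.0 * float(np.nanmean(a)) / float(np.nanmean(b)),
                "t": float(t_stat),
                "p": float(p_val),
            }
        )
    table = pd.DataFrame(rows).set_index("parameter")
    return MolecularEvaluation(
        table=table,
        sample_retention=100.0 * core.size / gm.n_entries,
        core_size=core.size,
        original_size=gm.n_entries,
    )


def combine_cores(a: CoreSet, b: CoreSet) -> CoreSet:
    """Union of two cores drawn from the same original collection."""
    if a.source_ids is not None and b.source_ids is not None:
        if not set(a.source_ids) & set(b.source_ids):
            raise ValueError("cores come from disjoint original collections")
    seen: dict[str, None] = {}
    for e in list(a.entry_ids) + list(b.entry_ids):
        seen.setdefault(e, None)
    return CoreSet(
        list(seen),
        f"{a.method}+{b.method}",
        None,
        None,
        a.source_ids or b.source_ids,
    )
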