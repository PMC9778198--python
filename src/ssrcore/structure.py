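"""Admixture inference, cluster-number selection, trees and ordination.

The admixture model treats each individual ``i`` as a mixture over ``K``
clusters: ``Q[i, k]`` are mixing proportions and ``P[k, l, a]`` the allele
frequencies of cluster ``k`` at locus ``l``.  Each observed allele copy is
drawn from ``sum_k Q[i,k] P[k,l,.]``; the log-likelihood is maximized by EM
(deterministic for a fixed seed).  The number of clusters is suggested by the
Evanno delta-K statistic on replicate runs:

.. math::

    \\Delta K = \\frac{|\\bar L(K+1) - 2\\bar L(K) + \\bar L(K-1)|}{sd\\,L(K)}

Trees use the shared-allele distance ``d(i,j) = 1 - (shared alleles)/2``
averaged over pairwise-complete loci and Saitou–Nei neighbor joining;
ordination is classical PCoA (Gower centering, via scikit-bio).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .io import GenotypeMatrix


@dataclass
class AdmixtureResult:
    """Fitted admixture model: mixing proportions Q and cluster frequencies P."""

    K: int
    entry_ids: list[str]
    Q: np.ndarray
    P: np.ndarray  # (K, n_loci, max_alleles), zero-padded beyond each locus' alleles
    loglik: float
    loglik_path: np.ndarray
    n_iter: int
    converged: bool
    seed: int

    def assignments(self) -> np.ndarray:
        """Hard cluster labels by argmax of Q (no admixture cutoff)."""
        return np.argmax(self.Q, axis=1)

    def q_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.Q, index=self.entry_ids, columns=[f"Q{k + 1}" for k in range(self.K)]
        )


@dataclass
class DeltaKTable:
    """Evanno table: mean/sd of L(K) over replicates and the delta-K statistic."""

    table: pd.DataFrame
    best_k: int


@dataclass
class PcoaResult:
    """Principal coordinates, eigenvalues and percent variance per axis."""

    entry_ids: list[str]
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    pct_variance: np.ndarray
    warnings: list[str] = field(default_factory=list)

    def frame(self) -> pd.DataFrame:
        cols = [f"Axis{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.entry_ids, columns=cols)


# ---------------------------------------------------------------------------
# admixture EM
# ---------------------------------------------------------------------------

def _observations(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Flatten non-missing allele copies to (entry, locus, allele-code) triples."""
    codes, alleles = gm.indexed()
    n, L, _ = codes.shape
    ii, ll, ss = np.nonzero(codes >= 0)
    return ii, ll, codes[ii, ll, ss], np.asarray([len(a) for a in alleles])


def admixture_em(
    gm: GenotypeMatrix,
    K: int,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> AdmixtureResult:
    """Maximum-likelihood admixture fit by EM.

    ``tol`` is the absolute log-likelihood improvement below which iteration
    stops.  The log-likelihood path is non-decreasing (EM ascent property);
    this is asserted at runtime.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > gm.n_entries:
        raise ValueError(f"K={K} exceeds the number of entries ({gm.n_entries})")
    ii, ll, aa, n_alleles = _observations(gm)
    n, L = gm.n_entries, gm.n_loci
    Jmax = int(n_alleles.max())
    rng = np.random.default_rng(seed)

    # allele-frequency mask: valid (locus, allele) slots
    valid = np.zeros((L, Jmax), dtype=bool)
    for l in range(L):
        valid[l, : n_alleles[l]] = True

    # pooled frequencies for initialization
    pooled = np.zeros((L, Jmax))
    np.add.at(pooled, (ll, aa), 1.0)
    pooled /= pooled.sum(axis=1, keepdims=True)

    if K == 1:
        Q = np.ones((n, 1))
        P = pooled[None, :, :].copy()
        ll_val = float(np.sum(np.log(pooled[ll, aa])))
        return AdmixtureResult(
            K, list(gm.entry_ids), Q, P, ll_val, np.asarray([ll_val]), 0, True, seed
        )

    Q = rng.dirichlet(np.ones(K), size=n)
    P = pooled[None, :, :] * (0.8 + 0.4 * rng.random((K, L, Jmax)))
    P[:, ~valid] = 0.0
    P /= P.sum(axis=2, keepdims=True)

    eps = 1e-12
    path = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: responsibilities per observed allele copy
        W = Q[ii] * P[:, ll, aa].T  # (n_obs, K)
        denom = W.sum(axis=1)
        ll_val = float(np.log(np.maximum(denom, eps)).sum())
        path.append(ll_val)
        if len(path) > 1:
            if path[-1] < path[-2] - 1e-8:
                raise AssertionError("EM log-likelihood decreased")
            if abs(path[-1] - path[-2]) < tol:
                converged = True
                break
        R = W / np.maximum(denom, eps)[:, None]
        # M-step
        Qnew = np.zeros_like(Q)
        np.add.at(Qnew, ii, R)
        Qnew /= np.maximum(Qnew.sum(axis=1, keepdims=True), eps)
        Pnew = np.zeros_like(P)
        np.add.at(Pnew.transpose(1, 2, 0), (ll, aa), R)
        Pnew = np.maximum(Pnew, 0.0)
        Pnew[:, valid] = np.maximum(Pnew[:, valid], eps)
        Pnew[:, ~valid] = 0.0
        Pnew /= Pnew.sum(axis=2, keepdims=True)
        Q, P = Qnew, Pnew
    return AdmixtureResult(
        K, list(gm.entry_ids), Q, P, path[-1], np.asarray(path), it, converged, seed
    )


def replicate_admixture_runs(
    gm: GenotypeMatrix,
    k_values=range(1, 11),
    n_replicates: int = 10,
    seed: int = 0,
    **em_kwargs,
) -> pd.DataFrame:
    """Run admixture_em over a K grid with replicate seeds; returns the (K, replicate, loglik) table."""
    rows = []
    for K in k_values:
        for rep in range(n_replicates):
            sub_seed = (seed * 100003 + K * 1009 + rep) % (2**31 - 1)
            fit = admixture_em(gm, K, seed=sub_seed, **em_kwargs)
            rows.append({"K": K, "replicate": rep, "loglik": fit.loglik})
    return pd.DataFrame(rows)


def evanno_delta_k(runs: pd.DataFrame) -> DeltaKTable:
    """Evanno second-difference statistic over replicate log-likelihoods.

    ``runs`` needs columns ``K`` and ``loglik`` (replicates as repeated K
    rows).  Delta-K is defined only for interior K with positive replicate
    standard deviation; a zero-sd K is flagged undefined (NaN).
    """
    grp = runs.groupby("K")["loglik"]
    ks = np.asarray(sorted(grp.groups))
    if ks.size < 3 or np.any(np.diff(ks) != 1):
        raise ValueError("need >=3 consecutive K values")
    if (grp.count() < 2).any():
        raise ValueError("need >=2 replicates per K")
    mean = grp.mean().reindex(ks).to_numpy()
    sd = grp.std(ddof=1).reindex(ks).to_numpy()
    delta = np.full(ks.size, np.nan)
    for j in range(1, ks.size - 1):
        if sd[j] > 0:
            delta[j] = abs(mean[j + 1] - 2 * mean[j] + mean[j - 1]) / sd[j]
    table = pd.DataFrame({"K": ks, "mean_loglik": mean, "sd_loglik": sd, "delta_K": delta}).set_index("K")
    if np.all(np.isnan(delta)):
        raise ValueError("delta-K undefined at every interior K (zero replicate sd)")
    best_k = int(ks[np.nanargmax(delta)])
    return DeltaKTable(table, best_k)


# ---------------------------------------------------------------------------
# distances, trees, ordination
# ---------------------------------------------------------------------------

def shared_allele_distance(gm: GenotypeMatrix) -> tuple[list[str], np.ndarray]:
    """1 - (proportion of shared alleles), averaged over pairwise-complete loci.

    The shared-allele count per locus is ``sum_a min(c_i(a), c_j(a))`` on the
    allele-dosage vectors, so identical genotypes score 0 distance and
    genotypes without a common allele score 1.
    """
    counts, locus_of_col, obs = gm.allele_count_blocks()
    n, L = gm.n_entries, gm.n_loci
    dist_sum = np.zeros((n, n))
    shared = np.zeros((n, n), dtype=np.int32)
    X = counts.astype(float)
    for l in range(L):
        xl = X[:, locus_of_col == l]
        # sum_a min(ci,cj) = (sum ci + sum cj - sum |ci-cj|)/2 = 2 - L1/4*2...
        l1 = np.abs(xl[:, None, :] - xl[None, :, :]).sum(axis=2)
        dl = l1 / 4.0  # 1 - shared/2, since shared = 2 - l1/2
        both = np.outer(obs[:, l], obs[:, l])
        dist_sum += np.where(both, dl, 0.0)
        shared += both.astype(np.int32)
    np.fill_diagonal(shared, 1)
    if (shared == 0).any():
        i, j = np.argwhere(shared == 0)[0]
        raise ValueError(
            f"entries {gm.entry_ids[i]!r} and {gm.entry_ids[j]!r} share no non-missing locus"
        )
    d = dist_sum / shared
    np.fill_diagonal(d, 0.0)
    return list(gm.entry_ids), (d + d.T) / 2.0


def neighbor_joining(d: np.ndarray, ids: list[str]) -> str:
    """Saitou–Nei neighbor joining; returns an unrooted tree as a newick string.

    Negative branch lengths are clamped to zero with the deficit transferred
    to the sister branch, preserving the path length between the joined pair.
    Ties in the Q-criterion resolve to the lowest (row, column) index pair.
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if not np.all(np.isfinite(d)):
        raise ValueError("distances must be finite")
    n = d.shape[0]
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 entries")

    def esc(label: str) -> str:
        return label.replace(" ", "_").replace(",", "_").replace("(", "_").replace(")", "_").replace(":", "_").replace(";", "_")

    nodes = [esc(str(x)) for x in ids]
    D = d.copy()
    active = list(range(n))
    while len(active) > 2:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Qc = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Qc, np.inf)
        # lowest (row, col) index pair on ties
        flat = np.argmin(np.round(Qc, 12), axis=None)
        i_loc, j_loc = divmod(flat, m)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        i, j = active[i_loc], active[j_loc]
        dij = D[i, j]
        bi = 0.5 * dij + (r[i_loc] - r[j_loc]) / (2.0 * (m - 2))
        bj = dij - bi
        # clamp negatives, moving the deficit to the sister branch
        if bi < 0:
            bj += bi
            bi = 0.0
        if bj < 0:
            bi += bj
            bj = 0.0
        bj = max(bj, 0.0)
        new_label = f"({nodes[i]}:{bi:.10g},{nodes[j]}:{bj:.10g})"
        dnew = 0.5 * (D[i, :] + D[j, :] - dij)
        D = np.vstack([D, dnew])
        D = np.hstack([D, np.append(dnew, 0.0)[:, None]])
        nodes.append(new_label)
        active = [a for a in active if a not in (i, j)] + [D.shape[0] - 1]
    i, j = active
    b = max(D[i, j], 0.0)
    return f"({nodes[i]}:{b / 2.0:.10g},{nodes[j]}:{b / 2.0:.10g});"


def pcoa(d: np.ndarray, ids: list[str], n_axes: int | None = None) -> PcoaResult:
    """Classical principal coordinate analysis of a distance matrix.

    Negative eigenvalues (non-Euclidean distances) are reported but excluded
    from the percent-variance denominators.  ``n_axes`` beyond the number of
    positive eigenvalues is truncated with a warning note.
    """
    import warnings as _w

    from skbio import DistanceMatrix

    d = np.asarray(d, dtype=float)
    with _w.catch_warnings():
        # full-spectrum eigh and negative-eigenvalue notices are expected here
        _w.simplefilter("ignore", RuntimeWarning)
        res = _skbio_pcoa(DistanceMatrix((d + d.T) / 2.0, ids=[str(x) for x in ids]))
    eig = res.eigvals.to_numpy()
    coords = res.samples.to_numpy()
    pos = eig > 1e-12
    n_pos = int(pos.sum())
    warnings = []
    if n_axes is None:
        n_axes = n_pos
    if n_axes > n_pos:
        warnings.append(f"requested {n_axes} axes, only {n_pos} positive eigenvalues")
        n_axes = n_pos
    pct = np.where(eig > 0, 100.0 * eig / eig[pos].sum(), 0.0)
    return PcoaResult(
        entry_ids=[str(x) for x in ids],
        coordinates=coords[:, :n_axes],
        eigenvalues=eig,
        pct_variance=pct[:n_axes],
        warnings=warnings,
    )
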