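"""AMOVA variance partitioning, Phi-statistics, and per-locus Gst / gene flow.

The two-stratum analysis of molecular variance partitions squared genetic
distances into among- and within-population components:

.. math::

    SS_{total} = \\frac{1}{N}\\sum_{i<j} d^2_{ij}, \\qquad
    SS_{within} = \\sum_g \\frac{1}{n_g} \\sum_{i<j \\in g} d^2_{ij}

with ``MS = SS/df``, the weighted average sample size
``n0 = (N - sum n_g^2 / N) / (k - 1)``, the variance components
``sigma2_w = MS_within`` and ``sigma2_a = (MS_among - MS_within)/n0``
(negative estimates truncated at zero), and
``PhiPT = sigma2_a / (sigma2_a + sigma2_w)``.  Significance comes from
permuting population labels; the p-value uses the add-one rule
``(count + 1)/(n_perm + 1)``.

Genotype distances follow the codominant-genotypic convention: per locus,
half the squared Euclidean distance between the two individuals'
allele-count vectors (identical genotypes 0, one shared allele 1, two
non-overlapping heterozygotes 2, opposite homozygotes 4), summed over
pairwise-complete loci and rescaled by ``n_loci / n_shared``.

``fst_and_nm`` computes per-locus Nei Gst, ``(Ht - Hs)/Ht`` over unweighted
population means, and the island-model gene-flow estimate
``Nm = (1 - Fst)/(4 Fst)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, PopulationMap


@dataclass
class SquaredDistanceMatrix:
    """Symmetric matrix of squared genetic distances with zero diagonal."""

    entry_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.entry_ids):
            raise ValueError("distance matrix shape does not match entry_ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if (np.diag(v) != 0).any():
            raise ValueError("distance matrix diagonal must be zero")
        if (v < 0).any():
            raise ValueError("squared distances must be non-negative")
        self.values = v


@dataclass
class AmovaResult:
    """Two-stratum AMOVA table plus Phi-statistic and permutation p-value."""

    df_among: int
    df_within: int
    ss_among: float
    ss_within: float
    ms_among: float
    ms_within: float
    n0: float
    sigma2_among: float
    sigma2_within: float
    pct_among: float
    pct_within: float
    phi_pt: float
    p_value: float | None
    n_perm: int
    degenerate: bool = False
    notes: list[str] = field(default_factory=list)

    @property
    def df_total(self) -> int:
        return self.df_among + self.df_within

    @property
    def ss_total(self) -> float:
        return self.ss_among + self.ss_within

    def to_frame(self) -> pd.DataFrame:
        """Report table with Source / df / SS / MS / variance / % / Phi / p rows."""
        total_var = self.sigma2_among + self.sigma2_within
        rows = [
            ("Among Populations", self.df_among, self.ss_among, self.ms_among,
             self.sigma2_among, self.pct_among, self.phi_pt,
             self.p_value if self.p_value is not None else np.nan),
            ("Within Populations", self.df_within, self.ss_within, self.ms_within,
             self.sigma2_within, self.pct_within, np.nan, np.nan),
            ("Total", self.df_total, self.ss_total, self.ss_total / self.df_total,
             total_var, 100.0, np.nan, np.nan),
        ]
        return pd.DataFrame(
            rows,
            columns=["Source", "df", "SS", "MS", "Est.Var", "Pct", "PhiPT", "p"],
        ).set_index("Source")


def genotype_distance_matrix(gm: GenotypeMatrix) -> SquaredDistanceMatrix:
    """Squared codominant-genotypic distances summed over pairwise-complete loci."""
    counts, locus_of_col, obs = gm.allele_count_blocks()
    n, L = gm.n_entries, gm.n_loci
    total = np.zeros((n, n))
    shared = np.zeros((n, n), dtype=np.int32)
    X = counts.astype(float)
    for l in range(L):
        cols = locus_of_col == l
        xl = X[:, cols]
        sq = np.einsum("ij,ij->i", xl, xl)
        d2 = sq[:, None] + sq[None, :] - 2.0 * xl @ xl.T
        both = np.outer(obs[:, l], obs[:, l])
        total += np.where(both, 0.5 * d2, 0.0)
        shared += both.astype(np.int32)
    np.fill_diagonal(shared, 1)
    if (shared == 0).any():
        i, j = np.argwhere(shared == 0)[0]
        raise ValueError(
            f"entries {gm.entry_ids[i]!r} and {gm.entry_ids[j]!r} share no non-missing locus"
        )
    total *= L / shared
    np.fill_diagonal(total, 0.0)
    total = np.clip((total + total.T) / 2.0, 0.0, None)
    return SquaredDistanceMatrix(list(gm.entry_ids), total)


def _ss_within(values: np.ndarray, codes: np.ndarray, k: int) -> float:
    ss = 0.0
    for g in range(k):
        idx = np.nonzero(codes == g)[0]
        if idx.size == 0:
            raise ValueError(f"population index {g} has no members")
        if idx.size > 1:
            sub = values[np.ix_(idx, idx)]
            ss += sub.sum() / (2.0 * idx.size)
    return ss


def amova(
    d: SquaredDistanceMatrix,
    pm: PopulationMap,
    n_perm: int = 999,
    seed: int | None = 0,
) -> AmovaResult:
    """Two-stratum AMOVA from a squared-distance matrix and population labels."""
    labels = pm.labels_for(d.entry_ids)
    pops = pm.populations
    k = len(pops)
    if k < 2:
        raise ValueError("AMOVA needs at least two populations")
    codes = np.asarray([pops.index(p) for p in labels])
    sizes = np.bincount(codes, minlength=k)
    if (sizes == 0).any():
        raise ValueError("empty population after filtering")
    N = len(d.entry_ids)
    values = d.values

    ss_total = values.sum() / (2.0 * N)
    ss_within = _ss_within(values, codes, k)
    ss_among = max(ss_total - ss_within, 0.0)
    res = amova_from_mean_squares(
        ss_among / (k - 1), ss_within / (N - k), sizes, ss=(ss_among, ss_within)
    )

    degenerate = ss_total <= 1e-12
    notes = list(res.notes)
    if degenerate:
        notes.append("all pairwise distances are zero; PhiPT reported as 0")

    # Permutation ranking uses the untruncated statistic: zero-truncation
    # creates a point mass at PhiPT = 0 under the null, which would tie most
    # permutations and defeat the uniformity of the p-value.
    def _raw_phi(ssw: float) -> float:
        ms_a = (ss_total - ssw) / (k - 1)
        ms_w = ssw / (N - k)
        s_a = (ms_a - ms_w) / res.n0
        total = s_a + ms_w
        return s_a / total if total > 0 else 0.0

    p_value = None
    if n_perm > 0 and not degenerate:
        rng = np.random.default_rng(seed)
        observed = _raw_phi(ss_within)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(codes)
            if _raw_phi(_ss_within(values, perm, k)) >= observed - 1e-12:
                count += 1
        p_value = (count + 1) / (n_perm + 1)

    return AmovaResult(
        df_among=res.df_among,
        df_within=res.df_within,
        ss_among=ss_among,
        ss_within=ss_within,
        ms_among=res.ms_among,
        ms_within=res.ms_within,
        n0=res.n0,
        sigma2_among=res.sigma2_among,
        sigma2_within=res.sigma2_within,
        pct_among=res.pct_among,
        pct_within=res.pct_within,
        phi_pt=0.0 if degenerate else res.phi_pt,
        p_value=p_value,
        n_perm=n_perm,
        degenerate=degenerate,
        notes=notes,
    )


def amova_from_mean_squares(
    ms_among: float,
    ms_within: float,
    pop_sizes,
    ss: tuple[float, float] | None = None,
) -> AmovaResult:
    """Solve the AMOVA variance components from mean squares and sample sizes.

    Useful both internally and for desk-checking published AMOVA tables whose
    mean squares and population sizes are printed.
    """
    sizes = np.asarray(pop_sizes, dtype=float)
    k = sizes.size
    N = sizes.sum()
    df_among = int(k - 1)
    df_within = int(N - k)
    n0 = (N - (sizes**2).sum() / N) / (k - 1)
    sigma2_w = ms_within
    sigma2_a = (ms_among - ms_within) / n0
    notes = []
    if sigma2_a < 0:
        notes.append("negative among-population component truncated at zero")
        sigma2_a = 0.0
    total = sigma2_a + sigma2_w
    phi = sigma2_a / total if total > 0 else 0.0
    ss_among = ss[0] if ss else ms_among * df_among
    ss_within = ss[1] if ss else ms_within * df_within
    return AmovaResult(
        df_among=df_among,
        df_within=df_within,
        ss_among=ss_among,
        ss_within=ss_within,
        ms_among=ms_among,
        ms_within=ms_within,
        n0=float(n0),
        sigma2_among=float(sigma2_a),
        sigma2_within=float(sigma2_w),
        pct_among=100.0 * sigma2_a / total if total > 0 else 0.0,
        pct_within=100.0 * sigma2_w / total if total > 0 else 100.0,
        phi_pt=float(phi),
        p_value=None,
        n_perm=0,
        notes=notes,
    )


def fst_and_nm(
    gm: GenotypeMatrix, pm: PopulationMap, corrected: bool = False
) -> pd.DataFrame:
    """Per-locus Fst (Nei Gst over unweighted population means) and Nm, with a Mean row.

    ``corrected=True`` applies the Nei & Chesser (1983) small-sample
    corrections (unbiased within-population gene diversity and the
    ``Hs/(2*n_tilde*k)`` total correction), appropriate when the goal is to
    recover the underlying differentiation parameter rather than to mirror
    the plug-in estimator of the standard desktop tools.

    Loci monomorphic over the pooled collection (Ht = 0) have undefined Fst;
    they appear as NaN and are excluded from the Mean row.
    """
    labels = pm.labels_for(gm.entry_ids)
    pops = pm.populations
    k = len(pops)
    if k < 2:
        raise ValueError("Fst needs at least two populations")
    codes, alleles = gm.indexed()
    obs = ~gm.missing_mask
    rows = []
    for l, locus in enumerate(gm.locus_ids):
        J = len(alleles[l])
        pmat = np.full((k, J), np.nan)
        ns = np.zeros(k)
        for g, p in enumerate(pops):
            idx = np.nonzero((labels == p) & obs[:, l])[0]
            if idx.size == 0:
                continue
            ns[g] = idx.size
            cnt = np.bincount(codes[idx, l, :].ravel(), minlength=J)
            pmat[g] = cnt / cnt.sum()
        have = ns > 0
        if have.sum() < 2:
            rows.append({"Locus": locus, "Hs": np.nan, "Ht": np.nan, "Fst": np.nan, "Nm": np.nan})
            continue
        P = pmat[have]
        n_g = ns[have]
        hs_g = 1.0 - np.sum(P**2, axis=1)
        if corrected:
            hs_g = hs_g * (2 * n_g) / (2 * n_g - 1)
        hs = float(hs_g.mean())
        pbar = P.mean(axis=0)
        ht = float(1.0 - np.sum(pbar**2))
        if corrected:
            n_tilde = have.sum() / np.sum(1.0 / n_g)  # harmonic mean
            ht = ht + hs / (2 * n_tilde * have.sum())
        if ht <= 1e-12:
            rows.append({"Locus": locus, "Hs": hs, "Ht": ht, "Fst": np.nan, "Nm": np.nan})
            continue
        fst = (ht - hs) / ht
        nm = 0.25 * (1.0 - fst) / fst if fst > 0 else np.nan
        rows.append({"Locus": locus, "Hs": hs, "Ht": ht, "Fst": fst, "Nm": nm})
    tab = pd.DataFrame(rows).set_index("Locus")
    tab.loc["Mean"] = tab.mean(axis=0, skipna=True)
    return tab
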