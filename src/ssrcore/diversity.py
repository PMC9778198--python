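"""Per-locus and per-population SSR diversity statistics.

For allele frequencies :math:`p_i` at a locus:

* ``Na`` — number of distinct alleles observed,
* ``Ne`` — effective number of alleles, :math:`1/\\sum p_i^2`,
* ``Ho`` — observed heterozygosity (fraction of non-missing genotypes whose
  two alleles differ),
* ``He`` — expected heterozygosity :math:`1-\\sum p_i^2`,
* ``uHe`` — Nei's unbiased expected heterozygosity
  :math:`\\frac{2n}{2n-1}\\,He` (``n`` = non-missing individuals),
* ``I`` — Shannon information index :math:`-\\sum p_i \\ln p_i`,
* ``PIC`` — polymorphism information content (Botstein),
  :math:`1-\\sum p_i^2-\\sum_{i<j}2p_i^2p_j^2`.

Missing genotypes are excluded from the denominator, following the CERVUS
convention.  A monomorphic locus yields Na=Ne=1 and zero for the remaining
statistics; it is a valid (degenerate) record, not an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, PopulationMap

STAT_COLUMNS = ["n", "Na", "Ne", "Ho", "He", "uHe", "I", "PIC"]


@dataclass
class AlleleFreqTable:
    """Relative allele frequencies per (group, locus).

    ``freqs[(group, locus)]`` is a pandas Series indexed by allele label;
    ``n[(group, locus)]`` is the count of non-missing individuals.  A
    (group, locus) cell with every call missing is absent from ``freqs`` and
    recorded in ``empty_cells``.
    """

    freqs: dict[tuple[str, str], pd.Series]
    n: dict[tuple[str, str], int]
    empty_cells: list[tuple[str, str]] = field(default_factory=list)


def allele_frequencies(
    gm: GenotypeMatrix, pm: PopulationMap | None = None
) -> AlleleFreqTable:
    """Tally each individual's two alleles within each group.

    With ``pm=None`` the whole collection forms a single group labelled
    ``"all"``.
    """
    if pm is None:
        groups = {"all": np.arange(gm.n_entries)}
    else:
        labels = pm.labels_for(gm.entry_ids)
        groups = {p: np.nonzero(labels == p)[0] for p in pm.populations}
    freqs: dict[tuple[str, str], pd.Series] = {}
    ns: dict[tuple[str, str], int] = {}
    empty: list[tuple[str, str]] = []
    obs = ~gm.missing_mask
    for g, rows in groups.items():
        for l, locus in enumerate(gm.locus_ids):
            ok = rows[obs[rows, l]]
            if ok.size == 0:
                empty.append((g, locus))
                continue
            alleles = gm.calls[ok, l, :].ravel()
            labels_, counts = np.unique(alleles.astype(str), return_counts=True)
            freqs[(g, locus)] = pd.Series(
                counts / counts.sum(), index=labels_, name=f"{g}:{locus}"
            )
            ns[(g, locus)] = int(ok.size)
    return AlleleFreqTable(freqs, ns, empty)


def _record_from_freqs(p: np.ndarray, n: int, ho: float) -> dict[str, float]:
    s2 = float(np.sum(p**2))
    s4 = float(np.sum(p**4))
    he = 1.0 - s2
    uhe = (2 * n / (2 * n - 1)) * he if n > 1 else np.nan
    shannon = float(-np.sum(p * np.log(p)))
    # sum_{i<j} 2 p_i^2 p_j^2 = (sum p^2)^2 - sum p^4
    pic = 1.0 - s2 - (s2**2 - s4)
    return {
        "n": n,
        "Na": int(p.size),
        "Ne": 1.0 / s2,
        "Ho": ho,
        "He": he,
        "uHe": uhe,
        "I": shannon,
        "PIC": pic,
    }


def _stats_for_rows(gm: GenotypeMatrix, rows: np.ndarray) -> pd.DataFrame:
    obs = ~gm.missing_mask
    out = []
    for l, locus in enumerate(gm.locus_ids):
        ok = rows[obs[rows, l]]
        if ok.size == 0:
            out.append({c: np.nan for c in STAT_COLUMNS} | {"n": 0, "Locus": locus})
            continue
        calls = gm.calls[ok, l, :].astype(str)
        _, counts = np.unique(calls.ravel(), return_counts=True)
        p = counts / counts.sum()
        ho = float(np.mean(calls[:, 0] != calls[:, 1]))
        out.append(_record_from_freqs(p, int(ok.size), ho) | {"Locus": locus})
    return pd.DataFrame(out).set_index("Locus")[STAT_COLUMNS]


def locus_stats(gm: GenotypeMatrix) -> pd.DataFrame:
    """Diversity record per locus over the whole collection (one group).

    Returns a DataFrame indexed by locus with columns
    ``n, Na, Ne, Ho, He, uHe, I, PIC``.
    """
    return _stats_for_rows(gm, np.arange(gm.n_entries))


def population_stats(
    gm: GenotypeMatrix, pm: PopulationMap, detail: bool = False
) -> pd.DataFrame | tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Within-population diversity, averaged over loci, plus a cross-population mean row.

    Statistics are computed per (population, locus) and then averaged over
    loci for each population; the ``Mean`` row holds the arithmetic mean of
    the per-population column values.  For a population of one individual
    ``uHe`` is undefined (NaN).  With ``detail=True`` the per-locus tables are
    returned as well.
    """
    labels = pm.labels_for(gm.entry_ids)
    per_pop: dict[str, pd.DataFrame] = {}
    rows = []
    for p in pm.populations:
        idx = np.nonzero(labels == p)[0]
        tab = _stats_for_rows(gm, idx)
        per_pop[p] = tab
        mean = tab.mean(axis=0, skipna=True)
        mean["n"] = idx.size
        rows.append(mean.rename(p))
    out = pd.DataFrame(rows)
    out.loc["Mean"] = out.mean(axis=0)
    out.loc["Mean", "n"] = out["n"].iloc[:-1].mean()
    out.index.name = "Population"
    return (out, per_pop) if detail else out


def locus_table(gm: GenotypeMatrix, pm: PopulationMap | None = None) -> pd.DataFrame:
    """Per-locus report with the standard column set, plus Fst and Nm when a
    population map is supplied, and a trailing ``Mean`` row."""
    tab = locus_stats(gm)[["Na", "Ne", "Ho", "He", "PIC", "I"]].copy()
    if pm is not None:
        from .amova import fst_and_nm

        f = fst_and_nm(gm, pm)
        tab["Fst"] = f["Fst"]
        tab["Nm"] = f["Nm"]
    tab.loc["Mean"] = tab.mean(axis=0, skipna=True)
    return tab
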