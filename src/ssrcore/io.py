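"""Readers, writers and validated containers for SSR genotype and phenotype data.

Three interchange formats are supported:

* GenAlEx-style CSV — numeric header rows (loci / entries / populations /
  population sizes), then one row per individual with two allele columns per
  locus.
* plain two-column CSV — one header row, one row per individual, columns
  ``entry_id, population, <locus>.1, <locus>.2, ...``.
* STRUCTURE text — two rows per individual, one integer allele column per
  locus, missing coded as -9.

Allele labels are opaque strings compared by equality; nothing downstream
assigns numeric meaning (such as repeat length) to them.  The missing codes
``0``, ``-9``, the empty string and ``NA`` are all normalized to one internal
marker on input, and a half-called genotype (one readable allele) is demoted
to fully missing because every codominant statistic downstream needs both
allele copies.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: internal marker for a missing allele call
MISSING = ""

#: input tokens normalized to :data:`MISSING`
MISSING_CODES = {"", "0", "-9", "NA", "na", "?"}


class GenotypeParseError(ValueError):
    """Raised when an input file violates the format or the container invariants."""


def _normalize_allele(token: str) -> str:
    token = token.strip()
    return MISSING if token in MISSING_CODES else token


@dataclass
class GenotypeMatrix:
    """Diploid SSR genotypes: two allele calls per (entry, locus) cell.

    Parameters
    ----------
    entry_ids : ordered unique individual identifiers.
    locus_ids : ordered unique marker identifiers.
    calls : object ndarray of shape ``(n_entries, n_loci, 2)`` holding allele
        label strings; both slots equal to the empty string mark a missing call.
    """

    entry_ids: list[str]
    locus_ids: list[str]
    calls: np.ndarray
    ploidy: int = 2
    _index_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.entry_ids = [str(e) for e in self.entry_ids]
        self.locus_ids = [str(l) for l in self.locus_ids]
        if len(set(self.entry_ids)) != len(self.entry_ids):
            dup = _first_duplicate(self.entry_ids)
            raise GenotypeParseError(f"duplicate entry ID {dup!r}")
        if len(set(self.locus_ids)) != len(self.locus_ids):
            dup = _first_duplicate(self.locus_ids)
            raise GenotypeParseError(f"duplicate locus ID {dup!r}")
        calls = np.asarray(self.calls, dtype=object)
        if calls.shape != (len(self.entry_ids), len(self.locus_ids), 2):
            raise GenotypeParseError(
                f"calls shape {calls.shape} does not match "
                f"{len(self.entry_ids)} entries x {len(self.locus_ids)} loci x 2"
            )
        # demote half-calls to fully missing
        one_missing = (calls[:, :, 0] == MISSING) ^ (calls[:, :, 1] == MISSING)
        if one_missing.any():
            calls = calls.copy()
            calls[one_missing] = MISSING
        self.calls = calls
        all_missing_locus = self.missing_mask.all(axis=0)
        if all_missing_locus.any():
            bad = [l for l, m in zip(self.locus_ids, all_missing_locus) if m]
            raise GenotypeParseError(f"loci with no non-missing call: {bad}")

    # -- basic geometry ----------------------------------------------------
    @property
    def n_entries(self) -> int:
        return len(self.entry_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean ``(n_entries, n_loci)``; True where the call is missing."""
        return np.asarray(self.calls[:, :, 0] == MISSING)

    def missing_rate(self) -> float:
        return float(self.missing_mask.mean())

    # -- integer-coded view ------------------------------------------------
    def indexed(self) -> tuple[np.ndarray, list[np.ndarray]]:
        """Integer-coded calls.

        Returns ``(codes, alleles)`` where ``codes`` is an int ndarray of shape
        ``(n_entries, n_loci, 2)`` with -1 for missing, and ``alleles[l]`` is
        the sorted array of distinct allele labels observed at locus ``l``
        (``codes[i, l, a]`` indexes into it).
        """
        if "indexed" not in self._index_cache:
            n, L = self.n_entries, self.n_loci
            codes = np.full((n, L, 2), -1, dtype=np.int32)
            alleles: list[np.ndarray] = []
            for l in range(L):
                col = self.calls[:, l, :]
                labels = sorted({a for a in col.ravel() if a != MISSING})
                lut = {a: i for i, a in enumerate(labels)}
                for i in range(n):
                    a, b = col[i]
                    if a != MISSING:
                        codes[i, l, 0] = lut[a]
                        codes[i, l, 1] = lut[b]
                alleles.append(np.asarray(labels, dtype=object))
            self._index_cache["indexed"] = (codes, alleles)
        return self._index_cache["indexed"]

    def allele_count_blocks(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-locus allele-count vectors, concatenated over loci.

        Returns ``(counts, locus_of_col, obs)``: ``counts`` is an
        ``(n_entries, total_alleles)`` int array of per-entry allele dosages
        (0/1/2, rows sum to 2 per non-missing locus), ``locus_of_col`` maps
        each column to its locus index and ``obs`` is the non-missing mask
        ``(n_entries, n_loci)``.
        """
        if "blocks" not in self._index_cache:
            codes, alleles = self.indexed()
            sizes = [len(a) for a in alleles]
            offs = np.concatenate([[0], np.cumsum(sizes)])
            counts = np.zeros((self.n_entries, offs[-1]), dtype=np.int16)
            for l in range(self.n_loci):
                for slot in range(2):
                    c = codes[:, l, slot]
                    ok = c >= 0
                    np.add.at(counts, (np.nonzero(ok)[0], offs[l] + c[ok]), 1)
            locus_of_col = np.repeat(np.arange(self.n_loci), sizes)
            self._index_cache["blocks"] = (counts, locus_of_col, ~self.missing_mask)
        return self._index_cache["blocks"]

    def subset(self, entry_ids: Sequence[str]) -> "GenotypeMatrix":
        """Row-subset preserving the requested order; IDs must exist."""
        pos = {e: i for i, e in enumerate(self.entry_ids)}
        missing = [e for e in entry_ids if e not in pos]
        if missing:
            raise KeyError(f"unknown entry IDs: {missing}")
        rows = [pos[e] for e in entry_ids]
        return GenotypeMatrix(list(entry_ids), list(self.locus_ids), self.calls[rows])


@dataclass
class PopulationMap:
    """Mapping from entry ID to population label."""

    assignments: dict[str, str]

    def __post_init__(self) -> None:
        self.assignments = {str(k): str(v) for k, v in self.assignments.items()}
        if not self.assignments:
            raise GenotypeParseError("population map is empty")

    def __getitem__(self, entry_id: str) -> str:
        return self.assignments[entry_id]

    def __len__(self) -> int:
        return len(self.assignments)

    @property
    def populations(self) -> list[str]:
        """Population labels in first-appearance order."""
        seen: dict[str, None] = {}
        for p in self.assignments.values():
            seen.setdefault(p, None)
        return list(seen)

    def sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for p in self.assignments.values():
            out[p] = out.get(p, 0) + 1
        return out

    def labels_for(self, entry_ids: Sequence[str]) -> np.ndarray:
        unmapped = [e for e in entry_ids if e not in self.assignments]
        if unmapped:
            raise GenotypeParseError(f"entries without population assignment: {unmapped}")
        return np.asarray([self.assignments[e] for e in entry_ids], dtype=object)


@dataclass
class PhenotypeTable:
    """Numeric trait measurements per entry; NaN marks a missing cell."""

    entry_ids: list[str]
    trait_ids: list[str]
    values: np.ndarray
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.entry_ids = [str(e) for e in self.entry_ids]
        self.trait_ids = [str(t) for t in self.trait_ids]
        if len(set(self.entry_ids)) != len(self.entry_ids):
            raise GenotypeParseError(
                f"duplicate entry ID {_first_duplicate(self.entry_ids)!r}"
            )
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (len(self.entry_ids), len(self.trait_ids)):
            raise GenotypeParseError("phenotype value shape mismatch")
        self.values = vals
        for j, t in enumerate(self.trait_ids):
            col = vals[:, j]
            finite = col[np.isfinite(col)]
            if finite.size and np.unique(finite).size < 2:
                self.warnings.append(f"trait {t!r} is constant")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.entry_ids, columns=self.trait_ids)

    def subset(self, entry_ids: Sequence[str]) -> "PhenotypeTable":
        pos = {e: i for i, e in enumerate(self.entry_ids)}
        rows = [pos[e] for e in entry_ids]
        return PhenotypeTable(list(entry_ids), list(self.trait_ids), self.values[rows])


def _first_duplicate(items: Iterable[str]) -> str:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return ""


# ---------------------------------------------------------------------------
# genotype CSV dialects
# ---------------------------------------------------------------------------

def read_genotypes(
    path: str | Path, dialect: str = "two-column-csv"
) -> tuple[GenotypeMatrix, PopulationMap | None]:
    """Read a genotype table; returns the matrix and, when present, the population map."""
    path = Path(path)
    if dialect == "genalex-csv":
        return _read_genalex(path)
    if dialect == "two-column-csv":
        return _read_two_column(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_two_column(path: Path) -> tuple[GenotypeMatrix, PopulationMap | None]:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise GenotypeParseError(f"{path}: empty file")
    header = [h.strip() for h in rows[0]]
    has_pop = len(header) > 1 and header[1].lower() in {"pop", "population"}
    first_allele = 2 if has_pop else 1
    allele_cols = header[first_allele:]
    if len(allele_cols) % 2:
        raise GenotypeParseError(
            f"{path}: odd number of allele columns ({len(allele_cols)})"
        )
    locus_ids = [c.rsplit(".", 1)[0] for c in allele_cols[::2]]
    entry_ids, pops, calls = [], {}, []
    for r, row in enumerate(rows[1:], start=2):
        if not any(cell.strip() for cell in row):
            continue
        if len(row) != len(header):
            raise GenotypeParseError(f"{path}: row {r} has {len(row)} fields, expected {len(header)}")
        eid = row[0].strip()
        if eid in pops or eid in set(entry_ids):
            raise GenotypeParseError(f"{path}: row {r}: duplicate entry ID {eid!r}")
        entry_ids.append(eid)
        if has_pop:
            pops[eid] = row[1].strip()
        toks = [_normalize_allele(t) for t in row[first_allele:]]
        calls.append([[toks[2 * l], toks[2 * l + 1]] for l in range(len(locus_ids))])
    gm = GenotypeMatrix(entry_ids, locus_ids, np.asarray(calls, dtype=object))
    return gm, (PopulationMap(pops) if has_pop else None)


def _read_genalex(path: Path) -> tuple[GenotypeMatrix, PopulationMap]:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if len(rows) < 4:
        raise GenotypeParseError(f"{path}: too short for GenAlEx layout")
    try:
        n_loci = int(rows[0][0])
        n_entries = int(rows[0][1])
        n_pops = int(rows[0][2])
    except (ValueError, IndexError) as exc:
        raise GenotypeParseError(f"{path}: malformed GenAlEx numeric header") from exc
    header = rows[2]
    allele_cols = header[2:]
    if len(allele_cols) < 2 * n_loci:
        raise GenotypeParseError(f"{path}: header names fewer than {2 * n_loci} allele columns")
    locus_ids = [allele_cols[2 * l].strip() for l in range(n_loci)]
    entry_ids, pops, calls = [], {}, []
    for r, row in enumerate(rows[3:], start=4):
        if not any(cell.strip() for cell in row):
            continue
        eid = row[0].strip()
        if eid in pops:
            raise GenotypeParseError(f"{path}: row {r}: duplicate entry ID {eid!r}")
        entry_ids.append(eid)
        pops[eid] = row[1].strip()
        toks = [_normalize_allele(t) for t in row[2 : 2 + 2 * n_loci]]
        if len(toks) < 2 * n_loci:
            raise GenotypeParseError(f"{path}: row {r}: expected {2 * n_loci} allele fields")
        calls.append([[toks[2 * l], toks[2 * l + 1]] for l in range(n_loci)])
    if len(entry_ids) != n_entries:
        raise GenotypeParseError(
            f"{path}: header announces {n_entries} entries, found {len(entry_ids)}"
        )
    pm = PopulationMap(pops)
    if len(pm.populations) != n_pops:
        raise GenotypeParseError(
            f"{path}: header announces {n_pops} populations, found {len(pm.populations)}"
        )
    gm = GenotypeMatrix(entry_ids, locus_ids, np.asarray(calls, dtype=object))
    return gm, pm


def write_genotypes(
    gm: GenotypeMatrix,
    path: str | Path,
    pm: PopulationMap | None = None,
    dialect: str = "two-column-csv",
) -> None:
    path = Path(path)
    if dialect == "two-column-csv":
        _write_two_column(gm, pm, path)
    elif dialect == "genalex-csv":
        if pm is None:
            raise ValueError("GenAlEx dialect requires a population map")
        _write_genalex(gm, pm, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _row_for(gm: GenotypeMatrix, i: int) -> list[str]:
    out = []
    for l in range(gm.n_loci):
        a, b = gm.calls[i, l]
        out += [a if a != MISSING else "NA", b if b != MISSING else "NA"]
    return out


def _write_two_column(gm: GenotypeMatrix, pm: PopulationMap | None, path: Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        head = ["entry_id"] + (["population"] if pm else [])
        for l in gm.locus_ids:
            head += [f"{l}.1", f"{l}.2"]
        w.writerow(head)
        for i, eid in enumerate(gm.entry_ids):
            row = [eid] + ([pm[eid]] if pm else []) + _row_for(gm, i)
            w.writerow(row)


def _write_genalex(gm: GenotypeMatrix, pm: PopulationMap, path: Path) -> None:
    pops = pm.populations
    sizes = pm.sizes()
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([gm.n_loci, gm.n_entries, len(pops)] + [sizes[p] for p in pops])
        w.writerow(["SSR genotypes", "", ""] + pops)
        head = ["entry_id", "population"]
        for l in gm.locus_ids:
            head += [l, ""]
        w.writerow(head)
        # GenAlEx groups individuals by population
        for p in pops:
            for i, eid in enumerate(gm.entry_ids):
                if pm[eid] == p:
                    w.writerow([eid, p] + _row_for(gm, i))


# ---------------------------------------------------------------------------
# STRUCTURE format
# ---------------------------------------------------------------------------

def write_structure_file(gm: GenotypeMatrix, pm: PopulationMap, path: str | Path) -> None:
    """Two rows per individual; allele labels must be integer-mappable; missing = -9."""
    bad = sorted(
        {
            str(a)
            for a in gm.calls.ravel()
            if a != MISSING and not str(a).lstrip("-").isdigit()
        }
    )
    if bad:
        raise GenotypeParseError(f"allele labels not mappable to integers: {bad}")
    pops = {p: i + 1 for i, p in enumerate(pm.populations)}
    with open(path, "w") as fh:
        fh.write("\t".join(["id", "pop"] + gm.locus_ids) + "\n")
        for i, eid in enumerate(gm.entry_ids):
            for slot in range(2):
                alleles = [
                    str(gm.calls[i, l, slot]) if gm.calls[i, l, slot] != MISSING else "-9"
                    for l in range(gm.n_loci)
                ]
                fh.write("\t".join([eid, str(pops[pm[eid]])] + alleles) + "\n")


def read_structure_file(path: str | Path) -> tuple[GenotypeMatrix, PopulationMap]:
    with open(path) as fh:
        lines = [ln.rstrip("\n").split("\t") for ln in fh if ln.strip()]
    if len(lines) < 3 or (len(lines) - 1) % 2:
        raise GenotypeParseError(f"{path}: expected a header plus two rows per individual")
    locus_ids = lines[0][2:]
    entry_ids, pops, calls = [], {}, []
    for j in range(1, len(lines), 2):
        r1, r2 = lines[j], lines[j + 1]
        if r1[0] != r2[0]:
            raise GenotypeParseError(f"{path}: row pair mismatch at {r1[0]!r}/{r2[0]!r}")
        eid = r1[0]
        if eid in pops:
            raise GenotypeParseError(f"{path}: duplicate entry ID {eid!r}")
        entry_ids.append(eid)
        pops[eid] = f"pop{r1[1]}"
        calls.append(
            [
                [_normalize_allele(r1[2 + l]), _normalize_allele(r2[2 + l])]
                for l in range(len(locus_ids))
            ]
        )
    gm = GenotypeMatrix(entry_ids, locus_ids, np.asarray(calls, dtype=object))
    return gm, PopulationMap(pops)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Delimited text, header row of trait names, first column entry ID."""
    path = Path(path)
    df = pd.read_csv(path, index_col=0, dtype=str)
    values = np.empty(df.shape, dtype=float)
    for j, trait in enumerate(df.columns):
        for i, cell in enumerate(df.iloc[:, j]):
            tok = "" if cell is None or (isinstance(cell, float) and np.isnan(cell)) else str(cell).strip()
            if tok in {"", "NA", "na", "NaN", "nan"}:
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(tok)
            except ValueError as exc:
                raise GenotypeParseError(
                    f"{path}: non-numeric value {tok!r} at entry {df.index[i]!r}, trait {trait!r}"
                ) from exc
    return PhenotypeTable(list(df.index.astype(str)), list(df.columns.astype(str)), values)


def write_phenotypes(pt: PhenotypeTable, path: str | Path) -> None:
    df = pt.to_frame()
    df.index.name = "entry_id"
    df.to_csv(path, na_rep="NA")
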