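"""Reading, writing and validating diploid microsatellite genotypes.

Genotypes are unordered pairs of positive integer allele codes (typically
repeat counts or fragment lengths); ``0`` encodes a missing allele.  A call is
either fully typed (both alleles > 0) or fully missing -- half-calls found in
input files are promoted to missing with a logged warning, because no
downstream statistic can use a single allele copy.

Supported on-disk formats:

* GenePop: title line, one locus name per line (or a single comma-separated
  line), ``Pop`` separators, and per individual ``id ,  0102 0000 ...`` with
  2- or 3-digit allele encodings (``00``/``000`` = missing).
* CSV-wide: columns ``id, <locus>_a1, <locus>_a2``; empty cells = missing.
* CSV-long: columns ``id, locus, allele1, allele2``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: sentinel allele code for a missing allele copy
MISSING = 0

GENOTYPE_FORMATS = ("genepop", "csv-wide", "csv-long")


class GenotypeParseError(ValueError):
    """A genotype file could not be parsed (malformed field, bad layout)."""


class GenotypeValidationError(ValueError):
    """Parsed data violate the genotype-table invariants."""


class GenotypeEncodingError(ValueError):
    """An allele code cannot be represented in the requested output encoding."""


class GenotypeTable:
    """Diploid multilocus genotypes for an ordered set of individuals.

    Parameters
    ----------
    individuals : sequence of str
        Unique identifiers, order preserved.
    loci : sequence of str
        Unique locus names, order preserved.
    calls : array-like, shape (n_individuals, n_loci, 2)
        Allele codes; ``0`` for missing.  Each pair is canonicalised to
        ascending order so genotype equality is well defined.
    """

    def __init__(
        self,
        individuals: Sequence[str],
        loci: Sequence[str],
        calls: np.ndarray,
    ) -> None:
        self.individuals = tuple(str(i) for i in individuals)
        self.loci = tuple(str(l) for l in loci)
        if len(set(self.individuals)) != len(self.individuals):
            dupes = sorted({i for i in self.individuals if self.individuals.count(i) > 1})
            raise GenotypeValidationError(f"duplicate individual id(s): {dupes[:5]}")
        if len(set(self.loci)) != len(self.loci):
            raise GenotypeValidationError("duplicate locus names")
        calls = np.asarray(calls, dtype=np.int32)
        if calls.shape != (len(self.individuals), len(self.loci), 2):
            raise GenotypeValidationError(
                f"calls shape {calls.shape} does not match "
                f"({len(self.individuals)}, {len(self.loci)}, 2)"
            )
        if (calls < 0).any():
            raise GenotypeValidationError("negative allele code")
        half = (calls == MISSING).sum(axis=2) == 1
        if half.any():
            i, l = np.argwhere(half)[0]
            raise GenotypeValidationError(
                f"half-missing call for individual {self.individuals[i]!r} "
                f"at locus {self.loci[l]!r}"
            )
        self.calls = np.sort(calls, axis=2)
        self.calls.flags.writeable = False
        self._index = {ind: k for k, ind in enumerate(self.individuals)}
        self._locus_index = {loc: k for k, loc in enumerate(self.loci)}

    # -- basic interface ---------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def typed_mask(self) -> np.ndarray:
        """Boolean (n_individuals, n_loci) array: True where the call is typed."""
        return self.calls[:, :, 0] != MISSING

    def index_of(self, individual: str) -> int:
        try:
            return self._index[individual]
        except KeyError:
            raise KeyError(f"unknown individual {individual!r}") from None

    def locus_index(self, locus: str) -> int:
        try:
            return self._locus_index[locus]
        except KeyError:
            raise KeyError(f"unknown locus {locus!r}") from None

    def genotype(self, individual: str, locus: str) -> tuple[int, int]:
        g = self.calls[self.index_of(individual), self.locus_index(locus)]
        return int(g[0]), int(g[1])

    def genotypes_of(self, individual: str) -> np.ndarray:
        """(n_loci, 2) genotype vector of one individual."""
        return self.calls[self.index_of(individual)]

    def monomorphic_loci(self) -> tuple[str, ...]:
        """Loci with at most one distinct observed allele (flagged, not dropped)."""
        out = []
        for j, locus in enumerate(self.loci):
            alleles = self.calls[:, j, :][self.calls[:, j, :] != MISSING]
            if np.unique(alleles).size <= 1:
                out.append(locus)
        return tuple(out)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            self.individuals == other.individuals
            and self.loci == other.loci
            and np.array_equal(self.calls, other.calls)
        )

    def __repr__(self) -> str:
        return f"GenotypeTable({self.n_individuals} individuals, {self.n_loci} loci)"


@dataclass(frozen=True)
class AlleleFrequencies:
    """Per-locus allele frequency estimates.

    ``n_typed`` holds the number of individuals with a non-missing call per
    locus and drives the small-sample (falling-factorial) moment corrections;
    ``None`` marks frequencies that are exact population values (e.g. the
    generating frequencies of a simulation), for which no correction applies.
    """

    loci: tuple[str, ...]
    freqs: tuple[Mapping[int, float], ...]
    n_typed: tuple[int | None, ...]

    def __post_init__(self) -> None:
        if len(self.freqs) != len(self.loci) or len(self.n_typed) != len(self.loci):
            raise ValueError("loci, freqs and n_typed must align")
        for locus, f in zip(self.loci, self.freqs):
            if not f:
                raise ValueError(f"locus {locus!r} has no alleles")
            if any(a <= 0 for a in f):
                raise ValueError(f"locus {locus!r}: allele codes must be positive")
            total = sum(f.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"locus {locus!r}: frequencies sum to {total}, not 1")

    @classmethod
    def from_frequencies(
        cls,
        loci: Sequence[str],
        freqs: Sequence[Mapping[int, float]],
        n_typed: Sequence[int | None] | None = None,
    ) -> "AlleleFrequencies":
        if n_typed is None:
            n_typed = [None] * len(loci)
        return cls(tuple(loci), tuple(dict(f) for f in freqs), tuple(n_typed))

    def _locus_pos(self, locus: str) -> int:
        try:
            return self.loci.index(locus)
        except ValueError:
            raise KeyError(f"unknown locus {locus!r}") from None

    def frequencies(self, locus: str) -> Mapping[int, float]:
        return self.freqs[self._locus_pos(locus)]

    def frequency_array(self, locus: str) -> np.ndarray:
        return np.array(sorted(self.frequencies(locus).values())[::-1], dtype=float)

    def moments(self, locus: str, corrected: bool = False) -> tuple[float, float, float]:
        """Sums of powers of allele frequencies (a2, a3, a4) for one locus.

        With ``corrected=True`` and a finite ``n_typed``, unbiased estimates of
        sum(p^k) are returned, computed from falling factorials of the allele
        counts in the 2*n_typed sampled gene copies.
        """
        j = self._locus_pos(locus)
        p = np.array(list(self.freqs[j].values()), dtype=float)
        n = self.n_typed[j]
        if not corrected or n is None:
            return float(np.sum(p**2)), float(np.sum(p**3)), float(np.sum(p**4))
        N = 2 * n
        s2, s3, s4 = (float(np.sum(p**k)) for k in (2, 3, 4))
        a2 = (N * s2 - 1.0) / (N - 1.0)
        a3 = (N * N * s3 - 3.0 * N * s2 + 2.0) / ((N - 1.0) * (N - 2.0))
        a4 = (N**3 * s4 - 6.0 * N * N * s3 + 11.0 * N * s2 - 6.0) / (
            (N - 1.0) * (N - 2.0) * (N - 3.0)
        )
        return a2, a3, a4


@dataclass(frozen=True)
class LocusExclusionList:
    """Locus names to drop before analysis (e.g. unreliable markers)."""

    loci: tuple[str, ...]

    @classmethod
    def of(cls, *loci: str) -> "LocusExclusionList":
        return cls(tuple(loci))


# ---------------------------------------------------------------------------
# Allele frequency estimation
# ---------------------------------------------------------------------------


def allele_frequencies(table: GenotypeTable) -> AlleleFrequencies:
    """Estimate per-locus allele frequencies by gene counting.

    Frequency of allele *a* at locus *l* is its count among non-missing
    allele copies over ``2 * n_typed(l)``; missing calls are excluded from
    numerator and denominator alike.
    """
    freqs: list[dict[int, float]] = []
    n_typed: list[int] = []
    for j, locus in enumerate(table.loci):
        col = table.calls[:, j, :]
        typed = col[:, 0] != MISSING
        n = int(typed.sum())
        if n == 0:
            raise GenotypeValidationError(f"locus {locus!r} has zero typed individuals")
        alleles, counts = np.unique(col[typed].ravel(), return_counts=True)
        freqs.append({int(a): float(c) / (2 * n) for a, c in zip(alleles, counts)})
        n_typed.append(n)
    return AlleleFrequencies.from_frequencies(table.loci, freqs, n_typed)


def apply_exclusions(table: GenotypeTable, excl: LocusExclusionList) -> GenotypeTable:
    """Drop the excluded loci; individuals are untouched."""
    unknown = [l for l in excl.loci if l not in table.loci]
    if unknown:
        raise GenotypeValidationError(f"unknown locus name(s) in exclusion list: {unknown}")
    keep = [j for j, l in enumerate(table.loci) if l not in excl.loci]
    if not keep:
        raise GenotypeValidationError("exclusion list removes every locus")
    return GenotypeTable(
        table.individuals,
        [table.loci[j] for j in keep],
        table.calls[:, keep, :],
    )


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_genotypes(path: str | Path, format: str) -> GenotypeTable:
    """Read a genotype file in one of :data:`GENOTYPE_FORMATS`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "genepop":
        return _read_genepop(path)
    if format == "csv-wide":
        return _read_csv_wide(path)
    if format == "csv-long":
        return _read_csv_long(path)
    raise ValueError(f"unknown genotype format {format!r}; expected one of {GENOTYPE_FORMATS}")


def _promote_half_calls(calls: np.ndarray, individuals, loci, where: str) -> np.ndarray:
    half = (calls == MISSING).sum(axis=2) == 1
    if half.any():
        n = int(half.sum())
        i, l = np.argwhere(half)[0]
        logger.warning(
            "%s: %d half-missing call(s) promoted to fully missing "
            "(first: individual %r, locus %r)",
            where, n, individuals[i], loci[l],
        )
        calls = calls.copy()
        calls[half] = MISSING
    return calls


def _read_genepop(path: Path) -> GenotypeTable:
    lines = path.read_text(encoding="utf-8").splitlines()
    if len(lines) < 3:
        raise GenotypeParseError(f"{path}: not a GenePop file (fewer than 3 lines)")
    # line 0 is the title; locus names follow until the first "Pop"
    loci: list[str] = []
    body_start = None
    for k, line in enumerate(lines[1:], start=1):
        if line.strip().lower() == "pop":
            body_start = k + 1
            break
        for name in line.split(","):
            name = name.strip()
            if name:
                loci.append(name)
    if body_start is None:
        raise GenotypeParseError(f"{path}: no 'Pop' line found")
    if not loci:
        raise GenotypeParseError(f"{path}: no locus names before first 'Pop'")

    individuals: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    width: int | None = None
    for k in range(body_start, len(lines)):
        line = lines[k].strip()
        if not line:
            continue
        if line.lower() == "pop":
            continue  # populations are concatenated
        if "," not in line:
            raise GenotypeParseError(f"{path}:{k + 1}: missing ',' after individual id")
        ind, _, geno = line.partition(",")
        ind = ind.strip()
        tokens = geno.split()
        if len(tokens) != len(loci):
            raise GenotypeParseError(
                f"{path}:{k + 1}: expected {len(loci)} genotype fields, got {len(tokens)}"
            )
        row: list[tuple[int, int]] = []
        for locus, tok in zip(loci, tokens):
            if not re.fullmatch(r"\d+", tok) or len(tok) not in (4, 6):
                raise GenotypeParseError(
                    f"{path}:{k + 1}: malformed allele field {tok!r} at locus {locus!r}"
                )
            w = len(tok) // 2
            if width is None:
                width = w
            elif w != width:
                raise GenotypeParseError(
                    f"{path}:{k + 1}: mixed {2 * width}- and {2 * w}-digit "
                    f"allele encodings at locus {locus!r}"
                )
            row.append((int(tok[:w]), int(tok[w:])))
        individuals.append(ind)
        rows.append(row)
    if not individuals:
        raise GenotypeParseError(f"{path}: no individuals after 'Pop'")
    calls = np.array(rows, dtype=np.int32)
    calls = _promote_half_calls(calls, individuals, loci, str(path))
    return GenotypeTable(individuals, loci, calls)


def _read_csv_wide(path: Path) -> GenotypeTable:
    df = pd.read_csv(path, dtype={0: str})
    if df.columns[0] != "id":
        raise GenotypeParseError(f"{path}: first column must be 'id', got {df.columns[0]!r}")
    loci: list[str] = []
    for col in df.columns[1:]:
        if col.endswith("_a1"):
            base = col[:-3]
            if f"{base}_a2" not in df.columns:
                raise GenotypeParseError(f"{path}: column {base}_a2 missing")
            loci.append(base)
        elif not col.endswith("_a2"):
            raise GenotypeParseError(f"{path}: unexpected column {col!r}")
    if not loci:
        raise GenotypeParseError(f"{path}: no <locus>_a1/<locus>_a2 column pairs")
    calls = np.zeros((len(df), len(loci), 2), dtype=np.int32)
    for j, locus in enumerate(loci):
        for s, c in enumerate(("_a1", "_a2")):
            vals = pd.to_numeric(df[locus + c], errors="coerce")
            calls[:, j, s] = vals.fillna(MISSING).astype(np.int32)
    individuals = df["id"].astype(str).tolist()
    calls = _promote_half_calls(calls, individuals, loci, str(path))
    return GenotypeTable(individuals, loci, calls)


def _read_csv_long(path: Path) -> GenotypeTable:
    df = pd.read_csv(path, dtype={"id": str, "locus": str})
    required = {"id", "locus", "allele1", "allele2"}
    if not required.issubset(df.columns):
        raise GenotypeParseError(f"{path}: need columns {sorted(required)}")
    individuals = list(dict.fromkeys(df["id"]))
    loci = list(dict.fromkeys(df["locus"]))
    calls = np.zeros((len(individuals), len(loci), 2), dtype=np.int32)
    ind_ix = {v: k for k, v in enumerate(individuals)}
    loc_ix = {v: k for k, v in enumerate(loci)}
    a1 = pd.to_numeric(df["allele1"], errors="coerce").fillna(MISSING).astype(np.int32)
    a2 = pd.to_numeric(df["allele2"], errors="coerce").fillna(MISSING).astype(np.int32)
    for row, v1, v2 in zip(df.itertuples(index=False), a1, a2):
        calls[ind_ix[row.id], loc_ix[row.locus]] = (v1, v2)
    calls = _promote_half_calls(calls, individuals, loci, str(path))
    return GenotypeTable(individuals, loci, calls)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_genotypes(
    table: GenotypeTable,
    path: str | Path,
    format: str,
    genepop_digits: int = 3,
    title: str = "hetmate export",
) -> None:
    """Write a genotype table; the output round-trips through :func:`read_genotypes`."""
    path = Path(path)
    if table.n_loci == 0:
        raise GenotypeValidationError("cannot write a table with zero loci")
    if format == "genepop":
        _write_genepop(table, path, genepop_digits, title)
    elif format == "csv-wide":
        _write_csv_wide(table, path)
    else:
        raise ValueError(f"unsupported output format {format!r}")


def _write_genepop(table: GenotypeTable, path: Path, digits: int, title: str) -> None:
    if digits not in (2, 3):
        raise GenotypeEncodingError("GenePop allele width must be 2 or 3 digits")
    limit = 10**digits
    if (table.calls >= limit).any():
        bad = int(table.calls.max())
        raise GenotypeEncodingError(
            f"allele code {bad} does not fit the {digits}-digit GenePop encoding"
        )
    out = [title]
    out.extend(table.loci)
    out.append("Pop")
    for i, ind in enumerate(table.individuals):
        fields = [
            f"{a:0{digits}d}{b:0{digits}d}" for a, b in table.calls[i]
        ]
        out.append(f"{ind} ,  " + " ".join(fields))
    path.write_text("\n".join(out) + "\n", encoding="utf-8")


def _write_csv_wide(table: GenotypeTable, path: Path) -> None:
    data: dict[str, object] = {"id": list(table.individuals)}
    for j, locus in enumerate(table.loci):
        for s, suffix in enumerate(("_a1", "_a2")):
            col = table.calls[:, j, s].astype(object)
            data[locus + suffix] = [a if a != MISSING else None for a in col]
    pd.DataFrame(data).to_csv(path, index=False)
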