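"""Genotype and breeding-pair ingestion.

Diploid microsatellite genotypes are stored as integer allele codes (fragment
lengths or arbitrary labels); codes are compared by equality only, never by
magnitude.  A genotype is either missing or exactly two codes; homozygotes
carry the same code twice.  Missing is encoded internally as ``MISSING`` (-1)
in both slots and accepted on input as an empty cell, ``NA``, or ``0``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "Individual",
    "GenotypeTable",
    "AlleleFrequencySet",
    "PairRecord",
    "read_genotypes",
    "write_genotypes",
    "allele_frequencies",
    "read_pairs",
    "pair_records_from_frame",
    "write_pairs",
]

MISSING = -1

_SEX_ALIASES = {
    "f": "female", "female": "female",
    "m": "male", "male": "male",
    "u": "unknown", "unknown": "unknown", "": "unknown", "na": "unknown",
}


def _normalize_sex(raw: object) -> str:
    key = str(raw).strip().lower()
    if key not in _SEX_ALIASES:
        raise ValueError(f"unrecognized sex value {raw!r}")
    return _SEX_ALIASES[key]


@dataclass(frozen=True)
class Individual:
    """One genotyped adult: stable id, sex, and the breeding seasons it was captured in."""

    id: str
    sex: str  # "female" | "male" | "unknown"
    years: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male", "unknown"):
            raise ValueError(f"invalid sex {self.sex!r} for individual {self.id!r}")


class GenotypeTable:
    """Individuals x loci diploid genotype matrix with fixed locus order.

    Parameters
    ----------
    individuals:
        Sequence of :class:`Individual`; ids must be unique.
    loci:
        Ordered locus names, identical for every individual.
    genotypes:
        Integer array of shape ``(n_individuals, n_loci, 2)``; missing
        genotypes have ``MISSING`` in both slots.
    """

    def __init__(
        self,
        individuals: Sequence[Individual],
        loci: Sequence[str],
        genotypes: np.ndarray,
    ) -> None:
        genotypes = np.asarray(genotypes, dtype=np.int64)
        if genotypes.shape != (len(individuals), len(loci), 2):
            raise ValueError(
                f"genotype array shape {genotypes.shape} does not match "
                f"{len(individuals)} individuals x {len(loci)} loci x 2"
            )
        ids = [ind.id for ind in individuals]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate individual ids: {dupes}")
        if len(set(loci)) != len(loci):
            raise ValueError("duplicate locus names")
        half_missing = (genotypes == MISSING).sum(axis=2) == 1
        if half_missing.any():
            raise ValueError("a genotype must be missing in both allele slots or neither")
        self.individuals: list[Individual] = list(individuals)
        self.loci: list[str] = list(loci)
        self.genotypes = genotypes
        self._index = {ind.id: k for k, ind in enumerate(self.individuals)}

    # -- basic accessors ---------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def ids(self) -> list[str]:
        return [ind.id for ind in self.individuals]

    def index_of(self, individual_id: str) -> int:
        try:
            return self._index[individual_id]
        except KeyError:
            raise KeyError(f"unknown individual id {individual_id!r}") from None

    def sex_of(self, individual_id: str) -> str:
        return self.individuals[self.index_of(individual_id)].sex

    def genotype(self, individual_id: str) -> np.ndarray:
        """(n_loci, 2) allele codes for one individual."""
        return self.genotypes[self.index_of(individual_id)]

    def missing_mask(self) -> np.ndarray:
        """(n, L) boolean array, True where the genotype is missing."""
        return self.genotypes[:, :, 0] == MISSING

    def subset(self, ids: Iterable[str]) -> "GenotypeTable":
        idx = [self.index_of(i) for i in ids]
        return GenotypeTable(
            [self.individuals[k] for k in idx], self.loci, self.genotypes[idx]
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            self.individuals == other.individuals
            and self.loci == other.loci
            and np.array_equal(self.genotypes, other.genotypes)
        )

    def __repr__(self) -> str:
        return f"GenotypeTable({self.n_individuals} individuals, {self.n_loci} loci)"

    # -- dataframe bridge --------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        cols: dict[str, list] = {
            "id": self.ids,
            "sex": [ind.sex for ind in self.individuals],
            "years": [";".join(str(y) for y in sorted(ind.years)) for ind in self.individuals],
        }
        for j, locus in enumerate(self.loci):
            for slot in (0, 1):
                vals = self.genotypes[:, j, slot]
                cols[f"{locus}_{slot + 1}"] = ["" if v == MISSING else int(v) for v in vals]
        return pd.DataFrame(cols)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenotypeTable":
        required = ("id", "sex", "years")
        for col in required:
            if col not in df.columns:
                raise ValueError(f"genotype table is missing required column {col!r}")
        allele_cols = [c for c in df.columns if c not in required]
        if len(allele_cols) % 2 != 0:
            raise ValueError(
                f"odd number of allele columns ({len(allele_cols)}); "
                "expected two columns per locus"
            )
        loci: list[str] = []
        for k in range(0, len(allele_cols), 2):
            c1, c2 = allele_cols[k], allele_cols[k + 1]
            if not (c1.endswith("_1") and c2.endswith("_2") and c1[:-2] == c2[:-2]):
                raise ValueError(f"allele columns {c1!r}, {c2!r} do not form a <locus>_1/_2 pair")
            loci.append(c1[:-2])
        individuals = []
        geno = np.full((len(df), len(loci), 2), MISSING, dtype=np.int64)
        for row_pos, (_, row) in enumerate(df.iterrows()):
            years = frozenset(
                int(tok) for tok in str(row["years"]).split(";") if tok.strip() not in ("", "nan")
            )
            try:
                individuals.append(Individual(str(row["id"]), _normalize_sex(row["sex"]), years))
            except ValueError as exc:
                raise ValueError(f"row {row_pos + 1}: {exc}") from exc
            for j, locus in enumerate(loci):
                a = _parse_allele(row[f"{locus}_1"], row_pos, locus)
                b = _parse_allele(row[f"{locus}_2"], row_pos, locus)
                if (a == MISSING) != (b == MISSING):
                    raise ValueError(
                        f"row {row_pos + 1}, locus {locus!r}: half-missing genotype"
                    )
                geno[row_pos, j] = (a, b)
        return cls(individuals, loci, geno)


def _parse_allele(value: object, row_pos: int, locus: str) -> int:
    """Allele cell -> integer code; empty / NA / 0 are the missing sentinels."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return MISSING
    text = str(value).strip()
    if text.lower() in ("", "na", "nan"):
        return MISSING
    try:
        code = int(float(text))
    except ValueError:
        raise ValueError(
            f"row {row_pos + 1}, locus {locus!r}: unparseable allele {value!r}"
        ) from None
    return MISSING if code == 0 else code


# ---------------------------------------------------------------------------
# readers / writers


def read_genotypes(
    path: str | Path,
    dialect: str = "csv",
    sidecar: str | Path | None = None,
) -> GenotypeTable:
    """Read a genotype table.

    ``dialect="csv"`` expects columns ``id, sex, years, <locus>_1, <locus>_2, ...``
    with years semicolon-separated.  ``dialect="genepop"`` reads a standard
    GenePop file (2- or 3-digit allele encoding, ``0`` = missing); sex and
    capture years then come from a ``sidecar`` CSV with columns
    ``id, sex, years`` (optional — without it all individuals are sex-unknown).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "csv":
        try:
            df = pd.read_csv(path, dtype=str, keep_default_na=False)
        except pd.errors.ParserError as exc:
            raise ValueError(f"malformed genotype CSV {path}: {exc}") from exc
        return GenotypeTable.from_frame(df)
    if dialect == "genepop":
        return _read_genepop(path, sidecar)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_genepop(path: Path, sidecar: str | Path | None) -> GenotypeTable:
    from Bio.PopGen import GenePop

    with open(path) as fh:
        record = GenePop.read(fh)
    meta: dict[str, tuple[str, frozenset]] = {}
    if sidecar is not None:
        side = pd.read_csv(sidecar, dtype=str, keep_default_na=False)
        for _, row in side.iterrows():
            years = frozenset(
                int(tok) for tok in str(row.get("years", "")).split(";") if tok.strip()
            )
            meta[str(row["id"])] = (_normalize_sex(row["sex"]), years)
    individuals: list[Individual] = []
    rows: list[list[tuple[int, int]]] = []
    for pop in record.populations:
        for name, genos in pop:
            ident = str(name).strip().rstrip(",").strip()
            sex, years = meta.get(ident, ("unknown", frozenset()))
            individuals.append(Individual(ident, sex, years))
            parsed = []
            for g in genos:
                if g is None or g[0] in (None, 0) or (len(g) > 1 and g[1] in (None, 0)):
                    parsed.append((MISSING, MISSING))
                elif len(g) == 1:  # haploid entry in an otherwise diploid file
                    raise ValueError(f"haploid genotype for {ident!r}; diploid data expected")
                else:
                    parsed.append((int(g[0]), int(g[1])))
            rows.append(parsed)
    geno = np.array(rows, dtype=np.int64) if rows else np.empty((0, len(record.loci_list), 2), int)
    return GenotypeTable(individuals, list(record.loci_list), geno)


def write_genotypes(table: GenotypeTable, path: str | Path) -> None:
    """Write the CSV dialect read back by :func:`read_genotypes` (exact round trip)."""
    table.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# allele frequencies


class AlleleFrequencySet:
    """Per-locus allele relative frequencies plus sample sizes.

    ``freqs[locus]`` maps allele code -> relative frequency; frequencies at a
    locus sum to one and are strictly positive.  ``n_typed[locus]`` is the
    number of non-missing genotypes the estimate is based on; ``counts``
    (optional) carries the raw allele-copy counts, used by estimators that
    apply small-sample moment corrections.
    """

    def __init__(
        self,
        loci: Sequence[str],
        freqs: Mapping[str, Mapping[int, float]],
        n_typed: Mapping[str, int],
        counts: Mapping[str, Mapping[int, int]] | None = None,
    ) -> None:
        self.loci = list(loci)
        self.freqs = {l: dict(freqs[l]) for l in self.loci}
        self.n_typed = {l: int(n_typed[l]) for l in self.loci}
        self.counts = {l: dict(counts[l]) for l in self.loci} if counts is not None else None
        for locus in self.loci:
            f = self.freqs[locus]
            if not f:
                raise ValueError(f"locus {locus!r} has no alleles")
            total = sum(f.values())
            if abs(total - 1.0) > 1e-12:
                raise ValueError(f"frequencies at locus {locus!r} sum to {total}, not 1")
            if any(not (0.0 < p <= 1.0) for p in f.values()):
                raise ValueError(f"locus {locus!r} has a frequency outside (0, 1]")
        # sorted code / probability arrays for fast lookup by the estimators
        self._codes = {l: np.array(sorted(self.freqs[l]), dtype=np.int64) for l in self.loci}
        self._probs = {
            l: np.array([self.freqs[l][c] for c in self._codes[l]]) for l in self.loci
        }

    def codes(self, locus: str) -> np.ndarray:
        return self._codes[locus]

    def probs(self, locus: str) -> np.ndarray:
        return self._probs[locus]

    def lookup(self, locus: str, alleles: np.ndarray) -> np.ndarray:
        """Frequencies for an array of allele codes at one locus."""
        codes = self._codes[locus]
        pos = np.searchsorted(codes, alleles)
        pos = np.clip(pos, 0, len(codes) - 1)
        found = codes[pos] == alleles
        if not np.all(found):
            bad = np.asarray(alleles)[~found]
            raise KeyError(f"allele(s) {sorted(set(bad.tolist()))} unknown at locus {locus!r}")
        return self._probs[locus][pos]

    def n_alleles(self, locus: str) -> int:
        return len(self.freqs[locus])

    def __repr__(self) -> str:
        return f"AlleleFrequencySet({len(self.loci)} loci)"


def allele_frequencies(
    table: GenotypeTable, years: Iterable[int] | None = None
) -> AlleleFrequencySet:
    """Observed allele relative frequencies, pooled over all genotyped adults.

    Frequency of allele *a* at locus *l* is its count among non-missing allele
    copies divided by ``2 * n_typed``.  ``years`` restricts the estimate to
    individuals captured in any of the given seasons (off by default: the
    panel is pooled across seasons).
    """
    if years is not None:
        wanted = set(years)
        keep = [ind.id for ind in table.individuals if ind.years & wanted]
        table = table.subset(keep)
    freqs: dict[str, dict[int, float]] = {}
    counts: dict[str, dict[int, int]] = {}
    n_typed: dict[str, int] = {}
    for j, locus in enumerate(table.loci):
        col = table.genotypes[:, j, :]
        alleles = col[col != MISSING]
        if alleles.size == 0:
            raise ValueError(f"locus {locus!r} has no non-missing genotypes")
        codes, cnt = np.unique(alleles, return_counts=True)
        counts[locus] = {int(c): int(k) for c, k in zip(codes, cnt)}
        freqs[locus] = {int(c): k / alleles.size for c, k in zip(codes, cnt)}
        n_typed[locus] = alleles.size // 2
    return AlleleFrequencySet(table.loci, freqs, n_typed, counts)


# ---------------------------------------------------------------------------
# breeding pairs


@dataclass(frozen=True)
class PairRecord:
    """One social breeding pair in one season.

    ``remated`` is True when the same female-male combination also bred
    together in an earlier recorded season; ``first_observation`` is True in
    the first season the combination appears.
    """

    year: int
    female_id: str
    male_id: str
    remated: bool = False
    first_observation: bool = True


def pair_records_from_frame(df: pd.DataFrame, table: GenotypeTable) -> list[PairRecord]:
    """Validate a (year, female_id, male_id) frame and compute pair-history flags.

    Flags are computed by scanning seasons in ascending order, so they do not
    depend on input row order.  Raises on unknown ids, sex mismatches, or an
    individual appearing in two pairs within one year.
    """
    for col in ("year", "female_id", "male_id"):
        if col not in df.columns:
            raise ValueError(f"pair table is missing required column {col!r}")
    rows = [
        (int(r.year), str(r.female_id), str(r.male_id))
        for r in df.itertuples(index=False)
    ]
    for year, fid, mid in rows:
        for ident, expected in ((fid, "female"), (mid, "male")):
            sex = table.sex_of(ident)  # raises KeyError for unknown ids
            if sex not in (expected, "unknown"):
                raise ValueError(
                    f"individual {ident!r} is recorded as {sex} but appears as "
                    f"{expected} in year {year}"
                )
    seen_in_year: dict[int, set[str]] = {}
    for year, fid, mid in rows:
        bucket = seen_in_year.setdefault(year, set())
        for ident in (fid, mid):
            if ident in bucket:
                raise ValueError(
                    f"individual {ident!r} appears in more than one pair in year {year}"
                )
            bucket.add(ident)
    first_year: dict[tuple[str, str], int] = {}
    for year, fid, mid in sorted(rows):
        first_year.setdefault((fid, mid), year)
    records = [
        PairRecord(
            year=year,
            female_id=fid,
            male_id=mid,
            remated=year > first_year[(fid, mid)],
            first_observation=year == first_year[(fid, mid)],
        )
        for year, fid, mid in rows
    ]
    records.sort(key=lambda r: (r.year, r.female_id))
    return records


def read_pairs(path: str | Path, table: GenotypeTable) -> list[PairRecord]:
    """Read a breeding-pair CSV (columns year, female_id, male_id) and validate it."""
    df = pd.read_csv(path, dtype={"female_id": str, "male_id": str})
    return pair_records_from_frame(df, table)


def write_pairs(records: Sequence[PairRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "year": [r.year for r in records],
            "female_id": [r.female_id for r in records],
            "male_id": [r.male_id for r in records],
        }
    ).to_csv(path, index=False)
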