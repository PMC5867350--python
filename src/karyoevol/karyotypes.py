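"""Karyotype records, formula parsing, and the karyotype divergence index.

A karyotype is summarised by its diploid number (2n, chromosomes per
somatic cell), a karyotype formula (KF) pooling chromosomes into bi-armed
(metacentric/submetacentric, "m-sm") and uni-armed
(subtelocentric/acrocentric, "st-a") classes, and constitutive
heterochromatin (CH) band positions revealed by C-banding.  The fundamental
number (FN) counts chromosome arms: bi-armed chromosomes contribute two
arms, uni-armed one, so FN = 2n + (number of bi-armed chromosomes).

The divergence index between two karyotypes is

    D(a, b) = |2n_a - 2n_b| / 2 + |FN_a - FN_b| / 2

in units of chromosome-pair changes.  It is a semimetric: non-negative,
symmetric, and zero exactly when the two (2n, FN) pairs coincide.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Sex",
    "CHBand",
    "KaryotypeRecord",
    "DivergenceMatrix",
    "KaryotypeFormulaError",
    "parse_karyotype_formula",
    "format_karyotype_formula",
    "fundamental_number",
    "divergence_index",
    "divergence_matrix",
    "compare_ch_bands",
    "parse_ch_bands",
    "format_ch_bands",
    "read_karyotype_table",
    "write_karyotype_table",
    "select_by_sex",
]


class Sex(str, Enum):
    male = "male"
    female = "female"
    unspecified = "unspecified"


class Arm(str, Enum):
    p = "p"
    q = "q"
    whole = "whole"
    pericentromeric = "pericentromeric"
    centromeric = "centromeric"


class BandPosition(str, Enum):
    centromeric = "centromeric"
    pericentromeric = "pericentromeric"
    proximal = "proximal"
    interstitial = "interstitial"
    distal = "distal"
    whole_arm = "whole_arm"


@dataclass(frozen=True, order=True)
class CHBand:
    """One constitutive-heterochromatin band site.

    ``chromosome_pair`` is the 1-based pair index as printed in karyograms;
    pair 0 is reserved for whole-karyotype bands ("centromeric region of
    all chromosomes").  Band identity is the triple
    (chromosome_pair, arm, position).
    """

    chromosome_pair: int
    arm: Arm
    position: BandPosition

    def __post_init__(self) -> None:
        if self.chromosome_pair < 0:
            raise ValueError("chromosome_pair must be >= 0 (0 = all pairs)")


class KaryotypeFormulaError(ValueError):
    """Raised when a karyotype-formula string cannot be parsed."""


_KF_PART = re.compile(r"^(\d+)(m-sm|st-a)$")


def parse_karyotype_formula(text: str) -> tuple[int, int]:
    """Parse a karyotype formula into (biarmed_count, uniarmed_count).

    Accepts the dialect ``"<N>m-sm/<M>st-a"``, ``"<N>m-sm"`` or
    ``"<M>st-a"``; an absent class counts as zero.

    >>> parse_karyotype_formula("38m-sm/2st-a")
    (38, 2)
    >>> parse_karyotype_formula("38st-a")
    (0, 38)
    """
    biarmed: int | None = None
    uniarmed: int | None = None
    stripped = text.strip()
    if not stripped:
        raise KaryotypeFormulaError("empty karyotype formula")
    for part in stripped.split("/"):
        m = _KF_PART.match(part.strip())
        if m is None:
            raise KaryotypeFormulaError(
                f"malformed karyotype-formula token {part.strip()!r} in {text!r}"
            )
        count, cls = int(m.group(1)), m.group(2)
        if cls == "m-sm":
            if biarmed is not None:
                raise KaryotypeFormulaError(f"duplicate m-sm class in {text!r}")
            biarmed = count
        else:
            if uniarmed is not None:
                raise KaryotypeFormulaError(f"duplicate st-a class in {text!r}")
            uniarmed = count
    return biarmed or 0, uniarmed or 0


def format_karyotype_formula(biarmed_count: int, uniarmed_count: int) -> str:
    """Inverse of :func:`parse_karyotype_formula` (canonical form)."""
    parts = []
    if biarmed_count:
        parts.append(f"{biarmed_count}m-sm")
    if uniarmed_count:
        parts.append(f"{uniarmed_count}st-a")
    if not parts:
        raise KaryotypeFormulaError("karyotype with zero chromosomes")
    return "/".join(parts)


@dataclass
class KaryotypeRecord:
    """One species/sex karyotype row.

    Invariants: ``biarmed_count + uniarmed_count == diploid_number`` and
    ``fundamental_number == diploid_number + biarmed_count``.
    """

    species_name: str
    diploid_number: int
    biarmed_count: int
    uniarmed_count: int
    sex: Sex = Sex.unspecified
    ch_bands: list[CHBand] = field(default_factory=list)
    sex_system: str | None = None

    def __post_init__(self) -> None:
        if self.diploid_number < 2:
            raise ValueError(f"{self.species_name}: diploid number must be >= 2")
        if self.biarmed_count < 0 or self.uniarmed_count < 0:
            raise ValueError(f"{self.species_name}: negative arm-class count")
        if self.biarmed_count + self.uniarmed_count != self.diploid_number:
            raise ValueError(
                f"{self.species_name}: arm-class counts "
                f"{self.biarmed_count}+{self.uniarmed_count} != 2n={self.diploid_number}"
            )
        for band in self.ch_bands:
            if band.chromosome_pair > self.diploid_number // 2:
                raise ValueError(
                    f"{self.species_name}: CH band pair {band.chromosome_pair} "
                    f"exceeds {self.diploid_number // 2} pairs"
                )

    @property
    def fundamental_number(self) -> int:
        return fundamental_number(self)

    @property
    def karyotype_formula(self) -> str:
        return format_karyotype_formula(self.biarmed_count, self.uniarmed_count)

    @classmethod
    def from_formula(
        cls,
        species_name: str,
        diploid_number: int,
        karyotype_formula: str,
        **kwargs,
    ) -> "KaryotypeRecord":
        biarmed, uniarmed = parse_karyotype_formula(karyotype_formula)
        return cls(
            species_name=species_name,
            diploid_number=diploid_number,
            biarmed_count=biarmed,
            uniarmed_count=uniarmed,
            **kwargs,
        )


def fundamental_number(record: KaryotypeRecord) -> int:
    """Chromosome-arm count: FN = 2n + number of bi-armed chromosomes."""
    return record.diploid_number + record.biarmed_count


def divergence_index(a: KaryotypeRecord, b: KaryotypeRecord) -> float:
    """Karyotype divergence index |d2n|/2 + |dFN|/2 (chromosome-pair changes)."""
    d2n = abs(a.diploid_number - b.diploid_number)
    dfn = abs(fundamental_number(a) - fundamental_number(b))
    return d2n / 2.0 + dfn / 2.0


@dataclass
class DivergenceMatrix:
    """Symmetric pairwise divergence-index matrix with an ordered taxon list."""

    taxa: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match taxon list")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("divergence matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("divergence matrix diagonal must be zero")
        if np.any(self.values < 0):
            raise ValueError("divergence matrix entries must be non-negative")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.taxa.index(a), self.taxa.index(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.taxa, columns=self.taxa)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="species")

    def to_phylip(self, path: str | Path) -> None:
        """Square PHYLIP distance-matrix format."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.taxa)}\n")
            for name, row in zip(self.taxa, self.values):
                fh.write(name + "  " + "  ".join(f"{v:.6f}" for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DivergenceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(taxa=list(df.columns), values=df.to_numpy())


def divergence_matrix(records: Sequence[KaryotypeRecord]) -> DivergenceMatrix:
    """All-pairs divergence indices for a set of karyotype records."""
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    names = [r.species_name for r in records]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate species names: {dupes}")
    n = len(records)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = divergence_index(records[i], records[j])
    return DivergenceMatrix(taxa=names, values=values)


def compare_ch_bands(
    a: KaryotypeRecord, b: KaryotypeRecord
) -> tuple[int, int, int]:
    """Compare CH band sets: (shared, a-only, b-only) site counts.

    Band identity is the (chromosome_pair, arm, position) triple; the three
    counts partition the union of the two band sets.
    """
    sa, sb = set(a.ch_bands), set(b.ch_bands)
    return len(sa & sb), len(sa - sb), len(sb - sa)


# --- CH band site-code serialization -------------------------------------
#
# Site codes follow the textual granularity of published karyotype tables:
#   cen:all      centromeric region of all chromosomes
#   cen:7        centromeric band on pair 7
#   pericen:1p   pericentromeric band on 1p
#   prox:8q      proximal band on 8q
#   int:12q      interstitial band on 12q
#   dist:9p      distal band on 9p
#   band:1p      whole-arm block on 1p (position not further specified)

_POSITION_CODES = {
    "cen": BandPosition.centromeric,
    "pericen": BandPosition.pericentromeric,
    "prox": BandPosition.proximal,
    "int": BandPosition.interstitial,
    "dist": BandPosition.distal,
    "band": BandPosition.whole_arm,
}
_POSITION_TO_CODE = {v: k for k, v in _POSITION_CODES.items()}
_SITE = re.compile(r"^(\d+)([pq]?)$")


def parse_ch_bands(text: str) -> list[CHBand]:
    """Parse a semicolon-separated CH site-code string (e.g. ``cen:all;int:2q``)."""
    bands: list[CHBand] = []
    if not text or text.strip() in {"", "-", "na"}:
        return bands
    for token in text.strip().split(";"):
        token = token.strip()
        if not token:
            continue
        try:
            code, site = token.split(":")
        except ValueError as exc:
            raise ValueError(f"malformed CH site code {token!r}") from exc
        position = _POSITION_CODES.get(code)
        if position is None:
            raise ValueError(f"unknown CH position code {code!r} in {token!r}")
        if site == "all":
            bands.append(CHBand(0, Arm.whole, position))
            continue
        m = _SITE.match(site)
        if m is None:
            raise ValueError(f"malformed CH site {site!r} in {token!r}")
        pair = int(m.group(1))
        arm = Arm(m.group(2)) if m.group(2) else Arm.whole
        bands.append(CHBand(pair, arm, position))
    return bands


def format_ch_bands(bands: Iterable[CHBand]) -> str:
    tokens = []
    for band in bands:
        code = _POSITION_TO_CODE[band.position]
        if band.chromosome_pair == 0:
            tokens.append(f"{code}:all")
        else:
            arm = "" if band.arm is Arm.whole else band.arm.value
            tokens.append(f"{code}:{band.chromosome_pair}{arm}")
    return ";".join(tokens)


# --- Karyotype table I/O --------------------------------------------------

_TABLE_COLUMNS = [
    "species",
    "sex",
    "diploid_number",
    "karyotype_formula",
    "ch_bands",
    "sex_system",
]


def read_karyotype_table(path: str | Path) -> list[KaryotypeRecord]:
    """Read a karyotype TSV (species, sex, 2n, KF, CH site codes, sex system)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _TABLE_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"karyotype table missing columns: {missing}")
    records = []
    for _, row in df.iterrows():
        records.append(
            KaryotypeRecord.from_formula(
                species_name=row["species"],
                diploid_number=int(row["diploid_number"]),
                karyotype_formula=row["karyotype_formula"],
                sex=Sex(row.get("sex") or "unspecified"),
                ch_bands=parse_ch_bands(row.get("ch_bands", "")),
                sex_system=(row.get("sex_system") or None),
            )
        )
    return records


def write_karyotype_table(records: Sequence[KaryotypeRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "species": r.species_name,
                "sex": r.sex.value,
                "diploid_number": r.diploid_number,
                "karyotype_formula": r.karyotype_formula,
                "ch_bands": format_ch_bands(r.ch_bands),
                "sex_system": r.sex_system or "",
            }
        )
    pd.DataFrame(rows, columns=_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def select_by_sex(
    records: Sequence[KaryotypeRecord], preference: Sex = Sex.female
) -> list[KaryotypeRecord]:
    """One record per species, resolving sex-dimorphic karyotypes.

    Species with a sex-chromosome system carry one row per sex; the female
    complement (even, homomorphic) is the default for interspecific
    comparison, with ``preference`` selecting the male complement instead.
    Species with a single unspecified-sex row pass through unchanged.
    """
    by_species: dict[str, list[KaryotypeRecord]] = {}
    for r in records:
        by_species.setdefault(r.species_name, []).append(r)
    out = []
    for name, rows in by_species.items():
        if len(rows) == 1:
            out.append(rows[0])
            continue
        chosen = [r for r in rows if r.sex is preference]
        if not chosen:
            chosen = [r for r in rows if r.sex is Sex.unspecified]
        if len(chosen) != 1:
            raise ValueError(f"{name}: cannot resolve a unique {preference.value} record")
        out.append(chosen[0])
    return out
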