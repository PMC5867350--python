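"""Packaged fixture data for the Brachyhypopomus analysis.

Three small files ship with the package:

* ``brachyhypopomus_karyotypes.tsv`` — the published cytogenetic compilation
  for eleven Brachyhypopomus species (diploid number, karyotype formula,
  CH band sites, sex-chromosome systems), one row per species/sex.
* ``hypopomidae_topology.nwk`` — the species-tree topology used for
  ancestral reconstruction, with the well-supported internal clades
  carrying their published labels (A, B, C, H, J, K, M, T, 2).  Branch
  lengths are not part of the fixture; analyses apply Grafen lengths with
  root depth 1.
* ``outgroup_diploid_numbers.tsv`` — diploid numbers for the outgroup tips
  (Sternopygus, Rhamphichthyidae, and the Steatogenys clade).  These are
  fixture assumptions taken from the gymnotiform cytogenetic literature
  (Rhamphichthyidae conserves 2n = 50; Sternopygus carries the high 2n =
  52 end of the scale), not values measured in this package.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .karyotypes import KaryotypeRecord, Sex, read_karyotype_table, select_by_sex
from .phylo import Phylogeny, read_newick

__all__ = [
    "data_path",
    "load_karyotypes",
    "load_topology",
    "load_outgroup_diploids",
    "fixture_diploid_numbers",
    "fixture_haploid_numbers",
]

INGROUP_LABEL = "Brachyhypopomus"


def data_path(name: str) -> Path:
    return Path(resources.files("karyoevol") / "data" / name)


def load_karyotypes() -> list[KaryotypeRecord]:
    """All karyotype rows (sex-dimorphic species contribute one row per sex)."""
    return read_karyotype_table(data_path("brachyhypopomus_karyotypes.tsv"))


def load_topology() -> Phylogeny:
    """The fixture species-tree topology (no branch lengths)."""
    return read_newick(data_path("hypopomidae_topology.nwk"))


def load_outgroup_diploids() -> dict[str, int]:
    df = pd.read_csv(data_path("outgroup_diploid_numbers.tsv"), sep="\t")
    return dict(zip(df["species"], df["diploid_number"].astype(int)))


def fixture_diploid_numbers(sex: Sex = Sex.female) -> dict[str, int]:
    """Diploid number per tree tip: karyotyped ingroup plus outgroup values.

    Sex-dimorphic species resolve to the requested complement (female by
    default, which is even and homomorphic).
    """
    records = select_by_sex(load_karyotypes(), preference=sex)
    values = {r.species_name: r.diploid_number for r in records}
    values.update(load_outgroup_diploids())
    return values


def fixture_haploid_numbers(sex: Sex = Sex.female) -> dict[str, int]:
    """Haploid numbers (2n/2) per tip; odd diploid complements are rejected."""
    out = {}
    for name, diploid in fixture_diploid_numbers(sex=sex).items():
        if diploid % 2:
            raise ValueError(
                f"{name}: odd diploid number {diploid}; "
                "use the female complement for haploid states"
            )
        out[name] = diploid // 2
    return out
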