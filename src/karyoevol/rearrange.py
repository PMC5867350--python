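"""Inference of Robertsonian fusions/fissions and pericentric inversions.

Rearrangement accounting works in chromosome-pair units on even diploid
numbers:

* a Robertsonian fusion joins the chromosomes of two uni-armed pairs into
  one bi-armed pair, reducing 2n by 2; a fission is the reverse;
* a pericentric inversion toggles one pair between uni-armed and bi-armed
  without changing 2n.

Between two karyotypes with diploid numbers 2n_a >= 2n_b, the number of
fusions is f = (2n_a - 2n_b) / 2.  Each fusion adds one bi-armed pair on
the lower-2n side, so the expected bi-armed pair count there is
m_higher + f; the pericentric inversion count is the absolute difference
between the observed and expected bi-armed pairs.  With equal diploid
numbers this reduces to |m_a - m_b|.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .chromevol import DiscreteAncestral
from .karyotypes import KaryotypeRecord, compare_ch_bands
from .phylo import Phylogeny

__all__ = [
    "BranchEvents",
    "infer_fusion_fission",
    "infer_pericentric_inversions",
    "annotate_tree_events",
    "write_branch_events",
]


@dataclass
class BranchEvents:
    """Event counts on the branch subtending ``branch_id`` (child node name).

    ``pericentric_inversions`` is filled only on terminal branches whose
    sister is also a karyotyped tip: internal karyotype formulas are not
    reconstructed, so inversion counts are tip-to-sister-tip divergences.
    ``ch_changed`` likewise flags CH-band divergence between sister tips.
    """

    branch_id: str
    fusions: int
    fissions: int
    pericentric_inversions: int | None = None
    ch_changed: bool | None = None

    def __post_init__(self) -> None:
        if self.fusions < 0 or self.fissions < 0:
            raise ValueError("event counts must be non-negative")
        if self.fusions and self.fissions:
            raise ValueError("a branch is net one direction: fusions * fissions must be 0")


def infer_fusion_fission(parent_2n: int, child_2n: int) -> tuple[int, int]:
    """(fusions, fissions) along a parent -> child diploid-number change."""
    for v, label in ((parent_2n, "parent"), (child_2n, "child")):
        if v <= 0 or v % 2:
            raise ValueError(f"{label} diploid number must be even and positive, got {v}")
    diff = parent_2n - child_2n
    if diff >= 0:
        return diff // 2, 0
    return 0, -diff // 2


def _biarmed_pairs(record: KaryotypeRecord) -> int:
    if record.biarmed_count % 2:
        raise ValueError(
            f"{record.species_name}: odd bi-armed count {record.biarmed_count}; "
            "pair-level accounting needs even class counts"
        )
    return record.biarmed_count // 2


def infer_pericentric_inversions(a: KaryotypeRecord, b: KaryotypeRecord) -> int:
    """Pericentric inversions separating two karyotypes (pair units).

    Symmetric in its arguments.  With unequal diploid numbers, fusions are
    first credited to the lower-2n karyotype (each converting two uni-armed
    pairs to one bi-armed pair) and inversions make up the remaining
    bi-armed-pair discrepancy.
    """
    if a.diploid_number % 2 or b.diploid_number % 2:
        raise ValueError("even diploid numbers required (use the female complement)")
    hi, lo = (a, b) if a.diploid_number >= b.diploid_number else (b, a)
    fusions, _ = infer_fusion_fission(hi.diploid_number, lo.diploid_number)
    expected_lo = _biarmed_pairs(hi) + fusions
    return abs(_biarmed_pairs(lo) - expected_lo)


def annotate_tree_events(
    tree: Phylogeny,
    ancestral: Sequence[DiscreteAncestral] | Mapping[str, int],
    tips: Sequence[KaryotypeRecord],
    tip_diploids: Mapping[str, int] | None = None,
) -> list[BranchEvents]:
    """Per-branch fusion/fission counts from reconstructed diploid states.

    Internal nodes take their diploid number from the ancestral
    reconstruction — either a list of :class:`DiscreteAncestral` or a
    ``{node_id: haploid state}`` mapping as returned by the joint
    reconstruction; tips take theirs from the karyotype records (or
    ``tip_diploids`` for tips without records, e.g. outgroups).
    Pericentric inversions and CH changes are evaluated on leaf cherries
    only, as tip-to-sister-tip divergences.
    """
    if isinstance(ancestral, Mapping):
        by_node = {k: 2 * int(v) for k, v in ancestral.items()}
    else:
        by_node = {a.node_id: a.best_diploid for a in ancestral}
    records = {r.species_name: r for r in tips}
    diploids: dict[int, int] = {}
    names: dict[int, str] = {}
    for k, node in enumerate(tree.root.preorder()):
        names[id(node)] = node.name if node.name else f"N{k}"
    for node in tree.root.preorder():
        nid = names[id(node)]
        if node.is_leaf:
            if nid in records:
                diploids[id(node)] = records[nid].diploid_number
            elif tip_diploids and nid in tip_diploids:
                diploids[id(node)] = int(tip_diploids[nid])
            else:
                raise ValueError(f"no diploid state for tip {nid!r}")
        else:
            if nid not in by_node:
                raise ValueError(f"no reconstructed state for internal node {nid!r}")
            diploids[id(node)] = by_node[nid]

    events: list[BranchEvents] = []
    for node in tree.root.preorder():
        if node is tree.root:
            continue
        fus, fis = infer_fusion_fission(diploids[id(node.parent)], diploids[id(node)])
        inv = None
        ch = None
        if node.is_leaf and node.name in records:
            siblings = [s for s in node.parent.children if s is not node]
            sister_tips = [s for s in siblings if s.is_leaf and s.name in records]
            if len(sister_tips) == 1:
                sister = records[sister_tips[0].name]
                own = records[node.name]
                inv = infer_pericentric_inversions(own, sister)
                shared, a_only, b_only = compare_ch_bands(own, sister)
                ch = bool(a_only or b_only)
        events.append(
            BranchEvents(
                branch_id=names[id(node)],
                fusions=fus,
                fissions=fis,
                pericentric_inversions=inv,
                ch_changed=ch,
            )
        )
    return events


def write_branch_events(events: Sequence[BranchEvents], path: str | Path) -> None:
    rows = [
        {
            "child_node": e.branch_id,
            "fusions": e.fusions,
            "fissions": e.fissions,
            "inversions": "" if e.pericentric_inversions is None else e.pericentric_inversions,
            "ch_changed": "" if e.ch_changed is None else str(e.ch_changed).lower(),
        }
        for e in events
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
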