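"""Synthetic data generators: Yule trees, Brownian traits, CTMC histories.

Everything is driven by ``numpy.random.SeedSequence`` so that a single
integer seed reproduces a whole simulation, and per-branch child streams
are spawned from the root sequence (keyed by the branch's preorder index)
so that the draws on one branch never depend on the traversal order of the
others.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .chromevol import RateModelSpec, build_rate_matrix
from .karyotypes import Arm, BandPosition, CHBand, KaryotypeRecord, Sex
from .phylo import Phylogeny, TreeNode

__all__ = [
    "random_yule_tree",
    "simulate_bm",
    "simulate_chrom_ctmc",
    "SimulatedEvent",
    "replay_events",
    "fabricate_karyotype_table",
]


def random_yule_tree(n_tips: int, birth_rate: float = 1.0, seed: int = 0) -> Phylogeny:
    """Pure-birth (Yule) tree with ``n_tips`` leaves, scaled to root height 1.

    Lineages split at rate ``birth_rate`` each; after the last split all
    pendant branches are extended to the present, so the tree is
    ultrametric.  Scaling to unit height matches the Grafen-prepared
    empirical trees used elsewhere in the package.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    root = TreeNode()
    first = [root.add_child(TreeNode()), root.add_child(TreeNode())]
    active: list[TreeNode] = first
    birth_time = {id(c): 0.0 for c in active}
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        k = rng.integers(len(active))
        node = active.pop(int(k))
        node.parent_edge_length = t - birth_time[id(node)]
        for _ in range(2):
            child = node.add_child(TreeNode())
            birth_time[id(child)] = t
            active.append(child)
    t_end = t + rng.exponential(1.0 / (birth_rate * len(active)))
    labels = iter(f"t{i + 1}" for i in range(n_tips))
    for node in active:
        node.parent_edge_length = t_end - birth_time[id(node)]
        node.name = next(labels)
    tree = Phylogeny(root)
    # rescale to root height exactly 1
    height = max(tree.depths().values())
    for node in tree.root.preorder():
        if node.parent_edge_length is not None:
            node.parent_edge_length /= height
    return tree


def simulate_bm(
    tree: Phylogeny,
    sigma2: float,
    root_value: float,
    lambda_signal: float = 1.0,
    seed: int = 0,
) -> dict[str, float]:
    """Tip values from (lambda-transformed) Brownian motion.

    Draws one multivariate normal sample with mean ``root_value`` and
    covariance ``sigma2`` times the lambda-transformed shared-path matrix.
    ``lambda_signal = 1`` is pure Brownian motion; ``0`` makes tips
    independent normals.
    """
    from .ancestral import phylo_covariance, _lambda_transform

    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    if not 0.0 <= lambda_signal <= 1.0:
        raise ValueError("lambda_signal must be in [0, 1]")
    names, C = phylo_covariance(tree)
    if sigma2 == 0:
        return {n: float(root_value) for n in names}
    cov = sigma2 * _lambda_transform(C, lambda_signal)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    values = rng.multivariate_normal(np.full(len(names), root_value), cov, method="cholesky")
    return dict(zip(names, map(float, values)))


@dataclass(frozen=True)
class SimulatedEvent:
    """One CTMC jump: which branch, when (from branch start), and the move."""

    branch_id: int  # preorder index of the child node
    time: float
    from_state: int
    to_state: int

    @property
    def kind(self) -> str:
        d = self.to_state - self.from_state
        if d == 1:
            return "gain"
        if d == -1:
            return "loss"
        return "duplication"


def simulate_chrom_ctmc(
    tree: Phylogeny,
    spec: RateModelSpec,
    rates: Mapping[str, float],
    root_haploid: int,
    seed: int = 0,
) -> tuple[dict[str, int], list[SimulatedEvent]]:
    """Gillespie simulation of haploid chromosome number along the tree.

    The jump process uses exactly the truncated generator matrix of the
    likelihood machinery, so transitions that would leave the state window
    simply never fire.  Returns tip states and the full event log;
    :func:`replay_events` reproduces the tips from the log.
    """
    spec.state_index(root_haploid)  # bounds check
    Q = build_rate_matrix(spec, rates)
    states = spec.states
    root_ss = np.random.SeedSequence(seed)
    nodes = list(tree.root.preorder())
    branch_streams = {
        id(node): np.random.default_rng(child_ss)
        for node, child_ss in zip(nodes, root_ss.spawn(len(nodes)))
    }
    preorder_index = {id(node): k for k, node in enumerate(nodes)}

    node_state: dict[int, int] = {id(tree.root): root_haploid}
    events: list[SimulatedEvent] = []
    tips: dict[str, int] = {}
    for node in tree.root.preorder():
        if node is tree.root:
            continue
        rng = branch_streams[id(node)]
        s = node_state[id(node.parent)]
        t_total = node.parent_edge_length
        if t_total is None:
            raise ValueError("missing branch length")
        clock = 0.0
        while True:
            i = spec.state_index(s)
            rate = -Q[i, i]
            if rate <= 0:
                break
            clock += rng.exponential(1.0 / rate)
            if clock >= t_total:
                break
            probs = Q[i].copy()
            probs[i] = 0.0
            probs /= probs.sum()
            j = int(rng.choice(len(states), p=probs))
            nxt = int(states[j])
            events.append(
                SimulatedEvent(
                    branch_id=preorder_index[id(node)],
                    time=clock,
                    from_state=s,
                    to_state=nxt,
                )
            )
            s = nxt
        node_state[id(node)] = s
        if node.is_leaf:
            tips[node.name] = s
    return tips, events


def replay_events(
    tree: Phylogeny, root_haploid: int, events: list[SimulatedEvent]
) -> dict[str, int]:
    """Re-derive tip states by applying the event log from the root down."""
    nodes = list(tree.root.preorder())
    by_branch: dict[int, list[SimulatedEvent]] = {}
    for ev in events:
        by_branch.setdefault(ev.branch_id, []).append(ev)
    state = {id(tree.root): root_haploid}
    tips: dict[str, int] = {}
    for k, node in enumerate(nodes):
        if node is tree.root:
            continue
        s = state[id(node.parent)]
        for ev in sorted(by_branch.get(k, []), key=lambda e: e.time):
            if ev.from_state != s:
                raise ValueError("event log inconsistent with replayed state")
            s = ev.to_state
        state[id(node)] = s
        if node.is_leaf:
            tips[node.name] = s
    return tips


def fabricate_karyotype_table(n_species: int, seed: int = 0) -> list[KaryotypeRecord]:
    """Internally consistent random karyotype records for pipeline tests.

    Diploid numbers are even draws from the teleost-typical 30..50 range,
    bi-armed counts are even, and CH bands are random site codes; records
    always satisfy the karyotype invariants.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    positions = [
        BandPosition.proximal,
        BandPosition.interstitial,
        BandPosition.distal,
        BandPosition.pericentromeric,
    ]
    records = []
    for i in range(n_species):
        diploid = int(rng.integers(15, 26)) * 2
        biarmed = int(rng.integers(0, diploid // 2 + 1)) * 2
        bands = [CHBand(0, Arm.whole, BandPosition.centromeric)]
        for _ in range(int(rng.integers(0, 5))):
            pair = int(rng.integers(1, diploid // 2 + 1))
            arm = Arm.p if rng.random() < 0.5 else Arm.q
            pos = positions[int(rng.integers(len(positions)))]
            bands.append(CHBand(pair, arm, pos))
        records.append(
            KaryotypeRecord(
                species_name=f"Species_{i + 1:02d}",
                diploid_number=diploid,
                biarmed_count=biarmed,
                uniarmed_count=diploid - biarmed,
                sex=Sex.unspecified,
                ch_bands=sorted(set(bands)),
            )
        )
    return records
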