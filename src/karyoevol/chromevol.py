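"""Chromosome-number evolution as a continuous-time Markov chain.

The state variable is the haploid chromosome number n, bounded to a finite
window [n_min, n_max].  Instantaneous events:

* gain  (n -> n+1): a chromosome fission;
* loss  (n -> n-1): a chromosome fusion;
* duplication (n -> 2n): whole-genome doubling;
* demi-duplication (n -> 1.5n): triploidy-like increase, with the rate for
  odd n split equally between floor(1.5n) and ceil(1.5n).

Eight model families combine these events with either constant or linear
state-dependent gain/loss rates (rate(n) = const + linear * (n - n_min),
clamped at zero).  Likelihoods use Felsenstein pruning with per-branch
transition matrices expm(Q t); models are fitted by multi-start bounded
maximum likelihood and compared by AIC = 2k - 2 logL.

In the cytogenetic vocabulary used throughout the outputs, gains are
fissions and losses are fusions.

Marginal ancestral states come from the standard up/down pass, and
per-branch expected event counts from stochastic mapping (endpoint-
conditioned simulation of event histories).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import expm
from scipy.stats import qmc

from .phylo import Phylogeny, TreeNode

__all__ = [
    "ModelFamily",
    "RateModelSpec",
    "RateModelFit",
    "DiscreteAncestral",
    "BranchEventExpectation",
    "default_state_bounds",
    "build_rate_matrix",
    "likelihood",
    "fit_model",
    "select_model",
    "marginal_ancestral_states",
    "joint_ancestral_states",
    "expected_events",
]

logger = logging.getLogger(__name__)


class ModelFamily(str, Enum):
    CONST_RATE = "CONST_RATE"
    CONST_RATE_DEMI = "CONST_RATE_DEMI"
    CONST_RATE_DEMI_EST = "CONST_RATE_DEMI_EST"
    CONST_RATE_NO_DUPL = "CONST_RATE_NO_DUPL"
    LINEAR_RATE = "LINEAR_RATE"
    LINEAR_RATE_DEMI = "LINEAR_RATE_DEMI"
    LINEAR_RATE_DEMI_EST = "LINEAR_RATE_DEMI_EST"
    LINEAR_RATE_NO_DUPL = "LINEAR_RATE_NO_DUPL"


# free parameters per family, in a fixed order
_FAMILY_PARAMS: dict[ModelFamily, tuple[str, ...]] = {
    ModelFamily.CONST_RATE: ("gain_const", "loss_const", "dupl"),
    ModelFamily.CONST_RATE_DEMI: ("gain_const", "loss_const", "dupl"),
    ModelFamily.CONST_RATE_DEMI_EST: ("gain_const", "loss_const", "dupl", "demi"),
    ModelFamily.CONST_RATE_NO_DUPL: ("gain_const", "loss_const"),
    ModelFamily.LINEAR_RATE: (
        "gain_const",
        "gain_linear",
        "loss_const",
        "loss_linear",
        "dupl",
    ),
    ModelFamily.LINEAR_RATE_DEMI: (
        "gain_const",
        "gain_linear",
        "loss_const",
        "loss_linear",
        "dupl",
    ),
    ModelFamily.LINEAR_RATE_DEMI_EST: (
        "gain_const",
        "gain_linear",
        "loss_const",
        "loss_linear",
        "dupl",
        "demi",
    ),
    ModelFamily.LINEAR_RATE_NO_DUPL: (
        "gain_const",
        "gain_linear",
        "loss_const",
        "loss_linear",
    ),
}

# parameters allowed to go negative (linear slopes; effective rates clamp at 0)
_SIGNED = {"gain_linear", "loss_linear"}


@dataclass(frozen=True)
class RateModelSpec:
    """A model family on the haploid state window [n_min, n_max]."""

    family: ModelFamily
    n_min: int
    n_max: int

    def __post_init__(self) -> None:
        if self.n_min < 1:
            raise ValueError("n_min must be >= 1")
        if self.n_max <= self.n_min:
            raise ValueError("n_max must exceed n_min")

    @property
    def parameter_names(self) -> tuple[str, ...]:
        return _FAMILY_PARAMS[self.family]

    @property
    def k(self) -> int:
        return len(self.parameter_names)

    @property
    def states(self) -> np.ndarray:
        return np.arange(self.n_min, self.n_max + 1)

    @property
    def n_states(self) -> int:
        return self.n_max - self.n_min + 1

    @property
    def has_dupl(self) -> bool:
        return "dupl" in self.parameter_names

    @property
    def has_demi(self) -> bool:
        return self.family in (
            ModelFamily.CONST_RATE_DEMI,
            ModelFamily.CONST_RATE_DEMI_EST,
            ModelFamily.LINEAR_RATE_DEMI,
            ModelFamily.LINEAR_RATE_DEMI_EST,
        )

    def state_index(self, haploid: int) -> int:
        if not self.n_min <= haploid <= self.n_max:
            raise ValueError(
                f"haploid count {haploid} outside state bounds "
                f"[{self.n_min}, {self.n_max}]"
            )
        return haploid - self.n_min


@dataclass
class RateModelFit:
    spec: RateModelSpec
    rates: dict[str, float]
    logL: float
    converged: bool

    @property
    def aic(self) -> float:
        return 2.0 * self.spec.k - 2.0 * self.logL


@dataclass
class DiscreteAncestral:
    node_id: str
    posterior: np.ndarray
    best_haploid: int

    @property
    def best_diploid(self) -> int:
        return 2 * self.best_haploid


@dataclass
class BranchEventExpectation:
    branch_id: str
    expected_gains: float
    expected_losses: float
    mc_error: float


def default_state_bounds(tip_haploids: Mapping[str, int]) -> tuple[int, int]:
    """Window wide enough not to truncate duplications of observed states."""
    lo = max(1, min(tip_haploids.values()) - 10)
    hi = 2 * max(tip_haploids.values()) + 10
    return lo, hi


def build_rate_matrix(spec: RateModelSpec, rates: Mapping[str, float]) -> np.ndarray:
    """Generator matrix Q over states n_min..n_max.

    Linear families use rate(n) = const + linear * (n - n_min), clamped at
    zero; transitions that would leave the window are truncated (their
    probability mass stays on the diagonal via the row-sum constraint).
    """
    for name in spec.parameter_names:
        if name not in rates:
            raise ValueError(f"missing rate parameter {name!r}")
        if name not in _SIGNED and rates[name] < 0:
            raise ValueError(f"rate {name!r} must be non-negative")
    states = spec.states
    S = spec.n_states
    Q = np.zeros((S, S))
    clamped = 0

    def effective(const_key: str, linear_key: str | None, n: int) -> float:
        nonlocal clamped
        r = rates[const_key]
        if linear_key is not None and linear_key in rates:
            r = r + rates[linear_key] * (n - spec.n_min)
        if r < 0:
            clamped += 1
            return 0.0
        return r

    linear = spec.family.value.startswith("LINEAR")
    dupl = rates.get("dupl", 0.0)
    if spec.has_demi:
        demi = rates["demi"] if "demi" in spec.parameter_names else dupl
    else:
        demi = 0.0

    for i, n in enumerate(states):
        gain = effective("gain_const", "gain_linear" if linear else None, n)
        loss = effective("loss_const", "loss_linear" if linear else None, n)
        if n + 1 <= spec.n_max:
            Q[i, spec.state_index(n + 1)] += gain
        if n - 1 >= spec.n_min:
            Q[i, spec.state_index(n - 1)] += loss
        if spec.has_dupl and 2 * n != n and spec.n_min <= 2 * n <= spec.n_max:
            Q[i, spec.state_index(2 * n)] += dupl
        if demi > 0:
            lo_t = int(math.floor(1.5 * n))
            hi_t = int(math.ceil(1.5 * n))
            if lo_t == hi_t:
                targets = [(lo_t, demi)]
            else:
                targets = [(lo_t, demi / 2.0), (hi_t, demi / 2.0)]
            for t, r in targets:
                if t != n and spec.n_min <= t <= spec.n_max:
                    Q[i, spec.state_index(t)] += r
        Q[i, i] = 0.0
        Q[i, i] = -Q[i].sum()
    if clamped:
        logger.debug("clamped %d negative effective rates to 0", clamped)
    return Q


class _Propagator:
    """Transition matrices P(t) = expm(Q t) via eigendecomposition.

    One eigendecomposition per rate evaluation makes repeated per-branch
    propagation cheap; an expm fallback covers ill-conditioned spectra.
    """

    def __init__(self, Q: np.ndarray):
        self.Q = Q
        self._ok = False
        try:
            w, V = np.linalg.eig(Q)
            Vinv = np.linalg.inv(V)
            # accept only if the factorisation reproduces Q accurately
            if np.max(np.abs((V * w) @ Vinv - Q)) < 1e-9 * max(1.0, np.abs(Q).max()):
                self.w, self.V, self.Vinv = w, V, Vinv
                self._ok = True
        except np.linalg.LinAlgError:
            pass

    def __call__(self, t: float) -> np.ndarray:
        if self._ok:
            P = (self.V * np.exp(self.w * t)) @ self.Vinv
            P = np.real(P)
        else:
            P = expm(self.Q * t)
        np.clip(P, 0.0, None, out=P)
        # renormalise tiny numerical drift
        P /= P.sum(axis=1, keepdims=True)
        return P


def _tip_likelihoods(
    tree: Phylogeny, tip_haploids: Mapping[str, int], spec: RateModelSpec
) -> dict[int, np.ndarray]:
    out: dict[int, np.ndarray] = {}
    for leaf in tree.root.leaves():
        if leaf.name not in tip_haploids:
            raise ValueError(f"no haploid count for tip {leaf.name!r}")
        vec = np.zeros(spec.n_states)
        vec[spec.state_index(int(tip_haploids[leaf.name]))] = 1.0
        out[id(leaf)] = vec
    return out


def _prune(
    tree: Phylogeny,
    tip_haploids: Mapping[str, int],
    spec: RateModelSpec,
    prop: _Propagator,
) -> tuple[dict[int, np.ndarray], float]:
    """Conditional likelihoods per node, with log-scaling; returns (L, logscale)."""
    tipL = _tip_likelihoods(tree, tip_haploids, spec)
    cond: dict[int, np.ndarray] = {}
    logscale = 0.0
    for node in tree.root.postorder():
        if node.is_leaf:
            cond[id(node)] = tipL[id(node)]
            continue
        vec = np.ones(spec.n_states)
        for child in node.children:
            t = child.parent_edge_length
            if t is None:
                raise ValueError("missing branch length")
            P = prop(t)
            vec = vec * (P @ cond[id(child)])
        s = vec.max()
        if s <= 0:
            return cond, -np.inf
        vec = vec / s
        logscale += math.log(s)
        cond[id(node)] = vec
    return cond, logscale


def _root_prior(root_cond: np.ndarray, convention: str) -> np.ndarray:
    if convention == "weighted":
        total = root_cond.sum()
        if total <= 0:
            return np.full_like(root_cond, 1.0 / len(root_cond))
        return root_cond / total
    if convention == "flat":
        return np.full_like(root_cond, 1.0 / len(root_cond))
    raise ValueError(f"unknown root convention {convention!r}")


def likelihood(
    tree: Phylogeny,
    tip_haploids: Mapping[str, int],
    spec: RateModelSpec,
    rates: Mapping[str, float],
    root: str = "weighted",
) -> float:
    """Log-likelihood of the tip haploid counts by Felsenstein pruning.

    The root is handled either by weighting each root state by its own
    normalised conditional likelihood ("weighted", the maximum-likelihood-
    style default) or by a flat prior over states ("flat").
    """
    Q = build_rate_matrix(spec, rates)
    prop = _Propagator(Q)
    cond, logscale = _prune(tree, tip_haploids, spec, prop)
    if not np.isfinite(logscale):
        return -np.inf
    root_cond = cond[id(tree.root)]
    pi = _root_prior(root_cond, root)
    total = float(pi @ root_cond)
    if total <= 0:
        return -np.inf
    return math.log(total) + logscale


def _lhs_starts(k: int, n_restarts: int, seed: int) -> np.ndarray:
    """Latin-hypercube starting points in log10-rate space [-3, 1]."""
    sampler = qmc.LatinHypercube(d=k, seed=seed)
    u = sampler.random(n_restarts)
    return -3.0 + 4.0 * u


def fit_model(
    tree: Phylogeny,
    tip_haploids: Mapping[str, int],
    spec: RateModelSpec,
    n_restarts: int = 10,
    seed: int = 0,
    root: str = "weighted",
) -> RateModelFit:
    """Maximum-likelihood rates by multi-start bounded optimisation.

    Non-negative rates are optimised on a log scale; linear slope terms on
    a linear scale (they may be negative, with effective rates clamped at
    zero in the generator).  Starting points are Latin-hypercube draws.
    """
    from scipy.optimize import minimize

    names = spec.parameter_names
    signed = [n in _SIGNED for n in names]

    def unpack(theta: np.ndarray) -> dict[str, float]:
        vals = {}
        for name, s, v in zip(names, signed, theta):
            vals[name] = float(v) if s else float(10.0 ** v)
        return vals

    def neg(theta: np.ndarray) -> float:
        ll = likelihood(tree, tip_haploids, spec, unpack(theta), root=root)
        return -ll if np.isfinite(ll) else 1e12

    starts = _lhs_starts(len(names), n_restarts, seed)
    # signed slope parameters start near zero on a linear scale
    for j, s in enumerate(signed):
        if s:
            starts[:, j] = (starts[:, j] + 1.0) * 0.05

    bounds = [(-0.5, 0.5) if s else (-8.0, 3.0) for s in signed]
    best_val, best_theta, best_ok = np.inf, None, False
    for theta0 in starts:
        res = minimize(
            neg,
            theta0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": 1e-12, "gtol": 1e-9, "maxiter": 500},
        )
        if res.fun < best_val - 1e-12:
            best_val, best_theta, best_ok = res.fun, res.x, bool(res.success)
    if best_theta is None:
        raise RuntimeError("optimization failed from every start")
    return RateModelFit(
        spec=spec,
        rates=unpack(best_theta),
        logL=-best_val,
        converged=best_ok,
    )


def select_model(
    tree: Phylogeny,
    tip_haploids: Mapping[str, int],
    families: Sequence[ModelFamily] | None = None,
    n_min: int | None = None,
    n_max: int | None = None,
    n_restarts: int = 10,
    seed: int = 0,
    root: str = "weighted",
) -> tuple[list[RateModelFit], RateModelFit]:
    """Fit each family and pick the lowest-AIC model.

    Returns (fits in family order, best fit).  Ties on AIC go to the
    family with fewer parameters, then to family-name order, so the choice
    is deterministic.
    """
    if families is None:
        families = list(ModelFamily)
    if not families:
        raise ValueError("need at least one family")
    lo, hi = default_state_bounds(tip_haploids)
    if n_min is not None:
        lo = n_min
    if n_max is not None:
        hi = n_max
    fits = []
    for fam in families:
        spec = RateModelSpec(family=fam, n_min=lo, n_max=hi)
        fits.append(
            fit_model(tree, tip_haploids, spec, n_restarts=n_restarts, seed=seed, root=root)
        )
    best = min(fits, key=lambda f: (f.aic, f.spec.k, f.spec.family.value))
    return fits, best


# --- Marginal ancestral states -------------------------------------------


def _node_ids(tree: Phylogeny) -> dict[int, str]:
    ids: dict[int, str] = {}
    for k, node in enumerate(tree.root.preorder()):
        ids[id(node)] = node.name if node.name else f"N{k}"
    return ids


def marginal_ancestral_states(
    tree: Phylogeny,
    tip_haploids: Mapping[str, int],
    fit: RateModelFit,
    root: str = "weighted",
) -> list[DiscreteAncestral]:
    """Marginal posterior state distributions at every internal node.

    Standard two-pass algorithm: the upward pass gives conditional
    likelihoods of the data below each node; the downward pass propagates
    the root prior and the rest-of-tree likelihood.  Best states are
    posterior argmax (smallest haploid number on exact ties); reported
    diploid values are exactly twice the haploid argmax.
    """
    spec = fit.spec
    Q = build_rate_matrix(spec, fit.rates)
    prop = _Propagator(Q)
    cond, logscale = _prune(tree, tip_haploids, spec, prop)
    if not np.isfinite(logscale):
        raise ValueError("data have zero likelihood under this fit")
    pi = _root_prior(cond[id(tree.root)], root)

    down: dict[int, np.ndarray] = {id(tree.root): pi}
    for node in tree.root.preorder():
        for child in node.children:
            P = prop(child.parent_edge_length)
            # message into the parent excluding this child's subtree
            msg = down[id(node)].copy()
            for sib in node.children:
                if sib is child:
                    continue
                Ps = prop(sib.parent_edge_length)
                msg = msg * (Ps @ cond[id(sib)])
            d = msg @ P  # sum_i msg_i P_ij
            s = d.sum()
            down[id(child)] = d / s if s > 0 else d

    ids = _node_ids(tree)
    out: list[DiscreteAncestral] = []
    for node in tree.root.preorder():
        if node.is_leaf:
            continue
        post = down[id(node)] * cond[id(node)]
        total = post.sum()
        if total <= 0:
            raise ValueError(f"zero posterior at node {ids[id(node)]}")
        post = post / total
        best = int(spec.states[int(np.argmax(post))])
        out.append(DiscreteAncestral(node_id=ids[id(node)], posterior=post, best_haploid=best))
    return out


def joint_ancestral_states(
    tree: Phylogeny,
    tip_haploids: Mapping[str, int],
    fit: RateModelFit,
    root: str = "weighted",
) -> dict[str, int]:
    """Jointly most probable ancestral haploid states (max-product DP).

    Unlike the marginal reconstruction — which can report near-tied
    neighbouring states at individual nodes — the joint reconstruction
    returns the single assignment of states to all internal nodes that
    maximises the posterior probability of the whole history (the Pupko
    dynamic-programming algorithm).  This is the per-node value a
    chromosome-evolution narrative reads off the tree.  Returns
    {node_id: haploid state} for internal nodes.
    """
    spec = fit.spec
    Q = build_rate_matrix(spec, fit.rates)
    prop = _Propagator(Q)
    cond, logscale = _prune(tree, tip_haploids, spec, prop)
    if not np.isfinite(logscale):
        raise ValueError("data have zero likelihood under this fit")
    pi = _root_prior(cond[id(tree.root)], root)
    S = spec.n_states

    with np.errstate(divide="ignore"):
        logP = {
            id(node): np.log(prop(node.parent_edge_length))
            for node in tree.root.preorder()
            if node is not tree.root
        }

    # upward: score[v][j] = best log-score of v's subtree given state(v)=j
    score: dict[int, np.ndarray] = {}
    for node in tree.root.postorder():
        if node.is_leaf:
            vec = np.full(S, -np.inf)
            vec[spec.state_index(int(tip_haploids[node.name]))] = 0.0
        else:
            vec = np.zeros(S)
            for child in node.children:
                # message into node: max over child state j of P_ij + score
                M = logP[id(child)] + score[id(child)][None, :]
                vec = vec + M.max(axis=1)
        score[id(node)] = vec

    ids = _node_ids(tree)
    assign: dict[int, int] = {}
    with np.errstate(divide="ignore"):
        root_score = np.log(pi) + score[id(tree.root)]
    assign[id(tree.root)] = int(np.argmax(root_score))
    for node in tree.root.preorder():
        i = assign[id(node)]
        for child in node.children:
            M = logP[id(child)][i] + score[id(child)]
            assign[id(child)] = int(np.argmax(M))
    return {
        ids[id(node)]: int(spec.states[assign[id(node)]])
        for node in tree.root.preorder()
        if not node.is_leaf
    }


# --- Stochastic mapping ---------------------------------------------------


def _sample_path(
    rng: np.random.Generator,
    Q: np.ndarray,
    spec: RateModelSpec,
    start: int,
    end: int,
    t: float,
    max_tries: int,
) -> tuple[int, int] | None:
    """Endpoint-conditioned (gains, losses) by rejection sampling.

    Simulates the chain forward from ``start`` for time ``t`` and accepts
    the path when it ends in ``end``.  Returns None when every try is
    rejected.
    """
    states = spec.states
    for _ in range(max_tries):
        s = start
        clock = 0.0
        gains = losses = 0
        while True:
            i = spec.state_index(s)
            rate = -Q[i, i]
            if rate <= 0:
                break
            clock += rng.exponential(1.0 / rate)
            if clock >= t:
                break
            probs = Q[i].copy()
            probs[i] = 0.0
            probs = probs / probs.sum()
            j = rng.choice(len(states), p=probs)
            nxt = int(states[j])
            if nxt == s + 1:
                gains += 1
            elif nxt == s - 1:
                losses += 1
            s = nxt
        if s == end:
            return gains, losses
    return None


def expected_events(
    tree: Phylogeny,
    tip_haploids: Mapping[str, int],
    fit: RateModelFit,
    n_maps: int = 500,
    seed: int = 0,
    root: str = "weighted",
    max_tries: int = 2000,
) -> tuple[list[BranchEventExpectation], dict[str, float]]:
    """Per-branch expected gain (fission) and loss (fusion) counts.

    Stochastic mapping conditional on the tip data: joint node states are
    sampled from the posterior by backward sampling, then each branch's
    event history is drawn conditional on its endpoints.  Returns the
    per-branch table and totals, with mc_error = std / sqrt(n_maps) of the
    per-map total.
    """
    if n_maps < 100:
        raise ValueError("n_maps must be >= 100")
    spec = fit.spec
    Q = build_rate_matrix(spec, fit.rates)
    prop = _Propagator(Q)
    cond, logscale = _prune(tree, tip_haploids, spec, prop)
    if not np.isfinite(logscale):
        raise ValueError("data have zero likelihood under this fit")
    pi = _root_prior(cond[id(tree.root)], root)
    rng = np.random.default_rng(seed)
    ids = _node_ids(tree)

    nodes = list(tree.root.preorder())
    branch_nodes = [n for n in nodes if n is not tree.root]
    Pcache = {id(n): prop(n.parent_edge_length) for n in branch_nodes}

    gains_acc = {id(n): 0.0 for n in branch_nodes}
    losses_acc = {id(n): 0.0 for n in branch_nodes}
    sq_acc = {id(n): [0.0, 0.0] for n in branch_nodes}
    total_losses_per_map = np.zeros(n_maps)
    total_gains_per_map = np.zeros(n_maps)
    rejected = 0

    root_post = pi * cond[id(tree.root)]
    root_post = root_post / root_post.sum()

    for m in range(n_maps):
        # backward-sample joint node states
        state: dict[int, int] = {}
        i_root = rng.choice(spec.n_states, p=root_post)
        state[id(tree.root)] = int(spec.states[i_root])
        for node in tree.root.preorder():
            for child in node.children:
                i = spec.state_index(state[id(node)])
                w = Pcache[id(child)][i] * cond[id(child)]
                w = w / w.sum()
                j = rng.choice(spec.n_states, p=w)
                state[id(child)] = int(spec.states[j])
        # endpoint-conditioned histories per branch
        for node in branch_nodes:
            res = _sample_path(
                rng,
                Q,
                spec,
                state[id(node.parent)],
                state[id(node)],
                node.parent_edge_length,
                max_tries,
            )
            if res is None:
                rejected += 1
                continue
            g, l = res
            gains_acc[id(node)] += g
            losses_acc[id(node)] += l
            sq_acc[id(node)][0] += g * g
            sq_acc[id(node)][1] += l * l
            total_gains_per_map[m] += g
            total_losses_per_map[m] += l

    n_branch_draws = n_maps * len(branch_nodes)
    if rejected > 0.999 * n_branch_draws:
        raise RuntimeError(
            "stochastic mapping rejection rate above 99.9%; increase n_maps/max_tries"
        )

    table: list[BranchEventExpectation] = []
    for node in branch_nodes:
        g = gains_acc[id(node)] / n_maps
        l = losses_acc[id(node)] / n_maps
        var_l = max(0.0, sq_acc[id(node)][1] / n_maps - l * l)
        table.append(
            BranchEventExpectation(
                branch_id=ids[id(node)],
                expected_gains=g,
                expected_losses=l,
                mc_error=math.sqrt(var_l / n_maps),
            )
        )
    totals = {
        "total_gains": float(total_gains_per_map.mean()),
        "total_losses": float(total_losses_per_map.mean()),
        "total_gains_mc_error": float(total_gains_per_map.std() / math.sqrt(n_maps)),
        "total_losses_mc_error": float(total_losses_per_map.std() / math.sqrt(n_maps)),
    }
    return table, totals
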