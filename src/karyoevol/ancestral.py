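"""Brownian-motion ancestral state reconstruction and phylogenetic signal.

A continuous trait (here: diploid chromosome number) evolving by Brownian
motion on a rooted tree with branch lengths induces a multivariate normal
distribution over tip values: mean mu (the root state) and covariance
sigma^2 * C, where C_ij is the shared root-to-tip path length of tips i
and j.  Maximum-likelihood ancestral states are the generalized
least-squares (GLS) predictions under this model, computed here with the
linear-time two-pass (re-rooting) recursion; an explicit O(n^3)
covariance-inversion oracle lives in the test suite.

Phylogenetic signal statistics:

* Pagel's lambda — a multiplier on the off-diagonal entries of C.  lambda
  is estimated by profile maximum likelihood and tested against lambda = 0
  (star phylogeny) with a 1-df likelihood-ratio test.
* Blomberg's K — the ratio of the observed MSE0/MSE to its Brownian-motion
  expectation on the same tree; K = 1 under pure Brownian motion, K > 1
  means closer relatives are more similar than Brownian motion predicts.
  The p-value is a one-tailed permutation test on MSE (add-one rule).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import optimize, stats

from .phylo import Phylogeny, TreeNode

__all__ = [
    "AncestralEstimate",
    "SignalStats",
    "phylo_covariance",
    "bm_ancestral_states",
    "pagel_lambda",
    "blomberg_k",
]

logger = logging.getLogger(__name__)

_Z975 = 1.959963984540054  # 97.5% normal quantile


@dataclass
class AncestralEstimate:
    node_id: str
    estimate: float
    variance: float
    ci_lower: float
    ci_upper: float


@dataclass
class SignalStats:
    lambda_hat: float
    lambda_logL: float
    lambda_p: float
    k_stat: float
    k_p: float
    n_permutations: int
    seed: int


def _tip_vector(tree: Phylogeny, tips: Mapping[str, float]) -> np.ndarray:
    names = tree.leaf_names
    missing = [n for n in names if n not in tips]
    if missing:
        raise ValueError(f"missing tip values for: {missing}")
    x = np.array([float(tips[n]) for n in names])
    if not np.all(np.isfinite(x)):
        raise ValueError("tip values must be finite")
    return x


def phylo_covariance(tree: Phylogeny) -> tuple[list[str], np.ndarray]:
    """Unit-rate Brownian covariance: C_ij = shared root-to-tip path length."""
    leaves = tree.root.leaves()
    names = [leaf.name for leaf in leaves]
    index = {id(leaf): i for i, leaf in enumerate(leaves)}
    n = len(leaves)
    C = np.zeros((n, n))
    depths = tree.depths()

    def collect(node: TreeNode) -> list[int]:
        if node.is_leaf:
            return [index[id(node)]]
        groups = [collect(c) for c in node.children]
        h = depths[id(node)]
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                for i in groups[a]:
                    for j in groups[b]:
                        C[i, j] = C[j, i] = h
        return [i for g in groups for i in g]

    collect(tree.root)
    for leaf in leaves:
        C[index[id(leaf)], index[id(leaf)]] = depths[id(leaf)]
    return names, C


def _guard_lengths(tree: Phylogeny) -> Phylogeny:
    """Replace zero-length branches by a small fraction of tree height."""
    depths = tree.depths()
    height = max(depths.values())
    if height <= 0:
        raise ValueError("tree has zero total height")
    eps = 1e-8 * height
    out = tree.copy()
    bumped = 0
    for node in out.root.preorder():
        if node is not out.root and node.parent_edge_length == 0.0:
            node.parent_edge_length = eps
            bumped += 1
    if bumped:
        logger.warning("replaced %d zero-length branches by %.3g", bumped, eps)
    return out


def _node_ids(tree: Phylogeny) -> dict[int, str]:
    """Stable node identifiers: existing labels, else N<preorder-index>."""
    ids: dict[int, str] = {}
    for k, node in enumerate(tree.root.preorder()):
        ids[id(node)] = node.name if node.name else f"N{k}"
    return ids


def bm_ancestral_states(
    tree: Phylogeny, tips: Mapping[str, float]
) -> tuple[list[AncestralEstimate], float]:
    """ML ancestral states for every internal node, plus the ML rate sigma2.

    The estimate at a node equals the GLS/ML reconstruction under Brownian
    motion (the precision-weighted average over the tree re-rooted at that
    node); the variance is the conditional variance of that average scaled
    by the ML rate estimate sigma2_hat = (x - mu)' C^{-1} (x - mu) / n.
    95% intervals use the normal quantile.
    """
    tree = _guard_lengths(tree)
    x = _tip_vector(tree, tips)
    names, C = phylo_covariance(tree)
    n = len(names)

    # ML rate via GLS at the root
    Cinv_x = np.linalg.solve(C, x)
    Cinv_1 = np.linalg.solve(C, np.ones(n))
    mu = float(np.ones(n) @ Cinv_x / (np.ones(n) @ Cinv_1))
    resid = x - mu
    sigma2 = float(resid @ np.linalg.solve(C, resid) / n)

    # upward pass: conditional (mean, variance-multiple) per node
    up: dict[int, tuple[float, float]] = {}
    for node in tree.root.postorder():
        if node.is_leaf:
            up[id(node)] = (float(tips[node.name]), 0.0)
        else:
            prec = 0.0
            wmean = 0.0
            for child in node.children:
                m, v = up[id(child)]
                w = 1.0 / (v + child.parent_edge_length)
                prec += w
                wmean += w * m
            up[id(node)] = (wmean / prec, 1.0 / prec)

    # downward pass: message from the rest of the tree, excluding each subtree
    down: dict[int, tuple[float, float] | None] = {id(tree.root): None}
    for node in tree.root.preorder():
        parent_msg = down[id(node)]
        for child in node.children:
            others: list[tuple[float, float]] = []
            if parent_msg is not None:
                others.append(parent_msg)
            for sib in node.children:
                if sib is child:
                    continue
                ms, vs = up[id(sib)]
                others.append((ms, vs + sib.parent_edge_length))
            prec = sum(1.0 / v for _, v in others)
            wmean = sum(m / v for m, v in others)
            down[id(child)] = (
                wmean / prec,
                1.0 / prec + child.parent_edge_length,
            )

    ids = _node_ids(tree)
    estimates: list[AncestralEstimate] = []
    for node in tree.root.preorder():
        if node.is_leaf:
            continue
        m_up, v_up = up[id(node)]
        msg = down[id(node)]
        if msg is None:
            est, v = m_up, v_up
        else:
            m_dn, v_dn = msg
            prec = 1.0 / v_up + 1.0 / v_dn if v_up > 0 else None
            if v_up == 0.0:
                est, v = m_up, 0.0
            else:
                est = (m_up / v_up + m_dn / v_dn) / prec
                v = 1.0 / prec
        var = sigma2 * v
        half = _Z975 * math.sqrt(var)
        estimates.append(
            AncestralEstimate(
                node_id=ids[id(node)],
                estimate=est,
                variance=var,
                ci_lower=est - half,
                ci_upper=est + half,
            )
        )
    return estimates, sigma2


# --- Pagel's lambda -------------------------------------------------------


def _lambda_transform(C: np.ndarray, lam: float) -> np.ndarray:
    out = C * lam
    np.fill_diagonal(out, np.diag(C))
    return out


def _profile_loglik(C: np.ndarray, x: np.ndarray) -> float:
    """BM log-likelihood profiled over root state and rate."""
    n = len(x)
    sign, logdet = np.linalg.slogdet(C)
    if sign <= 0:
        return -np.inf
    one = np.ones(n)
    Cinv_x = np.linalg.solve(C, x)
    Cinv_1 = np.linalg.solve(C, one)
    mu = float(one @ Cinv_x / (one @ Cinv_1))
    resid = x - mu
    sigma2 = float(resid @ np.linalg.solve(C, resid) / n)
    if sigma2 <= 0:
        return -np.inf
    return -0.5 * (n * math.log(2 * math.pi * sigma2) + logdet + n)


def lambda_max_bound(C: np.ndarray) -> float:
    """Largest lambda keeping every transformed covariance valid.

    The transform scales off-diagonals by lambda; validity requires every
    pair's shared path not to exceed either tip's total depth, i.e.
    lambda <= min_i C_ii / max_{j != i} C_ij.  On an ultrametric tree with
    short terminal branches this bound sits slightly above 1.
    """
    n = C.shape[0]
    off = C.copy()
    np.fill_diagonal(off, 0.0)
    bounds = [C[i, i] / off[i].max() for i in range(n) if off[i].max() > 0]
    return min(bounds) if bounds else 1.0


def pagel_lambda(
    tree: Phylogeny, tips: Mapping[str, float], n_restarts: int = 5
) -> tuple[float, float, float]:
    """Profile-ML Pagel's lambda with a chi-square LRT against lambda = 0.

    Returns (lambda_hat, logL at lambda_hat, p-value).
    """
    tree = _guard_lengths(tree)
    x = _tip_vector(tree, tips)
    if len(x) < 4:
        raise ValueError("need at least 4 tips for a meaningful lambda test")
    if np.ptp(x) == 0:
        raise ValueError("trait is constant; lambda likelihood is flat")
    _, C = phylo_covariance(tree)
    lam_max = lambda_max_bound(C)

    def neg(lam: float) -> float:
        return -_profile_loglik(_lambda_transform(C, lam), x)

    best_lam, best_val = 0.0, neg(0.0)
    edges = np.linspace(0.0, lam_max, n_restarts + 1)
    for lo, hi in zip(edges[:-1], edges[1:]):
        res = optimize.minimize_scalar(
            neg, bounds=(lo, hi), method="bounded", options={"xatol": 1e-8}
        )
        if res.fun < best_val:
            best_lam, best_val = float(res.x), float(res.fun)
    for endpoint in (0.0, lam_max):
        v = neg(endpoint)
        if v < best_val:
            best_lam, best_val = endpoint, v

    logL1 = -best_val
    logL0 = _profile_loglik(_lambda_transform(C, 0.0), x)
    lr = max(0.0, 2.0 * (logL1 - logL0))
    p = float(stats.chi2.sf(lr, df=1))
    return best_lam, logL1, p


# --- Blomberg's K ---------------------------------------------------------


def _k_mse_parts(C: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    n = len(x)
    one = np.ones(n)
    Cinv_x = np.linalg.solve(C, x)
    Cinv_1 = np.linalg.solve(C, one)
    a_hat = float(one @ Cinv_x / (one @ Cinv_1))
    resid = x - a_hat
    mse0 = float(resid @ resid) / (n - 1)
    mse = float(resid @ np.linalg.solve(C, resid)) / (n - 1)
    return mse0, mse


def blomberg_k(
    tree: Phylogeny,
    tips: Mapping[str, float],
    n_permutations: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Blomberg's K with a one-tailed permutation test.

    K = (MSE0/MSE)_observed / E[MSE0/MSE | Brownian motion on this tree],
    with the expectation in closed form: (tr(C) - n / (1'C^{-1}1)) / (n-1).
    The p-value is the fraction of tip permutations whose phylogenetic MSE
    is <= the observed MSE, observed included (add-one rule).
    """
    tree = _guard_lengths(tree)
    x = _tip_vector(tree, tips)
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 tips")
    if np.ptp(x) == 0:
        raise ValueError("trait is constant; K is undefined")
    if n_permutations < 100:
        logger.warning("n_permutations=%d is low; p-value will be coarse", n_permutations)
    _, C = phylo_covariance(tree)
    one = np.ones(n)
    Cinv_1 = np.linalg.solve(C, one)
    expected_ratio = (float(np.trace(C)) - n / float(one @ Cinv_1)) / (n - 1)
    mse0, mse = _k_mse_parts(C, x)
    k = (mse0 / mse) / expected_ratio

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        xp = rng.permutation(x)
        _, mse_p = _k_mse_parts(C, xp)
        if mse_p <= mse:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return float(k), float(p)
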