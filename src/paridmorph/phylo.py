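"""Phylogenetic comparative methods under Brownian motion (BM).

The phylogeny enters every method through the BM covariance matrix ``C``
(shared root-to-tip path lengths). Implemented here:

* Blomberg's K with a tip-permutation significance test;
* Pagel's λ by maximum likelihood with a likelihood-ratio test against λ=0;
* phylogenetic generalized least squares (PGLS) with fixed BM correlation,
  optionally with λ estimated jointly;
* squared-change parsimony ancestral states (the branch-length-weighted
  solution, identical to the BM maximum-likelihood ancestral means);
* phylomorphospace coordinates (tips at observed ordination scores, internal
  nodes at reconstructed states).

Traits are passed as mappings or pandas Series keyed by tip label; tip
matching is by exact string after whitespace normalization, and any
unmatched name is a hard error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .data_io import Phylogeny

__all__ = [
    "SignalResult",
    "PglsResult",
    "AncestralStates",
    "phylo_vcv",
    "blomberg_k",
    "pagel_lambda",
    "pgls",
    "squared_change_parsimony",
    "phylomorphospace",
]


@dataclass
class SignalResult:
    statistic_name: str  # "K" or "lambda"
    estimate: float
    p: float
    n_permutations: int | None = None
    logL: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p outside [0, 1]")


@dataclass
class PglsResult:
    slope: float
    intercept: float
    slope_se: float
    t: float
    p: float
    sigma2: float
    lam: float = 1.0


@dataclass
class AncestralStates:
    """Values at internal nodes, keyed by node id; ``node_order`` gives the
    preorder ids so callers can map back to the tree."""

    node_values: dict[str, float]


def phylo_vcv(tree: Phylogeny) -> tuple[list[str], np.ndarray]:
    """BM phylogenetic covariance: shared root-to-tip path lengths."""
    return tree.vcv()


def _align_trait(tree: Phylogeny, trait) -> tuple[np.ndarray, list[str], np.ndarray]:
    labels, C = tree.vcv()
    if isinstance(trait, pd.Series):
        trait = trait.to_dict()
    trait = {str(k).strip(): v for k, v in dict(trait).items()}
    tips = [lab.strip() for lab in labels]
    missing = [t for t in tips if t not in trait]
    if missing:
        raise ValueError(f"trait missing for tips: {missing}")
    x = np.array([float(trait[t]) for t in tips])
    if not np.isfinite(x).all():
        raise ValueError("non-finite trait value")
    return x, labels, C


def _phylo_mean_and_mse(x: np.ndarray, C_cho, ones: np.ndarray):
    """GLS (phylogenetically corrected) mean and the GLS mean squared error."""
    Ci1 = cho_solve(C_cho, ones)
    a_hat = float(x @ Ci1 / (ones @ Ci1))
    d = x - a_hat
    mse = float(d @ cho_solve(C_cho, d)) / (len(x) - 1)
    mse0 = float(d @ d) / (len(x) - 1)
    return a_hat, mse0, mse


def blomberg_k(
    tree: Phylogeny, trait, n_perm: int = 999, seed: int | None = None
) -> SignalResult:
    """Blomberg's K with a tip-permutation test.

    K is the observed MSE0/MSE ratio scaled by its BM expectation on the
    same tree, so K≈1 under BM, K→0 with no signal. The permutation p is the
    (+1-corrected) fraction of tip shuffles whose GLS mean squared error is
    at most the observed one.
    """
    x, _, C = _align_trait(tree, trait)
    if np.ptp(x) == 0:
        raise ValueError("constant trait: K undefined")
    n = len(x)
    ones = np.ones(n)
    cho = cho_factor(C)
    _, mse0, mse = _phylo_mean_and_mse(x, cho, ones)
    Ci1 = cho_solve(cho, ones)
    expected = (np.trace(C) - n / (ones @ Ci1)) / (n - 1)
    K = (mse0 / mse) / expected

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        xp = rng.permutation(x)
        _, _, mse_p = _phylo_mean_and_mse(xp, cho, ones)
        if mse_p <= mse:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return SignalResult("K", float(K), float(p), n_permutations=n_perm)


def _lambda_cov(C: np.ndarray, lam: float) -> np.ndarray:
    Cl = lam * C
    np.fill_diagonal(Cl, np.diag(C))
    return Cl


def _lambda_loglik(x: np.ndarray, C: np.ndarray, lam: float) -> float:
    n = len(x)
    Cl = _lambda_cov(C, lam)
    sign, logdet = np.linalg.slogdet(Cl)
    if sign <= 0:
        return -np.inf
    cho = cho_factor(Cl)
    ones = np.ones(n)
    Ci1 = cho_solve(cho, ones)
    a_hat = float(x @ Ci1 / (ones @ Ci1))
    d = x - a_hat
    s2 = float(d @ cho_solve(cho, d)) / n  # ML variance
    if s2 <= 0:
        return -np.inf
    return -0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)


def _lambda_max(C: np.ndarray, cap: float = 5.0) -> float:
    """Largest λ keeping the λ-transformed covariance positive definite."""

    def pd_ok(lam: float) -> bool:
        return np.linalg.eigvalsh(_lambda_cov(C, lam)).min() > 1e-12 * np.diag(C).max()

    if not pd_ok(1.0):
        return 1.0
    lo, hi = 1.0, cap
    if pd_ok(hi):
        return hi
    for _ in range(60):
        mid = (lo + hi) / 2
        if pd_ok(mid):
            lo = mid
        else:
            hi = mid
    return lo


def pagel_lambda(tree: Phylogeny, trait) -> SignalResult:
    """Maximum-likelihood Pagel's λ with a χ²₁ likelihood-ratio test vs λ=0.

    λ scales the off-diagonal entries of the BM covariance; λ̂ is found by a
    bounded 1-D search on [0, λ_max] where λ_max is the largest value keeping
    the covariance positive definite (≥ 1 for ultrametric trees).
    """
    x, _, C = _align_trait(tree, trait)
    if np.ptp(x) == 0:
        raise ValueError("constant trait: lambda undefined")
    lam_max = _lambda_max(C)

    res = optimize.minimize_scalar(
        lambda lam: -_lambda_loglik(x, C, lam),
        bounds=(0.0, lam_max),
        method="bounded",
        options={"xatol": 1e-8},
    )
    if not res.success:
        raise RuntimeError(f"lambda optimization failed: {res.message}")
    # the bounded optimizer can miss a boundary optimum; compare explicitly
    candidates = [(float(res.x), -float(res.fun))]
    for b in (0.0, lam_max):
        candidates.append((b, _lambda_loglik(x, C, b)))
    lam_hat, logL = max(candidates, key=lambda c: c[1])
    logL0 = _lambda_loglik(x, C, 0.0)
    lr = max(0.0, 2.0 * (logL - logL0))
    p = float(stats.chi2.sf(lr, df=1))
    return SignalResult("lambda", float(lam_hat), p, logL=float(logL))


def pgls(y, x, tree: Phylogeny, estimate_lambda: bool = False) -> PglsResult:
    """Phylogenetic generalized least squares of y on x under BM.

    With ``estimate_lambda`` the residual correlation's λ is estimated by
    maximum likelihood jointly with the regression; otherwise λ=1 (plain BM).
    """
    yv, labels, C = _align_trait(tree, y)
    xv, _, _ = _align_trait(tree, x)
    n = len(yv)
    if n < 4:
        raise ValueError("PGLS needs at least 4 tips")
    X = np.column_stack([np.ones(n), xv])

    def fit(lam: float):
        Cl = _lambda_cov(C, lam)
        cho = cho_factor(Cl)
        CiX = cho_solve(cho, X)
        XtCiX = X.T @ CiX
        beta = np.linalg.solve(XtCiX, CiX.T @ yv)
        resid = yv - X @ beta
        rss = float(resid @ cho_solve(cho, resid))
        return beta, XtCiX, rss, Cl

    lam = 1.0
    if estimate_lambda:
        lam_max = _lambda_max(C)

        def negll(l):
            beta, _, rss, Cl = fit(l)
            sign, logdet = np.linalg.slogdet(Cl)
            s2 = rss / n
            return 0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)

        res = optimize.minimize_scalar(
            negll, bounds=(0.0, lam_max), method="bounded", options={"xatol": 1e-8}
        )
        lam = float(res.x)

    beta, XtCiX, rss, _ = fit(lam)
    if not np.isfinite(np.linalg.cond(XtCiX)) or np.linalg.cond(XtCiX) > 1e12:
        raise ValueError("singular design (constant predictor?)")
    sigma2 = rss / (n - 2)
    cov_beta = sigma2 * np.linalg.inv(XtCiX)
    se = float(np.sqrt(cov_beta[1, 1]))
    t = float(beta[1] / se)
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return PglsResult(
        slope=float(beta[1]),
        intercept=float(beta[0]),
        slope_se=se,
        t=t,
        p=p,
        sigma2=float(sigma2),
        lam=lam,
    )


# ---------------------------------------------------------------------------
# ancestral states
# ---------------------------------------------------------------------------


def _node_ids(tree: Phylogeny) -> dict:
    """Stable preorder ids: tips keep their labels, internal nodes get
    ``node_<i>``."""
    ids = {}
    counter = 0
    for node in tree.dendropy_tree.preorder_node_iter():
        if node.is_leaf():
            ids[node] = node.taxon.label
        else:
            ids[node] = f"node_{counter}"
            counter += 1
    return ids


def squared_change_parsimony(tree: Phylogeny, tip_values) -> AncestralStates:
    """Ancestral states minimizing Σ (Δvalue)²/branch_length over the edges.

    Solved exactly as a linear (weighted Laplacian) system; each internal
    node's value is the branch-length-weighted average of its neighbours,
    which coincides with the BM maximum-likelihood ancestral mean. Nodes
    joined by a zero-length internal branch are merged and share a value.
    """
    x, labels, _ = _align_trait(tree, tip_values)
    tipval = dict(zip([l.strip() for l in labels], x))
    dtree = tree.dendropy_tree
    ids = _node_ids(tree)

    # union-find over internal nodes to merge zero-length internal edges
    parent_of: dict = {}

    def find(n):
        while parent_of.get(n, n) is not n:
            n = parent_of.get(n, n)
        return n

    internals = [n for n in dtree.preorder_node_iter() if not n.is_leaf()]
    for node in internals:
        for child in node.child_nodes():
            if not child.is_leaf() and (child.edge.length or 0.0) == 0.0:
                parent_of[find(child)] = find(node)

    groups = list(dict.fromkeys(find(n) for n in internals))
    gidx = {g: i for i, g in enumerate(groups)}
    m = len(groups)
    A = np.zeros((m, m))
    b = np.zeros(m)
    for node in internals:
        gi = gidx[find(node)]
        neigh = []
        if node.parent_node is not None:
            neigh.append((node.parent_node, node.edge.length or 0.0))
        for child in node.child_nodes():
            neigh.append((child, child.edge.length or 0.0))
        for other, ln in neigh:
            if ln == 0.0 and not other.is_leaf():
                continue  # merged
            if ln <= 0.0:
                if other.is_leaf():
                    raise ValueError("zero-length pendant edge not supported")
                continue
            w = 1.0 / ln
            A[gi, gi] += w
            if other.is_leaf():
                b[gi] += w * tipval[other.taxon.label.strip()]
            else:
                A[gi, gidx[find(other)]] -= w
    vals = np.linalg.solve(A, b)
    node_values = {ids[n]: float(vals[gidx[find(n)]]) for n in internals}
    return AncestralStates(node_values=node_values)


def phylomorphospace(
    tree: Phylogeny, scores: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Project the phylogeny into a 2-D ordination.

    ``scores`` must hold one row per tip (index = tip labels) and exactly two
    columns (the chosen axes). Returns ``(nodes, edges)``: nodes with columns
    ``node_id, kind, <axis1>, <axis2>``, edges with parent/child node ids.
    Internal nodes sit at their squared-change-parsimony reconstructions.
    """
    if scores.shape[1] != 2:
        raise ValueError("scores must have exactly two columns")
    tips = set(tree.tip_labels)
    missing = tips - set(map(str, scores.index))
    if missing:
        raise ValueError(f"missing tip scores: {sorted(missing)}")
    ax1, ax2 = scores.columns
    anc1 = squared_change_parsimony(tree, scores[ax1].to_dict()).node_values
    anc2 = squared_change_parsimony(tree, scores[ax2].to_dict()).node_values
    ids = _node_ids(tree)
    rows = []
    for node, nid in ids.items():
        if node.is_leaf():
            rows.append(
                {
                    "node_id": nid,
                    "kind": "tip",
                    ax1: float(scores.loc[nid, ax1]),
                    ax2: float(scores.loc[nid, ax2]),
                }
            )
        else:
            rows.append(
                {"node_id": nid, "kind": "internal", ax1: anc1[nid], ax2: anc2[nid]}
            )
    nodes = pd.DataFrame(rows)
    edges = []
    for node, nid in ids.items():
        for child in node.child_nodes():
            edges.append({"parent": nid, "child": ids[child]})
    return nodes, pd.DataFrame(edges)
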