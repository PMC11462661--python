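"""Recursively partitioned beta-mixture clustering of methylation profiles.

The model treats each sample's beta values as independent draws from
per-probe beta distributions whose parameters depend on a latent class.
A node of the tree is split into two classes by EM; the split is accepted
only when the two-class BIC improves on the one-class BIC, and recursion
stops at ``max_level``, on rejection, or when a node holds fewer than four
samples.  Leaves are labelled by their left/right path from the root
(``r`` -> ``rL``/``rR`` -> ...), with ``L`` the child of higher median
methylation — the convention under which ``rL`` is the expected *low*
cfDNA-release cluster and ``rR`` the expected high one.

EM details: responsibilities are initialised from 2-means on logit-beta
with a fixed seed; the M-step computes the exact weighted maximum-likelihood
beta parameters per probe and class (method-of-moments start, damped Newton
on the concave beta log-likelihood), which guarantees a monotone
log-likelihood trace.  Values are clipped away from {0, 1} before any
likelihood evaluation, since the beta density diverges at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import betaln, gammaln, logsumexp, polygamma, psi
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

log = logging.getLogger(__name__)

CLIP = 1e-6
CIMP_LABELS = ("CIMP-H", "CIMP-L", "CIMP3", "CIMP4")


def _clip_beta(values: np.ndarray) -> np.ndarray:
    return np.clip(np.asarray(values, dtype=float), CLIP, 1.0 - CLIP)


def _log_beta_density(logx, log1mx, a, b):
    """Per-sample per-class log joint density over probes.

    logx, log1mx: (n, p); a, b: (k, p).  Returns (n, k).
    """
    return logx @ (a - 1.0).T + log1mx @ (b - 1.0).T - betaln(a, b).sum(axis=1)


def _weighted_beta_mle(
    logx: np.ndarray, log1mx: np.ndarray, x: np.ndarray, w: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted MLE of beta parameters per probe.

    Maximises ``sum_i w_i log Beta(x_ip | a_p, b_p)`` for every probe p.
    Method-of-moments start, then damped Newton on the (concave)
    log-likelihood; backtracks on any non-increasing step.
    """
    wsum = w.sum()
    s1 = (w @ logx) / wsum
    s2 = (w @ log1mx) / wsum
    m = np.clip((w @ x) / wsum, CLIP, 1.0 - CLIP)
    v = (w @ (x - m) ** 2) / wsum
    v = np.clip(v, 1e-10, m * (1.0 - m) - 1e-10)
    conc = np.clip(m * (1.0 - m) / v - 1.0, 1e-2, 1e7)
    a = m * conc
    b = (1.0 - m) * conc

    def objective(a, b):
        return a * s1 + b * s2 - betaln(a, b)

    obj = objective(a, b)
    for _ in range(60):
        psum = psi(a + b)
        g1 = s1 - (psi(a) - psum)
        g2 = s2 - (psi(b) - psum)
        if max(np.abs(g1).max(), np.abs(g2).max()) < 1e-10:
            break
        t1 = polygamma(1, a)
        t2 = polygamma(1, b)
        ts = polygamma(1, a + b)
        # Newton step for the negative Hessian [[t1-ts, -ts], [-ts, t2-ts]]
        det = (t1 - ts) * (t2 - ts) - ts * ts
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        da = ((t2 - ts) * g1 + ts * g2) / det
        db = (ts * g1 + (t1 - ts) * g2) / det
        step = np.ones_like(a)
        for _ in range(40):
            na = a + step * da
            nb = b + step * db
            bad = (na <= 0) | (nb <= 0)
            nobj = np.where(bad, -np.inf, objective(np.where(bad, 1.0, na), np.where(bad, 1.0, nb)))
            shrink = nobj < obj
            if not shrink.any():
                break
            step = np.where(shrink, step * 0.5, step)
        improved = nobj >= obj
        a = np.where(improved, a + step * da, a)
        b = np.where(improved, b + step * db, b)
        obj = np.where(improved, nobj, obj)
        if not improved.any():
            break
    return np.clip(a, 1e-3, 1e8), np.clip(b, 1e-3, 1e8)


@dataclass
class BetaMixtureNode:
    """A fitted beta-mixture model for one set of samples."""

    a: np.ndarray  # (k, p) beta shape parameters
    b: np.ndarray  # (k, p)
    weights: np.ndarray  # (k,) mixing proportions
    resp: np.ndarray  # (n, k) membership weights, rows sum to 1
    log_likelihood: float
    bic: float
    converged: bool
    n_iter: int
    loglik_trace: np.ndarray
    flags: list[str] = field(default_factory=list)

    @property
    def k(self) -> int:
        return self.a.shape[0]

    def hard_assignments(self) -> np.ndarray:
        return np.argmax(self.resp, axis=1)


def _fit_one_class(x: np.ndarray) -> BetaMixtureNode:
    n, p = x.shape
    logx, log1mx = np.log(x), np.log1p(-x)
    w = np.ones(n)
    a, b = _weighted_beta_mle(logx, log1mx, x, w)
    ll = float(_log_beta_density(logx, log1mx, a[None, :], b[None, :]).sum())
    bic = -2.0 * ll + 2.0 * p * np.log(n)
    return BetaMixtureNode(
        a[None, :], b[None, :], np.array([1.0]), np.ones((n, 1)), ll, bic,
        True, 0, np.array([ll]),
    )


def fit_beta_mixture(
    beta_sub: pd.DataFrame | np.ndarray,
    k: int = 2,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int = 0,
    max_restarts: int = 3,
) -> BetaMixtureNode:
    """EM fit of a k-class mixture of independent per-probe beta densities.

    Initialisation is k-means on logit-beta with ``seed``.  Convergence is
    declared when the relative log-likelihood change drops below ``tol``.
    Non-convergence at ``max_iter`` and degenerate classes (mixing weight
    below 1/n after retries with fresh seeds) are flagged on the result,
    never raised.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    x = _clip_beta(beta_sub.to_numpy() if hasattr(beta_sub, "to_numpy") else beta_sub)
    if x.ndim != 2 or x.size == 0:
        raise ValueError("beta matrix must be non-empty and 2-dimensional")
    if np.isnan(x).any():
        raise ValueError("beta matrix contains missing values; drop or impute first")
    if k == 1:
        return _fit_one_class(x)
    n, p = x.shape
    logx, log1mx = np.log(x), np.log1p(-x)

    best = None
    for attempt in range(max_restarts + 1):
        node = _fit_em_once(x, logx, log1mx, k, tol, max_iter, seed + 1000 * attempt)
        degenerate = bool((node.weights < 1.0 / n).any())
        if not degenerate:
            return node
        if best is None or node.log_likelihood > best.log_likelihood:
            best = node
    best.flags.append("degenerate-class")
    log.warning("beta mixture kept a degenerate class after %d restarts", max_restarts)
    return best


def _fit_em_once(x, logx, log1mx, k, tol, max_iter, seed) -> BetaMixtureNode:
    n, p = x.shape
    km = KMeans(n_clusters=min(k, n), n_init=1, random_state=seed)
    labels = km.fit_predict(np.log(x / (1.0 - x)))
    resp = np.full((n, k), 0.05 / max(k - 1, 1))
    resp[np.arange(n), labels] = 0.95
    resp /= resp.sum(axis=1, keepdims=True)

    a = np.empty((k, p))
    b = np.empty((k, p))
    trace = []
    ll = -np.inf
    converged = False
    flags: list[str] = []
    for it in range(max_iter):
        # M-step: exact weighted MLE per class -> EM ascent is guaranteed
        weights = resp.mean(axis=0)
        weights = np.clip(weights, 1e-12, None)
        weights /= weights.sum()
        for c in range(k):
            a[c], b[c] = _weighted_beta_mle(logx, log1mx, x, resp[:, c])
        # E-step
        logdens = _log_beta_density(logx, log1mx, a, b) + np.log(weights)
        norm = logsumexp(logdens, axis=1)
        new_ll = float(norm.sum())
        resp = np.exp(logdens - norm[:, None])
        if trace and new_ll < trace[-1] - 1e-8 * (abs(trace[-1]) + 1.0):
            flags.append("non-monotone")
        trace.append(new_ll)
        if np.isfinite(ll) and abs(new_ll - ll) < tol * (abs(ll) + 1.0):
            converged = True
            ll = new_ll
            break
        ll = new_ll
    if not converged:
        flags.append("max-iter")
    npar = (k - 1) + 2 * k * p
    bic = -2.0 * ll + npar * np.log(n)
    return BetaMixtureNode(
        a, b, weights, resp, ll, bic, converged, len(trace), np.array(trace), flags
    )


@dataclass
class RPMMNode:
    """One node of the recursive partition."""

    label: str
    level: int
    sample_ids: list[str]
    median_beta: float
    mixture: BetaMixtureNode | None = None
    children: list["RPMMNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class RPMMTree:
    root: RPMMNode
    max_level: int

    def leaves(self) -> list[RPMMNode]:
        out: list[RPMMNode] = []

        def walk(node: RPMMNode):
            if node.is_leaf:
                out.append(node)
            for child in node.children:
                walk(child)

        walk(self.root)
        return out

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def assignments(self) -> pd.Series:
        """Hard leaf label per sample."""
        pairs = [(s, leaf.label) for leaf in self.leaves() for s in leaf.sample_ids]
        return pd.Series(dict(pairs), name="rpmm_cluster")


def rpmm_cluster(
    beta_sub: pd.DataFrame,
    max_level: int = 2,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    min_node_size: int = 4,
) -> RPMMTree:
    """Recursively split samples into a binary tree of beta-mixture classes.

    A node splits only when the 2-class BIC beats the 1-class BIC on that
    node's samples; the ``L`` child is the one with higher median beta.
    """
    if max_level < 1:
        raise ValueError("max_level must be >= 1")
    if beta_sub.shape[0] == 0 or beta_sub.shape[1] == 0:
        raise ValueError("empty beta matrix")
    if beta_sub.isna().to_numpy().any():
        raise ValueError("beta matrix contains missing values")

    def build(label: str, level: int, ids: list[str]) -> RPMMNode:
        sub = beta_sub.loc[ids]
        node = RPMMNode(label, level, ids, float(np.median(sub.to_numpy())))
        if level >= max_level or len(ids) < min_node_size:
            return node
        one = _fit_one_class(_clip_beta(sub.to_numpy()))
        two = fit_beta_mixture(sub, k=2, tol=tol, max_iter=max_iter, seed=seed)
        if two.bic >= one.bic or "degenerate-class" in two.flags:
            return node
        hard = two.hard_assignments()
        groups = [
            [s for s, h in zip(ids, hard) if h == c] for c in (0, 1)
        ]
        if any(len(g) == 0 for g in groups):
            return node
        med = [float(np.median(beta_sub.loc[g].to_numpy())) for g in groups]
        # L = higher-methylation child (the expected low-release side)
        ordered = sorted(zip(med, groups), key=lambda t: -t[0])
        node.mixture = two
        node.children = [
            build(label + suffix, level + 1, grp)
            for suffix, (_, grp) in zip(("L", "R"), ordered)
        ]
        return node

    root = build("r", 0, list(beta_sub.index))
    return RPMMTree(root, max_level)


def assign_release_class(
    tree: RPMMTree, beta_sub: pd.DataFrame, signature: pd.DataFrame | list[str]
) -> pd.DataFrame:
    """Name the two top-level clusters by their signature methylation.

    The cluster with the higher median beta across signature probes becomes
    ``expected-low`` (high methylation, low shedding); the other
    ``expected-high``.  Requires a 2-leaf tree; exactly equal medians are a
    degenerate fit and raise.
    """
    leaves = tree.leaves()
    if len(leaves) != 2:
        raise ValueError(f"release-class naming needs exactly 2 clusters, got {len(leaves)}")
    probes = list(signature.index) if hasattr(signature, "index") else list(signature)
    probes = [p for p in probes if p in beta_sub.columns]
    if not probes:
        raise ValueError("no signature probes present in the beta matrix")
    medians = {
        leaf.label: float(np.nanmedian(beta_sub.loc[leaf.sample_ids, probes].to_numpy()))
        for leaf in leaves
    }
    if medians[leaves[0].label] == medians[leaves[1].label]:
        raise ValueError(
            "cluster medians are exactly equal; degenerate fit requires manual "
            "disambiguation"
        )
    low_label = max(medians, key=medians.get)
    rows = []
    for leaf in leaves:
        pred = "expected-low" if leaf.label == low_label else "expected-high"
        rows += [(s, leaf.label, pred) for s in leaf.sample_ids]
    out = pd.DataFrame(rows, columns=["sample_id", "rpmm_cluster", "prediction"])
    out = out.set_index("sample_id")
    ordered_ids = [s for s in beta_sub.index if s in out.index]
    return out.loc[ordered_ids]


def silhouette_rank(beta_sub: pd.DataFrame, predictions: pd.DataFrame) -> pd.DataFrame:
    """Silhouette widths (Euclidean on beta vectors) and the global ranking
    from most-confident expected-high to most-confident expected-low.

    Samples in a singleton cluster receive silhouette 0 (convention) and a
    warning is logged.
    """
    preds = predictions.loc[predictions.index.intersection(beta_sub.index)].copy()
    labels = preds["rpmm_cluster"].to_numpy()
    if len(pd.unique(labels)) < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    counts = preds["rpmm_cluster"].value_counts()
    if (counts == 1).any():
        log.warning(
            "singleton cluster(s) %s: silhouette width set to 0",
            list(counts.index[counts == 1]),
        )
    x = beta_sub.loc[preds.index].to_numpy(dtype=float)
    preds["silhouette_width"] = silhouette_samples(x, labels, metric="euclidean")

    high = preds[preds["prediction"] == "expected-high"].sort_values(
        "silhouette_width", ascending=False, kind="stable"
    )
    low = preds[preds["prediction"] == "expected-low"].sort_values(
        "silhouette_width", ascending=True, kind="stable"
    )
    ordered = pd.concat([high, low])
    ordered["rank"] = np.arange(1, len(ordered) + 1)
    return ordered


def classify_cimp(
    beta: pd.DataFrame,
    cimp_probes: list[str],
    seed: int = 0,
    max_level: int = 2,
) -> pd.DataFrame:
    """CIMP class calls from a fixed panel of CIMP-associated probes.

    Panel probes carrying any missing value are dropped; the survivors are
    clustered by the recursive beta-mixture tree at ``max_level`` (up to 4
    leaves), and leaves are labelled CIMP-H, CIMP-L, CIMP3, CIMP4 from the
    highest to the lowest median methylation.  With fewer than four leaves,
    labels are assigned from the top of that ordering downward.
    """
    panel = [p for p in cimp_probes if p in beta.columns]
    if len(panel) < 2:
        raise ValueError("fewer than 2 CIMP panel probes present in the beta matrix")
    sub = beta.loc[:, panel]
    usable = sub.columns[~sub.isna().any(axis=0)]
    if len(usable) < 2:
        raise ValueError("fewer than 2 CIMP panel probes without missing values")
    sub = sub.loc[:, usable]
    tree = rpmm_cluster(sub, max_level=max_level, seed=seed)
    leaves = sorted(tree.leaves(), key=lambda lf: -lf.median_beta)
    if len(leaves) == 1:
        log.warning("CIMP clustering produced a single leaf; all samples CIMP-H")
    rows = []
    for label, leaf in zip(CIMP_LABELS, leaves):
        rows += [(s, label, leaf.label) for s in leaf.sample_ids]
    out = pd.DataFrame(rows, columns=["sample_id", "cimp_class", "rpmm_cluster"])
    out["n_probes_used"] = len(usable)
    return out.set_index("sample_id").loc[beta.index]
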