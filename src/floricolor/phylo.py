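"""Phylogenetic comparative methods on a fixed study tree.

Under the Brownian-motion (BM) model of continuous-trait evolution, tip
values are multivariate normal with covariance ``sigma2 * C``, where
``C[i, j]`` is the shared root-to-tip path length of tips i and j. This
module provides:

* Newick parsing and pruning (via dendropy) with the derived C matrix;
* BM trait simulation on the tree;
* phylogenetic ANOVA — the classical one-way F statistic referred to a
  null distribution of F values from BM simulations on the same tree,
  so group differences are judged against the non-independence the
  phylogeny induces;
* Holm step-down adjustment for families of such tests;
* maximum-likelihood ancestral state estimation for continuous traits
  (the GLS / conditional-normal solution, computed as a weighted
  least-squares problem on the tree's edges).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
from statsmodels.stats.multitest import multipletests


class NewickParseError(ValueError):
    pass


@dataclass
class Phylogeny:
    """A rooted tree with branch lengths; tips carry sample/species ids."""

    tree: dendropy.Tree
    tip_labels: list[str] = field(init=False)

    def __post_init__(self) -> None:
        labels = [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise NewickParseError("duplicate tip labels")
        self.tip_labels = labels

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def vcv(self) -> np.ndarray:
        """Tip-tip shared-path-length matrix C (BM covariance up to sigma2)."""
        idx = {label: i for i, label in enumerate(self.tip_labels)}
        n = len(idx)
        c = np.zeros((n, n))
        # depth of each node = sum of branch lengths from the root
        depth: dict[int, float] = {}
        tipsets: dict[int, list[int]] = {}
        for node in self.tree.preorder_node_iter():
            edge = node.edge.length or 0.0
            parent = node.parent_node
            depth[id(node)] = (depth[id(parent)] if parent is not None else 0.0) + edge
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                i = idx[node.taxon.label]
                tipsets[id(node)] = [i]
                c[i, i] = depth[id(node)]
                continue
            child_sets = [tipsets.pop(id(ch)) for ch in node.child_nodes()]
            d = depth[id(node)]
            for a in range(len(child_sets)):
                for b in range(a + 1, len(child_sets)):
                    for i in child_sets[a]:
                        for j in child_sets[b]:
                            c[i, j] = c[j, i] = d
            tipsets[id(node)] = [i for s in child_sets for i in s]
        return c

    def prune_to(self, labels) -> "Phylogeny":
        """Subtree spanning `labels`, preserving pairwise path lengths."""
        keep = set(labels)
        missing = keep - set(self.tip_labels)
        if missing:
            raise KeyError(f"tips not in tree: {sorted(missing)}")
        sub = self.tree.clone(depth=1)
        sub.retain_taxa_with_labels(sorted(keep))
        return Phylogeny(tree=sub)

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick").strip()


def read_newick(text: str) -> Phylogeny:
    """Parse a Newick string (branch lengths required on non-root edges)."""
    try:
        tree = dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:  # dendropy raises assorted error types
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    for node in tree.preorder_node_iter():
        if node.parent_node is not None and node.edge.length is None:
            raise NewickParseError("tree has edges without branch lengths")
        if (node.edge.length or 0.0) < 0:
            raise NewickParseError("negative branch length")
    return Phylogeny(tree=tree)


def _cov_factor(c: np.ndarray) -> np.ndarray:
    """A matrix L with L L' = C; Cholesky when possible, eigen fallback
    for the positive semi-definite (degenerate) case."""
    try:
        return np.linalg.cholesky(c)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(c)
        w = np.clip(w, 0.0, None)
        return v * np.sqrt(w)


def simulate_brownian(
    t: Phylogeny,
    sigma2: float,
    root_value: float = 0.0,
    seed: int | None = None,
    n_draws: int = 1,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw BM tip values: MVN(root_value, sigma2 * C). Shape (n_draws, n_tips)."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    rng = np.random.default_rng(seed) if rng is None else rng
    factor = _cov_factor(t.vcv())
    z = rng.standard_normal((n_draws, t.n_tips))
    return root_value + np.sqrt(sigma2) * (z @ factor.T)


def _anova_f(y: np.ndarray, group_index: np.ndarray, n_groups: int) -> np.ndarray:
    """Classical one-way ANOVA F, vectorized over rows of `y` ((m, n))."""
    y = np.atleast_2d(y)
    n = y.shape[1]
    counts = np.bincount(group_index, minlength=n_groups).astype(float)
    sums = np.vstack([y[:, group_index == g].sum(axis=1) for g in range(n_groups)]).T
    grand_mean = y.mean(axis=1, keepdims=True)
    group_means = sums / counts
    ssb = (counts * (group_means - grand_mean) ** 2).sum(axis=1)
    sst = ((y - grand_mean) ** 2).sum(axis=1)
    ssw = sst - ssb
    dfb, dfw = n_groups - 1, n - n_groups
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / dfb) / (ssw / dfw)
    f = np.where(ssw <= 1e-300, np.inf, f)
    return f


def brownian_rate_ml(t: Phylogeny, values: np.ndarray) -> tuple[float, float]:
    """ML estimates (sigma2, root state) of BM from tip values.

    Root state is the GLS phylogenetic mean ``(1'C^-1 y)/(1'C^-1 1)``;
    sigma2 is the ML (1/n) quadratic form of the GLS residuals.
    """
    c = t.vcv()
    y = np.asarray(values, dtype=float)
    cinv_y = np.linalg.solve(c, y)
    cinv_1 = np.linalg.solve(c, np.ones_like(y))
    a = float(cinv_y.sum() / cinv_1.sum())
    resid = y - a
    sigma2 = float(resid @ np.linalg.solve(c, resid) / len(y))
    return sigma2, a


@dataclass
class PhylAnovaResult:
    f_obs: float
    p_sim: float
    n_sim: int
    sigma2_hat: float
    seed: int | None
    adjusted_p: float | None = None


def phyl_anova(
    t: Phylogeny,
    trait: np.ndarray,
    groups,
    n_sim: int = 10_000,
    seed: int | None = None,
) -> PhylAnovaResult:
    """Phylogenetic ANOVA with a Brownian-motion simulation null.

    `trait` and `groups` are aligned with ``t.tip_labels``. The observed
    one-way F is compared with F values from `n_sim` BM simulations on
    the tree (rate = pooled ML estimate; group labels held fixed);
    ``p_sim = (count(F_sim >= F_obs) + 1) / (n_sim + 1)``.
    """
    y = np.asarray(trait, dtype=float)
    if len(y) != t.n_tips:
        raise ValueError("trait length does not match tip count")
    labels, group_index = np.unique(np.asarray(groups), return_inverse=True)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    counts = np.bincount(group_index)
    if counts.min() < 2:
        raise ValueError("each group needs at least 2 tips")
    f_obs = float(_anova_f(y, group_index, len(labels))[0])
    sigma2_hat, root = brownian_rate_ml(t, y)
    if sigma2_hat <= 0:
        sigma2_hat = np.finfo(float).tiny
    sims = simulate_brownian(t, sigma2_hat, root_value=root, seed=seed, n_draws=n_sim)
    f_sim = _anova_f(sims, group_index, len(labels))
    p = (int(np.sum(f_sim >= f_obs)) + 1) / (n_sim + 1)
    return PhylAnovaResult(
        f_obs=f_obs, p_sim=p, n_sim=n_sim, sigma2_hat=sigma2_hat, seed=seed
    )


def holm_adjust(pvals) -> list[float]:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(list(pvals), dtype=float)
    if len(p) == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="holm")[1].tolist()


@dataclass
class AncestralEstimates:
    """Per-internal-node ML state estimates and variances under BM."""

    node_ids: list[str]
    estimates: np.ndarray
    variances: np.ndarray
    root_estimate: float


def ancestral_states_bm(t: Phylogeny, trait) -> AncestralEstimates:
    """ML ancestral states for a continuous trait under Brownian motion.

    Joint ML over internal-node states minimizes
    ``sum_edges (x_parent - x_child)^2 / length`` with tips fixed — a
    weighted least-squares (graph Laplacian) system whose solution
    equals the GLS conditional-normal estimate; the root estimate is the
    GLS phylogenetic mean. Variances are ``sigma2_ML`` times the
    diagonal of the inverted system. Zero-length edges get a small ridge
    (with a warning) to keep the system nonsingular.
    """
    if isinstance(trait, dict):
        y = np.array([trait[label] for label in t.tip_labels], dtype=float)
    else:
        y = np.asarray(trait, dtype=float)
        if len(y) != t.n_tips:
            raise ValueError("trait length does not match tip count")
    tip_value = dict(zip(t.tip_labels, y))

    internal = [n for n in t.tree.preorder_node_iter() if not n.is_leaf()]
    index = {id(n): i for i, n in enumerate(internal)}
    m = len(internal)
    lap = np.zeros((m, m))
    rhs = np.zeros(m)
    ridged = False
    for node in t.tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            continue
        length = node.edge.length or 0.0
        if length <= 0:
            ridged = True
            length = 1e-8
        w = 1.0 / length
        i = index[id(parent)]
        if node.is_leaf():
            lap[i, i] += w
            rhs[i] += w * tip_value[node.taxon.label]
        else:
            j = index[id(node)]
            lap[i, i] += w
            lap[j, j] += w
            lap[i, j] -= w
            lap[j, i] -= w
    if ridged:
        warnings.warn("zero-length edge(s): applied 1e-8 ridge", stacklevel=2)
    lap_inv = np.linalg.inv(lap)
    est = lap_inv @ rhs
    sigma2, _ = brownian_rate_ml(t, y)
    node_ids = [
        n.label if n.label else f"node{i}" for i, n in enumerate(internal)
    ]
    return AncestralEstimates(
        node_ids=node_ids,
        estimates=est,
        variances=sigma2 * np.diag(lap_inv),
        root_estimate=float(est[0]),
    )
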