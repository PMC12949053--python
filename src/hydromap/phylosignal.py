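"""Phylogenetic signal in genus-mean embolism resistance.

Implements Blomberg's K with tip-randomisation significance, maximum-likelihood
(GLS) ancestral state reconstruction under Brownian motion, and the node-level
randomisation that maps which clades drive the signal.

The trait of interest is the xylem pressure at 50 % loss of conductivity
(psi50, MPa, negative); throughout this module "more resistant" means a more
negative psi50, i.e. a *larger* transformed absolute value. Square- and
cube-root transformations therefore operate on ``abs(psi50)`` so the sign
convention maps resistance onto larger numbers.

Trees are handled through :class:`Phylogeny`, a thin cached wrapper around a
:mod:`dendropy` tree that exposes the Brownian-motion covariance structure:
``V[i, j]`` is the branch-length depth of the most recent common ancestor of
tips ``i`` and ``j``, the covariance (up to the rate sigma^2) of their trait
values under BM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .errors import (
    DegenerateDataError,
    IllConditionedTreeError,
    InvalidArgumentError,
    InvalidTreeError,
    MissingTaxonError,
)

__all__ = [
    "Phylogeny",
    "SignalResult",
    "NodeRandomisationResult",
    "apply_transformation",
    "tree_covariance",
    "blomberg_k",
    "permutation_test",
    "ancestral_states",
    "node_randomisation",
]

TRANSFORMATIONS = ("none", "sqrt", "cbrt")


def apply_transformation(values: np.ndarray, transformation: str) -> np.ndarray:
    """Apply the configured normalising transform.

    ``sqrt`` and ``cbrt`` act on ``abs(values)`` so that for negative psi50
    data more resistant (more negative) taxa map to larger numbers; ``none``
    returns the input unchanged.
    """
    values = np.asarray(values, dtype=float)
    if transformation == "none":
        return values
    if transformation == "sqrt":
        return np.sqrt(np.abs(values))
    if transformation == "cbrt":
        return np.cbrt(np.abs(values))
    raise InvalidArgumentError(
        f"unknown transformation {transformation!r}; expected one of {TRANSFORMATIONS}"
    )


class Phylogeny:
    """Rooted tree with branch lengths and unique tip labels.

    Wraps a :class:`dendropy.Tree` and caches the arrays the signal statistics
    need: tip depths, the tip-tip shared-path matrix V and the node-tip
    shared-path matrix used for ancestral reconstruction. Polytomies are
    accepted; branch lengths must be present (the root edge may be absent and
    is treated as zero) and non-negative.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._index()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(cls, source: str) -> "Phylogeny":
        """Parse a Newick string (quoted labels supported)."""
        tree = dendropy.Tree.get(
            data=source, schema="newick", preserve_underscores=True
        )
        return cls(tree)

    @classmethod
    def from_newick_file(cls, path) -> "Phylogeny":
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
        return cls(tree)

    def to_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    # -- indexing ----------------------------------------------------------

    def _index(self) -> None:
        tree = self._tree
        root = tree.seed_node
        tips = []
        internals = []
        depth = {}
        for node in tree.preorder_node_iter():
            if node is root:
                d = node.edge.length or 0.0
            else:
                if node.edge.length is None:
                    raise InvalidTreeError("tree has edges without branch lengths")
                if node.edge.length < 0:
                    raise InvalidTreeError("tree has negative branch lengths")
                d = depth[node.parent_node] + node.edge.length
            depth[node] = d
            if node.is_leaf():
                tips.append(node)
            else:
                internals.append(node)
        labels = []
        for t in tips:
            label = t.taxon.label if t.taxon is not None else t.label
            if label is None:
                raise InvalidTreeError("tree has unlabelled tips")
            labels.append(str(label))
        if len(set(labels)) != len(labels):
            raise InvalidTreeError("tip labels are not unique")

        self._tips = tips
        self._internals = internals
        self._depth = depth
        self.tip_labels: list[str] = labels
        self._tip_index = {lab: i for i, lab in enumerate(labels)}
        self.node_ids: list[str] = [f"node{j}" for j in range(len(internals))]
        self._node_index = {id(n): j for j, n in enumerate(internals)}
        self._V: np.ndarray | None = None
        self._C: np.ndarray | None = None

    @property
    def n_tips(self) -> int:
        return len(self._tips)

    @property
    def n_internal(self) -> int:
        return len(self._internals)

    def tip_depths(self) -> np.ndarray:
        return np.array([self._depth[t] for t in self._tips])

    def node_depths(self) -> np.ndarray:
        return np.array([self._depth[n] for n in self._internals])

    def node_tip_sets(self) -> list[frozenset[str]]:
        """Descendant tip labels of each internal node (parallel to node_ids)."""
        out: list[frozenset[str]] = [frozenset()] * len(self._internals)
        memo: dict[int, frozenset[str]] = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                lab = node.taxon.label if node.taxon is not None else node.label
                memo[id(node)] = frozenset([str(lab)])
            else:
                s = frozenset().union(*(memo[id(c)] for c in node.child_nodes()))
                memo[id(node)] = s
                out[self._node_index[id(node)]] = s
        return out

    def mrca_node_id(self, tip_labels) -> str:
        """Internal-node id of the most recent common ancestor of the tips."""
        want = set(map(str, tip_labels))
        missing = want - set(self.tip_labels)
        if missing:
            raise MissingTaxonError(missing)
        best = None
        for j, s in enumerate(self.node_tip_sets()):
            if want <= s and (best is None or len(s) < best[1]):
                best = (j, len(s))
        assert best is not None  # root always contains every tip
        return self.node_ids[best[0]]

    # -- covariance structure ---------------------------------------------

    def _build_shared_depths(self) -> None:
        """One postorder pass fills both V (tip x tip) and C (node x tip).

        The shared path length of two leaves (or of an internal node and a
        leaf) from the root is the depth of their MRCA, which is exactly the
        node at which their subtrees first meet during the postorder merge.
        """
        n = self.n_tips
        m = self.n_internal
        V = np.zeros((n, n))
        C = np.zeros((m, n))
        tip_sets: dict[int, list[int]] = {}
        node_sets: dict[int, list[int]] = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                i = self._tip_index[
                    str(node.taxon.label if node.taxon is not None else node.label)
                ]
                V[i, i] = self._depth[node]
                tip_sets[id(node)] = [i]
                node_sets[id(node)] = []
                continue
            d = self._depth[node]
            children = node.child_nodes()
            ctips = [tip_sets.pop(id(c)) for c in children]
            cnodes = [node_sets.pop(id(c)) for c in children]
            for a in range(len(children)):
                for b in range(len(children)):
                    if a == b:
                        continue
                    if ctips[a] and ctips[b]:
                        V[np.ix_(ctips[a], ctips[b])] = d
                    if cnodes[a] and ctips[b]:
                        C[np.ix_(cnodes[a], ctips[b])] = d
            all_tips = [i for sub in ctips for i in sub]
            all_nodes = [j for sub in cnodes for j in sub]
            j = self._node_index[id(node)]
            C[j, all_tips] = d
            all_nodes.append(j)
            tip_sets[id(node)] = all_tips
            node_sets[id(node)] = all_nodes
        self._V = V
        self._C = C

    def covariance(self) -> np.ndarray:
        """Tip-tip shared-path-length matrix V in this tree's tip order."""
        if self._V is None:
            self._build_shared_depths()
        return self._V.copy()

    def node_tip_covariance(self) -> np.ndarray:
        """Internal-node x tip shared-path matrix (rows follow node_ids)."""
        if self._C is None:
            self._build_shared_depths()
        return self._C.copy()


# ---------------------------------------------------------------------------
# results


@dataclass
class SignalResult:
    """Blomberg's K with optional permutation null.

    ``p_value`` uses the add-one permutation convention
    ``(1 + #extreme) / (1 + n_permutations)`` doubled for two-sidedness and
    capped at 1; ``significant`` applies the percentile rule: the observed K
    lies outside the [2.5 %, 97.5 %] band of the null distribution.
    """

    k: float
    n_genera: int
    transformation: str = "none"
    p_value: float | None = None
    n_permutations: int = 0
    null_distribution: np.ndarray | None = None
    significant: bool | None = None
    dropped_tips: list[str] = field(default_factory=list)


@dataclass
class NodeRandomisationResult:
    """Per-node ancestral values ranked against a tip-randomisation null."""

    node_ids: list[str]
    observed: np.ndarray
    null_rank: np.ndarray  # fraction of null draws below the observed value
    p_values: np.ndarray  # tail-appropriate permutation p per node
    flagged: np.ndarray  # boolean
    n_permutations: int
    alpha: float
    tail: str

    def flagged_ids(self) -> list[str]:
        return [nid for nid, f in zip(self.node_ids, self.flagged) if f]


# ---------------------------------------------------------------------------
# internals


def _align(
    tree: Phylogeny, values: dict, require_full: bool = False
) -> tuple[np.ndarray, list[str], list[str]]:
    """Match trait values to tree tips by normalised genus name.

    Trait entries without a matching tip are dropped and reported (an 88-genus
    trait table joining an 87-tip tree is normal); tips without data are
    likewise dropped unless ``require_full`` — the statistics then run on the
    covariance submatrix of the matched tips, which equals pruning the tree.
    """
    norm = {str(k).strip().casefold(): float(v) for k, v in values.items()}
    x = []
    order = []
    matched = []
    for lab in tree.tip_labels:
        key = lab.strip().casefold()
        if key in norm:
            x.append(norm[key])
            order.append(lab)
            matched.append(key)
    dropped = sorted(set(norm) - set(matched))
    if len(x) < tree.n_tips and require_full:
        missing = [
            lab for lab in tree.tip_labels if lab.strip().casefold() not in norm
        ]
        raise MissingTaxonError(missing, f"tips without trait data: {missing}")
    if not x:
        raise MissingTaxonError(
            list(norm), "no trait entry matches any tree tip"
        )
    return np.array(x), order, dropped


def _prune_to(tree: Phylogeny, keep: set[str]) -> Phylogeny:
    t = dendropy.Tree(tree._tree)  # deep clone keeps the original intact
    t.retain_taxa_with_labels([lab for lab in tree.tip_labels if lab in keep])
    return Phylogeny(t)


def prune_to_overlap(tree: Phylogeny, values: dict) -> tuple[Phylogeny, dict, list[str]]:
    """Restrict tree and trait map to their shared genera.

    Returns the pruned tree, the matching trait subset, and the labels dropped
    from either side.
    """
    norm = {str(k).strip().casefold(): float(v) for k, v in values.items()}
    tip_by_key = {lab.strip().casefold(): lab for lab in tree.tip_labels}
    shared = sorted(set(norm) & set(tip_by_key))
    if len(shared) < 3:
        raise DegenerateDataError(
            f"only {len(shared)} genera shared between tree and trait table"
        )
    dropped = sorted(
        [tip_by_key[k] for k in set(tip_by_key) - set(shared)]
        + [k for k in set(norm) - set(shared)]
    )
    pruned = _prune_to(tree, {tip_by_key[k] for k in shared})
    sub = {tip_by_key[k]: norm[k] for k in shared}
    return pruned, sub, dropped


def _chol(V: np.ndarray) -> np.ndarray:
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError as exc:
        raise IllConditionedTreeError(
            "phylogenetic covariance matrix is not positive definite"
        ) from exc
    cond = np.linalg.cond(V)
    if not np.isfinite(cond) or cond > 1e12:
        raise IllConditionedTreeError(
            f"phylogenetic covariance matrix is ill-conditioned (cond={cond:.3g})"
        )
    return L


def _k_statistics(V: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Blomberg's K for each column of X given covariance V.

    K = (MSE0/MSE) / E_BM[MSE0/MSE] with the GLS (phylogenetic) mean
    a = (1'V^-1 1)^-1 1'V^-1 x used for both mean squares and
    E_BM = [tr(V) - n / (1'V^-1 1)] / (n-1).
    """
    n = V.shape[0]
    L = _chol(V)
    ones = np.ones((n, 1))
    Vi_ones = np.linalg.solve(V, ones)  # V^-1 1  (via LU; V is PD so fine)
    denom = (ones.T @ Vi_ones).item()
    X = np.atleast_2d(X.T).T  # (n, B)
    a_hat = (Vi_ones.T @ X) / denom  # (1, B)
    R = X - ones @ a_hat
    mse0 = np.sum(R * R, axis=0) / (n - 1)
    W = np.linalg.solve(V, R)
    mse = np.sum(R * W, axis=0) / (n - 1)
    expected = (np.trace(V) - n / denom) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        k = (mse0 / mse) / expected
    del L
    return k


# ---------------------------------------------------------------------------
# public operations


def tree_covariance(tree: Phylogeny, tips: list[str] | None = None) -> np.ndarray:
    """Shared path-length (BM covariance) matrix for the requested tips.

    ``V[i, j]`` is the root-to-MRCA distance of tips i and j; the diagonal
    holds root-to-tip depths. Row/column order follows ``tips`` (defaults to
    the tree's own tip order).
    """
    V = tree.covariance()
    if tips is None:
        return V
    missing = [t for t in tips if t not in tree._tip_index]
    if missing:
        raise MissingTaxonError(missing)
    idx = [tree._tip_index[t] for t in tips]
    return V[np.ix_(idx, idx)]


def blomberg_k(
    tree: Phylogeny,
    values: dict,
    transformation: str = "none",
) -> SignalResult:
    """Blomberg's K for a genus -> trait map on the tree.

    The statistic compares the observed ratio of non-phylogenetic to
    phylogenetic mean squared error with its Brownian-motion expectation;
    K = 1 under BM, K -> 0 for phylogenetically random data. The transform
    (sqrt/cbrt of the absolute trait) is applied before computing K.
    Signal is detectable on trees with at least ~20 tips; a warning is issued
    below that.
    """
    x, order, dropped = _align(tree, values)
    n = len(x)
    if n < 20:
        import warnings

        warnings.warn(
            f"Blomberg's K on only {n} genera; power is poor below 20 observations",
            stacklevel=2,
        )
    x = apply_transformation(x, transformation)
    if np.ptp(x) == 0 or np.var(x) == 0:
        raise DegenerateDataError("trait vector is constant; K undefined")
    V = tree_covariance(tree, order)
    k = float(_k_statistics(V, x[:, None])[0])
    return SignalResult(
        k=k, n_genera=n, transformation=transformation, dropped_tips=dropped
    )


def permutation_test(
    tree: Phylogeny,
    values: dict,
    n_permutations: int = 1000,
    seed: int | None = None,
    transformation: str = "none",
) -> SignalResult:
    """Tip-randomisation significance test for Blomberg's K.

    Trait values are shuffled across tips ``n_permutations`` times and K is
    recomputed for each shuffle; the observed K is deemed significant when it
    falls outside the 2.5-97.5 percentile band of the null distribution.
    """
    if n_permutations < 100:
        raise InvalidArgumentError("n_permutations must be >= 100")
    base = blomberg_k(tree, values, transformation)
    x, order, _ = _align(tree, values)
    x = apply_transformation(x, transformation)
    V = tree_covariance(tree, order)
    rng = np.random.default_rng(seed)
    perms = np.empty((len(x), n_permutations))
    for b in range(n_permutations):
        perms[:, b] = rng.permutation(x)
    null = _k_statistics(V, perms)
    n_low = int(np.sum(null <= base.k))
    n_high = int(np.sum(null >= base.k))
    p = min(1.0, 2.0 * (1 + min(n_low, n_high)) / (1 + n_permutations))
    lo, hi = np.percentile(null, [2.5, 97.5])
    base.p_value = p
    base.n_permutations = n_permutations
    base.null_distribution = null
    base.significant = bool(base.k < lo or base.k > hi)
    return base


def _asr_operator(tree: Phylogeny, order: list[str]) -> np.ndarray:
    """Linear map A with node_values = A @ tip_values.

    The ML (GLS) reconstruction under BM is the conditional mean of the joint
    Gaussian: mu_node = a + C V^-1 (x - a 1) with a the GLS root estimate, so
    the whole reconstruction is linear in x and permutation nulls reduce to a
    single matrix product.
    """
    V = tree_covariance(tree, order)
    _chol(V)  # conditioning check
    C = tree.node_tip_covariance()
    idx = [tree._tip_index[t] for t in order]
    C = C[:, idx]
    n = V.shape[0]
    ones = np.ones((n, 1))
    Vi_ones = np.linalg.solve(V, ones)
    w = (Vi_ones / (ones.T @ Vi_ones).item()).T  # (1, n): GLS mean weights
    CVi = np.linalg.solve(V.T, C.T).T  # C V^-1
    m = C.shape[0]
    A = np.ones((m, 1)) @ w + CVi @ (np.eye(n) - ones @ w)
    return A


def ancestral_states(tree: Phylogeny, values: dict) -> dict[str, float]:
    """ML Brownian-motion ancestral values for every internal node.

    Returns a ``node_id -> value`` map; node ids follow the tree's internal
    node order (``tree.node_ids``), with the root included.
    """
    x, order, _ = _align(tree, values, require_full=True)
    A = _asr_operator(tree, order)
    est = A @ x
    return dict(zip(tree.node_ids, map(float, est)))


def node_randomisation(
    tree: Phylogeny,
    values: dict,
    n_permutations: int = 1000,
    alpha: float = 0.05,
    tail: str = "upper",
    seed: int | None = None,
    transformation: str = "none",
) -> NodeRandomisationResult:
    """Locate the clades that carry the signal.

    Tip values are randomised across the tree ``n_permutations`` times, the
    ancestral reconstruction is repeated for each shuffle, and each observed
    node value is ranked within its own permutation null. With
    ``tail='upper'`` a node is flagged when its observed reconstruction
    exceeds the null at level ``alpha`` — with sqrt/cbrt transforms of
    ``abs(psi50)`` the upper tail is the "more embolism-resistant than
    expected by chance" direction.
    """
    if tail not in ("lower", "upper", "two-sided"):
        raise InvalidArgumentError(f"unknown tail {tail!r}")
    if not 0.0 <= alpha <= 1.0:
        raise InvalidArgumentError("alpha must lie in [0, 1]")
    x, order, _ = _align(tree, values, require_full=True)
    x = apply_transformation(x, transformation)
    A = _asr_operator(tree, order)
    obs = A @ x
    rng = np.random.default_rng(seed)
    B = n_permutations
    perms = np.empty((len(x), B))
    for b in range(B):
        perms[:, b] = rng.permutation(x)
    null = A @ perms  # (nodes, B)
    # tolerance absorbs summation-order float noise (e.g. constant traits)
    tol = 1e-9 * max(float(np.abs(null).max()), float(np.abs(obs).max()), 1e-12)
    less = np.sum(null < obs[:, None] - tol, axis=1)
    ties = np.sum(np.abs(null - obs[:, None]) <= tol, axis=1)
    geq = B - less
    leq = less + ties
    rank = (less + 0.5 * ties) / B
    p_upper = (1 + geq) / (1 + B)
    p_lower = (1 + leq) / (1 + B)
    if tail == "upper":
        p = p_upper
    elif tail == "lower":
        p = p_lower
    else:
        p = np.minimum(1.0, 2.0 * np.minimum(p_upper, p_lower))
    flagged = p <= alpha
    return NodeRandomisationResult(
        node_ids=list(tree.node_ids),
        observed=obs,
        null_rank=rank,
        p_values=p,
        flagged=flagged,
        n_permutations=B,
        alpha=alpha,
        tail=tail,
    )
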