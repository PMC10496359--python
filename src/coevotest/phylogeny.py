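"""Trees, phylogenetically independent contrasts, and evolutionary covariance.

The evolutionary correlation COR_E between two traits is the Pearson
correlation of their independent contrasts across a rooted phylogeny of
natural strains or species.  Contrasts (Felsenstein's pruning) remove the
non-independence caused by shared ancestry: n tips yield n - 1 contrasts,
which under Brownian motion are independent with mean zero, so covariances
are computed through the origin by default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .core import CorrelationMatrix, CovarianceMatrix, TraitTable

logger = logging.getLogger("coevotest")

__all__ = [
    "Phylogeny",
    "ContrastSet",
    "parse_newick",
    "independent_contrasts",
    "evolutionary_covariance",
]


class Phylogeny:
    """Rooted tree with branch lengths and unique tip labels.

    Thin wrapper over a :class:`dendropy.Tree` that enforces the contract
    the contrast machinery needs: rooted (no basal polytomy), every non-root
    edge carries a non-negative length, tips uniquely labelled.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        self._validate()
        self._contrast_cache: dict = {}
        self._incidence_cache = None

    def _validate(self) -> None:
        root = self.tree.seed_node
        if len(root.child_nodes()) > 2:
            raise ValueError(
                "basal polytomy: tree appears unrooted; a rooted tree is required"
            )
        labels = []
        for node in self.tree.preorder_node_iter():
            if node is root:
                continue
            if node.edge.length is None:
                raise ValueError(f"missing branch length on edge to {_describe(node)}")
            if node.edge.length < 0:
                raise ValueError(f"negative branch length on edge to {_describe(node)}")
            if node.is_leaf():
                if node.taxon is None or not node.taxon.label:
                    raise ValueError("unlabelled tip in tree")
                labels.append(node.taxon.label)
            elif len(node.child_nodes()) < 2:
                raise ValueError("internal node with a single child")
        if len(labels) != len(set(labels)):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")
        if len(labels) < 2:
            raise ValueError("tree must have at least 2 tips")
        self._tip_labels = labels

    @property
    def tip_labels(self) -> list[str]:
        return list(self._tip_labels)

    @property
    def n_tips(self) -> int:
        return len(self._tip_labels)

    @property
    def n_contrasts(self) -> int:
        return self.n_tips - 1

    @property
    def height(self) -> float:
        """Maximum root-to-tip path length."""
        h = 0.0
        for leaf in self.tree.leaf_node_iter():
            d = 0.0
            node = leaf
            while node.parent_node is not None:
                d += node.edge.length or 0.0
                node = node.parent_node
            h = max(h, d)
        return h

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        return parse_newick(text)

    @classmethod
    def from_file(cls, path) -> "Phylogeny":
        with open(path) as fh:
            return parse_newick(fh.read())

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    # ------------------------------------------------------------------
    # linear-operator views used by contrasts, BM simulation and synthetic
    # data injection
    # ------------------------------------------------------------------

    def contrast_operator(self, zero_branch_floor: float | str = "auto") -> tuple[np.ndarray, list[str]]:
        """Matrix U ((n_tips - 1) x n_tips) mapping tip values to contrasts.

        Each contrast is a linear combination of tip values; ``U @ x`` equals
        the standardized independent contrasts of the tip vector ``x``.
        Multifurcations (non-root) are resolved into zero-length binary
        splits first; zero-length terminal branches are floored at
        ``zero_branch_floor`` (default 1e-8 x tree height) to avoid division
        by zero.
        """
        key = zero_branch_floor
        if key not in self._contrast_cache:
            self._contrast_cache[key] = _build_contrast_operator(self, zero_branch_floor)
        return self._contrast_cache[key]

    def branch_incidence(self) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """(A, lengths, tip_labels): A[i, b] = 1 if branch b is on the root
        path of tip i.  Used by the Brownian-motion simulator."""
        if self._incidence_cache is None:
            tips = self.tip_labels
            tip_index = {t: i for i, t in enumerate(tips)}
            lengths = []
            rows = []  # (tip, branch) pairs
            for node in self.tree.preorder_node_iter():
                if node is self.tree.seed_node:
                    node._branch_path = []
                    continue
                b = len(lengths)
                lengths.append(node.edge.length)
                node._branch_path = node.parent_node._branch_path + [b]
                if node.is_leaf():
                    for bb in node._branch_path:
                        rows.append((tip_index[node.taxon.label], bb))
            A = np.zeros((len(tips), len(lengths)))
            for i, b in rows:
                A[i, b] = 1.0
            self._incidence_cache = (A, np.asarray(lengths, dtype=float), tips)
        return self._incidence_cache

    def __repr__(self) -> str:  # pragma: no cover
        return f"Phylogeny({self.n_tips} tips)"


def _describe(node) -> str:
    if node.is_leaf() and node.taxon is not None:
        return f"tip {node.taxon.label!r}"
    kids = [c.taxon.label for c in node.leaf_iter() if c.taxon]
    return f"internal node above {kids[:4]}"


def parse_newick(text: str) -> Phylogeny:
    """Parse a Newick string (branch lengths required) into a Phylogeny."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy errors carry position info
        raise ValueError(f"malformed Newick: {exc}") from exc
    return Phylogeny(tree)


def _build_contrast_operator(
    phylo: Phylogeny, zero_branch_floor: float | str = "auto"
) -> tuple[np.ndarray, list[str]]:
    tips = phylo.tip_labels
    tip_index = {t: i for i, t in enumerate(tips)}
    n = len(tips)

    if zero_branch_floor == "auto":
        zero_branch_floor = 1e-8 * phylo.height

    # (weight vector over tips, adjusted branch length) per node, postorder
    rows: list[np.ndarray] = []
    stack: dict[int, tuple[np.ndarray, float]] = {}
    n_resolved = 0
    n_floored = 0
    for node in phylo.tree.postorder_node_iter():
        if node.is_leaf():
            w = np.zeros(n)
            w[tip_index[node.taxon.label]] = 1.0
            v = node.edge.length
            if v == 0 and zero_branch_floor:
                v = zero_branch_floor
                n_floored += 1
            stack[id(node)] = (w, v)
            continue
        children = [stack.pop(id(c)) for c in node.child_nodes()]
        if len(children) > 2:
            n_resolved += 1
        # resolve multifurcations as a zero-length ladder: combine the first
        # two children, treat the result as a child with adjusted branch 0+extra
        while len(children) > 1:
            (w1, v1), (w2, v2) = children[0], children[1]
            vsum = v1 + v2
            if vsum == 0:
                raise ValueError(
                    f"zero-length cherry at {_describe(node)}: contrast undefined"
                )
            rows.append((w1 - w2) / np.sqrt(vsum))
            w = (w1 * v2 + w2 * v1) / vsum  # BLUE ancestral value
            extra = v1 * v2 / vsum
            children = [(w, extra)] + children[2:]
        w, extra = children[0]
        edge = node.edge.length if node.parent_node is not None else 0.0
        stack[id(node)] = (w, (edge or 0.0) + extra)
    if n_resolved:
        logger.info("resolved %d multifurcation(s) with zero-length splits", n_resolved)
    if n_floored:
        logger.info(
            "floored %d zero-length terminal branch(es) at %g", n_floored, zero_branch_floor
        )
    U = np.vstack(rows)
    assert U.shape == (n - 1, n)
    return U, tips


@dataclass
class ContrastSet:
    """(n_tips - 1) x traits matrix of standardized independent contrasts."""

    trait_ids: list[str]
    contrasts: np.ndarray
    tip_labels: list[str] = field(default_factory=list)

    @property
    def n_contrasts(self) -> int:
        return self.contrasts.shape[0]


def independent_contrasts(
    tree: Phylogeny,
    table: TraitTable,
    zero_branch_floor: float | str = "auto",
) -> ContrastSet:
    """Felsenstein's standardized independent contrasts for every trait.

    At each (binarized) internal node with child values x1, x2 on adjusted
    branches v1, v2 the contrast is ``(x1 - x2) / sqrt(v1 + v2)``; the
    ancestral value is the branch-length-weighted mean and the parent branch
    is extended by ``v1 v2 / (v1 + v2)``.
    """
    missing = set(tree.tip_labels) - set(table.unit_ids)
    if missing:
        raise ValueError(f"tips missing from trait table: {sorted(missing)}")
    U, tips = tree.contrast_operator(zero_branch_floor)
    x = table.data.loc[tips].to_numpy(dtype=float)
    if np.isnan(x).any():
        bad = [tips[i] for i in np.flatnonzero(np.isnan(x).any(axis=1))]
        raise ValueError(f"missing trait values for tree tips: {bad}")
    return ContrastSet(trait_ids=table.trait_ids, contrasts=U @ x, tip_labels=tips)


def evolutionary_covariance(
    contrasts: ContrastSet,
    center: bool = False,
) -> tuple[CovarianceMatrix, CorrelationMatrix]:
    """Evolutionary covariance and correlation matrices from contrasts.

    By default computed through the origin (no mean-centering): contrasts
    have expectation zero under Brownian motion, so ``cov(i, j)`` is the
    mean over contrasts of ``c_i * c_j``.  ``center=True`` switches to the
    ordinary mean-centered sample covariance (ddof=1).
    """
    c = contrasts.contrasts
    if c.shape[0] < 1:
        raise ValueError("need at least 1 contrast")
    if center:
        if c.shape[0] < 2:
            raise ValueError("centered covariance needs at least 2 contrasts")
        cov = np.cov(c, rowvar=False, ddof=1)
    else:
        cov = c.T @ c / c.shape[0]
    ss = np.diag(cov).copy()
    # round-off can leave ~1e-32-relative residue in truly constant traits
    zero = np.flatnonzero(ss <= max(ss.max(), 0.0) * 1e-24)
    ss[zero] = 0.0
    sd = np.sqrt(np.where(ss > 0, ss, np.nan))
    with np.errstate(invalid="ignore"):
        corr = cov / np.outer(sd, sd)
    if zero.size:
        names = [contrasts.trait_ids[i] for i in zero]
        warnings.warn(
            f"trait(s) with all-zero contrasts, correlations undefined: {names}",
            RuntimeWarning,
        )
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(corr, -1.0, 1.0)
    return (
        CovarianceMatrix(cov, contrasts.trait_ids),
        CorrelationMatrix(corr, contrasts.trait_ids),
    )
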