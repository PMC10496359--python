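"""Synthetic data generators for every pipeline stage.

Emulates the empirical study designs the pipeline targets — large mutant
panels (thousands of deletion lines or ~150 MA lines) phenotyped for many
traits, a modest set of natural strains related by a rooted tree, and
block-modular covariance structure (e.g. three trait modules) — without any
external data.  Defaults mirror those designs; every generator is
deterministic under a fixed seed.

Mutant panels are multivariate-normal draws around a target covariance;
divergence data are Brownian-motion tip values along a supplied tree, with
optional per-pair "injections" that force the across-contrast correlation
of a trait pair to a chosen target (selection distortion with exact ground
truth).  Injection operates in contrast space: target-correlated contrast
vectors E are drawn and mapped to tip space through the pseudo-inverse of
the tree's contrast operator, so the contrasts the estimator computes are
exactly E.
"""

from __future__ import annotations

import logging

import dendropy
import numpy as np
import pandas as pd

from .core import CovarianceMatrix, TraitTable
from .neutral_null import _bm_tip_values, _m_factor
from .phylogeny import Phylogeny

logger = logging.getLogger("coevotest")

__all__ = [
    "gen_mutant_panel",
    "gen_tree",
    "balanced_tree",
    "gen_divergence_data",
    "gen_modular_cov",
]

#: panel/tree sizes of the study designs this module emulates
YEAST_DEFAULTS = {"n_lines": 4817, "n_traits": 220, "n_tips": 16}
FLY_DEFAULTS = {"n_lines": 150, "n_traits": 24, "n_tips": 110}


def _as_cov(target) -> CovarianceMatrix:
    if isinstance(target, CovarianceMatrix):
        return target
    return CovarianceMatrix(np.asarray(target, dtype=float))


def gen_mutant_panel(
    n_lines: int,
    target: CovarianceMatrix | np.ndarray,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    unit_prefix: str = "line",
) -> TraitTable:
    """Mutant panel drawn i.i.d. from a multivariate normal.

    The target covariance must be positive definite; estimated correlations
    converge to the targets as ``n_lines`` grows (s.e. ~ (1 - rho^2)/sqrt(n)).
    """
    cov = _as_cov(target)
    min_eig = float(np.linalg.eigvalsh(cov.entries)[0])
    if min_eig < 1e-10:
        raise ValueError(
            f"target covariance must be positive definite (min eigenvalue {min_eig:.3e})"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    factor, _ = _m_factor(cov)
    values = rng.standard_normal((n_lines, cov.n_traits)) @ factor.T
    index = [f"{unit_prefix}_{i + 1}" for i in range(n_lines)]
    return TraitTable(pd.DataFrame(values, index=index, columns=cov.trait_ids))


def gen_tree(
    n_tips: int,
    birth_rate: float = 1.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    tip_prefix: str = "t",
) -> Phylogeny:
    """Pure-birth (Yule) ultrametric tree with exponential waiting times."""
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if rng is None:
        rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    # active lineages: (node, birth time of its pendant edge)
    now = 0.0
    active = []
    for _ in range(2):
        child = root.new_child()
        active.append((child, now))
    while len(active) < n_tips:
        now += rng.exponential(1.0 / (birth_rate * len(active)))
        i = int(rng.integers(len(active)))
        node, born = active.pop(i)
        node.edge.length = now - born
        for _ in range(2):
            child = node.new_child()
            active.append((child, now))
    now += rng.exponential(1.0 / (birth_rate * len(active)))
    labels = iter(f"{tip_prefix}{i + 1}" for i in range(n_tips))
    for node, born in active:
        node.edge.length = now - born
        node.taxon = tns.new_taxon(next(labels))
    return Phylogeny(tree)


def balanced_tree(n_tips: int, edge_length: float = 1.0) -> Phylogeny:
    """Fully balanced ultrametric tree (n_tips must be a power of 2)."""
    if n_tips < 2 or n_tips & (n_tips - 1):
        raise ValueError("n_tips must be a power of 2 and >= 2")
    labels = iter(f"t{i + 1}" for i in range(n_tips))

    def clade(k: int) -> str:
        if k == 1:
            return f"{next(labels)}:{edge_length:g}"
        return f"({clade(k // 2)},{clade(k // 2)}):{edge_length:g}"

    newick = f"({clade(n_tips // 2)},{clade(n_tips // 2)});"
    return Phylogeny.from_newick(newick)


def gen_divergence_data(
    tree: Phylogeny,
    M: CovarianceMatrix | np.ndarray,
    injections: dict[tuple[str, str], float] | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    scaling: str = "standard",
) -> TraitTable:
    """Strain phenotypes: Brownian motion along ``tree`` with optional
    selection distortions.

    ``injections`` maps trait pairs to a target across-contrast correlation
    (strengthen, weaken or reverse relative to the mutational correlation,
    depending on the target chosen).  Injected pairs have their tip values
    replaced by ``pinv(U) @ E`` where E holds i.i.d. contrast rows at the
    target correlation, so the contrasts the estimator computes realize the
    target exactly up to sampling noise; non-injected traits keep their
    neutral Brownian values.  The default ``standard`` (sqrt(l)) scaling is
    canonical Brownian motion, under which contrasts are exactly i.i.d.
    """
    M = _as_cov(M)
    if rng is None:
        rng = np.random.default_rng(seed)
    values = _bm_tip_values(tree, M, rng, 1, scaling)[0]
    trait_ids = list(M.trait_ids)
    if injections:
        index = {t: i for i, t in enumerate(trait_ids)}
        seen: dict[str, tuple] = {}
        for pair in injections:
            for t in pair:
                if t not in index:
                    raise ValueError(f"injection references unknown trait {t!r}")
                if t in seen:
                    raise ValueError(
                        f"conflicting injections share trait {t!r}: "
                        f"{seen[t]} and {pair} (targets may be jointly unsatisfiable)"
                    )
                seen[t] = pair
        U, tips = tree.contrast_operator()
        U_pinv = np.linalg.pinv(U)
        scale = np.sqrt(np.diag(M.entries))
        for (ti, tj), target in injections.items():
            if not -1 < target < 1:
                raise ValueError(f"injection target must lie in (-1, 1), got {target}")
            chol = np.array(
                [[1.0, 0.0], [target, np.sqrt(1.0 - target**2)]]
            )
            e = rng.standard_normal((tree.n_contrasts, 2)) @ chol.T
            e *= scale[[index[ti], index[tj]]][None, :]
            pair_tips = U_pinv @ e
            values[:, index[ti]] = pair_tips[:, 0]
            values[:, index[tj]] = pair_tips[:, 1]
    return TraitTable(pd.DataFrame(values, index=tree.tip_labels, columns=trait_ids))


def gen_modular_cov(
    module_sizes,
    r_within: float,
    r_between: float,
    variances=None,
    module_labels=None,
) -> tuple[CovarianceMatrix, dict[str, str]]:
    """Exact block-modular covariance matrix plus its trait -> module map.

    Traits within a module correlate at ``r_within``, traits in different
    modules at ``r_between``; suitable for closed-form CR / V_eigen checks.
    """
    module_sizes = list(module_sizes)
    if len(module_sizes) < 2 or min(module_sizes) < 2:
        raise ValueError("need >= 2 modules with >= 2 traits each")
    if module_labels is None:
        module_labels = [f"module_{i + 1}" for i in range(len(module_sizes))]
    n = sum(module_sizes)
    corr = np.full((n, n), float(r_between))
    partition: dict[str, str] = {}
    trait_ids = []
    start = 0
    for size, label in zip(module_sizes, module_labels):
        corr[start : start + size, start : start + size] = r_within
        for j in range(size):
            tid = f"{label}_t{j + 1}"
            trait_ids.append(tid)
            partition[tid] = label
        start += size
    np.fill_diagonal(corr, 1.0)
    if variances is None:
        variances = np.ones(n)
    variances = np.asarray(variances, dtype=float)
    sd = np.sqrt(variances)
    cov = corr * np.outer(sd, sd)
    min_eig = float(np.linalg.eigvalsh(cov)[0])
    if min_eig < 1e-8:
        raise ValueError(
            f"block-modular matrix not positive definite (min eigenvalue {min_eig:.3e})"
        )
    return CovarianceMatrix(cov, trait_ids), partition
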