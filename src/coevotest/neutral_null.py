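"""Neutral Brownian-motion null for the selection scan.

Simulates neutral phenotypic evolution along a tree with the mutational
covariance matrix M as input: per branch one multivariate-normal deviate
with covariance M is drawn and scaled by the branch length, and a tip's
phenotype is the sum of the increments on its root path (root phenotype 0).
Repeating the simulation yields the null distribution of significant-pair
counts against which the observed scan is compared.

Two branch-length scalings are provided.  ``as_printed`` multiplies the
deviate by l (tip variance grows with the sum of squared branch lengths);
``standard`` multiplies by sqrt(l), the canonical Brownian motion with tip
variance proportional to total path length.  Every branch contributes
covariance proportional to M under either rule, so the pairwise trait
correlations that the selection test consumes are the same; only the
relative weighting of branches differs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CorrelationMatrix, CovarianceMatrix, TraitTable
from .phylogeny import Phylogeny
from .sel_test import CATEGORIES, _scan_arrays

logger = logging.getLogger("coevotest")

__all__ = ["BMDataset", "simulate_bm", "neutral_count_null", "NeutralNullResult"]

_SCALINGS = ("as_printed", "standard")


def _m_factor(M) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(M, CovarianceMatrix):
        m, ids = M.entries, M.trait_ids
    else:
        m, ids = np.asarray(M, dtype=float), None
    eigval, eigvec = np.linalg.eigh(m)
    if eigval.min() < -1e-8:
        raise ValueError(
            f"M is not positive semidefinite (min eigenvalue {eigval.min():.3e})"
        )
    return eigvec * np.sqrt(np.clip(eigval, 0.0, None)), ids


def _bm_tip_values(
    tree: Phylogeny,
    M,
    rng: np.random.Generator,
    n_datasets: int,
    scaling: str = "as_printed",
) -> np.ndarray:
    """(n_datasets, n_tips, n_traits) array of simulated tip phenotypes."""
    if scaling not in _SCALINGS:
        raise ValueError(f"scaling must be one of {_SCALINGS}")
    factor, _ = _m_factor(M)
    A, lengths, _tips = tree.branch_incidence()
    w = lengths if scaling == "as_printed" else np.sqrt(lengths)
    n_traits = factor.shape[0]
    z = rng.standard_normal((n_datasets, len(lengths), n_traits))
    increments = (z @ factor.T) * w[None, :, None]
    return np.einsum("tb,dbk->dtk", A, increments)


@dataclass
class BMDataset:
    """One neutrally simulated tip-phenotype dataset."""

    table: TraitTable
    tree: Phylogeny
    seed: int | None
    scaling: str


def simulate_bm(
    tree: Phylogeny,
    M,
    seed: int | None = None,
    scaling: str = "as_printed",
    rng: np.random.Generator | None = None,
) -> BMDataset:
    """Simulate one neutral dataset of tip phenotypes along ``tree``.

    ``M`` is the mutational covariance matrix (jointly sampled, so simulated
    traits inherit the full cross-pair dependence structure).  All traits
    start at 0 at the root.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    values = _bm_tip_values(tree, M, rng, 1, scaling)[0]
    _, ids = _m_factor(M)
    if ids is None:
        ids = [f"trait_{i + 1}" for i in range(values.shape[1])]
    table = TraitTable(pd.DataFrame(values, index=tree.tip_labels, columns=ids))
    return BMDataset(table=table, tree=tree, seed=seed, scaling=scaling)


@dataclass
class NeutralNullResult:
    """Null distribution of per-category significant-pair counts."""

    counts: pd.DataFrame  # one row per simulated dataset
    medians: pd.Series
    n_datasets: int

    def empirical_p(self, observed_total: int) -> float:
        """Fraction of neutral datasets whose total significant-pair count
        reaches the observed one."""
        return float((self.counts["total"] >= observed_total).mean())


def neutral_count_null(
    tree: Phylogeny,
    mcorr: CorrelationMatrix,
    M: CovarianceMatrix,
    n_m: int,
    n_datasets: int = 1000,
    fdr: float = 0.05,
    nominal_alpha: float = 0.05,
    n_e: int | None = None,
    scaling: str = "as_printed",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> NeutralNullResult:
    """Significant-pair counts expected under neutral Brownian motion.

    Per dataset: simulate tip phenotypes with mutational input ``M``,
    estimate COR_E via independent contrasts, scan against the fixed input
    ``mcorr``, and record counts per category.  The summary medians play the
    role of the scan's neutral expectation; ``empirical_p`` gives the
    fraction of datasets at or above an observed count.
    """
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    if sorted(mcorr.trait_ids) != sorted(M.trait_ids):
        raise ValueError("mcorr and M must cover the same traits")
    if rng is None:
        rng = np.random.default_rng(seed)
    M = M.reindex(mcorr.trait_ids)
    if n_e is None:
        n_e = tree.n_contrasts
    U, _tips = tree.contrast_operator()
    tips_values = _bm_tip_values(tree, M, rng, n_datasets, scaling)
    t = len(mcorr.trait_ids)
    iu, ju = np.triu_indices(t, k=1)
    rm = np.clip(mcorr.entries[iu, ju], -1 + 1e-12, 1 - 1e-12)
    rows = np.empty((n_datasets, len(CATEGORIES)), dtype=int)
    for d in range(n_datasets):
        c = U @ tips_values[d]
        s = c.T @ c
        sd = np.sqrt(np.diag(s))
        with np.errstate(invalid="ignore", divide="ignore"):
            rmat = s / np.outer(sd, sd)
        re_ = np.clip(rmat[iu, ju], -1 + 1e-12, 1 - 1e-12)
        cats = _scan_arrays(rm, re_, n_e, n_m, fdr, nominal_alpha)[-1]
        rows[d] = [(cats == cat).sum() for cat in CATEGORIES]
    counts = pd.DataFrame(rows, columns=list(CATEGORIES))
    counts["total"] = (
        counts["strengthened"]
        + counts["weakened"]
        + counts["reversed"]
        + counts["unclassified"]
    )
    medians = counts.median()
    return NeutralNullResult(counts=counts, medians=medians, n_datasets=n_datasets)
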