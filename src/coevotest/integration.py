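"""Phenotypic integration (V_eigen) and modularity (CR) statistics.

V_eigen, the population variance of the eigenvalues of a correlation
matrix, measures overall integration: 0 when traits are uncorrelated and
n - 1 when all pairwise correlations are +/-1, so V_eigen / (n - 1) is a
relative index in [0, 1].  The covariance-ratio statistic CR contrasts
between-module covariances with within-module (off-diagonal) covariances;
smaller CR means stronger modularity.  Both statistics are compared with
rank-matched subsampling nulls built from the mutant panel, so that sample
size (which bounds the number of positive eigenvalues) does not confound
the mutation-vs-evolution comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd

from .core import CorrelationMatrix, CovarianceMatrix, TraitTable

logger = logging.getLogger("coevotest")

__all__ = [
    "v_eigen",
    "VEigen",
    "cr_statistic",
    "check_partition",
    "rank_matched_null",
    "empirical_two_tailed_p",
    "EmpiricalP",
]

CR_VARIANTS = ("as_printed", "product_denominator")


@dataclass
class VEigen:
    value: float  # population variance of the eigenvalues
    relative: float  # value / (n_traits - 1), in [0, 1]


def v_eigen(corr: CorrelationMatrix | np.ndarray) -> VEigen:
    """Eigenvalue variance of a correlation matrix.

    Uses the population (divide-by-n) variance so that the relative index
    ``V_eigen / (n - 1)`` spans exactly [0, 1].
    """
    if not isinstance(corr, CorrelationMatrix):
        corr = CorrelationMatrix(np.asarray(corr, dtype=float))
    lam = np.linalg.eigvalsh(corr.entries)
    v = float(lam.var(ddof=0))
    return VEigen(value=v, relative=v / (corr.n_traits - 1))


def check_partition(partition: Mapping[str, str] | pd.Series) -> dict[str, list[str]]:
    """Validate a trait -> module assignment; returns module -> traits."""
    if isinstance(partition, pd.Series):
        partition = partition.to_dict()
    modules: dict[str, list[str]] = {}
    for trait, mod in partition.items():
        modules.setdefault(str(mod), []).append(str(trait))
    if len(modules) < 2:
        raise ValueError("need at least 2 modules")
    small = [m for m, ts in modules.items() if len(ts) < 2]
    if small:
        raise ValueError(f"module(s) with fewer than 2 traits: {small}")
    return modules


def _cr_pair(cov: np.ndarray, idx1: np.ndarray, idx2: np.ndarray, variant: str) -> float:
    m12 = cov[np.ix_(idx1, idx2)]
    num = float(np.sum(m12 * m12))  # trace(M12 M21) = ||M12||_F^2
    m11 = cov[np.ix_(idx1, idx1)].copy()
    m22 = cov[np.ix_(idx2, idx2)].copy()
    np.fill_diagonal(m11, 0.0)
    np.fill_diagonal(m22, 0.0)
    t11 = float(np.sum(m11 * m11))
    t22 = float(np.sum(m22 * m22))
    if variant == "as_printed":
        den = np.sqrt(t11 + t22)
    else:
        den = np.sqrt(t11 * t22)
    if den == 0:
        raise ValueError(
            "CR denominator is zero: a module has no within-module "
            f"off-diagonal covariance (variant={variant})"
        )
    return float(np.sqrt(num / den))


def cr_statistic(
    cov: CovarianceMatrix | np.ndarray,
    partition: Mapping[str, str] | pd.Series,
    variant: str = "as_printed",
) -> float:
    """Covariance-ratio modularity statistic, averaged over module pairs.

    Per module pair, ``CR = sqrt(trace(M12 M21) / denom)`` with M12/M21 the
    between-module covariance blocks and the denominator built from the
    within-module blocks with zeroed diagonals.  ``as_printed`` sums the two
    within-module traces inside the inner square root; ``product_denominator``
    multiplies them (the form used in the morphometrics CR literature, which
    is scale-invariant).  With more than two modules the unweighted mean over
    module pairs is returned.
    """
    if variant not in CR_VARIANTS:
        raise ValueError(f"variant must be one of {CR_VARIANTS}")
    modules = check_partition(partition)
    if isinstance(cov, CovarianceMatrix):
        ids, entries = cov.trait_ids, cov.entries
    else:
        entries = np.asarray(cov, dtype=float)
        ids = [f"trait_{i + 1}" for i in range(entries.shape[0])]
    index = {t: i for i, t in enumerate(ids)}
    missing = [t for ts in modules.values() for t in ts if t not in index]
    if missing:
        raise ValueError(f"partition traits missing from matrix: {missing}")
    values = []
    for m1, m2 in combinations(sorted(modules), 2):
        idx1 = np.array([index[t] for t in modules[m1]])
        idx2 = np.array([index[t] for t in modules[m2]])
        values.append(_cr_pair(entries, idx1, idx2, variant))
    return float(np.mean(values))


def rank_matched_null(
    mutant_table: TraitTable,
    k: int,
    n_subsets: int,
    statistic: str = "v_eigen",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    partition: Mapping[str, str] | pd.Series | None = None,
    variant: str = "as_printed",
) -> np.ndarray:
    """Subsampling null for V_eigen or CR, matched for sample size.

    Each of ``n_subsets`` statistics is computed from k mutant lines drawn
    uniformly without replacement, so the null carries the same
    finite-sample rank limitation as the evolutionary matrix it is compared
    with.  ``statistic="v_eigen"`` uses the subset correlation matrix;
    ``"cr"`` uses the subset covariance matrix and requires ``partition``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if statistic not in ("v_eigen", "cr"):
        raise ValueError("statistic must be 'v_eigen' or 'cr'")
    if statistic == "cr" and partition is None:
        raise ValueError("CR null requires a module partition")
    table = mutant_table.dropna_rows()
    x = table.values
    if k > x.shape[0]:
        raise ValueError(f"k={k} exceeds the {x.shape[0]} complete mutant lines")
    if rng is None:
        rng = np.random.default_rng(seed)
    n_traits = x.shape[1]
    out = np.empty(n_subsets)
    for i in range(n_subsets):
        rows = rng.choice(x.shape[0], size=k, replace=False)
        sub = x[rows]
        if statistic == "v_eigen":
            corr = np.corrcoef(sub, rowvar=False)
            lam = np.linalg.eigvalsh(corr)
            out[i] = lam.var(ddof=0)
        else:
            cov = np.cov(sub, rowvar=False, ddof=1)
            out[i] = cr_statistic(
                CovarianceMatrix(cov, table.trait_ids), partition, variant
            )
    return out


@dataclass
class EmpiricalP:
    """Two-tailed empirical P from the location of a statistic in a null."""

    p: float
    q: float  # fraction of null values strictly below the observed one
    n_null: int
    band: str | None = None  # reporting band when observed is beyond all nulls

    def __str__(self) -> str:
        return self.band if self.band is not None else f"{self.p:.4g}"


def empirical_two_tailed_p(observed: float, null) -> EmpiricalP:
    """Two-tailed empirical P-value: ``2 * min(q, 1 - q)`` where q is the
    fraction of null values strictly below the observed statistic.  When the
    observed value lies beyond every null value the P is reported as the
    resolution band ``< 2 / n_null``."""
    null = np.asarray(null, dtype=float)
    null = null[np.isfinite(null)]
    if null.size == 0:
        raise ValueError("empty null distribution")
    q = float((null < observed).mean())
    p = 2.0 * min(q, 1.0 - q)
    band = None
    if observed > null.max() or observed < null.min():
        band = f"< {2.0 / null.size:g}"
    return EmpiricalP(p=p, q=q, n_null=int(null.size), band=band)
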