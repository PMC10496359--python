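"""Per-pair comparison of mutational and evolutionary correlations.

For each trait pair, COR_M and COR_E are mapped to Fisher z-scores and
compared with

    Z = (Z_E - Z_M) / sqrt(1 / (n_E - 3) + 1 / (n_M - 3)),

where n_E is the number of independent contrasts and n_M the number of
mutant lines.  Two-sided normal P-values are adjusted by Benjamini-Hochberg
across all pairs; significant pairs are classified as strengthened,
weakened or reversed depending on the signs and magnitudes of the two
correlations and on per-correlation tests against zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import CorrelationMatrix

logger = logging.getLogger("coevotest")

__all__ = [
    "fisher_z",
    "compare_correlations",
    "bh_adjust",
    "correlation_nonzero_p",
    "classify_pair",
    "run_pairwise_scan",
    "PairTestResult",
    "PairScanResult",
    "disjoint_pairing_control",
    "overlap_expectation",
    "OverlapNull",
]

CATEGORIES = ("strengthened", "weakened", "reversed", "not_significant", "unclassified")


def fisher_z(r):
    """Fisher r-to-Z transformation, ``z = (1/2)[ln(1+r) - ln(1-r)]``."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("|r| >= 1: Fisher z is infinite")
    z = np.arctanh(r)
    return float(z) if z.ndim == 0 else z


def compare_correlations(cor_e, cor_m, n_e: int, n_m: int):
    """Z statistic and two-sided P for the difference of two correlations."""
    if n_e <= 3 or n_m <= 3:
        raise ValueError(f"sample sizes must exceed 3 (n_e={n_e}, n_m={n_m})")
    z_e = fisher_z(cor_e)
    z_m = fisher_z(cor_m)
    se = np.sqrt(1.0 / (n_e - 3) + 1.0 / (n_m - 3))
    z = (np.asarray(z_e) - np.asarray(z_m)) / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    if np.ndim(z) == 0:
        return float(z), float(p)
    return z, p


def bh_adjust(p_values):
    """Benjamini-Hochberg step-up adjusted P-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("P-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def correlation_nonzero_p(r, n: int):
    """Two-sided Fisher-z test of a single correlation against zero:
    ``z = arctanh(r) * sqrt(n - 3)`` referred to the standard normal."""
    if n <= 3:
        raise ValueError(f"sample size must exceed 3, got {n}")
    z = np.arctanh(np.asarray(r, dtype=float)) * np.sqrt(n - 3)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return float(p) if np.ndim(p) == 0 else p


@dataclass
class PairTestResult:
    """Selection-test outcome for one unordered trait pair."""

    trait_i: str
    trait_j: str
    cor_m: float
    cor_e: float
    z_m: float
    z_e: float
    z_stat: float
    p_raw: float
    p_adj: float
    cor_m_nonzero_p: float
    cor_e_nonzero_p: float
    category: str = "not_significant"


def _classify_arrays(
    cor_m: np.ndarray,
    cor_e: np.ndarray,
    p_adj: np.ndarray,
    p_m_nonzero: np.ndarray,
    p_e_nonzero: np.ndarray,
    fdr: float,
    nominal_alpha: float,
) -> np.ndarray:
    """Vectorized category assignment (returns an object array of labels)."""
    sig = p_adj < fdr
    same_sign = cor_e * cor_m > 0
    m_nz = p_m_nonzero < nominal_alpha
    e_nz = p_e_nonzero < nominal_alpha
    strengthened = (same_sign & (np.abs(cor_e) > np.abs(cor_m))) | (
        ~same_sign & e_nz & ~m_nz
    )
    weakened = (same_sign & (np.abs(cor_e) < np.abs(cor_m))) | (
        ~same_sign & m_nz & ~e_nz
    )
    reversed_ = ~same_sign & m_nz & e_nz
    return np.select(
        [~sig, strengthened, weakened, reversed_],
        ["not_significant", "strengthened", "weakened", "reversed"],
        default="unclassified",
    )


def classify_pair(
    result: PairTestResult, fdr: float = 0.05, nominal_alpha: float = 0.05
) -> str:
    """Selection category for a single tested pair.

    ``not_significant`` when the adjusted P fails the FDR cut; otherwise
    strengthened (same sign, |COR_E| > |COR_M|, or sign flip with only COR_E
    nonzero), weakened (mirror image), reversed (sign flip with both
    correlations nonzero at the nominal alpha), else ``unclassified``.
    """
    return str(
        _classify_arrays(
            np.array([result.cor_m]),
            np.array([result.cor_e]),
            np.array([result.p_adj]),
            np.array([result.cor_m_nonzero_p]),
            np.array([result.cor_e_nonzero_p]),
            fdr,
            nominal_alpha,
        )[0]
    )


@dataclass
class PairScanResult:
    """Full pairwise scan: one row per unordered trait pair plus counts."""

    results: pd.DataFrame
    counts: dict
    n_e: int
    n_m: int
    fdr: float
    nominal_alpha: float

    @property
    def n_pairs(self) -> int:
        return len(self.results)

    @property
    def n_significant(self) -> int:
        return self.n_pairs - self.counts["not_significant"]

    def significant_pairs(self, category: str | None = None) -> set[tuple[str, str]]:
        df = self.results
        if category is None:
            mask = df["category"] != "not_significant"
        else:
            mask = df["category"] == category
        return set(zip(df.loc[mask, "trait_i"], df.loc[mask, "trait_j"]))


def _scan_arrays(rm, re_, n_e, n_m, fdr, nominal_alpha):
    z_m = np.arctanh(rm)
    z_e = np.arctanh(re_)
    se = np.sqrt(1.0 / (n_e - 3) + 1.0 / (n_m - 3))
    z = (z_e - z_m) / se
    p_raw = 2.0 * stats.norm.sf(np.abs(z))
    p_adj = bh_adjust(p_raw)
    p_m_nz = 2.0 * stats.norm.sf(np.abs(z_m) * np.sqrt(n_m - 3))
    p_e_nz = 2.0 * stats.norm.sf(np.abs(z_e) * np.sqrt(n_e - 3))
    cats = _classify_arrays(rm, re_, p_adj, p_m_nz, p_e_nz, fdr, nominal_alpha)
    return z_m, z_e, z, p_raw, p_adj, p_m_nz, p_e_nz, cats


def run_pairwise_scan(
    mcorr: CorrelationMatrix,
    ecorr: CorrelationMatrix,
    n_e: int,
    n_m: int,
    fdr: float = 0.05,
    nominal_alpha: float = 0.05,
) -> PairScanResult:
    """Test every unordered trait pair for a COR_E vs COR_M difference.

    BH adjustment is applied across all pairs; counts per category summarize
    the scan.
    """
    if n_e <= 3 or n_m <= 3:
        raise ValueError(f"sample sizes must exceed 3 (n_e={n_e}, n_m={n_m})")
    if set(mcorr.trait_ids) != set(ecorr.trait_ids):
        diff = sorted(set(mcorr.trait_ids) ^ set(ecorr.trait_ids))
        raise ValueError(f"trait sets differ between matrices: {diff}")
    traits = mcorr.trait_ids
    ecorr = ecorr.reindex(traits)
    iu, ju = np.triu_indices(len(traits), k=1)
    rm = mcorr.entries[iu, ju]
    re_ = ecorr.entries[iu, ju]
    for name, arr in (("COR_M", rm), ("COR_E", re_)):
        if np.any(np.abs(arr) >= 1):
            k = int(np.argmax(np.abs(arr) >= 1))
            raise ValueError(
                f"|{name}| >= 1 for pair ({traits[iu[k]]}, {traits[ju[k]]}); "
                "Fisher z undefined"
            )
        if np.any(~np.isfinite(arr)):
            raise ValueError(f"{name} contains undefined (NaN) correlations")
    z_m, z_e, z, p_raw, p_adj, p_m_nz, p_e_nz, cats = _scan_arrays(
        rm, re_, n_e, n_m, fdr, nominal_alpha
    )
    results = pd.DataFrame(
        {
            "trait_i": [traits[i] for i in iu],
            "trait_j": [traits[j] for j in ju],
            "cor_m": rm,
            "cor_e": re_,
            "z_m": z_m,
            "z_e": z_e,
            "z_stat": z,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "cor_m_nonzero_p": p_m_nz,
            "cor_e_nonzero_p": p_e_nz,
            "category": cats,
        }
    )
    counts = {c: int((cats == c).sum()) for c in CATEGORIES}
    return PairScanResult(
        results=results,
        counts=counts,
        n_e=n_e,
        n_m=n_m,
        fdr=fdr,
        nominal_alpha=nominal_alpha,
    )


def disjoint_pairing_control(
    trait_ids,
    significant_pairs: set[tuple[str, str]],
    n_repeats: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Fractions of significant pairs over random non-overlapping pairings.

    Per repeat a uniform perfect matching of the traits is drawn (an odd
    trait is dropped at random, logged) and the fraction of matched pairs
    that are in ``significant_pairs`` is recorded.  Controls for the reuse
    of each trait in many pairs of the full scan.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    traits = list(trait_ids)
    if rng is None:
        rng = np.random.default_rng(seed)
    sig = {frozenset(p) for p in significant_pairs}
    if len(traits) % 2:
        logger.info("odd trait count (%d): dropping one trait per repeat", len(traits))
    fractions = np.empty(n_repeats)
    arr = np.array(traits, dtype=object)
    for rep in range(n_repeats):
        perm = rng.permutation(arr)
        if len(perm) % 2:
            perm = perm[:-1]
        hits = sum(
            1 for a, b in zip(perm[0::2], perm[1::2]) if frozenset((a, b)) in sig
        )
        fractions[rep] = hits / (len(perm) // 2)
    return fractions


@dataclass
class OverlapNull:
    """Null distribution for the overlap of two significant-pair sets."""

    observed: int
    null_counts: np.ndarray
    p_value: float  # fraction of draws with overlap >= observed
    null_median: float


def overlap_expectation(
    set_a,
    set_b,
    universe,
    n_draws: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> OverlapNull:
    """Is the overlap of two significant-pair sets larger than random?

    Per draw, ``|set_b|`` pairs are drawn uniformly without replacement from
    the universe of tested pairs and the overlap with ``set_a`` counted; the
    empirical P is the fraction of draws with overlap >= the observed one.
    """
    universe = [frozenset(p) for p in universe]
    uset = set(universe)
    a = {frozenset(p) for p in set_a}
    b = {frozenset(p) for p in set_b}
    if not a <= uset or not b <= uset:
        raise ValueError("significant-pair sets must be subsets of the universe")
    if len(b) > len(universe):
        raise ValueError("|set_b| exceeds the universe size")
    if rng is None:
        rng = np.random.default_rng(seed)
    in_a = np.array([p in a for p in universe])
    observed = len(a & b)
    k = len(b)
    null_counts = np.empty(n_draws, dtype=int)
    for d in range(n_draws):
        idx = rng.choice(len(universe), size=k, replace=False)
        null_counts[d] = int(in_a[idx].sum())
    p = float((null_counts >= observed).mean())
    return OverlapNull(
        observed=observed,
        null_counts=null_counts,
        p_value=p,
        null_median=float(np.median(null_counts)),
    )
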