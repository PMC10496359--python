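"""Standardization and mutational covariance estimation for mutant panels.

The mutational correlation COR_M between two traits is the Pearson
correlation of their standardized values across a panel of mutant lines
(gene-deletion or mutation-accumulation lines).  Trait values are
standardized as the natural log of the ratio to a reference phenotype
(wild type or MA progenitor), which makes them approximately normal and
dimensionless.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CorrelationMatrix, CovarianceMatrix, TraitTable

logger = logging.getLogger("coevotest")

__all__ = [
    "standardize_traits",
    "mutational_correlation",
    "estimate_bias_coefficient",
    "matrix_sampling_error_check",
    "pc_envelope_check",
    "PCEnvelopeResult",
]


def standardize_traits(raw: pd.DataFrame | TraitTable, reference) -> TraitTable:
    """Log-ratio standardization of raw trait measurements.

    Each cell becomes ``ln(raw / reference)`` for its trait.  ``reference``
    is either a per-trait :class:`pandas.Series` of positive values or the
    ID of a row of ``raw`` (e.g. the MA progenitor line); a named row is
    used as the reference and removed from the output.
    """
    if isinstance(raw, TraitTable):
        raw = raw.data
    raw = raw.astype(float)

    if isinstance(reference, str):
        if reference not in raw.index:
            raise ValueError(f"reference row {reference!r} not found in table")
        ref = raw.loc[reference]
        raw = raw.drop(index=reference)
        logger.info("using row %r as reference; removed from output", reference)
    else:
        ref = pd.Series(reference).astype(float)

    if set(ref.index) != set(raw.columns):
        missing = sorted(set(raw.columns) - set(ref.index))
        extra = sorted(set(ref.index) - set(raw.columns))
        raise ValueError(
            f"reference traits do not match table traits "
            f"(missing: {missing}, extra: {extra})"
        )
    ref = ref.reindex(raw.columns)

    bad = np.argwhere(~(raw.to_numpy() > 0))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"non-positive raw value at unit {raw.index[i]!r}, "
            f"trait {raw.columns[j]!r}: {raw.iloc[i, j]}"
        )
    bad_ref = ref[~(ref > 0)]
    if len(bad_ref):
        raise ValueError(
            f"non-positive reference value for trait {bad_ref.index[0]!r}: "
            f"{bad_ref.iloc[0]}"
        )
    return TraitTable(np.log(raw / ref))


def mutational_correlation(
    table: TraitTable | pd.DataFrame,
) -> tuple[CorrelationMatrix, CovarianceMatrix]:
    """Pearson correlation (and sample covariance) matrix across mutant lines.

    Rows with any missing trait value are dropped (logged) so every pairwise
    statistic shares one sample size n_M.  Requires at least 4 complete lines
    and nonzero variance for every trait.
    """
    if isinstance(table, pd.DataFrame):
        table = TraitTable(table)
    table = table.dropna_rows()
    if table.n_units < 4:
        raise ValueError(f"need at least 4 complete units, got {table.n_units}")
    x = table.values
    var = x.var(axis=0, ddof=1)
    zero = np.flatnonzero(var == 0)
    if zero.size:
        names = [table.trait_ids[i] for i in zero]
        raise ValueError(f"zero-variance trait(s): {names}")
    cov = np.cov(x, rowvar=False, ddof=1)
    sd = np.sqrt(np.diag(cov))
    corr = cov / np.outer(sd, sd)
    np.fill_diagonal(corr, 1.0)
    return (
        CorrelationMatrix(corr, table.trait_ids),
        CovarianceMatrix(cov, table.trait_ids),
    )


def estimate_bias_coefficient(values) -> float:
    """Mutational-bias coefficient B of one trait across mutant lines.

    With p̄ the mean of the strictly positive standardized values and n̄ the
    mean of the strictly negative ones, ``B = sqrt(max(|p̄|, |n̄|) /
    min(|p̄|, |n̄|)) >= 1``: the square root of the ratio of mean magnitudes,
    larger magnitude in the numerator.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    pos = values[values > 0]
    neg = values[values < 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError(
            "bias coefficient undefined: need at least one positive and one "
            "negative value"
        )
    p, n = abs(pos.mean()), abs(neg.mean())
    return float(np.sqrt(max(p, n) / min(p, n)))


def matrix_sampling_error_check(
    M: CovarianceMatrix | np.ndarray,
    n_samples: int,
    n_reps: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Sampling-error diagnostic for an estimated covariance matrix.

    Per repetition, draws ``n_samples`` phenotype vectors from the
    multivariate normal with covariance ``M``, re-estimates the covariance
    matrix, and returns the Pearson correlation between the (descending)
    eigenvalue lists of the true and re-estimated matrices.  Values near 1
    across repetitions indicate that sampling error barely perturbs the
    matrix spectrum at this sample size.
    """
    m = M.entries if isinstance(M, CovarianceMatrix) else np.asarray(M, dtype=float)
    if rng is None:
        rng = np.random.default_rng(seed)
    eig_true, vecs = np.linalg.eigh(m)
    if eig_true.min() < -1e-8:
        raise ValueError("M must be positive semidefinite")
    if np.ptp(eig_true) < 1e-12:
        warnings.warn(
            "all eigenvalues of M are equal; eigenvalue correlation undefined",
            RuntimeWarning,
        )
        return np.full(n_reps, np.nan)
    factor = vecs * np.sqrt(np.clip(eig_true, 0.0, None))
    eig_true_sorted = np.sort(eig_true)[::-1]
    out = np.empty(n_reps)
    for r in range(n_reps):
        z = rng.standard_normal((n_samples, m.shape[0]))
        sample = z @ factor.T
        est = np.cov(sample, rowvar=False, ddof=1)
        eig_est = np.sort(np.linalg.eigvalsh(est))[::-1]
        if np.ptp(eig_est) < 1e-15:
            out[r] = np.nan
        else:
            out[r] = np.corrcoef(eig_true_sorted, eig_est)[0, 1]
    return out


@dataclass
class PCEnvelopeResult:
    """Per-PC verdicts on whether a query phenotype sits inside the central
    95% of the replicate projections, plus the variance fraction those PCs
    explain."""

    table: pd.DataFrame  # columns: projection, lower, upper, inside
    variance_explained: float

    @property
    def all_inside(self) -> bool:
        return bool(self.table["inside"].all())


def pc_envelope_check(
    replicates: TraitTable | pd.DataFrame,
    query: pd.Series,
    n_pcs: int,
) -> PCEnvelopeResult:
    """Project a query phenotype onto the PCs of a replicate cloud.

    Principal components are computed from the replicate rows (centered on
    the replicate mean).  For each of the first ``n_pcs`` components the
    query projection is compared with the [2.5%, 97.5%] empirical quantile
    interval of the replicate projections.  Used to check whether e.g. an
    environment-shifted phenotype still falls within the distribution of
    biological replicates.
    """
    if isinstance(replicates, pd.DataFrame):
        replicates = TraitTable(replicates)
    if set(query.index) != set(replicates.trait_ids):
        raise ValueError("query trait set does not match replicate traits")
    x = replicates.values
    if replicates.n_units <= n_pcs:
        raise ValueError(
            f"need more replicate rows ({replicates.n_units}) than PCs ({n_pcs})"
        )
    center = x.mean(axis=0)
    xc = x - center
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    if n_pcs > rank:
        raise ValueError(f"n_pcs={n_pcs} exceeds matrix rank {rank}")
    proj_reps = u[:, :n_pcs] * s[:n_pcs]  # replicate scores
    q = query.reindex(replicates.trait_ids).to_numpy(dtype=float) - center
    proj_query = q @ vt[:n_pcs].T
    lower = np.quantile(proj_reps, 0.025, axis=0)
    upper = np.quantile(proj_reps, 0.975, axis=0)
    inside = (proj_query >= lower) & (proj_query <= upper)
    var_explained = float((s[:n_pcs] ** 2).sum() / (s**2).sum())
    table = pd.DataFrame(
        {
            "projection": proj_query,
            "lower": lower,
            "upper": upper,
            "inside": inside,
        },
        index=pd.Index([f"PC{i + 1}" for i in range(n_pcs)], name="component"),
    )
    return PCEnvelopeResult(table=table, variance_explained=var_explained)
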