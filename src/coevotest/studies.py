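"""End-to-end reproduction studies built from the pipeline's own pieces.

Each driver wires the synthetic generators, the contrast machinery and the
selection test into one study and returns plain numbers, so the same code
backs both the test suite and ``scripts/acceptance.py``:

* :func:`table2_grid` — the full simulation grid of selection regimes
  (no optimum, four ridges, a point optimum, random optima) crossed with
  mutational correlations 0.9 / 0.5 / 0.1;
* :func:`type_one_calibration` — raw-P calibration of the COR_E vs COR_M
  test on fully neutral synthetic pairs;
* :func:`reversal_power_study` — recovery of injected sign-reversed pairs,
  with :func:`fisher_power_prediction` as the closed-form/normal-theory
  benchmark;
* :func:`bm_null_single_pair_study` — type-I behaviour of the scan on a
  single pair under the Brownian-motion null.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .neutral_null import neutral_count_null
from .phenotypes import mutational_correlation
from .phylogeny import evolutionary_covariance, independent_contrasts
from .sel_test import _scan_arrays, run_pairwise_scan
from .selection_sim import SelectionRegime, SimConfig, build_m_matrix, simulate_regime
from .synthetic import balanced_tree, gen_divergence_data, gen_mutant_panel, gen_tree

logger = logging.getLogger("coevotest")

__all__ = [
    "table2_grid",
    "TABLE2_REGIMES",
    "type_one_calibration",
    "fisher_power_prediction",
    "reversal_power_study",
    "bm_null_single_pair_study",
]

#: the simulation grid: regime x COR_M in {0.9, 0.5, 0.1}
TABLE2_REGIMES = (
    ("no_optimum", SelectionRegime.none()),
    ("ridge_y=x", SelectionRegime.ridge(1.0)),
    ("ridge_y=0.5x", SelectionRegime.ridge(0.5)),
    ("ridge_y=-0.5x", SelectionRegime.ridge(-0.5)),
    ("ridge_y=-x", SelectionRegime.ridge(-1.0)),
    ("point_(0,0)", SelectionRegime.point(0.0, 0.0)),
    ("random_optima", SelectionRegime.random_optima()),
)
TABLE2_COR_M = (0.9, 0.5, 0.1)


def table2_grid(
    seed: int = 0,
    n_reps: int = 200,
    n_lineages: int = 50,
    time_units: int = 1000,
    v_m: float = 0.01,
    ne: float = 1e4,
    regimes=TABLE2_REGIMES,
    cor_m_values=TABLE2_COR_M,
) -> pd.DataFrame:
    """Run the full two-trait coevolution grid and summarize each cell.

    Returns one row per (regime, COR_M) with the median end-of-simulation
    COR_E, the fraction of repetitions with COR_E > COR_M, and the verdict
    from the 2.5%-tail rule.
    """
    rows = []
    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(len(regimes) * len(cor_m_values)))
    for label, regime in regimes:
        for cor_m in cor_m_values:
            rng = np.random.default_rng(next(children))
            config = SimConfig(
                cor_m=cor_m,
                v_m=v_m,
                ne=ne,
                n_lineages=n_lineages,
                n_reps=n_reps,
                time_units=time_units,
            )
            res = simulate_regime(config, regime, rng=rng)
            rows.append(
                {
                    "regime": label,
                    "cor_m": cor_m,
                    "median_cor_e": res.median_cor_e,
                    "frac_cor_e_above_cor_m": res.frac_above,
                    "significant": res.significant,
                    "verdict": res.verdict,
                }
            )
            logger.info(
                "%s COR_M=%.1f: median COR_E=%.3f frac_above=%.3f %s",
                label, cor_m, res.median_cor_e, res.frac_above, res.verdict,
            )
    return pd.DataFrame(rows)


def type_one_calibration(
    seed: int = 0,
    n_pairs: int = 2000,
    n_tips: int = 16,
    n_m: int = 4817,
    v_m: float = 0.01,
    rho_range: tuple[float, float] = (-0.8, 0.8),
    alpha: float = 0.05,
) -> dict:
    """Raw-P calibration of the selection test under full neutrality.

    Per synthetic pair: a generating correlation rho is drawn uniformly from
    ``rho_range``; a mutant panel of ``n_m`` lines gives COR_M; neutral
    Brownian tips on a fresh Yule tree give COR_E via contrasts; the pair is
    tested at n_E = n_tips - 1.  Returns the fraction of raw P < alpha,
    which should sit near alpha when the test is calibrated.
    """
    rng = np.random.default_rng(seed)
    tree = gen_tree(n_tips, rng=rng)
    n_e = tree.n_contrasts
    p_raw = np.empty(n_pairs)
    for k in range(n_pairs):
        rho = rng.uniform(*rho_range)
        M = build_m_matrix(v_m, rho)
        panel = gen_mutant_panel(n_m, M, rng=rng)
        mcorr, _ = mutational_correlation(panel)
        tips = gen_divergence_data(tree, M, rng=rng)
        _, ecorr = evolutionary_covariance(independent_contrasts(tree, tips))
        p_raw[k] = _scan_arrays(
            np.array([mcorr.entries[0, 1]]),
            np.array([ecorr.entries[0, 1]]),
            n_e,
            n_m,
            alpha,
            alpha,
        )[3][0]
    return {
        "fraction_raw_p_below_alpha": float((p_raw < alpha).mean()),
        "n_pairs": n_pairs,
        "alpha": alpha,
    }


def fisher_power_prediction(
    rho_e: float,
    rho_m: float,
    n_e: int,
    n_m: int,
    alpha: float = 0.05,
    nominal_alpha: float = 0.05,
    n_draws: int = 200_000,
    seed: int = 0,
) -> dict:
    """Normal-theory benchmark for detection and classification rates.

    Under the Fisher approximation ``z_E ~ N(arctanh(rho_e), 1/(n_E - 3))``
    and ``z_M ~ N(arctanh(rho_m), 1/(n_M - 3))`` independently.  The
    detection power has the closed form
    ``Phi(-z_crit + |lambda|) + Phi(-z_crit - |lambda|)`` with
    ``lambda = (arctanh(rho_e) - arctanh(rho_m)) / SE``; the probability of
    the full "reversed" label (detected, opposite signs, both correlations
    nonzero at the nominal alpha) is evaluated by Monte Carlo on the same
    approximation, independently of the simulation pipeline it benchmarks.
    """
    se = np.sqrt(1.0 / (n_e - 3) + 1.0 / (n_m - 3))
    lam = (np.arctanh(rho_e) - np.arctanh(rho_m)) / se
    z_crit = stats.norm.isf(alpha / 2.0)
    power = float(stats.norm.sf(z_crit - abs(lam)) + stats.norm.cdf(-z_crit - abs(lam)))

    rng = np.random.default_rng(seed)
    z_e = rng.normal(np.arctanh(rho_e), 1.0 / np.sqrt(n_e - 3), n_draws)
    z_m = rng.normal(np.arctanh(rho_m), 1.0 / np.sqrt(n_m - 3), n_draws)
    detected = np.abs(z_e - z_m) / se > z_crit
    z_nom = stats.norm.isf(nominal_alpha / 2.0)
    e_nz = np.abs(z_e) * np.sqrt(n_e - 3) > z_nom
    m_nz = np.abs(z_m) * np.sqrt(n_m - 3) > z_nom
    opposite = np.tanh(z_e) * np.tanh(z_m) < 0
    reversed_rate = float((detected & opposite & e_nz & m_nz).mean())
    return {"power_detect": power, "power_reversed_label": reversed_rate}


def reversal_power_study(
    seed: int = 0,
    n_reps: int = 200,
    rho_m: float = 0.8,
    rho_e_target: float = -0.8,
    n_tips: int = 16,
    n_m: int = 5000,
    v_m: float = 0.01,
    fdr: float = 0.05,
) -> dict:
    """Recovery rate of an injected sign-reversed trait pair.

    Per replicate, a mutant panel at COR_M = ``rho_m`` and divergence data
    with the pair's across-contrast correlation injected at
    ``rho_e_target`` are generated, the single pair is scanned, and the
    fraction of replicates labeled "reversed" is returned alongside the
    detection fraction.
    """
    rng = np.random.default_rng(seed)
    tree = gen_tree(n_tips, rng=rng)
    M = build_m_matrix(v_m, rho_m)
    ti, tj = M.trait_ids
    detected = 0
    labeled_reversed = 0
    for _ in range(n_reps):
        panel = gen_mutant_panel(n_m, M, rng=rng)
        mcorr, _ = mutational_correlation(panel)
        tips = gen_divergence_data(tree, M, injections={(ti, tj): rho_e_target}, rng=rng)
        _, ecorr = evolutionary_covariance(independent_contrasts(tree, tips))
        scan = run_pairwise_scan(mcorr, ecorr, tree.n_contrasts, n_m, fdr=fdr)
        cat = scan.results["category"].iloc[0]
        detected += cat != "not_significant"
        labeled_reversed += cat == "reversed"
    return {
        "detected_rate": detected / n_reps,
        "reversed_rate": labeled_reversed / n_reps,
        "n_reps": n_reps,
    }


def bm_null_single_pair_study(
    seed: int = 0,
    n_datasets: int = 1000,
    rho: float = 0.5,
    n_tips: int = 16,
    n_m: int = 4817,
    v_m: float = 0.01,
    alpha: float = 0.05,
) -> dict:
    """Fraction of neutral datasets where a single pair tests significant.

    A balanced ``n_tips`` tree keeps contrasts independent under either
    branch-length scaling, so the raw-P rate at threshold ``alpha`` gauges
    the calibration of the Brownian-motion count null in its simplest
    (one-pair) configuration.
    """
    tree = balanced_tree(n_tips)
    M = build_m_matrix(v_m, rho)
    from .core import CorrelationMatrix

    mcorr = CorrelationMatrix(
        np.array([[1.0, rho], [rho, 1.0]]), M.trait_ids
    )
    null = neutral_count_null(
        tree,
        mcorr,
        M,
        n_m=n_m,
        n_datasets=n_datasets,
        fdr=alpha,
        seed=seed,
    )
    frac = float((null.counts["total"] > 0).mean())
    return {"fraction_significant": frac, "n_datasets": n_datasets}
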