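"""Seeded simulation studies validating the statistical machinery.

Each function runs one self-contained study — mixture-tail accuracy,
permutation-oracle agreement, type-I error calibration, single-marker
concordance, interaction-effect recovery, power ordering — and returns a
plain dict of measured quantities plus the tolerances used.  The CLI
``validate`` subcommand and the test suite both drive these functions, so
the numbers a user sees are exactly the numbers the tests check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import MarkerMatrix, SampleTable
from .interaction_model import (fit_interaction_model,
                                fit_single_marker_regression)
from .kernel_score_test import (NullDistribution, fit_null_model,
                                kst_region_test, permutation_pvalue,
                                pvalue_mixture_chisq)
from .synthetic_data import (SimulationConfig, calibrate_effect_sizes,
                             null_config, simulate_genotypes,
                             simulate_methylation, simulate_phenotype)

ALPHA = 0.05


def expected_rejection_band(n_reps: int, alpha: float = ALPHA,
                            level: float = 0.99) -> tuple[float, float]:
    """Exact binomial acceptance band around alpha for a calibrated test."""
    tail = (1.0 - level) / 2.0
    lo = stats.binom.ppf(tail, n_reps, alpha) / n_reps
    hi = stats.binom.ppf(1.0 - tail, n_reps, alpha) / n_reps
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# mixture-of-chi-squares tail accuracy
# ---------------------------------------------------------------------------

def mixture_tail_study(seed: int, n_spectra: int = 25,
                       n_draws: int = 10 ** 6, k_max: int = 10) -> dict:
    """Inversion p-values vs analytic chi-square tails and Monte Carlo.

    Checks the two analytic anchors (chi-square with 1 and 2 degrees of
    freedom at their 0.05 upper quantiles) and, on ``n_spectra`` random
    spectra with up to ``k_max`` weights, agreement with the empirical
    tail of ``n_draws`` simulated mixture draws within 3 MC standard
    errors.
    """
    rng = np.random.default_rng(seed)
    p1, _ = pvalue_mixture_chisq(
        float(stats.chi2.ppf(0.95, 1)),
        NullDistribution(np.array([1.0]), 0.0))
    p2, _ = pvalue_mixture_chisq(
        float(stats.chi2.ppf(0.95, 2)),
        NullDistribution(np.array([1.0, 1.0]), 0.0))
    rows = []
    for _ in range(n_spectra):
        k = int(rng.integers(1, k_max + 1))
        lam = np.sort(rng.uniform(0.2, 3.0, size=k))[::-1]
        draws = (lam[None, :] * rng.chisquare(1, size=(n_draws, k))).sum(
            axis=1)
        mean, sd = lam.sum(), np.sqrt(2.0 * (lam ** 2).sum())
        q = float(mean + rng.uniform(0.5, 2.5) * sd)
        p_mc = float(np.mean(draws > q))
        se = float(np.sqrt(max(p_mc * (1 - p_mc), 1e-12) / n_draws))
        p_an, method = pvalue_mixture_chisq(
            q, NullDistribution(lam, 0.0))
        rows.append({"k": k, "q": q, "p_analytic": p_an, "p_mc": p_mc,
                     "mc_se": se, "method": method,
                     "within_3se": abs(p_an - p_mc) <= 3 * se})
    return {
        "chi2_df1_tail": p1,
        "chi2_df2_tail": p2,
        "chi2_tail_abs_error": max(abs(p1 - 0.05), abs(p2 - 0.05)),
        "spectra": rows,
        "n_within_3se": sum(r["within_3se"] for r in rows),
        "n_spectra": n_spectra,
        "all_within_3se": all(r["within_3se"] for r in rows),
    }


# ---------------------------------------------------------------------------
# permutation-oracle agreement
# ---------------------------------------------------------------------------

def _null_tables(rng: np.random.Generator, n: int, m: int,
                 config: SimulationConfig) -> tuple[SampleTable, MarkerMatrix]:
    """A covariates-plus-noise response and an unassociated CpG block."""
    age = rng.normal(config.age_mean, config.age_sd, size=n).clip(20, 85)
    pre = rng.normal(config.pre_lntg_mean, config.pre_lntg_sd, size=n)
    y = (config.intercept + config.coef_pre_lntg * pre
         + config.coef_age * age
         + rng.normal(0.0, config.residual_sd, size=n))
    ids = tuple(f"S{i + 1:04d}" for i in range(n))
    table = SampleTable(sample_ids=ids, response=y,
                        covariates=pd.DataFrame({"pre_lntg": pre,
                                                 "age": age}))
    mu, c = config.methylation_mean, config.methylation_concentration
    Z = MarkerMatrix(sample_ids=ids,
                     marker_ids=tuple(f"cg{j + 1}" for j in range(m)),
                     values=rng.beta(mu * c, (1 - mu) * c, size=(n, m)),
                     marker_kind="methylation")
    return table, Z


def permutation_agreement_study(seed: int, n_datasets: int = 20,
                                n: int = 50, m_values=(1, 3, 8),
                                n_perm: int = 10 ** 4) -> dict:
    """Analytic mixture p vs seeded residual-permutation p on null data."""
    rng = np.random.default_rng(seed)
    config = null_config()
    rows = []
    for i in range(n_datasets):
        m = m_values[i % len(m_values)]
        table, Z = _null_tables(rng, n, m, config)
        res = kst_region_test(table, Z, region_name=f"null{i}")
        p_perm = permutation_pvalue(table, Z, n_perm=n_perm,
                                    seed=int(rng.integers(2 ** 31)))
        se = float(np.sqrt(max(p_perm * (1 - p_perm), 1e-12) / n_perm))
        rows.append({"m": m, "p_davies": res.p_value, "p_perm": p_perm,
                     "perm_se": se,
                     "within_3se": abs(res.p_value - p_perm) <= 3 * se})
    return {
        "datasets": rows,
        "n_within_3se": sum(r["within_3se"] for r in rows),
        "n_datasets": n_datasets,
        "all_within_3se": all(r["within_3se"] for r in rows),
        "max_abs_diff": max(abs(r["p_davies"] - r["p_perm"]) for r in rows),
    }


# ---------------------------------------------------------------------------
# type-I error and null-p uniformity
# ---------------------------------------------------------------------------

def type1_error_study(seed: int, n_reps: int = 5000,
                      n: int | None = None) -> dict:
    """Rejection rate and p-value uniformity of the KST at zero effect.

    Each replicate draws a fresh zero-effect dataset from the generator
    (default sample size) and tests the first region's 3-kbp CpG window.
    """
    config = null_config() if n is None else null_config(n=n)
    rng = np.random.default_rng(seed)
    anchor = config.anchor_cpg_id(0)
    # 3-kbp window members around the anchor of region 1
    members = [config.cpg_id(0, j) for j, off in enumerate(config.cpg_offsets)
               if abs(off) <= 3000]
    pvals = np.empty(n_reps)
    for i in range(n_reps):
        genotypes = simulate_genotypes(config, rng)
        _, post = simulate_methylation(config, rng)
        table = simulate_phenotype(config, genotypes, post, rng)
        Z = post.restrict_markers(members)
        pvals[i] = kst_region_test(table, Z, region_name="ROI-1").p_value
    rate = float(np.mean(pvals < ALPHA))
    lo, hi = expected_rejection_band(n_reps)
    ks = stats.kstest(pvals, "uniform")
    return {
        "n_reps": n_reps,
        "n": config.n,
        "anchor": anchor,
        "rejection_rate": rate,
        "band_99": (lo, hi),
        "rate_in_band": lo <= rate <= hi,
        "ks_statistic": float(ks.statistic),
        "ks_pvalue": float(ks.pvalue),
        "uniform_at_1pct": ks.pvalue > 0.01,
    }


# ---------------------------------------------------------------------------
# single-marker concordance (kernel test vs regression)
# ---------------------------------------------------------------------------

def single_marker_concordance_study(seed: int, n_datasets: int = 200,
                                    n: int = 150) -> dict:
    """Spearman correlation of m = 1 KST p-values with regression p-values.

    A one-marker kernel window is the set-test analogue of single-marker
    regression; their p-values should be nearly rank-identical.
    """
    rng = np.random.default_rng(seed)
    config = null_config(n=n)
    p_kst = np.empty(n_datasets)
    p_reg = np.empty(n_datasets)
    for i in range(n_datasets):
        table, Z = _null_tables(rng, n, 1, config)
        p_kst[i] = kst_region_test(table, Z).p_value
        p_reg[i] = fit_single_marker_regression(table, Z).p("marker")
    rho = stats.spearmanr(p_kst, p_reg).statistic
    return {
        "n_datasets": n_datasets,
        "n": n,
        "spearman_rho": float(rho),
        "max_abs_diff": float(np.max(np.abs(p_kst - p_reg))),
    }


# ---------------------------------------------------------------------------
# interaction model: recovery and power
# ---------------------------------------------------------------------------

def interaction_recovery_study(seed: int, n: int = 500) -> dict:
    """Recover (beta, -beta) for the SNP and product terms at large n.

    Data follow the attenuation mechanism Y = beta*g*(1 - m) + covariates
    + noise, which in the interaction parameterization is beta1 = beta,
    beta2 = 0, beta12 = -beta.
    """
    config = SimulationConfig(n=n)
    rng = np.random.default_rng(seed)
    genotypes = simulate_genotypes(config, rng)
    _, post = simulate_methylation(config, rng)
    table = simulate_phenotype(config, genotypes, post, rng)
    beta = float(calibrate_effect_sizes(config)[0])
    snp = genotypes.restrict_markers([config.snp_id(0)])
    cpg = post.restrict_markers([config.anchor_cpg_id(0)])
    fit = fit_interaction_model(table, snp, cpg)
    t_snp = fit.terms["snp"]
    t_int = fit.terms["snp_x_cpg"]
    return {
        "n": n,
        "true_beta": beta,
        "snp_estimate": t_snp.estimate, "snp_se": t_snp.stderr,
        "interaction_estimate": t_int.estimate,
        "interaction_se": t_int.stderr,
        "snp_z_from_truth": (t_snp.estimate - beta) / t_snp.stderr,
        "interaction_z_from_truth":
            (t_int.estimate + beta) / t_int.stderr,
        "recovered_within_3se":
            abs(t_snp.estimate - beta) <= 3 * t_snp.stderr
            and abs(t_int.estimate + beta) <= 3 * t_int.stderr,
    }


def power_study(seed: int, n_reps: int = 1000,
                config: SimulationConfig | None = None) -> dict:
    """Empirical power of the SNP test, with and without the CpG terms.

    Per replicate one full dataset is drawn and every causal region is
    analyzed two ways: the interaction model (SNP + nearest CpG + product)
    and the SNP-only regression.  Paired replicates keep the power curves
    comparable across regions.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    n_causal = config.n_causal
    rej_int = np.zeros(n_causal)
    rej_snp = np.zeros(n_causal)
    for _ in range(n_reps):
        genotypes = simulate_genotypes(config, rng)
        _, post = simulate_methylation(config, rng)
        table = simulate_phenotype(config, genotypes, post, rng)
        for r in range(n_causal):
            snp = genotypes.restrict_markers([config.snp_id(r)])
            cpg = post.restrict_markers([config.anchor_cpg_id(r)])
            fit_i = fit_interaction_model(table, snp, cpg)
            fit_s = fit_single_marker_regression(table, snp)
            rej_int[r] += fit_i.p("snp") < ALPHA
            rej_snp[r] += fit_s.p("marker") < ALPHA
    power_int = rej_int / n_reps
    power_snp = rej_snp / n_reps
    return {
        "n_reps": n_reps,
        "n": config.n,
        "heritabilities": list(config.heritabilities),
        "power_interaction_snp_term": power_int.tolist(),
        "power_snp_only": power_snp.tolist(),
        "interaction_beats_snp_only_top":
            power_int[0] > power_snp[0],
        "power_nonincreasing":
            bool(np.all(np.diff(power_int) <= 0)),
    }
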