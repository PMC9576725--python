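"""Seeded simulation studies that characterize the pipeline.

Each function regenerates its synthetic inputs from a base seed, runs the
relevant pipeline stage end to end, and returns summary rates. They back
both the acceptance checks and the numbered analysis drivers, so the study
conditions (sample sizes, planted effects, seed counts) live here in one
place.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from .normalize import COMMON, NONE, aggregate_effects, call_hits, normalize_screen
from .simulate import CohortSimConfig, ScreenSimConfig, generate_cohort, generate_screen
from .survival import NONE_CALL, NS, UNFAVORABLE, logrank_test, mutation_stratified_scan, scan_48

_MOD = 2**31 - 1


def derive_seed(base_seed: int, index: int) -> int:
    """Deterministic per-repetition seed below 2^31."""
    return int((base_seed * 1_000_003 + 7919 * index + 1) % _MOD)


def null_screen_type1(base_seed: int = 1, n_seeds: int = 20, n_genes: int = 390):
    """Type-I calibration: fraction of null genes with p_count < 0.01.

    Full-scale null screens (no planted effects, 3 batches); the single-arm
    count p-values should be uniform, so the fraction below 0.01 should
    match 0.01 up to Monte-Carlo error.
    """
    fractions = []
    for i in range(n_seeds):
        cfg = ScreenSimConfig(n_genes=n_genes, seed=derive_seed(base_seed, i))
        norm = normalize_screen(generate_screen(cfg))
        effects = aggregate_effects(norm)
        p = np.array([e.p_count for e in effects if e.arm == "SINGLE"])
        fractions.append(float(np.mean(p < 0.01)))
    fractions = np.asarray(fractions)
    return {
        "fraction_mean": float(fractions.mean()),
        "fraction_se": float(fractions.std(ddof=1) / np.sqrt(n_seeds)),
        "per_seed": fractions,
        "nominal": 0.01,
    }


def hit_recovery(
    base_seed: int = 1,
    n_seeds: int = 25,
    n_planted: int = 40,
    n_null: int = 350,
    effect: float = -1.5,
):
    """Power/specificity of hit calling with planted two-arm inhibitors.

    ``n_planted`` genes carry the given log2 count effect in both arms at
    the default 10% count CV; the rest are nulls. Sensitivity is the rate of
    planted genes called COMMON; the null call rate counts null genes given
    any hit category.
    """
    sens, null_rate = [], []
    planted = {f"G{i + 1:03d}": (effect, effect) for i in range(n_planted)}
    for i in range(n_seeds):
        cfg = ScreenSimConfig(
            n_genes=n_planted + n_null,
            planted_effects=planted,
            seed=derive_seed(base_seed, 10_000 + i),
        )
        norm = normalize_screen(generate_screen(cfg))
        calls = call_hits(aggregate_effects(norm))
        by_gene = {c.gene: c.category for c in calls}
        sens.append(
            np.mean([by_gene[g] == COMMON for g in planted])
        )
        nulls = [g for g in by_gene if g not in planted]
        null_rate.append(np.mean([by_gene[g] != NONE for g in nulls]))
    return {
        "sensitivity": float(np.mean(sens)),
        "null_call_rate": float(np.mean(null_rate)),
        "per_seed_sensitivity": np.asarray(sens, dtype=float),
        "per_seed_null_rate": np.asarray(null_rate, dtype=float),
    }


def resistance_correlation(base_seed: int = 1):
    """Spearman correlation between normalized count and viability-per-cell
    over treated (combined-arm) gene wells of one study screen with
    the resistance mechanism on. Negative when survivors of stronger
    knockdowns look metabolically healthier."""
    from .metrics import viability_per_cell
    from .simulate import study_screen_config

    cfg = study_screen_config(seed=derive_seed(base_seed, 20_000))
    norm = normalize_screen(generate_screen(cfg))
    treated = norm[
        (norm["co_treatment"] == "CISPLATIN")
        & ~norm["perturbation"].isin(["NC", "PLK1"])
    ]
    vpc = viability_per_cell(treated["viability"].to_numpy(), treated["count"].to_numpy())
    rho, _ = sps.spearmanr(treated["norm_count"].to_numpy(), vpc)
    return float(rho)


def logrank_null_calibration(base_seed: int = 1, n_seeds: int = 200, n: int = 60):
    """Null calibration of the asymptotic log-rank p-value.

    Two equal groups with identical exponential survival and independent
    censoring; returns the p-values and a KS test against Uniform(0,1).
    """
    pvals = []
    for i in range(n_seeds):
        rng = np.random.default_rng(derive_seed(base_seed, 30_000 + i))
        times = rng.exponential(1000.0, size=n)
        censor = rng.exponential(2000.0, size=n)
        t = np.minimum(times, censor)
        e = times <= censor
        g = np.zeros(n, dtype=bool)
        g[rng.choice(n, size=n // 2, replace=False)] = True
        _, p = logrank_test(g, t, e)
        pvals.append(p)
    pvals = np.asarray(pvals)
    ks_stat, ks_p = sps.kstest(pvals, "uniform")
    return {"p_values": pvals, "ks_stat": float(ks_stat), "ks_p": float(ks_p)}


def prognosis_recovery(
    base_seed: int = 1, n_seeds: int = 50, hr: float = 2.5, n: int = 300
):
    """Recovery of a planted unfavorable expression-hazard effect by the
    48-cell scan: rate of UNFAVORABLE calls with a non-NS tier."""
    hits = []
    for i in range(n_seeds):
        cfg = CohortSimConfig(
            n_samples=n, hr_high_expression=hr, seed=derive_seed(base_seed, 40_000 + i)
        )
        _, call = scan_48(generate_cohort(cfg), cfg.target_gene)
        hits.append(call.call == UNFAVORABLE and call.tier != NS)
    return {"recovery_rate": float(np.mean(hits)), "n_seeds": n_seeds}


def scan_null_inflation(base_seed: int = 1, n_seeds: int = 50, n: int = 300):
    """Best-of-48 multiplicity inflation under a null cohort (HR = 1):
    empirical rate of best_p < 0.05 and of a non-NONE call."""
    best_p_sig, none_calls = [], []
    for i in range(n_seeds):
        cfg = CohortSimConfig(n_samples=n, seed=derive_seed(base_seed, 50_000 + i))
        _, call = scan_48(generate_cohort(cfg), cfg.target_gene)
        best_p_sig.append(call.best_p < 0.05)
        none_calls.append(call.call == NONE_CALL)
    return {
        "rate_best_p_below_0.05": float(np.mean(best_p_sig)),
        "rate_none_call": float(np.mean(none_calls)),
        "n_seeds": n_seeds,
    }


def interaction_discrimination(
    base_seed: int = 1,
    n_seeds: int = 50,
    hr_interaction: float = 3.0,
    carrier_fraction: float = 0.25,
    n: int = 400,
):
    """Mutation-stratified vs unstratified scan on cohorts where expression
    is hazardous only in mutation carriers.

    Returns the rates of (a) stratified UNFAVORABLE, (b) unstratified NONE,
    and (c) both at once, over seeds.
    """
    strat_hits, unstrat_none, joint = [], [], []
    for i in range(n_seeds):
        cfg = CohortSimConfig(
            n_samples=n,
            hr_high_expression=1.0,
            hr_interaction=hr_interaction,
            carrier_fraction=carrier_fraction,
            seed=derive_seed(base_seed, 60_000 + i),
        )
        cohort = generate_cohort(cfg)
        _, strat = mutation_stratified_scan(cohort, cfg.target_gene, cfg.interaction_geneset)
        _, unstrat = scan_48(cohort, cfg.target_gene)
        a = strat.call == UNFAVORABLE
        b = unstrat.call == NONE_CALL
        strat_hits.append(a)
        unstrat_none.append(b)
        joint.append(a and b)
    return {
        "stratified_unfavorable_rate": float(np.mean(strat_hits)),
        "unstratified_none_rate": float(np.mean(unstrat_none)),
        "joint_rate": float(np.mean(joint)),
        "n_seeds": n_seeds,
    }
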