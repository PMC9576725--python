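"""Seeded generators for synthetic screens and survival cohorts.

The screen generator emulates a triplicate 384-well siRNA screen: siNC and
siPLK1 control columns on every plate, planted per-gene log2 count effects
in a vehicle (single-treatment) and a cisplatin (combined) arm, lognormal
multiplicative noise on both readouts, per-batch shifts, and a resistance
term that inflates per-cell viability as the planted effect depletes the
count (surviving cells look metabolically healthier). The positive control
siPLK1 depletes counts without the resistance inflation, matching its
screen behavior. Counts are lognormal around 400 seeded cells grown ~4
doublings (baseline 1600) and rounded to integers, which keeps the
noiseless generator an exact oracle for the log2 analysis pipeline.

The cohort generator draws exponential survival with a hazard multiplied by
``hr_high_expression`` for latently high-expressing patients and
additionally by ``hr_interaction`` for high expressers carrying a mutation
from the interaction geneset, with independent exponential censoring.
Disease-free survival events never postdate overall survival.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .io import (
    ARMS,
    EMPTY_WELL,
    GENDERS,
    NEGATIVE_CONTROL,
    POSITIVE_CONTROL,
    ROWS,
    STAGES,
    SurvivalSample,
    WellRecord,
)

GENE_COLS = 22  # columns 1-22 hold library genes; 23 = siNC, 24 = siPLK1
NC_COL, PLK1_COL = 23, 24
GENES_PER_PLATE = len(ROWS) * GENE_COLS  # 352


def _log2_sigma(cv: float) -> float:
    """Log2-scale sigma of a lognormal with the given coefficient of variation."""
    if cv < 0:
        raise ValidationError("noise CV must be >= 0")
    return float(np.sqrt(np.log1p(cv**2)) / np.log(2))


@dataclass
class ScreenSimConfig:
    n_genes: int = 390
    n_batches: int = 3
    n_nc: int = 16
    n_plk1: int = 16
    control_effect_plk1: float = -3.0  # log2 count effect of siPLK1
    planted_effects: dict[str, tuple[float, float]] = field(default_factory=dict)
    count_noise_cv: float = 0.10
    viability_noise_cv: float = 0.20
    batch_shift_sd: float = 0.10  # per-batch log2 multiplicative shift
    resistance_gain: float = 0.30  # per-cell viability log2 rise per log2 kill
    cisplatin_effect: float = -1.0  # global log2 count shift in the combined arm
    baseline_count: int = 1600  # ~400 seeded cells over 4 days
    percell_viability: float = 2.0  # fluorescence a.u. per cell, noiseless
    genes: list[str] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_nc < 2 or self.n_plk1 < 2:
            raise ValidationError("need >= 2 siNC and >= 2 siPLK1 wells per plate")
        if self.n_nc > len(ROWS) or self.n_plk1 > len(ROWS):
            raise ValidationError("at most 16 control wells per control column")
        if self.genes is None:
            self.genes = [f"G{i + 1:03d}" for i in range(self.n_genes)]
        if len(self.genes) != self.n_genes:
            raise ValidationError("genes list length must equal n_genes")
        unknown = set(self.planted_effects) - set(self.genes)
        if unknown:
            raise ValidationError(f"planted effects for unknown genes: {sorted(unknown)}")


def tiny_screen_config(**overrides) -> ScreenSimConfig:
    """12-gene preset that runs in well under a second."""
    defaults = dict(n_genes=12, planted_effects={"G001": (-2.0, -2.0)})
    defaults.update(overrides)
    return ScreenSimConfig(**defaults)


def study_screen_config(**overrides) -> ScreenSimConfig:
    """390-gene, 3-batch, two-arm preset with a hit structure resembling the
    screen being emulated: 37 genes inhibitory in both arms and 9 genes whose
    inhibition appears only with cisplatin."""
    common = {f"G{i + 1:03d}": (-1.5, -1.7) for i in range(37)}
    sensitized = {f"G{i + 1:03d}": (-0.2, -1.6) for i in range(37, 46)}
    defaults = dict(n_genes=390, planted_effects={**common, **sensitized})
    defaults.update(overrides)
    return ScreenSimConfig(**defaults)


def generate_screen(config: ScreenSimConfig) -> list[WellRecord]:
    """Simulate all wells of a screen (both arms, all batches).

    count = round(baseline * 2^(effect + batch shift + arm shift + noise));
    viability = count * per-cell base * 2^(resistance + noise). Deterministic
    for a fixed config seed.
    """
    rng = np.random.default_rng(config.seed)
    sig_c = _log2_sigma(config.count_noise_cv)
    sig_v = _log2_sigma(config.viability_noise_cv)
    n_plates = int(np.ceil(config.n_genes / GENES_PER_PLATE))
    batch_shifts = rng.normal(0.0, config.batch_shift_sd, size=config.n_batches)

    # fixed plate layout shared by every batch and arm
    layout: list[list[tuple[str, int, str]]] = []  # per plate: (row, col, perturbation)
    gi = 0
    for _ in range(n_plates):
        plate_layout = []
        for col in range(1, GENE_COLS + 1):
            for row in ROWS:
                pert = config.genes[gi] if gi < config.n_genes else EMPTY_WELL
                plate_layout.append((row, col, pert))
                if gi < config.n_genes:
                    gi += 1
        for i, row in enumerate(ROWS):
            plate_layout.append(
                (row, NC_COL, NEGATIVE_CONTROL if i < config.n_nc else EMPTY_WELL)
            )
            plate_layout.append(
                (row, PLK1_COL, POSITIVE_CONTROL if i < config.n_plk1 else EMPTY_WELL)
            )
        layout.append(plate_layout)

    wells: list[WellRecord] = []
    for batch in range(1, config.n_batches + 1):
        for arm in ARMS:
            arm_shift = config.cisplatin_effect if arm == "CISPLATIN" else 0.0
            arm_tag = "S" if arm == "VEHICLE" else "C"
            for p, plate_layout in enumerate(layout, start=1):
                plate_id = f"B{batch}{arm_tag}P{p}"
                for row, col, pert in plate_layout:
                    if pert == EMPTY_WELL:
                        wells.append(
                            WellRecord(plate_id, batch, row, col, EMPTY_WELL, arm, None, None)
                        )
                        continue
                    if pert == POSITIVE_CONTROL:
                        effect, resist = config.control_effect_plk1, 0.0
                    elif pert == NEGATIVE_CONTROL:
                        effect, resist = 0.0, 0.0
                    else:
                        single, combined = config.planted_effects.get(pert, (0.0, 0.0))
                        effect = combined if arm == "CISPLATIN" else single
                        resist = config.resistance_gain * max(0.0, -effect)
                    log2_count = (
                        effect
                        + batch_shifts[batch - 1]
                        + arm_shift
                        + (rng.normal(0.0, sig_c) if sig_c > 0 else 0.0)
                    )
                    count = int(round(config.baseline_count * 2.0**log2_count))
                    log2_v = resist + (rng.normal(0.0, sig_v) if sig_v > 0 else 0.0)
                    viability = count * config.percell_viability * 2.0**log2_v
                    wells.append(
                        WellRecord(
                            plate_id, batch, row, col, pert, arm,
                            float(viability), max(count, 0),
                        )
                    )
    return wells


def generate_self_renewal(
    effect_cisplatin: float = -30.0,
    effect_sirna: float = -20.0,
    interaction: float = 0.0,
    cv: float = 0.08,
    n_replicates: int = 3,
    densities: tuple[int, ...] = (40, 80, 120, 200, 400, 800, 1200, 2000),
    seed: int = 0,
):
    """Simulate a four-condition self-renewal (regrowth) assay.

    Effects are percent-of-control changes: the combined condition's
    expectation is the sum of the single-treatment changes plus
    ``interaction`` (negative = synergy beyond additivity). Final counts are
    lognormal around 4x the seeding density. Returns a long-format DataFrame
    with condition, seeding_density, replicate, final_count.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    pct = {
        "siNC-DMF": 100.0,
        "siNC-cisplatin": 100.0 + effect_cisplatin,
        "siGPCR-DMF": 100.0 + effect_sirna,
        "siGPCR-cisplatin": 100.0 + effect_cisplatin + effect_sirna + interaction,
    }
    rows = []
    for density in densities:
        base = density * 4.0
        for cond, level in pct.items():
            for rep in range(1, n_replicates + 1):
                noise = rng.normal(0.0, _log2_sigma(cv)) if cv > 0 else 0.0
                count = base * (level / 100.0) * 2.0**noise
                rows.append(
                    {
                        "condition": cond,
                        "seeding_density": density,
                        "replicate": rep,
                        "final_count": max(int(round(count)), 0),
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class CohortSimConfig:
    n_samples: int = 300
    # exponential death hazard with median OS ~ 49 months, and censoring with
    # median follow-up ~ 2.5 years: ~37% of patients have an observed death,
    # the shape of a lung-adenocarcinoma registry cohort
    baseline_hazard: float = 0.000465  # events per day (ln2 / ~1490 d)
    hr_high_expression: float = 1.0
    interaction_geneset: tuple[str, ...] = ("MUTA", "MUTB", "MUTC")
    hr_interaction: float = 1.0
    carrier_fraction: float = 0.25
    censoring_rate: float = 0.00077  # per day (ln2 / ~900 d follow-up)
    gender_probs: tuple[float, float] = (0.5, 0.5)  # FEMALE, MALE
    stage_probs: tuple[float, float, float, float] = (0.54, 0.24, 0.16, 0.06)
    target_gene: str = "TARGET"
    n_noise_genes: int = 4
    expr_mu_low: float = 2.0  # log2(TPM+1) location of the low component
    expr_delta: float = 2.0  # high-component location shift
    expr_sd: float = 1.0
    background_mut_genes: tuple[str, ...] = ("BG1", "BG2", "BG3", "BG4", "BG5")
    background_mut_rate: float = 0.12
    dfs_hazard_ratio: float = 0.7  # recurrence hazard relative to death hazard
    seed: int = 0

    def __post_init__(self):
        if self.baseline_hazard <= 0 or self.censoring_rate <= 0:
            raise ValidationError("hazard and censoring rates must be > 0")
        if not np.isclose(sum(self.gender_probs), 1.0) or not np.isclose(
            sum(self.stage_probs), 1.0
        ):
            raise ValidationError("category probabilities must sum to 1")
        if not 0.0 <= self.carrier_fraction <= 1.0:
            raise ValidationError("carrier_fraction must be in [0, 1]")


def generate_cohort(config: CohortSimConfig) -> list[SurvivalSample]:
    """Simulate a survival cohort with a planted expression-hazard effect,
    optionally conditional on mutation-carrier status."""
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    high = rng.random(n) < 0.5
    carrier = rng.random(n) < config.carrier_fraction
    hazard = (
        config.baseline_hazard
        * config.hr_high_expression ** high.astype(float)
        * config.hr_interaction ** (high & carrier).astype(float)
    )
    death = rng.exponential(1.0 / hazard)
    censor = rng.exponential(1.0 / config.censoring_rate, size=n)
    recurrence = rng.exponential(1.0 / (config.dfs_hazard_ratio * hazard))
    os_time = np.maximum(np.minimum(death, censor), 1e-3)
    os_event = death <= censor
    dfs_event_time = np.minimum(recurrence, death)
    dfs_time = np.maximum(np.minimum(dfs_event_time, censor), 1e-3)
    dfs_event = dfs_event_time <= censor
    gender = rng.choice(GENDERS, size=n, p=config.gender_probs)
    stage = rng.choice(STAGES, size=n, p=config.stage_probs)
    expr_target = rng.normal(
        config.expr_mu_low + config.expr_delta * high.astype(float), config.expr_sd
    )
    noise_genes = [f"N{i + 1:02d}" for i in range(config.n_noise_genes)]
    noise_expr = rng.normal(config.expr_mu_low, config.expr_sd, size=(n, len(noise_genes)))

    samples: list[SurvivalSample] = []
    for i in range(n):
        mutations: set[str] = set()
        if carrier[i] and config.interaction_geneset:
            k = 1 + rng.binomial(len(config.interaction_geneset) - 1, 0.2)
            mutations |= set(
                rng.choice(config.interaction_geneset, size=k, replace=False)
            )
        for g in config.background_mut_genes:
            if rng.random() < config.background_mut_rate:
                mutations.add(g)
        expression = {config.target_gene: float(expr_target[i])}
        expression.update(
            {g: float(noise_expr[i, j]) for j, g in enumerate(noise_genes)}
        )
        samples.append(
            SurvivalSample(
                sample_id=f"S{i + 1:04d}",
                os_time=float(os_time[i]),
                os_event=bool(os_event[i]),
                dfs_time=float(dfs_time[i]),
                dfs_event=bool(dfs_event[i]),
                gender=str(gender[i]),
                stage=str(stage[i]),
                expression=expression,
                mutations=mutations,
            )
        )
    return samples
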