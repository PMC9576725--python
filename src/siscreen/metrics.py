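"""Derived screen statistics: viability per cell, % growth inhibition,
additive expectation for combinations, synergy flagging and the
serial-treatment contrast.

Viability per cell (well viability fluorescence / well cell count) proxies
the per-cell metabolic state of surviving cells: anti-proliferative
treatments that leave resistant survivors push this ratio up as the count
falls. The combination analysis uses a strictly additive null — the
expected combined change is the sum of the two single-treatment changes —
rather than a formal Bliss/Loewe model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import UndefinedStatisticError, ValidationError

SEEDING_DENSITIES = (40, 80, 120, 200, 400, 800, 1200, 2000)
SELF_RENEWAL_CONDITIONS = (
    "siNC-DMF",
    "siNC-cisplatin",
    "siGPCR-DMF",
    "siGPCR-cisplatin",
)
CONTROL_CONDITION = "siNC-DMF"


@dataclass(frozen=True)
class GrowthAssayRecord:
    """Cell counts for the growth-inhibition formula: time zero, treated
    and untreated wells at 96 h."""

    count_0h: float
    count_treat_96h: float
    count_ctrl_96h: float


def viability_per_cell(raw_viability, raw_count):
    """Well viability divided by well cell count (a.u. per cell).

    Vectorized; missing values propagate. A zero count anywhere is
    signalled (the ratio is undefined, not infinite).
    """
    v = np.asarray(raw_viability, dtype=float)
    c = np.asarray(raw_count, dtype=float)
    if np.any(c == 0):
        raise UndefinedStatisticError("viability per cell undefined at zero cell count")
    out = v / c
    return float(out) if out.ndim == 0 else out


def percent_growth_inhibition(rec: GrowthAssayRecord) -> float:
    """(treated growth / control growth) x 100 over a 96 h window.

    100 means the treatment did not slow growth at all, 0 means no net
    growth under treatment; values below 0 indicate net kill below the
    seeding count.
    """
    denom = rec.count_ctrl_96h - rec.count_0h
    if denom == 0:
        raise UndefinedStatisticError(
            "growth inhibition undefined: control did not change from time zero"
        )
    return (rec.count_treat_96h - rec.count_0h) / denom * 100.0


def additive_expectation(delta_cisplatin_alone: float, delta_sirna_alone: float) -> float:
    """Additive null for a combination: the sum of the two single-treatment
    changes. Both deltas must be on the same scale (percent-of-control or
    count change); mixing scales is undetectable and the caller's contract.
    """
    return delta_cisplatin_alone + delta_sirna_alone


def synergy_flag(
    observed_combined_change: float, additive_expected: float, tolerance: float = 0.0
) -> bool:
    """True iff the observed combined decrease exceeds the additive
    expectation by strictly more than ``tolerance`` (changes are signed;
    more negative = larger decrease)."""
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    return bool(observed_combined_change < additive_expected - tolerance)


def self_renewal_percent_of_control(df: pd.DataFrame) -> pd.DataFrame:
    """Express final counts as % of the siNC-DMF condition per seeding density.

    Input columns: condition, seeding_density, final_count and optionally
    replicate. The control condition maps to 100 by construction (its
    replicate mean is the denominator).
    """
    for col in ("condition", "seeding_density", "final_count"):
        if col not in df.columns:
            raise ValidationError(f"self-renewal table missing column {col!r}")
    bad = set(df["condition"]) - set(SELF_RENEWAL_CONDITIONS)
    if bad:
        raise ValidationError(f"unknown self-renewal condition(s): {sorted(bad)}")
    bad_density = set(df["seeding_density"]) - set(SEEDING_DENSITIES)
    if bad_density:
        raise ValidationError(
            f"seeding density not in {SEEDING_DENSITIES}: {sorted(bad_density)}"
        )
    out = df.copy()
    ctrl = (
        df[df["condition"] == CONTROL_CONDITION]
        .groupby("seeding_density")["final_count"]
        .mean()
    )
    missing = set(df["seeding_density"]) - set(ctrl.index)
    if missing:
        raise ValidationError(
            f"no {CONTROL_CONDITION} wells at seeding density {sorted(missing)}"
        )
    out["percent_of_control"] = (
        df["final_count"] / df["seeding_density"].map(ctrl).astype(float) * 100.0
    )
    return out


def assess_synergy(df: pd.DataFrame, tolerance: float | None = None) -> dict:
    """Additive-null synergy assessment of a four-condition self-renewal table.

    Changes are on the percent-of-control scale (condition mean - 100),
    averaged over seeding densities with per-density values retained.
    ``tolerance`` defaults to the replicate standard error of the combined
    condition's percent-of-control values.
    """
    pct = self_renewal_percent_of_control(df)
    per_density = (
        pct.groupby(["condition", "seeding_density"])["percent_of_control"]
        .mean()
        .unstack("condition")
    )
    for cond in SELF_RENEWAL_CONDITIONS:
        if cond not in per_density.columns or per_density[cond].isna().any():
            raise ValidationError(f"condition {cond!r} missing at some density")
    means = per_density.mean(axis=0)
    delta_cis = means["siNC-cisplatin"] - 100.0
    delta_sirna = means["siGPCR-DMF"] - 100.0
    observed = means["siGPCR-cisplatin"] - 100.0
    expected = additive_expectation(delta_cis, delta_sirna)
    if tolerance is None:
        combo = pct.loc[
            pct["condition"] == "siGPCR-cisplatin", "percent_of_control"
        ].to_numpy()
        tolerance = float(combo.std(ddof=1) / np.sqrt(len(combo))) if len(combo) > 1 else 0.0
    return {
        "delta_cisplatin_alone": float(delta_cis),
        "delta_sirna_alone": float(delta_sirna),
        "observed_combined_change": float(observed),
        "additive_expected": float(expected),
        "tolerance": float(tolerance),
        "synergy": synergy_flag(observed, expected, tolerance),
        "per_density": per_density,
    }


def serial_treatment_contrast(
    fresh_cell_effects, pretreated_cell_effects
) -> tuple[float, float]:
    """Fresh vs cisplatin-pretreated anti-proliferation contrast for one gene.

    Inputs are replicate percent-of-siNC values in each context. Returns
    (difference of means, pretreated - fresh; two-sided Student's t p).
    The p-value is missing with fewer than two replicates in a context.
    """
    fresh = np.asarray(fresh_cell_effects, dtype=float)
    pre = np.asarray(pretreated_cell_effects, dtype=float)
    diff = float(pre.mean() - fresh.mean())
    if len(fresh) < 2 or len(pre) < 2:
        return diff, float("nan")
    t, p = sps.ttest_ind(pre, fresh, equal_var=True)
    return diff, float(p)
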