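"""Per-plate log2 normalization against siNC and replicate-level hit calling.

Each raw readout is converted to log2(raw / center(siNC raws)) within its
plate and co-treatment arm, so negative values mean fewer cells (or less
viability signal) than the negative controls. Per-gene effects are the mean
of the per-batch normalized values over the three screening repeats, with a
two-sided two-sample Student's t-test against the same-arm siNC wells.

Hits are inhibitory only (log2 fold change <= -1, i.e. > twofold growth
inhibition) at raw p < 0.01 with no multiple-testing correction — this
mirrors the screening design being reproduced and is deliberate; see the
methods note for the implied false-positive behavior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError
from .io import (
    EMPTY_WELL,
    GeneEffect,
    NEGATIVE_CONTROL,
    POSITIVE_CONTROL,
    WellRecord,
    wells_to_frame,
)

ARM_LABELS = {"VEHICLE": "SINGLE", "CISPLATIN": "COMBINED"}

COMMON = "COMMON"
CISPLATIN_SENSITIZED = "CISPLATIN_SENSITIZED"
SINGLE_ONLY = "SINGLE_ONLY"
COMBINED_ONLY = "COMBINED_ONLY"
NONE = "NONE"

_READOUT_COLS = {"COUNT": "count", "VIABILITY": "viability"}


@dataclass
class HitCall:
    gene: str
    category: str
    single: GeneEffect
    combined: GeneEffect
    sensitization_p: float  # combined-vs-single contrast p (NaN if < 2 reps)
    sensitized: bool


def _nc_center(values: np.ndarray, method: str) -> float:
    if method == "median":
        return float(np.median(values))
    if method == "mean":
        return float(np.mean(values))
    raise ValueError(f"unknown siNC center {method!r}")


def normalize_plate(
    plate_df: pd.DataFrame, readout: str, nc_center: str = "median"
) -> pd.Series:
    """log2(raw / siNC center) for every well of one plate+arm.

    Returns a Series aligned to ``plate_df.index``. Missing raw values
    propagate as missing; an all-missing readout yields an all-missing
    column without raising. Zero or negative raw values and plates with
    fewer than two siNC measurements are errors.
    """
    col = _READOUT_COLS[readout]
    raw = plate_df[col].astype(float)
    if raw.isna().all():
        return pd.Series(np.nan, index=plate_df.index)
    if (raw.dropna() <= 0).any():
        bad = plate_df.loc[raw <= 0]
        raise ValidationError(
            f"plate {bad['plate'].iloc[0]}: non-positive {col} value; "
            "log2 normalization undefined"
        )
    nc = raw[plate_df["perturbation"] == NEGATIVE_CONTROL].dropna()
    if len(nc) < 2:
        plate = plate_df["plate"].iloc[0] if len(plate_df) else "?"
        raise ValidationError(
            f"plate {plate}: needs >= 2 siNC wells with {col} values for normalization"
        )
    center = _nc_center(nc.to_numpy(), nc_center)
    return np.log2(raw / center)


def normalize_screen(
    wells: list[WellRecord] | pd.DataFrame, nc_center: str = "median"
) -> pd.DataFrame:
    """Normalize both readouts per (plate, batch, arm) across a whole screen.

    Returns the long-format well table with ``norm_count`` and
    ``norm_viability`` columns; EMPTY wells are excluded.
    """
    df = wells_to_frame(wells) if not isinstance(wells, pd.DataFrame) else wells.copy()
    df = df[df["perturbation"] != EMPTY_WELL].reset_index(drop=True)
    for readout, col in _READOUT_COLS.items():
        norm = pd.Series(np.nan, index=df.index)
        for _, idx in df.groupby(["plate", "batch", "co_treatment"]).groups.items():
            sub = df.loc[idx]
            norm.loc[idx] = normalize_plate(sub, readout, nc_center=nc_center)
        df[f"norm_{col}"] = norm
    return df


def _pooled_t_p(m1, s1, n1, m2, s2, n2):
    """Two-sided pooled-variance (Student) t-test p from summary stats.

    Vectorized over group 1; returns NaN where n1 < 2.
    """
    m1, s1, n1 = np.asarray(m1, float), np.asarray(s1, float), np.asarray(n1, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
        t = (m1 - m2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        p = 2 * sps.t.sf(np.abs(t), df)
    return np.where(n1 >= 2, p, np.nan)


def aggregate_gene(
    norm_df: pd.DataFrame, gene: str, arm: str, test_against: str = "nc"
) -> GeneEffect:
    """Aggregate one gene's replicates in one arm (SINGLE or COMBINED)."""
    effects = aggregate_effects(norm_df, genes=[gene], test_against=test_against)
    for e in effects:
        if e.arm == arm:
            return e
    raise ValidationError(f"gene {gene!r} has no wells in arm {arm!r}")


def aggregate_effects(
    norm_df: pd.DataFrame,
    genes: list[str] | None = None,
    test_against: str = "nc",
) -> list[GeneEffect]:
    """Per-(gene, arm) replicate aggregation over a normalized screen table.

    The effect is the mean over batches of the per-plate normalized value;
    the p-value is a two-sided Student's t-test of the gene's per-batch
    values against the normalized siNC wells of the same plates and arm
    (``test_against="nc"``), or a one-sample t-test against zero
    (``test_against="zero"``). Fewer than two replicates leaves the p-value
    missing while still reporting the effect.
    """
    if test_against not in ("nc", "zero"):
        raise ValueError(f"test_against must be 'nc' or 'zero', got {test_against!r}")
    df = norm_df
    is_control = df["perturbation"].isin([NEGATIVE_CONTROL, POSITIVE_CONTROL])
    gene_df = df[~is_control]
    if genes is not None:
        gene_df = gene_df[gene_df["perturbation"].isin(genes)]
    nc_df = df[df["perturbation"] == NEGATIVE_CONTROL]

    effects: list[GeneEffect] = []
    for arm_raw, arm_sub in gene_df.groupby("co_treatment"):
        arm = ARM_LABELS[arm_raw]
        nc_arm = nc_df[nc_df["co_treatment"] == arm_raw]
        # genes sharing a plate position share their siNC comparison wells
        for plates, plate_sub in arm_sub.groupby(
            arm_sub.groupby("perturbation")["plate"]
            .transform(lambda s: "|".join(sorted(set(s))))
        ):
            nc_vals = {
                ro: nc_arm.loc[
                    nc_arm["plate"].isin(plates.split("|")), f"norm_{col}"
                ].dropna().to_numpy()
                for ro, col in _READOUT_COLS.items()
            }
            piv = {
                ro: plate_sub.pivot_table(
                    index="perturbation", columns="batch", values=f"norm_{col}"
                )
                for ro, col in _READOUT_COLS.items()
            }
            gene_index = piv["COUNT"].index
            res = {}
            for ro in _READOUT_COLS:
                vals = piv[ro].reindex(gene_index).to_numpy()
                n1 = np.sum(~np.isnan(vals), axis=1)
                with np.errstate(invalid="ignore"):
                    m1 = np.nanmean(np.where(np.isnan(vals), np.nan, vals), axis=1)
                    s1 = np.nanstd(vals, axis=1, ddof=1)
                if test_against == "nc":
                    nc = nc_vals[ro]
                    p = _pooled_t_p(m1, s1, n1, nc.mean(), nc.std(ddof=1), len(nc))
                else:
                    with np.errstate(divide="ignore", invalid="ignore"):
                        t = m1 / (s1 / np.sqrt(n1))
                        p = 2 * sps.t.sf(np.abs(t), n1 - 1)
                    p = np.where(n1 >= 2, p, np.nan)
                res[ro] = (m1, p, n1, vals)
            for i, g in enumerate(gene_index):
                effects.append(
                    GeneEffect(
                        gene=str(g),
                        arm=arm,
                        log2fc_count=float(res["COUNT"][0][i]),
                        log2fc_viability=float(res["VIABILITY"][0][i]),
                        p_count=float(res["COUNT"][1][i]),
                        p_viability=float(res["VIABILITY"][1][i]),
                        n_reps=int(res["COUNT"][2][i]),
                        batch_values_count=tuple(
                            v for v in res["COUNT"][3][i] if not np.isnan(v)
                        ),
                        batch_values_viability=tuple(
                            v for v in res["VIABILITY"][3][i] if not np.isnan(v)
                        ),
                    )
                )
    effects.sort(key=lambda e: (e.gene, e.arm))
    return effects


def _arm_significant(e: GeneEffect, p_threshold: float, fold_threshold: float) -> bool:
    return (
        not np.isnan(e.p_count)
        and e.p_count < p_threshold
        and e.log2fc_count <= -fold_threshold
    )


def call_hits(
    effects: list[GeneEffect],
    p_threshold: float = 0.01,
    fold_threshold: float = 1.0,
) -> list[HitCall]:
    """Categorize genes from their SINGLE/COMBINED effect pairs.

    Per-arm significance requires p_count < p_threshold and a count log2
    fold change at or below -fold_threshold (inhibition only). COMMON needs
    both arms significant. A gene is cisplatin-sensitized when the
    combined-vs-single contrast (Student's t on per-batch normalized counts)
    has p < p_threshold with the combined arm more inhibitory, and the
    combined arm is itself significant; sensitized non-COMMON genes are
    categorized CISPLATIN_SENSITIZED.
    """
    by_gene: dict[str, dict[str, GeneEffect]] = {}
    for e in effects:
        by_gene.setdefault(e.gene, {})[e.arm] = e
    calls: list[HitCall] = []
    for gene, arms in sorted(by_gene.items()):
        if "SINGLE" not in arms or "COMBINED" not in arms:
            raise ValidationError(f"gene {gene!r} is missing an arm; both required")
        single, combined = arms["SINGLE"], arms["COMBINED"]
        s_sig = _arm_significant(single, p_threshold, fold_threshold)
        c_sig = _arm_significant(combined, p_threshold, fold_threshold)
        a, b = np.asarray(combined.batch_values_count), np.asarray(
            single.batch_values_count
        )
        if len(a) >= 2 and len(b) >= 2:
            sens_p = float(
                _pooled_t_p(
                    a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b)
                )
            )
        else:
            sens_p = float("nan")
        sensitized = (
            not np.isnan(sens_p)
            and sens_p < p_threshold
            and a.mean() < b.mean()
            and c_sig
        )
        if s_sig and c_sig:
            category = COMMON
        elif sensitized:
            category = CISPLATIN_SENSITIZED
        elif c_sig:
            category = COMBINED_ONLY
        elif s_sig:
            category = SINGLE_ONLY
        else:
            category = NONE
        calls.append(
            HitCall(
                gene=gene,
                category=category,
                single=single,
                combined=combined,
                sensitization_p=sens_p,
                sensitized=sensitized,
            )
        )
    return calls


def effects_frame(effects: list[GeneEffect]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [e.gene for e in effects],
            "arm": [e.arm for e in effects],
            "log2fc_count": [e.log2fc_count for e in effects],
            "log2fc_viability": [e.log2fc_viability for e in effects],
            "p_count": [e.p_count for e in effects],
            "p_viability": [e.p_viability for e in effects],
            "n_reps": [e.n_reps for e in effects],
        }
    )


def hits_frame(calls: list[HitCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [c.gene for c in calls],
            "category": [c.category for c in calls],
            "log2fc_count_single": [c.single.log2fc_count for c in calls],
            "log2fc_count_combined": [c.combined.log2fc_count for c in calls],
            "p_count_single": [c.single.p_count for c in calls],
            "p_count_combined": [c.combined.p_count for c in calls],
            "sensitization_p": [c.sensitization_p for c in calls],
            "sensitized": [c.sensitized for c in calls],
        }
    )
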