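"""Data model and readers/writers for plate-format screen data and cohorts.

The screen is a long-format table: one row per well, identified by
(plate, batch, row, col) with a perturbation label, a co-treatment arm and
two raw readouts (fluorescence viability and image-derived cell count).
Cohort data are three tables sharing sample identifiers: clinical
(survival endpoints, gender, stage), an expression matrix (genes x samples,
log2(TPM+1) or FPKM) and a long-format somatic-mutation table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

ROWS = [chr(ord("A") + i) for i in range(16)]  # 384-well: A..P x 1..24
N_COLS = 24

NEGATIVE_CONTROL = "NC"
POSITIVE_CONTROL = "PLK1"
EMPTY_WELL = "EMPTY"
RESERVED_PERTURBATIONS = {NEGATIVE_CONTROL, POSITIVE_CONTROL, EMPTY_WELL}

ARMS = ("VEHICLE", "CISPLATIN")
READOUTS = ("COUNT", "VIABILITY")

GENDERS = ("FEMALE", "MALE")
STAGES = ("I", "II", "III", "IV")

PLATE_COLUMNS = [
    "plate",
    "batch",
    "row",
    "col",
    "perturbation",
    "co_treatment",
    "viability",
    "count",
]


@dataclass(frozen=True)
class WellRecord:
    """One well of a 384-well screening plate."""

    plate_id: str
    batch_id: int
    row: str
    col: int
    perturbation: str
    co_treatment: str
    raw_viability: float | None  # fluorescence, a.u., >= 0; None = missing
    raw_count: int | None  # nuclei per well, >= 0; None = missing

    @property
    def well(self) -> str:
        return f"{self.row}{self.col}"

    @property
    def is_empty(self) -> bool:
        return self.perturbation == EMPTY_WELL


@dataclass(frozen=True)
class ControlStats:
    """Per-plate control summary feeding the z'-factor.

    Positive controls are siPLK1 (strong growth inhibition), negative
    controls siNC (non-targeting). SDs are sample (n-1) standard deviations.
    """

    plate_id: str
    readout: str
    avg_pos: float
    sd_pos: float
    avg_neg: float
    sd_neg: float
    n_pos: int = 0
    n_neg: int = 0


@dataclass
class GeneEffect:
    """Replicate-aggregated effect of one siRNA in one treatment arm.

    log2fc_* is the mean over screening batches of the per-plate
    log2(raw / siNC center); p_* is a two-sided two-sample t-test of the
    gene's per-batch values against the same-arm siNC well values.
    """

    gene: str
    arm: str  # SINGLE or COMBINED
    log2fc_count: float
    log2fc_viability: float
    p_count: float  # NaN when < 2 replicates
    p_viability: float
    n_reps: int
    # per-batch normalized values, kept for downstream contrasts
    batch_values_count: tuple[float, ...] = ()
    batch_values_viability: tuple[float, ...] = ()


@dataclass
class SurvivalSample:
    """One patient: endpoints, covariates, expression and mutation calls."""

    sample_id: str
    os_time: float  # days > 0
    os_event: bool
    dfs_time: float
    dfs_event: bool
    gender: str
    stage: str
    expression: dict[str, float] = field(default_factory=dict)
    mutations: set[str] = field(default_factory=set)

    def time_event(self, endpoint: str) -> tuple[float, bool]:
        if endpoint == "OS":
            return self.os_time, self.os_event
        if endpoint == "DFS":
            return self.dfs_time, self.dfs_event
        raise ValueError(f"unknown endpoint {endpoint!r}")


def _delimiter_for(path: str) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def _parse_readout(value, name: str, line: int) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    try:
        v = float(value)
    except (TypeError, ValueError):
        raise ValidationError(f"non-numeric {name} value {value!r}", line)
    if v < 0:
        raise ValidationError(f"negative {name} value {v}", line)
    return v


def read_plate_table(path) -> list[WellRecord]:
    """Read a long-format plate table (CSV/TSV by extension).

    Required columns: plate, batch, row, col, perturbation, co_treatment,
    viability, count. Empty readout cells become missing values (never 0).
    EMPTY wells are retained. Plates lacking siNC or siPLK1 controls trigger
    a warning (quality control will refuse them later); coordinate or value
    errors raise with the offending line number.
    """
    df = pd.read_csv(path, sep=_delimiter_for(path), dtype=str)
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(
            f"plate table is missing required column(s): {', '.join(missing)}"
        )
    wells: list[WellRecord] = []
    for i, rec in enumerate(df.to_dict("records")):
        line = i + 2  # header is line 1
        row = str(rec["row"]).strip().upper()
        if row not in ROWS:
            raise ValidationError(f"row {row!r} outside 384-well bounds A-P", line)
        try:
            col = int(rec["col"])
        except (TypeError, ValueError):
            raise ValidationError(f"non-integer column {rec['col']!r}", line)
        if not 1 <= col <= N_COLS:
            raise ValidationError(f"column {col} outside 384-well bounds 1-24", line)
        pert = str(rec["perturbation"]).strip()
        if pert.upper() in RESERVED_PERTURBATIONS:
            pert = pert.upper()
        arm = str(rec["co_treatment"]).strip().upper()
        if arm not in ARMS:
            raise ValidationError(
                f"co_treatment {rec['co_treatment']!r} not in {ARMS}", line
            )
        try:
            batch = int(rec["batch"])
        except (TypeError, ValueError):
            raise ValidationError(f"non-integer batch {rec['batch']!r}", line)
        viability = _parse_readout(rec["viability"], "viability", line)
        count_f = _parse_readout(rec["count"], "count", line)
        if count_f is not None:
            if count_f != int(count_f):
                raise ValidationError(f"count {count_f} is not an integer", line)
            count = int(count_f)
        else:
            count = None
        wells.append(
            WellRecord(
                plate_id=str(rec["plate"]).strip(),
                batch_id=batch,
                row=row,
                col=col,
                perturbation=pert,
                co_treatment=arm,
                raw_viability=viability,
                raw_count=count,
            )
        )
    _warn_missing_controls(wells)
    return wells


def _warn_missing_controls(wells: list[WellRecord]) -> None:
    by_plate: dict[str, set[str]] = {}
    for w in wells:
        by_plate.setdefault(w.plate_id, set()).add(w.perturbation)
    for plate, perts in sorted(by_plate.items()):
        for ctrl in (NEGATIVE_CONTROL, POSITIVE_CONTROL):
            if ctrl not in perts:
                warnings.warn(
                    f"plate {plate} has no si{ctrl} control wells", stacklevel=3
                )


def wells_to_frame(wells: list[WellRecord]) -> pd.DataFrame:
    """Long-format DataFrame view of a well list (missing readouts as NaN)."""
    return pd.DataFrame(
        {
            "plate": [w.plate_id for w in wells],
            "batch": [w.batch_id for w in wells],
            "row": [w.row for w in wells],
            "col": [w.col for w in wells],
            "perturbation": [w.perturbation for w in wells],
            "co_treatment": [w.co_treatment for w in wells],
            "viability": [
                np.nan if w.raw_viability is None else w.raw_viability for w in wells
            ],
            "count": [np.nan if w.raw_count is None else w.raw_count for w in wells],
        }
    )


def frame_to_wells(df: pd.DataFrame) -> list[WellRecord]:
    wells = []
    for rec in df.to_dict("records"):
        count = rec["count"]
        viability = rec["viability"]
        wells.append(
            WellRecord(
                plate_id=str(rec["plate"]),
                batch_id=int(rec["batch"]),
                row=str(rec["row"]),
                col=int(rec["col"]),
                perturbation=str(rec["perturbation"]),
                co_treatment=str(rec["co_treatment"]),
                raw_viability=None if pd.isna(viability) else float(viability),
                raw_count=None if pd.isna(count) else int(count),
            )
        )
    return wells


def write_plate_table(wells: list[WellRecord], path) -> None:
    df = wells_to_frame(wells)
    # integer counts where present; empty cells for missing
    df["count"] = df["count"].astype("Int64")
    df.to_csv(path, sep=_delimiter_for(path), index=False)


def write_results(table: pd.DataFrame, path) -> None:
    """Write any result table as CSV/TSV (delimiter from extension).

    Round-trips losslessly through ``pandas.read_csv`` with the same
    delimiter; missing values are written as empty cells.
    """
    table.to_csv(path, sep=_delimiter_for(path), index=False)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=_delimiter_for(path))


# ---------------------------------------------------------------------------
# Cohort tables


def _clinical_days(rec, key) -> float | None:
    v = rec.get(key)
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return float(v)


def read_cohort_tables(clinical_path, expression_path, mutations_path) -> list[SurvivalSample]:
    """Join clinical, expression and mutation tables into SurvivalSamples.

    Clinical columns: sample_id, vital_status (ALIVE/DEAD), days_to_death,
    days_to_last_follow_up, days_to_new_tumor_event, gender, stage.
    Expression matrix: genes as rows, first column ``gene``, one column per
    sample (log2(TPM+1) scale). Mutations: long format, columns sample_id,
    gene; absence of rows for a sample means no recorded mutations.

    OS time is days_to_death for deceased patients, else censoring at last
    follow-up. DFS time is the first of new tumor event or death, censored at
    last follow-up when neither occurred. Clinical samples absent from the
    expression matrix are dropped with a warning.
    """
    clinical = pd.read_csv(clinical_path, sep=_delimiter_for(clinical_path))
    if clinical["sample_id"].duplicated().any():
        dupes = clinical.loc[clinical["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicated sample_id in clinical table: {dupes}")
    expr = pd.read_csv(expression_path, sep=_delimiter_for(expression_path))
    gene_col = expr.columns[0]
    expr = expr.set_index(gene_col)
    muts = pd.read_csv(mutations_path, sep=_delimiter_for(mutations_path))
    mut_by_sample: dict[str, set[str]] = {}
    for rec in muts.to_dict("records"):
        mut_by_sample.setdefault(str(rec["sample_id"]), set()).add(str(rec["gene"]))

    expr_samples = set(expr.columns)
    samples: list[SurvivalSample] = []
    dropped = []
    for rec in clinical.to_dict("records"):
        sid = str(rec["sample_id"])
        if sid not in expr_samples:
            dropped.append(sid)
            continue
        dead = str(rec["vital_status"]).strip().upper() == "DEAD"
        d_death = _clinical_days(rec, "days_to_death")
        d_fu = _clinical_days(rec, "days_to_last_follow_up")
        d_new = _clinical_days(rec, "days_to_new_tumor_event")
        os_time = d_death if dead and d_death is not None else d_fu
        if os_time is None or os_time <= 0:
            raise ValidationError(f"sample {sid}: non-positive or missing OS time")
        os_event = dead and d_death is not None
        dfs_candidates = [d for d in (d_new, d_death if dead else None) if d is not None]
        if dfs_candidates:
            dfs_time, dfs_event = min(dfs_candidates), True
        else:
            dfs_time, dfs_event = d_fu, False
        if dfs_time is None or dfs_time <= 0:
            raise ValidationError(f"sample {sid}: non-positive or missing DFS time")
        gender = str(rec["gender"]).strip().upper()
        if gender not in GENDERS:
            raise ValidationError(f"sample {sid}: gender {gender!r} not in {GENDERS}")
        stage = str(rec["stage"]).strip().upper()
        if stage not in STAGES:
            raise ValidationError(f"sample {sid}: stage {stage!r} not in {STAGES}")
        samples.append(
            SurvivalSample(
                sample_id=sid,
                os_time=float(os_time),
                os_event=bool(os_event),
                dfs_time=float(dfs_time),
                dfs_event=bool(dfs_event),
                gender=gender,
                stage=stage,
                expression=expr[sid].to_dict(),
                mutations=mut_by_sample.get(sid, set()),
            )
        )
    if dropped:
        warnings.warn(
            f"{len(dropped)} clinical sample(s) absent from expression matrix, "
            f"dropped: {', '.join(dropped[:5])}{'...' if len(dropped) > 5 else ''}",
            stacklevel=2,
        )
    if not samples:
        raise ValidationError("zero samples shared between clinical and expression tables")
    return samples


def write_cohort_tables(samples: list[SurvivalSample], clinical_path, expression_path, mutations_path) -> None:
    """Inverse of read_cohort_tables for generator output and round-trips."""
    clin = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "vital_status": ["DEAD" if s.os_event else "ALIVE" for s in samples],
            "days_to_death": [s.os_time if s.os_event else np.nan for s in samples],
            "days_to_last_follow_up": [
                np.nan if s.os_event else s.os_time for s in samples
            ],
            "days_to_new_tumor_event": [
                s.dfs_time if s.dfs_event else np.nan for s in samples
            ],
            "gender": [s.gender for s in samples],
            "stage": [s.stage for s in samples],
        }
    )
    clin.to_csv(clinical_path, sep=_delimiter_for(clinical_path), index=False)
    genes = sorted({g for s in samples for g in s.expression})
    expr = pd.DataFrame(
        {s.sample_id: [s.expression.get(g, np.nan) for g in genes] for s in samples}
    )
    expr.insert(0, "gene", genes)
    expr.to_csv(expression_path, sep=_delimiter_for(expression_path), index=False)
    rows = [
        {"sample_id": s.sample_id, "gene": g}
        for s in samples
        for g in sorted(s.mutations)
    ]
    pd.DataFrame(rows, columns=["sample_id", "gene"]).to_csv(
        mutations_path, sep=_delimiter_for(mutations_path), index=False
    )
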