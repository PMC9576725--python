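"""Per-plate, per-readout z'-factor quality control.

The z'-factor measures the separation between the positive-control
(siPLK1, strong growth inhibition) and negative-control (siNC) well
distributions on a plate:

    z' = 1 - 3 (SD_pos + SD_neg) / |AVG_pos - AVG_neg|

It ranges over (-inf, 1]; z' > 0.5 indicates an excellent assay and
z' > 0 a borderline assay. An AS_PRINTED variant that subtracts the two
SDs in the numerator is provided for reproducibility of a published
typesetting of the formula; it is not the canonical statistic (it returns
1.0 for equally noisy controls) and is off by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import UndefinedStatisticError, ValidationError
from .io import (
    ControlStats,
    NEGATIVE_CONTROL,
    POSITIVE_CONTROL,
    READOUTS,
    WellRecord,
)

STANDARD = "STANDARD"
AS_PRINTED = "AS_PRINTED"

EXCELLENT = "EXCELLENT"
BORDERLINE = "BORDERLINE"
FAIL = "FAIL"


@dataclass(frozen=True)
class PlateQCResult:
    plate_id: str
    batch_id: int
    co_treatment: str
    readout: str
    z_prime: float
    quality: str


def compute_z_prime(stats: ControlStats, variant: str = STANDARD) -> float:
    """z'-factor from control statistics.

    STANDARD sums the control SDs (canonical definition); AS_PRINTED
    subtracts them. Raises if the control means coincide (zero separation
    leaves the statistic undefined).
    """
    sep = abs(stats.avg_pos - stats.avg_neg)
    if sep == 0:
        raise UndefinedStatisticError(
            f"plate {stats.plate_id} ({stats.readout}): control means coincide, "
            "z'-factor undefined"
        )
    if variant == STANDARD:
        num = stats.sd_pos + stats.sd_neg
    elif variant == AS_PRINTED:
        num = stats.sd_pos - stats.sd_neg
    else:
        raise ValueError(f"unknown z' variant {variant!r}")
    return 1.0 - 3.0 * num / sep


def classify_assay_quality(
    z_prime: float, excellent: float = 0.5, borderline: float = 0.0
) -> str:
    """Map a z'-factor to EXCELLENT (> 0.5), BORDERLINE (> 0) or FAIL.

    Both thresholds are strict inequalities.
    """
    if not math.isfinite(z_prime):
        raise UndefinedStatisticError(f"non-finite z'-factor {z_prime}")
    if z_prime > excellent:
        return EXCELLENT
    if z_prime > borderline:
        return BORDERLINE
    return FAIL


def control_stats(
    wells: list[WellRecord], plate_id: str, readout: str
) -> ControlStats:
    """Sample mean/SD of siPLK1 and siNC raw values on one plate.

    Raw (un-normalized) values within the wells' co-treatment arm; missing
    readouts are excluded. Requires >= 2 wells of each control class.
    """
    attr = "raw_count" if readout == "COUNT" else "raw_viability"
    pos = [getattr(w, attr) for w in wells if w.perturbation == POSITIVE_CONTROL]
    neg = [getattr(w, attr) for w in wells if w.perturbation == NEGATIVE_CONTROL]
    pos = np.asarray([v for v in pos if v is not None], dtype=float)
    neg = np.asarray([v for v in neg if v is not None], dtype=float)
    if len(pos) < 2 or len(neg) < 2:
        raise ValidationError(
            f"plate {plate_id}: needs >= 2 siPLK1 and >= 2 siNC wells with "
            f"{readout} values (got {len(pos)} / {len(neg)})"
        )
    return ControlStats(
        plate_id=plate_id,
        readout=readout,
        avg_pos=float(pos.mean()),
        sd_pos=float(pos.std(ddof=1)),
        avg_neg=float(neg.mean()),
        sd_neg=float(neg.std(ddof=1)),
        n_pos=len(pos),
        n_neg=len(neg),
    )


def qc_report(
    wells: list[WellRecord],
    variant: str = STANDARD,
    excellent: float = 0.5,
    borderline: float = 0.0,
) -> list[PlateQCResult]:
    """One QC result per (plate, batch, co-treatment arm, readout)."""
    groups: dict[tuple[str, int, str], list[WellRecord]] = {}
    for w in wells:
        groups.setdefault((w.plate_id, w.batch_id, w.co_treatment), []).append(w)
    results = []
    for (plate, batch, arm), group in sorted(groups.items()):
        for readout in READOUTS:
            stats = control_stats(group, plate, readout)
            z = compute_z_prime(stats, variant=variant)
            results.append(
                PlateQCResult(
                    plate_id=plate,
                    batch_id=batch,
                    co_treatment=arm,
                    readout=readout,
                    z_prime=z,
                    quality=classify_assay_quality(z, excellent, borderline),
                )
            )
    return results
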