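"""Kaplan–Meier estimation, log-rank testing and the 48-condition
survival-biomarker scan.

The scan dichotomizes patients by a gene's expression (median split, or
top-quartile vs bottom-quartile with the middle half excluded), within every
combination of endpoint (overall survival OS / disease-free survival DFS),
gender filter (female, male, both) and tumor stage (I–IV): 2 x 2 x 3 x 4 =
48 log-rank tests per gene. The minimum p over the 48 cells is the gene's
"best p" and its direction classifies the gene as FAVORABLE (high expression
survives better) or UNFAVORABLE (high expression survives worse). The
best-of-48 selection is reproduced as published — uncorrected for
multiplicity — and its null inflation is quantified by simulation rather
than adjusted away.

KM and the two-group log-rank are implemented directly (product-limit
estimator; hypergeometric variance at each distinct event time; chi-square
with one degree of freedom), with an exact/near-exact permutation version
for small samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import UndefinedStatisticError, ValidationError
from .io import GENDERS, STAGES, SurvivalSample

ENDPOINTS = ("OS", "DFS")
SPLITS = ("MEDIAN", "QUARTILE")
GENDER_FILTERS = ("FEMALE", "MALE", "BOTH")

HIGH, LOW, EXCLUDED = "HIGH", "LOW", "EXCLUDED"
FAVORABLE, UNFAVORABLE, NONE_CALL = "FAVORABLE", "UNFAVORABLE", "NONE"
P01, P05, NS = "P01", "P05", "NS"


@dataclass
class KMCurve:
    """Product-limit survival estimate."""

    event_times: np.ndarray  # ascending distinct times with >= 1 event
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # n at risk at each event time
    n_events: np.ndarray
    n_censored: int
    n: int

    def survival_at(self, t: float) -> float:
        """Step-function value S(t)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class ScanCell:
    """One of the 48 scan configurations and its log-rank outcome."""

    endpoint: str
    split: str
    gender_filter: str
    stage_filter: str
    p_value: float  # NaN when the cell is degenerate
    direction: int  # +1 high group survives better, -1 worse, 0 undefined
    n_high: int
    n_low: int


@dataclass
class PrognosisCall:
    gene: str
    best_p: float
    best_cell: ScanCell | None
    call: str  # FAVORABLE / UNFAVORABLE / NONE
    tier: str  # P01 / P05 / NS
    n_samples: int = 0


def fpkm_to_log2tpm(fpkm) -> np.ndarray:
    """Convert one sample's FPKM vector over genes to log2(TPM + 1).

    TPM_i = FPKM_i / sum_j FPKM_j * 1e6, so TPM sums to one million per
    sample; the transform is invariant to rescaling all FPKM by a constant.
    """
    f = np.asarray(fpkm, dtype=float)
    if np.any(f < 0):
        raise ValidationError("FPKM values must be >= 0")
    total = f.sum()
    if total == 0:
        raise ValidationError("all-zero FPKM sample cannot be converted to TPM")
    tpm = f / total * 1e6
    return np.log2(tpm + 1.0)


def fpkm_matrix_to_log2tpm(expr: pd.DataFrame) -> pd.DataFrame:
    """Per-sample (column-wise) FPKM -> log2(TPM+1) for a genes x samples matrix."""
    return expr.apply(lambda col: pd.Series(fpkm_to_log2tpm(col), index=expr.index))


def km_estimate(times, events) -> KMCurve:
    """Kaplan–Meier product-limit estimator.

    At tied times, events precede censorings: a subject censored at t is
    still at risk for events at t.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise ValidationError("empty survival input")
    if np.any(t <= 0):
        raise ValidationError("survival times must be strictly positive")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    event_times = np.unique(t[e])
    at_risk = np.array([(t >= u).sum() for u in event_times])
    n_events = np.array([(e & (t == u)).sum() for u in event_times])
    with np.errstate(divide="ignore", invalid="ignore"):
        surv = np.cumprod(1.0 - n_events / at_risk)
    return KMCurve(
        event_times=event_times,
        survival=surv,
        at_risk=at_risk,
        n_events=n_events,
        n_censored=int((~e).sum()),
        n=int(t.size),
    )


def _logrank_chi2(g: np.ndarray, t: np.ndarray, e: np.ndarray) -> float:
    """Two-group log-rank chi-square (group 1 = True labels)."""
    event_times = np.unique(t[e])
    o = ex = v = 0.0
    for u in event_times:
        at_risk = t >= u
        n = at_risk.sum()
        n1 = (at_risk & g).sum()
        dying = e & (t == u)
        d = dying.sum()
        d1 = (dying & g).sum()
        o += d1
        ex += d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if v == 0:
        return float("nan")
    return (o - ex) ** 2 / v


def logrank_test(group_labels, times, events) -> tuple[float, float]:
    """Two-group log-rank test.

    ``group_labels`` is boolean (or any two-level labelling). Returns the
    chi-square statistic and its p-value from a chi-square distribution with
    one degree of freedom. Raises if either group is empty; returns NaN
    statistics when no events occur or the variance degenerates.
    """
    g = np.asarray(group_labels)
    if g.dtype != bool:
        levels = np.unique(g)
        if len(levels) != 2:
            raise ValidationError(
                f"log-rank requires exactly two groups, got {len(levels)}"
            )
        g = g == levels[1]
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if g.sum() == 0 or (~g).sum() == 0:
        raise ValidationError("log-rank requires two non-empty groups")
    chi2 = _logrank_chi2(g, t, e)
    if np.isnan(chi2):
        return float("nan"), float("nan")
    return float(chi2), float(sps.chi2.sf(chi2, df=1))


def logrank_permutation_p(
    group_labels, times, events, max_exact_n: int = 12, n_perm: int = 2000, seed: int = 0
) -> float:
    """Permutation p-value for the log-rank statistic.

    Enumerates all label assignments when n <= ``max_exact_n`` (exact test),
    otherwise samples ``n_perm`` random permutations. Serves as the
    small-sample oracle for the asymptotic chi-square p.
    """
    g = np.asarray(group_labels, dtype=bool)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    observed = _logrank_chi2(g, t, e)
    if np.isnan(observed):
        return float("nan")
    n, k = len(g), int(g.sum())
    if n <= max_exact_n:
        stats = []
        for idx in combinations(range(n), k):
            perm = np.zeros(n, dtype=bool)
            perm[list(idx)] = True
            stats.append(_logrank_chi2(perm, t, e))
        stats = np.asarray(stats)
    else:
        rng = np.random.default_rng(seed)
        stats = np.empty(n_perm)
        for i in range(n_perm):
            perm = np.zeros(n, dtype=bool)
            perm[rng.choice(n, size=k, replace=False)] = True
            stats[i] = _logrank_chi2(perm, t, e)
    valid = ~np.isnan(stats)
    return float(np.mean(stats[valid] >= observed - 1e-12))


def split_by_expression(values, method: str) -> np.ndarray:
    """Dichotomize expression values.

    MEDIAN: HIGH if value > median else LOW (ties go LOW). QUARTILE: HIGH
    above the 75th percentile, LOW below the 25th, middle half EXCLUDED.
    Percentiles use linear interpolation.
    """
    v = np.asarray(values, dtype=float)
    if method == "MEDIAN":
        if v.size < 2:
            raise ValidationError("median split needs n >= 2")
        cut = np.median(v)
        return np.where(v > cut, HIGH, LOW)
    if method == "QUARTILE":
        if v.size < 4:
            raise ValidationError("quartile split needs n >= 4")
        lo, hi = np.percentile(v, [25, 75])
        out = np.full(v.shape, EXCLUDED, dtype=object)
        out[v > hi] = HIGH
        out[v < lo] = LOW
        return out.astype(str)
    raise ValueError(f"unknown split method {method!r}")


def _samples_frame(samples: list[SurvivalSample], gene: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "os_time": [s.os_time for s in samples],
            "os_event": [s.os_event for s in samples],
            "dfs_time": [s.dfs_time for s in samples],
            "dfs_event": [s.dfs_event for s in samples],
            "gender": [s.gender for s in samples],
            "stage": [s.stage for s in samples],
            "expr": [s.expression[gene] for s in samples],
        }
    )


def _direction(g: np.ndarray, t: np.ndarray, e: np.ndarray) -> int:
    """Sign of (high-group survival - low-group survival) via observed vs
    expected events in the HIGH group: fewer events than expected means the
    high group survives better."""
    event_times = np.unique(t[e])
    o = ex = 0.0
    for u in event_times:
        at_risk = t >= u
        n1 = (at_risk & g).sum()
        d = (e & (t == u)).sum()
        o += (e & (t == u) & g).sum()
        ex += d * n1 / at_risk.sum()
    return int(np.sign(ex - o))


def scan_48(samples: list[SurvivalSample], gene: str) -> tuple[list[ScanCell], PrognosisCall]:
    """All 48 scan cells for one gene, plus the best-p prognosis call.

    Cells where a stratum is empty or a split leaves an empty group carry a
    missing p. best_p is the minimum over valid cells; ties break on the
    fixed cell ordering (endpoint, split, gender, stage). The call is
    UNFAVORABLE when the best cell's high-expression group survives worse,
    FAVORABLE when better, NONE when best_p >= 0.05; the tier marks
    best_p < 0.01 (P01), < 0.05 (P05) or neither (NS).
    """
    for s in samples:
        if gene not in s.expression:
            raise ValidationError(f"gene {gene!r} missing from sample {s.sample_id}")
    df = _samples_frame(samples, gene)
    cells: list[ScanCell] = []
    for endpoint in ENDPOINTS:
        tcol, ecol = f"{endpoint.lower()}_time", f"{endpoint.lower()}_event"
        for split in SPLITS:
            for gender in GENDER_FILTERS:
                for stage in STAGES:
                    sub = df[df["stage"] == stage]
                    if gender != "BOTH":
                        sub = sub[sub["gender"] == gender]
                    p, direction, n_high, n_low = float("nan"), 0, 0, 0
                    min_n = 2 if split == "MEDIAN" else 4
                    if len(sub) >= min_n:
                        labels = split_by_expression(sub["expr"].to_numpy(), split)
                        high = labels == HIGH
                        low = labels == LOW
                        n_high, n_low = int(high.sum()), int(low.sum())
                        if n_high > 0 and n_low > 0:
                            keep = high | low
                            g = high[keep]
                            t = sub[tcol].to_numpy()[keep]
                            e = sub[ecol].to_numpy(bool)[keep]
                            _, p = logrank_test(g, t, e)
                            if not np.isnan(p):
                                direction = _direction(g, t, e)
                    cells.append(
                        ScanCell(
                            endpoint=endpoint,
                            split=split,
                            gender_filter=gender,
                            stage_filter=stage,
                            p_value=p,
                            direction=direction,
                            n_high=n_high,
                            n_low=n_low,
                        )
                    )
    call = _prognosis_call(gene, cells, len(samples))
    return cells, call


def _prognosis_call(gene: str, cells: list[ScanCell], n_samples: int) -> PrognosisCall:
    valid = [c for c in cells if not np.isnan(c.p_value)]
    if not valid:
        return PrognosisCall(gene, float("nan"), None, NONE_CALL, NS, n_samples)
    best = min(valid, key=lambda c: c.p_value)  # first minimum = fixed-order tiebreak
    best_p = best.p_value
    tier = P01 if best_p < 0.01 else P05 if best_p < 0.05 else NS
    if best_p >= 0.05 or best.direction == 0:
        call = NONE_CALL
    elif best.direction < 0:
        call = UNFAVORABLE
    else:
        call = FAVORABLE
    return PrognosisCall(gene, float(best_p), best, call, tier, n_samples)


def mutation_stratified_scan(
    samples: list[SurvivalSample], gene: str, mutation_geneset
) -> tuple[list[ScanCell], PrognosisCall]:
    """Run the 48-cell scan on samples whose mutation set intersects the
    given geneset (carriers of at least one of the listed mutations)."""
    geneset = set(mutation_geneset)
    if not geneset:
        raise ValidationError("mutation geneset is empty")
    subset = [s for s in samples if s.mutations & geneset]
    if not subset:
        raise ValidationError(
            f"no samples carry any of the {len(geneset)} geneset mutations "
            "(subset size 0)"
        )
    return scan_48(subset, gene)


def scan_cells_frame(gene: str, cells: list[ScanCell]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": gene,
            "endpoint": [c.endpoint for c in cells],
            "split": [c.split for c in cells],
            "gender_filter": [c.gender_filter for c in cells],
            "stage_filter": [c.stage_filter for c in cells],
            "p_value": [c.p_value for c in cells],
            "direction": [c.direction for c in cells],
            "n_high": [c.n_high for c in cells],
            "n_low": [c.n_low for c in cells],
        }
    )


def oncoprint_matrix(
    samples: list[SurvivalSample], genes: list[str]
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Binary sample x gene mutation matrix with summary counts.

    Returns (matrix, per-gene carrier counts, gene x gene co-occurrence
    counts). Rendering is out of scope; the matrix is the artifact.
    """
    mat = pd.DataFrame(
        [[int(g in s.mutations) for g in genes] for s in samples],
        index=[s.sample_id for s in samples],
        columns=list(genes),
        dtype=int,
    )
    freqs = mat.sum(axis=0)
    cooc = mat.T @ mat
    return mat, freqs, cooc
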