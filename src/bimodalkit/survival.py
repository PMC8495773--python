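"""Kaplan–Meier / log-rank prognosis screen for bimodal genes.

For every gene called bimodal, patients labeled peak 1 (lower expression
mode) and peak 2 (higher mode) are compared with the two-group log-rank
test; significance is flagged at the 5% and 1% levels.  Samples discarded by
the mixture filters never enter the comparison — only labeled peak-1/peak-2
patients do.

Kaplan–Meier estimation and the log-rank statistic are computed with
lifelines; this module adapts them to the screen's record types.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy.stats import false_discovery_control

from .io_formats import ClinicalTable, match_sample_ids

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit survival estimate over distinct event times."""

    event_times: np.ndarray     # ascending distinct times with >= 1 event
    survival_prob: np.ndarray   # S(t) just after each event time
    at_risk: np.ndarray         # n at risk entering each event time
    events: np.ndarray          # events at each event time

    def __post_init__(self) -> None:
        if np.any(np.diff(self.event_times) <= 0):
            raise ValueError("event times must be strictly ascending")
        if np.any(np.diff(self.survival_prob) > 1e-12):
            raise ValueError("survival probabilities must be non-increasing")


@dataclass(frozen=True)
class LogrankResult:
    chi_square: float
    p_value: float
    n_group1: int
    n_group2: int
    events_group1: int
    events_group2: int


@dataclass(frozen=True)
class PrognosisRecord:
    gene_id: str
    cohort_label: str
    result: LogrankResult
    significant_05: bool
    significant_01: bool

    def __post_init__(self) -> None:
        if self.significant_01 and not self.significant_05:
            raise ValueError("significance at 1% implies significance at 5%")


def _check_times_events(times, events):
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("at least one survival record required")
    if t.size != e.size:
        raise ValueError("times and events must have equal length")
    if np.any(t <= 0) or not np.all(np.isfinite(t)):
        raise ValueError("survival times must be finite and positive")
    if not np.isin(e, [0, 1]).all():
        raise ValueError("event indicators must be 0 or 1")
    return t, e


def kaplan_meier(times, events) -> SurvivalCurve:
    """Product-limit estimate Ŝ(t) = Π_{tᵢ≤t} (1 − dᵢ/nᵢ) over event times.

    Censored-only times shrink the risk set without producing a step.
    """
    t, e = _check_times_events(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    table = kmf.event_table
    with_events = table[table["observed"] > 0]
    ev_times = with_events.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(ev_times).to_numpy()
    return SurvivalCurve(
        event_times=ev_times,
        survival_prob=surv,
        at_risk=with_events["at_risk"].to_numpy(dtype=int),
        events=with_events["observed"].to_numpy(dtype=int),
    )


def logrank_test(times1, events1, times2, events2) -> LogrankResult:
    """Classic two-group log-rank test, chi-square with 1 df.

    When neither group has an event the statistic is degenerate; the result
    is (chi² = 0, p = 1) with a warning.
    """
    t1, e1 = _check_times_events(times1, events1)
    t2, e2 = _check_times_events(times2, events2)
    if e1.sum() + e2.sum() == 0:
        logger.warning("log-rank with no events: returning chi2=0, p=1")
        chi2, p = 0.0, 1.0
    else:
        res = _ll_logrank(t1, t2, event_observed_A=e1, event_observed_B=e2)
        chi2, p = float(res.test_statistic), float(res.p_value)
    return LogrankResult(chi2, p, int(t1.size), int(t2.size),
                         int(e1.sum()), int(e2.sum()))


def prognosis_screen(stratifications, clinical: ClinicalTable,
                     alpha_levels: tuple[float, float] = (0.05, 0.01),
                     truncate_barcode: int | None = None,
                     bh_correct: bool = False) -> list["PrognosisRecord"]:
    """Log-rank screen of every stratified (bimodal) gene against survival.

    Peak labels are intersected with the clinical table (optionally matching
    TCGA-style barcodes by prefix); genes whose intersection leaves an empty
    group are excluded with a logged reason.  ``bh_correct`` applies
    Benjamini–Hochberg across genes before flagging significance.
    """
    if not stratifications:
        raise ValueError("at least one stratification required")
    alpha_hi, alpha_lo = max(alpha_levels), min(alpha_levels)
    clin = clinical.data.set_index("sample_id")

    raw: list[tuple] = []
    n_overlapping = 0
    for strat in stratifications:
        mapping = match_sample_ids(strat.labels.keys(), clin.index,
                                   truncate=truncate_barcode)
        groups = {"peak1": [], "peak2": []}
        n_missing = 0
        for sid, label in strat.labels.items():
            if sid in mapping:
                groups[label].append(mapping[sid])
            else:
                n_missing += 1
        if n_missing:
            logger.info("%s/%s: %d stratified samples absent from clinical "
                        "table", strat.gene_id, strat.cohort_label, n_missing)
        if not groups["peak1"] or not groups["peak2"]:
            logger.info("%s/%s excluded: a peak group has no clinical overlap",
                        strat.gene_id, strat.cohort_label)
            continue
        n_overlapping += 1
        g1 = clin.loc[groups["peak1"]]
        g2 = clin.loc[groups["peak2"]]
        res = logrank_test(g1["os_time"], g1["os_event"],
                           g2["os_time"], g2["os_event"])
        raw.append((strat, res))

    if n_overlapping == 0:
        raise ValueError("no stratification overlaps the clinical table")

    pvals = np.array([r.p_value for _, r in raw])
    adj = false_discovery_control(pvals, method="bh") if bh_correct else pvals
    records = []
    for (strat, res), p in zip(raw, adj):
        records.append(PrognosisRecord(
            strat.gene_id, strat.cohort_label, res,
            significant_05=bool(p < alpha_hi),
            significant_01=bool(p < alpha_lo)))
    return records
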