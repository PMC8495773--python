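"""Tabular I/O for expression matrices, clinical tables, and result files.

Conventions: expression matrices are genes-in-rows TSV/CSV with a header row
of sample ids and FPKM values in the body; clinical tables carry one row per
sample with overall-survival time (days) and an event indicator.  The readers
validate identifiers and values before any math runs, and every dropped row
is counted — nothing is coerced silently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MONTHS_TO_DAYS = 30.44


class FormatError(ValueError):
    """Raised when an input file violates the expected tabular format."""


def _sep_for(path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if str(path).endswith(".csv") else "\t"


@dataclass
class ExpressionMatrix:
    """Gene × sample grid of FPKM values for one cohort."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray          # shape (n_genes, n_samples), FPKM
    cohort_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.gene_ids) == 0 or len(self.sample_ids) == 0:
            raise FormatError("expression matrix needs >= 1 gene and sample")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError("value grid shape does not match ids")
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise FormatError(f"duplicate {name} id: {i!r}")
                seen.add(i)
        if not np.all(np.isfinite(self.values)):
            raise FormatError("expression values must be finite")
        if np.any(self.values < 0):
            raise FormatError("expression values must be non-negative (FPKM)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gene_values(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]


@dataclass
class ClinicalTable:
    """Per-sample overall-survival records (time in days, event in {0,1})."""

    data: pd.DataFrame          # columns: sample_id, os_time, os_event
    n_dropped: int = 0

    def __post_init__(self) -> None:
        df = self.data
        required = {"sample_id", "os_time", "os_event"}
        if not required.issubset(df.columns):
            raise FormatError(f"clinical table missing columns "
                              f"{sorted(required - set(df.columns))}")
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise FormatError(f"duplicate sample id: {dup!r}")
        if len(df) == 0:
            raise FormatError("clinical table has no valid rows")
        if not np.all(np.isfinite(df["os_time"])) or (df["os_time"] <= 0).any():
            bad = df.loc[~np.isfinite(df["os_time"]) | (df["os_time"] <= 0)].index[0]
            raise FormatError(f"os_time must be finite and positive (row {bad})")
        bad_ev = ~df["os_event"].isin([0, 1])
        if bad_ev.any():
            raise FormatError(
                f"os_event must be 0 or 1 (row {df.index[bad_ev][0]}, "
                f"value {df.loc[bad_ev, 'os_event'].iloc[0]!r})")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def sample_ids(self) -> list[str]:
        return self.data["sample_id"].tolist()


def read_expression_matrix(path, cohort_label: str = "",
                           delimiter: str | None = None) -> ExpressionMatrix:
    """Read a genes-in-rows expression matrix; reject malformed cells.

    The delimiter is inferred from the extension (.csv → comma, otherwise
    tab) unless given explicitly.
    """
    path = Path(path)
    sep = _sep_for(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"{path}: empty expression matrix body")
    gene_ids = [str(g).strip() for g in df.index]
    sample_ids = [str(s).strip() for s in df.columns]
    values = np.empty(df.shape, dtype=float)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            try:
                values[i, j] = float(raw[i, j])
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: non-numeric cell {raw[i, j]!r} at gene "
                    f"{gene_ids[i]!r}, sample {sample_ids[j]!r}") from None
    if np.any(np.isnan(values)):
        i, j = map(int, np.argwhere(np.isnan(values))[0])
        raise FormatError(f"{path}: missing value at gene {gene_ids[i]!r}, "
                          f"sample {sample_ids[j]!r}")
    return ExpressionMatrix(gene_ids, sample_ids, values, cohort_label)


def write_expression_matrix(matrix: ExpressionMatrix, path,
                            delimiter: str | None = None) -> None:
    path = Path(path)
    df = pd.DataFrame(matrix.values, index=matrix.gene_ids,
                      columns=matrix.sample_ids)
    df.to_csv(path, sep=_sep_for(path, delimiter), float_format="%.6g")


def read_clinical_table(path, delimiter: str | None = None,
                        sample_col: str = "sample_id",
                        time_col: str = "os_time",
                        event_col: str = "os_event",
                        time_unit: str = "days") -> ClinicalTable:
    """Read a clinical table, dropping (and counting) incomplete rows.

    ``time_unit='months'`` rescales survival times to days (×30.44), matching
    cBioPortal's OS_MONTHS convention.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, delimiter))
    for col in (sample_col, time_col, event_col):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    df = df.rename(columns={sample_col: "sample_id", time_col: "os_time",
                            event_col: "os_event"})
    df["sample_id"] = df["sample_id"].astype(str).str.strip()
    df["os_time"] = pd.to_numeric(df["os_time"], errors="coerce")
    df["os_event"] = pd.to_numeric(df["os_event"], errors="coerce")
    complete = df["os_time"].notna() & df["os_event"].notna()
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.warning("%s: dropped %d rows with missing time/event",
                       path, n_dropped)
    df = df.loc[complete, ["sample_id", "os_time", "os_event"]].reset_index(drop=True)
    if len(df) == 0:
        raise FormatError(f"{path}: no valid clinical rows")
    if time_unit == "months":
        df["os_time"] = df["os_time"] * MONTHS_TO_DAYS
    elif time_unit != "days":
        raise ValueError(f"unknown time unit {time_unit!r}")
    df["os_event"] = df["os_event"].astype(int)
    return ClinicalTable(df, n_dropped=n_dropped)


def write_clinical_table(table: ClinicalTable, path,
                         delimiter: str | None = None) -> None:
    table.data.to_csv(Path(path), sep=_sep_for(path, delimiter), index=False,
                      float_format="%.6g")


def match_sample_ids(expression_ids, clinical_ids,
                     truncate: int | None = None) -> dict[str, str]:
    """Map expression sample ids to clinical sample ids.

    Matching is by exact string after whitespace trimming; ``truncate``
    compares only the first N characters, which reconciles TCGA sample
    barcodes (e.g. ``TCGA-XX-YYYY-01``) with patient barcodes
    (``TCGA-XX-YYYY``).
    """
    def key(s: str) -> str:
        s = s.strip()
        return s[:truncate] if truncate else s

    clin = {}
    for c in clinical_ids:
        clin.setdefault(key(c), c)
    return {e: clin[key(e)] for e in expression_ids if key(e) in clin}


# ---------------------------------------------------------------------------
# result records

_CALL_COLUMNS = ["gene_id", "cohort_label", "status", "n_samples_used",
                 "n_initial_peaks", "initial_peak_locations",
                 "n_confirmed_peaks", "confirmed_peak_locations",
                 "n_peak1", "n_peak2"]
_STRAT_COLUMNS = ["gene_id", "cohort_label", "sample_id", "peak"]
_PROGNOSIS_COLUMNS = ["gene_id", "cohort_label", "n_group1", "n_group2",
                      "events_group1", "events_group2", "chi_square",
                      "p_value", "significant_05", "significant_01"]


def _fmt_locs(locs) -> str:
    return ";".join(f"{x:.6g}" for x in locs)


def write_results(calls, stratifications, prognosis, out_dir) -> set[Path]:
    """Write the three result TSVs (calls, stratification, prognosis).

    Column order is stable; floats carry 6 significant digits.  Empty inputs
    yield header-only files so downstream tooling always finds the columns.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    strat_by_key = {(s.gene_id, s.cohort_label): s for s in stratifications}
    call_rows = []
    for c in calls:
        strat = strat_by_key.get((c.gene_id, c.cohort_label))
        counts = strat.peak_counts() if strat is not None else (0, 0)
        call_rows.append({
            "gene_id": c.gene_id, "cohort_label": c.cohort_label,
            "status": c.status, "n_samples_used": c.n_samples_used,
            "n_initial_peaks": c.initial_peaks.n_peaks if c.initial_peaks else 0,
            "initial_peak_locations":
                _fmt_locs(c.initial_peaks.peak_locations) if c.initial_peaks else "",
            "n_confirmed_peaks":
                c.confirmed_peaks.n_peaks if c.confirmed_peaks else 0,
            "confirmed_peak_locations":
                _fmt_locs(c.confirmed_peaks.peak_locations) if c.confirmed_peaks else "",
            "n_peak1": counts[0], "n_peak2": counts[1],
        })
    strat_rows = [
        {"gene_id": s.gene_id, "cohort_label": s.cohort_label,
         "sample_id": sid, "peak": label}
        for s in stratifications for sid, label in sorted(s.labels.items())
    ]
    prog_rows = [
        {"gene_id": p.gene_id, "cohort_label": p.cohort_label,
         "n_group1": p.result.n_group1, "n_group2": p.result.n_group2,
         "events_group1": p.result.events_group1,
         "events_group2": p.result.events_group2,
         "chi_square": float(f"{p.result.chi_square:.6g}"),
         "p_value": float(f"{p.result.p_value:.6g}"),
         "significant_05": int(p.significant_05),
         "significant_01": int(p.significant_01)}
        for p in prognosis
    ]

    written = set()
    for name, rows, cols in (("bimodal_calls", call_rows, _CALL_COLUMNS),
                             ("stratification", strat_rows, _STRAT_COLUMNS),
                             ("prognosis", prog_rows, _PROGNOSIS_COLUMNS)):
        path = out_dir / f"{name}.tsv"
        pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
        written.add(path)
    return written


def read_results(out_dir) -> dict[str, pd.DataFrame]:
    """Re-read the result TSVs written by :func:`write_results`."""
    out_dir = Path(out_dir)
    return {name: pd.read_csv(out_dir / f"{name}.tsv", sep="\t")
            for name in ("bimodal_calls", "stratification", "prognosis")}
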