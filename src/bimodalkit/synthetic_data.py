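"""Synthetic expression cohorts and linked survival data with ground truth.

The generator emulates the distributional features bulk RNA-seq FPKM data
shows at the gene level: right-skewed, strictly non-negative expression with
a noise floor near zero, occasional outlier tails, and — for planted bimodal
genes — a two-component mixture.  Each mode is log-normal (Gaussian on the
log scale), so the detector's Gaussian mixture step is exercised through its
log-transform path.  Survival times are exponential with a hazard that can
differ between the two planted modes, under independent uniform censoring.

All randomness flows from explicit seeds, so every cohort is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io_formats import ClinicalTable, ExpressionMatrix

#: default ln-scale within-mode standard deviation; mode separations quoted
#: "in sigma" are multiples of this.
DEFAULT_MODE_SD = 0.4


@dataclass(frozen=True)
class GeneSpec:
    """Ground-truth generative description of one gene."""

    gene_id: str
    kind: str                    # bimodal | unimodal | noise_floor
    mode1_mean: float = 1.0      # expression-scale (FPKM) center of mode 1
    mode2_mean: float = 0.0      # center of mode 2 (bimodal genes only)
    mode_sd: float = DEFAULT_MODE_SD   # ln-scale spread within a mode
    mixing_weight: float = 0.5   # P(sample drawn from mode 1)
    chromosome: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("bimodal", "unimodal", "noise_floor"):
            raise ValueError(f"gene {self.gene_id!r}: unknown kind {self.kind!r}")
        if not 0 <= self.mixing_weight <= 1:
            raise ValueError(f"gene {self.gene_id!r}: mixing_weight outside [0,1]")
        if self.kind == "bimodal" and self.mode2_mean <= self.mode1_mean:
            raise ValueError(
                f"gene {self.gene_id!r}: bimodal requires mode2_mean > mode1_mean")
        if self.mode_sd <= 0:
            raise ValueError(f"gene {self.gene_id!r}: mode_sd must be positive")
        if self.mode1_mean <= 0:
            raise ValueError(f"gene {self.gene_id!r}: mode1_mean must be positive")


def bimodal_spec(gene_id: str, separation_sigma: float = 5.0,
                 mode1_mean: float = 1.0, mode_sd: float = DEFAULT_MODE_SD,
                 mixing_weight: float = 0.5,
                 chromosome: str | None = None) -> GeneSpec:
    """A bimodal gene whose ln-scale mode gap is ``separation_sigma·mode_sd``."""
    mode2 = float(mode1_mean * np.exp(separation_sigma * mode_sd))
    return GeneSpec(gene_id, "bimodal", mode1_mean, mode2, mode_sd,
                    mixing_weight, chromosome)


@dataclass
class SimulatedCohort:
    matrix: ExpressionMatrix
    truth: dict                  # gene_id -> GeneSpec
    mode_labels: dict            # (gene_id, sample_id) -> 1 | 2
    seed: int

    def labels_for(self, gene_id: str) -> dict:
        return {sid: mode for (g, sid), mode in self.mode_labels.items()
                if g == gene_id}


def _draw_gene(spec: GeneSpec, n: int, rng: np.random.Generator):
    if spec.kind == "noise_floor":
        # mostly sub-detection-floor values around 0.005 FPKM
        vals = rng.lognormal(np.log(0.005), 1.0, n)
        return vals, np.ones(n, dtype=int)
    if spec.kind == "unimodal":
        vals = rng.lognormal(np.log(spec.mode1_mean), spec.mode_sd, n)
        return vals, np.ones(n, dtype=int)
    modes = np.where(rng.random(n) < spec.mixing_weight, 1, 2)
    centers = np.where(modes == 1, np.log(spec.mode1_mean),
                       np.log(spec.mode2_mean))
    vals = rng.lognormal(centers, spec.mode_sd)
    return vals, modes


def simulate_cohort(n_samples: int, gene_specs, seed: int,
                    cohort_label: str = "SIM") -> SimulatedCohort:
    """Draw one expression cohort with per-gene, per-sample truth labels."""
    specs = list(gene_specs)
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if not specs:
        raise ValueError("at least one gene spec required")
    rng = np.random.default_rng(seed)
    sample_ids = [f"S{i:04d}" for i in range(n_samples)]
    values = np.empty((len(specs), n_samples))
    truth, mode_labels = {}, {}
    for gi, spec in enumerate(specs):
        vals, modes = _draw_gene(spec, n_samples, rng)
        values[gi] = np.clip(vals, 0.0, None)
        truth[spec.gene_id] = spec
        for sid, mode in zip(sample_ids, modes):
            mode_labels[(spec.gene_id, sid)] = int(mode)
    matrix = ExpressionMatrix([s.gene_id for s in specs], sample_ids, values,
                              cohort_label)
    return SimulatedCohort(matrix, truth, mode_labels, seed)


def _censoring_horizon(rates, target_frac: float) -> float:
    """Horizon T of Uniform(0, T) censoring giving the target censored
    fraction for a population mixing exponential event rates ``rates``."""
    rates = np.asarray(rates, dtype=float)

    def censored_frac(T):
        # P(C < E) for C ~ U(0,T), E ~ Exp(rate), averaged over the mix
        return float(np.mean((1 - np.exp(-rates * T)) / (rates * T))) - target_frac

    # censored fraction decreases from 1 (T→0) to 0 (T→∞)
    lo, hi = 1e-9, 1.0
    while censored_frac(hi) > 0:
        hi *= 2
    return brentq(censored_frac, lo, hi)


def simulate_survival(mode_labels: dict, hazard_ratio: float,
                      baseline_rate: float, censoring_rate: float,
                      seed: int) -> ClinicalTable:
    """Exponential survival with mode-dependent hazard and uniform censoring.

    Mode-1 samples have event rate ``baseline_rate``; mode-2 samples
    ``baseline_rate × hazard_ratio``.  Censoring times are Uniform(0, T) with
    T solved so the expected censored fraction equals ``censoring_rate``.
    """
    if not mode_labels:
        raise ValueError("mode_labels must be non-empty")
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be positive")
    if not 0 <= censoring_rate < 1:
        raise ValueError("censoring_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    sids = sorted(mode_labels)
    rates = np.array([baseline_rate * (hazard_ratio if mode_labels[s] == 2 else 1.0)
                      for s in sids])
    event_times = rng.exponential(1.0 / rates)
    if censoring_rate == 0:
        times, events = event_times, np.ones(len(sids), dtype=int)
    else:
        T = _censoring_horizon(rates, censoring_rate)
        cens = rng.uniform(0, T, len(sids))
        events = (event_times <= cens).astype(int)
        times = np.minimum(event_times, cens)
    df = pd.DataFrame({"sample_id": sids, "os_time": times, "os_event": events})
    return ClinicalTable(df)


def write_truth(cohort: SimulatedCohort, path) -> None:
    """Ground-truth TSV: one row per gene spec plus per-sample mode labels."""
    rows = [{"gene_id": s.gene_id, "kind": s.kind, "mode1_mean": s.mode1_mean,
             "mode2_mean": s.mode2_mean, "mode_sd": s.mode_sd,
             "mixing_weight": s.mixing_weight,
             "chromosome": s.chromosome or ""}
            for s in cohort.truth.values()]
    pd.DataFrame(rows).to_csv(Path(path), sep="\t", index=False,
                              float_format="%.6g")
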