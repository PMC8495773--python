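"""Per-gene and per-cohort orchestration of the bimodality screen.

The screen is a three-step process per gene: (a) density-derivative peak
detection on the expression values, (b) a ``k+1``-component Gaussian mixture
fit that stratifies samples and filters outliers/unreliable assignments, and
(c) a confirmation peak detection, identical to (a), on the retained samples.
A gene is called bimodal only if both detections find exactly two peaks.

Seven parameters configure the screen (see :class:`DetectionConfig`); the
defaults are minExpression = 0.02 FPKM, minSampleSize = 50,
minClusterSize = 10% of samples, threshold up/down = 10%/20% of the maximum
density, spline smoothing on, no log transform, and a 46% reliability cutoff
for mixture assignments.
"""

from __future__ import annotations

import json
import logging
import zlib
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import hypergeom

from . import density_peaks as dp
from . import mixture as mx
from .density_peaks import PeakSet
from .io_formats import ExpressionMatrix

logger = logging.getLogger(__name__)

STATUS_BIMODAL = "bimodal"
STATUS_UNIMODAL = "unimodal"
STATUS_REJECTED = "rejected_confirmation"
STATUS_SKIPPED = "skipped_min_samples"


@dataclass(frozen=True)
class DetectionConfig:
    """The screen's seven tunable parameters plus the random seed."""

    min_expression: float = 0.02      # FPKM floor; drops near-zero noise
    min_sample_size: int = 50         # genes with fewer samples are skipped
    min_cluster_frac: float = 0.10    # minimum cluster size, fraction of samples
    threshold_up: float = 0.10        # min peak-valley gap, fraction of max density
    threshold_down: float = 0.20      # min peak height, fraction of max density
    smoothing: bool = True            # GCV spline smoothing of the derivative
    use_log: str = "none"             # none | log2 | log10
    min_posterior: float = 0.46       # mixture-assignment reliability cutoff
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("min_cluster_frac", "threshold_up", "threshold_down",
                     "min_posterior"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.min_expression < 0:
            raise ValueError("min_expression must be >= 0")
        if self.min_sample_size < 2:
            raise ValueError("min_sample_size must be >= 2")
        if self.use_log not in ("none", "log2", "log10"):
            raise ValueError("use_log must be one of none, log2, log10")

    @classmethod
    def from_file(cls, path) -> "DetectionConfig":
        """Load a config from JSON or ``key = value`` lines."""
        text = Path(path).read_text()
        try:
            raw = json.loads(text)
        except json.JSONDecodeError:
            raw = {}
            for line in text.splitlines():
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, val = line.partition("=")
                raw[key.strip()] = val.strip()
        kwargs = {}
        for f_name, f_type in (("min_expression", float), ("min_sample_size", int),
                               ("min_cluster_frac", float), ("threshold_up", float),
                               ("threshold_down", float), ("smoothing", None),
                               ("use_log", str), ("min_posterior", float),
                               ("seed", int)):
            if f_name not in raw:
                continue
            v = raw[f_name]
            if f_name == "smoothing":
                v = v if isinstance(v, bool) else str(v).lower() in ("true", "1", "yes")
            else:
                v = f_type(v)
            kwargs[f_name] = v
        return cls(**kwargs)


@dataclass(frozen=True)
class BimodalCall:
    """Per-gene verdict of the screen."""

    gene_id: str
    cohort_label: str
    status: str
    n_samples_used: int
    initial_peaks: PeakSet | None = None
    confirmed_peaks: PeakSet | None = None

    def __post_init__(self) -> None:
        is_bimodal = self.status == STATUS_BIMODAL
        two_confirmed = (self.confirmed_peaks is not None
                         and self.confirmed_peaks.n_peaks == 2)
        if is_bimodal != two_confirmed:
            raise ValueError("status bimodal iff exactly 2 confirmed peaks")


@dataclass(frozen=True)
class Stratification:
    """Peak-1/peak-2 sample labels for one bimodal gene.

    Peak 1 is always the lower-expression mode.
    """

    gene_id: str
    cohort_label: str
    labels: dict  # sample_id -> "peak1" | "peak2"

    def peak_counts(self) -> tuple[int, int]:
        c = Counter(self.labels.values())
        return c.get("peak1", 0), c.get("peak2", 0)

    def samples_in(self, peak: str) -> list[str]:
        return sorted(s for s, p in self.labels.items() if p == peak)


def gene_seed(global_seed: int, gene_id: str) -> int:
    """Stable per-gene seed independent of gene order within the cohort."""
    return (int(global_seed) + zlib.crc32(gene_id.encode())) % (2 ** 31)


def preprocess_gene(values, sample_ids, config: DetectionConfig):
    """Apply the expression floor, sample-size gate, and log transform.

    Returns ``(values, sample_ids)`` after filtering, or ``None`` when fewer
    than ``min_sample_size`` samples survive the expression floor (the skip
    signal — a status, not an error).
    """
    x = np.asarray(values, dtype=float)
    ids = np.asarray(list(sample_ids), dtype=object)
    keep = x >= config.min_expression
    x, ids = x[keep], ids[keep]
    if x.size < config.min_sample_size:
        return None
    if config.use_log == "log2":
        x = np.log2(x)
    elif config.use_log == "log10":
        x = np.log10(x)
    return x, list(ids)


def _detect(x, config: DetectionConfig) -> PeakSet:
    bw = dp.rule_of_thumb_bandwidth(x)
    curve = dp.kernel_density(x, bw)
    deriv = dp.smoothed_derivative(curve, config.smoothing)
    return dp.detect_peaks(curve, deriv, config.threshold_up,
                           config.threshold_down)


def analyze_gene(gene_id: str, values, sample_ids, config: DetectionConfig,
                 cohort_label: str = ""):
    """Run the full three-step screen on one gene.

    Returns ``(BimodalCall, Stratification | None)``; a Stratification exists
    iff the call status is bimodal.
    """
    pre = preprocess_gene(values, sample_ids, config)
    if pre is None:
        return BimodalCall(gene_id, cohort_label, STATUS_SKIPPED, 0), None
    x, ids = pre
    n_used = len(x)

    if np.ptp(x) == 0:  # constant expression: no density structure
        return BimodalCall(gene_id, cohort_label, STATUS_UNIMODAL, n_used,
                           initial_peaks=PeakSet()), None

    initial = _detect(x, config)
    k = initial.n_peaks
    if k != 2:
        if k > 2:
            logger.info("%s: %d initial peaks; only two-peak genes pursued",
                        gene_id, k)
        return BimodalCall(gene_id, cohort_label, STATUS_UNIMODAL, n_used,
                           initial_peaks=initial), None

    # step (b): k+1 = 3-component mixture, filters
    fit = mx.fit_univariate_gmm(x, n_components=k + 1,
                                seed=gene_seed(config.seed, gene_id))
    assignments = mx.posterior_assignments(fit, x, ids)
    retained, _ = mx.select_retained_samples(
        assignments, fit, initial.peak_locations,
        min_posterior=config.min_posterior,
        min_cluster_frac=config.min_cluster_frac, n_total=n_used)

    idx = {sid: i for i, sid in enumerate(ids)}
    kept_ids = sorted(retained)
    x_kept = np.array([x[idx[s]] for s in kept_ids])

    if x_kept.size < 2 or np.ptp(x_kept) == 0:
        return BimodalCall(gene_id, cohort_label, STATUS_REJECTED, n_used,
                           initial_peaks=initial), None

    # step (c): confirmation detection, identical to step (a)
    confirmed = _detect(x_kept, config)
    labels = {s: f"peak{retained[s] + 1}" for s in kept_ids}
    groups = Counter(labels.values())
    if confirmed.n_peaks != 2 or groups.get("peak1", 0) == 0 \
            or groups.get("peak2", 0) == 0:
        return BimodalCall(gene_id, cohort_label, STATUS_REJECTED, n_used,
                           initial_peaks=initial), None

    call = BimodalCall(gene_id, cohort_label, STATUS_BIMODAL, n_used,
                       initial_peaks=initial, confirmed_peaks=confirmed)
    return call, Stratification(gene_id, cohort_label, labels)


def analyze_cohort(matrix: ExpressionMatrix, config: DetectionConfig):
    """Apply :func:`analyze_gene` to every gene of a cohort matrix."""
    if matrix.shape[0] == 0:
        raise ValueError("empty expression matrix")
    calls, strats = [], []
    for gi, gene_id in enumerate(matrix.gene_ids):
        call, strat = analyze_gene(gene_id, matrix.values[gi],
                                   matrix.sample_ids, config,
                                   cohort_label=matrix.cohort_label)
        calls.append(call)
        if strat is not None:
            strats.append(strat)
    counts = Counter(c.status for c in calls)
    logger.info("cohort %s: %s", matrix.cohort_label, dict(counts))
    return calls, strats


@dataclass
class CohortSummary:
    per_cohort_counts: dict            # cohort_label -> n bimodal genes
    multi_cohort_genes: list           # [(gene_id, n_cohorts)], n >= 2, desc
    gene_cohort_counts: dict = field(default_factory=dict)


def cross_cohort_summary(calls_by_cohort: dict) -> CohortSummary:
    """Count bimodal genes per cohort and list multi-cohort bimodal genes."""
    if not calls_by_cohort:
        raise ValueError("at least one cohort required")
    per_cohort = {}
    gene_counts: Counter = Counter()
    for cohort, calls in calls_by_cohort.items():
        seen = set()
        for c in calls:
            key = (c.gene_id, cohort)
            if key in seen:
                raise ValueError(f"duplicate call for {key}")
            seen.add(key)
        bimodal = [c.gene_id for c in calls if c.status == STATUS_BIMODAL]
        per_cohort[cohort] = len(bimodal)
        gene_counts.update(bimodal)
    multi = sorted(((g, n) for g, n in gene_counts.items() if n >= 2),
                   key=lambda t: (-t[1], t[0]))
    return CohortSummary(per_cohort, multi, dict(gene_counts))


def chromosome_bias_test(foreground_genes, background_genes, chrom_map,
                         target_chrom: str):
    """Hypergeometric test for chromosome enrichment in a gene list.

    Upper-tail probability of drawing at least the observed number of
    ``target_chrom`` genes when sampling ``len(foreground)`` genes without
    replacement from the background.  Returns
    ``(observed, expected, p_value)``.
    """
    fg = list(dict.fromkeys(foreground_genes))
    bg = list(dict.fromkeys(background_genes))
    if not fg:
        raise ValueError("empty foreground gene list")
    bg_set = set(bg)
    for g in fg:
        if g not in bg_set:
            raise ValueError(f"foreground gene {g!r} not in background")
        if g not in chrom_map:
            raise ValueError(f"no chromosome annotation for gene {g!r}")
    M = len(bg)
    K = sum(1 for g in bg if chrom_map.get(g) == target_chrom)
    N = len(fg)
    observed = sum(1 for g in fg if chrom_map[g] == target_chrom)
    expected = N * K / M
    p = float(hypergeom.sf(observed - 1, M, K, N))
    return observed, expected, p
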