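"""Univariate Gaussian mixture fitting and sample stratification filters.

Second step of the bimodality screen.  Given ``k`` detected peaks, a mixture
of ``k + 1`` Gaussians (unequal variances) is fit by expectation–maximization:
the extra component absorbs samples with low affinity to the main clusters.
Samples are then filtered by three rules before peak confirmation:

* samples in the extra (k+1-th) cluster are discarded;
* samples whose assignment reliability — the maximum posterior probability —
  is not above ``min_posterior`` (default 0.46) are discarded;
* whole clusters holding fewer than ``min_cluster_frac`` (default 10%) of the
  samples are discarded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class MixtureFit:
    """A fitted univariate Gaussian mixture, components sorted by mean."""

    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    log_likelihood: float
    log_likelihood_trace: np.ndarray
    n_iter: int
    converged: bool

    @property
    def n_components(self) -> int:
        return len(self.weights)

    @property
    def components(self) -> list[tuple[float, float, float]]:
        return [(float(w), float(m), float(v))
                for w, m, v in zip(self.weights, self.means, self.variances)]


@dataclass(frozen=True)
class SampleAssignment:
    sample_id: str
    component_index: int
    posterior: float          # reliability = max posterior = 1 − uncertainty
    posteriors: np.ndarray    # full posterior vector over components


def _log_gauss(x: np.ndarray, mean: float, var: float) -> np.ndarray:
    return -0.5 * (_LOG_2PI + np.log(var) + (x - mean) ** 2 / var)


def _log_resp(x, weights, means, variances):
    """Log joint per component and log-evidence per sample."""
    lj = np.stack([np.log(w) + _log_gauss(x, m, v)
                   for w, m, v in zip(weights, means, variances)], axis=1)
    m = lj.max(axis=1, keepdims=True)
    log_norm = m[:, 0] + np.log(np.exp(lj - m).sum(axis=1))
    return lj, log_norm


def fit_univariate_gmm(values, n_components: int, seed: int | None = None,
                       tol: float = 1e-6, max_iter: int = 500,
                       n_restarts: int = 0) -> MixtureFit:
    """Fit a univariate unequal-variance Gaussian mixture by EM.

    Initialization is deterministic: component means at evenly spaced
    quantiles of the data, equal weights, pooled variance.  Optional
    ``n_restarts`` adds seeded random-jitter restarts and returns the fit with
    the best log-likelihood.  Variances are floored at ``1e-6·var(values)`` to
    prevent component collapse; convergence is a relative log-likelihood
    change below ``tol``.
    """
    x = np.asarray(values, dtype=float)
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if x.size < n_components:
        raise ValueError(
            f"n_components={n_components} exceeds sample size {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    total_var = float(np.var(x))
    if total_var == 0.0:
        raise ValueError("all values identical; mixture is undefined")
    var_floor = 1e-6 * total_var

    if n_components == 1:
        mean = float(np.mean(x))
        var = max(total_var, var_floor)
        ll = float(_log_gauss(x, mean, var).sum())
        return MixtureFit(np.array([1.0]), np.array([mean]), np.array([var]),
                          ll, np.array([ll]), n_iter=0, converged=True)

    qs = np.linspace(0, 100, n_components + 2)[1:-1]
    base_means = np.percentile(x, qs)
    rng = np.random.default_rng(seed)
    inits = [base_means]
    for _ in range(n_restarts):
        inits.append(base_means + rng.normal(0, np.sqrt(total_var), n_components))

    best: MixtureFit | None = None
    for init_means in inits:
        fit = _em(x, np.sort(init_means), total_var, var_floor, tol, max_iter)
        if best is None or fit.log_likelihood > best.log_likelihood:
            best = fit
    assert best is not None
    return best


def _em(x, means, total_var, var_floor, tol, max_iter) -> MixtureFit:
    k = len(means)
    weights = np.full(k, 1.0 / k)
    variances = np.full(k, total_var)
    trace = []
    converged = False
    n_iter = 0
    prev_ll = -np.inf
    for n_iter in range(1, max_iter + 1):
        lj, log_norm = _log_resp(x, weights, means, variances)
        resp = np.exp(lj - log_norm[:, None])
        ll = float(log_norm.sum())
        trace.append(ll)
        if prev_ll > -np.inf and abs(ll - prev_ll) <= tol * abs(prev_ll):
            converged = True
            break
        prev_ll = ll
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        weights = nk / x.size
        means = (resp * x[:, None]).sum(axis=0) / nk
        variances = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        variances = np.maximum(variances, var_floor)

    order = np.argsort(means)
    return MixtureFit(weights[order], means[order], variances[order],
                      trace[-1], np.asarray(trace), n_iter, converged)


def posterior_assignments(fit: MixtureFit, values, sample_ids) -> list[SampleAssignment]:
    """Bayes-rule posterior responsibilities and hard argmax labels."""
    x = np.asarray(values, dtype=float)
    ids = list(sample_ids)
    if x.size != len(ids):
        raise ValueError("values and sample_ids must have equal length")
    _, log_norm = _log_resp(x, fit.weights, fit.means, fit.variances)
    lj, _ = _log_resp(x, fit.weights, fit.means, fit.variances)
    post = np.exp(lj - log_norm[:, None])
    out = []
    for sid, p in zip(ids, post):
        j = int(np.argmax(p))
        out.append(SampleAssignment(sid, j, float(p[j]), p))
    return out


def match_components_to_peaks(fit: MixtureFit, peak_locations) -> dict[int, int]:
    """Greedy nearest-mean matching of detected peaks to fitted components.

    Closest (component, peak) pairs are matched first, without replacement.
    Returns ``{component_index: peak_index}``; exactly one component — the one
    explaining no peak — is left out and plays the role of the extra
    "cluster k+1" whose samples are discarded.
    """
    peaks = list(peak_locations)
    if fit.n_components != len(peaks) + 1:
        raise ValueError(
            f"mixture has {fit.n_components} components but expected "
            f"{len(peaks) + 1} (k+1) for k={len(peaks)} peaks")
    pairs = sorted(
        ((abs(fit.means[c] - p), c, j)
         for c in range(fit.n_components) for j, p in enumerate(peaks)),
        key=lambda t: (t[0], t[1], t[2]))
    matched: dict[int, int] = {}
    used_peaks: set[int] = set()
    for _, c, j in pairs:
        if c in matched or j in used_peaks:
            continue
        matched[c] = j
        used_peaks.add(j)
    return matched


def select_retained_samples(assignments, fit: MixtureFit, peak_locations,
                            min_posterior: float = 0.46,
                            min_cluster_frac: float = 0.10,
                            n_total: int | None = None):
    """Apply the extra-cluster, reliability, and cluster-size filters.

    Returns ``(retained, discarded)`` where ``retained`` maps sample_id to the
    matched peak index (0 = lower peak) and ``discarded`` is a list of
    ``(sample_id, reason)`` with reason in {extra_cluster, low_reliability,
    small_cluster}.  Retention requires posterior strictly above
    ``min_posterior``; matched clusters smaller than
    ``min_cluster_frac × n_total`` are dropped wholesale.
    """
    matched = match_components_to_peaks(fit, peak_locations)
    if n_total is None:
        n_total = len(assignments)

    by_component: dict[int, list] = {c: [] for c in range(fit.n_components)}
    for a in assignments:
        by_component[a.component_index].append(a)

    retained: dict[str, int] = {}
    discarded: list[tuple[str, str]] = []
    for c, members in by_component.items():
        if c not in matched:
            discarded.extend((a.sample_id, "extra_cluster") for a in members)
            continue
        if len(members) < min_cluster_frac * n_total:
            discarded.extend((a.sample_id, "small_cluster") for a in members)
            continue
        for a in members:
            if a.posterior > min_posterior:
                retained[a.sample_id] = matched[c]
            else:
                discarded.append((a.sample_id, "low_reliability"))
    return retained, discarded
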