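"""Replication significance of docking-success changes.

When two protocols are compared on a benchmark, some inputs flip between
success and failure.  To ask whether K flips could be explained by sampling
noise alone, the probability that mere resampling flips an input's outcome
is estimated by drawing subsamples from each input's model pool, and the
number of observed flips is tested against a one-tailed binomial null:
P(X >= K) with n inputs and per-input flip probability p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

from .ranking import ModelRecord, select_and_rank, success_metrics
from .structure import WaterdockError


@dataclass
class ReplicationTable:
    """Machine form of a replication-significance row."""

    n_trials: int
    flip_probability: float
    k_changed: int
    p_value: float


def binomial_tail(n: int, p: float, k: int) -> float:
    """Exact one-tailed binomial P(X >= k), summed in log space.

    Log-space summation keeps tails of order 1e-10 and below accurate; no
    normal approximation is used.
    """
    if not (0.0 <= p <= 1.0):
        raise WaterdockError(f"probability out of range: {p}")
    if k < 0 or k > n + 1:
        raise WaterdockError(f"k={k} outside [0, n+1]")
    if k <= 0:
        return 1.0
    if k == n + 1:
        return 0.0
    if p == 0.0:
        return 0.0
    if p == 1.0:
        return 1.0
    ks = np.arange(k, n + 1)
    log_terms = (
        gammaln(n + 1)
        - gammaln(ks + 1)
        - gammaln(n - ks + 1)
        + ks * np.log(p)
        + (n - ks) * np.log1p(-p)
    )
    return float(np.exp(logsumexp(log_terms)))


def _subsample_success(
    pool: list[ModelRecord], indices: np.ndarray, top_frac: float
) -> bool:
    sub = [pool[i] for i in indices]
    cut = max(1, int(round(top_frac * len(sub))))
    ranked = select_and_rank(sub, n_total_cut=cut)
    return success_metrics(ranked)["top1_success"]


def resampling_probabilities(
    pools: dict[str, list[ModelRecord]],
    subsample_size: int,
    n_draws: int = 500,
    rng: np.random.Generator | None = None,
    top_frac: float = 0.1,
) -> tuple[float, float]:
    """Estimate (P(fail | full-pool success), P(success | full-pool failure)).

    For each input, ``n_draws`` subsamples of ``subsample_size`` models are
    drawn without replacement; a subsample succeeds when its top model by
    interface score (after a ``top_frac`` total-score cut, the 1000->100
    rule rescaled) has RMSD under 2 A.  Flip frequencies are aggregated over
    inputs by the full pool's outcome class.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    fail_given_success = []
    success_given_failure = []
    for name in sorted(pools):
        pool = pools[name]
        if len(pool) < subsample_size:
            import warnings

            warnings.warn(f"pool {name!r} smaller than subsample size; skipped")
            continue
        cut = max(1, int(round(top_frac * len(pool))))
        full_success = success_metrics(select_and_rank(pool, cut))["top1_success"]
        flips = 0
        for _ in range(n_draws):
            idx = rng.choice(len(pool), size=subsample_size, replace=False)
            if _subsample_success(pool, idx, top_frac) != full_success:
                flips += 1
        rate = flips / n_draws
        if full_success:
            fail_given_success.append(rate)
        else:
            success_given_failure.append(rate)
    p_fs = float(np.mean(fail_given_success)) if fail_given_success else 0.0
    p_sf = float(np.mean(success_given_failure)) if success_given_failure else 0.0
    return p_fs, p_sf


def significance_report(
    n_successes: int,
    n_failures: int,
    p_fail: float,
    p_success: float,
    k_sf: int,
    k_fs: int,
) -> tuple[ReplicationTable, ReplicationTable]:
    """Binomial tails for successes-becoming-failures and the reverse."""
    if k_sf > n_successes or k_fs > n_failures:
        raise WaterdockError("flip count exceeds trial count")
    return (
        ReplicationTable(
            n_successes, p_fail, k_sf, binomial_tail(n_successes, p_fail, k_sf)
        ),
        ReplicationTable(
            n_failures, p_success, k_fs, binomial_tail(n_failures, p_success, k_fs)
        ),
    )
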