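"""Depth normalisation and within-sample diversity statistics.

Samples are normalised to a common sequencing depth (default 2,883 reads,
without replacement); richness is summarised by the observed cluster count
and the Chao1 estimator, evenness by the Shannon index (natural log), and
sampling curves by the analytic hypergeometric rarefaction expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln


@dataclass
class CountVector:
    """Cluster read counts for one sample at one clustering threshold."""

    counts: dict[str, int]

    def __post_init__(self):
        self.counts = {k: int(v) for k, v in self.counts.items() if v > 0}

    @property
    def N(self) -> int:
        return sum(self.counts.values())

    @property
    def S_obs(self) -> int:
        return len(self.counts)

    @property
    def F1(self) -> int:
        return sum(1 for v in self.counts.values() if v == 1)

    @property
    def F2(self) -> int:
        return sum(1 for v in self.counts.values() if v == 2)

    def values(self) -> np.ndarray:
        return np.array([self.counts[k] for k in sorted(self.counts)], dtype=int)


def subsample(
    cv: CountVector, depth: int = 2883, rng: np.random.Generator | None = None
) -> CountVector | None:
    """Draw ``depth`` reads without replacement; ``None`` if the sample is
    too shallow (mirroring the exclusion of under-sequenced samples)."""
    if rng is None:
        rng = np.random.default_rng()
    if cv.N < depth:
        return None
    if cv.N == depth:
        return CountVector(dict(cv.counts))
    keys = sorted(cv.counts)
    drawn = rng.multivariate_hypergeometric([cv.counts[k] for k in keys], depth)
    return CountVector({k: int(d) for k, d in zip(keys, drawn) if d > 0})


def mixed_sample(
    subsampled: list[CountVector], depth: int = 2883,
    rng: np.random.Generator | None = None,
) -> CountVector:
    """Pool equal-depth subsamples and draw ``depth`` reads from the pool.

    With ten inputs at depth 2,883 the pool holds 28,830 reads before the
    draw.  Requires at least two inputs, each exactly at ``depth``.
    """
    if len(subsampled) < 2:
        raise ValueError("mixed sample needs at least two subsampled inputs")
    for cv in subsampled:
        if cv.N != depth:
            raise ValueError("all inputs must be subsampled to the target depth")
    pooled: dict[str, int] = {}
    for cv in subsampled:
        for k, v in cv.counts.items():
            pooled[k] = pooled.get(k, 0) + v
    if rng is None:
        rng = np.random.default_rng()
    return subsample(CountVector(pooled), depth, rng)


def chao1(cv: CountVector, bias_corrected: bool = True) -> float:
    """Chao1 richness estimate from singleton/doubleton counts.

    Default is the bias-corrected form S_obs + F1(F1-1) / (2(F2+1)), defined
    for F2 = 0; the classic form S_obs + F1^2 / (2 F2) is available
    (returning S_obs when F1 = 0).
    """
    S, F1, F2 = cv.S_obs, cv.F1, cv.F2
    if bias_corrected:
        return S + F1 * (F1 - 1) / (2.0 * (F2 + 1))
    if F1 == 0:
        return float(S)
    if F2 == 0:
        return S + F1 * (F1 - 1) / 2.0  # fall back to bias-corrected term
    return S + F1 * F1 / (2.0 * F2)


def shannon(cv: CountVector) -> float:
    """Shannon diversity H = -sum p_i ln p_i (natural log)."""
    if cv.N == 0:
        return 0.0
    p = cv.values() / cv.N
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def rarefy_expectation(cv: CountVector, n: int) -> float:
    """Expected richness in a subsample of size ``n`` (hypergeometric form).

    E[S_n] = sum_i [1 - C(N - N_i, n) / C(N, n)], evaluated stably with
    log-gamma.  E[S_0] = 0 and E[S_N] = S_obs.
    """
    N = cv.N
    if not 0 <= n <= N:
        raise ValueError(f"subsample size {n} outside [0, {N}]")
    if n == 0:
        return 0.0
    Ni = cv.values().astype(float)
    rest = N - Ni
    with np.errstate(invalid="ignore"):
        log_num = gammaln(rest + 1) - gammaln(rest - n + 1)
        log_den = gammaln(N + 1) - gammaln(N - n + 1)
        ratio = np.where(rest >= n, np.exp(log_num - log_den), 0.0)
    return float(np.sum(1.0 - ratio))


def rarefaction_curve(cv: CountVector, n_points: int = 50) -> pd.DataFrame:
    """Analytic rarefaction curve as (n, E_Sn) points up to the full depth."""
    ns = np.unique(np.linspace(0, cv.N, n_points + 1).astype(int))
    return pd.DataFrame(
        {"n": ns, "E_Sn": [rarefy_expectation(cv, int(n)) for n in ns]}
    )


def diversity_row(cv: CountVector) -> dict:
    return {
        "N": cv.N,
        "S_obs": cv.S_obs,
        "F1": cv.F1,
        "F2": cv.F2,
        "chao1": chao1(cv),
        "shannon": shannon(cv),
    }
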