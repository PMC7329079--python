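"""Single-chain MCMC convergence diagnostics applied per reaction.

Four diagnostics, each with the conventional pass/fail threshold:

* Raftery–Lewis: dependence factor ``I = (M_warm_est + N_max) / N_min``;
  chains with ``I > 5`` are flagged as highly autocorrelated.
* Geweke: Z-score comparing the mean of the first 10% against the last 50%
  of the chain, with spectral-density standard errors; fails when |Z| > 1.28.
* Interval-based PSRF (IPSRF): the first and last thirds are treated as two
  "parallel" chains; the width of the pooled central 80% interval divided by
  the mean within-segment width; fails outside (0.9, 1.1).
* Hellinger distance between kernel density estimates of the first and last
  thirds; fails when HD > 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .deterministic_samplers import Chain

__all__ = [
    "DiagnosticReport",
    "raftery_lewis",
    "geweke",
    "ipsrf",
    "hellinger",
    "convergence_summary",
    "RL_THRESHOLD",
    "GEWEKE_THRESHOLD",
    "IPSRF_BOUNDS",
    "HD_THRESHOLD",
]

RL_THRESHOLD = 5.0
GEWEKE_THRESHOLD = 1.28
IPSRF_BOUNDS = (0.9, 1.1)
HD_THRESHOLD = 0.1

_TESTS = ("rl", "geweke", "ipsrf", "hd")


@dataclass
class DiagnosticReport:
    """Per-reaction diagnostic values, pass/fail flags and failure proportions."""

    values: pd.DataFrame  # one row per reaction, columns per statistic
    failed: pd.DataFrame  # boolean flags, one column per test
    failure_proportions: dict[str, float]
    not_evaluable: dict[str, int] = field(default_factory=dict)
    algorithm: str = ""

    def failed_reactions(self, test: str) -> list[str]:
        col = self.failed[test]
        return list(col.index[col.fillna(False)])


# ---------------------------------------------------------------------------
# Raftery–Lewis


def _binary_markov_bic(z: np.ndarray) -> float:
    """BIC-style statistic comparing a 2nd- vs 1st-order Markov fit of a 0/1
    chain; >= 0 means the 2nd-order model is preferred (chain too dependent)."""
    n = len(z) - 2
    tran = np.zeros((2, 2, 2))
    for t in range(n):
        tran[z[t], z[t + 1], z[t + 2]] += 1.0
    g2 = 0.0
    for i in range(2):
        for j in range(2):
            for k in range(2):
                if tran[i, j, k] == 0:
                    continue
                fitted = np.sum(tran[i, j, :]) * np.sum(tran[:, j, k]) / np.sum(tran[:, j, :])
                g2 += 2.0 * tran[i, j, k] * np.log(tran[i, j, k] / fitted)
    return g2 - 2.0 * np.log(n)


def raftery_lewis(
    x: np.ndarray,
    q: float = 0.025,
    r: float = 0.005,
    s: float = 0.95,
    epsilon: float = 0.001,
) -> tuple[float, float, int, float]:
    """Raftery–Lewis run-length diagnostic for estimating the q-quantile to
    within +/- r with probability s.

    Returns ``(M_warm_est, N_max, N_min, I)``.  The chain is dichotomised at
    its empirical q-quantile; the thinning step k is the smallest for which a
    first-order Markov chain is preferred (BIC) over a second-order one; the
    two-state transition rates then give the burn-in and run-length estimates
    from the standard spectral formulas, and
    ``N_min = ceil(Phi^-1((s+1)/2)^2 q(1-q) / r^2)``.
    """
    x = np.asarray(x, float)
    phi = stats.norm.ppf(0.5 * (1.0 + s))
    n_min = int(np.ceil(q * (1.0 - q) * phi**2 / r**2))
    if len(x) < n_min:
        raise ValueError(f"chain of length {len(x)} is shorter than N_min={n_min} for (q={q}, r={r}, s={s})")
    if np.ptp(x) == 0:
        raise ValueError("constant chain: quantile dichotomisation undefined")
    cut = np.quantile(x, q)
    dichot = (x <= cut).astype(np.int64)

    kthin = 1
    while True:
        z = dichot[::kthin]
        if len(z) < 3 or _binary_markov_bic(z) < 0:
            break
        kthin += 1
    z = dichot[::kthin]

    # two-state transition rates of the thinned binary chain
    from_ = z[:-1]
    to = z[1:]
    t00 = np.sum((from_ == 0) & (to == 0))
    t01 = np.sum((from_ == 0) & (to == 1))
    t10 = np.sum((from_ == 1) & (to == 0))
    t11 = np.sum((from_ == 1) & (to == 1))
    n0 = t00 + t01
    n1 = t10 + t11
    if n0 == 0 or n1 == 0:
        # the chain never leaves one state at this thinning: treat as iid limit
        alpha = beta = 0.5
    else:
        alpha = t01 / n0  # P(0 -> 1)
        beta = t10 / n1  # P(1 -> 0)
        alpha = min(max(alpha, 1e-12), 1 - 1e-12)
        beta = min(max(beta, 1e-12), 1 - 1e-12)

    absum = alpha + beta
    m_est = np.log(epsilon * absum / max(alpha, beta)) / np.log(abs(1.0 - absum)) if abs(1.0 - absum) not in (0.0, 1.0) else 1.0
    m_warm = float(np.ceil(max(m_est, 0.0)) * kthin)
    n_post = (2.0 - absum) * alpha * beta * phi**2 / (absum**3 * r**2)
    n_max = float(np.ceil(n_post) * kthin)
    dependence = (m_warm + n_max) / n_min
    return m_warm, n_max, n_min, float(dependence)


# ---------------------------------------------------------------------------
# Geweke


def _spectrum0_ar(x: np.ndarray) -> float:
    """Spectral density at frequency zero by an AIC-selected AR fit,
    normalised per observation (variance of the sample mean ~ s0 / n)."""
    from statsmodels.tsa.ar_model import AutoReg, ar_select_order

    x = np.asarray(x, float)
    n = len(x)
    if np.var(x) == 0:
        raise ValueError("zero-variance segment")
    maxlag = min(int(10 * np.log10(n)), n // 2 - 1, 30)
    order = None
    if maxlag >= 1:
        try:
            sel = ar_select_order(x, maxlag=maxlag, ic="aic", old_names=False)
            order = sel.ar_lags
        except Exception:
            order = None
    if not order:
        return float(np.var(x, ddof=1))
    res = AutoReg(x, lags=len(order), old_names=False).fit()
    sigma2 = np.sum(res.resid**2) / len(res.resid)
    rho_sum = np.sum(res.params[1:])
    denom = (1.0 - rho_sum) ** 2
    if denom < 1e-12:
        denom = 1e-12
    return float(sigma2 / denom)


def geweke(x: np.ndarray, frac1: float = 0.1, frac2: float = 0.5) -> float:
    """Geweke Z-score between the first ``frac1`` and last ``frac2`` of the
    chain, with AR-spectral standard errors of the segment means."""
    x = np.asarray(x, float)
    n = len(x)
    n1 = int(np.floor(frac1 * n))
    n2 = int(np.floor(frac2 * n))
    if n1 < 10 or n2 < 10:
        raise ValueError("segments must contain at least 10 samples each")
    b1 = x[:n1]
    b2 = x[n - n2:]
    if np.var(b1) == 0 or np.var(b2) == 0:
        raise ValueError("zero-variance segment: Geweke Z undefined")
    var1 = _spectrum0_ar(b1) / n1
    var2 = _spectrum0_ar(b2) / n2
    return float((np.mean(b1) - np.mean(b2)) / np.sqrt(var1 + var2))


# ---------------------------------------------------------------------------
# IPSRF


def ipsrf(x: np.ndarray, interval_prob: float = 0.8) -> float:
    """Interval-based potential scale reduction factor on a single chain.

    First and last thirds act as two parallel chains.  The statistic is the
    width of the pooled central ``interval_prob`` interval divided by the mean
    of the two within-segment interval widths.
    """
    x = np.asarray(x, float)
    third = len(x) // 3
    if third < 20:
        raise ValueError("each third must contain at least 20 samples")
    seg1 = x[:third]
    seg2 = x[-third:]
    lo = (1.0 - interval_prob) / 2.0
    hi = 1.0 - lo
    w1 = np.quantile(seg1, hi) - np.quantile(seg1, lo)
    w2 = np.quantile(seg2, hi) - np.quantile(seg2, lo)
    if w1 == 0 and w2 == 0:
        raise ValueError("zero within-segment interval widths")
    pooled = np.concatenate([seg1, seg2])
    wp = np.quantile(pooled, hi) - np.quantile(pooled, lo)
    return float(wp / (0.5 * (w1 + w2)))


# ---------------------------------------------------------------------------
# Hellinger distance


def _silverman_bw(x: np.ndarray) -> float:
    n = len(x)
    sd = np.std(x, ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    scale = min(sd, iqr / 1.349) if iqr > 0 else sd
    return 0.9 * scale * n ** (-0.2)


def hellinger(x: np.ndarray) -> float:
    """Hellinger distance between KDEs of the first and last thirds.

    ``HD = sqrt(1/2 * int (sqrt(p1) - sqrt(p3))^2 dv)``, evaluated by adaptive
    quadrature on the union support extended by 3 bandwidths, clipped to
    [0, 1].  A zero-variance segment is a point mass: returns 1 with a warning.
    """
    import warnings

    x = np.asarray(x, float)
    third = len(x) // 3
    if third < 50:
        raise ValueError("each third must contain at least 50 samples")
    seg1 = x[:third]
    seg3 = x[-third:]
    if np.var(seg1) == 0 or np.var(seg3) == 0:
        if np.array_equal(seg1, seg3):
            return 0.0
        warnings.warn("degenerate segment (zero variance); Hellinger distance set to 1", stacklevel=2)
        return 1.0
    k1 = stats.gaussian_kde(seg1, bw_method="silverman")
    k3 = stats.gaussian_kde(seg3, bw_method="silverman")
    bw = max(_silverman_bw(seg1), _silverman_bw(seg3))
    lo = min(seg1.min(), seg3.min()) - 3.0 * bw
    hi = max(seg1.max(), seg3.max()) + 3.0 * bw

    def integrand(v):
        p1 = max(float(k1(v)[0]), 1e-300)
        p3 = max(float(k3(v)[0]), 1e-300)
        return (np.sqrt(p1) - np.sqrt(p3)) ** 2

    val, _ = integrate.quad(integrand, lo, hi, epsabs=1e-8, limit=200)
    return float(np.clip(np.sqrt(0.5 * val), 0.0, 1.0))


# ---------------------------------------------------------------------------
# Per-chain summary


def convergence_summary(
    chain: Chain,
    tests: tuple[str, ...] = _TESTS,
    rl_settings: tuple[float, float, float] = (0.025, 0.005, 0.95),
    interval_prob: float = 0.8,
) -> DiagnosticReport:
    """Apply the selected diagnostics to every reaction of a chain.

    Per-reaction errors are recorded as not-evaluable and excluded from the
    failure proportions.
    """
    tests = tuple(tests)
    if not tests:
        raise ValueError("empty test selection")
    unknown = set(tests) - set(_TESTS)
    if unknown:
        raise ValueError(f"unknown tests {sorted(unknown)}; choose from {_TESTS}")

    X = chain.samples
    ids = chain.reaction_ids
    values: dict[str, dict[str, float]] = {rid: {} for rid in ids}
    failed: dict[str, dict[str, object]] = {rid: {} for rid in ids}
    not_evaluable = {t: 0 for t in tests}

    for j, rid in enumerate(ids):
        x = X[:, j]
        if "rl" in tests:
            try:
                m_warm, n_max, n_min, dep = raftery_lewis(x, *rl_settings)
                values[rid].update(
                    {"rl_M_warm_est": m_warm, "rl_N_max": n_max, "rl_N_min": n_min, "rl_I": dep}
                )
                failed[rid]["rl"] = dep > RL_THRESHOLD
            except ValueError:
                not_evaluable["rl"] += 1
                failed[rid]["rl"] = None
        if "geweke" in tests:
            try:
                z = geweke(x)
                values[rid]["geweke_Z"] = z
                failed[rid]["geweke"] = abs(z) > GEWEKE_THRESHOLD
            except ValueError:
                not_evaluable["geweke"] += 1
                failed[rid]["geweke"] = None
        if "ipsrf" in tests:
            try:
                v = ipsrf(x, interval_prob)
                values[rid]["ipsrf"] = v
                failed[rid]["ipsrf"] = not (IPSRF_BOUNDS[0] < v < IPSRF_BOUNDS[1])
            except ValueError:
                not_evaluable["ipsrf"] += 1
                failed[rid]["ipsrf"] = None
        if "hd" in tests:
            try:
                h = hellinger(x)
                values[rid]["hd"] = h
                failed[rid]["hd"] = h > HD_THRESHOLD
            except ValueError:
                not_evaluable["hd"] += 1
                failed[rid]["hd"] = None

    values_df = pd.DataFrame.from_dict(values, orient="index")
    failed_df = pd.DataFrame.from_dict(failed, orient="index")[list(tests)]
    proportions = {}
    for t in tests:
        col = failed_df[t]
        evaluable = col.notna()
        proportions[t] = float(col[evaluable].astype(bool).mean()) if evaluable.any() else float("nan")
    return DiagnosticReport(
        values=values_df,
        failed=failed_df,
        failure_proportions=proportions,
        not_evaluable=not_evaluable,
        algorithm=chain.algorithm,
    )
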