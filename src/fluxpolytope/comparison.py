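"""Cross-algorithm consistency and efficiency statistics.

Two chains over the same reactions are compared by: per-reaction sample
means/SDs and their Pearson correlation across reactions (after removing
reactions whose mean or SD difference exceeds 2 SD of that difference);
per-reaction Kullback-Leibler divergence between kernel density estimates,
classified as good (< 0.05), medium (0.05–0.5) or poor (> 0.5) agreement;
and per-reaction effective sample size (ESS) with the efficiency
``E = ESS / runtime`` (independent samples per second).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .deterministic_samplers import Chain

__all__ = [
    "ComparisonReport",
    "chain_moments",
    "pearson_with_outliers",
    "kld",
    "kld_class",
    "autocorr",
    "ess",
    "efficiency",
    "compare_chains",
    "KLD_GOOD",
    "KLD_POOR",
]

KLD_GOOD = 0.05
KLD_POOR = 0.5


@dataclass
class ComparisonReport:
    """Cross-algorithm summary for one (reference, other) chain pair."""

    reference: str
    other: str
    per_reaction: pd.DataFrame  # means/sds for both, KLD + class, ESS for both
    r_means: float
    r_sds: float
    outliers: list[str]
    outlier_proportion: float
    efficiency: pd.DataFrame | None = None
    extra: dict = field(default_factory=dict)


def chain_moments(chain: Chain) -> tuple[np.ndarray, np.ndarray]:
    """Per-reaction sample means and SDs (1/(M-1) denominator)."""
    if chain.M < 2:
        raise ValueError("need at least two samples")
    return chain.samples.mean(axis=0), chain.samples.std(axis=0, ddof=1)


def _outlier_mask(ref: np.ndarray, other: np.ndarray) -> np.ndarray:
    # deviation from the mean difference, so a systematic offset between two
    # algorithms (e.g. shrinkage) does not flag every reaction
    diff = ref - other
    sd = np.std(diff, ddof=1)
    if sd == 0:
        return np.zeros(len(diff), bool)
    return np.abs(diff - diff.mean()) > 2.0 * sd


def pearson_with_outliers(
    summary_ref: tuple[np.ndarray, np.ndarray],
    summary_other: tuple[np.ndarray, np.ndarray],
    reaction_ids: list[str] | None = None,
) -> tuple[float, float, list]:
    """Pearson r of per-reaction means and SDs between two algorithms,
    omitting the union of mean- and SD-outliers (difference beyond 2 SD of
    the across-reaction differences).

    Returns ``(r_means, r_sds, outlier_ids)``.
    """
    mean_ref, sd_ref = (np.asarray(a, float) for a in summary_ref)
    mean_oth, sd_oth = (np.asarray(a, float) for a in summary_other)
    if mean_ref.shape != mean_oth.shape:
        raise ValueError("summaries must cover the same reactions")
    n = len(mean_ref)
    if reaction_ids is None:
        reaction_ids = list(range(n))
    out = _outlier_mask(mean_ref, mean_oth) | _outlier_mask(sd_ref, sd_oth)
    keep = ~out
    if np.sum(keep) < 3:
        raise ValueError("fewer than 3 reactions remain after outlier removal")

    def _r(a, b):
        if np.std(a[keep]) == 0 or np.std(b[keep]) == 0:
            return 1.0 if np.allclose(a[keep], b[keep]) else float("nan")
        return float(stats.pearsonr(a[keep], b[keep])[0])

    return _r(mean_ref, mean_oth), _r(sd_ref, sd_oth), [reaction_ids[i] for i in np.nonzero(out)[0]]


def kld(samples_ref: np.ndarray, samples_other: np.ndarray) -> tuple[float, str]:
    """KL divergence ``KLD(p2 | p1) = int ln(p1/p2) p1`` between KDEs, with
    the reference density p1 weighting the integral, plus the agreement class.

    Integration runs over the reference-sample range extended by 3 bandwidths;
    p2 is floored at 1e-12 of its maximum so stray support mismatches yield a
    large but finite divergence.
    """
    x1 = np.asarray(samples_ref, float)
    x2 = np.asarray(samples_other, float)
    if len(x1) < 50 or len(x2) < 50:
        raise ValueError("need at least 50 samples per side")
    if np.var(x1) == 0:
        raise ValueError("degenerate reference sample")
    k1 = stats.gaussian_kde(x1, bw_method="silverman")
    k2 = stats.gaussian_kde(x2, bw_method="silverman") if np.var(x2) > 0 else None
    bw = np.sqrt(k1.covariance[0, 0])
    lo, hi = x1.min() - 3.0 * bw, x1.max() + 3.0 * bw
    grid = np.linspace(lo, hi, 2048)
    p1 = np.maximum(k1(grid), 0.0)
    if k2 is None:
        p2 = np.zeros_like(grid)
    else:
        p2 = np.maximum(k2(grid), 0.0)
    floor = max(p2.max(), 1e-300) * 1e-12
    p2 = np.maximum(p2, floor)
    with np.errstate(divide="ignore", invalid="ignore"):
        integrand = np.where(p1 > 0, p1 * np.log(np.maximum(p1, 1e-300) / p2), 0.0)
    val = float(integrate.trapezoid(integrand, grid))
    val = max(val, 0.0)  # numeric floor; KLD is nonnegative
    return val, kld_class(val)


def kld_class(value: float) -> str:
    if value < KLD_GOOD:
        return "good"
    if value <= KLD_POOR:
        return "medium"
    return "poor"


def autocorr(x: np.ndarray, k: int) -> float:
    """Lag-k autocorrelation with 1/(M-k) numerator and 1/M denominator
    normalisation."""
    x = np.asarray(x, float)
    M = len(x)
    if not 0 <= k < M:
        raise ValueError("lag must satisfy 0 <= k < M")
    xc = x - x.mean()
    denom = np.dot(xc, xc) / M
    if denom == 0:
        raise ValueError("constant chain")
    num = np.dot(xc[: M - k], xc[k:]) / (M - k)
    return float(num / denom)


def ess(x: np.ndarray) -> float:
    """Effective sample size ``M / (1 + 2 sum_k rho_k)`` with the
    autocorrelation sum truncated at the first non-positive lag
    (initial-positive-sequence rule); clipped to (0, M]."""
    x = np.asarray(x, float)
    M = len(x)
    if M < 10:
        raise ValueError("need at least 10 samples")
    xc = x - x.mean()
    denom = np.dot(xc, xc) / M
    if denom == 0:
        return float(M)
    # FFT autocovariance, then renormalise to the 1/(M-k) numerator convention
    nfft = int(2 ** np.ceil(np.log2(2 * M)))
    f = np.fft.rfft(xc, nfft)
    acov_sums = np.fft.irfft(f * np.conjugate(f), nfft)[:M].real  # sum_l xc_l xc_{l+k}
    lags = np.arange(M)
    rho = (acov_sums / (M - lags)) / denom
    total = 0.0
    for k in range(1, M):
        if rho[k] <= 0:
            break
        total += rho[k]
    value = M / (1.0 + 2.0 * total)
    return float(np.clip(value, np.finfo(float).tiny, M))


def efficiency(ess_values: np.ndarray, runtime_seconds: float) -> tuple[np.ndarray, float]:
    """Per-reaction efficiency ``E = ESS / runtime`` plus the time (seconds)
    to generate 100 independent samples, ``100 * runtime / mean(ESS)``."""
    if runtime_seconds <= 0:
        raise ValueError("runtime must be positive")
    ess_values = np.asarray(ess_values, float)
    E = ess_values / runtime_seconds
    time_to_100 = 100.0 * runtime_seconds / float(np.mean(ess_values))
    return E, time_to_100


def compare_chains(
    ref: Chain,
    other: Chain,
    geweke_flags: dict[str, bool] | None = None,
    sd_quantile_cap: float | None = None,
) -> ComparisonReport:
    """Full consistency/efficiency comparison of two chains.

    Only reactions present in both chains enter.  Reactions failing the
    Geweke test in either chain (``geweke_flags``) are flagged in the output
    but kept in the moment scatter data.  ``sd_quantile_cap`` optionally
    restricts the SD correlation to reactions below that SD quantile of the
    reference (e.g. 0.99).
    """
    common = [rid for rid in ref.reaction_ids if rid in set(other.reaction_ids)]
    if len(common) < 1:
        raise ValueError("chains share no reactions")
    i_ref = [ref.reaction_ids.index(r) for r in common]
    i_oth = [other.reaction_ids.index(r) for r in common]
    Xr = ref.samples[:, i_ref]
    Xo = other.samples[:, i_oth]

    mean_r, sd_r = Xr.mean(axis=0), Xr.std(axis=0, ddof=1)
    mean_o, sd_o = Xo.mean(axis=0), Xo.std(axis=0, ddof=1)

    keep_sd = np.ones(len(common), bool)
    if sd_quantile_cap is not None:
        keep_sd = sd_r <= np.quantile(sd_r, sd_quantile_cap)

    r_means, r_sds, outliers = pearson_with_outliers(
        (mean_r, sd_r * np.where(keep_sd, 1.0, np.nan)),
        (mean_o, sd_o * np.where(keep_sd, 1.0, np.nan)),
        common,
    ) if sd_quantile_cap is None else _pearson_capped(mean_r, sd_r, mean_o, sd_o, keep_sd, common)

    rows = {}
    for j, rid in enumerate(common):
        k, cls = kld(Xr[:, j], Xo[:, j])
        rows[rid] = {
            "mean_ref": mean_r[j],
            "mean_other": mean_o[j],
            "sd_ref": sd_r[j],
            "sd_other": sd_o[j],
            "kld": k,
            "kld_class": cls,
            "ess_ref": ess(Xr[:, j]),
            "ess_other": ess(Xo[:, j]),
            "geweke_failed": bool(geweke_flags.get(rid, False)) if geweke_flags else False,
            "outlier": rid in set(outliers),
        }
    per_reaction = pd.DataFrame.from_dict(rows, orient="index")

    eff = None
    if ref.runtime_seconds > 0 and other.runtime_seconds > 0:
        E_ref, t100_ref = efficiency(per_reaction["ess_ref"].to_numpy(), ref.runtime_seconds)
        E_oth, t100_oth = efficiency(per_reaction["ess_other"].to_numpy(), other.runtime_seconds)
        eff = pd.DataFrame(
            {"E_ref": E_ref, "E_other": E_oth}, index=per_reaction.index
        )
        eff.attrs["time_to_100_ref"] = t100_ref
        eff.attrs["time_to_100_other"] = t100_oth

    return ComparisonReport(
        reference=ref.algorithm,
        other=other.algorithm,
        per_reaction=per_reaction,
        r_means=r_means,
        r_sds=r_sds,
        outliers=outliers,
        outlier_proportion=len(outliers) / len(common),
        efficiency=eff,
    )


def _pearson_capped(mean_r, sd_r, mean_o, sd_o, keep_sd, ids):
    r_means, _, out_means = pearson_with_outliers((mean_r, mean_r), (mean_o, mean_o), ids)
    _, r_sds, out_sds = pearson_with_outliers(
        (mean_r[keep_sd], sd_r[keep_sd]),
        (mean_o[keep_sd], sd_o[keep_sd]),
        [i for i, k in zip(ids, keep_sd) if k],
    )
    outliers = sorted(set(out_means) | set(out_sds))
    return r_means, r_sds, outliers
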