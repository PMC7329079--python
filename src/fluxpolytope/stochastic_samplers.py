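"""Samplers for the stochastic formulation of flux analysis.

Two stochastic models are supported:

* **Linear inverse problem** (mirror-Metropolis): the steady state
  ``S v = 0`` holds exactly, optional flux measurements enter as
  ``A v = b + eps`` with ``eps ~ N(0, Sigma)``.  In null-space coordinates the
  target is the truncated Gaussian
  ``p(u) ∝ exp(-1/2 (A G u - b)' Sigma^-1 (A G u - b))`` on the bound box;
  with no measurements this degenerates to the uniform distribution on the
  polytope.  Proposals are Gaussian random walks; points leaving the box are
  reflected ("mirrored") across each violated bounding hyperplane in turn.

* **Bayesian relaxed steady state** (Gibbs): the steady state is softened to
  ``S v = beta``, ``beta ~ N(0, Gamma)``, combined with a Gaussian flux prior
  and optional measurements.  Standard Gaussian conjugacy gives the posterior
  ``N(mu, C)`` truncated to the flux bounds; the Gibbs sampler whitens
  ``v = mu + L w`` (``C = L L'``) and cyclically redraws each whitened
  coordinate from its one-dimensional truncated-normal conditional.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.linalg import cholesky, solve_triangular

from .deterministic_samplers import Chain
from .model_io import MetabolicModel
from .polytope import FluxPolytope

__all__ = [
    "MeasurementSet",
    "TMVNSpec",
    "mirror_sample",
    "build_tmvn_posterior",
    "gibbs_tmvn_sample",
    "default_jump_lengths",
]

_REFLECTION_CAP = 10_000


@dataclass(frozen=True)
class MeasurementSet:
    """Measured fluxes: selector diagonal ``a``, data ``b`` and noise variances.

    ``a[i] == 1`` iff flux i is measured; ``sigma2[i]`` is the measurement
    noise variance for measured fluxes (ignored elsewhere).
    """

    a: np.ndarray
    b: np.ndarray
    sigma2: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "a", np.asarray(self.a, float))
        object.__setattr__(self, "b", np.asarray(self.b, float))
        object.__setattr__(self, "sigma2", np.asarray(self.sigma2, float))
        if not set(np.unique(self.a)) <= {0.0, 1.0}:
            raise ValueError("selector diagonal must be 0/1")
        if self.a.shape != self.b.shape or self.a.shape != self.sigma2.shape:
            raise ValueError("a, b, sigma2 must share one shape")
        measured = self.a == 1.0
        if np.any(self.sigma2[measured] <= 0):
            raise ValueError("measurement variances must be positive where measured")
        if not np.all(np.isfinite(self.b[measured])):
            raise ValueError("measured values must be finite")

    @property
    def n_measured(self) -> int:
        return int(np.sum(self.a))


@dataclass(frozen=True)
class TMVNSpec:
    """A truncated multivariate normal target N(mu, C) on [v_lb, v_ub]."""

    mu: np.ndarray
    C: np.ndarray
    L: np.ndarray
    v_lb: np.ndarray
    v_ub: np.ndarray
    gamma: np.ndarray | None = None
    prior_var: np.ndarray | None = None
    reaction_ids: list[str] | None = None

    def __post_init__(self) -> None:
        for name in ("mu", "C", "L", "v_lb", "v_ub"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        n = self.mu.shape[0]
        if self.C.shape != (n, n):
            raise ValueError("C must be n x n")
        if not np.allclose(self.C, self.C.T, atol=1e-8 * max(1.0, np.abs(self.C).max())):
            raise ValueError("C must be symmetric")
        if not np.allclose(self.L @ self.L.T, self.C, atol=1e-6 * max(1.0, np.abs(self.C).max())):
            raise ValueError("L L' must reproduce C")
        if np.any(self.v_lb > self.v_ub):
            raise ValueError("v_lb must not exceed v_ub")

    @property
    def n(self) -> int:
        return self.mu.shape[0]


def default_jump_lengths(v_lb: np.ndarray, v_ub: np.ndarray, scale: float = 0.5) -> np.ndarray:
    """Jump lengths ``scale * (v_ub - v_lb)`` (the customary 0.5, or 0.01 for
    the conservative variant)."""
    return scale * (np.asarray(v_ub, float) - np.asarray(v_lb, float))


def _mirror_into(A: np.ndarray, b: np.ndarray, u: np.ndarray) -> np.ndarray | None:
    """Reflect u across violated hyperplanes of ``A u <= b`` in index order,
    re-checking after each reflection; None when the cap is exceeded."""
    row_norm2 = np.einsum("ij,ij->i", A, A)
    for _ in range(_REFLECTION_CAP):
        resid = A @ u - b
        viol = np.nonzero(resid > 0)[0]
        if viol.size == 0:
            return u
        i = viol[0]
        u = u - 2.0 * resid[i] / row_norm2[i] * A[i]
    return None


def mirror_sample(
    poly: FluxPolytope,
    meas: MeasurementSet | None = None,
    jump: np.ndarray | float | None = None,
    M: int = 1000,
    thinning: int = 1,
    seed: int = 0,
) -> Chain:
    """Mirror-Metropolis sampling of the linear-inverse-problem target.

    ``jump`` holds the per-coordinate proposal standard deviations in u-space
    (diagonal of Omega); a scalar is broadcast.  Defaults to 0.5 times the
    u-space chord span through the anchor per coordinate.
    """
    d = poly.dim
    rng = np.random.default_rng(seed)
    if jump is None:
        # span of the polytope along each u-axis through the anchor
        from .polytope import chord_extent

        spans = np.empty(d)
        for j in range(d):
            e = np.zeros(d)
            e[j] = 1.0
            lo, hi = chord_extent(poly, poly.anchor, e)
            spans[j] = hi - lo
        jump = 0.5 * spans
    jump = np.broadcast_to(np.asarray(jump, float), (d,)).copy()
    if np.any(jump <= 0):
        raise ValueError("jump lengths must be positive")

    if meas is not None and meas.n_measured > 0:
        measured = meas.a == 1.0
        Gm = poly.G[measured, :]
        bm = meas.b[measured]
        w = 1.0 / meas.sigma2[measured]

        def neg_half_quad(u):
            r = Gm @ u - bm
            return -0.5 * np.dot(r * w, r)

    else:

        def neg_half_quad(u):
            return 0.0

    u = np.array(poly.anchor, float)
    logp = neg_half_quad(u)
    out = np.empty((M, d))
    kept = it = 0
    n_prop = n_capped = 0
    t0 = time.perf_counter()
    while kept < M:
        prop = u + jump * rng.standard_normal(d)
        n_prop += 1
        prop = _mirror_into(poly.A_ineq, poly.b_ineq, prop)
        if prop is None:
            n_capped += 1
            if n_capped > 10 and n_capped > 0.01 * n_prop:
                raise RuntimeError(
                    "more than 1% of proposals exceeded the reflection cap; "
                    "use smaller jump lengths"
                )
            warnings.warn("proposal exceeded the reflection cap; rejected", stacklevel=2)
        else:
            logp_prop = neg_half_quad(prop)
            # mirrored proposals are treated as symmetric (reflections are isometries)
            if logp_prop - logp >= 0 or rng.uniform() < np.exp(logp_prop - logp):
                u, logp = prop, logp_prop
        it += 1
        if it % thinning == 0:
            out[kept] = u
            kept += 1
    runtime = time.perf_counter() - t0
    return Chain(
        samples=poly.to_fluxes(out),
        algorithm="mirror",
        reaction_ids=list(poly.reaction_ids),
        M=M,
        M_warm=0,
        thinning=thinning,
        seed=seed,
        runtime_seconds=runtime,
        extra={"u_samples": out, "reflection_capped": n_capped, "proposals": n_prop},
    )


def _closest_to_zero_in_box(v_lb: np.ndarray, v_ub: np.ndarray) -> np.ndarray:
    return np.clip(0.0, v_lb, v_ub)


def build_tmvn_posterior(
    model: MetabolicModel,
    meas: MeasurementSet | None = None,
    gamma: float | np.ndarray = 1e-4,
    prior_cap: float = 1000.0,
    prior_var: np.ndarray | None = None,
) -> TMVNSpec:
    """Gaussian-conjugacy posterior of the relaxed-steady-state model.

    Prior ``v ~ N(m0, diag(prior_var))`` with m0 the closest point to zero in
    the bounds and ``prior_var = (min(0.5 (v_ub - v_lb), prior_cap))**2``
    unless given; likelihoods ``S v ~ N(0, Gamma)`` and, if measurements are
    present, ``A v ~ N(b, Sigma)``.  Then

        C  = (diag(prior_var)^-1 + S' Gamma^-1 S + A' Sigma^-1 A)^-1
        mu = C (diag(prior_var)^-1 m0 + A' Sigma^-1 b)

    The Cholesky factor is computed with jitter escalation; persistent
    indefiniteness suggests smaller prior variances (a tighter ``prior_cap``).
    """
    n, m = model.n, model.m
    gamma = np.broadcast_to(np.asarray(gamma, float), (m,))
    if np.any(gamma <= 0):
        raise ValueError("gamma must be positive")
    if prior_var is None:
        prior_var = np.minimum(0.5 * (model.v_ub - model.v_lb), prior_cap) ** 2
        prior_var = np.maximum(prior_var, 1e-12)  # fixed fluxes get a tiny slab
    prior_var = np.asarray(prior_var, float)
    if np.any(prior_var <= 0):
        raise ValueError("prior variances must be positive")

    m0 = _closest_to_zero_in_box(model.v_lb, model.v_ub)
    precision = np.diag(1.0 / prior_var) + model.S.T @ (model.S / gamma[:, None])
    rhs = m0 / prior_var
    if meas is not None and meas.n_measured > 0:
        measured = meas.a == 1.0
        w = np.zeros(n)
        w[measured] = 1.0 / meas.sigma2[measured]
        precision[np.diag_indices(n)] += w
        rhs = rhs + np.where(measured, meas.b * w, 0.0)

    C = np.linalg.inv(precision)
    C = (C + C.T) / 2.0
    mu = C @ rhs
    L = _chol_with_jitter(C)
    return TMVNSpec(
        mu=mu,
        C=C,
        L=L,
        v_lb=model.v_lb,
        v_ub=model.v_ub,
        gamma=gamma,
        prior_var=prior_var,
        reaction_ids=list(model.reaction_ids),
    )


def _chol_with_jitter(C: np.ndarray) -> np.ndarray:
    n = C.shape[0]
    jitter = 0.0
    base = np.trace(C) / n
    for k in range(8):
        try:
            return cholesky(C + jitter * np.eye(n), lower=True)
        except np.linalg.LinAlgError:
            jitter = base * 10.0 ** (k - 12)
    raise np.linalg.LinAlgError(
        "posterior covariance numerically indefinite even with jitter "
        f"{jitter:.1e}; use smaller prior variances (lower prior_cap)"
    )


def _truncnorm_draw(rng: np.random.Generator, lo: float, hi: float) -> float:
    """One standard-normal draw truncated to [lo, hi], inverse-CDF with
    log-space tail handling for far tails."""
    if not lo < hi:
        raise ValueError("empty interval")
    if lo > 6.0 or hi < -6.0:
        # far tail: work in the tail's own coordinates via truncnorm logcdf math
        a, b = (lo, hi) if lo > 0 else (-hi, -lo)
        x = stats.truncnorm.rvs(a, b, random_state=rng)
        return float(x if lo > 0 else -x)
    plo = stats.norm.cdf(lo)
    phi = stats.norm.cdf(hi)
    if phi - plo < 1e-14:
        return float(np.clip(0.5 * (lo + hi), lo, hi))
    u = rng.uniform(plo, phi)
    return float(np.clip(stats.norm.ppf(u), lo, hi))


def gibbs_tmvn_sample(
    spec: TMVNSpec,
    M: int = 1000,
    thinning: int = 1,
    seed: int = 0,
) -> Chain:
    """Gibbs sampling of TMVN(mu, C, v_lb, v_ub) by Cholesky whitening.

    With ``v = mu + L w`` the box constraints become per-sweep linear
    constraints on each whitened coordinate; each full sweep redraws
    ``w_j | w_{-j}`` from a 1-D truncated standard normal.  The chain starts
    from the posterior mode projected into the box (no warm-up is used).
    Every ``thinning``-th sweep is kept.
    """
    n = spec.n
    L = spec.L
    rng = np.random.default_rng(seed)

    v0 = np.clip(spec.mu, spec.v_lb, spec.v_ub)
    # strictly interior start where possible, so conditionals are nonempty
    width = spec.v_ub - spec.v_lb
    inner = np.where(width > 0, np.minimum(1e-9, 0.45 * width), 0.0)
    v0 = np.clip(v0, spec.v_lb + inner, spec.v_ub - inner)
    w = solve_triangular(L, v0 - spec.mu, lower=True)

    out = np.empty((M, n))
    kept = 0
    sweeps = 0
    n_empty = 0
    n_draws = 0
    t0 = time.perf_counter()
    Lv = L  # alias
    partial = spec.mu + Lv @ w  # current v
    while kept < M:
        for j in range(n):
            col = Lv[:, j]
            nz = np.nonzero(np.abs(col) > 1e-300)[0]
            base = partial - col * w[j]
            lo, hi = -np.inf, np.inf
            for i in nz:
                lo_i = (spec.v_lb[i] - base[i]) / col[i]
                hi_i = (spec.v_ub[i] - base[i]) / col[i]
                if col[i] < 0:
                    lo_i, hi_i = hi_i, lo_i
                lo = max(lo, lo_i)
                hi = min(hi, hi_i)
            n_draws += 1
            if not lo < hi:
                n_empty += 1
                if n_empty > 100 and n_empty > 0.01 * n_draws:
                    raise RuntimeError(
                        "more than 1% of conditional intervals were empty; "
                        "the posterior may be numerically degenerate"
                    )
                continue  # keep current value
            w[j] = _truncnorm_draw(rng, lo, hi)
            partial = base + col * w[j]
        sweeps += 1
        if sweeps % thinning == 0:
            out[kept] = np.clip(partial, spec.v_lb, spec.v_ub)
            kept += 1
    runtime = time.perf_counter() - t0
    return Chain(
        samples=out,
        algorithm="gibbs",
        reaction_ids=list(spec.reaction_ids or [f"v{j}" for j in range(n)]),
        M=M,
        M_warm=0,
        thinning=thinning,
        seed=seed,
        runtime_seconds=runtime,
        extra={"empty_conditionals": n_empty},
    )
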