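"""Synthetic inputs with analytic ground truth for every pipeline stage.

Generators cover: the two-flux toy network (one metabolite, input flux equals
output flux, so the polytope is a line segment); random sparse stoichiometries
with a feasibility certificate; axis-aligned box and simplex polytopes with
known uniform moments (including anisotropic boxes for rounding studies);
stationary AR(1) chains for diagnostic calibration; and exact
rejection-sampled draws from low-dimensional truncated multivariate normals
as an oracle for the Gibbs sampler.

Every generator is seed-deterministic, and ground truth is attached to the
returned object rather than recomputed downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_io import MetabolicModel
from .polytope import FluxPolytope
from .stochastic_samplers import TMVNSpec

__all__ = [
    "GroundTruth",
    "make_two_flux_model",
    "make_random_network",
    "make_box_polytope",
    "make_simplex_polytope",
    "make_ar1",
    "rejection_tmvn",
]


@dataclass(frozen=True)
class GroundTruth:
    """Analytic facts about a generated object (uniform-sampling moments,
    feasible-set geometry, certificates)."""

    mean: np.ndarray | None = None
    var: np.ndarray | None = None
    description: str = ""
    extras: dict = field(default_factory=dict)


def make_two_flux_model(
    lb: tuple[float, float] = (0.0, 0.0),
    ub: tuple[float, float] = (10.0, 10.0),
) -> MetabolicModel:
    """One metabolite fed by v1 and drained by v2: S = [1, -1].

    The steady-state set is the segment v1 = v2 over the intersection of the
    two bound intervals; under uniform sampling each flux is uniform there.
    """
    lb = np.asarray(lb, float)
    ub = np.asarray(ub, float)
    return MetabolicModel(
        S=np.array([[1.0, -1.0]]),
        v_lb=lb,
        v_ub=ub,
        reaction_ids=["v1", "v2"],
        metabolite_ids=["x1"],
        name="two_flux",
    )


def make_random_network(
    m: int, n: int, density: float = 0.4, seed: int = 0
) -> tuple[MetabolicModel, np.ndarray]:
    """Random sparse integer stoichiometry with guaranteed feasibility.

    Entries are drawn from {-2, -1, 1, 2}.  A random interior flux ``v*`` in
    the null space certifies feasibility: bounds are set to ``v* -/+`` random
    positive widths.  Returns ``(model, v_star)``.
    """
    if not (n > m >= 1):
        raise ValueError("need n > m >= 1")
    if density <= 0 or density > 1:
        raise ValueError("density must be in (0, 1]")
    rng = np.random.default_rng(seed)
    for _ in range(200):
        S = np.zeros((m, n))
        mask = rng.uniform(size=(m, n)) < density
        # every metabolite needs at least two incident reactions to balance
        for i in range(m):
            while mask[i].sum() < 2:
                mask[i, rng.integers(n)] = True
        S[mask] = rng.choice([-2.0, -1.0, 1.0, 2.0], size=int(mask.sum()))
        if np.linalg.matrix_rank(S) == m:
            break
    else:
        raise RuntimeError("failed to draw a full-rank stoichiometry")
    from scipy.linalg import null_space

    G = null_space(S)
    v_star = G @ rng.standard_normal(G.shape[1])
    widths_lo = rng.uniform(0.5, 2.0, size=n)
    widths_hi = rng.uniform(0.5, 2.0, size=n)
    model = MetabolicModel(
        S=S,
        v_lb=v_star - widths_lo,
        v_ub=v_star + widths_hi,
        reaction_ids=[f"r{j}" for j in range(n)],
        metabolite_ids=[f"m{i}" for i in range(m)],
        name=f"random_{m}x{n}",
    )
    return model, v_star


def _free_polytope(A: np.ndarray, b: np.ndarray, anchor: np.ndarray, ids: list[str]) -> FluxPolytope:
    d = A.shape[1]
    return FluxPolytope(G=np.eye(d), A_ineq=A, b_ineq=b, anchor=anchor, reaction_ids=ids)


def make_box_polytope(side_lengths) -> tuple[FluxPolytope, GroundTruth]:
    """Axis-aligned box ``[0, s_1] x ... x [0, s_d]`` as a FluxPolytope
    (identity flux map, so u- and flux-space coincide).

    Ground truth for uniform sampling: mean ``s/2``, variance ``s^2/12``.
    Side ratios up to 1e5 emulate severely anisotropic flux polytopes; the
    analytic sandwiching ratio (circumscribed over inscribed ball radius) is
    attached.
    """
    s = np.asarray(side_lengths, float)
    if s.ndim != 1 or s.size == 0:
        raise ValueError("side_lengths must be a nonempty 1-D vector")
    if np.any(s <= 0):
        raise ValueError("sides must be positive")
    d = len(s)
    A = np.vstack([np.eye(d), -np.eye(d)])
    b = np.concatenate([s, np.zeros(d)])
    poly = _free_polytope(A, b, s / 2.0, [f"u{j}" for j in range(d)])
    truth = GroundTruth(
        mean=s / 2.0,
        var=s**2 / 12.0,
        description=f"uniform box with sides {s.tolist()}",
        extras={"sandwiching_ratio": float(np.linalg.norm(s / 2.0) / (np.min(s) / 2.0))},
    )
    return poly, truth


def make_simplex_polytope(d: int, scale: float = 1.0) -> tuple[FluxPolytope, GroundTruth]:
    """Standard simplex ``{u >= 0, sum u <= scale}``.

    Uniform moments per coordinate: mean ``scale/(d+1)``, variance
    ``scale^2 d / ((d+1)^2 (d+2))``.
    """
    if d < 1:
        raise ValueError("dimension must be >= 1")
    if scale <= 0:
        raise ValueError("scale must be positive")
    A = np.vstack([-np.eye(d), np.ones((1, d))])
    b = np.concatenate([np.zeros(d), [scale]])
    anchor = np.full(d, scale / (2.0 * (d + 1)))
    poly = _free_polytope(A, b, anchor, [f"u{j}" for j in range(d)])
    mean = scale / (d + 1.0)
    var = scale**2 * d / ((d + 1.0) ** 2 * (d + 2.0))
    truth = GroundTruth(
        mean=np.full(d, mean),
        var=np.full(d, var),
        description=f"uniform {d}-simplex scaled by {scale}",
    )
    return poly, truth


def make_ar1(M: int, phi: float, seed: int = 0) -> np.ndarray:
    """Stationary AR(1) chain with unit innovation variance and a stationary
    start (marginal variance ``1/(1-phi^2)``)."""
    if not abs(phi) < 1:
        raise ValueError("|phi| must be < 1 for stationarity")
    rng = np.random.default_rng(seed)
    x = np.empty(M)
    x[0] = rng.standard_normal() / np.sqrt(1.0 - phi**2)
    eps = rng.standard_normal(M - 1)
    for t in range(1, M):
        x[t] = phi * x[t - 1] + eps[t - 1]
    return x


def rejection_tmvn(spec: TMVNSpec, M: int, seed: int = 0, max_batches: int = 10_000) -> np.ndarray:
    """Exact TMVN draws by accept/reject from the untruncated Gaussian.

    Only viable in low dimension (<= 4) with acceptance probability >= 1e-4;
    heavier truncation should use the Gibbs sampler instead.
    """
    if spec.n > 4:
        raise ValueError("rejection oracle limited to dimension <= 4")
    rng = np.random.default_rng(seed)
    out = np.empty((M, spec.n))
    got = 0
    tried = 0
    batch = max(4 * M, 1000)
    for _ in range(max_batches):
        Z = rng.standard_normal((batch, spec.n))
        V = spec.mu + Z @ spec.L.T
        ok = np.all((V >= spec.v_lb) & (V <= spec.v_ub), axis=1)
        acc = V[ok]
        take = min(len(acc), M - got)
        out[got : got + take] = acc[:take]
        got += take
        tried += batch
        if got >= M:
            return out
        if tried >= 100 * M and got < 1e-4 * tried:
            break
    raise RuntimeError(
        "acceptance probability below 1e-4; rejection sampling infeasible — use the Gibbs sampler"
    )
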