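"""Uniform polytope samplers: HR, CHR, ACHR, OPTGP and CHRR.

All samplers walk in null-space (u) coordinates and emit flux-space chains.
The common protocol: discard ``M_warm`` warm-up iterations, then keep every
``thinning``-th state of the underlying chain until ``M`` samples are
collected (thinning counts iterations, never emitted samples).

* HR: direction uniform on the unit sphere, step uniform on the feasible
  chord.  Markovian; mixes slowly on anisotropic polytopes.
* CHR: HR with directions drawn from the coordinate axes.
* ACHR: after a sphere-direction warm-up, directions point from the running
  sample mean ("artificial center") to a uniformly chosen earlier iterate,
  which lengthens steps along elongated directions.  Non-Markovian.
* OPTGP: ACHR-style moves started from the 2n flux-variability optima,
  several short chains sharing one center, keeping every k-th state.
* CHRR: rounds the polytope to near-isotropy via the maximum-volume inscribed
  ellipsoid, runs CHR in rounded space, and maps samples back.  Markovian,
  so distributional convergence is guaranteed.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .model_io import MetabolicModel
from .polytope import FluxPolytope, chord_extent, round_polytope

__all__ = ["Chain", "hr_sample", "achr_sample", "optgp_sample", "chrr_sample"]

#: Bound-violation tolerance for emitted fluxes after back-transformation.
FEASIBILITY_EPS = 1e-6
#: Chords narrower than this trigger a direction redraw.
DEGENERATE_CHORD = 1e-14


@dataclass
class Chain:
    """An ordered block of flux samples with sampling metadata."""

    samples: np.ndarray  # (M, n) flux vectors
    algorithm: str
    reaction_ids: list[str]
    M: int
    M_warm: int = 0
    thinning: int = 1
    seed: int | None = None
    runtime_seconds: float = 0.0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, float)
        if self.samples.ndim != 2 or self.samples.shape[0] != self.M:
            raise ValueError("samples must be an (M, n) array")
        if self.samples.shape[1] != len(self.reaction_ids):
            raise ValueError("reaction_ids must match the sample columns")

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.samples, columns=self.reaction_ids)

    def marginal(self, reaction_id: str) -> np.ndarray:
        return self.samples[:, self.reaction_ids.index(reaction_id)]

    def write(self, directory, stem: str | None = None) -> None:
        """CSV of samples plus a JSON metadata sidecar."""
        import json
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        stem = stem or self.algorithm
        self.to_dataframe().to_csv(directory / f"{stem}.csv", index=False)
        meta = {
            "algorithm": self.algorithm,
            "M": self.M,
            "M_warm": self.M_warm,
            "thinning": self.thinning,
            "seed": self.seed,
            "runtime_seconds": self.runtime_seconds,
        }
        with open(directory / f"{stem}.json", "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def read(cls, directory, stem: str) -> "Chain":
        import json
        from pathlib import Path

        import pandas as pd

        directory = Path(directory)
        df = pd.read_csv(directory / f"{stem}.csv")
        with open(directory / f"{stem}.json") as fh:
            meta = json.load(fh)
        return cls(
            samples=df.to_numpy(),
            algorithm=meta["algorithm"],
            reaction_ids=list(df.columns),
            M=len(df),
            M_warm=meta.get("M_warm", 0),
            thinning=meta.get("thinning", 1),
            seed=meta.get("seed"),
            runtime_seconds=meta.get("runtime_seconds", 0.0),
        )


def _emit_loop(
    poly: FluxPolytope,
    u0: np.ndarray,
    M: int,
    thinning: int,
    rng: np.random.Generator,
    step_fn,
) -> np.ndarray:
    """Run ``M * thinning`` iterations of ``step_fn`` and keep every
    ``thinning``-th u-state."""
    u = np.array(u0, float)
    out = np.empty((M, poly.dim))
    kept = 0
    it = 0
    while kept < M:
        u = step_fn(u, it, rng)
        it += 1
        if it % thinning == 0:
            out[kept] = u
            kept += 1
    return out


def _sphere_direction(rng: np.random.Generator, d: int) -> np.ndarray:
    theta = rng.standard_normal(d)
    nrm = np.linalg.norm(theta)
    while nrm < DEGENERATE_CHORD:
        theta = rng.standard_normal(d)
        nrm = np.linalg.norm(theta)
    return theta / nrm


def _coordinate_direction(rng: np.random.Generator, d: int) -> np.ndarray:
    theta = np.zeros(d)
    theta[rng.integers(d)] = 1.0
    return theta


def _hr_step_factory(poly: FluxPolytope, direction_mode: str):
    draw = _sphere_direction if direction_mode == "sphere" else _coordinate_direction

    def step(u, it, rng):
        for attempt in range(100):
            theta = draw(rng, poly.dim)
            lam_min, lam_max = chord_extent(poly, u, theta)
            if lam_max - lam_min >= DEGENERATE_CHORD:
                lam = rng.uniform(lam_min, lam_max)
                return u + lam * theta
        warnings.warn("100 consecutive degenerate chords; point may sit on a face", stacklevel=2)
        return u

    return step


def hr_sample(
    poly: FluxPolytope,
    start: np.ndarray | None = None,
    M: int = 1000,
    thinning: int = 1,
    seed: int = 0,
    direction_mode: str = "sphere",
    M_warm: int = 0,
) -> Chain:
    """Hit-and-run (``direction_mode='sphere'``) or coordinate hit-and-run
    (``'coordinate'``) uniform sampling of the polytope."""
    if direction_mode not in ("sphere", "coordinate"):
        raise ValueError("direction_mode must be 'sphere' or 'coordinate'")
    if M < 1 or thinning < 1:
        raise ValueError("M and thinning must be >= 1")
    u = np.array(poly.anchor if start is None else start, float)
    if not poly.contains(u):
        raise ValueError("start point is not inside the polytope")
    rng = np.random.default_rng(seed)
    step = _hr_step_factory(poly, direction_mode)
    t0 = time.perf_counter()
    for it in range(M_warm):
        u = step(u, it, rng)
    U = _emit_loop(poly, u, M, thinning, rng, step)
    runtime = time.perf_counter() - t0
    name = "hr" if direction_mode == "sphere" else "chr"
    return Chain(
        samples=poly.to_fluxes(U),
        algorithm=name,
        reaction_ids=list(poly.reaction_ids),
        M=M,
        M_warm=M_warm,
        thinning=thinning,
        seed=seed,
        runtime_seconds=runtime,
        extra={"u_samples": U},
    )


def achr_sample(
    poly: FluxPolytope,
    start: np.ndarray | None = None,
    M: int = 1000,
    M_warm: int | None = None,
    thinning: int = 1,
    seed: int = 0,
    _warm_points: np.ndarray | None = None,
) -> Chain:
    """Artificial-centering hit-and-run.

    Warm-up uses sphere directions; afterwards the direction is the
    normalised difference between a uniformly chosen earlier iterate and the
    running mean of all iterates (the artificial center, initialised at the
    start point and updated by ``c <- (a c + u_a)/(a + 1)`` each iteration).
    """
    d = poly.dim
    if M_warm is None:
        M_warm = d
    if M_warm < d and _warm_points is None:
        raise ValueError(f"ACHR requires M_warm >= polytope dimension ({d})")
    u = np.array(poly.anchor if start is None else start, float)
    if not poly.contains(u):
        raise ValueError("start point is not inside the polytope")
    rng = np.random.default_rng(seed)
    t0 = time.perf_counter()

    center = u.copy()
    history: list[np.ndarray] = [u.copy()]
    a = 0

    def advance(u, warm):
        nonlocal center, a
        for attempt in range(100):
            if warm:
                theta = _sphere_direction(rng, d)
            else:
                for _ in range(100):
                    i = int(rng.integers(len(history)))
                    diff = history[i] - center
                    nrm = np.linalg.norm(diff)
                    if nrm >= DEGENERATE_CHORD:
                        break
                else:
                    theta = _sphere_direction(rng, d)
                    nrm = 1.0
                    diff = theta
                theta = diff / nrm
            lam_min, lam_max = chord_extent(poly, u, theta)
            if lam_max - lam_min >= DEGENERATE_CHORD:
                lam = rng.uniform(lam_min, lam_max)
                u = u + lam * theta
                break
        else:
            warnings.warn("100 consecutive degenerate chords in ACHR", stacklevel=2)
        a += 1
        center = (a * center + u) / (a + 1)
        history.append(u.copy())
        return u

    if _warm_points is not None:
        # OPTGP-style warm-up: seed the history with precomputed points.
        for p in _warm_points:
            history.append(np.asarray(p, float))
            a += 1
            center = (a * center + history[-1]) / (a + 1)
    else:
        for _ in range(M_warm):
            u = advance(u, warm=True)

    U = _emit_loop(poly, u, M, thinning, rng, lambda uu, it, rr: advance(uu, warm=False))
    runtime = time.perf_counter() - t0
    return Chain(
        samples=poly.to_fluxes(U),
        algorithm="achr",
        reaction_ids=list(poly.reaction_ids),
        M=M,
        M_warm=M_warm if _warm_points is None else len(_warm_points),
        thinning=thinning,
        seed=seed,
        runtime_seconds=runtime,
        extra={"u_samples": U},
    )


def _fva_warmup_points(poly: FluxPolytope, model: MetabolicModel) -> np.ndarray:
    """The 2n flux-variability optima projected to u-space and pulled 1e-6 of
    the way toward the Chebyshev center so they are strictly interior."""
    n = model.n
    d = poly.dim
    pts = np.empty((2 * n, d))
    bounds = list(zip(model.v_lb, model.v_ub))
    k = 0
    for j in range(n):
        for sense in (1.0, -1.0):
            c = np.zeros(n)
            c[j] = sense
            res = linprog(c, A_eq=model.S, b_eq=np.zeros(model.m), bounds=bounds, method="highs")
            if res.status != 0:
                raise RuntimeError(f"warm-up LP failed for reaction {model.reaction_ids[j]!r}: {res.message}")
            pts[k] = poly.G.T @ res.x
            k += 1
    shrink = 1e-6
    return (1 - shrink) * pts + shrink * poly.anchor


def optgp_sample(
    poly: FluxPolytope,
    model: MetabolicModel,
    M: int = 1000,
    n_chains: int = 4,
    k: int = 100,
    seed: int = 0,
) -> Chain:
    """OPTGP: ACHR-style chains from the 2n FVA optima, keeping every k-th point.

    ``n_chains`` short chains share the artificial center and the warm-up
    history; they are advanced with interleaved RNG streams (the contract is
    statistical, not concurrent).
    """
    if n_chains < 1 or k < 1:
        raise ValueError("n_chains and k must be >= 1")
    rng = np.random.default_rng(seed)
    t0 = time.perf_counter()
    warm = _fva_warmup_points(poly, model)
    d = poly.dim

    history = [w.copy() for w in warm]
    center = np.mean(warm, axis=0)
    a = len(history) - 1

    starts = [history[int(rng.integers(len(history)))].copy() for _ in range(n_chains)]
    states = [s.copy() for s in starts]

    def advance(u):
        nonlocal center, a
        for attempt in range(100):
            i = int(rng.integers(len(history)))
            diff = history[i] - center
            nrm = np.linalg.norm(diff)
            if nrm < DEGENERATE_CHORD:
                continue
            theta = diff / nrm
            lam_min, lam_max = chord_extent(poly, u, theta)
            if lam_max - lam_min >= DEGENERATE_CHORD:
                u = u + rng.uniform(lam_min, lam_max) * theta
                break
        else:
            warnings.warn("100 consecutive degenerate proposals in OPTGP", stacklevel=2)
        a += 1
        center = (a * center + u) / (a + 1)
        history.append(u.copy())
        return u

    U = np.empty((M, d))
    kept = 0
    counters = [0] * n_chains
    c_idx = 0
    while kept < M:
        states[c_idx] = advance(states[c_idx])
        counters[c_idx] += 1
        if counters[c_idx] % k == 0:
            U[kept] = states[c_idx]
            kept += 1
        c_idx = (c_idx + 1) % n_chains
    runtime = time.perf_counter() - t0
    return Chain(
        samples=poly.to_fluxes(U),
        algorithm="optgp",
        reaction_ids=list(poly.reaction_ids),
        M=M,
        M_warm=len(warm),
        thinning=k,
        seed=seed,
        runtime_seconds=runtime,
        extra={"u_samples": U, "n_chains": n_chains},
    )


def chrr_sample(
    poly: FluxPolytope,
    M: int = 1000,
    M_warm: int = 0,
    thinning: int = 1,
    seed: int = 0,
) -> Chain:
    """Coordinate hit-and-run with rounding.

    Rounds the polytope via the maximum-volume inscribed ellipsoid, runs CHR
    in the rounded space, and maps kept states back to u- and flux-space.
    Markovian, so convergence to the uniform target is guaranteed.
    """
    t0 = time.perf_counter()
    rounded, transform = round_polytope(poly)
    rng = np.random.default_rng(seed)
    step = _hr_step_factory(rounded, "coordinate")
    y = np.array(rounded.anchor, float)
    for it in range(M_warm):
        y = step(y, it, rng)
    Y = _emit_loop(rounded, y, M, thinning, rng, step)
    U = transform.to_original(Y)
    runtime = time.perf_counter() - t0
    return Chain(
        samples=poly.to_fluxes(U),
        algorithm="chrr",
        reaction_ids=list(poly.reaction_ids),
        M=M,
        M_warm=M_warm,
        thinning=thinning,
        seed=seed,
        runtime_seconds=runtime,
        extra={"u_samples": U, "log_det_T": transform.log_det_T},
    )


def check_chain_feasibility(
    chain: Chain, model: MetabolicModel, eps: float = FEASIBILITY_EPS
) -> None:
    """Validate the Chain invariant: bounds within eps and ||S v||_inf <= eps.

    Violations beyond eps on more than 0.1% of entries raise; smaller
    excursions are clipped in place and counted in ``chain.extra``.
    """
    V = chain.samples
    lo = model.v_lb - eps
    hi = model.v_ub + eps
    bad = np.sum((V < lo) | (V > hi))
    if bad > 0.001 * V.size:
        raise RuntimeError(f"{bad} of {V.size} flux entries violate bounds beyond {eps}")
    np.clip(V, model.v_lb, model.v_ub, out=V)
    resid = np.max(np.abs(V @ model.S.T)) if V.size else 0.0
    # clipping can only move points by <= eps per coordinate
    if resid > eps * (1 + np.abs(model.S).sum()):
        raise RuntimeError(f"steady-state residual {resid:.2e} exceeds tolerance")
    chain.extra["clipped_entries"] = int(bad)
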