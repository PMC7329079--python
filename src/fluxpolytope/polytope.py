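"""Null-space representation, chords and rounding of the flux polytope.

The steady-state set ``{v : S v = 0, v_lb <= v <= v_ub}`` lives inside the
null space of S.  With G an orthonormal null-space basis (n x d,
d = n - rank S) every steady-state flux is ``v = G u``, and the polytope
becomes the full-dimensional set ``{u : A u <= b}`` with
``A = [G; -G], b = [v_ub; -v_lb]``.  All line samplers operate on u; fluxes
are recovered via ``v = G u``.

Hit-and-run mixing degrades on anisotropic polytopes: the mixing time scales
with the squared sandwiching ratio R_s/R_b (circumscribed over inscribed ball
radius), which reaches 1e5 for genome-scale models.  Rounding fixes this by
computing the maximum-volume inscribed ellipsoid (MVE) ``{c + B y : |y| <= 1}``
and changing variables so the ellipsoid becomes the unit ball.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import null_space
from scipy.optimize import linprog, minimize

from .model_io import MetabolicModel

__all__ = [
    "FluxPolytope",
    "RoundingTransform",
    "nullspace_basis",
    "build_polytope",
    "chord_extent",
    "round_polytope",
    "chebyshev_center",
    "max_volume_ellipsoid",
    "sandwiching_ratio_estimate",
]

# Denominators below this magnitude in the chord ratio test count as parallel.
_PARALLEL_TOL = 1e-12


@dataclass(frozen=True)
class FluxPolytope:
    """Flux polytope in null-space (u) coordinates.

    Attributes
    ----------
    G : ndarray, shape (n, d)
        Map from u-space to flux space, ``v = G u``.  Orthonormal for
        polytopes built from a model; a general invertible composition after
        rounding.
    A_ineq, b_ineq : ndarray
        Inequalities ``A u <= b`` (2n rows: upper bounds then lower bounds).
    anchor : ndarray, shape (d,)
        Strictly interior point in u-space (Chebyshev center at build time).
    reaction_ids : list of str
    """

    G: np.ndarray
    A_ineq: np.ndarray
    b_ineq: np.ndarray
    anchor: np.ndarray
    reaction_ids: list[str]

    @property
    def dim(self) -> int:
        return self.G.shape[1]

    @property
    def n_reactions(self) -> int:
        return self.G.shape[0]

    def contains(self, u: np.ndarray, tol: float = 1e-9) -> bool:
        u = np.asarray(u, float)
        return bool(np.all(self.A_ineq @ u <= self.b_ineq + tol))

    def slack(self, u: np.ndarray) -> np.ndarray:
        return self.b_ineq - self.A_ineq @ np.asarray(u, float)

    def to_fluxes(self, u: np.ndarray) -> np.ndarray:
        """Map u-space points (d,) or (M, d) to flux space."""
        return np.asarray(u, float) @ self.G.T

    def save(self, path) -> None:
        """Serialize to a compressed matrix container (npz) for reuse."""
        np.savez_compressed(
            path,
            G=self.G,
            A_ineq=self.A_ineq,
            b_ineq=self.b_ineq,
            anchor=self.anchor,
            reaction_ids=np.array(self.reaction_ids),
        )

    @classmethod
    def load(cls, path) -> "FluxPolytope":
        with np.load(path, allow_pickle=False) as doc:
            return cls(
                G=doc["G"],
                A_ineq=doc["A_ineq"],
                b_ineq=doc["b_ineq"],
                anchor=doc["anchor"],
                reaction_ids=[str(r) for r in doc["reaction_ids"]],
            )


@dataclass(frozen=True)
class RoundingTransform:
    """Affine change of variables u = T y + shift used by rounding."""

    T: np.ndarray
    shift: np.ndarray
    log_det_T: float

    def to_original(self, y: np.ndarray) -> np.ndarray:
        return np.asarray(y, float) @ self.T.T + self.shift

    def to_rounded(self, u: np.ndarray) -> np.ndarray:
        return np.linalg.solve(self.T, (np.asarray(u, float) - self.shift).T).T


def nullspace_basis(S: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Orthonormal basis G of ``{v : S v = 0}`` via SVD.

    Rank is the number of singular values above ``tol * sigma_max``.
    Raises if the null space is trivial (the polytope is a point).
    """
    S = np.atleast_2d(np.asarray(S, float))
    if S.size == 0:
        raise ValueError("empty stoichiometric matrix")
    if not np.any(S):
        return np.eye(S.shape[1])
    G = null_space(S, rcond=tol)
    if G.shape[1] == 0:
        raise ValueError("trivial null space: the steady-state polytope is a single point")
    return G


def chebyshev_center(A: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, float]:
    """Center and radius of the largest ball inside ``{x : A x <= b}``.

    LP: maximise r subject to ``A x + r ||a_i|| <= b``.
    """
    A = np.atleast_2d(A)
    b = np.asarray(b, float)
    norms = np.linalg.norm(A, axis=1)
    d = A.shape[1]
    c = np.zeros(d + 1)
    c[-1] = -1.0
    A_ub = np.hstack([A, norms[:, None]])
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b,
        bounds=[(None, None)] * d + [(0, None)],
        method="highs",
    )
    if res.status != 0:
        raise ValueError(f"Chebyshev-center LP failed ({res.message}); polytope may be empty or unbounded")
    return res.x[:d], float(res.x[-1])


def build_polytope(model: MetabolicModel) -> FluxPolytope:
    """Null-space inequality representation of the model's flux polytope.

    Fixed fluxes (v_lb == v_ub) stay as a pair of tight inequalities; the
    interior requirement applies to the free subspace only, which the
    Chebyshev-center LP handles because tight rows have zero ball clearance in
    their normal direction only when the row is degenerate in u-space.
    """
    G = nullspace_basis(model.S)
    A = np.vstack([G, -G])
    b = np.concatenate([model.v_ub, -model.v_lb])
    # Drop rows with numerically zero normal (fluxes identically zero in the
    # null space): feasibility there is a constant check.
    norms = np.linalg.norm(A, axis=1)
    degenerate = norms < 1e-12
    if np.any(degenerate & (b < -1e-9)):
        raise ValueError("model infeasible: a zero-flux direction has a negative bound")
    A, b = A[~degenerate], b[~degenerate]
    center, radius = chebyshev_center(A, b)
    if radius <= 0:
        raise ValueError(
            "flux polytope has empty interior in null-space coordinates; "
            "run FVA reduction first to remove blocked/fixed reactions"
        )
    return FluxPolytope(G=G, A_ineq=A, b_ineq=b, anchor=center, reaction_ids=list(model.reaction_ids))


def chord_extent(
    poly: FluxPolytope, u: np.ndarray, theta: np.ndarray
) -> tuple[float, float]:
    """Extent ``[lambda_min, lambda_max]`` of the feasible chord through u.

    Ratio test over all inequality rows; rows with ``|a . theta|`` below
    1e-12 are parallel to the direction and impose no limit.
    """
    u = np.asarray(u, float)
    theta = np.asarray(theta, float)
    if np.linalg.norm(theta) < _PARALLEL_TOL:
        raise ValueError("zero direction")
    slack = poly.slack(u)
    if np.any(slack < -1e-9):
        raise ValueError("chord origin is outside the polytope")
    a_theta = poly.A_ineq @ theta
    lam_max = np.inf
    lam_min = -np.inf
    pos = a_theta > _PARALLEL_TOL
    neg = a_theta < -_PARALLEL_TOL
    if np.any(pos):
        lam_max = np.min(slack[pos] / a_theta[pos])
    if np.any(neg):
        lam_min = np.max(slack[neg] / a_theta[neg])
    # numerical slack can put the origin epsilon outside a face
    lam_max = max(lam_max, 0.0)
    lam_min = min(lam_min, 0.0)
    return float(lam_min), float(lam_max)


def _mve_box_exact(A: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray] | None:
    """Exact MVE when the rows of A are axis-aligned (a box): semi-axes are
    half the side lengths.  Returns None when not a box."""
    d = A.shape[1]
    lo = np.full(d, -np.inf)
    hi = np.full(d, np.inf)
    for a, bi in zip(A, b):
        nz = np.nonzero(np.abs(a) > 1e-14)[0]
        if len(nz) != 1:
            return None
        j = nz[0]
        if a[j] > 0:
            hi[j] = min(hi[j], bi / a[j])
        else:
            lo[j] = max(lo[j], bi / a[j])
    if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi))):
        return None
    c = (lo + hi) / 2.0
    B = np.diag((hi - lo) / 2.0)
    return c, B


def max_volume_ellipsoid(
    A: np.ndarray, b: np.ndarray, tol: float = 1e-10, max_iter: int = 400
) -> tuple[np.ndarray, np.ndarray]:
    """Maximum-volume inscribed ellipsoid ``{c + B y : |y| <= 1}`` of ``A x <= b``.

    Solved as a log-det maximisation over symmetric B subject to the support
    constraints ``a_i . c + |B a_i| <= b_i`` (SLSQP from the Chebyshev ball).
    Axis-aligned boxes short-circuit to the analytic solution.
    """
    A = np.atleast_2d(np.asarray(A, float))
    b = np.asarray(b, float)
    d = A.shape[1]
    exact = _mve_box_exact(A, b)
    if exact is not None:
        return exact
    center, radius = chebyshev_center(A, b)
    if not np.isfinite(radius) or radius <= 0:
        raise ValueError("polytope is empty or unbounded; cannot inscribe an ellipsoid")

    tri = np.tril_indices(d)

    def unpack(x):
        c = x[:d]
        Bl = np.zeros((d, d))
        Bl[tri] = x[d:]
        B = (Bl + Bl.T) / 2.0
        B[np.diag_indices(d)] = np.diag(Bl)
        return c, B

    def negloogdet(x):
        _, B = unpack(x)
        sign, logdet = np.linalg.slogdet(B)
        if sign <= 0:
            return 1e6
        return -logdet

    def cons_f(x):
        c, B = unpack(x)
        return b - A @ c - np.linalg.norm(A @ B, axis=1)

    x0 = np.concatenate([center, (radius * np.eye(d))[tri]])
    res = minimize(
        negloogdet,
        x0,
        method="SLSQP",
        constraints=[{"type": "ineq", "fun": cons_f}],
        options={"maxiter": max_iter, "ftol": tol},
    )
    c, B = unpack(res.x)
    # symmetrise and check PD
    B = (B + B.T) / 2.0
    w, V = np.linalg.eigh(B)
    if np.any(w <= 0):
        raise RuntimeError(f"MVE optimisation failed (non-PD result, status {res.status}: {res.message})")
    return c, B


def sandwiching_ratio_estimate(B: np.ndarray) -> float:
    """R_s/R_b estimate from MVE semi-axes: circumscribed-ball radius of the
    ellipsoid's bounding box diagonal over its smallest semi-axis."""
    s = np.linalg.svd(B, compute_uv=False)
    return float(np.sqrt(np.sum(s**2)) / np.min(s))


def round_polytope(poly: FluxPolytope) -> tuple[FluxPolytope, RoundingTransform]:
    """Affinely round the polytope so its MVE becomes the unit ball.

    Returns the rounded polytope in y-space and the transform ``u = B y + c``.
    The flux map of a y-space point is affine (``v = G B y + G c``), so map
    samples back to u with ``transform.to_original`` before calling
    ``to_fluxes`` on the original polytope.
    """
    c, B = max_volume_ellipsoid(poly.A_ineq, poly.b_ineq)
    sign, logdet = np.linalg.slogdet(B)
    transform = RoundingTransform(T=B, shift=c, log_det_T=float(logdet))
    rounded = FluxPolytope(
        G=poly.G,
        A_ineq=poly.A_ineq @ B,
        b_ineq=poly.b_ineq - poly.A_ineq @ c,
        anchor=np.zeros(poly.dim),
        reaction_ids=list(poly.reaction_ids),
    )
    return rounded, transform
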