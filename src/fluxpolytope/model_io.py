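"""Metabolic model input, flux-variability reduction and summary statistics.

A model is the pair (S, bounds): the m x n stoichiometric matrix S whose
entry ``S[i, j]`` is the signed stoichiometric coefficient of metabolite i in
reaction j, plus per-reaction flux bounds ``v_lb <= v <= v_ub`` (typically in
mmol gDW^-1 h^-1).  Reversible reactions keep signed bounds; they are never
split into forward/backward halves, so the steady-state solution set
``{v : S v = 0, v_lb <= v <= v_ub}`` is a polytope in signed flux space.

Before sampling, models are routinely tightened and pruned: flux variability
analysis (FVA) computes the achievable min/max flux of every reaction, the
bounds are replaced by those values, and reactions that cannot carry flux
(both extremes below a threshold in magnitude) are discarded.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import linprog

__all__ = [
    "MetabolicModel",
    "FvaResult",
    "load_model",
    "flux_variability",
    "reduce_model",
    "average_flux_range",
    "write_bigg_json",
]

#: Default bound magnitude used when a BiGG JSON reaction omits a bound.
DEFAULT_BOUND = 1000.0


@dataclass(frozen=True)
class MetabolicModel:
    """Stoichiometric matrix with flux bounds and identifiers.

    Attributes
    ----------
    S : ndarray, shape (m, n)
        Stoichiometric coefficients (metabolites x reactions).
    v_lb, v_ub : ndarray, shape (n,)
        Lower/upper flux bounds per reaction.
    reaction_ids, metabolite_ids : list of str
        Unique identifiers, aligned with the columns/rows of ``S``.
    """

    S: np.ndarray
    v_lb: np.ndarray
    v_ub: np.ndarray
    reaction_ids: list[str]
    metabolite_ids: list[str]
    name: str = "model"

    def __post_init__(self) -> None:
        S = np.atleast_2d(np.asarray(self.S, dtype=float))
        object.__setattr__(self, "S", S)
        object.__setattr__(self, "v_lb", np.asarray(self.v_lb, dtype=float))
        object.__setattr__(self, "v_ub", np.asarray(self.v_ub, dtype=float))
        m, n = S.shape
        if m < 1 or n < 1:
            raise ValueError("model must have at least one metabolite and one reaction")
        if self.v_lb.shape != (n,) or self.v_ub.shape != (n,):
            raise ValueError(f"bounds must have shape ({n},)")
        if len(self.reaction_ids) != n or len(set(self.reaction_ids)) != n:
            raise ValueError("reaction ids must be unique and match the number of columns")
        if len(self.metabolite_ids) != m or len(set(self.metabolite_ids)) != m:
            raise ValueError("metabolite ids must be unique and match the number of rows")
        if np.any(self.v_lb > self.v_ub):
            bad = [self.reaction_ids[j] for j in np.nonzero(self.v_lb > self.v_ub)[0]]
            raise ValueError(f"lower bound exceeds upper bound for reactions {bad}")

    @property
    def m(self) -> int:
        return self.S.shape[0]

    @property
    def n(self) -> int:
        return self.S.shape[1]


@dataclass(frozen=True)
class FvaResult:
    """Per-reaction achievable flux extremes under S v = 0 and the bounds."""

    v_min: np.ndarray
    v_max: np.ndarray
    status: list[str] = field(default_factory=list)


def load_model(path, format: str | None = None) -> MetabolicModel:
    """Read a metabolic model from SBML or BiGG-style JSON.

    Parameters
    ----------
    path : str or Path
        Model file.
    format : {"sbml", "bigg_json"}, optional
        Inferred from the file suffix when omitted.
    """
    path = str(path)
    if format is None:
        format = "bigg_json" if path.endswith(".json") else "sbml"
    if format == "bigg_json":
        return _load_bigg_json(path)
    if format == "sbml":
        return _load_sbml(path)
    raise ValueError(f"unknown model format {format!r}")


def _load_bigg_json(path: str) -> MetabolicModel:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"{path} is not valid JSON: {exc}") from exc
    try:
        reactions = doc["reactions"]
        metabolites = doc["metabolites"]
    except (KeyError, TypeError) as exc:
        raise ValueError(f"{path} lacks BiGG-style 'reactions'/'metabolites' sections") from exc

    met_ids = [m["id"] for m in metabolites]
    if len(set(met_ids)) != len(met_ids):
        raise ValueError("duplicate metabolite id in model file")
    met_index = {mid: i for i, mid in enumerate(met_ids)}

    rxn_ids: list[str] = []
    lbs, ubs = [], []
    cols = []
    for rxn in reactions:
        rid = rxn["id"]
        if rid in rxn_ids:
            raise ValueError(f"duplicate reaction id {rid!r}")
        rxn_ids.append(rid)
        lb = rxn.get("lower_bound")
        ub = rxn.get("upper_bound")
        if lb is None or ub is None:
            warnings.warn(
                f"reaction {rid!r} missing bounds; defaulting to +/-{DEFAULT_BOUND}",
                stacklevel=3,
            )
            lb = -DEFAULT_BOUND if lb is None else lb
            ub = DEFAULT_BOUND if ub is None else ub
        lbs.append(float(lb))
        ubs.append(float(ub))
        col = np.zeros(len(met_ids))
        for mid, coeff in rxn.get("metabolites", {}).items():
            if mid not in met_index:
                raise ValueError(f"reaction {rid!r} references unknown metabolite {mid!r}")
            col[met_index[mid]] = float(coeff)
        cols.append(col)

    S = np.column_stack(cols) if cols else np.zeros((len(met_ids), 0))
    return MetabolicModel(
        S=S,
        v_lb=np.array(lbs),
        v_ub=np.array(ubs),
        reaction_ids=rxn_ids,
        metabolite_ids=met_ids,
        name=doc.get("id", "model"),
    )


def _load_sbml(path: str) -> MetabolicModel:
    # cobra handles SBML level/version and FBC bounds.
    import cobra.io
    from cobra.util.array import create_stoichiometric_matrix

    try:
        cmodel = cobra.io.read_sbml_model(path)
    except Exception as exc:  # cobra raises assorted types for bad files
        raise ValueError(f"could not parse SBML file {path}: {exc}") from exc
    S = create_stoichiometric_matrix(cmodel, array_type="dense")
    rxn_ids = [r.id for r in cmodel.reactions]
    met_ids = [m.id for m in cmodel.metabolites]
    lb = np.array([r.lower_bound for r in cmodel.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in cmodel.reactions], dtype=float)
    if np.any(~np.isfinite(lb)) or np.any(~np.isfinite(ub)):
        j = int(np.nonzero(~np.isfinite(lb) | ~np.isfinite(ub))[0][0])
        raise ValueError(f"reaction {rxn_ids[j]!r} has a non-finite bound")
    return MetabolicModel(S, lb, ub, rxn_ids, met_ids, name=cmodel.id or "model")


def write_bigg_json(model: MetabolicModel, path) -> None:
    """Write a model in the BiGG-style JSON dialect read by :func:`load_model`."""
    reactions = []
    for j, rid in enumerate(model.reaction_ids):
        nz = np.nonzero(model.S[:, j])[0]
        reactions.append(
            {
                "id": rid,
                "lower_bound": float(model.v_lb[j]),
                "upper_bound": float(model.v_ub[j]),
                "metabolites": {model.metabolite_ids[i]: float(model.S[i, j]) for i in nz},
            }
        )
    doc = {
        "id": model.name,
        "metabolites": [{"id": mid} for mid in model.metabolite_ids],
        "reactions": reactions,
        "genes": [],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def flux_variability(model: MetabolicModel, lp_tolerance: float = 1e-9) -> FvaResult:
    """Per-reaction flux minima/maxima over ``{S v = 0, v_lb <= v <= v_ub}``.

    Solves 2n independent LPs (HiGHS), in fixed reaction order for
    reproducibility.  Unbounded directions are clamped to the model bound and
    flagged in ``status``.
    """
    n = model.n
    bounds = list(zip(model.v_lb, model.v_ub))
    v_min = np.empty(n)
    v_max = np.empty(n)
    status: list[str] = []
    options = {"primal_feasibility_tolerance": max(lp_tolerance, 1e-10)}
    for j in range(n):
        st = []
        for sense, target in ((1.0, v_min), (-1.0, v_max)):
            c = np.zeros(n)
            c[j] = sense
            res = linprog(
                c,
                A_eq=model.S,
                b_eq=np.zeros(model.m),
                bounds=bounds,
                method="highs",
                options=options,
            )
            if res.status == 0:
                target[j] = sense * res.fun
                st.append("optimal")
            elif res.status == 3:  # unbounded: clamp to the box bound
                target[j] = model.v_lb[j] if sense > 0 else model.v_ub[j]
                st.append("unbounded")
            elif res.status == 2:
                raise ValueError("model is infeasible: S v = 0 has no solution within bounds")
            else:
                raise RuntimeError(f"LP failed for reaction {model.reaction_ids[j]!r}: {res.message}")
        status.append(st[0] if st[0] == st[1] else "mixed")
    # LP round-off can nudge optima marginally past the box; clip back.
    v_min = np.clip(v_min, model.v_lb, model.v_ub)
    v_max = np.clip(v_max, model.v_lb, model.v_ub)
    v_min, v_max = np.minimum(v_min, v_max), np.maximum(v_min, v_max)
    return FvaResult(v_min=v_min, v_max=v_max, status=status)


def reduce_model(
    model: MetabolicModel,
    fva: FvaResult | None = None,
    null_threshold: float = 1e-9,
) -> MetabolicModel:
    """Tighten bounds to the FVA extremes and drop reactions that carry no flux.

    A reaction is null when ``max(|v_min|, |v_max|) < null_threshold``.
    Metabolite rows left all-zero by the pruning are removed so the null-space
    dimension of the reduced S stays well defined.
    """
    if fva is None:
        fva = flux_variability(model)
    mag = np.maximum(np.abs(fva.v_min), np.abs(fva.v_max))
    keep = mag >= null_threshold
    if not np.any(keep):
        raise ValueError("every reaction is blocked; reduction would empty the model")
    S = model.S[:, keep]
    keep_mets = np.any(S != 0, axis=1)
    S = S[keep_mets, :]
    if S.shape[0] == 0:  # keep a placeholder row so shapes stay valid
        S = np.zeros((1, S.shape[1]))
        met_ids = ["_empty"]
    else:
        met_ids = [mid for mid, k in zip(model.metabolite_ids, keep_mets) if k]
    return MetabolicModel(
        S=S,
        v_lb=fva.v_min[keep],
        v_ub=fva.v_max[keep],
        reaction_ids=[r for r, k in zip(model.reaction_ids, keep) if k],
        metabolite_ids=met_ids,
        name=model.name + "_reduced",
    )


def average_flux_range(model: MetabolicModel) -> float:
    """Average flux range AFR = (1/n) sum_j (v_ub_j - v_lb_j) of the full model."""
    return float(np.mean(model.v_ub - model.v_lb))


def with_bounds(model: MetabolicModel, v_lb, v_ub) -> MetabolicModel:
    """Copy of ``model`` with replaced bounds (no pruning)."""
    return replace(model, v_lb=np.asarray(v_lb, float), v_ub=np.asarray(v_ub, float))
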