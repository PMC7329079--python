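"""End-to-end experiment orchestration: reduce, sample, diagnose, compare.

One declarative configuration drives the whole comparison: a model (file path
or synthetic spec), a list of samplers with per-algorithm parameters, the
diagnostic selection and the reference algorithm.  Chains, reports and a
manifest (config hash, seeds, runtimes) are written to the output directory;
a failing sampler is logged and excluded from the comparison rather than
aborting the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import synthetic_data
from .comparison import ComparisonReport, compare_chains
from .deterministic_samplers import (
    Chain,
    achr_sample,
    chrr_sample,
    hr_sample,
    optgp_sample,
)
from .diagnostics import DiagnosticReport, convergence_summary
from .model_io import MetabolicModel, flux_variability, load_model, reduce_model
from .polytope import build_polytope
from .stochastic_samplers import (
    MeasurementSet,
    build_tmvn_posterior,
    gibbs_tmvn_sample,
    mirror_sample,
)

logger = logging.getLogger("fluxpolytope")

__all__ = ["ExperimentConfig", "run_experiment"]

_KNOWN_ALGORITHMS = ("hr", "chr", "achr", "optgp", "chrr", "mirror", "gibbs")


@dataclass
class ExperimentConfig:
    """Declarative description of one sampling experiment.

    Defaults follow the customary genome-scale protocol: M=20,000 samples,
    thinning 1000, warm-up 20,000, steady-state slack gamma=1e-4.  Tests and
    the acceptance pipeline scale M and thinning down.
    """

    model_path: str | None = None
    model_format: str | None = None
    synthetic: dict | None = None  # e.g. {"kind": "two_flux", "lb": [...], "ub": [...]}
    algorithms: dict[str, dict] = field(default_factory=dict)
    reference: str = "chrr"
    tests: tuple[str, ...] = ("rl", "geweke", "ipsrf", "hd")
    reduce: bool = True
    null_threshold: float = 1e-9
    M: int = 20_000
    M_warm: int = 20_000
    thinning: int = 1000
    seed: int = 0
    gamma: float = 1e-4
    prior_cap: float = 1000.0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if not self.algorithms:
            raise ValueError("at least one algorithm must be configured")
        unknown = set(self.algorithms) - set(_KNOWN_ALGORITHMS)
        if unknown:
            raise ValueError(f"unknown algorithms {sorted(unknown)}")
        if self.null_threshold <= 0 or self.gamma <= 0:
            raise ValueError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if "tests" in doc:
            doc["tests"] = tuple(doc["tests"])
        return cls(**doc)

    def config_hash(self) -> str:
        blob = json.dumps(
            {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.__dict__.items()},
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _resolve_model(config: ExperimentConfig) -> MetabolicModel:
    if config.model_path is not None:
        return load_model(config.model_path, config.model_format)
    if config.synthetic is None:
        raise ValueError("config needs either model_path or a synthetic spec")
    spec = dict(config.synthetic)
    kind = spec.pop("kind")
    if kind == "two_flux":
        return synthetic_data.make_two_flux_model(**spec)
    if kind == "random_network":
        model, _ = synthetic_data.make_random_network(**spec)
        return model
    raise ValueError(f"unknown synthetic model kind {kind!r}")


def _run_sampler(name, params, poly, model, config) -> Chain:
    M = params.get("M", config.M)
    thinning = params.get("thinning", config.thinning)
    seed = params.get("seed", config.seed)
    if name == "hr":
        return hr_sample(poly, M=M, thinning=thinning, seed=seed, direction_mode="sphere",
                         M_warm=params.get("M_warm", 0))
    if name == "chr":
        return hr_sample(poly, M=M, thinning=thinning, seed=seed, direction_mode="coordinate",
                         M_warm=params.get("M_warm", 0))
    if name == "achr":
        return achr_sample(poly, M=M, M_warm=params.get("M_warm", config.M_warm),
                           thinning=thinning, seed=seed)
    if name == "optgp":
        return optgp_sample(poly, model, M=M, n_chains=params.get("n_chains", 4),
                            k=params.get("k", thinning), seed=seed)
    if name == "chrr":
        return chrr_sample(poly, M=M, M_warm=params.get("M_warm", 0),
                           thinning=thinning, seed=seed)
    if name == "mirror":
        meas = params.get("measurements")
        if isinstance(meas, dict):
            meas = MeasurementSet(**meas)
        return mirror_sample(poly, meas=meas, jump=params.get("jump"),
                             M=M, thinning=thinning, seed=seed)
    if name == "gibbs":
        spec = build_tmvn_posterior(
            model,
            meas=params.get("measurements"),
            gamma=params.get("gamma", config.gamma),
            prior_cap=params.get("prior_cap", config.prior_cap),
        )
        return gibbs_tmvn_sample(spec, M=M, thinning=thinning, seed=seed)
    raise ValueError(name)


def run_experiment(
    config: ExperimentConfig,
) -> tuple[dict[str, DiagnosticReport], dict[str, ComparisonReport], dict]:
    """Run the configured experiment.

    Returns per-algorithm diagnostic reports, per-algorithm comparison
    reports against the reference, and the manifest.  Chains and reports are
    written under ``config.out_dir`` when set.
    """
    t_start = time.perf_counter()
    model = _resolve_model(config)
    logger.info("model %s: m=%d, n=%d", model.name, model.m, model.n)
    if config.reduce:
        fva = flux_variability(model)
        sampling_model = reduce_model(model, fva, config.null_threshold)
        logger.info("reduced to n=%d reactions", sampling_model.n)
    else:
        sampling_model = model
    poly = build_polytope(sampling_model)

    chains: dict[str, Chain] = {}
    failures: dict[str, str] = {}
    for name, params in config.algorithms.items():
        try:
            t0 = time.perf_counter()
            chains[name] = _run_sampler(name, params or {}, poly, sampling_model, config)
            logger.info("%s: %d samples in %.2fs", name, chains[name].M, time.perf_counter() - t0)
        except Exception as exc:
            failures[name] = str(exc)
            logger.warning("sampler %s failed and is excluded: %s", name, exc)

    if not chains:
        raise RuntimeError(f"all samplers failed: {failures}")

    diagnostics = {name: convergence_summary(chain, config.tests) for name, chain in chains.items()}

    comparisons: dict[str, ComparisonReport] = {}
    ref_name = config.reference if config.reference in chains else next(iter(chains))
    ref_chain = chains[ref_name]
    for name, chain in chains.items():
        if name == ref_name:
            continue
        geweke_flags = None
        if "geweke" in config.tests:
            flags_ref = diagnostics[ref_name].failed.get("geweke")
            flags_oth = diagnostics[name].failed.get("geweke")
            geweke_flags = {
                rid: bool(flags_ref.get(rid)) or bool(flags_oth.get(rid))
                for rid in chain.reaction_ids
                if rid in flags_ref.index
            }
        try:
            comparisons[name] = compare_chains(ref_chain, chain, geweke_flags=geweke_flags)
        except ValueError as exc:
            failures[f"compare:{name}"] = str(exc)

    manifest = {
        "config_hash": config.config_hash(),
        "model": model.name,
        "n_full": model.n,
        "n_sampled": sampling_model.n,
        "reference": ref_name,
        "seeds": {name: chains[name].seed for name in chains},
        "runtimes_seconds": {name: chains[name].runtime_seconds for name in chains},
        "failures": failures,
        "wall_seconds": time.perf_counter() - t_start,
        "numpy_version": np.__version__,
    }

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, chain in chains.items():
            chain.write(out, name)
        for name, rep in diagnostics.items():
            rep.values.to_csv(out / f"diagnostics_{name}.csv")
        for name, rep in comparisons.items():
            rep.per_reaction.to_csv(out / f"comparison_{ref_name}_vs_{name}.csv")
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)

    return diagnostics, comparisons, manifest
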