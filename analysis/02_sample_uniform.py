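"""Sample the reduced random network with all five uniform samplers.

Runs HR, CHR, ACHR, OPTGP and CHRR on the same FVA-reduced polytope with one
protocol (M samples, shared thinning) and stores the chains for the
diagnostic and comparison stages.  Prints per-sampler runtimes — the raw
material of the efficiency statistic E = ESS/runtime.

Writes: results/chains/<algorithm>.{csv,json}
"""

from pathlib import Path

import fluxpolytope as fp

OUT = Path(__file__).resolve().parent.parent / "results"
CHAINS = OUT / "chains"

M = 4000
THINNING = 5
SEED = 20


def main() -> None:
    model, _ = fp.synthetic_data.make_random_network(6, 12, density=0.4, seed=2)
    red = fp.reduce_model(model)
    poly = fp.build_polytope(red)
    print(f"model {model.name}: n={model.n}, n_red={red.n}, polytope dim={poly.dim}")

    chains = {
        "hr": fp.hr_sample(poly, M=M, thinning=THINNING, seed=SEED),
        "chr": fp.hr_sample(poly, M=M, thinning=THINNING, seed=SEED + 1, direction_mode="coordinate"),
        "achr": fp.achr_sample(poly, M=M, M_warm=200, thinning=THINNING, seed=SEED + 2),
        "optgp": fp.optgp_sample(poly, red, M=M, n_chains=4, k=THINNING, seed=SEED + 3),
        "chrr": fp.chrr_sample(poly, M=M, thinning=THINNING, seed=SEED + 4),
    }
    CHAINS.mkdir(parents=True, exist_ok=True)
    for name, chain in chains.items():
        chain.write(CHAINS, name)
        print(f"{name:>6}: M={chain.M}, runtime={chain.runtime_seconds:.2f}s")


if __name__ == "__main__":
    main()
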