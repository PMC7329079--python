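"""Apply the four single-chain convergence diagnostics to every stored chain.

For each algorithm and each reaction: Raftery-Lewis dependence factor
(fails at I > 5), Geweke Z (|Z| > 1.28), interval-based PSRF (outside
0.9-1.1) and Hellinger distance between first and last thirds (HD > 0.1).
The headline statistic is the proportion of reactions failing each test per
algorithm; per-reaction flag sets are kept because different diagnostics do
not necessarily reject the same reactions.

Reads results/chains/; writes results/convergence_failures.csv and
results/diagnostics_<algorithm>.csv.
"""

from pathlib import Path

import pandas as pd

import fluxpolytope as fp

OUT = Path(__file__).resolve().parent.parent / "results"
CHAINS = OUT / "chains"


def main() -> None:
    rows = []
    for path in sorted(CHAINS.glob("*.json")):
        name = path.stem
        chain = fp.Chain.read(CHAINS, name)
        report = fp.convergence_summary(chain, tests=("geweke", "ipsrf", "hd"))
        report.values.to_csv(OUT / f"diagnostics_{name}.csv")
        row = {"algorithm": name, **report.failure_proportions}
        flags = {
            t: ",".join(report.failed_reactions(t)) or "-"
            for t in ("geweke", "ipsrf", "hd")
        }
        rows.append(row)
        print(f"{name:>6}: failure proportions {report.failure_proportions}")
        print(f"        failing reactions per test: {flags}")

    table = pd.DataFrame(rows)
    table.to_csv(OUT / "convergence_failures.csv", index=False)
    print("\nProportion of reactions failing each diagnostic:")
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
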