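"""Cross-algorithm consistency: moments, Pearson r, KLD classes, efficiency.

Uses CHRR (guaranteed convergence) as the reference and compares every other
stored chain against it: Pearson correlation of per-reaction means and SDs
after 2-SD outlier removal, per-reaction KL divergence with the
good (<0.05) / medium (0.05-0.5) / poor (>0.5) classification, per-reaction
ESS, the efficiency E = ESS/runtime, and the time to generate 100
independent samples.

Reads results/chains/; writes results/consistency_summary.csv and
results/comparison_chrr_vs_<algorithm>.csv (the data behind the usual
mean/SD scatter, KLD CDF and efficiency CDF plots).
"""

from pathlib import Path

import pandas as pd

import fluxpolytope as fp
from fluxpolytope.comparison import compare_chains

OUT = Path(__file__).resolve().parent.parent / "results"
CHAINS = OUT / "chains"
REFERENCE = "chrr"


def main() -> None:
    ref = fp.Chain.read(CHAINS, REFERENCE)
    rows = []
    for path in sorted(CHAINS.glob("*.json")):
        name = path.stem
        if name == REFERENCE:
            continue
        other = fp.Chain.read(CHAINS, name)
        rep = compare_chains(ref, other)
        rep.per_reaction.to_csv(OUT / f"comparison_{REFERENCE}_vs_{name}.csv")
        classes = rep.per_reaction["kld_class"].value_counts().to_dict()
        rows.append(
            {
                "algorithm": name,
                "r_means": rep.r_means,
                "r_sds": rep.r_sds,
                "outlier_prop": rep.outlier_proportion,
                "kld_good": classes.get("good", 0),
                "kld_medium": classes.get("medium", 0),
                "kld_poor": classes.get("poor", 0),
                "mean_ess": rep.per_reaction["ess_other"].mean(),
                "time_to_100_s": rep.efficiency.attrs["time_to_100_other"]
                if rep.efficiency is not None
                else float("nan"),
            }
        )
        print(
            f"{name:>6} vs {REFERENCE}: r_means={rep.r_means:.4f}, r_sds={rep.r_sds:.4f}, "
            f"outliers={rep.outlier_proportion:.1%}, KLD classes={classes}"
        )

    table = pd.DataFrame(rows)
    table.to_csv(OUT / "consistency_summary.csv", index=False)
    print("\nConsistency and efficiency against the CHRR reference:")
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
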