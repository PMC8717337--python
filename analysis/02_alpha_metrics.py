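"""Observed per-site alpha metrics (S, PD, MPD, MNTD, VPD) for every scenario.

Metrics are computed on each tree of the posterior-like sample and summarized
by the per-site median; tables go to results/alpha_<scenario>.tsv.
"""

from pathlib import Path

import pandas as pd

from soilphylo import align_dataset, compute_alpha, read_community, \
    read_environment, read_newick

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    for d in sorted((ROOT / "datasets").iterdir()):
        comm, env, trees = align_dataset(
            read_community(d / "community.csv"),
            read_environment(d / "environment.csv"),
            read_newick(d / "trees.nwk"))
        stacked = pd.concat([compute_alpha(comm, t) for t in trees],
                            keys=range(len(trees)), names=["tree"])
        med = (stacked.drop(columns="site")
               .groupby(level="site", sort=True).median(numeric_only=True))
        out = ROOT / f"alpha_{d.name}.tsv"
        med.to_csv(out, sep="\t")
        rich = med.join(env.set_index("site")["formation"], how="left")
        by_form = rich.groupby("formation", observed=True)["S"].mean()
        print(f"{d.name:10s}: mean S by formation "
              + ", ".join(f"{f}={v:.1f}" for f, v in by_form.items())
              + f" -> {out.name}")


if __name__ == "__main__":
    main()
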