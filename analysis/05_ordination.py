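"""PCoA ordination of the turnover matrices with environmental arrows.

For each scenario, ordinates the Sorensen and cross-tree-median PhyloSor
matrices, correlates log10 base cations (plus covariates) with the first two
axes, and draws a biplot to results/figures/.
"""

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from soilphylo import align_dataset, beta_over_trees, envfit_axes, pcoa, \
    read_community, read_environment, read_newick, sorensen_matrix

ROOT = Path(__file__).resolve().parents[1] / "results"
FIGS = ROOT / "figures"
COLORS = {"Solimoes": "#b2182b", "Ica": "#2166ac", "Terrace": "#4dac26"}


def main() -> None:
    FIGS.mkdir(parents=True, exist_ok=True)
    for d in sorted((ROOT / "datasets").iterdir()):
        comm, env, trees = align_dataset(
            read_community(d / "community.csv"),
            read_environment(d / "environment.csv"),
            read_newick(d / "trees.nwk"))
        for metric, bm in (("sorensen", sorensen_matrix(comm)),
                           ("phylosor", beta_over_trees(comm, trees))):
            ordn = pcoa(bm, k=2)
            ordn.scores_frame().to_csv(
                ROOT / f"pcoa_{metric}_{d.name}_scores.tsv", sep="\t")
            variables = {"base_cation": "log10", "phosphorus": "log10",
                         "aluminum": "identity", "pH": "identity"}
            variables = {v: t for v, t in variables.items() if v in env.columns}
            arrows = envfit_axes(ordn, env, variables)
            arrows.to_csv(ROOT / f"pcoa_{metric}_{d.name}_envfit.tsv",
                          sep="\t", index=False)

            fig, ax = plt.subplots(figsize=(5, 4.5))
            form = env.set_index("site").loc[list(ordn.sites), "formation"]
            for f, color in COLORS.items():
                sel = (form == f).to_numpy()
                ax.scatter(ordn.scores[sel, 0], ordn.scores[sel, 1],
                           s=22, c=color, label=f)
            scale = 0.9 * abs(ordn.scores).max()
            for _, row in arrows.iterrows():
                ax.annotate("", xy=(row.r_axis1 * scale, row.r_axis2 * scale),
                            xytext=(0, 0),
                            arrowprops=dict(arrowstyle="->", color="gray"))
                ax.text(row.r_axis1 * scale, row.r_axis2 * scale,
                        row.variable, fontsize=8, color="gray")
            rel = ordn.relative_eigenvalues
            ax.set_xlabel(f"PCoA 1 ({rel[0] * 100:.0f}%)")
            ax.set_ylabel(f"PCoA 2 ({rel[1] * 100:.0f}%)")
            ax.legend(fontsize=8)
            ax.set_title(f"{d.name} / {metric}")
            fig.tight_layout()
            fig.savefig(FIGS / f"pcoa_{metric}_{d.name}.png", dpi=120)
            plt.close(fig)
            r1 = arrows.set_index("variable").loc["base_cation", "r_axis1"]
            print(f"{d.name:10s} {metric:9s}: axis1 {rel[0] * 100:.0f}%, "
                  f"r(log10 cations, axis1) = {r1:+.2f}")


if __name__ == "__main__":
    main()
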