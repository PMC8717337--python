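"""Linear and quadratic regressions of community metrics on soil base cations.

Regresses S, VPD and the SES metrics (from 03) on log10 cation concentration
per scenario, writes results/regressions_<scenario>.tsv, flags fits with
p < .05, and draws the richness gradient to results/figures/.
"""

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from soilphylo import fit_gradient_models, read_environment

ROOT = Path(__file__).resolve().parents[1] / "results"
FIGS = ROOT / "figures"


def main() -> None:
    FIGS.mkdir(parents=True, exist_ok=True)
    for d in sorted((ROOT / "datasets").iterdir()):
        env = read_environment(d / "environment.csv")
        tbl = pd.read_csv(ROOT / f"alpha_{d.name}.tsv", sep="\t")
        ses = pd.read_csv(ROOT / f"ses_alpha_{d.name}.tsv", sep="\t")
        wide = ses.pivot(index="site", columns="metric", values="ses")
        wide.columns = [f"SES.{c}" for c in wide.columns]
        tbl = tbl.merge(wide.reset_index(), on="site", how="left")
        metrics = ["S", "VPD"] + list(wide.columns)
        fits = fit_gradient_models(tbl, env, metrics)
        fits.to_csv(ROOT / f"regressions_{d.name}.tsv", sep="\t", index=False)
        sig = fits.loc[fits["linear_significant"], "metric"].tolist()
        s_fit = fits.set_index("metric").loc["S"]
        print(f"{d.name:10s}: S slope {s_fit['linear_slope']:+.1f} "
              f"(p={s_fit['linear_p']:.2g}), significant at .05: {sig}")

        x = np.log10(env.set_index("site").loc[tbl['site'], 'base_cation'])
        fig, ax = plt.subplots(figsize=(4.5, 3.5))
        ax.scatter(x, tbl["S"], s=18, c="k")
        if s_fit["linear_significant"]:
            grid = np.linspace(x.min(), x.max(), 50)
            ax.plot(grid, s_fit["linear_intercept"]
                    + s_fit["linear_slope"] * grid, "r-")
        ax.set_xlabel("log10 base cations (cmol(+)/kg)")
        ax.set_ylabel("species richness S")
        ax.set_title(d.name)
        fig.tight_layout()
        fig.savefig(FIGS / f"richness_gradient_{d.name}.png", dpi=120)
        plt.close(fig)


if __name__ == "__main__":
    main()
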