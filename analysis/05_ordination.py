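"""Bray-Curtis NMDS ordination at four levels of taxonomic resolution.

Ordinates the community at phylum, genus, 97%-OTU and oligotype resolution,
draws per-individual covariance ellipses, and checks how often independently
restarted fits reproduce the oligotype-level layout.
"""

import json

from oligoprint import community, ordination

from study_config import N_TRIALS, RESULTS, SEED


def main() -> None:
    report = {}
    for i, level in enumerate(("phylum", "genus", "otu97", "oligotype")):
        table = community.AbundanceTable.read_tsv(
            RESULTS / "tables" / f"{level}_relative.tsv"
        )
        res = ordination.ordinate_table(
            table,
            n_trials=N_TRIALS if level == "oligotype" else 0,
            seed=SEED + i,
        )
        ordination.write_ordination(res, table, RESULTS / "ordination", level)
        overlap = _mean_ellipse_spread(res)
        line = f"{level:>9}: stress {res.stress:.3f}, ellipse spread {overlap:.3f}"
        if res.n_trials:
            line += f", topology consistent in {res.n_consistent}/{res.n_trials} trials"
        print(line)
        report[level] = {
            "stress": res.stress,
            "n_consistent": res.n_consistent,
            "n_trials": res.n_trials,
            "ellipse_spread": overlap,
        }
    (RESULTS / "05_ordination_summary.json").write_text(json.dumps(report, indent=2))
    _maybe_plot()


def _mean_ellipse_spread(res) -> float:
    """Mean 1-SD ellipse radius relative to the spread of group centers —
    small values mean individuals occupy distinct regions of the plot."""
    import numpy as np

    centers = np.array([e.mean for e in res.group_ellipses.values()])
    radii = [float(np.sqrt(e.eigenvalues.mean())) for e in res.group_ellipses.values()]
    center_spread = float(np.std(centers, axis=0).mean())
    return float(np.mean(radii) / center_spread) if center_spread else float("inf")


def _maybe_plot() -> None:
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        import pandas as pd
    except ImportError:
        return
    fig, axes = plt.subplots(2, 2, figsize=(9, 8))
    for ax, level in zip(axes.ravel(), ("phylum", "genus", "otu97", "oligotype")):
        coords = pd.read_csv(
            RESULTS / "ordination" / f"{level}_coordinates.tsv", sep="\t"
        )
        for ind, block in coords.groupby("individual"):
            ax.scatter(block["axis1"], block["axis2"], s=12, label=ind)
        ax.set_title(level)
        ax.set_xticks([])
        ax.set_yticks([])
    axes[0, 0].legend(fontsize=6, ncol=2)
    outdir = RESULTS / "figures"
    outdir.mkdir(parents=True, exist_ok=True)
    fig.tight_layout()
    fig.savefig(outdir / "nmds_levels.png", dpi=120)
    print(f"Figure written to {outdir / 'nmds_levels.png'}")


if __name__ == "__main__":
    main()
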