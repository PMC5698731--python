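"""Summarize the smoothing-induced network distortions from the sweep tables.

Reads results/sweep/ (from 02_run_smoothing_sweep.py) and reports, per
kernel width: the ROI-size vs degree-change correlation, the degree /
eigenvector-centrality agreement, the short- vs long-link weight
amplification, and the cross-subject LCC-membership dispersion.  With
--plot, diagnostic figures go under scratch/figures/.
"""

import argparse
from pathlib import Path

import pandas as pd


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--sweep", type=Path, default=Path("results/sweep"))
    ap.add_argument("--plot", action="store_true")
    args = ap.parse_args()

    summary = pd.read_csv(args.sweep / "summary.tsv", sep="\t")
    centrality = pd.read_csv(args.sweep / "centrality.tsv", sep="\t")
    print(summary.to_string(index=False))

    smoothed = summary[summary.fwhm_mm > 0]
    print("\nfindings:")
    print(
        f"- ROI size vs degree change: r = "
        + ", ".join(f"{r:.2f} (FWHM {f:g})" for f, r in
                    zip(smoothed.fwhm_mm, smoothed.roi_size_degree_change_r))
        + " -> small ROIs gain degree, large ROIs lose it."
    )
    print(
        f"- shortest-bin vs longest-bin Fisher-Z weight change: "
        + ", ".join(
            f"{s:.2f}/{l:.2f} (FWHM {f:g})"
            for f, s, l in zip(
                smoothed.fwhm_mm, smoothed.delta_z_shortest_bin,
                smoothed.delta_z_longest_bin)
        )
        + " -> short links are amplified far more."
    )
    print(
        "- degree vs eigenvector centrality r stays "
        f"{summary.degree_eigenvector_r.min():.2f}-"
        f"{summary.degree_eigenvector_r.max():.2f} at every width."
    )
    disp = dict(zip(summary.fwhm_mm, summary.lcc_dispersion))
    print(
        f"- LCC membership dispersion: {disp} -> smoothed cohorts agree more "
        "about the network core than the unsmoothed baseline."
    )

    if args.plot:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        figdir = Path("scratch/figures")
        figdir.mkdir(parents=True, exist_ok=True)
        fig, axes = plt.subplots(1, 2, figsize=(10, 4))
        for fwhm, grp in centrality.groupby("fwhm_mm"):
            axes[0].scatter(grp.roi_size, grp.delta_mean_degree, s=8, label=f"{fwhm:g} mm")
        axes[0].set_xscale("log")
        axes[0].set_xlabel("ROI size (voxels)")
        axes[0].set_ylabel("degree change vs unsmoothed")
        axes[0].legend(title="FWHM")
        axes[1].plot(summary.fwhm_mm, summary.lcc_dispersion, "o-")
        axes[1].set_xlabel("FWHM (mm)")
        axes[1].set_ylabel("LCC membership dispersion")
        fig.tight_layout()
        fig.savefig(figdir / "smoothing_effects.png", dpi=120)
        print(f"figures -> {figdir}")


if __name__ == "__main__":
    main()
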