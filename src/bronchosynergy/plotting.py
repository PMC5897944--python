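"""Optional matplotlib figures: Fa-CI plots, normalized isobolograms,
observed-vs-expected Bliss panels with delta bars.  Rendering is a
convenience, not part of the analysis contract."""

from __future__ import annotations

from pathlib import Path


def write_figures(report, out_dir: str | Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    written: list[Path] = []
    for cell in report.cells:
        tag = f"{cell.compartment}_{cell.sensitization}"
        if cell.ci_profile is not None:
            fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
            tab = cell.ci_profile.table
            ax1.plot(tab["fa"], tab["log10_ci"], "o-", ms=4)
            ax1.axhline(0.0, color="k", lw=0.8)
            ax1.set_xlabel("fraction affected (fa)")
            ax1.set_ylabel("log10 Combination Index")
            ax1.set_title("Fa-CI plot")
            iso = cell.ci_profile.isobologram_points
            ax2.plot([0, 1], [1, 0], "k-", lw=0.8)
            ax2.scatter(iso["x"], iso["y"])
            for _, row in iso.iterrows():
                ax2.annotate(f"fa={row['fa']:.2f}", (row["x"], row["y"]), fontsize=7)
            ax2.set_xlabel("D1 / Dx1")
            ax2.set_ylabel("D2 / Dx2")
            ax2.set_title("normalized isobologram")
            fig.suptitle(tag)
            path = out / f"unified_{tag}.png"
            fig.tight_layout()
            fig.savefig(path, dpi=120)
            plt.close(fig)
            written.append(path)
        if cell.bliss is not None:
            tab = cell.bliss.table
            fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
            ax1.errorbar(tab["concentration_total"], tab["observed_percent"],
                         yerr=tab["sem_observed"], fmt="o-", label="observed", ms=4)
            ax1.errorbar(tab["concentration_total"], tab["expected_percent"],
                         yerr=tab["sem_expected"], fmt="s--", label="expected (BI)", ms=4)
            ax1.set_xscale("log")
            ax1.set_xlabel("combination total (ng/ml)")
            ax1.set_ylabel("relaxation (% papaverine max)")
            ax1.legend()
            ax2.bar(range(len(tab)), tab["delta"])
            ax2.set_xticks(range(len(tab)))
            ax2.set_xticklabels(
                [f"{c:.3g}" for c in tab["concentration_total"]], rotation=45, fontsize=7
            )
            ax2.set_xlabel("combination total (ng/ml)")
            ax2.set_ylabel("delta (observed - expected, points)")
            fig.suptitle(tag)
            path = out / f"bliss_{tag}.png"
            fig.tight_layout()
            fig.savefig(path, dpi=120)
            plt.close(fig)
            written.append(path)
    return written
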