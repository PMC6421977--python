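"""Optional matplotlib rendering of view-spec JSON documents.

Renderers consume specs only — positions, widths and flags — never the
dataset.  This keeps the drawing layer replaceable: the specs are the
contract.  Requires the ``render`` extra (matplotlib).
"""

from __future__ import annotations

__all__ = ["render_spec"]


def render_spec(spec: dict, out_path: str) -> None:
    """Draw a basic rendition of any of the six view specs to a file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    view = spec.get("view")
    fig, ax = plt.subplots(figsize=(7, 4.5))
    if view == "parallel_coordinates":
        axes = spec["axes"]
        xs = range(len(axes))
        for line in spec["polylines"]:
            ys = line["positions"]
            colour = "tab:blue" if line["highlighted"] else "0.6"
            segs_x, segs_y = [], []
            for x, y in zip(xs, ys):
                if y is None:
                    if segs_x:
                        ax.plot(segs_x, segs_y, color=colour, alpha=0.7)
                    segs_x, segs_y = [], []
                else:
                    segs_x.append(x)
                    segs_y.append(y)
            if segs_x:
                ax.plot(segs_x, segs_y, color=colour, alpha=0.7)
        ax.set_xticks(list(xs), [a["variable"] for a in axes], rotation=20, ha="right")
        ax.set_ylabel("normalised position")
    elif view == "scatter":
        for p in spec["points"]:
            ax.plot(p["x"], p["y"], "o", color="tab:blue" if p["highlighted"] else "0.5")
        ax.set_xlabel(spec["x_variable"])
        ax.set_ylabel(spec["y_variable"])
    elif view == "box_plot":
        stats = [
            {
                "med": g["stats"]["median"], "q1": g["stats"]["q1"], "q3": g["stats"]["q3"],
                "whislo": g["stats"]["whisker_lo"], "whishi": g["stats"]["whisker_hi"],
                "fliers": g["stats"]["outliers"], "label": str(g["value"]),
            }
            for g in spec["groups"]
        ]
        ax.bxp(stats, showfliers=True)
        ax.set_ylabel(spec["value_variable"])
    elif view == "radar":
        import numpy as np

        fig.clf()
        ax = fig.add_subplot(polar=True)
        n = len(spec["axes"])
        angles = np.linspace(0, 2 * np.pi, n, endpoint=False).tolist()
        for poly in spec["polygons"]:
            vals = poly["positions"]
            ax.plot(angles + angles[:1], vals + vals[:1],
                    color="tab:blue" if poly["highlighted"] else "0.6", alpha=0.7)
        ax.set_xticks(angles, spec["axes"])
    elif view == "parallel_sets":
        tiers = spec["tiers"]
        for i, tier in enumerate(tiers):
            x = 0.0
            for bar in tier["bars"]:
                w = bar["width_fraction"]
                ax.barh(i, w, left=x, height=0.4, edgecolor="white")
                if w > 0:
                    ax.text(x + w / 2, i, str(bar["value"]), ha="center", va="center", fontsize=8)
                x += w
        ax.set_yticks(range(len(tiers)), [t["variable"] for t in tiers])
        ax.set_xlabel("fraction of complete rows")
    elif view == "table":
        ax.axis("off")
        cols = spec["columns"]
        cells = [[str(r["values"][c]) for c in cols] for r in spec["rows"][:30]]
        if cells:
            ax.table(cellText=cells, colLabels=cols, loc="center")
    else:
        raise ValueError(f"cannot render unknown view {view!r}")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
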