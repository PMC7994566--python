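"""Publication-style rendering of prediction results.

Renders (1) a bar chart of significantly predicted EF targets' mean true-vs-
predicted correlations, grouped and coloured by EF domain, and (2) per-target
tables of the five most important fluency features with their Spearman
follow-up correlations, using the conventional report marks (bold at
p < 0.1, star at p < 0.05).  Every number is read from the results files;
nothing is recomputed at render time.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

_DOMAIN_COLOURS = {
    "cognitive flexibility": "#4c72b0",
    "working memory": "#dd8452",
    "inhibition": "#c44e52",
    "attention": "#55a868",
    "vigilance": "#8172b3",
}


def render_prediction_figure(
    screened: pd.DataFrame, out_path: str | Path, title: str = ""
) -> Path:
    """Bar chart of significant targets' mean r, grouped by EF domain."""
    out_path = Path(out_path)
    fig, ax = plt.subplots(figsize=(max(6.0, 0.45 * max(len(screened), 1) + 2), 4.5))
    if len(screened) == 0:
        ax.text(0.5, 0.5, "No EF target passed the significance screen",
                ha="center", va="center", transform=ax.transAxes)
        ax.set_axis_off()
    else:
        df = screened.copy()
        if "domain" in df.columns:
            df = df.sort_values(["domain", "mean_r"], ascending=[True, False])
            colours = [_DOMAIN_COLOURS.get(d, "#999999") for d in df["domain"]]
        else:
            df = df.sort_values("mean_r", ascending=False)
            colours = ["#4c72b0"] * len(df)
        ax.bar(range(len(df)), df["mean_r"], color=colours)
        ax.set_xticks(range(len(df)))
        ax.set_xticklabels(df["target"], rotation=60, ha="right", fontsize=8)
        ax.set_ylabel("mean r (true vs predicted)")
        seen = dict.fromkeys(df.get("domain", pd.Series(dtype=str)))
        handles = [
            plt.Rectangle((0, 0), 1, 1, color=_DOMAIN_COLOURS.get(d, "#999999"))
            for d in seen
        ]
        if handles:
            ax.legend(handles, list(seen), fontsize=8, title="EF domain")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path


def format_top5_table(top5: pd.DataFrame) -> pd.DataFrame:
    """Add the bold/star report marks to a Spearman follow-up table."""
    out = top5.copy()
    out["mark"] = [
        ("*" if sig else "") + ("bold" if trend else "")
        for trend, sig in zip(out["trend"], out["significant"])
    ]
    return out


def render_reports(results_dir: str | Path) -> list[Path]:
    """Render figures/tables from a results directory written by the CLI.

    Expects ``results_full.tsv`` / ``results_classical.tsv`` (or a single
    ``results.tsv``) and optional ``top5_spearman.tsv``.
    """
    results_dir = Path(results_dir)
    written: list[Path] = []
    for arm in ("full", "classical", ""):
        name = f"results_{arm}.tsv" if arm else "results.tsv"
        path = results_dir / name
        if not path.exists():
            continue
        df = pd.read_csv(path, sep="\t")
        screened = df[df["significant"] == True]  # noqa: E712 (TSV bools)
        fig_path = results_dir / (f"prediction_{arm or 'all'}.png")
        render_prediction_figure(
            screened, fig_path,
            title=f"Significantly predicted EF targets ({arm or 'all'} feature set)",
        )
        written.append(fig_path)
    top5_path = results_dir / "top5_spearman.tsv"
    if top5_path.exists():
        table = format_top5_table(pd.read_csv(top5_path, sep="\t"))
        out = results_dir / "top5_spearman_marked.tsv"
        table.to_csv(out, sep="\t", index=False)
        written.append(out)
    return written
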