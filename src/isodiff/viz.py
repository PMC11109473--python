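"""Exploratory figures: abundance bars, stacked MDV bars, enrichment and
time-course curves, PCA scatter, metabologram rings.

Every plotting function returns ``(figure, values_table)`` where the
table holds exactly the numbers drawn, so tests (and users) can check the
content of a figure without inspecting pixels. Rendering is deterministic:
fixed font, fixed SVG hash salt, no timestamp metadata — identical inputs
produce identical SVG text.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless by design

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib import cm
from matplotlib.colors import TwoSlopeNorm

from .metabologram import Metabologram
from .multivariate import PCAResult
from .preprocess import Dataset
from .tables import GroupSelector, MetaboliteTable

plt.rcParams.update(
    {
        "svg.hashsalt": "isodiff",
        "font.family": "DejaVu Sans",
        "figure.max_open_warning": 0,
    }
)

#: one stable color per isotopologue index, shared by every figure in a run
MAX_ISOTOPOLOGUES = 13
ISOTOPOLOGUE_COLORS = [cm.viridis(i / (MAX_ISOTOPOLOGUES - 1)) for i in range(MAX_ISOTOPOLOGUES)]


def save_figure(fig, path: str | Path, dpi: int = 150) -> None:
    """Write SVG (deterministic) and PNG twins of a figure."""
    path = Path(path)
    fig.savefig(path.parent / (path.name + ".svg"), metadata={"Date": None})
    fig.savefig(path.parent / (path.name + ".png"), dpi=dpi)
    plt.close(fig)


def _group_samples(dataset: Dataset, groups: list[GroupSelector]) -> dict[str, list[str]]:
    out = {}
    for g in groups:
        samples = dataset.samplesheet.select(g.condition, g.timepoint)
        if samples:
            out[g.label()] = samples
    return out


def abundance_bars(
    table: MetaboliteTable, dataset: Dataset, groups: list[GroupSelector]
) -> tuple[plt.Figure, pd.DataFrame]:
    """Comparative bars of group means with SD error bars and replicate dots."""
    resolved = _group_samples(dataset, groups)
    rows = []
    for met in table.metabolites:
        for label, samples in resolved.items():
            vals = table.data.loc[met, samples].astype(float)
            rows.append(
                {"metabolite": met, "group": label,
                 "mean": float(vals.mean()), "sd": float(vals.std(ddof=1)) if vals.notna().sum() > 1 else 0.0,
                 "n": int(vals.notna().sum())}
            )
    values = pd.DataFrame(rows)

    mets = list(table.metabolites)
    labels = list(resolved)
    width = 0.8 / max(len(labels), 1)
    fig, ax = plt.subplots(figsize=(max(6, 0.8 * len(mets)), 4))
    x = np.arange(len(mets))
    for gi, label in enumerate(labels):
        sub = values[values["group"] == label].set_index("metabolite").loc[mets]
        offs = x + (gi - (len(labels) - 1) / 2) * width
        ax.bar(offs, sub["mean"], width=width * 0.9, yerr=sub["sd"],
               capsize=2, label=label)
        for met, off in zip(mets, offs):
            pts = table.data.loc[met, resolved[label]].astype(float).dropna()
            ax.plot(np.full(len(pts), off), pts, "k.", ms=3, zorder=3)
    ax.set_xticks(x, mets, rotation=45, ha="right")
    ax.set_ylabel(table.quantity.replace("_", " "))
    ax.legend()
    fig.tight_layout()
    return fig, values


def isotopologue_stacked_bars(
    dataset: Dataset, groups: list[GroupSelector]
) -> tuple[plt.Figure, pd.DataFrame]:
    """Stacked mean isotopologue proportions per group, m+0 at the bottom."""
    table = dataset.isotopologues_proportion
    if table is None:
        raise ValueError("stacked bars require isotopologue proportions")
    resolved = _group_samples(dataset, groups)
    rows = []
    for met in table.metabolites:
        n = table.carbon_counts[met]
        for label, samples in resolved.items():
            for i in range(n + 1):
                vals = table.data.loc[(met, i), samples].astype(float)
                rows.append({"metabolite": met, "group": label,
                             "isotopologue_index": i, "mean": float(vals.mean())})
    values = pd.DataFrame(rows)

    mets = list(table.metabolites)
    labels = list(resolved)
    fig, ax = plt.subplots(figsize=(max(6, 0.9 * len(mets) * len(labels)), 4))
    positions, ticklabels = [], []
    pos = 0.0
    for met in mets:
        for label in labels:
            sub = values[(values["metabolite"] == met) & (values["group"] == label)]
            bottom = 0.0
            for _, r in sub.sort_values("isotopologue_index").iterrows():
                i = int(r["isotopologue_index"])
                ax.bar(pos, r["mean"], bottom=bottom, width=0.8,
                       color=ISOTOPOLOGUE_COLORS[i % MAX_ISOTOPOLOGUES],
                       label=f"m+{i}" if (met == mets[0] and label == labels[0]) else None)
                bottom += 0.0 if np.isnan(r["mean"]) else r["mean"]
            positions.append(pos)
            ticklabels.append(f"{met}\n{label}")
            pos += 1.0
        pos += 0.5
    ax.set_xticks(positions, ticklabels, fontsize=7)
    ax.set_ylabel("isotopologue proportion")
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    return fig, values


def timecourse_curves(
    dataset: Dataset, quantity: str, *, condition: str | None = None
) -> tuple[plt.Figure, pd.DataFrame]:
    """Group mean ± SD per metabolite across numeric time (hours)."""
    tables = dataset.quantity_tables()
    if quantity not in tables:
        raise ValueError(f"quantity {quantity!r} not available in dataset")
    frame = tables[quantity]
    tp = dataset.samplesheet.timepoints()
    hours = tp["timepoint_hours"].to_numpy()
    if hours.size < 2:
        raise ValueError("time-course curves need ≥2 timepoints")

    rows = []
    for feat in frame.index:
        for h in hours:
            samples = dataset.samplesheet.select(condition, float(h))
            vals = frame.loc[feat, samples].astype(float)
            rows.append(
                {"feature_id": feat, "hours": float(h),
                 "mean": float(vals.mean()),
                 "sd": float(vals.std(ddof=1)) if vals.notna().sum() > 1 else 0.0}
            )
    values = pd.DataFrame(rows)

    feats = list(frame.index)
    ncols = min(4, len(feats))
    nrows_ = int(np.ceil(len(feats) / ncols))
    fig, axes = plt.subplots(nrows_, ncols, figsize=(3 * ncols, 2.4 * nrows_),
                             squeeze=False, sharex=True)
    for ax, feat in zip(axes.flat, feats):
        sub = values[values["feature_id"] == feat]
        ax.errorbar(sub["hours"], sub["mean"], yerr=sub["sd"], marker="o", ms=3)
        ax.set_title(str(feat), fontsize=8)
    for ax in axes.flat[len(feats):]:
        ax.axis("off")
    fig.supxlabel("time (h)")
    fig.supylabel(quantity.replace("_", " "))
    fig.tight_layout()
    return fig, values


def pca_plot(result: PCAResult, dataset: Dataset) -> tuple[plt.Figure, pd.DataFrame]:
    """PC1/PC2 scatter colored by condition."""
    scores = result.scores
    conds = dataset.samplesheet.data.loc[scores.index, "condition"]
    values = scores.assign(condition=conds)
    fig, ax = plt.subplots(figsize=(5, 4))
    for cond, sub in values.groupby("condition", sort=True):
        ax.scatter(sub["PC1"], sub["PC2"], label=str(cond), s=30)
    evr = result.explained_variance_ratio
    ax.set_xlabel(f"PC1 ({evr[0] * 100:.1f}%)")
    if len(evr) > 1:
        ax.set_ylabel(f"PC2 ({evr[1] * 100:.1f}%)")
    ax.legend()
    fig.tight_layout()
    return fig, values


def metabologram_figure(gram: Metabologram) -> tuple[plt.Figure, pd.DataFrame]:
    """Paired-ring rendering: metabolites inner, genes outer.

    Colors map the raw signed values onto a diverging scale whose limits
    are the symmetric ``value_domain``, so negating every effect mirrors
    the colors exactly. Non-significant segments are drawn muted (hatched),
    unmeasured ones grey.
    """
    values = gram.to_frame()
    vmax = gram.value_domain[1] or 1.0
    norm = TwoSlopeNorm(vcenter=0.0, vmin=-vmax, vmax=vmax)
    cmap = cm.coolwarm

    fig, ax = plt.subplots(figsize=(5, 5), subplot_kw={"aspect": "equal"})
    for ring, (segs, r0, r1) in enumerate(
        ((gram.metabolite_segments, 0.35, 0.65), (gram.gene_segments, 0.7, 1.0))
    ):
        if not segs:
            continue
        theta = 360.0 / len(segs)
        for k, seg in enumerate(segs):
            color = cmap(norm(seg.value)) if seg.measured else (0.85, 0.85, 0.85, 1.0)
            wedge = matplotlib.patches.Wedge(
                (0, 0), r1, k * theta, (k + 1) * theta, width=r1 - r0,
                facecolor=color, edgecolor="white",
                hatch=None if seg.significant or not seg.measured else "///",
                linewidth=1.0,
            )
            ax.add_patch(wedge)
            ang = np.deg2rad((k + 0.5) * theta)
            rr = (r0 + r1) / 2
            ax.text(rr * np.cos(ang), rr * np.sin(ang), seg.member_id,
                    ha="center", va="center", fontsize=6)
    ax.set_xlim(-1.1, 1.1)
    ax.set_ylim(-1.1, 1.1)
    ax.axis("off")
    ax.set_title(f"{gram.pathway_id} — {gram.comparison}", fontsize=9)
    sm = cm.ScalarMappable(norm=norm, cmap=cmap)
    fig.colorbar(sm, ax=ax, shrink=0.7, label="differential value")
    fig.tight_layout()
    return fig, values
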