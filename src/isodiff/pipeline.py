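"""Top-level orchestration: preprocess → statistics → figures → integration.

``run_pipeline`` executes everything a configuration enables and writes a
reproducible output tree::

    <output_dir>/
      tables/    derived quantity tables and result tables (TSV)
      figures/   SVG + PNG twins of every figure
      logs/      human log + JSON-lines event log
      manifest.json   config hash, seed, package versions

Identical configuration + seed produce hash-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd
import scipy
import sklearn
import yaml

from . import __version__, io
from .bivariate import timecourse_mdv
from .config import RunConfig
from .diffstats import run_comparison, time_responsive, timecourse_comparisons
from .metabologram import (
    build_metabologram,
    project_subnetwork,
    read_pathway_definitions,
    read_pathway_graph,
)
from .multivariate import pca_overview
from .preprocess import Dataset, harmonize_inputs
from .simulate import generate_preset
from .tables import (
    FRACTIONAL_CONTRIBUTION,
    TOTAL_ABUNDANCE,
    ComparisonSpec,
    GroupSelector,
)
from .viz import (
    abundance_bars,
    isotopologue_stacked_bars,
    metabologram_figure,
    pca_plot,
    save_figure,
    timecourse_curves,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


def load_dataset(cfg: RunConfig, base_dir: Path | None = None) -> Dataset:
    """Materialize the dataset a config describes (files or preset)."""
    d = cfg.dataset
    if d.preset is not None:
        dataset, _truth = generate_preset(d.preset, seed=cfg.statistics.seed)
        return dataset
    base = base_dir or Path(".")

    def _p(rel: str | None) -> Path | None:
        return None if rel is None else (base / rel)

    sheet = io.read_sample_sheet(_p(d.samplesheet))
    iso = (
        io.read_isotopologue_table(_p(d.isotopologues), mode=d.isotopologues_mode)
        if d.isotopologues
        else None
    )
    abund = (
        io.read_metabolite_table(_p(d.abundances), quantity=TOTAL_ABUNDANCE)
        if d.abundances
        else None
    )
    frac = (
        io.read_metabolite_table(_p(d.fractional), quantity=FRACTIONAL_CONTRIBUTION)
        if d.fractional
        else None
    )
    return harmonize_inputs(
        samplesheet=sheet, isotopologues=iso, abundance=abund, fractional=frac
    )


def _comparison_spec(c, stats_cfg) -> ComparisonSpec:
    groups = [GroupSelector(g.condition, g.timepoint) for g in c.groups]
    test = c.test or ("kruskal_wallis" if c.kind == "multigroup" else "permutation")
    return ComparisonSpec(
        kind=c.kind, groups=groups, test=test,
        correction=stats_cfg.fdr_method, alpha=stats_cfg.alpha,
    )


def run_pipeline(cfg: RunConfig, base_dir: Path | None = None) -> Path:
    """Execute the configured workflow; returns the output directory."""
    out = Path(cfg.output_dir)
    tables_dir = out / "tables"
    figures_dir = out / "figures"
    logs_dir = out / "logs"
    for d in (tables_dir, figures_dir, logs_dir):
        d.mkdir(parents=True, exist_ok=True)

    events: list[dict] = []

    def event(stage: str, **kw) -> None:
        events.append({"stage": stage, **kw})
        logger.info("%s: %s", stage, kw)

    def run_stage(stage: str, fn):
        try:
            return fn()
        except Exception as err:  # noqa: BLE001 - re-raised with stage context
            raise StageError(stage, err) from err

    # -- preprocess --------------------------------------------------------
    dataset = run_stage("preprocess", lambda: load_dataset(cfg, base_dir))
    for line in dataset.log:
        event("preprocess", note=line)
    if dataset.isotopologues_absolute is not None:
        io.write_isotopologue_table(
            dataset.isotopologues_absolute, tables_dir / "isotopologues_absolute.tsv"
        )
    if dataset.isotopologues_proportion is not None:
        io.write_isotopologue_table(
            dataset.isotopologues_proportion, tables_dir / "isotopologues_proportions.tsv"
        )
    if dataset.abundance is not None:
        io.write_metabolite_table(dataset.abundance, tables_dir / "total_abundances.tsv")
    if dataset.fractional is not None:
        io.write_metabolite_table(
            dataset.fractional, tables_dir / "fractional_contributions.tsv"
        )
    io.write_sample_sheet(dataset.samplesheet, tables_dir / "samplesheet.tsv")

    stats_cfg = cfg.statistics
    comparison_results: dict[str, dict[str, pd.DataFrame]] = {}

    # -- pairwise / multigroup comparisons --------------------------------
    for c in cfg.comparisons:
        spec = _comparison_spec(c, stats_cfg)
        res = run_stage(
            f"diff[{spec.label()}]",
            lambda spec=spec: run_comparison(
                dataset, spec,
                tests_per_quantity=stats_cfg.tests_per_quantity or None,
                n_permutations=stats_cfg.n_permutations,
                seed=stats_cfg.seed,
            ),
        )
        comparison_results[spec.label()] = res
        for quantity, frame in res.items():
            name = f"diff_{spec.label()}_{quantity}.tsv".replace("/", "-")
            io.write_result_table(frame, tables_dir / name)
            event("diff", comparison=spec.label(), quantity=quantity,
                  n_features=len(frame), n_significant=int(frame["significant"].sum()))

        if dataset.abundance is not None:
            fig, vals = abundance_bars(
                dataset.abundance, dataset,
                [GroupSelector(g.condition, g.timepoint) for g in c.groups],
            )
            save_figure(fig, figures_dir / f"abundance_bars_{spec.label()}".replace("/", "-"))
            io.write_result_table(
                vals, tables_dir / f"abundance_bars_{spec.label()}_values.tsv".replace("/", "-")
            )
        if dataset.isotopologues_proportion is not None:
            fig, vals = isotopologue_stacked_bars(
                dataset, [GroupSelector(g.condition, g.timepoint) for g in c.groups]
            )
            save_figure(fig, figures_dir / f"stacked_mdv_{spec.label()}".replace("/", "-"))
            io.write_result_table(
                vals, tables_dir / f"stacked_mdv_{spec.label()}_values.tsv".replace("/", "-")
            )

    # -- time course -------------------------------------------------------
    if cfg.timecourse.enabled:
        tc = run_stage(
            "timecourse",
            lambda: timecourse_comparisons(
                dataset, condition=cfg.timecourse.condition,
                test=cfg.timecourse.test, correction=stats_cfg.fdr_method,
                alpha=stats_cfg.alpha, n_permutations=stats_cfg.n_permutations,
                seed=stats_cfg.seed,
            ),
        )
        io.write_result_table(tc, tables_dir / "timecourse_comparisons.tsv")
        io.write_result_table(time_responsive(tc), tables_dir / "time_responsive.tsv")
        event("timecourse", n_families=tc["comparison"].nunique())
        for quantity in dataset.quantity_tables():
            if quantity == "isotopologue_proportion":
                continue
            fig, vals = timecourse_curves(
                dataset, quantity, condition=cfg.timecourse.condition
            )
            save_figure(fig, figures_dir / f"timecourse_{quantity}")
            io.write_result_table(vals, tables_dir / f"timecourse_{quantity}_values.tsv")

    # -- bivariate MDV -----------------------------------------------------
    if cfg.bivariate.enabled:
        if dataset.isotopologues_proportion is None:
            event("bivariate", skipped="no isotopologue data")
        else:
            bi = run_stage(
                "bivariate",
                lambda: timecourse_mdv(
                    dataset, condition=cfg.bivariate.condition,
                    correction=stats_cfg.fdr_method, alpha=stats_cfg.alpha,
                ),
            )
            io.write_result_table(bi, tables_dir / "mdv_correlations.tsv")
            event("bivariate", n_rows=len(bi))

    # -- PCA ---------------------------------------------------------------
    if cfg.pca.enabled:
        table = (
            dataset.abundance if cfg.pca.quantity == TOTAL_ABUNDANCE else dataset.fractional
        )
        if table is None:
            event("pca", skipped=f"{cfg.pca.quantity} unavailable")
        else:
            res = run_stage(
                "pca",
                lambda: pca_overview(
                    table, scaling=cfg.pca.scaling, n_components=cfg.pca.n_components
                ),
            )
            res.scores.to_csv(tables_dir / "pca_scores.tsv", sep="\t",
                              float_format=io.FLOAT_FORMAT, lineterminator="\n")
            res.loadings.to_csv(tables_dir / "pca_loadings.tsv", sep="\t",
                                float_format=io.FLOAT_FORMAT, lineterminator="\n")
            fig, vals = pca_plot(res, dataset)
            save_figure(fig, figures_dir / "pca")
            event("pca", explained=[round(float(v), 4) for v in res.explained_variance_ratio])

    # -- metabologram ------------------------------------------------------
    mg = cfg.metabologram
    if mg.enabled and mg.pathways and mg.deg:
        base = base_dir or Path(".")
        pathways = read_pathway_definitions(base / mg.pathways)
        deg = pd.read_csv(base / mg.deg, sep="\t")
        label = mg.comparison or (next(iter(comparison_results), None))
        if label is None or label not in comparison_results:
            event("metabologram", skipped="no matching comparison results")
        else:
            met_res = comparison_results[label][
                TOTAL_ABUNDANCE if mg.quantity == TOTAL_ABUNDANCE else FRACTIONAL_CONTRIBUTION
            ]
            seg_frames = []
            for pw in pathways:
                gram = run_stage(
                    f"metabologram[{pw.pathway_id}]",
                    lambda pw=pw: build_metabologram(
                        pw, met_res, deg, alpha=stats_cfg.alpha, comparison=label
                    ),
                )
                fig, vals = metabologram_figure(gram)
                save_figure(fig, figures_dir / f"metabologram_{pw.pathway_id}")
                seg_frames.append(vals)
            io.write_result_table(
                pd.concat(seg_frames, ignore_index=True),
                tables_dir / "metabologram_segments.tsv",
            )
            if mg.graph_edges and mg.graph_nodes and FRACTIONAL_CONTRIBUTION in comparison_results[label]:
                graph = read_pathway_graph(base / mg.graph_edges, base / mg.graph_nodes)
                net = project_subnetwork(
                    graph,
                    comparison_results[label][TOTAL_ABUNDANCE],
                    comparison_results[label][FRACTIONAL_CONTRIBUTION],
                    deg, alpha=stats_cfg.alpha,
                )
                edges = pd.DataFrame(
                    [{"source": u, "target": v, "style": d["style"]}
                     for u, v, d in net.graph.edges(data=True)]
                )
                io.write_result_table(edges, tables_dir / "subnetwork_edges.tsv")
            event("metabologram", n_pathways=len(pathways))

    # -- manifest and logs -------------------------------------------------
    config_text = yaml.safe_dump(cfg.dump(), sort_keys=True)
    manifest = {
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "seed": stats_cfg.seed,
        "versions": {
            "isodiff": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "scikit-learn": sklearn.__version__,
            "matplotlib": matplotlib.__version__,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (logs_dir / "events.jsonl").write_text(
        "".join(json.dumps(e, sort_keys=True) + "\n" for e in events)
    )
    (logs_dir / "run.log").write_text(
        "\n".join(f"{e['stage']}: " + ", ".join(f"{k}={v}" for k, v in e.items() if k != "stage")
                  for e in events) + "\n"
    )
    return out
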