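"""Deterministic synthetic SIRM datasets with known ground truth.

The generator emulates a targeted ¹³C₆-glucose tracing experiment: each
(metabolite, sample) cell is a total pool size times a mass distribution
vector. Pool sizes are lognormal around a condition mean (multiplicative
replicate noise, as measured intensities typically are); replicate MDVs
are drawn from a Dirichlet centered on the condition/timepoint MDV, which
keeps them on the simplex by construction. Time courses start unlabeled
(all mass in m+0 at t = 0) and relax exponentially toward a steady-state
MDV, mimicking label incorporation before isotopic steady state.

Two presets mirror a typical study design: a two-condition knockout
comparison in triplicate at one timepoint, and a single-condition
six-timepoint labeling kinetics experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .preprocess import Dataset, harmonize_inputs
from .tables import ABSOLUTE, IsotopologueTable, SampleSheet


@dataclass(frozen=True)
class Effect:
    """One injected group difference, referenced by the ground-truth table.

    ``magnitude`` units depend on the target: for ``abundance`` it is the
    shift of the log-scale mean in units of the replicate log-SD (so 2.0
    means a 2σ effect); for ``enrichment`` it is the absolute shift of the
    fractional contribution φ (e.g. 0.15).
    """

    metabolite: str
    target: str  # "abundance" | "enrichment"
    direction: int  # +1 or -1
    magnitude: float

    def __post_init__(self) -> None:
        if self.target not in ("abundance", "enrichment"):
            raise ValueError(f"unknown effect target {self.target!r}")
        if self.magnitude < 0:
            raise ValueError("effect magnitudes must be ≥ 0")
        if self.direction not in (-1, 1):
            raise ValueError("direction must be ±1")


@dataclass(frozen=True)
class FixtureSpec:
    """Full description of a synthetic experiment."""

    metabolites: tuple[tuple[str, int], ...]  # (id, carbon count n)
    conditions: tuple[str, ...]
    timepoints_hours: tuple[float, ...]
    replicates: int = 3
    effects: tuple[Effect, ...] = ()
    cv: float = 0.2  # lognormal replicate CV of total abundances
    dirichlet_concentration: float = 500.0  # MDV replicate tightness
    label_halftime_hours: float = 2.0  # default labeling relaxation time
    unlabeled_metabolites: tuple[str, ...] = ()  # never incorporate tracer
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv <= 0 or self.dirichlet_concentration <= 0:
            raise ValueError("cv and dirichlet_concentration must be > 0")
        declared = {m for m, _ in self.metabolites}
        for e in self.effects:
            if e.metabolite not in declared:
                raise ValueError(f"effect references undeclared metabolite {e.metabolite!r}")

    @property
    def sigma_log(self) -> float:
        """Log-scale SD implied by the lognormal CV."""
        return float(np.sqrt(np.log1p(self.cv**2)))


def _steady_mdv(rng: np.random.Generator, n: int) -> np.ndarray:
    """A plausible steady-state MDV: labeled but not saturated."""
    raw = rng.dirichlet(np.ones(n + 1) * 1.5)
    # guarantee some unlabeled and some labeled mass
    raw = 0.85 * raw + 0.15 / (n + 1)
    return raw / raw.sum()


def _shift_enrichment(mdv: np.ndarray, delta_phi: float) -> np.ndarray:
    """Mix the MDV toward the fully (un)labeled corner to move φ by delta."""
    n = mdv.size - 1
    j = np.arange(n + 1)
    phi = float((mdv * j).sum() / n)
    target_vec = np.zeros(n + 1)
    if delta_phi >= 0:
        target_vec[-1] = 1.0
        gap = 1.0 - phi
    else:
        target_vec[0] = 1.0
        gap = phi
    if gap <= 0:
        return mdv
    w = min(abs(delta_phi) / gap, 1.0)
    return (1 - w) * mdv + w * target_vec


def generate_dataset(spec: FixtureSpec) -> tuple[Dataset, pd.DataFrame]:
    """Simulate the experiment and return (dataset, ground-truth table).

    The ground truth lists, per metabolite, the injected abundance and
    enrichment effects (0 for null features), so recovery studies can
    score detections without ambiguity. The same spec (same seed) always
    produces byte-identical tables.
    """
    rng = np.random.default_rng(spec.seed)
    mets = dict(spec.metabolites)
    reference = spec.conditions[0]

    # per-metabolite baseline parameters, drawn once
    base_mean = {m: 10 ** rng.uniform(4.5, 6.5) for m in mets}
    steady = {m: _steady_mdv(rng, n) for m, n in mets.items()}
    for m in spec.unlabeled_metabolites:
        vec = np.zeros(mets[m] + 1)
        vec[0] = 1.0
        steady[m] = vec  # stays at m+0: no tracer incorporation
    halftime = {
        m: spec.label_halftime_hours * 2 ** rng.uniform(-1, 1) for m in mets
    }

    eff_by_met: dict[str, dict[str, float]] = {m: {"abundance": 0.0, "enrichment": 0.0} for m in mets}
    for e in spec.effects:
        eff_by_met[e.metabolite][e.target] += e.direction * e.magnitude

    samples: list[str] = []
    sheet_rows = []
    columns: dict[str, np.ndarray] = {}
    index = pd.MultiIndex.from_tuples(
        [(m, i) for m, n in spec.metabolites for i in range(n + 1)],
        names=["metabolite", "isotopologue_index"],
    )

    def fmt_h(h: float) -> str:
        return str(int(h)) if float(h).is_integer() else f"{h:g}"

    for cond in spec.conditions:
        for hours in spec.timepoints_hours:
            for rep in range(1, spec.replicates + 1):
                sid = f"{cond}_T{fmt_h(hours)}_{rep}"
                samples.append(sid)
                sheet_rows.append(
                    {"sample_id": sid, "condition": cond,
                     "timepoint_name": f"T{fmt_h(hours)}",
                     "timepoint_hours": float(hours), "replicate": rep}
                )
                col = np.empty(len(index))
                pos = 0
                for m, n in spec.metabolites:
                    # label incorporation: unlabeled at t=0, exponential approach
                    w = 1.0 - 2 ** (-float(hours) / halftime[m])
                    mdv = np.zeros(n + 1)
                    mdv[0] = 1.0
                    mdv = (1 - w) * mdv + w * steady[m]
                    mu = np.log(base_mean[m])
                    if cond != reference:
                        mu += eff_by_met[m]["abundance"] * spec.sigma_log
                        dphi = eff_by_met[m]["enrichment"]
                        if dphi != 0.0 and n >= 1:
                            mdv = _shift_enrichment(mdv, dphi * w if hours > 0 else 0.0)
                    total = float(np.exp(rng.normal(mu, spec.sigma_log)))
                    alpha = spec.dirichlet_concentration * (mdv + 1e-6)
                    mdv_rep = rng.dirichlet(alpha)
                    col[pos:pos + n + 1] = total * mdv_rep
                    pos += n + 1
                columns[sid] = col

    iso = IsotopologueTable(
        data=pd.DataFrame(columns, index=index), mode=ABSOLUTE
    )
    sheet = SampleSheet(data=pd.DataFrame(sheet_rows).set_index("sample_id"))
    dataset = harmonize_inputs(samplesheet=sheet, isotopologues=iso)

    truth = pd.DataFrame(
        [
            {"metabolite": m, "n_carbons": n,
             "abundance_effect": eff_by_met[m]["abundance"],
             "enrichment_effect": eff_by_met[m]["enrichment"],
             "is_null": eff_by_met[m]["abundance"] == 0 and eff_by_met[m]["enrichment"] == 0}
            for m, n in spec.metabolites
        ]
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# DEG table generator (feeds the integration stage)
# ---------------------------------------------------------------------------

def generate_deg_table(
    genes: list[str],
    effects: dict[str, float] | None = None,
    *,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic differential-expression results with known up/down genes.

    Genes in ``effects`` get the configured log2 fold change (plus small
    noise) and an adjusted p below ``alpha``; all other genes are null:
    near-zero fold change and a non-significant adjusted p.
    """
    rng = np.random.default_rng(seed)
    effects = effects or {}
    rows = []
    for g in genes:
        if g in effects:
            lfc = effects[g] + rng.normal(0, 0.05)
            p_adj = float(rng.uniform(alpha * 1e-3, alpha * 0.8))
        else:
            lfc = rng.normal(0, 0.1)
            p_adj = float(rng.uniform(max(alpha * 1.5, 0.2), 1.0))
        rows.append({"gene": g, "effect": float(lfc), "p_adj": p_adj})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

#: two-condition knockout comparison: triplicates at 48 h, ten metabolites
#: including 5-carbon analogs of alpha-ketoglutarate and glutamate whose
#: enrichment drops while the AKG-like pool accumulates
LDH_KO_48H = FixtureSpec(
    metabolites=(
        ("AKG_like", 5), ("Glutamate_like", 5), ("Citrate_like", 6),
        ("Malate_like", 4), ("Aspartate_like", 4), ("Succinate_like", 4),
        ("Pyruvate_like", 3), ("Lactate_like", 3), ("Alanine_like", 3),
        ("Serine_like", 3),
    ),
    conditions=("control", "KO"),
    timepoints_hours=(48.0,),
    replicates=3,
    effects=(
        Effect("AKG_like", "abundance", +1, 2.0),
        Effect("Citrate_like", "abundance", -1, 2.0),
        Effect("Lactate_like", "abundance", -1, 2.0),
        Effect("AKG_like", "enrichment", -1, 0.15),
        Effect("Glutamate_like", "enrichment", -1, 0.15),
    ),
    seed=0,
)

#: single-condition labeling kinetics: six timepoints spanning 0–24 h in
#: triplicate; one metabolite never labels (its MDV stays at m+0)
TIMECOURSE_P3 = FixtureSpec(
    metabolites=(
        ("AKG_like", 5), ("Glutamate_like", 5), ("Glutamine_like", 5),
        ("Malate_like", 4), ("Aspartate_like", 4), ("Succinate_like", 4),
        ("Oxaloacetate_like", 4), ("Pyruvate_like", 3),
        ("Unlabeled_control", 3),
    ),
    conditions=("control",),
    timepoints_hours=(0.0, 1.0, 2.0, 4.0, 6.0, 24.0),
    replicates=3,
    effects=(),
    unlabeled_metabolites=("Unlabeled_control",),
    seed=0,
)

PRESETS: dict[str, FixtureSpec] = {
    "ldh_ko_48h": LDH_KO_48H,
    "timecourse_p3": TIMECOURSE_P3,
}


def generate_preset(name: str, seed: int | None = None) -> tuple[Dataset, pd.DataFrame]:
    """Generate a named preset, optionally re-seeded."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    spec = PRESETS[name]
    if seed is not None:
        spec = replace(spec, seed=seed)
    return generate_dataset(spec)
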