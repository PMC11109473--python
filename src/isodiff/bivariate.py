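"""Bivariate comparison of whole labeling profiles (MDVs).

Instead of testing isotopologues one at a time, the entire mass
distribution vector of a metabolite in one group is correlated against
its counterpart in another group using Spearman's rank correlation. A
high ρ across a comparison indicates that the labeling pattern is
preserved (e.g. a sustained, shape-stable increase in enrichment over a
time course), while a low ρ flags a qualitative change in the pattern.

Profiles are group means of per-sample proportions. p-values come from
the exact permutation distribution of ρ for short profiles (n+1 ≤ 8
isotopologues) and from the t approximation otherwise; the per-comparison
collection is FDR-adjusted with the same machinery as the univariate
results.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffstats import adjust_pvalues
from .preprocess import Dataset
from .tables import GroupSelector

#: profiles up to this length use the exact permutation null for ρ
EXACT_PROFILE_LIMIT = 8


@dataclass
class MDVProfilePair:
    """Mean MDV of one metabolite under two groups."""

    metabolite_id: str
    profile_a: np.ndarray
    profile_b: np.ndarray
    group_labels: tuple[str, str] = ("A", "B")

    def __post_init__(self) -> None:
        self.profile_a = np.asarray(self.profile_a, dtype=float)
        self.profile_b = np.asarray(self.profile_b, dtype=float)
        if self.profile_a.shape != self.profile_b.shape:
            raise ValueError("profiles must have equal length")


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """P(|ρ*| ≥ |ρ|) over all permutations of one profile's ranks."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = rx.size
    rhos = np.array(
        [np.corrcoef(rx, np.take(ry, perm))[0, 1]
         for perm in itertools.permutations(range(n))]
    )
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def mdv_correlation(pair: MDVProfilePair) -> tuple[float, float]:
    """Spearman ρ (midrank ties) and two-sided p for one profile pair.

    Raises ``ValueError`` for profiles shorter than 3 points (n ≤ 1
    carbons — rank correlation is degenerate there) and returns
    ``(nan, nan)`` when either profile is constant, since ρ is undefined
    without rank variance.
    """
    a, b = pair.profile_a, pair.profile_b
    if a.size < 3:
        raise ValueError(
            f"{pair.metabolite_id}: profile length {a.size} < 3; "
            "correlation is degenerate for ≤2-point MDVs"
        )
    if np.any(~np.isfinite(a)) or np.any(~np.isfinite(b)):
        raise ValueError(f"{pair.metabolite_id}: missing entries in mean profile")
    if np.unique(a).size == 1 or np.unique(b).size == 1:
        return float("nan"), float("nan")
    rho = float(stats.spearmanr(a, b).statistic)
    # snap float residue so perfectly concordant/discordant ranks give ±1
    if abs(abs(rho) - 1.0) < 1e-12:
        rho = float(np.sign(rho))
    if a.size <= EXACT_PROFILE_LIMIT:
        p = _exact_spearman_p(a, b, rho)
    else:
        p = float(stats.spearmanr(a, b).pvalue)
    return rho, p


def _mean_profiles(dataset: Dataset, samples: list[str]) -> dict[str, np.ndarray]:
    table = dataset.isotopologues_proportion
    if table is None:
        raise ValueError("bivariate analysis requires isotopologue proportions")
    sub = table.data[samples].mean(axis=1)
    return {
        met: sub.loc[met].sort_index().to_numpy(dtype=float)
        for met in table.metabolites
    }


def compare_mdv_profiles(
    dataset: Dataset,
    group_a: GroupSelector,
    group_b: GroupSelector,
    *,
    correction: str = "BH",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Correlate every metabolite's mean MDV between two groups.

    Metabolites with n ≤ 1 carbons or incomplete mean profiles are
    reported with a reason code instead of a correlation. The ρ p-values
    of the comparison form one FDR family.
    """
    samples_a = dataset.samplesheet.select(group_a.condition, group_a.timepoint)
    samples_b = dataset.samplesheet.select(group_b.condition, group_b.timepoint)
    if not samples_a or not samples_b:
        raise ValueError("a group selector matches no samples")
    prof_a = _mean_profiles(dataset, samples_a)
    prof_b = _mean_profiles(dataset, samples_b)

    label = f"{group_a.label()}_vs_{group_b.label()}"
    rows = []
    for met in sorted(prof_a):
        a, b = prof_a[met], prof_b[met]
        row = {"metabolite": met, "comparison": label,
               "rho": np.nan, "p_raw": np.nan, "reason": ""}
        if a.size < 3:
            row["reason"] = "skipped: n ≤ 1 carbons, 2-point profile"
        elif np.any(~np.isfinite(a)) or np.any(~np.isfinite(b)):
            row["reason"] = "skipped: missing values in mean profile"
        else:
            rho, p = mdv_correlation(MDVProfilePair(met, a, b))
            if np.isnan(rho):
                row["reason"] = "undefined: constant profile (no rank variance)"
            else:
                row["rho"], row["p_raw"] = rho, p
        rows.append(row)
    out = pd.DataFrame(rows)
    out["p_adj"] = adjust_pvalues(out["p_raw"].to_numpy(), correction)
    out["significant"] = out["p_adj"].le(alpha).fillna(False)
    return out


def timecourse_mdv(
    dataset: Dataset,
    *,
    condition: str | None = None,
    correction: str = "BH",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """MDV profile correlation for every consecutive timepoint pair."""
    tp = dataset.samplesheet.timepoints()
    hours = tp["timepoint_hours"].to_numpy()
    frames = []
    for t0, t1 in zip(hours[:-1], hours[1:]):
        res = compare_mdv_profiles(
            dataset,
            GroupSelector(condition=condition, timepoint=float(t1)),
            GroupSelector(condition=condition, timepoint=float(t0)),
            correction=correction,
            alpha=alpha,
        )
        t0s = str(int(t0)) if t0.is_integer() else f"{t0:g}"
        t1s = str(int(t1)) if t1.is_integer() else f"{t1:g}"
        frames.append(res.assign(comparison=f"{t1s}vs{t0s}"))
    return pd.concat(frames, ignore_index=True)
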