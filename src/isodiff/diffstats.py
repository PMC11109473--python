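"""Univariate differential testing with FDR control.

Pairwise two-group tests (parametric and nonparametric), a multi-group
Kruskal–Wallis test, a permutation test with automatic exhaustive
enumeration at small sample sizes, Benjamini–Hochberg (and related)
multiple-testing adjustment, and the orchestration that applies one test
per feature across a whole dataset and per quantity type.

Conventions
-----------
* All p-values are two-sided.
* Test statistics are oriented so that a positive value means group A is
  located above group B (rank statistics are centered at their null mean).
* Multiple-testing families are one (comparison × quantity type): results
  for total abundances are never pooled with isotopologue results.
* Randomness is controlled by a single top-level seed; each feature gets
  a sub-seed derived from the feature id, so feature order never changes
  any result.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass
from math import comb
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import Dataset
from .tables import (
    FRACTIONAL_CONTRIBUTION,
    ISOTOPOLOGUE_PROPORTION,
    RESULT_COLUMNS,
    TOTAL_ABUNDANCE,
    ComparisonSpec,
    GroupSelector,
)


class ConfigurationError(ValueError):
    """A statistical option is out of its supported range."""


class SpecificationError(ValueError):
    """A comparison spec cannot be resolved against the sample sheet."""


class InsufficientDataError(ValueError):
    """Too few non-missing observations for the requested test."""


# ---------------------------------------------------------------------------
# Test catalog
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TestCatalogEntry:
    name: str
    paired: bool
    min_group_size: int
    arity: Literal["2", ">=2", ">=3"]


TEST_CATALOG: dict[str, TestCatalogEntry] = {
    "t_test": TestCatalogEntry("t_test", paired=False, min_group_size=2, arity="2"),
    "mann_whitney": TestCatalogEntry("mann_whitney", paired=False, min_group_size=2, arity="2"),
    "wilcoxon_signed_rank": TestCatalogEntry(
        "wilcoxon_signed_rank", paired=True, min_group_size=2, arity="2"
    ),
    "wilcoxon_rank_sum": TestCatalogEntry(
        "wilcoxon_rank_sum", paired=False, min_group_size=2, arity="2"
    ),
    "kruskal_wallis": TestCatalogEntry(
        "kruskal_wallis", paired=False, min_group_size=2, arity=">=2"
    ),
    "permutation": TestCatalogEntry("permutation", paired=False, min_group_size=2, arity="2"),
}

#: both rank-test groups at or below this size use the exact null distribution
EXACT_SIZE_LIMIT = 25

#: defaults mirroring the use the tests see in practice: rank-sum for
#: isotopologue proportions, permutation for abundances and enrichment
DEFAULT_TESTS_PER_QUANTITY = {
    TOTAL_ABUNDANCE: "permutation",
    FRACTIONAL_CONTRIBUTION: "permutation",
    ISOTOPOLOGUE_PROPORTION: "wilcoxon_rank_sum",
}


def _clean(x: Sequence[float]) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x[np.isfinite(x)]


def _has_ties(pooled: np.ndarray) -> bool:
    return np.unique(pooled).size < pooled.size


# ---------------------------------------------------------------------------
# Pairwise tests
# ---------------------------------------------------------------------------

def pairwise_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    test: str = "mann_whitney",
    *,
    n_permutations: int = 10_000,
    permutation_statistic: str = "mean_diff",
    rng: np.random.Generator | int | None = None,
    equal_var: bool = True,
) -> tuple[float, float]:
    """Two-sided comparison of two sample vectors.

    Returns ``(statistic, p_raw)``. The statistic is signed so that a
    positive value indicates group A located above group B. Missing values
    are removed pairwise (paired tests drop incomplete pairs).
    """
    entry = TEST_CATALOG.get(test)
    if entry is None:
        raise ConfigurationError(
            f"unknown test {test!r}; supported: {sorted(TEST_CATALOG)}"
        )

    if entry.paired:
        a = np.asarray(values_a, dtype=float)
        b = np.asarray(values_b, dtype=float)
        if a.size != b.size:
            raise InsufficientDataError("paired test requires equal-length aligned vectors")
        keep = np.isfinite(a) & np.isfinite(b)
        a, b = a[keep], b[keep]
    else:
        a, b = _clean(values_a), _clean(values_b)

    if min(a.size, b.size) < entry.min_group_size:
        raise InsufficientDataError(
            f"{test}: group sizes ({a.size}, {b.size}) below minimum {entry.min_group_size}"
        )

    if test == "t_test":
        res = stats.ttest_ind(a, b, equal_var=equal_var)
        # zero pooled variance with unequal means gives p = 0 exactly;
        # clamp into (0, 1] so the FDR contract holds for degenerate data
        p = float(res.pvalue)
        if p == 0.0:
            p = float(np.finfo(float).tiny)
        return float(res.statistic), p

    if test in ("mann_whitney", "wilcoxon_rank_sum"):
        pooled = np.concatenate([a, b])
        if _has_ties(pooled) or max(a.size, b.size) > EXACT_SIZE_LIMIT:
            method = "asymptotic"
        else:
            method = "exact"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        # centered U: identical to the centered rank sum of group A
        statistic = float(res.statistic) - a.size * b.size / 2.0
        return statistic, float(res.pvalue)

    if test == "wilcoxon_signed_rank":
        d = a - b
        if np.all(d == 0):
            # degenerate: no information against the null
            return 0.0, 1.0
        nz = d[d != 0]
        method = (
            "exact"
            if (nz.size <= EXACT_SIZE_LIMIT and not _has_ties(np.abs(nz)))
            else "approx"
        )
        res = stats.wilcoxon(a, b, zero_method="wilcox", method=method)
        # scipy reports min(W+, W−); recover W+ for a signed orientation
        ranks = stats.rankdata(np.abs(nz))
        w_plus = float(ranks[nz > 0].sum())
        statistic = w_plus - nz.size * (nz.size + 1) / 4.0
        return statistic, float(res.pvalue)

    if test == "kruskal_wallis":
        h, p = multigroup_test([a, b], min_groups=2)
        sign = np.sign(np.mean(a) - np.mean(b)) or 1.0
        return float(sign * h), p

    if test == "permutation":
        stat, p, _exact = permutation_test(
            a, b, n_permutations=n_permutations,
            statistic=permutation_statistic, rng=rng,
        )
        return stat, p

    raise AssertionError(f"unhandled test {test}")  # pragma: no cover


# ---------------------------------------------------------------------------
# Permutation test
# ---------------------------------------------------------------------------

_PERM_STATISTICS = ("mean_diff", "abs_mean_diff", "rank_sum")


def _perm_stat_values(pooled: np.ndarray, statistic: str) -> np.ndarray:
    """Pooled per-observation values whose group-A sum defines the statistic."""
    if statistic == "rank_sum":
        return stats.rankdata(pooled)  # midranks
    return pooled


def permutation_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    n_permutations: int = 10_000,
    statistic: str = "mean_diff",
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float, bool]:
    """Two-group permutation test on group labels.

    The null distribution is built by re-assigning group labels. When the
    number of distinct labelings C(n_A + n_B, n_A) does not exceed
    ``n_permutations``, all labelings are enumerated and the p-value is
    exact (flagged by the returned boolean). Otherwise ``n_permutations``
    random labelings are drawn and the add-one rule
    ``p = (1 + #{|T*| ≥ |T|}) / (1 + n_permutations)`` guarantees p > 0.

    Returns ``(statistic, p_raw, exact)``.
    """
    if statistic not in _PERM_STATISTICS:
        raise ConfigurationError(
            f"unknown permutation statistic {statistic!r}; supported: {_PERM_STATISTICS}"
        )
    if n_permutations < 100:
        raise ConfigurationError("n_permutations must be at least 100")

    a, b = _clean(values_a), _clean(values_b)
    na, nb = a.size, b.size
    if na + nb < 4 or na < 1 or nb < 1:
        raise InsufficientDataError(
            f"permutation test needs ≥4 pooled observations (got {na}+{nb})"
        )

    pooled = np.concatenate([a, b])
    base = _perm_stat_values(pooled, statistic)

    def group_stat(sum_a: np.ndarray) -> np.ndarray:
        total = base.sum()
        if statistic == "rank_sum":
            # centered rank sum of group A
            return sum_a - na * (na + nb + 1) / 2.0
        diff = sum_a / na - (total - sum_a) / nb
        return np.abs(diff) if statistic == "abs_mean_diff" else diff

    t_obs = float(group_stat(np.asarray(base[:na].sum())))
    thresh = abs(t_obs) - 1e-12 * max(1.0, abs(t_obs))

    n_total = comb(na + nb, na)
    if n_total <= n_permutations:
        idx = np.fromiter(
            itertools.chain.from_iterable(itertools.combinations(range(na + nb), na)),
            dtype=np.intp, count=n_total * na,
        ).reshape(n_total, na)
        t_all = group_stat(base[idx].sum(axis=1))
        p = float(np.count_nonzero(np.abs(t_all) >= thresh)) / n_total
        return t_obs, p, True

    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    tiled = np.broadcast_to(base, (n_permutations, base.size))
    perms = rng.permuted(tiled, axis=1)
    t_perm = group_stat(perms[:, :na].sum(axis=1))
    count = int(np.count_nonzero(np.abs(t_perm) >= thresh))
    p = (1.0 + count) / (1.0 + n_permutations)
    return t_obs, p, False


# ---------------------------------------------------------------------------
# Multi-group test
# ---------------------------------------------------------------------------

def multigroup_test(
    groups: Sequence[Sequence[float]], min_groups: int = 3
) -> tuple[float, float]:
    """Kruskal–Wallis H with tie correction; p from χ²(k−1).

    The nonparametric alternative to one-way ANOVA used for three or more
    groups where normality and homoscedasticity cannot be assumed.
    """
    cleaned = [_clean(g) for g in groups]
    if len(cleaned) < min_groups:
        raise ConfigurationError(f"multi-group test needs ≥{min_groups} groups")
    for i, g in enumerate(cleaned):
        if g.size < 2:
            raise InsufficientDataError(f"group {i} has {g.size} non-missing values (<2)")
    pooled = np.concatenate(cleaned)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0  # all observations identical: H = 0 by continuity
    h, p = stats.kruskal(*cleaned)
    return float(h), float(p)


# ---------------------------------------------------------------------------
# Multiple-testing adjustment
# ---------------------------------------------------------------------------

#: step-up / step-down procedures resolved through statsmodels
FDR_METHODS: dict[str, str] = {
    "BH": "fdr_bh",
    "benjamini-hochberg": "fdr_bh",
    "BY": "fdr_by",
    "benjamini-yekutieli": "fdr_by",
    "bonferroni": "bonferroni",
    "holm": "holm",
    "holm-sidak": "holm-sidak",
    "sidak": "sidak",
    "hommel": "hommel",
    "fdr_tsbh": "fdr_tsbh",
    "fdr_tsbky": "fdr_tsbky",
}


def adjust_pvalues(p_raw: Sequence[float], method: str = "BH") -> np.ndarray:
    """Adjust raw p-values for multiple testing (Benjamini–Hochberg default).

    Missing entries pass through as missing and do not count toward the
    family size. Adjusted values are clipped to 1.
    """
    if method not in FDR_METHODS:
        raise ConfigurationError(
            f"unknown FDR method {method!r}; supported: {sorted(FDR_METHODS)}"
        )
    p = np.asarray(p_raw, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    if mask.any():
        vals = p[mask]
        if np.any((vals <= 0) | (vals > 1)):
            raise ValueError("p-values must lie in (0, 1]")
        out[mask] = multipletests(vals, method=FDR_METHODS[method])[1]
    return np.minimum(out, 1.0, where=np.isfinite(out), out=out)


# ---------------------------------------------------------------------------
# Effect sizes
# ---------------------------------------------------------------------------

def effect_size(a: np.ndarray, b: np.ndarray, quantity: str) -> float:
    """Signed effect of A versus B for one feature.

    Abundances (strictly positive, spanning decades) use the log2 ratio of
    group geometric means. Bounded quantities — fractional contributions
    and isotopologue proportions — use the difference of group means.
    """
    a, b = _clean(a), _clean(b)
    if quantity == TOTAL_ABUNDANCE:
        a, b = a[a > 0], b[b > 0]
        if a.size == 0 or b.size == 0:
            return float("nan")
        return float(np.mean(np.log2(a)) - np.mean(np.log2(b)))
    if a.size == 0 or b.size == 0:
        return float("nan")
    return float(np.mean(a) - np.mean(b))


# ---------------------------------------------------------------------------
# Dataset-level orchestration
# ---------------------------------------------------------------------------

def _feature_rng(seed: int, feature_id: str) -> np.random.Generator:
    # crc32 keyed sub-seed: independent of feature order, stable across runs
    return np.random.default_rng([seed, zlib.crc32(feature_id.encode())])


def _resolve_groups(dataset: Dataset, spec: ComparisonSpec) -> list[list[str]]:
    groups = []
    for sel in spec.groups:
        samples = dataset.samplesheet.select(sel.condition, sel.timepoint)
        if not samples:
            raise SpecificationError(f"selector {sel} matches no samples")
        groups.append(samples)
    return groups


def _align_pairs(
    sheet_data: pd.DataFrame, samples_a: list[str], samples_b: list[str]
) -> tuple[list[str], list[str]]:
    """Order paired groups by replicate index; require a full match."""
    rep_a = sheet_data.loc[samples_a, "replicate"].sort_values()
    rep_b = sheet_data.loc[samples_b, "replicate"].sort_values()
    if list(rep_a.values) != list(rep_b.values):
        raise SpecificationError(
            "paired test requires matching replicate indices in both groups"
        )
    return list(rep_a.index), list(rep_b.index)


def run_comparison(
    dataset: Dataset,
    spec: ComparisonSpec,
    *,
    tests_per_quantity: dict[str, str] | None = None,
    n_permutations: int = 10_000,
    permutation_statistic: str = "mean_diff",
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Apply one comparison to every feature of every quantity type.

    Returns one result frame per quantity type present in the dataset.
    FDR adjustment runs within each (comparison × quantity type) family;
    features with too few observations are reported with a reason code and
    a missing p-value, and do not count toward the family size.
    """
    groups = _resolve_groups(dataset, spec)
    tests = dict(DEFAULT_TESTS_PER_QUANTITY)
    if tests_per_quantity:
        tests.update(tests_per_quantity)

    results: dict[str, pd.DataFrame] = {}
    comparison_label = spec.label()
    for quantity, frame in dataset.quantity_tables().items():
        test = spec.test if spec.kind == "multigroup" else tests.get(quantity, spec.test)
        if spec.kind != "multigroup" and spec.test != "permutation":
            # an explicitly chosen pairwise test overrides the per-quantity default
            test = spec.test
        rows = []
        entry = TEST_CATALOG[test] if test in TEST_CATALOG else None
        group_samples = groups
        if entry is not None and entry.paired and len(groups) == 2:
            group_samples = list(
                _align_pairs(dataset.samplesheet.data, groups[0], groups[1])
            )
        for feature_id in frame.index:
            vals = [frame.loc[feature_id, g].to_numpy(dtype=float) for g in group_samples]
            row: dict = {
                "feature_id": feature_id,
                "comparison": comparison_label,
                "quantity": quantity,
                "mean_A": float(np.nanmean(vals[0])) if np.isfinite(vals[0]).any() else np.nan,
                "mean_B": float(np.nanmean(vals[1])) if len(vals) > 1 and np.isfinite(vals[1]).any() else np.nan,
                "effect": np.nan,
                "statistic": np.nan,
                "p_raw": np.nan,
                "reason": "",
            }
            try:
                if spec.kind == "multigroup":
                    stat, p = multigroup_test(vals)
                else:
                    stat, p = pairwise_test(
                        vals[0], vals[1], test,
                        n_permutations=n_permutations,
                        permutation_statistic=permutation_statistic,
                        rng=_feature_rng(seed, feature_id),
                    )
                    row["effect"] = effect_size(vals[0], vals[1], quantity)
                row["statistic"], row["p_raw"] = stat, p
            except InsufficientDataError as err:
                row["reason"] = f"skipped: {err}"
            rows.append(row)
        table = pd.DataFrame(rows)
        table["p_adj"] = adjust_pvalues(table["p_raw"].to_numpy(), spec.correction)
        table["significant"] = table["p_adj"].le(spec.alpha).fillna(False)
        results[quantity] = table[RESULT_COLUMNS]
    return results


# ---------------------------------------------------------------------------
# Time-course comparisons
# ---------------------------------------------------------------------------

def _fmt_hours(h: float) -> str:
    return str(int(h)) if float(h).is_integer() else f"{h:g}"


def timecourse_comparisons(
    dataset: Dataset,
    *,
    condition: str | None = None,
    test: str = "wilcoxon_rank_sum",
    correction: str = "BH",
    alpha: float = 0.05,
    tests_per_quantity: dict[str, str] | None = None,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Automatically compare consecutive timepoints t_{i+1} versus t_i.

    For T ordered timepoints, exactly T−1 comparison families are produced,
    labeled ``"<t_{i+1}>vs<t_i>"`` in hours. FDR runs within each
    (family × quantity type). The concatenated result frame is returned;
    use :func:`time_responsive` to collapse it to per-feature flags.
    """
    sheet = dataset.samplesheet
    tp = sheet.timepoints()
    if condition is not None:
        hours_present = sheet.data.loc[
            sheet.data["condition"] == condition, "timepoint_hours"
        ].unique()
        tp = tp[tp["timepoint_hours"].isin(hours_present)].reset_index(drop=True)
    hours = tp["timepoint_hours"].to_numpy()
    if hours.size < 2:
        raise SpecificationError("time-course analysis needs at least 2 timepoints")
    if np.unique(hours).size != hours.size:
        raise SpecificationError("duplicate timepoint hour values")

    frames = []
    tests = tests_per_quantity
    if tests is None:
        # one test across the board is the norm for time courses
        tests = {q: test for q in (TOTAL_ABUNDANCE, FRACTIONAL_CONTRIBUTION,
                                   ISOTOPOLOGUE_PROPORTION)}
    for t0, t1 in zip(hours[:-1], hours[1:]):
        spec = ComparisonSpec(
            kind="consecutive_timepoints",
            groups=[
                GroupSelector(condition=condition, timepoint=float(t1)),
                GroupSelector(condition=condition, timepoint=float(t0)),
            ],
            test=test,
            correction=correction,
            alpha=alpha,
        )
        res = run_comparison(
            dataset, spec, tests_per_quantity=tests,
            n_permutations=n_permutations, seed=seed,
        )
        label = f"{_fmt_hours(t1)}vs{_fmt_hours(t0)}"
        for quantity, frame in res.items():
            frame = frame.assign(comparison=label)
            frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def time_responsive(results: pd.DataFrame) -> pd.DataFrame:
    """Per-(feature, quantity) flag: significant in ≥1 consecutive comparison."""
    grouped = results.groupby(["feature_id", "quantity"], sort=True)
    out = grouped["significant"].any().rename("time_responsive").reset_index()
    out["n_significant_intervals"] = grouped["significant"].sum().to_numpy()
    return out
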