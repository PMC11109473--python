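"""Domain types for targeted stable-isotope tracing data.

The central objects are measurement tables indexed by feature and sample:

* :class:`IsotopologueTable` — one row per (metabolite, isotopologue index),
  holding either absolute corrected intensities ``M0..Mn`` or mass
  distribution vector (MDV) proportions ``c0..cn``.
* :class:`MetaboliteTable` — one row per metabolite, holding a scalar
  quantity per sample: total abundance ``m = Σ Mj`` or fractional
  contribution (mean enrichment) ``φ = Σ(cj·j)/n``.
* :class:`SampleSheet` — sample → (condition, timepoint, replicate).

Validation of the MDV algebra (index completeness, simplex constraints,
non-negativity) lives here as well.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

ABSOLUTE = "absolute"
PROPORTION = "proportion"
TOTAL_ABUNDANCE = "total_abundance"
FRACTIONAL_CONTRIBUTION = "fractional_contribution"
ISOTOPOLOGUE_PROPORTION = "isotopologue_proportion"

#: default tolerance for per-(metabolite, sample) proportion sums
DEFAULT_SUM_TOLERANCE = 0.02

_FEATURE_ID_RE = re.compile(r"^(?P<met>.+)_m\+(?P<idx>\d+)$")


def make_feature_id(metabolite: str, index: int) -> str:
    """Canonical isotopologue feature id, e.g. ``"Glutamate_m+2"``."""
    return f"{metabolite}_m+{int(index)}"


def split_feature_id(feature_id: str) -> tuple[str, int]:
    """Parse a ``metabolite_m+i`` id into (metabolite, isotopologue index)."""
    m = _FEATURE_ID_RE.match(feature_id)
    if m is None:
        raise ValueError(
            f"feature id {feature_id!r} does not follow the 'metabolite_m+i' convention"
        )
    return m.group("met"), int(m.group("idx"))


class StructuralError(ValueError):
    """Input table is malformed beyond what a violation record can express."""


@dataclass(frozen=True)
class Violation:
    """One validation failure, localized to (metabolite, sample, rule)."""

    metabolite: str
    sample: str | None
    rule: str
    detail: str = ""

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        where = self.metabolite if self.sample is None else f"{self.metabolite}/{self.sample}"
        return f"[{self.rule}] {where}: {self.detail}"


def _check_sample_axis(columns: Iterable[str]) -> list[str]:
    cols = list(columns)
    if len(cols) != len(set(cols)):
        raise StructuralError("duplicated sample columns")
    return cols


@dataclass
class IsotopologueTable:
    """Per-(metabolite, isotopologue-index) measurements across samples.

    ``data`` has a two-level row MultiIndex (metabolite, isotopologue_index)
    and one column per sample. ``mode`` is ``"absolute"`` for corrected
    intensities or ``"proportion"`` for MDV fractions.
    """

    data: pd.DataFrame
    mode: Literal["absolute", "proportion"]
    carbon_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in (ABSOLUTE, PROPORTION):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.data.index.nlevels != 2:
            raise StructuralError("expected a (metabolite, isotopologue_index) row index")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise StructuralError(f"duplicated (metabolite, isotopologue) entries: {dups}")
        _check_sample_axis(self.data.columns)
        self.data.index = self.data.index.set_names(["metabolite", "isotopologue_index"])
        inferred = self._infer_carbon_counts()
        for met, n in self.carbon_counts.items():
            if met in inferred and inferred[met] != n:
                raise StructuralError(
                    f"metabolite {met!r}: declared carbon count {n} but "
                    f"{inferred[met] + 1} isotopologue rows imply n={inferred[met]}"
                )
        self.carbon_counts = {**inferred, **self.carbon_counts}

    def _infer_carbon_counts(self) -> dict[str, int]:
        return {
            met: int(sub.max())
            for met, sub in pd.Series(
                self.data.index.get_level_values(1),
                index=self.data.index.get_level_values(0),
            ).groupby(level=0, sort=False)
        }

    # -- accessors ---------------------------------------------------------
    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def metabolites(self) -> list[str]:
        return list(dict.fromkeys(self.data.index.get_level_values(0)))

    def vector(self, metabolite: str, sample: str) -> np.ndarray:
        """The (M0..Mn) or (c0..cn) vector of one metabolite in one sample."""
        sub = self.data.loc[metabolite, sample]
        return sub.sort_index().to_numpy(dtype=float)

    # -- construction ------------------------------------------------------
    @classmethod
    def from_flat(cls, frame: pd.DataFrame, mode: str) -> "IsotopologueTable":
        """Build from a flat frame whose index holds ``metabolite_m+i`` ids."""
        mets, idxs = zip(*(split_feature_id(str(f)) for f in frame.index))
        data = frame.copy()
        data.index = pd.MultiIndex.from_arrays(
            [mets, idxs], names=["metabolite", "isotopologue_index"]
        )
        return cls(data=data.sort_index(), mode=mode)

    def to_flat(self) -> pd.DataFrame:
        """Flat frame with ``metabolite_m+i`` feature ids (write dialect)."""
        out = self.data.copy()
        out.index = pd.Index(
            [make_feature_id(m, i) for m, i in out.index], name="feature_id"
        )
        return out

    def feature_ids(self) -> list[str]:
        return [make_feature_id(m, i) for m, i in self.data.index]


@dataclass
class MetaboliteTable:
    """Per-metabolite scalar quantity (abundance or enrichment) across samples."""

    data: pd.DataFrame  # metabolite × sample
    quantity: Literal["total_abundance", "fractional_contribution"]

    def __post_init__(self) -> None:
        if self.quantity not in (TOTAL_ABUNDANCE, FRACTIONAL_CONTRIBUTION):
            raise ValueError(f"unknown quantity {self.quantity!r}")
        if self.data.index.duplicated().any():
            raise StructuralError("duplicated metabolite rows")
        _check_sample_axis(self.data.columns)
        self.data.index = self.data.index.set_names("metabolite")

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def metabolites(self) -> list[str]:
        return list(self.data.index)


@dataclass
class SampleSheet:
    """Sample metadata: condition, named/numeric timepoint, replicate."""

    data: pd.DataFrame  # columns: condition, timepoint_name, timepoint_hours, replicate

    REQUIRED = ("condition", "timepoint_name", "timepoint_hours", "replicate")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise StructuralError(f"sample sheet missing columns: {missing}")
        if self.data.index.duplicated().any():
            raise StructuralError("duplicated sample_ids in sample sheet")
        self.data.index = self.data.index.set_names("sample_id")
        self.data["timepoint_hours"] = self.data["timepoint_hours"].astype(float)
        self.data["replicate"] = self.data["replicate"].astype(int)

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.data["condition"]))

    def timepoints(self) -> pd.DataFrame:
        """Unique timepoints sorted by numeric hour."""
        tp = self.data[["timepoint_name", "timepoint_hours"]].drop_duplicates()
        return tp.sort_values("timepoint_hours").reset_index(drop=True)

    def select(
        self, condition: str | None = None, timepoint: str | float | None = None
    ) -> list[str]:
        """Sample ids matching a (condition, timepoint) selector.

        ``timepoint`` matches the timepoint name, or the numeric hour when
        a number is given.
        """
        mask = pd.Series(True, index=self.data.index)
        if condition is not None:
            mask &= self.data["condition"] == condition
        if timepoint is not None:
            if isinstance(timepoint, (int, float)) and not isinstance(timepoint, bool):
                mask &= self.data["timepoint_hours"] == float(timepoint)
            else:
                mask &= self.data["timepoint_name"] == str(timepoint)
        return list(self.data.index[mask])

    def check_alignment(self, sample_columns: Sequence[str]) -> None:
        unknown = [s for s in sample_columns if s not in self.data.index]
        if unknown:
            raise StructuralError(
                f"samples present in a measurement table but absent from the sample sheet: {unknown}"
            )


# ---------------------------------------------------------------------------
# Comparison specification / results
# ---------------------------------------------------------------------------

PAIRWISE_CONDITION = "pairwise_condition"
CONSECUTIVE_TIMEPOINTS = "consecutive_timepoints"
MULTIGROUP = "multigroup"

RESULT_COLUMNS = [
    "feature_id",
    "comparison",
    "quantity",
    "mean_A",
    "mean_B",
    "effect",
    "statistic",
    "p_raw",
    "p_adj",
    "significant",
    "reason",
]


@dataclass(frozen=True)
class GroupSelector:
    """A (condition, timepoint) pair; either part may be None (= any)."""

    condition: str | None = None
    timepoint: str | float | None = None

    def label(self) -> str:
        def fmt(p):
            if isinstance(p, float) and p.is_integer():
                return str(int(p))
            return str(p)

        parts = [fmt(p) for p in (self.condition, self.timepoint) if p is not None]
        return "-".join(parts) if parts else "all"


@dataclass
class ComparisonSpec:
    """One statistical comparison: which groups, which test, which FDR rule."""

    kind: Literal["pairwise_condition", "consecutive_timepoints", "multigroup"]
    groups: list[GroupSelector]
    test: str = "permutation"
    correction: str = "BH"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1 and self.alpha != 0:
            raise ValueError("alpha must lie in [0, 1)")
        if self.kind == MULTIGROUP:
            if len(self.groups) < 3:
                raise ValueError("multigroup comparisons need ≥3 groups")
            if self.test != "kruskal_wallis":
                raise ValueError("multigroup comparisons require the Kruskal–Wallis test")
        elif self.kind == PAIRWISE_CONDITION and len(self.groups) != 2:
            raise ValueError("pairwise comparisons need exactly 2 groups")

    def label(self) -> str:
        return "_vs_".join(g.label() for g in self.groups)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_isotopologue_table(
    table: IsotopologueTable, tolerance: float = DEFAULT_SUM_TOLERANCE
) -> list[Violation]:
    """Check the MDV invariants; return one record per violation.

    Rules checked:

    * ``index_gap`` — a metabolite's isotopologue indices are not the
      contiguous range 0..n.
    * ``negative_value`` — a negative entry in absolute mode.
    * ``proportion_range`` — a proportion outside [0, 1 + tolerance].
    * ``normalization`` — per-(metabolite, sample) proportion sum outside
      [1 − tolerance, 1 + tolerance] (missing-only cells are skipped).

    Validation is pure: it never mutates the table, and an empty return
    value means the table satisfies every invariant at this tolerance.
    """
    violations: list[Violation] = []
    idx = table.data.index
    for met in table.metabolites:
        indices = sorted(idx[idx.get_level_values(0) == met].get_level_values(1))
        n = table.carbon_counts[met]
        if indices != list(range(n + 1)):
            missing = sorted(set(range(n + 1)) - set(indices))
            violations.append(
                Violation(met, None, "index_gap", f"missing isotopologue indices {missing}")
            )

    values = table.data
    if table.mode == ABSOLUTE:
        neg = values < 0
        for (met, i), row in neg.iterrows():
            for sample in row.index[row]:
                violations.append(
                    Violation(
                        met, sample, "negative_value",
                        f"M{i} = {values.loc[(met, i), sample]:g} < 0",
                    )
                )
    else:
        bad = (values < 0) | (values > 1 + tolerance)
        for (met, i), row in bad.iterrows():
            for sample in row.index[row & values.loc[(met, i)].notna()]:
                violations.append(
                    Violation(
                        met, sample, "proportion_range",
                        f"c{i} = {values.loc[(met, i), sample]:g} outside [0, 1+{tolerance:g}]",
                    )
                )
        sums = values.groupby(level=0).sum(min_count=1)
        counts = values.notna().groupby(level=0).sum()
        expected = pd.Series(
            {m: table.carbon_counts[m] + 1 for m in sums.index}, name="expected"
        )
        for met in sums.index:
            for sample in sums.columns:
                total = sums.loc[met, sample]
                if pd.isna(total):
                    continue  # fully-missing cell: handled by the missing-data policy
                if counts.loc[met, sample] < expected[met]:
                    continue  # incomplete cell; the gap rule reports structure
                if not (1 - tolerance <= total <= 1 + tolerance):
                    violations.append(
                        Violation(
                            met, sample, "normalization",
                            f"Σc = {total:.6g} outside 1 ± {tolerance:g}",
                        )
                    )
    return violations


def validate_metabolite_table(
    table: MetaboliteTable, tolerance: float = DEFAULT_SUM_TOLERANCE
) -> list[Violation]:
    """Range checks for scalar quantity tables."""
    violations: list[Violation] = []
    vals = table.data
    if table.quantity == TOTAL_ABUNDANCE:
        bad = vals < 0
        rule, msg = "negative_value", "abundance < 0"
    else:
        bad = (vals < -tolerance) | (vals > 1 + tolerance)
        rule, msg = "enrichment_range", f"fractional contribution outside [0, 1] ± {tolerance:g}"
    for met, row in bad.iterrows():
        for sample in row.index[row & vals.loc[met].notna()]:
            violations.append(Violation(met, sample, rule, f"{msg}: {vals.loc[met, sample]:g}"))
    return violations
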