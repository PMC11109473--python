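"""Run configuration: YAML schema, validation, defaults.

The schema is strict — unknown keys are rejected with their location, and
all problems are reported at once rather than first-fail. Defaults are
injected on load so a dumped config always spells out the full parameter
set actually used.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .diffstats import FDR_METHODS, TEST_CATALOG


class ConfigError(ValueError):
    """Aggregated configuration problems with their locations."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DatasetConfig(_Strict):
    preset: Optional[str] = None  # named synthetic preset instead of files
    isotopologues: Optional[str] = None
    isotopologues_mode: Literal["absolute", "proportion"] = "absolute"
    abundances: Optional[str] = None
    fractional: Optional[str] = None
    samplesheet: Optional[str] = None

    @model_validator(mode="after")
    def _files_or_preset(self):
        if self.preset is None:
            if self.samplesheet is None:
                raise ValueError("either 'preset' or 'samplesheet' (+ tables) is required")
            if self.isotopologues is None and self.abundances is None and self.fractional is None:
                raise ValueError("at least one measurement table is required")
        return self


class GroupConfig(_Strict):
    condition: Optional[str] = None
    timepoint: Optional[float | str] = None


class ComparisonConfig(_Strict):
    kind: Literal["pairwise_condition", "consecutive_timepoints", "multigroup"] = (
        "pairwise_condition"
    )
    groups: list[GroupConfig]
    test: Optional[str] = None  # None: per-quantity defaults

    @model_validator(mode="after")
    def _check_test(self):
        if self.test is not None and self.test not in TEST_CATALOG:
            raise ValueError(
                f"unknown test {self.test!r}; supported tests: {sorted(TEST_CATALOG)}"
            )
        return self


class StatisticsConfig(_Strict):
    alpha: float = Field(default=0.05, gt=0, lt=1)
    fdr_method: str = "BH"
    n_permutations: int = Field(default=10_000, ge=100)
    seed: int = Field(default=0, ge=0)
    tests_per_quantity: dict[str, str] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check_names(self):
        if self.fdr_method not in FDR_METHODS:
            raise ValueError(
                f"unknown FDR method {self.fdr_method!r}; supported: {sorted(FDR_METHODS)}"
            )
        for q, t in self.tests_per_quantity.items():
            if t not in TEST_CATALOG:
                raise ValueError(
                    f"unknown test {t!r} for quantity {q!r}; "
                    f"supported tests: {sorted(TEST_CATALOG)}"
                )
        return self


class TimecourseConfig(_Strict):
    enabled: bool = False
    condition: Optional[str] = None
    test: str = "wilcoxon_rank_sum"

    @model_validator(mode="after")
    def _check_test(self):
        if self.test not in TEST_CATALOG:
            raise ValueError(
                f"unknown test {self.test!r}; supported tests: {sorted(TEST_CATALOG)}"
            )
        return self


class BivariateConfig(_Strict):
    enabled: bool = False
    condition: Optional[str] = None


class PCAConfig(_Strict):
    enabled: bool = True
    quantity: Literal["total_abundance", "fractional_contribution"] = "total_abundance"
    scaling: Optional[Literal["none", "unit_variance"]] = None
    n_components: Optional[int] = None


class MetabologramConfig(_Strict):
    enabled: bool = False
    pathways: Optional[str] = None
    deg: Optional[str] = None
    graph_edges: Optional[str] = None
    graph_nodes: Optional[str] = None
    quantity: Literal["total_abundance", "fractional_contribution"] = "total_abundance"
    comparison: Optional[str] = None  # label of the comparison to integrate


class RunConfig(_Strict):
    dataset: DatasetConfig
    comparisons: list[ComparisonConfig] = Field(default_factory=list)
    statistics: StatisticsConfig = Field(default_factory=StatisticsConfig)
    timecourse: TimecourseConfig = Field(default_factory=TimecourseConfig)
    bivariate: BivariateConfig = Field(default_factory=BivariateConfig)
    pca: PCAConfig = Field(default_factory=PCAConfig)
    metabologram: MetabologramConfig = Field(default_factory=MetabologramConfig)
    output_dir: str = "isodiff_results"

    def dump(self) -> dict:
        return self.model_dump(mode="json")


def _format_errors(err: ValidationError) -> str:
    lines = []
    for e in err.errors():
        loc = ".".join(str(p) for p in e["loc"]) or "<root>"
        lines.append(f"  {loc}: {e['msg']}")
    return "\n".join(lines)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    All schema violations are aggregated into one :class:`ConfigError`.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: configuration must be a YAML mapping")
    return parse_config(raw, source=str(path))


def parse_config(raw: dict, source: str = "<dict>") -> RunConfig:
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as err:
        raise ConfigError(
            f"{source}: {err.error_count()} configuration problem(s):\n{_format_errors(err)}"
        ) from None


def dump_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.dump(), sort_keys=True))
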