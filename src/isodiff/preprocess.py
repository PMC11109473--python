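"""Derivation of the three quantity types from corrected isotopologues.

Given corrected isotopologue intensities (M0..Mn) per metabolite and
sample, three quantities are derived:

* total abundance            m  = Σj Mj
* isotopologue proportions   ci = Mi / Σj Mj        (the MDV)
* fractional contribution    φ  = Σj (cj · j) / n   (mean enrichment)

Zero-total cells make the MDV undefined (0/0); they are recorded as
missing, never fabricated. Supplied tables always take precedence over
derived ones; discrepancies beyond a relative tolerance are reported, not
silently hidden.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import (
    ABSOLUTE,
    FRACTIONAL_CONTRIBUTION,
    PROPORTION,
    TOTAL_ABUNDANCE,
    IsotopologueTable,
    MetaboliteTable,
    SampleSheet,
    validate_isotopologue_table,
)

logger = logging.getLogger(__name__)

#: relative tolerance above which a supplied table is reported as
#: inconsistent with the one derived from isotopologues
SUPPLIED_VS_DERIVED_RTOL = 1e-6

#: column sums in this band are taken to be percentages and rescaled by 1/100
PERCENT_BAND = (98.0, 102.0)


class ModeError(ValueError):
    """An operation received an isotopologue table in the wrong mode."""


def total_abundance(table: IsotopologueTable) -> MetaboliteTable:
    """Sum absolute isotopologue intensities per metabolite: ``m = Σj Mj``.

    A missing Mi propagates: the metabolite's total in that sample is
    missing rather than a partial sum.
    """
    if table.mode != ABSOLUTE:
        raise ModeError("total abundances require absolute-mode isotopologues")
    sums = table.data.groupby(level=0, sort=True).sum(min_count=1)
    counts = table.data.notna().groupby(level=0, sort=True).sum()
    expected = pd.Series({m: table.carbon_counts[m] + 1 for m in sums.index})
    sums = sums.where(counts.ge(expected, axis=0))
    return MetaboliteTable(data=sums, quantity=TOTAL_ABUNDANCE)


def isotopologue_proportions(table: IsotopologueTable) -> IsotopologueTable:
    """Normalize absolute intensities to MDV proportions ``ci = Mi / Σj Mj``.

    Cells whose intensities sum to zero have no defined MDV and come back
    missing across all isotopologues of that (metabolite, sample).
    """
    if table.mode != ABSOLUTE:
        raise ModeError("proportions are derived from absolute-mode isotopologues")
    sums = table.data.groupby(level=0).transform("sum")
    expected = np.array(
        [table.carbon_counts[m] + 1 for m in table.data.index.get_level_values(0)]
    )
    complete = table.data.notna().groupby(level=0).transform("sum").eq(expected, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        props = table.data / sums.where((sums > 0) & complete)
    return IsotopologueTable(data=props, mode=PROPORTION)


def fractional_contribution(table: IsotopologueTable) -> MetaboliteTable:
    """Carbon-weighted mean of the MDV: ``φ = Σj (cj · j) / n``.

    φ is 0 for a fully unlabeled metabolite (all mass in c0) and 1 when all
    carbons carry the tracer (all mass in cn). Metabolites with n = 0 have
    no labeling degrees of freedom and are rejected.
    """
    if table.mode != PROPORTION:
        raise ModeError("fractional contributions require proportion-mode isotopologues")
    zero_n = [m for m, n in table.carbon_counts.items() if n == 0]
    if zero_n:
        raise ValueError(f"enrichment undefined for metabolites with n=0 carbons: {zero_n}")
    idx = table.data.index.get_level_values(1).to_numpy()
    weighted = table.data.mul(idx, axis=0)
    sums = weighted.groupby(level=0, sort=True).sum(min_count=1)
    counts = table.data.notna().groupby(level=0, sort=True).sum()
    expected = pd.Series({m: table.carbon_counts[m] + 1 for m in sums.index})
    sums = sums.where(counts.ge(expected, axis=0))
    n = pd.Series({m: table.carbon_counts[m] for m in sums.index}, dtype=float)
    return MetaboliteTable(data=sums.div(n, axis=0), quantity=FRACTIONAL_CONTRIBUTION)


def _maybe_rescale_percentages(table: IsotopologueTable) -> IsotopologueTable:
    """Auto-detect proportions supplied as percentages and rescale to 1."""
    sums = table.data.groupby(level=0).sum(min_count=1)
    finite = sums.to_numpy()[np.isfinite(sums.to_numpy())]
    if finite.size and PERCENT_BAND[0] <= np.median(finite) <= PERCENT_BAND[1]:
        logger.info("proportion table column sums ≈ 100: interpreting as percentages")
        return IsotopologueTable(data=table.data / 100.0, mode=PROPORTION)
    return table


@dataclass
class Dataset:
    """All quantity types for one experiment, aligned to one sample sheet."""

    samplesheet: SampleSheet
    isotopologues_absolute: IsotopologueTable | None = None
    isotopologues_proportion: IsotopologueTable | None = None
    abundance: MetaboliteTable | None = None
    fractional: MetaboliteTable | None = None
    log: list[str] = field(default_factory=list)

    def quantity_tables(self) -> dict[str, pd.DataFrame]:
        """Feature × sample frames per quantity type, isotopologues flattened."""
        out: dict[str, pd.DataFrame] = {}
        if self.abundance is not None:
            out[TOTAL_ABUNDANCE] = self.abundance.data
        if self.fractional is not None:
            out[FRACTIONAL_CONTRIBUTION] = self.fractional.data
        if self.isotopologues_proportion is not None:
            out["isotopologue_proportion"] = self.isotopologues_proportion.to_flat()
        return out


def harmonize_inputs(
    samplesheet: SampleSheet,
    isotopologues: IsotopologueTable | None = None,
    abundance: MetaboliteTable | None = None,
    fractional: MetaboliteTable | None = None,
    sum_tolerance: float = 0.02,
) -> Dataset:
    """Assemble a complete dataset, deriving whatever is missing.

    Any quantity derivable from the supplied isotopologues is computed;
    user-supplied tables win over derived ones (a discrepancy beyond
    ``SUPPLIED_VS_DERIVED_RTOL`` is logged into ``Dataset.log``). All
    tables must be column-aligned to the sample sheet.
    """
    if isotopologues is None and abundance is None and fractional is None:
        raise ValueError("at least one measurement table is required")

    ds = Dataset(samplesheet=samplesheet)

    for tbl in (isotopologues, abundance, fractional):
        if tbl is not None:
            samplesheet.check_alignment(tbl.data.columns)

    iso_abs: IsotopologueTable | None = None
    iso_prop: IsotopologueTable | None = None
    if isotopologues is not None:
        if isotopologues.mode == ABSOLUTE:
            iso_abs = isotopologues
            iso_prop = isotopologue_proportions(iso_abs)
        else:
            iso_prop = _maybe_rescale_percentages(isotopologues)
            for v in validate_isotopologue_table(iso_prop, tolerance=sum_tolerance):
                ds.log.append(f"validation: {v}")

    derived_abund = total_abundance(iso_abs) if iso_abs is not None else None
    derived_frac = fractional_contribution(iso_prop) if iso_prop is not None else None

    def _pick(supplied, derived, name):
        if supplied is None:
            return derived
        if derived is not None:
            a = supplied.data.reindex_like(derived.data).to_numpy(dtype=float)
            b = derived.data.to_numpy(dtype=float)
            both = np.isfinite(a) & np.isfinite(b)
            denom = np.maximum(np.abs(b[both]), 1e-300)
            rel = np.abs(a[both] - b[both]) / denom
            if rel.size and np.nanmax(rel) > SUPPLIED_VS_DERIVED_RTOL:
                msg = (
                    f"supplied {name} differs from values derived from isotopologues "
                    f"(max relative difference {np.nanmax(rel):.3g}); keeping supplied table"
                )
                logger.warning(msg)
                ds.log.append(msg)
        return supplied

    ds.isotopologues_absolute = iso_abs
    ds.isotopologues_proportion = iso_prop
    ds.abundance = _pick(abundance, derived_abund, "total abundances")
    ds.fractional = _pick(fractional, derived_frac, "fractional contributions")

    if ds.abundance is None:
        ds.log.append("total abundances unavailable: not supplied and not derivable")
    if ds.fractional is None:
        ds.log.append("fractional contributions unavailable: not supplied and not derivable")
    return ds
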