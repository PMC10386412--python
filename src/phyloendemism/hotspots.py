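"""Percentile hotspot detection, nano-hotspots, coverage and gap analysis.

A cell is a top-q hotspot for a metric when its value reaches the k-th
largest value of the surface, k = ceil(q N); ties at the threshold are all
included, so the selected set is deterministic and order-independent and
may exceed k cells.  Counting, per cell, how many of the seven metrics
(RE, WE, CWE, PD, PE, sesPD, EDGE) select it gives the 0–7 hotspot-count
surface; cells selected by most metrics at q = 1% are nano-hotspots.  For
sesPD "top" means largest z (the overdispersion direction) by default.

Coverage asks, per species, what fraction of its occupied cells fall inside
a hotspot set; gap analysis classifies hotspot cells by protection network
(Natura 2000, local-only, none).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import DataError, IncidenceMatrix, MetricSurface

#: The seven metrics combined in the hotspot-count surface.
DEFAULT_METRICS = ("RE", "WE", "CWE", "PD", "PE", "sesPD", "EDGE")

#: The percentile fractions reported throughout.
DEFAULT_FRACTIONS = (0.01, 0.025, 0.05, 0.10)


@dataclass
class HotspotConfig:
    metrics: tuple[str, ...] = DEFAULT_METRICS
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS
    #: number of coinciding top-1% metrics that makes a nano-hotspot
    nano_min_metrics: int = 5
    #: use |z| instead of +z when ranking sesPD
    sespd_absolute: bool = False

    def __post_init__(self) -> None:
        if not self.metrics:
            raise ValueError("metric list must be non-empty")
        for q in self.fractions:
            if not 0 < q < 1:
                raise ValueError(f"fraction {q} outside (0, 1)")


def top_fraction_cells(
    surface: MetricSurface, q: float, absolute: bool = False
) -> set[str]:
    """Cells in the top fraction *q* of the surface, ties included.

    With ``absolute`` the ranking uses |value| (an option for sesPD).
    """
    if not 0 < q < 1:
        raise ValueError(f"fraction {q} outside (0, 1)")
    values = surface.values.to_numpy(dtype=float)
    if absolute:
        values = np.abs(values)
    n = len(values)
    if n == 0:
        raise DataError("empty surface")
    k = math.ceil(q * n)
    threshold = np.partition(values, n - k)[n - k]
    return set(surface.values.index[values >= threshold])


def hotspot_counts(
    surfaces: dict[str, MetricSurface],
    q: float,
    config: HotspotConfig | None = None,
) -> tuple[MetricSurface, pd.DataFrame]:
    """Per-cell count of metrics whose top-q set contains the cell.

    Returns the count surface and a boolean membership table with one
    ``<metric>_top`` column per metric.  All surfaces must share a domain.
    """
    config = config or HotspotConfig()
    missing = [m for m in config.metrics if m not in surfaces]
    if missing:
        raise DataError(f"missing surfaces for metrics: {missing}")
    domains = {tuple(surfaces[m].values.index) for m in config.metrics}
    if len(domains) != 1:
        raise DataError("metric surfaces do not share a cell domain")
    cells = surfaces[config.metrics[0]].values.index
    membership = pd.DataFrame(index=cells.copy())
    membership.index.name = "cell_id"
    for m in config.metrics:
        top = top_fraction_cells(
            surfaces[m], q, absolute=(m == "sesPD" and config.sespd_absolute)
        )
        membership[f"{m}_top"] = membership.index.isin(top)
    counts = membership.sum(axis=1).astype(float)
    return MetricSurface("hotspot_count", counts), membership


def nano_hotspots(
    count_surface: MetricSurface, min_metrics: int = 5
) -> list[str]:
    """Cells where at least *min_metrics* metrics coincide in the top set."""
    values = count_surface.values
    return sorted(values.index[values >= min_metrics])


@dataclass
class CoverageTable:
    """Per-species and per-category coverage of a hotspot cell set."""

    species_fraction: pd.Series  # fraction of occupied cells inside hotspots
    by_category: pd.Series  # unweighted mean of species fractions
    overall_mean: float
    n_species_touched: int  # species with >= 1 covered cell
    fraction_species_touched: float
    details: pd.DataFrame = field(repr=False, default=None)


def species_coverage(
    incidence: IncidenceMatrix,
    hotspot_cells: set[str],
    iucn: pd.Series | None = None,
) -> CoverageTable:
    """Fraction of each species' range inside *hotspot_cells*, summarised.

    Category means are unweighted means over the species of each category;
    the overall mean is the unweighted mean over all species.
    """
    inc = incidence.restrict_to_occupied()
    in_hot = np.array([c in hotspot_cells for c in inc.cells])
    occupied = inc.presence.sum(axis=1).astype(float)
    covered = inc.presence[:, in_hot].sum(axis=1).astype(float)
    frac = pd.Series(covered / occupied, index=inc.species, name="coverage")
    details = pd.DataFrame(
        {"range": occupied.astype(int), "covered": covered.astype(int),
         "coverage": frac}
    )
    details.index.name = "species"
    if iucn is not None:
        cats = iucn.reindex(inc.species)
        details["iucn"] = cats
        by_cat = frac.groupby(cats).mean()
    else:
        by_cat = pd.Series(dtype=float)
    touched = int((covered > 0).sum())
    return CoverageTable(
        species_fraction=frac,
        by_category=by_cat,
        overall_mean=float(frac.mean()),
        n_species_touched=touched,
        fraction_species_touched=touched / inc.n_species,
        details=details,
    )


def coverage_by_fraction(
    incidence: IncidenceMatrix,
    surfaces: dict[str, MetricSurface],
    iucn: pd.Series,
    config: HotspotConfig | None = None,
) -> pd.DataFrame:
    """Coverage summary across percentile fractions (one column per q).

    The hotspot set at each q is the union of the metrics' top-q sets
    (cells with hotspot count >= 1).  Rows are IUCN categories plus an
    ``All categories`` mean; values are percentages.
    """
    config = config or HotspotConfig()
    columns = {}
    for q in config.fractions:
        counts, _ = hotspot_counts(surfaces, q, config)
        hot = set(counts.values.index[counts.values >= 1])
        cov = species_coverage(incidence, hot, iucn)
        col = cov.by_category * 100.0
        col.loc["All categories"] = cov.overall_mean * 100.0
        columns[f"top_{q:g}"] = col
    out = pd.DataFrame(columns)
    out.index.name = "iucn"
    order = [c for c in ("LC", "NT", "VU", "EN", "CR", "DD") if c in out.index]
    return out.loc[order + ["All categories"]]


def protection_gap(
    count_surface: MetricSurface,
    cell_table: pd.DataFrame,
    min_count: int = 1,
) -> pd.DataFrame:
    """Classify hotspot cells by protection network membership.

    Returns the hotspot cells (count >= min_count) with their counts and a
    ``protection_class`` of ``natura2000``, ``local_only`` or
    ``unprotected``; cells outside every network are the conservation gaps.
    """
    if "protection" not in cell_table.columns:
        raise DataError("cell table lacks a 'protection' column")
    values = count_surface.values
    hot = values.index[values >= min_count]
    missing = [c for c in hot if c not in cell_table.index]
    if missing:
        raise DataError(f"hotspot cells absent from cell table: {missing[:5]}")
    protection = cell_table.loc[hot, "protection"].replace({"none": "unprotected"})
    out = pd.DataFrame(
        {"count": values[hot].astype(int), "protection_class": protection}
    )
    out.index.name = "cell_id"
    return out.sort_values("count", ascending=False)


def gap_summary(gap_table: pd.DataFrame) -> pd.Series:
    """Number of hotspot cells per protection class."""
    return (
        gap_table["protection_class"]
        .value_counts()
        .reindex(["natura2000", "local_only", "unprotected"], fill_value=0)
    )
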