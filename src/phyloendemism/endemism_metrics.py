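"""Taxonomic endemism metrics: RE, WE and CWE per grid cell.

All three are computed on the analysis domain of occupied cells.  WE
partitions each species' unit weight 1 across its occupied cells, so the
surface sums exactly to the species count; CWE = WE / RE rescales that to
the mean fraction-of-range concentrated in the cell, bounded by (0, 1].
"""

from __future__ import annotations

import numpy as np

from .core_data import DataError, IncidenceMatrix, MetricSurface


def species_richness(incidence: IncidenceMatrix) -> MetricSurface:
    """Endemic species richness RE(c): number of species present in cell c."""
    inc = incidence.restrict_to_occupied()
    return MetricSurface("RE", inc.richness().astype(float))


def weighted_endemism(incidence: IncidenceMatrix) -> MetricSurface:
    """Weighted endemism WE(c) = sum over species in c of 1 / range size."""
    inc = incidence.restrict_to_occupied()
    ranges = inc.presence.sum(axis=1).astype(float)  # (S,)
    if (ranges == 0).any():
        raise DataError("species with zero range; validate the incidence first")
    we = (inc.presence.T / ranges).sum(axis=1)  # (C,)
    surface = MetricSurface("WE", dict(zip(inc.cells, we)))
    return surface


def corrected_weighted_endemism(
    we: MetricSurface, re: MetricSurface
) -> MetricSurface:
    """CWE(c) = WE(c) / RE(c), the range-restriction share of a cell's flora."""
    if list(we.values.index) != list(re.values.index):
        raise DataError("WE and RE surfaces must share the same cell domain")
    richness = re.values.to_numpy()
    if (richness <= 0).any():
        bad = re.values.index[richness <= 0].tolist()
        raise DataError(f"RE = 0 inside the analysis domain at cells {bad[:5]}")
    cwe = we.values.to_numpy() / richness
    if (cwe <= 0).any() or (cwe > 1 + 1e-12).any():
        raise DataError("CWE outside (0, 1]; inputs are inconsistent")
    return MetricSurface("CWE", dict(zip(we.values.index, np.minimum(cwe, 1.0))))


def taxonomic_surfaces(incidence: IncidenceMatrix) -> dict[str, MetricSurface]:
    """Convenience: RE, WE and CWE on the occupied-cell domain."""
    re = species_richness(incidence)
    we = weighted_endemism(incidence)
    return {"RE": re, "WE": we, "CWE": corrected_weighted_endemism(we, re)}
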