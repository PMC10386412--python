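"""Phylogenetic metrics: Faith's PD, sesPD, PE, fair-proportion ED, EDGE.

Conventions
-----------
* PD(c) is the total branch length of the minimal subtree connecting the
  species of cell c *including the path to the root* of the bound tree, so a
  single-species cell scores that tip's root distance and the full species
  set scores the total tree length.  This keeps the spatial decomposition of
  PE exact: summed over cells, PE returns the total tree length.
* The sesPD null shuffles tip labels on the phylogeny — one whole-tree
  permutation per replicate, applied to every cell — and standardises the
  observed PD by the sample mean and (n-1) standard deviation of the null.
  |z| > 1.96 marks significant phylogenetic clustering (z < -1.96) or
  overdispersion (z > +1.96).
* ED is fair-proportion evolutionary distinctiveness: each branch's length
  is split equally among its descendant tips and summed along each tip's
  root path.  EDGE = ln(1 + ED) + GE ln 2 with GE coding CR=4, EN=3, VU=2,
  NT=1, LC=0; data-deficient species are kept in the table but carry no
  GE or EDGE score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import DataError, IncidenceMatrix, MetricSurface
from .phylo import PhyloTree, edge_cell_incidence

logger = logging.getLogger(__name__)

#: IUCN category -> global endangerment score; DD is excluded from scoring.
GE_CODES = {"CR": 4, "EN": 3, "VU": 2, "NT": 1, "LC": 0}

#: z-score magnitude marking significant departure from the null.
SES_THRESHOLD = 1.96


def _occupied(incidence: IncidenceMatrix) -> IncidenceMatrix:
    inc = incidence.restrict_to_occupied()
    if inc.n_cells == 0:
        raise DataError("no occupied cells")
    return inc


def faith_pd(tree: PhyloTree, incidence: IncidenceMatrix) -> MetricSurface:
    """Faith's phylogenetic diversity per cell (rooted convention)."""
    inc = _occupied(incidence)
    edge_cells = edge_cell_incidence(tree, inc)
    pd_values = tree.arrays.edge_lengths @ edge_cells
    return MetricSurface("PD", dict(zip(inc.cells, pd_values)))


def phylogenetic_endemism(
    tree: PhyloTree, incidence: IncidenceMatrix
) -> MetricSurface:
    """Phylogenetic endemism PE(c) = sum over c's subtree of L_b / R_b.

    R_b is the number of cells occupied by the branch (cells holding any of
    its descendant tips), so each branch's length is partitioned across its
    range exactly as WE partitions a species' unit weight.
    """
    inc = _occupied(incidence)
    edge_cells = edge_cell_incidence(tree, inc)
    r = edge_cells.sum(axis=1).astype(float)  # R_b >= 1 on occupied domain
    weights = np.where(r > 0, tree.arrays.edge_lengths / np.maximum(r, 1), 0.0)
    pe_values = weights @ edge_cells
    return MetricSurface("PE", dict(zip(inc.cells, pe_values)))


@dataclass
class SesPDResult:
    """Observed PD, null moments and z-scores of the tip-shuffle null."""

    table: pd.DataFrame  # index cell_id; pd_obs, null_mean, null_sd, z, class
    reps: int
    seed: int

    @property
    def surface(self) -> MetricSurface:
        return MetricSurface("sesPD", self.table["z"])

    @property
    def classes(self) -> pd.Series:
        return self.table["class"]


def ses_pd(
    tree: PhyloTree,
    incidence: IncidenceMatrix,
    reps: int = 1000,
    seed: int | None = None,
) -> SesPDResult:
    """Standardised effect size of PD under a tip-label permutation null.

    Each replicate draws one uniform permutation of the tree's tip labels
    and recomputes PD for every cell under it.  Cells whose null standard
    deviation is zero (e.g. a cell containing every species) get z = 0 and
    class ``neutral``.
    """
    if reps < 2:
        raise ValueError("reps must be >= 2")
    if seed is None:
        raise ValueError("a seed is required for the permutation null")
    rng = np.random.default_rng(seed)
    inc = _occupied(incidence)
    arr = tree.arrays
    missing = [t for t in arr.tip_labels if t not in inc._species_index]
    if missing:
        raise DataError(f"tree tips absent from incidence: {missing[:10]}")

    d = arr.edge_tip.astype(np.float32)  # (E, T)
    p = np.vstack([inc.species_row(t) for t in arr.tip_labels]).astype(np.float32)
    lengths = arr.edge_lengths.astype(np.float64)
    pd_obs = lengths @ ((d @ p) > 0)

    n_tips = len(arr.tip_labels)
    null = np.empty((reps, inc.n_cells), dtype=np.float64)
    for r in range(reps):
        perm = rng.permutation(n_tips)
        null[r] = lengths @ ((d @ p[perm]) > 0)

    null_mean = null.mean(axis=0)
    null_sd = null.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(null_sd > 0, (pd_obs - null_mean) / null_sd, 0.0)
    n_degenerate = int((null_sd == 0).sum())
    if n_degenerate:
        logger.info(
            "%d cells with degenerate null (sd = 0) set to z = 0", n_degenerate
        )
    cls = np.full(inc.n_cells, "neutral", dtype=object)
    cls[z < -SES_THRESHOLD] = "clustered"
    cls[z > SES_THRESHOLD] = "overdispersed"
    table = pd.DataFrame(
        {
            "pd_obs": pd_obs,
            "null_mean": null_mean,
            "null_sd": null_sd,
            "z": z,
            "class": cls,
        },
        index=pd.Index(inc.cells, name="cell_id"),
    )
    return SesPDResult(table=table, reps=reps, seed=seed)


def fair_proportion_ed(tree: PhyloTree) -> pd.Series:
    """Fair-proportion evolutionary distinctiveness per tip.

    ED_i = sum over edges b on the root->tip_i path of L_b / n_b, where n_b
    counts the tips descending through b.  Summed over tips this returns the
    total tree length exactly.
    """
    arr = tree.arrays
    per_edge = np.divide(
        arr.edge_lengths,
        arr.n_tips_per_edge,
        out=np.zeros_like(arr.edge_lengths),
        where=arr.n_tips_per_edge > 0,
    )
    ed = arr.edge_tip.T.astype(float) @ per_edge
    return pd.Series(ed, index=pd.Index(arr.tip_labels, name="species"), name="ED")


def edge_scores(ed: pd.Series, iucn: pd.Series) -> pd.DataFrame:
    """Per-species GE and EDGE = ln(1 + ED) + GE ln 2.

    ``iucn`` maps species to Red List category.  DD species stay in the
    table with ED but empty GE/EDGE.  Unknown categories raise.
    """
    iucn = iucn.reindex(ed.index)
    if iucn.isna().any():
        missing = iucn.index[iucn.isna()].tolist()
        raise DataError(f"species without IUCN category: {missing[:10]}")
    unknown = set(iucn.unique()) - set(GE_CODES) - {"DD"}
    if unknown:
        raise DataError(f"unknown IUCN categories: {sorted(unknown)}")
    ge = iucn.map(GE_CODES)  # DD -> NaN
    edge = np.log1p(ed) + ge * np.log(2.0)
    out = pd.DataFrame({"iucn": iucn, "GE": ge, "ED": ed, "EDGE": edge})
    out.index.name = "species"
    return out


def grid_edge(
    incidence: IncidenceMatrix, species_scores: pd.DataFrame
) -> MetricSurface:
    """Per-cell sum of species EDGE scores (DD species contribute nothing)."""
    inc = _occupied(incidence)
    missing = [s for s in inc.species if s not in species_scores.index]
    if missing:
        raise DataError(f"species without EDGE scores: {missing[:10]}")
    edge = species_scores["EDGE"].reindex(inc.species)
    weights = edge.fillna(0.0).to_numpy()
    values = weights @ inc.presence
    scored = (~edge.isna()).to_numpy().astype(float) @ inc.presence
    n_unscored = int((scored == 0).sum())
    if n_unscored:
        logger.warning(
            "%d cells contain only unscored (DD) species; their grid EDGE is 0",
            n_unscored,
        )
    return MetricSurface("EDGE", dict(zip(inc.cells, values)))


def species_score_table(
    incidence: IncidenceMatrix, tree: PhyloTree, iucn: pd.Series
) -> pd.DataFrame:
    """Full per-species table: range size, IUCN, GE, ED, EDGE."""
    ed = fair_proportion_ed(tree)
    scores = edge_scores(ed, iucn)
    scores.insert(0, "range", incidence.range_sizes().reindex(scores.index))
    return scores
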