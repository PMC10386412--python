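"""Data model, validation and I/O for grid-based endemism analyses.

The substrate of every metric in this package is a species x grid-cell
presence/absence matrix (:class:`IncidenceMatrix`) together with a per-cell
attribute table (environmental covariates and protection status), a
per-species IUCN category table, and a rooted phylogeny bound to the dataset
species names.  This module reads, validates and round-trips those tables;
the phylogeny lives in :mod:`phyloendemism.phylo`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Environmental covariates expected in the cell attribute table.
COVARIATES = ["bio1", "bio8", "bio12", "elevation", "aspect", "slope", "dist_coast"]

#: Valid protection classes for a grid cell.  A cell inside both the
#: Natura 2000 network and a local network counts as ``natura2000``.
PROTECTION_LEVELS = ("natura2000", "local_only", "none")

#: Valid IUCN Red List categories.
IUCN_CATEGORIES = ("CR", "EN", "VU", "NT", "LC", "DD")


class DataError(ValueError):
    """Raised when an input table violates the data model."""


@dataclass
class IncidenceMatrix:
    """Species x cells presence/absence matrix.

    Parameters
    ----------
    species
        Ordered unique species identifiers (rows).
    cells
        Ordered unique cell identifiers (columns).
    presence
        Boolean array of shape ``(len(species), len(cells))``.

    After :meth:`validate`, every species occupies at least one cell and
    every cell holds at least one species; row sums are per-species range
    sizes and column sums are per-cell endemic richness.
    """

    species: list[str]
    cells: list[str]
    presence: np.ndarray

    def __post_init__(self) -> None:
        self.species = list(self.species)
        self.cells = list(self.cells)
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.presence.shape != (len(self.species), len(self.cells)):
            raise DataError(
                f"presence shape {self.presence.shape} does not match "
                f"{len(self.species)} species x {len(self.cells)} cells"
            )
        if len(set(self.species)) != len(self.species):
            raise DataError("duplicate species identifiers")
        if len(set(self.cells)) != len(self.cells):
            raise DataError("duplicate cell identifiers")
        self._species_index = {s: i for i, s in enumerate(self.species)}
        self._cell_index = {c: j for j, c in enumerate(self.cells)}

    # -- basic accessors -------------------------------------------------

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def species_row(self, species: str) -> np.ndarray:
        return self.presence[self._species_index[species]]

    def cells_of(self, species: str) -> list[str]:
        """Cells occupied by *species*."""
        row = self.species_row(species)
        return [c for c, p in zip(self.cells, row) if p]

    def range_sizes(self) -> pd.Series:
        """Per-species number of occupied cells (row sums)."""
        return pd.Series(self.presence.sum(axis=1), index=self.species, name="range")

    def richness(self) -> pd.Series:
        """Per-cell number of species present (column sums)."""
        return pd.Series(self.presence.sum(axis=0), index=self.cells, name="RE")

    def occupied_cells(self) -> list[str]:
        mask = self.presence.any(axis=0)
        return [c for c, m in zip(self.cells, mask) if m]

    def restrict_to_occupied(self) -> "IncidenceMatrix":
        """Drop cells holding no species (the default analysis domain)."""
        mask = self.presence.any(axis=0)
        if mask.all():
            return self
        cells = [c for c, m in zip(self.cells, mask) if m]
        return IncidenceMatrix(self.species, cells, self.presence[:, mask])

    def validate(self) -> None:
        if self.n_species == 0:
            raise DataError("incidence matrix has no species")
        empty = [s for s, n in self.range_sizes().items() if n == 0]
        if empty:
            raise DataError(f"species with no occurrences: {empty}")

    @classmethod
    def from_records(cls, records: pd.DataFrame) -> "IncidenceMatrix":
        """Build from a long table with columns ``species`` and ``cell_id``.

        Duplicate (species, cell) rows collapse to a single presence with a
        logged warning; extra columns (e.g. abundances) are ignored.
        """
        if not {"species", "cell_id"}.issubset(records.columns):
            raise DataError("occurrence table needs 'species' and 'cell_id' columns")
        extra = [c for c in records.columns if c not in ("species", "cell_id")]
        if extra:
            warnings.warn(
                f"ignoring non-presence columns in occurrence table: {extra}",
                stacklevel=2,
            )
        n_dup = records.duplicated(subset=["species", "cell_id"]).sum()
        if n_dup:
            logger.warning("collapsed %d duplicate (species, cell) rows", n_dup)
        dedup = records.drop_duplicates(subset=["species", "cell_id"])
        species = sorted(dedup["species"].unique())
        cells = sorted(dedup["cell_id"].unique())
        sidx = {s: i for i, s in enumerate(species)}
        cidx = {c: j for j, c in enumerate(cells)}
        presence = np.zeros((len(species), len(cells)), dtype=bool)
        presence[
            dedup["species"].map(sidx).to_numpy(),
            dedup["cell_id"].map(cidx).to_numpy(),
        ] = True
        return cls(species, cells, presence)

    def to_records(self) -> pd.DataFrame:
        rows, cols = np.nonzero(self.presence)
        return pd.DataFrame(
            {
                "species": [self.species[i] for i in rows],
                "cell_id": [self.cells[j] for j in cols],
            }
        )

    def to_frame(self) -> pd.DataFrame:
        """Dense 0/1 DataFrame, species rows x cell columns."""
        return pd.DataFrame(
            self.presence.astype(int), index=self.species, columns=self.cells
        )


@dataclass
class MetricSurface:
    """A named per-cell metric (RE, WE, CWE, PD, sesPD, PE or EDGE).

    ``values`` is indexed by cell identifier over the analysis domain
    (occupied cells by default) and must be finite everywhere.
    """

    name: str
    values: pd.Series

    def __post_init__(self) -> None:
        self.values = pd.Series(self.values, dtype=float)
        self.values.name = self.name
        if not np.isfinite(self.values.to_numpy()).all():
            bad = self.values.index[~np.isfinite(self.values.to_numpy())].tolist()
            raise DataError(f"metric {self.name!r} non-finite at cells {bad[:5]}")

    @property
    def cells(self) -> list[str]:
        return list(self.values.index)

    def __getitem__(self, cell: str) -> float:
        return float(self.values[cell])


@dataclass
class ValidationReport:
    """Summary statistics of a loaded dataset."""

    n_species: int
    n_occupied_cells: int
    n_records: int
    n_single_cell_species: int
    n_dd_species: int
    fatal: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.fatal

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = [
            f"species:                 {self.n_species}",
            f"occupied cells:          {self.n_occupied_cells}",
            f"occurrence records:      {self.n_records}",
            f"single-cell endemics:    {self.n_single_cell_species}",
            f"data-deficient species:  {self.n_dd_species}",
        ]
        if self.fatal:
            lines.append("FATAL: " + "; ".join(self.fatal))
        return "\n".join(lines)


@dataclass
class Dataset:
    """A validated bundle of incidence, cell attributes, IUCN table and tree."""

    incidence: IncidenceMatrix
    cell_table: pd.DataFrame
    iucn: pd.Series
    tree: "object | None" = None  # phylo.PhyloTree; optional for taxon-only runs


# ---------------------------------------------------------------------------
# readers


def read_occurrences(path: str | Path) -> IncidenceMatrix:
    """Read ``occurrences.csv`` (header ``species,cell_id``)."""
    df = pd.read_csv(path, dtype=str)
    if len(df) == 0:
        raise DataError(f"{path}: occurrence table is empty")
    return IncidenceMatrix.from_records(df)


def read_cells(path: str | Path) -> pd.DataFrame:
    """Read ``cells.csv`` into a cell-indexed attribute table.

    Expected header: ``cell_id,x,y,<covariates...>,protection``.
    """
    df = pd.read_csv(path)
    if "cell_id" not in df.columns:
        raise DataError(f"{path}: missing 'cell_id' column")
    df["cell_id"] = df["cell_id"].astype(str)
    if df["cell_id"].duplicated().any():
        raise DataError(f"{path}: duplicate cell identifiers")
    df = df.set_index("cell_id")
    missing = [c for c in COVARIATES if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing covariate columns {missing}")
    if df[COVARIATES].isna().any().any():
        bad = df.index[df[COVARIATES].isna().any(axis=1)].tolist()
        raise DataError(f"{path}: missing covariate values at cells {bad[:5]}")
    if "protection" in df.columns:
        bad_levels = set(df["protection"].unique()) - set(PROTECTION_LEVELS)
        if bad_levels:
            raise DataError(f"{path}: unknown protection levels {sorted(bad_levels)}")
    else:
        df["protection"] = "none"
    return df


def read_iucn(path: str | Path) -> pd.Series:
    """Read ``iucn.csv`` (header ``species,category``) into a Series."""
    df = pd.read_csv(path, dtype=str)
    if not {"species", "category"}.issubset(df.columns):
        raise DataError(f"{path}: needs 'species' and 'category' columns")
    if df["species"].duplicated().any():
        dups = df["species"][df["species"].duplicated()].tolist()
        raise DataError(f"{path}: duplicate species {dups}")
    bad = set(df["category"]) - set(IUCN_CATEGORIES)
    if bad:
        raise DataError(f"{path}: unknown IUCN categories {sorted(bad)}")
    return df.set_index("species")["category"]


def read_substitutions(path: str | Path) -> dict[str, str]:
    """Read ``substitutions.csv`` (header ``dataset_name,tree_name``)."""
    df = pd.read_csv(path, dtype=str)
    if not {"dataset_name", "tree_name"}.issubset(df.columns):
        raise DataError(f"{path}: needs 'dataset_name' and 'tree_name' columns")
    if df["dataset_name"].duplicated().any():
        raise DataError(f"{path}: duplicate dataset names in substitution table")
    return dict(zip(df["dataset_name"], df["tree_name"]))


def load_dataset(
    occurrence_path: str | Path,
    cells_path: str | Path,
    iucn_path: str | Path,
    tree_path: str | Path | None = None,
    substitutions_path: str | Path | None = None,
) -> Dataset:
    """Load and cross-validate all input tables (and optionally the tree).

    Raises :class:`DataError` naming the offending identifiers when an
    occurrence references a cell missing from the cell table, a species is
    missing from the IUCN table, or a tree tip cannot be matched.
    """
    incidence = read_occurrences(occurrence_path)
    incidence.validate()
    cell_table = read_cells(cells_path)
    iucn = read_iucn(iucn_path)

    missing_cells = sorted(set(incidence.cells) - set(cell_table.index))
    if missing_cells:
        raise DataError(
            f"occurrence cells absent from cell table: {missing_cells[:10]}"
        )
    missing_iucn = sorted(set(incidence.species) - set(iucn.index))
    if missing_iucn:
        raise DataError(f"species absent from IUCN table: {missing_iucn[:10]}")
    iucn = iucn.reindex(incidence.species)

    tree = None
    if tree_path is not None:
        from . import phylo

        tree = phylo.read_newick(tree_path)
        subs = (
            read_substitutions(substitutions_path)
            if substitutions_path is not None
            else {}
        )
        tree = phylo.bind_taxa(tree, incidence.species, subs)
    return Dataset(incidence=incidence, cell_table=cell_table, iucn=iucn, tree=tree)


def validate_dataset(dataset: Dataset) -> ValidationReport:
    """Report-only summary: counts of species, cells, records, narrow endemics."""
    inc = dataset.incidence
    ranges = inc.range_sizes()
    fatal: list[str] = []
    n_records = int(inc.presence.sum())
    if n_records == 0:
        fatal.append("zero occurrence records")
    dd = int((dataset.iucn == "DD").sum()) if dataset.iucn is not None else 0
    return ValidationReport(
        n_species=inc.n_species,
        n_occupied_cells=len(inc.occupied_cells()),
        n_records=n_records,
        n_single_cell_species=int((ranges == 1).sum()),
        n_dd_species=dd,
        fatal=fatal,
    )


# ---------------------------------------------------------------------------
# writers

#: float formatting for result tables: 12 significant digits round-trips
#: every value we produce bit-identically through read_csv.
_FLOAT_FORMAT = "%.12g"

RESULT_TABLES = (
    "metrics",
    "species_scores",
    "hotspots",
    "coverage",
    "model_avg",
)


def write_tables(results: dict[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """Write result tables as CSV and return the file manifest.

    ``results`` maps table name (see :data:`RESULT_TABLES`) to a DataFrame;
    unknown names are written too, so callers may add extra reports.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[Path] = []
    for name, table in results.items():
        path = out / f"{name}.csv"
        table.to_csv(path, float_format=_FLOAT_FORMAT)
        manifest.append(path)
    return manifest


def surfaces_to_frame(surfaces: list[MetricSurface]) -> pd.DataFrame:
    """Column-bind metric surfaces into one cell-indexed table."""
    df = pd.concat([s.values for s in surfaces], axis=1)
    df.index.name = "cell_id"
    return df
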