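"""End-to-end orchestration: metrics -> null model -> hotspots -> models.

Thin glue over the metric modules so the CLI, tests and reproduction script
share one code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import endemism_metrics, env_models, hotspots, phylo_metrics
from .core_data import Dataset, MetricSurface, surfaces_to_frame
from .hotspots import HotspotConfig


@dataclass
class AnalysisResult:
    surfaces: dict[str, MetricSurface]
    sespd: phylo_metrics.SesPDResult
    species_scores: pd.DataFrame
    spearman: pd.DataFrame
    hotspot_membership: dict[float, pd.DataFrame]
    hotspot_counts: dict[float, MetricSurface]
    coverage: pd.DataFrame
    gap_tables: dict[float, pd.DataFrame]
    model_averages: dict[str, env_models.ModelAverageResult] = field(
        default_factory=dict
    )

    def result_tables(self) -> dict[str, pd.DataFrame]:
        """The five standard output tables for :func:`core_data.write_tables`."""
        metrics = surfaces_to_frame(list(self.surfaces.values()))
        metrics["sesPD_class"] = self.sespd.classes
        hotspot_frames = []
        for q, membership in self.hotspot_membership.items():
            frame = membership.astype(int).copy()
            frame.insert(0, "q", q)
            frame["count"] = self.hotspot_counts[q].values.astype(int)
            hotspot_frames.append(frame.reset_index())
        model_rows = []
        for response, avg in self.model_averages.items():
            block = avg.coefficients.copy()
            block.insert(0, "response", response)
            model_rows.append(block.reset_index())
        return {
            "metrics": metrics,
            "species_scores": self.species_scores,
            "hotspots": pd.concat(hotspot_frames, ignore_index=True).set_index(
                "cell_id"
            ),
            "coverage": self.coverage,
            "model_avg": (
                pd.concat(model_rows, ignore_index=True).set_index("response")
                if model_rows
                else pd.DataFrame()
            ),
        }


def run_analysis(
    dataset: Dataset,
    seed: int,
    reps: int = 1000,
    config: HotspotConfig | None = None,
    fit_models: bool = True,
) -> AnalysisResult:
    """Compute all seven surfaces, hotspot sets, coverage, gaps and models."""
    config = config or HotspotConfig()
    inc = dataset.incidence.restrict_to_occupied()
    tree = dataset.tree
    if tree is None:
        raise ValueError("dataset has no bound tree")

    surfaces = endemism_metrics.taxonomic_surfaces(inc)
    surfaces["PD"] = phylo_metrics.faith_pd(tree, inc)
    surfaces["PE"] = phylo_metrics.phylogenetic_endemism(tree, inc)
    sespd = phylo_metrics.ses_pd(tree, inc, reps=reps, seed=seed)
    surfaces["sesPD"] = sespd.surface
    species_scores = phylo_metrics.species_score_table(inc, tree, dataset.iucn)
    surfaces["EDGE"] = phylo_metrics.grid_edge(inc, species_scores)

    spearman = env_models.spearman_matrix(surfaces)

    membership: dict[float, pd.DataFrame] = {}
    counts: dict[float, MetricSurface] = {}
    gaps: dict[float, pd.DataFrame] = {}
    for q in config.fractions:
        counts[q], membership[q] = hotspots.hotspot_counts(surfaces, q, config)
        gaps[q] = hotspots.protection_gap(counts[q], dataset.cell_table)
    coverage = hotspots.coverage_by_fraction(inc, surfaces, dataset.iucn, config)

    model_averages: dict[str, env_models.ModelAverageResult] = {}
    if fit_models:
        predictors = env_models.screen_predictors(dataset.cell_table)
        responses = ["RE", "WE", "CWE", "PD", "sesPD", "PE"]
        frame = env_models.transform_and_standardize(
            {r: surfaces[r] for r in responses}, dataset.cell_table, predictors
        )
        for response in responses:
            model_averages[response] = env_models.model_average_response(
                response, frame, predictors
            )

    return AnalysisResult(
        surfaces=surfaces,
        sespd=sespd,
        species_scores=species_scores,
        spearman=spearman,
        hotspot_membership=membership,
        hotspot_counts=counts,
        coverage=coverage,
        gap_tables=gaps,
        model_averages=model_averages,
    )
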