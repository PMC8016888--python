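"""End-to-end cohort analyses built from the lower-level modules.

``analyze_cohort`` takes a synthetic cohort through the full chain —
generation, temporal preprocessing, quality metrics, Pearson adjacency,
common threshold grid, GTA profiles — and ``headline_comparison`` runs the
central statistical contrast: group differences in the graph parameters with
demographic covariates only, and again with the signal-quality metrics (CNR,
tSNR) added to the regression.  When the two groups share the same latent
network and differ only in fluctuation amplitude, the first comparison shows
widespread "network differences" and the second abolishes them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import graphs, stats
from .pipeline import PipelineConfig, preprocess_subject
from .quality import QualityMetrics, subject_quality
from .synthetic import (CohortBundle, GroupSpec, LatentNetwork, SubjectData,
                        VolumeLayout, cohort_table, default_cohort_specs,
                        iter_cohort)

logger = logging.getLogger(__name__)

__all__ = [
    "GTA_TEST_METRICS",
    "SubjectResult",
    "CohortAnalysis",
    "process_subject",
    "analyze_cohort",
    "headline_comparison",
]

#: the seven graph parameters entering group comparisons (mean degree is
#: 2*n_edges/n, so edges stand in for the degree parameter)
GTA_TEST_METRICS = ("n_edges", "clustering", "transitivity", "path_length",
                    "global_efficiency", "local_efficiency", "small_worldness")


@dataclass
class SubjectResult:
    subject_id: str
    group: str
    quality: QualityMetrics
    adjacency: graphs.WeightedAdjacency
    tau_max: float
    amplitude: float | None = None


@dataclass
class CohortAnalysis:
    """Everything the statistical stage needs, with volumes discarded."""

    table: pd.DataFrame                 # cohort covariates + quality columns
    subjects: list[SubjectResult]
    profiles: pd.DataFrame              # tidy (subject_id, threshold, metric, value)
    grid: graphs.ThresholdGrid
    seed: int

    def adjacency_stack(self) -> np.ndarray:
        return np.stack([s.adjacency.weights for s in self.subjects])

    def groups(self) -> np.ndarray:
        return np.array([s.group for s in self.subjects])


def process_subject(sub: SubjectData,
                    config: PipelineConfig | None = None,
                    threshold_step: float = 0.01) -> SubjectResult:
    """Pipeline + quality + adjacency + individual disconnection threshold."""
    prep = preprocess_subject(sub.bold, sub.parcellation,
                              sub.air.probabilities, sub.motion, config)
    qm = subject_quality(prep.signals, prep.trimmed, sub.air,
                         brain_mask=sub.parcellation.labels > 0)
    adj = graphs.pearson_adjacency(prep.signals)
    tau_max = graphs.max_connected_threshold(adj, step=threshold_step)
    return SubjectResult(subject_id=sub.subject_id, group=sub.group,
                         quality=qm, adjacency=adj, tau_max=tau_max,
                         amplitude=sub.amplitude)


def analyze_cohort(seed: int,
                   latent: LatentNetwork | None = None,
                   specs: list[GroupSpec] | None = None,
                   layout: VolumeLayout | None = None,
                   pipeline_config: PipelineConfig | None = None,
                   threshold_step: float = 0.01,
                   n_random: int = 20) -> CohortAnalysis:
    """Generate and fully process a synthetic cohort.

    Subjects are generated and processed one at a time (volumes are not kept).
    The threshold grid is truncated to the minimum disconnection threshold
    across all subjects of both groups, so every network in every comparison
    is connected on the common grid.
    """
    latent = latent or LatentNetwork.default()
    specs = specs or default_cohort_specs()
    table = cohort_table(specs, seed)
    results: list[SubjectResult] = []
    for sub in iter_cohort(latent, specs, seed, layout):
        res = process_subject(sub, pipeline_config, threshold_step)
        results.append(res)
        logger.info("processed %s (tau_max=%.2f, tsnr=%.1f, cnr=%.2f)",
                    res.subject_id, res.tau_max, res.quality.tsnr,
                    res.quality.cnr)
    tau_common = min(r.tau_max for r in results)
    grid = graphs.ThresholdGrid.from_tau_max(tau_common, step=threshold_step)
    profiles = graphs.profiles_to_tidy({
        r.subject_id: graphs.gta_profile(r.adjacency, grid, seed=seed + 17 * i,
                                         n_random=n_random)
        for i, r in enumerate(results)})
    qdf = pd.DataFrame({"subject_id": [r.subject_id for r in results],
                        "snr": [r.quality.snr for r in results],
                        "tsnr": [r.quality.tsnr for r in results],
                        "cnr": [r.quality.cnr for r in results]})
    table = table.merge(qdf, on="subject_id", validate="one_to_one")
    return CohortAnalysis(table=table, subjects=results, profiles=profiles,
                          grid=grid, seed=seed)


def headline_comparison(analysis: CohortAnalysis, n_perm: int = 1000,
                        seed: int = 0, alpha: float = 0.05,
                        groups: tuple[str, str] | None = None) -> dict:
    """The central contrast: GTA group differences with and without
    signal-quality covariates.

    Returns a dict with the per-quality-metric permutation results, the two
    comparison tables (age+education; age+education+cnr+tsnr), the fraction
    of (metric, threshold) cells significant under each covariate set, and
    the mean functional connectivity per group.
    """
    table = analysis.table
    labels = table["group"].to_numpy()
    if groups is None:
        uniq = sorted(pd.unique(labels))
        groups = (uniq[0], uniq[1])
    in_b = labels == groups[1]

    quality_tests = {}
    for i, metric in enumerate(("snr", "tsnr", "cnr")):
        vals = table[metric].to_numpy(dtype=float)
        quality_tests[metric] = stats.permutation_test(
            vals[in_b], vals[~in_b], n_perm=n_perm, seed=seed + i)

    prof = analysis.profiles[analysis.profiles["metric"]
                             .isin(GTA_TEST_METRICS)]
    comparisons = {}
    fractions = {}
    for name, covs in (("age_education", ["age", "education_years"]),
                       ("age_education_quality",
                        ["age", "education_years", "cnr", "tsnr"])):
        cfg = stats.StatsConfig(alpha=alpha, n_perm=n_perm, seed=seed)
        comp = stats.gta_group_comparison(prof, table, covs, cfg, groups=groups)
        comparisons[name] = comp
        fractions[name] = float(comp["significant"].mean())

    fc = {g: float(np.mean([analysis.subjects[i].adjacency.upper_values().mean()
                            for i in np.flatnonzero(labels == g)]))
          for g in groups}
    return {"groups": groups, "quality_tests": quality_tests,
            "comparisons": comparisons, "fraction_significant": fractions,
            "mean_fc": fc, "n_thresholds": analysis.grid.values.size}
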