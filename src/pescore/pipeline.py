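"""End-to-end PES pipeline on in-memory study data.

Chains the stages in the order a full analysis runs them: gene-level
aggregation at every P_T, competitive pathway association, candidate
selection (P < 0.001), per-pathway score construction at the pathway's
chosen threshold, genome-wide PRS with Nagelkerke-optimised P_T, and
percentile profiling.  Mostly a convenience for simulations and the CLI;
each stage remains usable on its own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import genes, genesets, profiling, scoring

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    gene_results: pd.DataFrame
    set_results: pd.DataFrame
    candidates: list
    pes_definitions: list
    prs_definition: object
    prs_optimisation: object
    scores: pd.DataFrame               # PES columns + PRS_TOTAL
    flags: object = None               # PercentileFlags
    gene_map: dict = field(default_factory=dict)


def run_pipeline(study, thresholds=genes.DEFAULT_THRESHOLDS, alpha=0.001,
                 clump_r2=0.1, clump_kb=250, prs_grid=scoring.DEFAULT_PRS_GRID,
                 levels=profiling.DEFAULT_LEVELS, exclude_mhc=True) -> PipelineResult:
    """Run gene -> set -> candidate -> score -> profile on a study.

    ``study`` needs ``sumstats, annotation, genotypes, gene_sets,
    phenotypes`` (a :class:`~pescore.simulate.StudyData` or any object
    with those attributes); the cohort genotypes double as the LD
    reference panel.
    """
    gm = study.genotypes
    gene_results = genes.run_gene_analysis(
        study.sumstats, study.annotation, gm, thresholds=thresholds,
        exclude_mhc=exclude_mhc)
    set_results = genesets.run_set_analysis(gene_results, study.gene_sets)
    candidates = genesets.select_candidates(set_results, study.gene_sets, alpha=alpha)

    gene_map = genes.map_snps_to_genes(study.sumstats, study.annotation,
                                       exclude_mhc=exclude_mhc)
    pes_defs = scoring.build_pes_definitions(candidates, study.sumstats, gene_map,
                                             gm, r2=clump_r2, window_kb=clump_kb)
    prs_opt, prs_def = scoring.optimise_total_prs(
        study.sumstats, gm, study.phenotypes, grid=prs_grid,
        r2=clump_r2, window_kb=clump_kb)
    scores = scoring.score_matrix([*pes_defs, prs_def], gm)
    flags = None
    if pes_defs:
        flags = profiling.flag_percentiles(scores[[d.name for d in pes_defs]],
                                           levels=levels)
    return PipelineResult(gene_results=gene_results, set_results=set_results,
                          candidates=candidates, pes_definitions=pes_defs,
                          prs_definition=prs_def, prs_optimisation=prs_opt,
                          scores=scores, flags=flags, gene_map=gene_map)
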