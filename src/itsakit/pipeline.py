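"""End-to-end convenience: quant table in, called targets out."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .preprocess import (
    FilterReport,
    NormalizationFactors,
    apply_normalization_pipeline,
    filter_proteins,
)
from .quant import ProteinQuantTable
from .targets import (
    ThresholdSelection,
    call_targets,
    compute_group_stats,
    select_threshold_from_stats,
)


@dataclass
class PipelineResult:
    stats: pd.DataFrame                 # per-protein fc/log2fc/t/p/is_target
    summary: dict[str, int]
    filter_report: FilterReport
    factors: list[NormalizationFactors]
    threshold: ThresholdSelection | None
    fc_threshold: float
    alpha: float

    @property
    def target_genes(self) -> frozenset[str]:
        hit = self.stats.loc[self.stats["is_target"], "gene_symbol"]
        return frozenset(g.upper() for g in hit)

    @property
    def background_genes(self) -> frozenset[str]:
        return frozenset(g.upper() for g in self.stats["gene_symbol"])


def run_target_pipeline(
    table: ProteinQuantTable,
    min_sum_pep: float = 5.0,
    min_unique: int = 1,
    fc_threshold: float | None = 1.3,
    coverage_param: float = 0.88,
    alpha: float = 0.05,
    round_to: float | None = None,
) -> PipelineResult:
    """Filter -> normalize -> group stats -> threshold -> call.

    With ``fc_threshold=None`` the cutoff is chosen from the
    variance-coverage curve at ``coverage_param``; otherwise the
    explicit value is used and the curve is still reported.
    """
    filtered, report = filter_proteins(table, min_sum_pep, min_unique)
    normalized, factors = apply_normalization_pipeline(filtered)
    stats = compute_group_stats(normalized)
    selection = None
    if len(stats):
        selection = select_threshold_from_stats(stats, coverage_param, round_to)
    thr = fc_threshold if fc_threshold is not None else selection.fc_threshold
    called, summary = call_targets(stats, fc_threshold=thr, alpha=alpha)
    return PipelineResult(called, summary, report, factors, selection, thr, alpha)
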