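"""End-to-end orchestration: simulate -> preprocess -> detect -> CRQA -> stats.

Everything runs in memory on :class:`~facemimic.cohort.Cohort` objects; the
CLI and the analysis drivers wrap these functions with file I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .cohort import Cohort, CohortConfig, QuestionnaireModel, ResponseParams, generate_cohort
from .crqa import CRQAConfig, aggregate_instructed, instructed_crqa_table
from .preprocess import exclusion_summary, preprocess_records
from .spontaneous import MimicryWindows, mimicry_rates
from .stats import build_cohort_table, rq_report

__all__ = ["PipelineResult", "analyze_cohort", "run_pipeline"]


@dataclass
class PipelineResult:
    cohort: Cohort
    mimicry_rates: pd.DataFrame
    crqa_per_snippet: pd.DataFrame
    crqa_aggregates: pd.DataFrame
    table: pd.DataFrame
    exclusions: dict
    bundle: dict | None = None


def analyze_cohort(
    cohort: Cohort,
    windows: MimicryWindows = MimicryWindows(),
    crqa_config: CRQAConfig = CRQAConfig(),
    smooth_window: int = 10,
    nominal_count: int | None = 12,
    min_valid: int = 6,
    with_stats: bool = True,
    gg: bool = False,
) -> PipelineResult:
    """Run every analysis stage on an (in-memory) cohort.

    ``smooth_window`` is the low-pass filter applied to both trajectories
    before the cross-recurrence analysis; spontaneous detection runs on the
    raw binary activations.
    """
    records = preprocess_records(cohort.records, nominal_count, min_valid)
    rates = mimicry_rates(records, windows)
    instructed = [r for r in records if r.phase == "instructed"]
    if instructed:
        per_snippet = instructed_crqa_table(
            instructed, cohort.stimuli, crqa_config, smooth_window)
        crqa_agg = aggregate_instructed(per_snippet)
    else:
        per_snippet = pd.DataFrame()
        crqa_agg = pd.DataFrame()
    table = build_cohort_table(rates, crqa_agg if not crqa_agg.empty else None,
                               cohort.questionnaire)
    bundle = None
    if with_stats:
        truth_summary = {
            "seed": cohort.seed,
            "p_mimic_rfr": cohort.params.p_mimic_rfr,
            "p_mimic_cfr": cohort.params.p_mimic_cfr,
            "questionnaire_coupling": dict(cohort.qmodel.coupling),
        }
        bundle = rq_report(table, gg=gg, ground_truth=truth_summary)
    return PipelineResult(cohort, rates, per_snippet, crqa_agg, table,
                          exclusion_summary(records), bundle)


def run_pipeline(
    config: CohortConfig | None = None,
    params: ResponseParams | None = None,
    qmodel: QuestionnaireModel | None = None,
    seed: int = 0,
    **analysis_kwargs,
) -> PipelineResult:
    """Simulate a cohort and analyze it in one call."""
    cohort = generate_cohort(config, params, qmodel, seed=seed)
    return analyze_cohort(cohort, **analysis_kwargs)
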