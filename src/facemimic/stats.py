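"""Mixed-design statistical stage.

Runs the study's analysis plan on pipeline outputs:

* 3 x 3 mixed ANOVAs -- humanlikeness (between: characterlike / humanlike /
  morph) x embodiment (within: the three artificial agents) -- for each
  dependent variable, with partial eta squared effect sizes;
* follow-up 2 x 3 mixed ANOVAs contrasting artificiality (within: the mean
  of the three artificial agents vs the video-recorded human);
* Bonferroni-corrected pairwise paired post-hoc tests;
* simple regressions on standardized variables at participant x embodiment
  grain (pooled across embodiments), linking spontaneous mimicry to the
  perception scales and instructed to spontaneous mimicry.

The ANOVA decomposition is delegated to :func:`pingouin.mixed_anova`;
uncorrected degrees of freedom are reported by default, with a
Greenhouse-Geisser option.  Missing cells are handled by listwise deletion
within each analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

from .records import ARTIFICIAL_EMBODIMENTS, HUMAN_EMBODIMENT

__all__ = [
    "ANOVAResult", "PosthocResult", "RegressionResult",
    "build_cohort_table", "mixed_anova_3x3", "mixed_anova_2x3_artificiality",
    "bonferroni_posthoc", "simple_regression", "rq_report",
]


@dataclass(frozen=True)
class ANOVAResult:
    effect: str            # 'embodiment' / 'humanlikeness' / 'interaction' / 'artificiality'
    F: float
    df1: int
    df2: int
    p: float
    partial_eta_sq: float


@dataclass(frozen=True)
class PosthocResult:
    level_a: str
    level_b: str
    mean_a: float
    mean_b: float
    t: float
    df: int
    p_raw: float
    p_adjusted: float
    n_pairs: int


@dataclass(frozen=True)
class RegressionResult:
    beta_std: float
    t: float
    df: int
    p: float
    r_sq: float
    n: int
    defined: bool = True


# ---------------------------------------------------------------------------
# table assembly
# ---------------------------------------------------------------------------

def build_cohort_table(
    mimicry_rates: pd.DataFrame | None = None,
    crqa_aggregates: pd.DataFrame | None = None,
    questionnaire: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Long participant x embodiment x dependent-variable table.

    Dependent variables: ``spont_rfr`` / ``spont_cfr`` (mimicry rates),
    ``avg_cRR`` / ``avg_L`` / ``avg_Lmax`` / ``avg_DET`` (instructed
    aggregates) and every questionnaire scale column.
    """
    rows = []
    if mimicry_rates is not None and not mimicry_rates.empty:
        for _, r in mimicry_rates.iterrows():
            dv = "spont_rfr" if r["window"] == "RFR" else "spont_cfr"
            rows.append((r["participant_id"], r["group"], r["embodiment"],
                         dv, float(r["rate"])))
    if crqa_aggregates is not None and not crqa_aggregates.empty:
        for _, r in crqa_aggregates.iterrows():
            for dv in ("avg_cRR", "avg_L", "avg_Lmax", "avg_DET"):
                rows.append((r["participant_id"], r["group"], r["embodiment"],
                             dv, float(r[dv])))
    if questionnaire is not None and not questionnaire.empty:
        scales = [c for c in questionnaire.columns
                  if c not in ("participant_id", "group", "embodiment")]
        for _, r in questionnaire.iterrows():
            for dv in scales:
                rows.append((r["participant_id"], r["group"], r["embodiment"],
                             dv, float(r[dv])))
    return pd.DataFrame(rows, columns=["participant_id", "group",
                                       "embodiment", "dv_name", "value"])


def _dv_wide(table: pd.DataFrame, dv: str,
             embodiments: Sequence[str]) -> pd.DataFrame:
    """participant x embodiment wide frame for one dv, listwise complete."""
    sub = table[(table["dv_name"] == dv)
                & table["embodiment"].isin(embodiments)]
    wide = sub.pivot_table(index=["participant_id", "group"],
                           columns="embodiment", values="value",
                           aggfunc="mean")
    wide = wide.reindex(columns=list(embodiments)).dropna(axis=0, how="any")
    return wide.reset_index()


def _check_groups(wide: pd.DataFrame) -> None:
    counts = wide.groupby("group").size()
    if len(counts) < 2 or (counts < 2).any():
        raise ValueError(
            "mixed ANOVA needs at least 2 participants in each of >= 2 "
            f"groups after listwise deletion; got {counts.to_dict()}")


def _run_mixed(long: pd.DataFrame, within: str, gg: bool) -> list[ANOVAResult]:
    aov = pg.mixed_anova(data=long, dv="value", within=within,
                         subject="participant_id", between="group",
                         correction=bool(gg), effsize="np2")
    name_map = {"group": "humanlikeness", within: within,
                "Interaction": "interaction"}
    # column names differ across pingouin releases (p-unc vs p_unc)
    p_unc = "p_unc" if "p_unc" in aov.columns else "p-unc"
    gg_col = next((c for c in ("p_GG_corr", "p-GG-corr") if c in aov.columns),
                  None)
    p_col = gg_col if (gg and gg_col) else p_unc
    out = []
    for _, row in aov.iterrows():
        p = row[p_col] if not pd.isna(row.get(p_col)) else row[p_unc]
        out.append(ANOVAResult(
            effect=name_map.get(row["Source"], str(row["Source"])),
            F=float(row["F"]), df1=int(row["DF1"]), df2=int(row["DF2"]),
            p=float(p), partial_eta_sq=float(row["np2"])))
    return out


def mixed_anova_3x3(
    table: pd.DataFrame,
    dv: str,
    embodiments: Sequence[str] = ARTIFICIAL_EMBODIMENTS,
    gg: bool = False,
) -> list[ANOVAResult]:
    """Humanlikeness x embodiment mixed ANOVA over the artificial agents.

    Participants missing any embodiment cell are dropped listwise.
    Returns the two main effects and the interaction.
    """
    wide = _dv_wide(table, dv, embodiments)
    _check_groups(wide)
    long = wide.melt(id_vars=["participant_id", "group"],
                     var_name="embodiment", value_name="value")
    return _run_mixed(long, "embodiment", gg)


def mixed_anova_2x3_artificiality(
    table: pd.DataFrame,
    dv: str,
    artificial: Sequence[str] = ARTIFICIAL_EMBODIMENTS,
    human: str = HUMAN_EMBODIMENT,
    gg: bool = False,
) -> list[ANOVAResult]:
    """Humanlikeness x artificiality (artificial mean vs human) mixed ANOVA.

    The three artificial embodiments are collapsed to their per-participant
    mean (over the cells the participant has); participants without any
    artificial cell or without the human cell are dropped.
    """
    sub = table[table["dv_name"] == dv]
    wide = sub.pivot_table(index=["participant_id", "group"],
                           columns="embodiment", values="value",
                           aggfunc="mean")
    art_cols = [c for c in artificial if c in wide.columns]
    if human not in wide.columns or not art_cols:
        raise ValueError("artificiality ANOVA needs artificial and human cells")
    out = pd.DataFrame({
        "artificial": wide[art_cols].mean(axis=1),
        "human": wide[human],
    }).dropna(axis=0, how="any").reset_index()
    _check_groups(out)
    long = out.melt(id_vars=["participant_id", "group"],
                    var_name="artificiality", value_name="value")
    return _run_mixed(long, "artificiality", gg)


def bonferroni_posthoc(
    table: pd.DataFrame,
    dv: str,
    factor_levels: Sequence[str] = ARTIFICIAL_EMBODIMENTS,
) -> list[PosthocResult]:
    """Pairwise paired t-tests over factor levels, Bonferroni corrected.

    Each pair uses the participants observed on both levels; raw p-values
    are multiplied by the number of pairs and capped at 1.
    """
    sub = table[(table["dv_name"] == dv)
                & table["embodiment"].isin(factor_levels)]
    wide = sub.pivot_table(index="participant_id", columns="embodiment",
                           values="value", aggfunc="mean")
    pairs = list(combinations(factor_levels, 2))
    results = []
    for a, b in pairs:
        paired = wide[[a, b]].dropna(axis=0, how="any")
        x, y = paired[a].to_numpy(), paired[b].to_numpy()
        t, p = sps.ttest_rel(x, y)
        results.append(PosthocResult(
            level_a=a, level_b=b,
            mean_a=float(x.mean()), mean_b=float(y.mean()),
            t=float(t), df=len(paired) - 1, p_raw=float(p),
            p_adjusted=float(min(p * len(pairs), 1.0)),
            n_pairs=len(pairs)))
    return results


def simple_regression(predictor, outcome) -> RegressionResult:
    """OLS of the outcome on one predictor, both z-standardized.

    Observations with a missing value on either side are dropped.  Reports
    the standardized slope (the Pearson correlation), its t statistic with
    n - 2 degrees of freedom, the two-sided p-value, and r^2 = beta^2.
    A zero-variance predictor or outcome yields an undefined, flagged
    result rather than zeros.
    """
    x = np.asarray(predictor, dtype=float)
    y = np.asarray(outcome, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3 or x.std() == 0 or y.std() == 0:
        return RegressionResult(np.nan, np.nan, max(n - 2, 0), np.nan,
                                np.nan, n, defined=False)
    r = float(np.corrcoef(x, y)[0, 1])
    df = n - 2
    if abs(r) >= 1.0:
        t = np.inf if r > 0 else -np.inf
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = 2.0 * sps.t.sf(abs(t), df)
    return RegressionResult(beta_std=r, t=float(t), df=df, p=float(p),
                            r_sq=r * r, n=n)


def _paired_dv_values(table: pd.DataFrame, dv_x: str, dv_y: str,
                      embodiments: Sequence[str] | None) -> tuple[np.ndarray, np.ndarray]:
    sub = table
    if embodiments is not None:
        sub = sub[sub["embodiment"].isin(embodiments)]
    wide = sub[sub["dv_name"].isin([dv_x, dv_y])].pivot_table(
        index=["participant_id", "embodiment"], columns="dv_name",
        values="value", aggfunc="mean")
    if dv_x not in wide.columns or dv_y not in wide.columns:
        return np.array([]), np.array([])
    paired = wide[[dv_x, dv_y]].dropna(axis=0, how="any")
    return paired[dv_x].to_numpy(), paired[dv_y].to_numpy()


def regress_dvs(
    table: pd.DataFrame,
    predictor_dv: str,
    outcome_dv: str,
    embodiments: Sequence[str] | None = None,
) -> RegressionResult:
    """Simple regression between two dvs at participant x embodiment grain."""
    x, y = _paired_dv_values(table, predictor_dv, outcome_dv, embodiments)
    return simple_regression(x, y)


# ---------------------------------------------------------------------------
# results bundle
# ---------------------------------------------------------------------------

PERCEPTION_SCALES = (
    "co_presence", "attentional_allocation", "affective_understanding",
    "emotional_interdependence", "behavioral_interdependence",
    "anthropomorphism", "perceived_threat", "likability",
)

INSTRUCTED_DVS = ("avg_cRR", "avg_L", "avg_Lmax", "avg_DET")
SPONTANEOUS_DVS = ("spont_rfr", "spont_cfr")


def rq_report(
    table: pd.DataFrame,
    gg: bool = False,
    ground_truth: Mapping | None = None,
) -> dict:
    """Machine-readable bundle of the full analysis plan.

    Contains, per dependent variable: the 3 x 3 ANOVA, the 2 x 3
    artificiality ANOVA, embodiment post-hocs for the mimicry dvs, the
    mimicry -> perception regressions (artificial agents only) and the
    instructed -> spontaneous regressions (all embodiments).  Analyses
    that cannot run on the given table (missing dvs, too few rows) are
    recorded as ``{"error": ...}`` instead of aborting the bundle.
    """
    dvs_present = sorted(table["dv_name"].unique())
    bundle: dict = {"dvs": dvs_present, "anova_3x3": {},
                    "anova_2x3_artificiality": {}, "posthoc_embodiment": {},
                    "regressions_rq3": {}, "regressions_rq4": {}}
    for dv in dvs_present:
        try:
            bundle["anova_3x3"][dv] = [asdict(r) for r in
                                       mixed_anova_3x3(table, dv, gg=gg)]
        except ValueError as err:
            bundle["anova_3x3"][dv] = {"error": str(err)}
        try:
            bundle["anova_2x3_artificiality"][dv] = [
                asdict(r) for r in mixed_anova_2x3_artificiality(table, dv, gg=gg)]
        except ValueError as err:
            bundle["anova_2x3_artificiality"][dv] = {"error": str(err)}
    for dv in SPONTANEOUS_DVS:
        if dv in dvs_present:
            bundle["posthoc_embodiment"][dv] = [
                asdict(r) for r in bonferroni_posthoc(table, dv)]
    for pred in SPONTANEOUS_DVS:
        for outcome in PERCEPTION_SCALES:
            if pred in dvs_present and outcome in dvs_present:
                res = regress_dvs(table, pred, outcome,
                                  embodiments=ARTIFICIAL_EMBODIMENTS)
                bundle["regressions_rq3"][f"{pred}->{outcome}"] = asdict(res)
    for pred in INSTRUCTED_DVS:
        for outcome in SPONTANEOUS_DVS:
            if pred in dvs_present and outcome in dvs_present:
                res = regress_dvs(table, pred, outcome, embodiments=None)
                bundle["regressions_rq4"][f"{pred}->{outcome}"] = asdict(res)
    if ground_truth is not None:
        bundle["ground_truth"] = dict(ground_truth)
    return bundle
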