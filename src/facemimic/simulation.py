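"""Monte-Carlo validation studies of the full simulate -> analyze loop.

These runs treat the whole pipeline (generator, preprocessing, detection,
statistics) as a black box and measure its operating characteristics:
type-I error of the embodiment test under a null generator, power under a
known embodiment gap, recovery of a questionnaire coupling's sign, and
closure of the generator-detector loop on a known injection probability.

Replicate cohorts are scaled down (12 participants, spontaneous phase,
artificial embodiments only) where the question does not depend on the full
design size, so a 1000-replicate calibration stays in the minutes range on
one core.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import CohortConfig, QuestionnaireModel, ResponseParams, generate_cohort
from .pipeline import analyze_cohort
from .records import ARTIFICIAL_EMBODIMENTS
from .stats import mixed_anova_3x3, regress_dvs

__all__ = [
    "replicate_seeds", "type1_calibration", "embodiment_power",
    "coupling_sign_recovery", "cfr_closure",
]


def replicate_seeds(seed: int, n: int) -> np.ndarray:
    """Independent per-replicate seeds derived from one master seed."""
    return (np.random.SeedSequence(seed).generate_state(n) >> 1).astype(np.int64)


def _spontaneous_config(n_participants: int) -> CohortConfig:
    per_group = n_participants // 3
    return CohortConfig(
        n_participants=per_group * 3,
        group_sizes=(per_group,) * 3,
        embodiments=ARTIFICIAL_EMBODIMENTS,
        phases=("spontaneous",),
    )


def _embodiment_p(table_dv: str, cohort_seed: int, cfg, params) -> float:
    res = analyze_cohort(generate_cohort(cfg, params, seed=cohort_seed),
                         with_stats=False)
    aov = mixed_anova_3x3(res.table, table_dv)
    return next(a for a in aov if a.effect == "embodiment").p


def type1_calibration(
    n_reps: int = 1000,
    seed: int = 0,
    n_participants: int = 12,
    alpha: float = 0.05,
) -> dict:
    """Rejection rate of the embodiment main effect under a null generator.

    All embodiments share the same mimicry probabilities (the defaults), so
    any significant embodiment effect is a false positive; a calibrated
    pipeline rejects at about the nominal alpha.
    """
    cfg = _spontaneous_config(n_participants)
    params = ResponseParams()
    rejections = 0
    for s in replicate_seeds(seed, n_reps):
        p = _embodiment_p("spont_rfr", int(s), cfg, params)
        rejections += p < alpha
    return {"n_reps": n_reps, "alpha": alpha,
            "rejection_rate": rejections / n_reps}


def embodiment_power(
    n_reps: int = 100,
    seed: int = 0,
    gap: float = 0.25,
    base_p: float = 0.25,
    n_participants: int = 45,
    alpha: float = 0.05,
) -> dict:
    """Detection rate of a CFR mimicry-probability gap between embodiments.

    One artificial embodiment's injection probability sits ``gap`` above
    the other two; power is the fraction of replicates whose 3 x 3 ANOVA
    flags the embodiment main effect on the CFR rate.
    """
    cfg = _spontaneous_config(n_participants)
    params = ResponseParams(p_mimic_cfr={
        "virtual": base_p, "physical": base_p, "video_robot": base_p + gap})
    detections = 0
    for s in replicate_seeds(seed, n_reps):
        p = _embodiment_p("spont_cfr", int(s), cfg, params)
        detections += p < alpha
    return {"n_reps": n_reps, "gap": gap, "power": detections / n_reps}


def coupling_sign_recovery(
    n_reps: int = 100,
    seed: int = 0,
    coupling: float = -0.4,
    n_participants: int = 45,
) -> dict:
    """Fraction of replicates recovering the sign of a likability coupling.

    Cohorts are generated with a clearly negative latent-propensity ->
    likability coupling; recovery means the pooled standardized regression
    of likability on the measured RFR mimicry rate comes out negative.
    """
    cfg = _spontaneous_config(n_participants)
    params = ResponseParams()
    qmodel = QuestionnaireModel(coupling={"likability": coupling})
    hits = 0
    for s in replicate_seeds(seed, n_reps):
        res = analyze_cohort(
            generate_cohort(cfg, params, qmodel, seed=int(s)),
            with_stats=False)
        reg = regress_dvs(res.table, "spont_rfr", "likability",
                          embodiments=ARTIFICIAL_EMBODIMENTS)
        hits += (reg.beta_std < 0) == (coupling < 0)
    return {"n_reps": n_reps, "coupling": coupling,
            "sign_recovery_rate": hits / n_reps}


def cfr_closure(seed: int = 0, p_inject: float = 0.7) -> dict:
    """Generator-detector closure on a known CFR injection probability.

    A full-size cohort (45 participants, 4 embodiments, no occlusion, no
    participant heterogeneity) receives CFR injections with probability
    ``p_inject`` and no RFR injections; the detected mean CFR rate should
    sit within Monte-Carlo error of ``p_inject``.
    """
    cfg = CohortConfig(phases=("spontaneous",))
    params = ResponseParams(p_mimic_rfr=0.0, p_mimic_cfr=p_inject,
                            p_occlusion=0.0, participant_effect_sd=0.0)
    res = analyze_cohort(generate_cohort(cfg, params, seed=seed),
                         with_stats=False)
    cfr = res.mimicry_rates.query("window == 'CFR'")
    n_snippets = int(cfr["n_valid"].sum())
    mean_rate = float(cfr["n_mimicked"].sum() / n_snippets)
    mc_sd = float(np.sqrt(p_inject * (1 - p_inject) / n_snippets))
    return {"p_inject": p_inject, "mean_rate": mean_rate,
            "n_snippets": n_snippets, "mc_sd": mc_sd}
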