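"""Synthetic menstrual-cycle cohort: hormone panel + linear outcomes.

Participants are sampled at up to three phases (EFP, LFP, MLP) with
phase-specific oestradiol and progesterone distributions chosen to mimic
a healthy cycle: oestradiol low early-follicular, peaking (variably)
late-follicular, intermediate mid-luteal; progesterone low in both
follicular phases and high mid-luteal.  Outcomes are generated as

    value = intercept + slope_e2 * E2 + slope_resP * resP
            + participant_intercept + residual noise

where resP is progesterone residualised on oestradiol within the
generated panel itself, so the generating slopes are directly the
estimands of the mixed-model stage.  An optional missing-session pattern
thins the panel to the kind of unbalanced design a real cohort produces
(default pattern: 21 participants with 17/17/18 present per phase).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..stats import PHASES, residualize_progesterone

__all__ = ["CohortTruth", "gen_cohort", "DEFAULT_MISSING_PATTERN"]

#: (participant index, phase index) pairs left unsampled; mirrors an
#: unbalanced 21-participant imaging cohort with 17/17/18 per phase.
DEFAULT_MISSING_PATTERN: tuple[tuple[int, int], ...] = (
    (0, 0), (1, 0), (2, 0), (3, 0),
    (4, 1), (5, 1), (6, 1), (7, 1),
    (8, 2), (9, 2), (10, 2),
)


@dataclass
class CohortTruth:
    """Generating parameters of a synthetic cohort."""

    n_participants: int = 21
    phases: tuple[str, ...] = PHASES
    #: per-phase oestradiol mean/SD (pmol/L)
    e2_means: tuple[float, ...] = (150.0, 550.0, 400.0)
    e2_sds: tuple[float, ...] = (60.0, 250.0, 150.0)
    #: per-phase progesterone mean/SD (nmol/L)
    p4_means: tuple[float, ...] = (1.5, 3.0, 30.0)
    p4_sds: tuple[float, ...] = (0.8, 1.5, 12.0)
    #: fixed effects: outcome units per pmol/L (E2) and per nmol/L (resP)
    slope_oestradiol: float = 0.0195
    slope_resprog: float = 0.17
    intercept: float = 45.0
    random_intercept_sd: float = 5.0
    residual_sd: float = 2.5
    metric: str = "perfusion_global"
    missing_pattern: tuple[tuple[int, int], ...] | None = \
        DEFAULT_MISSING_PATTERN
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")
        if tuple(self.phases) != PHASES:
            raise ValueError(f"phases must be exactly {PHASES}")
        for sd in (*self.e2_sds, *self.p4_sds, self.random_intercept_sd,
                   self.residual_sd):
            if sd < 0:
                raise ValueError("all SDs must be non-negative")


def gen_cohort(truth: CohortTruth,
               roi_slopes: dict[str, float] | None = None
               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate ``(hormone_panel, outcome_table)``.

    The panel has one row per (participant, phase) present under the
    missing pattern, with ``oestradiol``, ``progesterone`` and the
    derived ``res_progesterone``.  The outcome table is long-format
    (participant, phase, metric, roi, laterality, value); by default a
    single global metric, or one row per ROI when ``roi_slopes`` maps
    ROI labels to oestradiol slopes (resP slope shared; label "global"
    uses the truth's base slope).
    """
    rng = np.random.default_rng(truth.seed)
    missing = set(truth.missing_pattern or ())
    ids = [f"P{i:02d}" for i in range(truth.n_participants)]
    b = rng.normal(0.0, truth.random_intercept_sd, truth.n_participants)

    rows = []
    for i, pid in enumerate(ids):
        for j, phase in enumerate(truth.phases):
            if (i, j) in missing:
                continue
            e2 = max(rng.normal(truth.e2_means[j], truth.e2_sds[j]), 5.0)
            p4 = max(rng.normal(truth.p4_means[j], truth.p4_sds[j]), 0.1)
            rows.append({"participant": pid, "phase": phase,
                         "oestradiol": e2, "progesterone": p4})
    panel = residualize_progesterone(pd.DataFrame(rows))

    out_rows = []
    rois = roi_slopes or {"global": truth.slope_oestradiol}
    for _, rec in panel.iterrows():
        i = ids.index(rec["participant"])
        for roi, slope_e2 in rois.items():
            value = (truth.intercept
                     + slope_e2 * rec["oestradiol"]
                     + truth.slope_resprog * rec["res_progesterone"]
                     + b[i])
            if truth.residual_sd > 0:
                value += rng.normal(0.0, truth.residual_sd)
            out_rows.append({"participant": rec["participant"],
                             "phase": rec["phase"], "metric": truth.metric,
                             "roi": roi, "laterality": "none",
                             "value": value})
    outcomes = pd.DataFrame(out_rows)
    return panel, outcomes
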