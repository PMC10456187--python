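"""Generative 2AFC observer with a planted mental prototype.

This is the synthetic-data engine: it answers "which face looks more like
the target expression?" by scoring each stimulus against a planted
prototype and choosing the higher-scoring one, with controllable noise.
It makes every estimator testable end-to-end without human data — it is a
test fixture with the minimal structure consistent with the dominant /
complementary dependency the estimators assume, not a model of human
perception.

Score of a stimulus:  w_d · [dominant active] + w_c · |C ∩ active set|,
with w_d > w_c > 0 so the dominant AU drives choices more than any single
complementary AU.  Choice noise has two knobs: a logistic ``temperature``
on the score difference (0 = hard argmax, exact ties by a seeded fair
coin) and a ``lapse_rate`` probability of answering uniformly at random.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .catalog import StimulusCatalog, StimulusVector
from .design import ResponseSet, TrialPair, enumerate_stimuli, sample_schedule
from .estimate import (
    ConvergenceCurve,
    MentalPrototype,
    complementary_proportions,
    complementary_set,
    convergence_curve,
    dominant_au,
    selection_proportions,
)

__all__ = ["ObserverModel", "RecoveryReport", "score_stimulus", "simulate_responses", "recovery_experiment"]


@dataclass(frozen=True)
class ObserverModel:
    """A simulated observer defined by a prototype and noise parameters."""

    true_prototype: MentalPrototype
    dominant_weight: float = 2.0
    complementary_weight: float = 1.0
    temperature: float = 0.0
    lapse_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.dominant_weight > self.complementary_weight > 0:
            raise ValueError(
                "weights must satisfy dominant_weight > complementary_weight > 0, "
                f"got {self.dominant_weight} and {self.complementary_weight}"
            )
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative")
        if not 0.0 <= self.lapse_rate <= 1.0:
            raise ValueError("lapse_rate must be in [0, 1]")


def score_stimulus(observer: ObserverModel, stimulus: StimulusVector) -> float:
    """w_d · [dominant active] + w_c · (number of complementary AUs active)."""
    proto = observer.true_prototype
    if stimulus.catalog.au_ids != proto.catalog.au_ids:
        raise ValueError("stimulus and prototype are on different catalogs")
    active = stimulus.active_ids
    return observer.dominant_weight * (proto.dominant in active) + (
        observer.complementary_weight * len(proto.complementary & active)
    )


def _choice_probabilities_left(
    observer: ObserverModel, score_left: np.ndarray, score_right: np.ndarray
) -> np.ndarray:
    """P(choose left) per trial before the lapse mixture."""
    diff = score_left - score_right
    if observer.temperature == 0:
        p = np.where(diff > 0, 1.0, np.where(diff < 0, 0.0, 0.5))
    else:
        p = 1.0 / (1.0 + np.exp(-diff / observer.temperature))
    return observer.lapse_rate * 0.5 + (1.0 - observer.lapse_rate) * p


def simulate_responses(
    observer: ObserverModel,
    schedule: Sequence[TrialPair],
    question_label: str = "",
) -> ResponseSet:
    """Answer every trial of a schedule; reproducible from ``observer.seed``."""
    proto = observer.true_prototype
    catalog = schedule[0].left.catalog if schedule else proto.catalog
    score_left = np.array([score_stimulus(observer, p.left) for p in schedule])
    score_right = np.array([score_stimulus(observer, p.right) for p in schedule])
    p_left = _choice_probabilities_left(observer, score_left, score_right)
    rng = np.random.default_rng(observer.seed)
    chose_left = rng.random(len(schedule)) < p_left
    trials = [
        (pair, "left" if chose_left[t] else "right")
        for t, pair in enumerate(schedule)
    ]
    return ResponseSet(
        trials,
        question_label=question_label,
        observer_id="simulated",
        catalog=catalog,
    )


@dataclass(frozen=True)
class RecoveryReport:
    """Outcome of one planted-prototype recovery run."""

    planted: MentalPrototype
    recovered: MentalPrototype
    dominant_match: bool
    complementary_match: bool
    exact_match: bool
    m: int
    dominant_curve: ConvergenceCurve | None = None
    complementary_curve: ConvergenceCurve | None = None


def recovery_experiment(
    observer: ObserverModel,
    catalog: StimulusCatalog,
    m: int,
    threshold: float,
    seed: int,
    curves: bool = False,
    curve_step: int = 10,
) -> RecoveryReport:
    """Design → simulate → estimate, then compare against the planted truth.

    ``seed`` drives the schedule draw; the observer's own seed drives its
    choices.  With ``curves=True`` the report carries the convergence
    diagnostics of both stages.
    """
    if m < 1:
        raise ValueError("m must be ≥ 1")
    stimuli = enumerate_stimuli(catalog)
    schedule = sample_schedule(stimuli, m=m, seed=seed)
    responses = simulate_responses(observer, schedule)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dom_table = selection_proportions(responses)
        d = dominant_au(dom_table)
        comp_table = complementary_proportions(responses, d)
        comp = complementary_set(comp_table, threshold)
        recovered = MentalPrototype(
            catalog=catalog,
            dominant=d,
            complementary=comp,
            threshold=threshold,
            provenance={"m": m, "schedule_seed": seed, "observer_seed": observer.seed},
        )
        dom_curve = comp_curve = None
        if curves:
            dom_curve = convergence_curve(responses, "dominant", step=curve_step)
            comp_curve = convergence_curve(
                responses, "complementary", step=max(1, curve_step // 10), d=d
            )

    planted = observer.true_prototype
    dom_ok = recovered.dominant == planted.dominant
    comp_ok = recovered.complementary == planted.complementary
    return RecoveryReport(
        planted=planted,
        recovered=recovered,
        dominant_match=dom_ok,
        complementary_match=comp_ok,
        exact_match=dom_ok and comp_ok,
        m=m,
        dominant_curve=dom_curve,
        complementary_curve=comp_curve,
    )
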