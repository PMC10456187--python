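"""Bundled reference datasets.

Small plain-text tables from a published crowd-sourced evaluation of
AU-based facial-expression prototypes: per-task Schulze path-strength
matrices (percentages; candidates are four observers' personalized
prototypes plus comparison prototypes "Ek." and "Yu." from the expression
literature) and the observers' own 1-5 satisfaction ratings.  For sadness,
observer #1's prototype was identical to "Ek.", so their preference data
were merged into the single candidate "#1/Ek.".
"""

from __future__ import annotations

from importlib import resources

from .ranking import OpinionScores, PathStrengthMatrix, read_ratings, read_strengths

__all__ = ["RANKING_TASKS", "load_published_strengths", "load_published_ratings"]

RANKING_TASKS = ("happiness", "sadness", "anger", "self-confidence")


def _data_path(name: str):
    return resources.files("aurevcorr").joinpath("data").joinpath(name)


def load_published_strengths(task: str) -> PathStrengthMatrix:
    """Published path-strength matrix for one ranking task."""
    if task not in RANKING_TASKS:
        raise KeyError(f"unknown task {task!r}; choose one of {RANKING_TASKS}")
    with resources.as_file(_data_path(f"strengths_{task}.csv")) as path:
        return read_strengths(path)


def load_published_ratings() -> OpinionScores:
    """Observers' 1-5 satisfaction ratings of their own prototypes."""
    with resources.as_file(_data_path("ratings_observers.csv")) as path:
        return read_ratings(path)
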