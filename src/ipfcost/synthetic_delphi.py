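"""Synthetic multi-round Delphi panel: generation, consensus, agreement.

Emulates a panel of experts answering numeric questions over several
rounds.  Responses are log-normal multiplicative noise around a centre
(positive, right-skewed — appropriate for costs and rates), truncated to
the question's admissible bounds.  Round 1 centres on the question's true
value; each later round centres on the previous round's median with the
dispersion shrunk by a convergence factor, so the panel clusters toward
consensus.  The consensus input set is the per-question median of the
final round.

The "agreement" metric — the fraction of experts within a relative
tolerance band around the round median — is a stated proxy for consensus
strength, not a reconstruction of any particular questionnaire's rule.
"""

from __future__ import annotations

import csv
import statistics
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import DomainError, ReferenceResolutionError
from .model_io import ModelInputs

__all__ = [
    "QuestionSpec",
    "PanelResponse",
    "generate_panel",
    "consensus_median",
    "agreement_rate",
    "panel_to_inputs",
    "write_panel_csv",
    "DEFAULT_CONVERGENCE",
]

DEFAULT_CONVERGENCE = 0.5


@dataclass(frozen=True)
class QuestionSpec:
    """One numeric elicitation question targeting a model-input field.

    ``target_field`` is a dotted path into :class:`ModelInputs`, with
    ``[i]`` list indexing — e.g. ``"epidemiology.prevalence_per_100k"`` or
    ``"courses[2].exacerbations_per_year"``.  ``dispersion`` is the
    relative spread (log-normal sigma) of expert responses.
    """

    question_id: str
    target_field: str
    true_value: float
    dispersion: float = 0.15
    bounds: tuple[float, float] = (0.0, float("inf"))

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise ValueError(f"dispersion must be >= 0, got {self.dispersion}")
        lo, hi = self.bounds
        if not lo <= self.true_value <= hi:
            raise ValueError(
                f"question {self.question_id!r}: true value {self.true_value} "
                f"outside bounds {self.bounds}"
            )


@dataclass(frozen=True)
class PanelResponse:
    expert_id: int
    round: int
    question_id: str
    value: float


def generate_panel(
    questions: Sequence[QuestionSpec],
    n_experts: int = 15,
    n_rounds: int = 3,
    seed: int = 0,
    convergence: float = DEFAULT_CONVERGENCE,
) -> list[PanelResponse]:
    """Simulate a reproducible multi-round panel.

    Round ``r`` uses dispersion ``sigma * convergence**(r-1)`` around the
    previous round's median (round 1: around the true value).  With zero
    dispersion every expert answers the centre exactly.
    """
    if n_experts < 1:
        raise DomainError(f"need at least one expert, got {n_experts}")
    if n_rounds < 1:
        raise DomainError(f"need at least one round, got {n_rounds}")
    if not 0 < convergence <= 1:
        raise DomainError(f"convergence factor must be in (0,1], got {convergence}")
    rng = np.random.default_rng(seed)
    responses: list[PanelResponse] = []
    for question in questions:
        centre = question.true_value
        lo, hi = question.bounds
        for rnd in range(1, n_rounds + 1):
            sigma = question.dispersion * convergence ** (rnd - 1)
            if sigma > 0 and centre > 0:
                values = centre * np.exp(rng.normal(0.0, sigma, size=n_experts))
            else:
                values = np.full(n_experts, centre, dtype=float)
            values = np.clip(values, lo, hi)
            responses.extend(
                PanelResponse(
                    expert_id=expert,
                    round=rnd,
                    question_id=question.question_id,
                    value=float(values[expert - 1]),
                )
                for expert in range(1, n_experts + 1)
            )
            centre = float(np.median(values))
    return responses


def _round_values(
    responses: Sequence[PanelResponse], round: int
) -> dict[str, list[float]]:
    per_question: dict[str, list[float]] = {}
    for r in responses:
        if r.round == round:
            per_question.setdefault(r.question_id, []).append(r.value)
    return per_question


def consensus_median(
    responses: Sequence[PanelResponse],
    round: int,
    question_ids: Sequence[str] | None = None,
) -> dict[str, float]:
    """Per-question median of one round (midpoint of central pair if even).

    If ``question_ids`` is given, every listed question must have at least
    one response in that round.
    """
    per_question = _round_values(responses, round)
    if question_ids is not None:
        missing = [q for q in question_ids if q not in per_question]
        if missing:
            raise ReferenceResolutionError(
                f"no round-{round} responses for questions: {missing}"
            )
        per_question = {q: per_question[q] for q in question_ids}
    return {q: statistics.median(vals) for q, vals in per_question.items()}


def agreement_rate(
    responses: Sequence[PanelResponse], round: int, tolerance: float = 0.2
) -> dict[str, float]:
    """Percent of experts within +/-tolerance (relative) of the round median."""
    if tolerance < 0:
        raise DomainError(f"tolerance must be >= 0, got {tolerance}")
    out: dict[str, float] = {}
    for question_id, values in _round_values(responses, round).items():
        med = statistics.median(values)
        band = abs(med) * tolerance
        inside = sum(1 for v in values if abs(v - med) <= band)
        out[question_id] = inside / len(values) * 100.0
    return out


def _set_path(tree: dict, path: str, value: float) -> None:
    """Assign ``value`` at a dotted/indexed path inside a nested dict tree."""
    node = tree
    tokens = path.split(".")
    steps: list[str | int] = []
    for token in tokens:
        while "[" in token:
            head, rest = token.split("[", 1)
            idx, token = rest.split("]", 1)
            if head:
                steps.append(head)
            steps.append(int(idx))
        if token:
            steps.append(token)
    try:
        for step in steps[:-1]:
            node = node[step]
        last = steps[-1]
        # Require the leaf to exist: elicitation overwrites, never invents.
        _ = node[last]
        node[last] = value
    except (KeyError, IndexError, TypeError):
        raise ReferenceResolutionError(f"target_field {path!r} does not resolve") from None


def panel_to_inputs(
    consensus: Mapping[str, float],
    questions: Sequence[QuestionSpec],
    template: ModelInputs,
) -> ModelInputs:
    """Write consensus values into a template's addressed fields; revalidate."""
    by_id = {q.question_id: q for q in questions}
    tree = template.model_dump()
    for question_id, value in consensus.items():
        try:
            question = by_id[question_id]
        except KeyError:
            raise ReferenceResolutionError(
                f"no question spec for consensus id {question_id!r}"
            ) from None
        _set_path(tree, question.target_field, value)
    return ModelInputs.model_validate(tree)


def write_panel_csv(
    responses: Sequence[PanelResponse], path: str | Path, seed: int | None = None
) -> Path:
    """Export responses as CSV; the seed is recorded in a comment header."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        writer = csv.writer(fh)
        writer.writerow(["expert_id", "round", "question_id", "value"])
        for r in responses:
            writer.writerow([r.expert_id, r.round, r.question_id, repr(r.value)])
    return path
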