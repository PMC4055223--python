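"""PAQ-C / PAQ-A scoring.

Both questionnaire forms are 7-day recalls whose items are answered on a
1-5 ordinal scale (higher = more active).  Item 1 is an activity checklist
scored as the mean of its entries; the remaining items cover PE class,
recess (children's form only), lunch, after school, evening, the weekend,
and two overall weekly-pattern questions.  The summary score is the plain
mean of the checklist score and the other item scores — 9 scored items for
PAQ-C, 8 for PAQ-A — and stays on the 1-5 scale.  Scores are stored at full
precision; one-decimal rounding is applied only where the score enters the
calibration equation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

FORM_CHILD = "PAQ-C"
FORM_ADOLESCENT = "PAQ-A"

#: Scored items beyond the checklist, in canonical order.
ITEMS_PAQ_C = (
    "pe", "recess", "lunch", "after_school", "evening", "weekend",
    "week_describe", "week_frequency",
)
ITEMS_PAQ_A = tuple(i for i in ITEMS_PAQ_C if i != "recess")

#: Items ignored for scoring if present in input (e.g. "were you sick").
NON_SCORED_ITEMS = frozenset({"sick"})


class ScoringError(ValueError):
    """Raised when a response sheet cannot be scored (missing/invalid item)."""


def _check_response(value: int, where: str) -> int:
    v = int(value)
    if v != value or not 1 <= v <= 5:
        raise ScoringError(f"{where}: response {value!r} not an integer in 1..5")
    return v


@dataclass
class PAQResponse:
    """One participant's questionnaire responses.

    ``checklist`` holds the item-1 activity entries (variable length);
    ``item_scores`` maps the remaining item names to their 1-5 responses.
    ``summary`` is filled by :func:`score_paq`.
    """

    participant_id: str
    form: str
    checklist: Sequence[int]
    item_scores: Mapping[str, int]
    summary: float | None = field(default=None)

    def __post_init__(self) -> None:
        if self.form not in (FORM_CHILD, FORM_ADOLESCENT):
            raise ScoringError(f"unknown form {self.form!r}")


def score_checklist(checklist: Sequence[int]) -> float:
    """Mean of the checklist activity responses (the item-1 score)."""
    if len(checklist) == 0:
        raise ScoringError("empty activity checklist")
    vals = [_check_response(v, f"checklist[{i}]") for i, v in enumerate(checklist)]
    return sum(vals) / len(vals)


def required_items(form: str) -> tuple[str, ...]:
    return ITEMS_PAQ_C if form == FORM_CHILD else ITEMS_PAQ_A


def score_paq(response: PAQResponse) -> float:
    """Compute the PAQ summary score (mean of item 1 and the other items).

    Missing required items raise :class:`ScoringError` naming the item — no
    imputation.  Extra non-scored items (e.g. the illness question) are
    ignored.  The returned score is full precision; round to one decimal for
    display or for the calibration equation.
    """
    items = required_items(response.form)
    scores = [score_checklist(response.checklist)]
    for name in items:
        if name not in response.item_scores:
            raise ScoringError(f"missing required item {name!r} for {response.form}")
        scores.append(_check_response(response.item_scores[name], name))
    if response.form == FORM_ADOLESCENT and "recess" in response.item_scores:
        raise ScoringError("recess item present on PAQ-A response")
    summary = sum(scores) / len(scores)
    response.summary = summary
    return summary


# ---------------------------------------------------------------------------
# CSV I/O (long format: participant_id, form, item, response)
# ---------------------------------------------------------------------------


def write_paq_csv(responses: Sequence[PAQResponse], path: str | Path) -> None:
    rows = []
    for r in responses:
        for i, v in enumerate(r.checklist, start=1):
            rows.append((r.participant_id, r.form, f"checklist_{i}", int(v)))
        for name, v in r.item_scores.items():
            rows.append((r.participant_id, r.form, name, int(v)))
    pd.DataFrame(rows, columns=["participant_id", "form", "item", "response"]).to_csv(
        path, index=False
    )


def read_paq_csv(path: str | Path) -> list[PAQResponse]:
    df = pd.read_csv(path, dtype={"participant_id": str})
    responses = []
    for (pid, form), grp in df.groupby(["participant_id", "form"], sort=True):
        checklist = [
            int(v)
            for item, v in zip(grp["item"], grp["response"])
            if str(item).startswith("checklist_")
        ]
        items = {
            str(item): int(v)
            for item, v in zip(grp["item"], grp["response"])
            if not str(item).startswith("checklist_")
            and str(item) not in NON_SCORED_ITEMS
        }
        responses.append(PAQResponse(str(pid), str(form), checklist, items))
    return responses


def score_table(responses: Sequence[PAQResponse]) -> pd.DataFrame:
    """Score a batch of responses into a participant/score table."""
    rows = [
        {
            "participant_id": r.participant_id,
            "form": r.form,
            "paq_score": score_paq(r),
        }
        for r in responses
    ]
    return pd.DataFrame(rows)
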