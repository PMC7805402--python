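"""PedsQL 4.0 Generic Core scoring.

The instrument has 23 items on a 5-point frequency scale (0 = never a
problem ... 4 = almost always a problem) split into four domains: physical
functioning (8 items), emotional, social, and school functioning (5 each).
Items are reverse-scored onto 0-100 (0→100, 1→75, 2→50, 3→25, 4→0), so
higher scores mean better health-related quality of life. A scale score is
the mean of its answered items; following the instrument's standard missing
rule, a scale with fewer than half of its items answered is not scored.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DOMAINS", "PedsQLResponse", "transform_item", "score", "score_table"]

#: 1-based item numbers per domain (23 items total)
DOMAINS: dict[str, tuple[int, ...]] = {
    "physical": tuple(range(1, 9)),
    "emotional": tuple(range(9, 14)),
    "social": tuple(range(14, 19)),
    "school": tuple(range(19, 24)),
}
N_ITEMS = 23
#: emotional + social + school; a common companion summary, not part of the
#: four-domain core report
PSYCHOSOCIAL = ("emotional", "social", "school")


@dataclass
class PedsQLResponse:
    """One questionnaire: 23 item responses (0-4 or NaN) and the respondent."""

    items: list
    respondent: str = "self"  # "self" or "proxy"

    def __post_init__(self) -> None:
        if self.respondent not in ("self", "proxy"):
            raise ValueError("respondent must be 'self' or 'proxy'")
        if len(self.items) != N_ITEMS:
            raise ValueError(f"expected {N_ITEMS} item responses, got {len(self.items)}")
        arr = np.asarray(self.items, dtype=float)
        answered = ~np.isnan(arr)
        if not np.isin(arr[answered], [0, 1, 2, 3, 4]).all():
            raise ValueError("item responses must be 0..4 or missing")
        self.items = arr


def transform_item(response: int) -> float:
    """Reverse-score one item onto 0-100: 0→100, 1→75, 2→50, 3→25, 4→0."""
    if response not in (0, 1, 2, 3, 4):
        raise ValueError(f"response must be in 0..4, got {response!r}")
    return 100.0 - 25.0 * float(response)


def _scale_mean(values: np.ndarray, min_answered_fraction: float) -> float:
    answered = ~np.isnan(values)
    if answered.sum() < min_answered_fraction * len(values) or answered.sum() == 0:
        return float("nan")
    return float(values[answered].mean())


def score(
    r: PedsQLResponse | list,
    min_answered_fraction: float = 0.5,
    psychosocial: bool = False,
) -> dict[str, float]:
    """Domain and total scores (0-100; NaN for unscorable scales).

    Each domain score is the mean of its transformed answered items and the
    total is the mean over all answered items; a scale answered below
    ``min_answered_fraction`` is reported missing. ``psychosocial=True``
    adds the emotional+social+school composite.
    """
    if not isinstance(r, PedsQLResponse):
        r = PedsQLResponse(items=list(r))
    transformed = 100.0 - 25.0 * r.items  # NaN propagates for missing items
    out: dict[str, float] = {}
    for domain, item_numbers in DOMAINS.items():
        idx = [i - 1 for i in item_numbers]
        out[domain] = _scale_mean(transformed[idx], min_answered_fraction)
    out["total"] = _scale_mean(transformed, min_answered_fraction)
    if psychosocial:
        idx = [i - 1 for d in PSYCHOSOCIAL for i in DOMAINS[d]]
        out["psychosocial"] = _scale_mean(transformed[idx], min_answered_fraction)
    return out


def score_table(responses: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Score a table of questionnaires.

    Expects columns ``item_1`` .. ``item_23`` and optionally ``respondent``;
    returns one row of scores per input row.
    """
    cols = [f"item_{i}" for i in range(1, N_ITEMS + 1)]
    missing = [c for c in cols if c not in responses.columns]
    if missing:
        raise ValueError(f"response table lacks columns: {missing}")
    rows = {}
    for idx, row in responses.iterrows():
        resp = PedsQLResponse(
            items=[row[c] for c in cols],
            respondent=row.get("respondent", "self"),
        )
        rows[idx] = score(resp, **kwargs)
    out = pd.DataFrame.from_dict(rows, orient="index")
    if "respondent" in responses.columns:
        out.insert(0, "respondent", responses["respondent"])
    return out
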