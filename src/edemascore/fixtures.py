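"""Synthetic reconstruction of the published seven-reader study.

The published study reports, for each of seven readers, how many of ten
edema cases (EVLW >= 15 mL/kg) and ten no-edema cases (EVLW <= 8 mL/kg)
were called correctly under each reading approach — but not which cases.
This module rebuilds concrete call matrices consistent with those
counts by marking, for each reader, the first k cases of each group as
correctly called (a nested construction: every reading a reader gets
right under the weaker approach they also get right under the stronger
one whenever their correct count did not decrease).

The per-case assignment is a choice. All pooled and per-reader point
metrics — confusion counts, sensitivity/specificity/PPV/NPV, and the NRI
point estimates — are invariant to it, because they depend only on the
per-reader correct counts. Statistics that depend on which cases
readers disagree on (pairwise agreement, kappa, NRI up/down splits) are
NOT reproduced by this fixture and should not be read off it.

EVLW values are likewise synthetic: evenly spread over the reported
ranges (4-8 and 15-21 mL/kg), anchored to the two published worked
examples (a no-edema case at 7 mL/kg, an edema case at 21 mL/kg).
"""

from __future__ import annotations

from .rubric import EDEMA, NO_EDEMA
from .stats import CallMatrix, ReferenceStandard

N_READERS = 7
N_PER_GROUP = 10

#: Correct calls out of 10 edema / 10 no-edema cases, readers 1-7.
SCORE_CORRECT_EDEMA = (8, 6, 8, 8, 7, 9, 8)
SCORE_CORRECT_NO_EDEMA = (10, 10, 10, 10, 10, 10, 10)
STANDARD_CORRECT_EDEMA = (5, 5, 6, 5, 5, 8, 6)
STANDARD_CORRECT_NO_EDEMA = (10, 10, 6, 9, 9, 10, 9)

EDEMA_CASE_IDS = tuple(f"E{i + 1:02d}" for i in range(N_PER_GROUP))
NO_EDEMA_CASE_IDS = tuple(f"N{i + 1:02d}" for i in range(N_PER_GROUP))
READER_IDS = tuple(f"reader_{i + 1}" for i in range(N_READERS))

#: Synthetic integer EVLW values spanning the reported ranges.
_EDEMA_EVLW = (21, 15, 16, 17, 18, 19, 20, 21, 15, 17)
_NO_EDEMA_EVLW = (7, 4, 5, 6, 7, 8, 4, 5, 6, 8)


def reference_standard() -> list[ReferenceStandard]:
    """Twenty-case reference: ten edema (15-21 mL/kg), ten no-edema (4-8 mL/kg)."""
    refs = [ReferenceStandard(c, v) for c, v in zip(EDEMA_CASE_IDS, _EDEMA_EVLW)]
    refs += [ReferenceStandard(c, v) for c, v in zip(NO_EDEMA_CASE_IDS, _NO_EDEMA_EVLW)]
    return refs


def _matrix(correct_edema: tuple[int, ...], correct_no_edema: tuple[int, ...]) -> CallMatrix:
    records = []
    for reader, k_ed, k_ne in zip(READER_IDS, correct_edema, correct_no_edema):
        for i, case in enumerate(EDEMA_CASE_IDS):
            records.append((reader, case, EDEMA if i < k_ed else NO_EDEMA))
        for i, case in enumerate(NO_EDEMA_CASE_IDS):
            records.append((reader, case, NO_EDEMA if i < k_ne else EDEMA))
    return CallMatrix.from_long(records)


def score_based_calls() -> CallMatrix:
    """Call matrix consistent with the score-based per-reader correct counts."""
    return _matrix(SCORE_CORRECT_EDEMA, SCORE_CORRECT_NO_EDEMA)


def standard_calls() -> CallMatrix:
    """Call matrix consistent with the standard-approach per-reader correct counts."""
    return _matrix(STANDARD_CORRECT_EDEMA, STANDARD_CORRECT_NO_EDEMA)
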