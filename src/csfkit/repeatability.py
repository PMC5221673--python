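"""Bland-Altman test-retest agreement and session handling.

The coefficient of repeatability (COR) is 1.96 times the standard deviation
of test-retest differences (session 2 minus session 1) -- the 95% limit of
agreement; smaller is more repeatable.  The mean difference is the bias.
The sample (n-1) standard deviation is used, the standard Bland-Altman
practice.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .fitting import rmse

__all__ = [
    "RepeatabilityResult",
    "bland_altman",
    "average_sessions",
    "rmse_test_retest",
]


@dataclass(frozen=True)
class RepeatabilityResult:
    """Bland-Altman agreement for one measure (test + frequency, or letter CS)."""

    measure_id: str
    cor: float
    bias: float
    n: int
    n_dropped: int = 0


def bland_altman(session1, session2, measure_id: str = "") -> RepeatabilityResult:
    """Coefficient of repeatability and bias from paired sessions.

    Pairs with a missing (NaN) entry in either session are dropped and
    counted in ``n_dropped``.  Differences are oriented session2 - session1.
    """
    s1 = np.asarray(session1, dtype=float)
    s2 = np.asarray(session2, dtype=float)
    if s1.shape != s2.shape or s1.ndim != 1:
        raise ValueError("sessions must be equal-length 1-d vectors paired by subject")
    ok = np.isfinite(s1) & np.isfinite(s2)
    dropped = int(s1.size - ok.sum())
    d = s2[ok] - s1[ok]
    if d.size < 2:
        raise ValueError(
            f"need at least 2 complete pairs for Bland-Altman, got {d.size}"
        )
    return RepeatabilityResult(
        measure_id=measure_id,
        cor=float(1.96 * np.std(d, ddof=1)),
        bias=float(np.mean(d)),
        n=int(d.size),
        n_dropped=dropped,
    )


def average_sessions(record):
    """Collapse a subject's two sessions into one by element-wise averaging.

    Letter CS and each test's logCS vectors are averaged across sessions;
    acuity is untouched.  A measure with a single session passes through
    unchanged with a note.  Idempotent on already-averaged records.
    """
    notes = list(record.notes)
    letter = (float(np.mean(record.letter_cs_sessions)),)
    if len(record.letter_cs_sessions) == 1:
        notes.append("letter_cs: single session passed through")
    csf_sessions = {}
    for test_id, sessions in record.csf_sessions.items():
        if len(sessions) == 1:
            csf_sessions[test_id] = sessions
            notes.append(f"{test_id}: single session passed through")
        else:
            mean_vec = np.mean([np.asarray(s, dtype=float) for s in sessions], axis=0)
            csf_sessions[test_id] = (tuple(float(v) for v in mean_vec),)
    return replace(
        record,
        letter_cs_sessions=letter,
        csf_sessions=csf_sessions,
        notes=tuple(notes),
    )


def rmse_test_retest(record, test_id: str) -> float:
    """Per-subject RMSE between session 1 and session 2 logCS vectors."""
    sessions = record.csf_sessions[test_id]
    if len(sessions) < 2:
        raise ValueError(
            f"subject {record.id}: test {test_id} has no retest session"
        )
    return rmse(sessions[0], sessions[1])
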