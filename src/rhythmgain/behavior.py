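"""Behavioral summaries for the chord-discrimination task.

Accuracy, signal-detection sensitivity (d') and criterion, and reaction
times are computed per subject and condition after excluding slow
responses (RT above the individual median + 2 SD).  In the jittered
condition only targets preceded by the canonical 1 s interval enter the
summaries, so the stimulation immediately before analysed targets is
matched across conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import statkit

__all__ = [
    "BehavioralSummary",
    "filter_rts",
    "signal_detection",
    "dprime_criterion",
    "summarize_condition",
    "condition_contrast",
]


@dataclass
class BehavioralSummary:
    condition: str
    accuracy: float  # percent correct of included responses
    dprime: float
    criterion: float
    mean_rt_ms: float
    n_included: int
    n_excluded: int


def filter_rts(rts) -> np.ndarray:
    """Retention mask: RTs strictly above median + 2 SD are excluded.

    The SD is computed over all responses before any exclusion; a response
    exactly at the threshold is retained.
    """
    rts = np.asarray(rts, dtype=float)
    if rts.size == 0:
        raise ValueError("no reaction times supplied")
    if rts.size < 2:
        return np.ones(rts.size, dtype=bool)
    thr = np.median(rts) + 2.0 * np.std(rts, ddof=1)
    return rts <= thr


def dprime_criterion(hit_rate: float, fa_rate: float) -> tuple[float, float]:
    """d' and criterion from raw hit and false-alarm rates (no correction)."""
    zh, zf = norm.ppf(hit_rate), norm.ppf(fa_rate)
    return float(zh - zf), float(-(zh + zf) / 2.0)


def signal_detection(responses) -> tuple[float, float]:
    """d' and criterion from (true identity, chosen identity) pairs.

    Identity 'A' is treated as the signal: a hit is A reported as A, a
    false alarm is B reported as A.  Extreme rates are handled with the
    log-linear correction (+0.5 to each count, +1 to each denominator).
    """
    pairs = list(responses)
    true = np.array([t for t, _ in pairs])
    chosen = np.array([c for _, c in pairs])
    n_a = int(np.sum(true == "A"))
    n_b = int(np.sum(true == "B"))
    if n_a == 0 or n_b == 0:
        raise ValueError("need at least one trial of each identity")
    hits = int(np.sum((true == "A") & (chosen == "A")))
    fas = int(np.sum((true == "B") & (chosen == "A")))
    hit_rate = (hits + 0.5) / (n_a + 1)
    fa_rate = (fas + 0.5) / (n_b + 1)
    return dprime_criterion(hit_rate, fa_rate)


def summarize_condition(
    responses: pd.DataFrame, condition: str, isi_ms: float = 1000.0
) -> BehavioralSummary:
    """Summarise one condition's responses from a trial table.

    Expects columns ``condition, true_identity, chosen_identity, correct,
    rt_ms, preceding_isi_ms``.  In the jittered condition only targets
    preceded by ``isi_ms`` are analysed; rhythmic targets all qualify.
    """
    sel = responses[responses["condition"] == condition]
    if condition == "jittered":
        sel = sel[sel["preceding_isi_ms"] == isi_ms]
    if len(sel) == 0:
        raise ValueError(f"no responses for condition {condition!r}")
    keep = filter_rts(sel["rt_ms"].to_numpy())
    inc = sel.loc[keep]
    dp, crit = signal_detection(zip(inc["true_identity"], inc["chosen_identity"]))
    return BehavioralSummary(
        condition=condition,
        accuracy=100.0 * float(inc["correct"].mean()),
        dprime=dp,
        criterion=crit,
        mean_rt_ms=float(inc["rt_ms"].mean()),
        n_included=int(keep.sum()),
        n_excluded=int((~keep).sum()),
    )


def condition_contrast(summaries: pd.DataFrame) -> pd.DataFrame:
    """Paired t tests of each behavioral measure between conditions.

    ``summaries`` holds one row per subject and condition with columns
    ``subject, condition, accuracy, dprime, criterion, mean_rt_ms``.
    Subjects missing either condition are dropped with a warning.
    """
    wide = summaries.pivot(index="subject", columns="condition")
    complete = wide.dropna()
    if len(complete) < len(wide):
        import warnings

        warnings.warn(
            f"dropped {len(wide) - len(complete)} subject(s) missing a condition",
            RuntimeWarning,
        )
    rows = []
    for measure in ("accuracy", "dprime", "criterion", "mean_rt_ms"):
        a = complete[(measure, "rhythmic")].to_numpy()
        b = complete[(measure, "jittered")].to_numpy()
        t, df, p = statkit.paired_t(a, b)
        rows.append(
            dict(
                measure=measure, mean_rhythmic=float(np.mean(a)),
                mean_jittered=float(np.mean(b)), t=t, df=df, p=p,
            )
        )
    return pd.DataFrame(rows)
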