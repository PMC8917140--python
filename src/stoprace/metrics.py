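"""Standard (non-model-based) stop-signal measures.

Per subject x task x condition cell: inhibition accuracy P_inhib, the
quantile-method SSRT, mean SSD, go accuracy P_Go, RT means (all / correct /
error go trials), intra-individual RT variability (IIV), and the go-failure
percentage, plus the participant-level exclusion filter used to screen
unreliable SSRT estimates.

Quantile-method SSRT: correct-go RTs are sorted ascending and the RT at the
(1 - P_inhib) quantile is selected by nearest rank — the ceil(q * n)-th value,
1-based, no interpolation — then the mean of all realized SSDs is subtracted.
The estimate may legitimately be negative (that is what exclusion criterion
(iii) screens).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SubjectSummary",
    "p_inhib",
    "ssrt_quantile",
    "rt_summaries",
    "exclusion_filter",
    "subject_summary",
    "summarize_dataset",
]


@dataclass(frozen=True)
class SubjectSummary:
    """Standard metrics for one subject-cell; undefined sub-means are NaN
    (never 0).  ``p_inhib``/``p_go`` are fractions; ``gf_pct`` is percent."""

    participant_id: str
    task: str
    condition: str
    p_inhib: float
    ssrt: float
    mean_ssd: float
    p_go: float
    rt_tot: float
    rt_correct: float
    rt_error: float
    iiv_rt: float
    gf_pct: float
    n_go: int
    n_stop: int


def _split(records):
    """Return (go_rows, stop_rows) as lists of TrialRecord-like objects."""
    if isinstance(records, pd.DataFrame):
        recs = list(records.itertuples(index=False))

        def rt(r):
            return None if pd.isna(r.rt_ms) else float(r.rt_ms)

        def ssd(r):
            return None if pd.isna(r.ssd_ms) else float(r.ssd_ms)

        def correct(r):
            return None if pd.isna(r.correct) else bool(r.correct)
        rows = [(r.trial_type, r.response, rt(r), ssd(r), correct(r))
                for r in recs]
    else:
        rows = [(r.trial_type, r.response, r.rt, r.ssd, r.correct)
                for r in records]
    go = [r for r in rows if r[0] == "go"]
    stop = [r for r in rows if r[0] == "stop"]
    return go, stop


def p_inhib(records) -> float:
    """Fraction of stop trials with no response (successful inhibition)."""
    _, stop = _split(records)
    if not stop:
        raise ValueError("p_inhib needs at least one stop trial")
    inhibited = sum(1 for r in stop if r[1] == "none")
    return inhibited / len(stop)


def ssrt_quantile(records, include_omissions: bool = False) -> float:
    """Quantile-method SSRT (ms): nearest-rank (1 - P_inhib) quantile of the
    ascending correct-go RTs minus the mean of all realized SSDs.

    ``include_omissions=True`` switches to the omission-replacement variant of
    the integration method: omitted go trials enter the RT list at the
    deadline value (1200 ms assumed when records carry no deadline).  Off by
    default — the estimator selects among correct go responses only.
    """
    go, stop = _split(records)
    if not stop:
        raise ValueError("ssrt needs at least one stop trial")
    rts = sorted(r[2] for r in go if r[1] != "none" and r[4])
    if include_omissions:
        rts = sorted(rts + [1200.0] * sum(1 for r in go if r[1] == "none"))
    if not rts:
        raise ValueError("ssrt needs at least one correct go RT")
    q = 1.0 - p_inhib(records)
    idx = max(1, math.ceil(q * len(rts)))        # 1-based nearest rank
    selected = rts[idx - 1]
    mean_ssd = float(np.mean([r[3] for r in stop]))
    return selected - mean_ssd


def rt_summaries(records):
    """(rt_tot, rt_correct, rt_error, iiv_rt, p_go, gf_pct) over go trials.

    Means are over responded go trials (all / correct-only / error-only);
    ``iiv_rt`` is the sample SD of responded-go RTs; ``p_go`` is correct
    responses / responded trials (omissions live in ``gf_pct``, percent of all
    go trials omitted).  Undefined quantities come back NaN.
    """
    go, _ = _split(records)
    if not go:
        raise ValueError("rt_summaries needs at least one go trial")
    responded = [r for r in go if r[1] != "none"]
    corr = [r[2] for r in responded if r[4]]
    err = [r[2] for r in responded if not r[4]]
    all_rt = [r[2] for r in responded]
    rt_tot = float(np.mean(all_rt)) if all_rt else float("nan")
    rt_correct = float(np.mean(corr)) if corr else float("nan")
    rt_error = float(np.mean(err)) if err else float("nan")
    iiv = float(np.std(all_rt, ddof=1)) if len(all_rt) > 1 else float("nan")
    p_go = len(corr) / len(responded) if responded else float("nan")
    gf_pct = 100.0 * (len(go) - len(responded)) / len(go)
    return rt_tot, rt_correct, rt_error, iiv, p_go, gf_pct


#: exclusion rules: (name, predicate on summary, description)
_EXCLUSION_RULES = (
    ("i", lambda s: s.p_inhib < 0.25 or s.p_inhib > 0.75,
     "P_inhib outside [25%, 75%]"),
    ("ii", lambda s: s.gf_pct > 40.0, "go-failure rate above 40%"),
    ("iii", lambda s: s.ssrt < 75.0, "SSRT negative or below 75 ms"),
)


def exclusion_filter(summary: SubjectSummary):
    """Screen one subject-cell: excluded iff any criterion holds; every
    violated criterion is reported, in rule order."""
    reasons = [f"({code}) {desc}" for code, pred, desc in _EXCLUSION_RULES
               if pred(summary)]
    return (not reasons), reasons


def subject_summary(records, participant_id: str | None = None,
                    task: str | None = None,
                    condition: str | None = None) -> SubjectSummary:
    """All standard metrics for one subject-cell's records."""
    go, stop = _split(records)
    rt_tot, rt_c, rt_e, iiv, pgo, gf = rt_summaries(records)
    pi = p_inhib(records)
    mean_ssd = float(np.mean([r[3] for r in stop]))

    def _field(name, given):
        if given is not None:
            return given
        if isinstance(records, pd.DataFrame):
            vals = records[name].unique()
            return str(vals[0])
        return str(getattr(records[0], name))

    return SubjectSummary(
        participant_id=_field("participant_id", participant_id),
        task=_field("task", task),
        condition=_field("condition", condition),
        p_inhib=pi,
        ssrt=ssrt_quantile(records),
        mean_ssd=mean_ssd,
        p_go=pgo,
        rt_tot=rt_tot,
        rt_correct=rt_c,
        rt_error=rt_e,
        iiv_rt=iiv,
        gf_pct=gf,
        n_go=len(go),
        n_stop=len(stop),
    )


def summarize_dataset(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-cell summary table: one row per participant x task x condition,
    with the standard metrics plus the exclusion verdict and reasons."""
    rows = []
    for (pid, task, cond), grp in trials.groupby(
            ["participant_id", "task", "condition"], sort=True):
        s = subject_summary(grp, str(pid), str(task), str(cond))
        include, reasons = exclusion_filter(s)
        d = s.__dict__.copy()
        d["include"] = include
        d["exclusion_reasons"] = "; ".join(reasons)
        rows.append(d)
    return pd.DataFrame(rows)
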