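"""File formats: the trial-level CSV, summary CSV, chain/diagnostic output.

The trial table is a comma-delimited UTF-8 CSV with exactly these columns:

    participant_id, task, condition, trial_index, trial_type, stimulus,
    ssd_ms, response, rt_ms, correct

Absent values (no SSD on go trials, no RT on unresponded trials, no
correctness on unresponded trials) are empty cells.  Validation reports the
offending file line (header = line 1).  Write -> read round-trips losslessly.
"""

from __future__ import annotations

import json
from dataclasses import asdict

import numpy as np
import pandas as pd

from .task import CONDITIONS, TASKS, TrialRecord

__all__ = [
    "TRIAL_COLUMNS",
    "records_to_frame",
    "frame_to_records",
    "read_trials",
    "write_trials",
    "validate_trials",
    "save_chains",
    "blueprint_to_yaml",
    "blueprint_from_yaml",
]

TRIAL_COLUMNS = (
    "participant_id", "task", "condition", "trial_index", "trial_type",
    "stimulus", "ssd_ms", "response", "rt_ms", "correct",
)

_RESPONSES = ("left", "right", "none")


def records_to_frame(records) -> pd.DataFrame:
    """TrialRecords -> schema DataFrame (None -> NaN/NA cells)."""
    rows = [{
        "participant_id": r.participant_id,
        "task": r.task,
        "condition": r.condition,
        "trial_index": r.trial_index,
        "trial_type": r.trial_type,
        "stimulus": str(r.stimulus),
        "ssd_ms": np.nan if r.ssd is None else float(r.ssd),
        "response": r.response,
        "rt_ms": np.nan if r.rt is None else float(r.rt),
        "correct": pd.NA if r.correct is None else bool(r.correct),
    } for r in records]
    df = pd.DataFrame(rows, columns=list(TRIAL_COLUMNS))
    df["correct"] = df["correct"].astype("boolean")
    return df


def frame_to_records(df: pd.DataFrame) -> list:
    """Schema DataFrame -> list of TrialRecords (stimulus strings kept;
    numeric-looking stimuli parsed back to float for the sensorial task)."""
    out = []
    for r in df.itertuples(index=False):
        stim = r.stimulus
        if r.task == "sensorial":
            stim = float(stim)
        out.append(TrialRecord(
            participant_id=str(r.participant_id), task=r.task,
            condition=r.condition, trial_index=int(r.trial_index),
            trial_type=r.trial_type, stimulus=stim,
            ssd=None if pd.isna(r.ssd_ms) else float(r.ssd_ms),
            response=r.response,
            rt=None if pd.isna(r.rt_ms) else float(r.rt_ms),
            correct=None if pd.isna(r.correct) else bool(r.correct)))
    return out


class TrialValidationError(ValueError):
    pass


def validate_trials(df: pd.DataFrame, source: str = "<frame>") -> None:
    """Schema validation; every error message carries the file line number
    (header is line 1, first data row line 2)."""
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrialValidationError(
            f"{source}: missing columns {missing} (line 1)")
    extra = [c for c in df.columns if c not in TRIAL_COLUMNS]
    if extra:
        raise TrialValidationError(
            f"{source}: unexpected columns {extra} (line 1)")
    errors = []
    for i, r in enumerate(df.itertuples(index=False)):
        line = i + 2
        if r.task not in TASKS:
            errors.append(f"line {line}: bad task {r.task!r}")
        if r.condition not in CONDITIONS:
            errors.append(f"line {line}: bad condition {r.condition!r}")
        if r.trial_type not in ("go", "stop"):
            errors.append(f"line {line}: bad trial_type {r.trial_type!r}")
        if r.response not in _RESPONSES:
            errors.append(f"line {line}: bad response {r.response!r}")
        if r.trial_type == "go" and not pd.isna(r.ssd_ms):
            errors.append(f"line {line}: go trial carries ssd_ms")
        if r.trial_type == "stop" and pd.isna(r.ssd_ms):
            errors.append(f"line {line}: stop trial lacks ssd_ms")
        if r.response == "none" and not pd.isna(r.rt_ms):
            errors.append(f"line {line}: response 'none' but rt_ms present")
        if r.response != "none":
            if pd.isna(r.rt_ms):
                errors.append(f"line {line}: responded trial lacks rt_ms")
            elif not (r.rt_ms > 0):
                errors.append(f"line {line}: rt_ms must be > 0")
        if errors and len(errors) >= 20:
            errors.append("... (further errors suppressed)")
            break
    if errors:
        raise TrialValidationError(f"{source}: " + "; ".join(errors))


def write_trials(records_or_frame, path) -> None:
    df = (records_or_frame if isinstance(records_or_frame, pd.DataFrame)
          else records_to_frame(records_or_frame))
    validate_trials(df, source=str(path))
    # %.17g preserves float64 exactly, so write -> read round-trips losslessly
    df.to_csv(path, index=False, float_format="%.17g")


def read_trials(path) -> pd.DataFrame:
    """Read + validate a trial CSV; empty file with a valid header is an
    empty dataset, not an error."""
    df = pd.read_csv(
        path,
        dtype={"participant_id": str, "task": str, "condition": str,
               "trial_type": str, "stimulus": str, "response": str},
        float_precision="round_trip",
    )
    if "correct" in df.columns:
        df["correct"] = df["correct"].map(
            {True: True, False: False, "True": True, "False": False}
        ).astype("boolean")
    validate_trials(df, source=str(path))
    return df


# ---------------------------------------------------------------------------
# posterior chains + diagnostics
# ---------------------------------------------------------------------------

def save_chains(chains, prefix) -> None:
    """Serialize a PosteriorChains: ``<prefix>_chains.csv`` (long columnar:
    chain, iteration, level, subject, parameter, value on the transformed
    scale) and ``<prefix>_diagnostics.json`` (R-hat, ESS, acceptance)."""
    C, T, S, d = chains.subj.shape
    frames = []
    cc, tt, ss_, dd = np.meshgrid(np.arange(C), np.arange(T), np.arange(S),
                                  np.arange(d), indexing="ij")
    frames.append(pd.DataFrame({
        "chain": cc.ravel(), "iteration": tt.ravel(), "level": "subject",
        "subject": ss_.ravel(),
        "parameter": np.asarray(chains.param_names)[dd.ravel()],
        "value": chains.subj.ravel(),
    }))
    for level, arr in (("group_location", chains.hyper_loc),
                       ("group_scale", chains.hyper_scale)):
        cc, tt, dd = np.meshgrid(np.arange(C), np.arange(T), np.arange(d),
                                 indexing="ij")
        frames.append(pd.DataFrame({
            "chain": cc.ravel(), "iteration": tt.ravel(), "level": level,
            "subject": -1,
            "parameter": np.asarray(chains.param_names)[dd.ravel()],
            "value": arr.ravel(),
        }))
    pd.concat(frames, ignore_index=True).to_csv(
        f"{prefix}_chains.csv", index=False)
    diag = {
        "rhat": chains.rhat(),
        "ess": chains.ess(),
        "accept_rate": chains.accept_rate,
        "n_chains": chains.n_chains,
        "n_iterations": chains.n_iterations,
        "n_burn": chains.n_burn,
        "param_names": list(chains.param_names),
    }
    with open(f"{prefix}_diagnostics.json", "w") as fh:
        json.dump(diag, fh, indent=2)


# ---------------------------------------------------------------------------
# blueprint YAML
# ---------------------------------------------------------------------------

def blueprint_to_yaml(blueprint, path) -> None:
    import yaml
    d = asdict(blueprint)
    d["means"] = {f"{t}:{c}": v for (t, c), v in d["means"].items()}
    d["sds"] = {f"{t}:{c}": v for (t, c), v in d["sds"].items()}
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def blueprint_from_yaml(path):
    import yaml

    from .study import StudyBlueprint
    with open(path) as fh:
        d = yaml.safe_load(fh)
    for key in ("means", "sds"):
        d[key] = {tuple(k.split(":")): v for k, v in d[key].items()}
    return StudyBlueprint(**d)
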