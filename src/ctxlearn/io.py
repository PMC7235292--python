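"""Tab-separated table I/O and schema validation.

All tabular artifacts are TSV with header rows; floats are written at 10
significant digits.  Schemas:

trials:  participant, t, context, action, side, outcome, rt_ms,
         shape_onset_s, selection_s, outcome_onset_s
latents: participant, t, q_<ctx>_<shape> x4, p_left, p_right,
         state_value, rpe
traits:  participant + seven trait scales
fits:    participant, alpha_hat, kappa_hat, loglik_max, n_ties
roi:     volume + one column per region
motion:  volume + six rigid-body axes
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .task import Session, TaskConfig, TRAIT_SCALES

FLOAT_FMT = "%.10g"

TRIAL_COLUMNS = [
    "participant", "t", "context", "action", "side", "outcome", "rt_ms",
    "shape_onset_s", "selection_s", "outcome_onset_s",
]


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_trials(sessions: list[Session], path: str | Path) -> None:
    write_tsv(pd.concat([s.to_frame() for s in sessions]), path)


def write_latents(sessions: list[Session], path: str | Path) -> None:
    write_tsv(pd.concat([s.latents_frame() for s in sessions]), path)


def read_sessions(
    path: str | Path, config: TaskConfig
) -> list[Session]:
    """Rebuild Session objects from a trial table (no latents attached)."""
    from .task import TrialRecord

    df = read_tsv(path)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns {sorted(missing)}")
    sessions = []
    for pid, grp in df.groupby("participant", sort=False):
        grp = grp.sort_values("t")
        trials = [
            TrialRecord(
                t=int(r.t),
                context=str(r.context),
                action=str(r.action),
                side=str(r.side),
                outcome=int(r.outcome),
                rt_ms=float(r.rt_ms),
                shape_onset_s=float(r.shape_onset_s),
                selection_s=float(r.selection_s),
                outcome_onset_s=float(r.outcome_onset_s),
            )
            for r in grp.itertuples()
        ]
        sessions.append(
            Session(participant=str(pid), config=config, trials=trials)
        )
    return sessions


def write_traits(traits: pd.DataFrame, path: str | Path) -> None:
    write_tsv(traits.reset_index(), path)


def read_traits(path: str | Path) -> pd.DataFrame:
    return read_tsv(path).set_index("participant")


def write_roi_timeseries(
    bold: np.ndarray, regions: tuple[str, ...], path: str | Path
) -> None:
    df = pd.DataFrame(bold, columns=list(regions))
    df.insert(0, "volume", np.arange(len(df)))
    write_tsv(df, path)


def read_roi_timeseries(path: str | Path) -> pd.DataFrame:
    return read_tsv(path).set_index("volume")


def write_motion(motion: np.ndarray, path: str | Path) -> None:
    from .glm import MOTION_LABELS

    df = pd.DataFrame(motion, columns=list(MOTION_LABELS))
    df.insert(0, "volume", np.arange(len(df)))
    write_tsv(df, path)


# ---------------------------------------------------------------------------
# Validation (reports, never raises)
# ---------------------------------------------------------------------------

def validate_trial_table(df: pd.DataFrame) -> list[str]:
    problems = []
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        return [f"missing columns: {sorted(missing)}"]
    for row in df.itertuples():
        line = row.Index + 2  # header + 1-based data line
        if row.outcome not in (0, 1):
            problems.append(f"line {line}: outcome {row.outcome!r} not in {{0, 1}}")
        if not (
            row.shape_onset_s < row.selection_s <= row.outcome_onset_s
        ):
            problems.append(
                f"line {line}: onsets not strictly increasing "
                f"({row.shape_onset_s}, {row.selection_s}, "
                f"{row.outcome_onset_s})"
            )
        if row.selection_s - row.shape_onset_s > 3.0 + 1e-9:
            problems.append(
                f"line {line}: selection later than the 3 s response window"
            )
        if not 0 < row.rt_ms <= 3000:
            problems.append(f"line {line}: rt_ms {row.rt_ms} outside (0, 3000]")
    return problems


def validate_latent_table(df: pd.DataFrame) -> list[str]:
    problems = []
    if not {"p_left", "p_right", "rpe"}.issubset(df.columns):
        return ["missing latent columns (p_left, p_right, rpe)"]
    bad = np.flatnonzero(
        np.abs(df["p_left"] + df["p_right"] - 1.0) > 1e-6
    )
    for i in bad:
        problems.append(f"line {i + 2}: choice probabilities do not sum to 1")
    return problems


def validate_trait_table(df: pd.DataFrame) -> list[str]:
    problems = []
    if "participant" not in df.columns:
        problems.append("missing participant column")
    for scale in TRAIT_SCALES:
        if scale not in df.columns:
            problems.append(f"missing trait column {scale!r}")
        elif not np.issubdtype(df[scale].dtype, np.number):
            problems.append(f"trait column {scale!r} is not numeric")
    return problems


def validate_numeric_table(
    df: pd.DataFrame, expected_cols: int | None = None, name: str = "table"
) -> list[str]:
    problems = []
    value_cols = [c for c in df.columns if c != "volume"]
    if expected_cols is not None and len(value_cols) != expected_cols:
        problems.append(
            f"{name}: expected {expected_cols} value columns, "
            f"found {len(value_cols)}"
        )
    for c in value_cols:
        if not np.issubdtype(df[c].dtype, np.number):
            problems.append(f"{name}: column {c!r} is not numeric")
    return problems
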