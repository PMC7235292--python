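"""Event-related GLM on ROI-mean BOLD time series.

The first-level model follows standard model-based fMRI practice: five
stick-function conditions (pain outcome, no-pain outcome, shape onset in
context A, shape onset in context B, shape selection), parametric
modulators (aversive prediction error on the two outcome conditions, state
value on the selection condition, mean-centered within condition before
convolution), six motion nuisance regressors and an intercept.  Sticks are
placed on a 0.1 s microtime grid, convolved with a canonical double-gamma
HRF, and sampled at volume acquisition times (TR = 3 s, 252 volumes by
default).  Estimation is ordinary least squares on the ROI-mean series;
the headline contrast is pain minus no-pain.

A synthetic BOLD generator (design x known betas + AR(1) noise) gives every
estimate a ground truth for recovery and calibration tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import DegenerateDataError, StatResult, paired_t
from .task import LatentTrajectory, Session

CONDITION_ORDER = (
    "outcome_pain",
    "outcome_nopain",
    "shape_A",
    "shape_B",
    "selection",
)
MODULATOR_PARENT = {
    "rpe_pain": "outcome_pain",
    "rpe_nopain": "outcome_nopain",
    "state_value": "selection",
}
MOTION_LABELS = ("mot_x", "mot_y", "mot_z", "mot_roll", "mot_pitch", "mot_yaw")


class DesignError(ValueError):
    """Raised for event/design inconsistencies (onsets, rank, lengths)."""


@dataclass(frozen=True)
class ScanTimeline:
    """Scan timing: TR, number of volumes, and the microtime resolution."""

    tr_s: float = 3.0
    n_volumes: int = 252
    microtime_dt_s: float = 0.1

    def __post_init__(self) -> None:
        if self.tr_s <= 0 or self.n_volumes <= 0:
            raise DesignError("tr_s and n_volumes must be positive")
        ratio = self.tr_s / self.microtime_dt_s
        if abs(ratio - round(ratio)) > 1e-9:
            raise DesignError("microtime_dt_s must divide tr_s")

    @property
    def duration_s(self) -> float:
        return self.tr_s * self.n_volumes

    @property
    def n_microtime(self) -> int:
        return int(round(self.duration_s / self.microtime_dt_s))

    @property
    def volume_micro_indices(self) -> np.ndarray:
        step = int(round(self.tr_s / self.microtime_dt_s))
        return np.arange(self.n_volumes) * step

    def micro_index(self, onset_s: float) -> int:
        if onset_s < 0 or onset_s >= self.duration_s:
            raise DesignError(
                f"onset {onset_s} s outside scan [0, {self.duration_s}) s"
            )
        return int(round(onset_s / self.microtime_dt_s))


@dataclass(frozen=True)
class HRFSpec:
    """Canonical double-gamma hemodynamic response function.

    Peak at ~6 s, undershoot at ~16 s, peak:undershoot ratio 6, 32 s
    kernel, unit peak amplitude.
    """

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_dispersion_s: float = 1.0
    undershoot_dispersion_s: float = 1.0
    peak_undershoot_ratio: float = 6.0
    length_s: float = 32.0

    def kernel(self, dt_s: float) -> np.ndarray:
        if self.length_s < 32.0:
            raise DesignError("HRF kernel must cover at least 32 s")
        t = np.arange(0.0, self.length_s, dt_s)
        peak = sps.gamma.pdf(
            t,
            a=self.peak_delay_s / self.peak_dispersion_s,
            scale=self.peak_dispersion_s,
        )
        under = sps.gamma.pdf(
            t,
            a=self.undershoot_delay_s / self.undershoot_dispersion_s,
            scale=self.undershoot_dispersion_s,
        )
        h = peak - under / self.peak_undershoot_ratio
        if h.sum() <= 0:
            raise DesignError("HRF kernel must integrate to a positive value")
        return h / h.max()


@dataclass
class EventSet:
    """Five stick-event streams plus parametric-modulator values.

    ``events`` maps condition name -> onset array (seconds); ``modulators``
    maps modulator name -> value array aligned with its parent condition's
    onsets.  Empty condition streams are permitted and flagged.
    """

    events: dict[str, np.ndarray]
    modulators: dict[str, np.ndarray]
    empty_conditions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, parent in MODULATOR_PARENT.items():
            if name in self.modulators:
                if len(self.modulators[name]) != len(
                    self.events.get(parent, ())
                ):
                    raise DesignError(
                        f"modulator {name!r} length does not match its "
                        f"parent condition {parent!r}"
                    )


def events_from_session(
    session: Session, latents: LatentTrajectory | None = None
) -> EventSet:
    """Build the five-condition event set from a session.

    RPE values attach to the outcome events and state values to the
    selection events.  Uses the session's stored latents unless an
    explicitly extracted trajectory is supplied.
    """
    latents = latents if latents is not None else session.latents
    if latents is None:
        raise DesignError("session has no latent trajectory attached")
    if len(latents) != len(session.trials):
        raise DesignError("latents are not aligned with the session")
    pain_on, nopain_on, rpe_pain, rpe_nopain = [], [], [], []
    shape_a, shape_b, select_on, values = [], [], [], []
    for i, tr in enumerate(session.trials):
        if tr.outcome == 1:
            pain_on.append(tr.outcome_onset_s)
            rpe_pain.append(latents.RPE[i])
        else:
            nopain_on.append(tr.outcome_onset_s)
            rpe_nopain.append(latents.RPE[i])
        (shape_a if tr.context == "A" else shape_b).append(tr.shape_onset_s)
        select_on.append(tr.selection_s)
        values.append(latents.V[i])
    events = {
        "outcome_pain": np.asarray(pain_on),
        "outcome_nopain": np.asarray(nopain_on),
        "shape_A": np.asarray(shape_a),
        "shape_B": np.asarray(shape_b),
        "selection": np.asarray(select_on),
    }
    empty = [c for c in CONDITION_ORDER if events[c].size == 0]
    if empty:
        warnings.warn(
            f"empty event stream(s): {empty}", RuntimeWarning, stacklevel=2
        )
    return EventSet(
        events=events,
        modulators={
            "rpe_pain": np.asarray(rpe_pain),
            "rpe_nopain": np.asarray(rpe_nopain),
            "state_value": np.asarray(values),
        },
        empty_conditions=empty,
    )


@dataclass
class DesignMatrix:
    matrix: np.ndarray  # (n_volumes, n_regressors)
    labels: list[str]
    dropped: list[str]
    timeline: ScanTimeline

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.labels)

    def column(self, label: str) -> np.ndarray:
        return self.matrix[:, self.labels.index(label)]


def _stick_column(
    onsets: np.ndarray,
    heights: np.ndarray | None,
    timeline: ScanTimeline,
    kernel: np.ndarray,
) -> np.ndarray:
    micro = np.zeros(timeline.n_microtime)
    h = np.ones(len(onsets)) if heights is None else heights
    for onset, height in zip(onsets, h):
        micro[timeline.micro_index(float(onset))] += height
    conv = np.convolve(micro, kernel)[: timeline.n_microtime]
    return conv[timeline.volume_micro_indices]


def build_design(
    events: EventSet,
    timeline: ScanTimeline | None = None,
    hrf: HRFSpec | None = None,
    motion: np.ndarray | None = None,
    merge_rpe: bool = False,
) -> DesignMatrix:
    """HRF-convolved design matrix on the volume grid.

    Condition sticks are unit height; modulator sticks carry the
    mean-centered modulator values (centering within condition, before
    convolution).  ``merge_rpe=True`` collapses the two RPE modulators into
    a single column spanning both outcome conditions.  Empty conditions and
    all-zero modulators are dropped and recorded.
    """
    timeline = timeline or ScanTimeline()
    hrf = hrf or HRFSpec()
    kernel = hrf.kernel(timeline.microtime_dt_s)
    columns, labels, dropped = [], [], []

    for cond in CONDITION_ORDER:
        onsets = events.events[cond]
        if onsets.size == 0:
            dropped.append(cond)
            continue
        columns.append(_stick_column(onsets, None, timeline, kernel))
        labels.append(cond)

    mod_items: list[tuple[str, np.ndarray, np.ndarray]] = []
    if merge_rpe:
        onsets = np.concatenate(
            [events.events["outcome_pain"], events.events["outcome_nopain"]]
        )
        vals = np.concatenate(
            [
                events.modulators.get("rpe_pain", np.empty(0)),
                events.modulators.get("rpe_nopain", np.empty(0)),
            ]
        )
        mod_items.append(("rpe", onsets, vals))
    else:
        for name in ("rpe_pain", "rpe_nopain"):
            if name in events.modulators:
                mod_items.append(
                    (name, events.events[MODULATOR_PARENT[name]],
                     events.modulators[name])
                )
    if "state_value" in events.modulators:
        mod_items.append(
            ("state_value", events.events["selection"],
             events.modulators["state_value"])
        )
    for name, onsets, vals in mod_items:
        if onsets.size == 0:
            dropped.append(name)
            continue
        centered = vals - vals.mean()
        if np.allclose(centered, 0.0):
            warnings.warn(
                f"modulator {name!r} has no variance after centering; "
                "column dropped",
                RuntimeWarning,
                stacklevel=2,
            )
            dropped.append(name)
            continue
        columns.append(_stick_column(onsets, centered, timeline, kernel))
        labels.append(name)

    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape != (timeline.n_volumes, 6):
            raise DesignError(
                f"motion must be (n_volumes, 6); got {motion.shape}"
            )
        for j, lab in enumerate(MOTION_LABELS):
            columns.append(motion[:, j])
            labels.append(lab)

    columns.append(np.ones(timeline.n_volumes))
    labels.append("intercept")
    return DesignMatrix(
        matrix=np.column_stack(columns),
        labels=labels,
        dropped=dropped,
        timeline=timeline,
    )


# ---------------------------------------------------------------------------
# Synthetic BOLD and estimation
# ---------------------------------------------------------------------------

def ar1_noise(
    n: int, sigma: float, rho: float, rng: np.random.Generator
) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation sigma."""
    if sigma < 0:
        raise DesignError("noise sigma must be >= 0")
    if not -1 < rho < 1:
        raise DesignError("AR(1) rho must lie in (-1, 1)")
    if sigma == 0:
        return np.zeros(n)
    e = np.empty(n)
    e[0] = sigma * rng.standard_normal()
    innov_sd = sigma * np.sqrt(1.0 - rho**2)
    w = innov_sd * rng.standard_normal(n - 1)
    for t in range(1, n):
        e[t] = rho * e[t - 1] + w[t - 1]
    return e


def simulate_roi_bold(
    design: DesignMatrix,
    true_betas: np.ndarray,
    sigma: float = 1.0,
    rho: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """y = X beta + AR(1) noise, reproducible by seed."""
    X = design.matrix
    beta = np.asarray(true_betas, dtype=float)
    if beta.shape != (X.shape[1],):
        raise DesignError(
            f"true_betas length {beta.shape} does not match "
            f"{X.shape[1]} regressors"
        )
    rng = np.random.default_rng(seed)
    return X @ beta + ar1_noise(X.shape[0], sigma, rho, rng)


@dataclass
class GlmFit:
    betas: pd.Series
    residual_variance: float
    df_resid: int
    contrast: float | None
    labels: list[str]
    residuals: np.ndarray

    def beta(self, label: str) -> float:
        return float(self.betas[label])


def fit_glm(ts: np.ndarray, design: DesignMatrix) -> GlmFit:
    """Ordinary least-squares fit of one ROI series on the design.

    Raises a rank-deficiency error naming the collinear columns.  The
    contrast is beta(pain) - beta(no-pain) when both conditions are
    present.
    """
    y = np.asarray(ts, dtype=float)
    X = design.matrix
    if y.shape != (X.shape[0],):
        raise DesignError(
            f"time series length {y.shape} does not match "
            f"{X.shape[0]} volumes"
        )
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    bad = [design.labels[i] for i in np.flatnonzero(diag < tol)]
    if bad:
        raise DesignError(f"design is rank deficient; collinear: {bad}")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = X.shape[0] - X.shape[1]
    contrast = None
    if "outcome_pain" in design.labels and "outcome_nopain" in design.labels:
        contrast = float(
            beta[design.labels.index("outcome_pain")]
            - beta[design.labels.index("outcome_nopain")]
        )
    return GlmFit(
        betas=pd.Series(beta, index=design.labels),
        residual_variance=float(resid @ resid / df) if df > 0 else np.nan,
        df_resid=df,
        contrast=contrast,
        labels=list(design.labels),
        residuals=resid,
    )


def group_level(values) -> StatResult:
    """One-sample t-test of per-participant estimates against zero."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("group test needs at least 2 participants")
    if np.allclose(v.std(ddof=1), 0.0):
        raise DegenerateDataError("group values have zero variance")
    t, p = sps.ttest_1samp(v, 0.0)
    return StatResult(
        statistic=float(t),
        df=v.size - 1,
        pvalue=float(p),
        test="one-sample-t-vs-0",
    )


def motion_summary(
    motion: np.ndarray,
    session: Session,
    timeline: ScanTimeline | None = None,
    phase_s: float = 3.0,
) -> dict[str, object]:
    """Compare head motion between pain and no-pain outcome phases.

    For each outcome event, volumes within ``phase_s`` of the onset form
    the outcome phase.  The per-metric aggregate is the mean absolute value
    over phase volumes, giving six pain and six no-pain values that are
    compared with a paired t-test across metrics.
    """
    timeline = timeline or ScanTimeline()
    motion = np.asarray(motion, dtype=float)
    if motion.shape != (timeline.n_volumes, 6):
        raise DesignError(
            f"motion must be (n_volumes, 6); got {motion.shape}"
        )
    vol_times = np.arange(timeline.n_volumes) * timeline.tr_s
    masks = {"pain": np.zeros(timeline.n_volumes, bool),
             "nopain": np.zeros(timeline.n_volumes, bool)}
    for tr in session.trials:
        key = "pain" if tr.outcome == 1 else "nopain"
        masks[key] |= (vol_times >= tr.outcome_onset_s) & (
            vol_times < tr.outcome_onset_s + phase_s
        )
    agg = {
        key: np.abs(motion[mask]).mean(axis=0)
        if mask.any()
        else np.zeros(6)
        for key, mask in masks.items()
    }
    d = agg["pain"] - agg["nopain"]
    if np.allclose(d, 0.0):
        result = StatResult(
            statistic=0.0, df=5, pvalue=1.0, test="paired-t (motion phases)"
        )
    else:
        result = paired_t(agg["pain"], agg["nopain"])
    return {"pain": agg["pain"], "nopain": agg["nopain"], "test": result}


def simulate_motion(
    timeline: ScanTimeline,
    sd_mm: float = 0.1,
    rho: float = 0.95,
    seed: int | None = None,
) -> np.ndarray:
    """Slowly drifting AR(1) motion traces for the six rigid-body axes."""
    rng = np.random.default_rng(seed)
    return np.column_stack(
        [ar1_noise(timeline.n_volumes, sd_mm, rho, rng) for _ in range(6)]
    )
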