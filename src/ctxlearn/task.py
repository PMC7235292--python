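"""Generative model of the contextual avoidance-learning task.

Two shapes (square, rhombus) are shown against one of two background
pictures (contexts A and B).  Choosing a shape triggers a painful outcome
with a probability that depends on both the shape and the context.  A
Q-learning agent with learning rate ``alpha`` and subjective painfulness
``kappa`` (kappa <= 0, pain mapped to negative return) chooses between the
shapes via a softmax over the action values of whatever is currently on the
left and right of the screen.

This module is the pipeline's synthetic-data source: it simulates single
sessions with recorded ground-truth latent trajectories, whole cohorts with
trait scores, and reaction times, all reproducibly seeded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

CONTEXTS = ("A", "B")
SHAPES = ("square", "rhombus")
SIDES = ("L", "R")

#: Trait scales of the 7-factor temperament/character inventory.
TRAIT_SCALES = (
    "novelty_seeking",
    "harm_avoidance",
    "reward_dependence",
    "persistence",
    "self_directedness",
    "cooperativeness",
    "self_transcendence",
)


class ConfigurationError(ValueError):
    """Raised when a task or simulation configuration is inconsistent."""


def default_contingency() -> dict[tuple[str, str], float]:
    """Context-reversed shape->pain mapping (the package default).

    In context A the rhombus is the high-risk shape (80% pain) and the
    square low-risk (20%); in context B the roles are swapped, so the
    background picture is informative.
    """
    return {
        ("A", "rhombus"): 0.8,
        ("A", "square"): 0.2,
        ("B", "square"): 0.8,
        ("B", "rhombus"): 0.2,
    }


def printed_contingency() -> dict[tuple[str, str], float]:
    """Alternative mapping with identical shape roles in both contexts
    (rhombus 80%, square 20% under either picture), in which the context
    carries no information about the contingency."""
    return {
        ("A", "rhombus"): 0.8,
        ("A", "square"): 0.2,
        ("B", "rhombus"): 0.8,
        ("B", "square"): 0.2,
    }


@dataclass(frozen=True)
class TaskConfig:
    """Structure and timing of one scanning session of the task.

    Defaults describe the 60-trial session (30 trials per context) that
    tiles a 756 s scan: each 12.6 s trial shows the shapes for up to 3 s,
    a fixation grid for 6 s, and the outcome at +9.0 s from trial onset.
    """

    n_trials: int = 60
    contexts: tuple[str, ...] = CONTEXTS
    actions: tuple[str, ...] = SHAPES
    contingency: Mapping[tuple[str, str], float] = field(
        default_factory=default_contingency
    )
    context_balance: Mapping[str, int] = field(
        default_factory=lambda: {"A": 30, "B": 30}
    )
    trial_length_s: float = 12.6
    shape_onset_offset_s: float = 0.0
    shape_duration_s: float = 3.0
    fixation_duration_s: float = 6.0
    outcome_onset_offset_s: float = 9.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ConfigurationError("n_trials must be >= 1")
        if set(self.context_balance) != set(self.contexts):
            raise ConfigurationError(
                "context_balance keys must match contexts"
            )
        if sum(self.context_balance.values()) != self.n_trials:
            raise ConfigurationError(
                f"context counts {dict(self.context_balance)} do not sum to "
                f"n_trials={self.n_trials}"
            )
        for ctx in self.contexts:
            for shape in self.actions:
                p = self.contingency.get((ctx, shape))
                if p is None:
                    raise ConfigurationError(
                        f"contingency missing entry for ({ctx}, {shape})"
                    )
                if not 0.0 <= p <= 1.0:
                    raise ConfigurationError(
                        f"pain probability {p} for ({ctx}, {shape}) "
                        "outside [0, 1]"
                    )
        if self.outcome_onset_offset_s < (
            self.shape_duration_s + self.fixation_duration_s
        ):
            raise ConfigurationError(
                "outcome onset must follow shape presentation and fixation"
            )

    @property
    def duration_s(self) -> float:
        return self.n_trials * self.trial_length_s

    def low_risk_shape(self, context: str) -> str:
        """Shape with the lower pain probability in ``context``."""
        return min(self.actions, key=lambda a: self.contingency[(context, a)])

    def high_risk_shape(self, context: str) -> str:
        return max(self.actions, key=lambda a: self.contingency[(context, a)])


@dataclass(frozen=True)
class AgentParams:
    """Q-learning agent parameters.

    alpha : learning rate in (0, 1].
    kappa : subjective painfulness, the (negative) return delivered by a
        painful outcome; kappa <= 0.
    """

    alpha: float
    kappa: float

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ConfigurationError(f"alpha={self.alpha} outside (0, 1]")
        if self.kappa > 0.0:
            raise ConfigurationError(f"kappa={self.kappa} must be <= 0")


@dataclass(frozen=True)
class TrialRecord:
    t: int  # 1-based trial index
    context: str
    action: str  # chosen shape
    side: str  # screen side of the chosen shape, "L" or "R"
    outcome: int  # 1 = painful stimulus delivered
    rt_ms: float
    shape_onset_s: float
    selection_s: float
    outcome_onset_s: float


@dataclass
class LatentTrajectory:
    """Per-trial latent series of the Q-learning model.

    ``Q`` holds the pre-update action-value table of each trial (trial x
    context x shape); ``P`` the (left, right) softmax probabilities; ``V``
    the state value of the current context; ``RPE`` the aversive prediction
    error kappa*R - Q(s, a) of the chosen action.
    """

    Q: np.ndarray  # (T, n_contexts, n_shapes)
    V: np.ndarray  # (T,)
    P: np.ndarray  # (T, 2) probabilities for (left, right)
    RPE: np.ndarray  # (T,)

    def __len__(self) -> int:
        return len(self.RPE)


@dataclass
class Session:
    participant: str
    config: TaskConfig
    trials: list[TrialRecord]
    latents: LatentTrajectory | None = None
    true_params: AgentParams | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.trials) != self.config.n_trials:
            raise ConfigurationError(
                f"{len(self.trials)} trials recorded but config declares "
                f"{self.config.n_trials}"
            )
        counts = {c: 0 for c in self.config.contexts}
        for tr in self.trials:
            if tr.context not in counts:
                raise ConfigurationError(
                    f"unknown context label {tr.context!r}"
                )
            counts[tr.context] += 1
        if counts != dict(self.config.context_balance):
            raise ConfigurationError(
                f"context counts {counts} do not match balance "
                f"{dict(self.config.context_balance)}"
            )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "participant": self.participant,
                "t": tr.t,
                "context": tr.context,
                "action": tr.action,
                "side": tr.side,
                "outcome": tr.outcome,
                "rt_ms": tr.rt_ms,
                "shape_onset_s": tr.shape_onset_s,
                "selection_s": tr.selection_s,
                "outcome_onset_s": tr.outcome_onset_s,
            }
            for tr in self.trials
        ]
        return pd.DataFrame(rows)

    def latents_frame(self) -> pd.DataFrame:
        if self.latents is None:
            raise ValueError("session carries no latent trajectory")
        lat = self.latents
        cols: dict[str, np.ndarray] = {
            "participant": np.repeat(self.participant, len(lat)),
            "t": np.arange(1, len(lat) + 1),
        }
        for ci, ctx in enumerate(self.config.contexts):
            for si, shape in enumerate(self.config.actions):
                cols[f"q_{ctx}_{shape}"] = lat.Q[:, ci, si]
        cols["p_left"] = lat.P[:, 0]
        cols["p_right"] = lat.P[:, 1]
        cols["state_value"] = lat.V
        cols["rpe"] = lat.RPE
        return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# Core model primitives (shared by the generative and inference sides)
# ---------------------------------------------------------------------------

def q_update(
    q: float, outcome: int, params: AgentParams
) -> tuple[float, float]:
    """Delta-rule update of one action value.

    Returns ``(q_new, rpe)`` with ``rpe = kappa*R - q`` and
    ``q_new = q + alpha*rpe``.
    """
    rpe = params.kappa * outcome - q
    return q + params.alpha * rpe, rpe


def choice_prob(q_left: float, q_right: float) -> float:
    """Softmax probability of choosing the shape on the left."""
    m = max(q_left, q_right)
    el = math.exp(q_left - m)
    er = math.exp(q_right - m)
    return el / (el + er)


def state_value(
    q_pair: Sequence[float],
    probs: Sequence[float],
    as_printed: bool = False,
) -> float:
    """Choice-probability-weighted state value.

    Default: sum_a P(a|s) Q(s,a).  ``as_printed=True`` selects the variant
    in which the left-choice probability multiplies both action values.
    """
    if as_printed:
        return probs[0] * q_pair[0] + probs[0] * q_pair[1]
    return probs[0] * q_pair[0] + probs[1] * q_pair[1]


# ---------------------------------------------------------------------------
# Schedules and simulation
# ---------------------------------------------------------------------------

def make_schedule(
    config: TaskConfig, seed: int | np.random.Generator | None
) -> list[tuple[str, str]]:
    """Randomized per-trial (context, left-shape) assignments.

    Context order is a seeded shuffle honouring ``context_balance`` exactly;
    the shape shown on the left is randomized independently per trial.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    contexts = np.repeat(
        list(config.context_balance.keys()),
        list(config.context_balance.values()),
    )
    rng.shuffle(contexts)
    left = rng.integers(0, 2, size=config.n_trials)
    return [
        (str(contexts[i]), config.actions[left[i]])
        for i in range(config.n_trials)
    ]


@dataclass(frozen=True)
class RTModel:
    """Log-normal reaction-time generator truncated to (0, max_ms].

    ``base_ms`` is the median RT; ``sigma_log`` the log-scale spread;
    ``prob_effect_ms`` is added when the chosen shape is the high-risk one,
    ``context_effect_ms`` when the context is the second one in the config.
    """

    base_ms: float = 1100.0
    sigma_log: float = 0.3
    prob_effect_ms: float = 0.0
    context_effect_ms: float = 0.0
    max_ms: float = 3000.0

    def sample(
        self, rng: np.random.Generator, high_risk: bool, context_idx: int
    ) -> float:
        rt = self.base_ms * math.exp(self.sigma_log * rng.standard_normal())
        if high_risk:
            rt += self.prob_effect_ms
        if context_idx == 1:
            rt += self.context_effect_ms
        return float(min(max(rt, 1.0), self.max_ms))


def simulate_session(
    config: TaskConfig,
    params: AgentParams,
    seed: int | None,
    participant: str = "sim",
    rt_model: RTModel | None = None,
    force_action: str | None = None,
) -> Session:
    """Run the Q-learning agent through one session of the task.

    Q is initialized at 0 for every (context, shape) pair, so the first
    choice in each context is uninformative (P = 0.5).  ``force_action``
    overrides the softmax policy with a fixed shape (used for forced-choice
    probes of the outcome contingencies).  The ground-truth latent
    trajectory and generating parameters are stored on the session.
    """
    rng = np.random.default_rng(seed)
    rt_model = rt_model or RTModel()
    schedule = make_schedule(config, rng)
    ctx_idx = {c: i for i, c in enumerate(config.contexts)}
    shp_idx = {s: i for i, s in enumerate(config.actions)}
    n_ctx, n_shp = len(config.contexts), len(config.actions)
    T = config.n_trials

    q = np.zeros((n_ctx, n_shp))
    Q = np.zeros((T, n_ctx, n_shp))
    V = np.zeros(T)
    P = np.zeros((T, 2))
    RPE = np.zeros(T)
    trials: list[TrialRecord] = []

    for i, (ctx, left_shape) in enumerate(schedule):
        ci = ctx_idx[ctx]
        right_shape = (
            config.actions[1 - shp_idx[left_shape]]
        )
        qL = q[ci, shp_idx[left_shape]]
        qR = q[ci, shp_idx[right_shape]]
        pL = choice_prob(qL, qR)
        pR = 1.0 - pL
        if force_action is not None:
            action = force_action
            side = "L" if left_shape == force_action else "R"
        else:
            chose_left = rng.random() < pL
            side = "L" if chose_left else "R"
            action = left_shape if chose_left else right_shape
        ai = shp_idx[action]
        outcome = int(rng.random() < config.contingency[(ctx, action)])

        Q[i] = q
        P[i] = (pL, pR)
        V[i] = state_value((qL, qR), (pL, pR))
        q_new, rpe = q_update(q[ci, ai], outcome, params)
        RPE[i] = rpe
        q[ci, ai] = q_new

        high_risk = action == config.high_risk_shape(ctx)
        rt = rt_model.sample(rng, high_risk, ci)
        start = i * config.trial_length_s
        shape_onset = start + config.shape_onset_offset_s
        trials.append(
            TrialRecord(
                t=i + 1,
                context=ctx,
                action=action,
                side=side,
                outcome=outcome,
                rt_ms=rt,
                shape_onset_s=shape_onset,
                selection_s=shape_onset + rt / 1000.0,
                outcome_onset_s=start + config.outcome_onset_offset_s,
            )
        )

    return Session(
        participant=participant,
        config=config,
        trials=trials,
        latents=LatentTrajectory(Q=Q, V=V, P=P, RPE=RPE),
        true_params=params,
        seed=seed,
    )


def simulate_rt(
    session: Session, rt_model: RTModel, seed: int | None
) -> Session:
    """Refill reaction times (and selection events) from an RT model."""
    rng = np.random.default_rng(seed)
    cfg = session.config
    ctx_idx = {c: i for i, c in enumerate(cfg.contexts)}
    new_trials = []
    for tr in session.trials:
        high_risk = tr.action == cfg.high_risk_shape(tr.context)
        rt = rt_model.sample(rng, high_risk, ctx_idx[tr.context])
        new_trials.append(
            replace(
                tr,
                rt_ms=rt,
                selection_s=tr.shape_onset_s + rt / 1000.0,
            )
        )
    return replace(session, trials=new_trials)


@dataclass(frozen=True)
class ParamSampler:
    """Population distribution of agent parameters for cohort simulation.

    Truncated normal draws: alpha on (0, 1], kappa on [-10, 0].  Defaults
    put the population near a moderate learning rate and a clearly aversive
    but not extreme subjective painfulness.
    """

    alpha_mean: float = 0.3
    alpha_sd: float = 0.15
    kappa_mean: float = -3.0
    kappa_sd: float = 1.5

    def sample(self, rng: np.random.Generator) -> AgentParams:
        while True:
            a = self.alpha_mean + self.alpha_sd * rng.standard_normal()
            if 0.01 <= a <= 1.0:
                break
        while True:
            k = self.kappa_mean + self.kappa_sd * rng.standard_normal()
            if -10.0 <= k <= 0.0:
                break
        return AgentParams(alpha=float(a), kappa=float(k))


@dataclass(frozen=True)
class TraitModel:
    """Linear map from a subject-level signal to seven trait scores.

    ``trait = intercept + coefficient * signal + N(0, noise_sd)`` per scale.
    ``signal`` names the subject-level quantity driving the traits:
    "neg_kappa" (painfulness magnitude, the default), "alpha", or "kappa".
    Default coefficients are all zero (null coupling).
    """

    coefficients: Mapping[str, float] = field(
        default_factory=lambda: {s: 0.0 for s in TRAIT_SCALES}
    )
    intercepts: Mapping[str, float] = field(
        default_factory=lambda: {s: 50.0 for s in TRAIT_SCALES}
    )
    noise_sd: float = 10.0
    signal: str = "neg_kappa"

    def signal_value(self, params: AgentParams) -> float:
        if self.signal == "neg_kappa":
            return -params.kappa
        if self.signal == "kappa":
            return params.kappa
        if self.signal == "alpha":
            return params.alpha
        raise ConfigurationError(f"unknown trait signal {self.signal!r}")

    def sample(
        self, params: AgentParams, rng: np.random.Generator
    ) -> dict[str, float]:
        x = self.signal_value(params)
        return {
            s: self.intercepts.get(s, 0.0)
            + self.coefficients.get(s, 0.0) * x
            + self.noise_sd * rng.standard_normal()
            for s in TRAIT_SCALES
        }


def simulate_cohort(
    n_subjects: int = 19,
    config: TaskConfig | None = None,
    param_sampler: ParamSampler | None = None,
    trait_model: TraitModel | None = None,
    rt_model: RTModel | None = None,
    seed: int | None = None,
    participant_fmt: str = "sub-{:02d}",
) -> tuple[list[Session], pd.DataFrame]:
    """Simulate a cohort of sessions plus a subjects x 7 trait table."""
    if n_subjects < 1:
        raise ConfigurationError("n_subjects must be >= 1")
    config = config or TaskConfig()
    param_sampler = param_sampler or ParamSampler()
    trait_model = trait_model or TraitModel()
    master = np.random.default_rng(seed)
    sessions: list[Session] = []
    trait_rows: list[dict[str, object]] = []
    for i in range(n_subjects):
        pid = participant_fmt.format(i + 1)
        params = param_sampler.sample(master)
        sess_seed = int(master.integers(0, 2**31 - 1))
        sess = simulate_session(
            config, params, sess_seed, participant=pid, rt_model=rt_model
        )
        sessions.append(sess)
        row: dict[str, object] = {"participant": pid}
        row.update(trait_model.sample(params, master))
        trait_rows.append(row)
    traits = pd.DataFrame(trait_rows).set_index("participant")
    return sessions, traits
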