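"""Effective-connectivity model selection over a four-node network.

Nodes are the left/right habenula and left/right hippocampus.  Candidate
models differ in (a) which task inputs (background images, pain outcomes,
state values, aversive prediction errors) drive which region pair and
(b) the inter-regional connection pattern.  Selection proceeds in two
stages: Process 1 chooses inputs and input regions under full
connectivity (24 candidates); Process 2 chooses the connection pattern
with the winning inputs fixed.

The forward model is deliberately simple and fully testable: linear
neural dynamics dz/dt = A z + C u integrated on the microtime grid with
the exact exponential propagator, a canonical-HRF observation stage, and
additive white noise.  Candidate scoring fits the free connection and
input weights by least squares (separable: input weights solve linearly
given connection weights) and approximates log model evidence by
-BIC / 2; posterior model probabilities follow from a uniform prior.
Hemispheric symmetry ties each weight to its left/right mirror image.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.linalg import expm, schur
from scipy.optimize import least_squares
from scipy.signal import lfilter

from .glm import HRFSpec, ScanTimeline
from .task import LatentTrajectory, Session

NODES = ("lHb", "rHb", "lHC", "rHC")
MIRROR = (1, 0, 3, 2)  # left/right homologue of each node
INPUTS = ("images", "pain", "state_value", "ape")
HB_PAIR = (0, 1)
HC_PAIR = (2, 3)

#: per-region SSE floor (mean square) so that exactly-fitting nested
#: models are ranked by the parameter-count penalty, not optimizer
#: round-off
SSE_FLOOR_PER_VOLUME = 1e-8


class StabilityError(ValueError):
    """Raised when a connection matrix has non-decaying dynamics."""


# ---------------------------------------------------------------------------
# Inputs
# ---------------------------------------------------------------------------

def build_input_timecourses(
    session: Session,
    latents: LatentTrajectory | None = None,
    timeline: ScanTimeline | None = None,
) -> dict[str, np.ndarray]:
    """Candidate input streams on the microtime grid.

    images: unit stick at every shape/background onset; pain: unit stick at
    painful outcomes; state_value: V_t sticks at selection; ape: RPE_t
    sticks at every outcome.
    """
    timeline = timeline or ScanTimeline()
    latents = latents if latents is not None else session.latents
    if latents is None or len(latents) != len(session.trials):
        raise ValueError("session needs an aligned latent trajectory")
    n = timeline.n_microtime
    streams = {name: np.zeros(n) for name in INPUTS}
    for i, tr in enumerate(session.trials):
        streams["images"][timeline.micro_index(tr.shape_onset_s)] += 1.0
        if tr.outcome == 1:
            streams["pain"][timeline.micro_index(tr.outcome_onset_s)] += 1.0
        streams["state_value"][
            timeline.micro_index(tr.selection_s)
        ] += latents.V[i]
        streams["ape"][
            timeline.micro_index(tr.outcome_onset_s)
        ] += latents.RPE[i]
    return streams


# ---------------------------------------------------------------------------
# Model structures
# ---------------------------------------------------------------------------

def _mirror_classes(
    pairs: list[tuple[int, int]], mirror_second: bool = True
) -> list[tuple[tuple[int, int], ...]]:
    """Group index pairs into left/right mirror-equivalence classes."""
    seen: set[tuple[int, int]] = set()
    classes = []
    for p in sorted(pairs):
        if p in seen:
            continue
        q = (MIRROR[p[0]], MIRROR[p[1]] if mirror_second else p[1])
        cls = tuple(sorted({p, q}))
        seen.update(cls)
        classes.append(cls)
    return classes


@dataclass
class NetworkModel:
    """One candidate network: connection mask, input mask, optional weights.

    ``a_mask[i, j]`` allows an influence of node j on node i (off-diagonal
    only; self-connections are a fixed negative decay).  ``c_mask[i, k]``
    allows input k to drive node i.  Under the symmetry flag (the default)
    homologous left/right weights are tied.
    """

    name: str
    a_mask: np.ndarray  # (4, 4) bool, off-diagonal
    c_mask: np.ndarray  # (4, n_inputs) bool
    input_names: tuple[str, ...] = INPUTS
    symmetric: bool = True
    self_decay: float = -1.0
    A: np.ndarray | None = None
    C: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.a_mask = np.asarray(self.a_mask, dtype=bool)
        self.c_mask = np.asarray(self.c_mask, dtype=bool)
        if self.a_mask.shape != (4, 4) or np.any(np.diag(self.a_mask)):
            raise ValueError("a_mask must be 4x4 with empty diagonal")
        if self.c_mask.shape != (4, len(self.input_names)):
            raise ValueError("c_mask shape must be (4, n_inputs)")
        if self.self_decay >= 0:
            raise StabilityError("self-connections must be strictly negative")

    def a_classes(self) -> list[tuple[tuple[int, int], ...]]:
        pairs = [tuple(p) for p in np.argwhere(self.a_mask)]
        if not self.symmetric:
            return [(p,) for p in sorted(pairs)]
        return _mirror_classes(pairs)

    def c_classes(self) -> list[tuple[tuple[int, int], ...]]:
        pairs = [tuple(p) for p in np.argwhere(self.c_mask)]
        if not self.symmetric:
            return [(p,) for p in sorted(pairs)]
        return _mirror_classes(pairs, mirror_second=False)

    @property
    def n_free_weights(self) -> int:
        return len(self.a_classes()) + len(self.c_classes())

    def build_A(self, class_weights: np.ndarray) -> np.ndarray:
        A = np.diag(np.full(4, self.self_decay))
        for w, cls in zip(class_weights, self.a_classes(), strict=True):
            for i, j in cls:
                A[i, j] = w
        return A

    def build_C(self, class_weights: np.ndarray) -> np.ndarray:
        C = np.zeros((4, len(self.input_names)))
        for w, cls in zip(class_weights, self.c_classes(), strict=True):
            for i, k in cls:
                C[i, k] = w
        return C

    def with_weights(
        self, a_weights, c_weights
    ) -> "NetworkModel":
        A = self.build_A(np.asarray(a_weights, dtype=float))
        C = self.build_C(np.asarray(c_weights, dtype=float))
        if not _is_stable(A):
            raise StabilityError(f"model {self.name!r} is unstable")
        return replace(self, A=A, C=C)


def _is_stable(A: np.ndarray, margin: float = 1e-9) -> bool:
    return bool(np.max(np.linalg.eigvals(A).real) < -margin)


@dataclass
class ModelSpace:
    process: int
    models: list[NetworkModel]
    recipe: str


_TARGETS = {"HC": HC_PAIR, "Hb": HB_PAIR, "both": HB_PAIR + HC_PAIR}
_BUNDLE_OPTIONAL = ("pain", "state_value", "ape")


def _bundle_name(bundle: tuple[str, ...]) -> str:
    short = {"images": "img", "pain": "pain", "state_value": "sv",
             "ape": "ape"}
    return "+".join(short[b] for b in bundle)


def enumerate_process1(
    input_names: tuple[str, ...] = INPUTS,
) -> ModelSpace:
    """24 fully-connected candidates: 8 input bundles x 3 target options.

    Bundles always include the background-image stream plus any subset of
    {pain, state_value, ape}; targets are the hippocampus pair, the
    habenula pair, or both pairs.
    """
    models = []
    full_a = ~np.eye(4, dtype=bool)
    for r in range(len(_BUNDLE_OPTIONAL) + 1):
        for extra in itertools.combinations(_BUNDLE_OPTIONAL, r):
            bundle = ("images",) + extra
            for target, nodes in _TARGETS.items():
                c_mask = np.zeros((4, len(input_names)), dtype=bool)
                for inp in bundle:
                    c_mask[list(nodes), input_names.index(inp)] = True
                models.append(
                    NetworkModel(
                        name=f"p1|{_bundle_name(bundle)}|{target}",
                        a_mask=full_a.copy(),
                        c_mask=c_mask,
                        input_names=input_names,
                    )
                )
    return ModelSpace(
        process=1,
        models=models,
        recipe="8 bundles (images + subsets of pain/state_value/ape) "
        "x targets (HC, Hb, both), fully connected",
    )


_P2_EDGES = {
    "hc_to_hb": [(0, 2), (0, 3), (1, 2), (1, 3)],
    "hb_to_hc": [(2, 0), (2, 1), (3, 0), (3, 1)],
    "inter": [(0, 1), (1, 0), (2, 3), (3, 2)],
}
_P2_PATTERNS = ("none", "hc_to_hb", "hb_to_hc", "bidirectional")


def enumerate_process2(winner: NetworkModel) -> ModelSpace:
    """Connection-pattern candidates sharing the Process-1 winner's inputs.

    Patterns: no inter-regional coupling, HC->Hb, Hb->HC, or bidirectional,
    each with or without interhemispheric (within-pair) links; all
    hemispherically symmetric.
    """
    models = []
    for pattern in _P2_PATTERNS:
        for inter in (False, True):
            edges: list[tuple[int, int]] = []
            if pattern in ("hc_to_hb", "bidirectional"):
                edges += _P2_EDGES["hc_to_hb"]
            if pattern in ("hb_to_hc", "bidirectional"):
                edges += _P2_EDGES["hb_to_hc"]
            if inter:
                edges += _P2_EDGES["inter"]
            a_mask = np.zeros((4, 4), dtype=bool)
            for i, j in edges:
                a_mask[i, j] = True
            suffix = "+inter" if inter else ""
            models.append(
                NetworkModel(
                    name=f"p2|{pattern}{suffix}",
                    a_mask=a_mask,
                    c_mask=winner.c_mask.copy(),
                    input_names=winner.input_names,
                    symmetric=True,
                    self_decay=winner.self_decay,
                )
            )
    return ModelSpace(
        process=2,
        models=models,
        recipe="patterns (none, hc_to_hb, hb_to_hc, bidirectional) x "
        "(+/- interhemispheric), inputs fixed to Process-1 winner",
    )


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

def _integrate_batch(
    A: np.ndarray, forcings: np.ndarray, dt: float
) -> np.ndarray:
    """Batched exponential-propagator integration.

    Solves z[k+1] = e^(A dt) z[k] + dt * s[k] for a batch of forcings of
    shape (m, n_steps, d).  The propagator is triangularized once with a
    complex Schur decomposition (valid for defective A, e.g. purely
    feedforward coupling), and the recursion is solved row by row from the
    bottom with one linear filter per Schur mode across the whole batch.
    """
    d = A.shape[0]
    T, Qmat = schur(np.asarray(A, dtype=complex), output="complex")
    R = np.triu(expm(T * dt))
    # (m, n, d) in Schur coordinates, scaled by the stick weight dt
    f = dt * (forcings @ Qmat.conj())
    y = np.empty_like(f)
    for i in range(d - 1, -1, -1):
        g = f[..., i]
        for j in range(i + 1, d):
            g = g + R[i, j] * y[..., j]
        y[..., i] = lfilter([0.0, 1.0], [1.0, -R[i, i]], g, axis=-1)
    return (y @ Qmat.T).real


def _integrate_batch_sampled(
    A: np.ndarray, forcings: np.ndarray, dt: float, sample_idx: np.ndarray
) -> np.ndarray:
    """Like :func:`_integrate_batch` but returns states only at the given
    time indices (the output rotation is applied after subsampling)."""
    d = A.shape[0]
    T, Qmat = schur(np.asarray(A, dtype=complex), output="complex")
    R = np.triu(expm(T * dt))
    f = dt * (forcings @ Qmat.conj())
    y = np.empty_like(f)
    for i in range(d - 1, -1, -1):
        g = f[..., i]
        for j in range(i + 1, d):
            g = g + R[i, j] * y[..., j]
        y[..., i] = lfilter([0.0, 1.0], [1.0, -R[i, i]], g, axis=-1)
    return (y[:, sample_idx, :] @ Qmat.T).real


def integrate_linear(
    A: np.ndarray, forcing: np.ndarray, dt: float
) -> np.ndarray:
    """Discrete solution of dz/dt = A z + s with stick (impulse) forcing.

    Exact exponential propagator: z[k+1] = e^(A dt) z[k] + dt * s[k], so a
    unit stick reproduces the analytic impulse response at grid points.
    ``forcing`` is (n_steps, n_nodes); returns z of the same shape.
    """
    return _integrate_batch(A, forcing[None], dt)[0]


def _hrf_convolve(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    return np.convolve(x, kernel)[: x.shape[0]]


def simulate_network(
    model: NetworkModel,
    inputs: dict[str, np.ndarray],
    timeline: ScanTimeline | None = None,
    hrf: HRFSpec | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Noisy 4-region BOLD from a weighted network model.

    Integrates the neural states on the microtime grid, convolves each
    node with the canonical HRF, samples at volume times, and adds white
    Gaussian noise.
    """
    if model.A is None or model.C is None:
        raise ValueError("model carries no weights; call with_weights first")
    if not _is_stable(model.A):
        raise StabilityError(f"model {model.name!r} is unstable")
    timeline = timeline or ScanTimeline()
    hrf = hrf or HRFSpec()
    U = np.column_stack([inputs[name] for name in model.input_names])
    forcing = U @ model.C.T  # (n_micro, 4)
    z = integrate_linear(model.A, forcing, timeline.microtime_dt_s)
    kernel = hrf.kernel(timeline.microtime_dt_s)
    bold = np.column_stack(
        [_hrf_convolve(z[:, i], kernel) for i in range(4)]
    )[timeline.volume_micro_indices]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        bold = bold + noise_sd * rng.standard_normal(bold.shape)
    return bold


# ---------------------------------------------------------------------------
# Scoring and selection
# ---------------------------------------------------------------------------

@dataclass
class ModelScore:
    name: str
    log_evidence: float
    sse: np.ndarray  # per-region
    k: int
    a_weights: np.ndarray
    c_weights: np.ndarray


def _convolved_inputs(
    inputs: dict[str, np.ndarray],
    timeline: ScanTimeline,
    hrf: HRFSpec,
) -> dict[str, np.ndarray]:
    kernel = hrf.kernel(timeline.microtime_dt_s)
    return {k: _hrf_convolve(v, kernel) for k, v in inputs.items()}


def score_model(
    ts: np.ndarray,
    model: NetworkModel,
    inputs: dict[str, np.ndarray],
    timeline: ScanTimeline | None = None,
    hrf: HRFSpec | None = None,
    conv_inputs: dict[str, np.ndarray] | None = None,
    max_nfev: int = 40,
) -> ModelScore:
    """Approximate log evidence (-BIC/2) of one candidate on 4-region data.

    Free weights are fitted by least squares.  Because both the
    discrete-time dynamics and the HRF stage are linear time-invariant,
    inputs are HRF-convolved up front; given the inter-regional weights
    the input weights then solve linearly, leaving a small nonlinear
    search over the connection weights only.
    """
    timeline = timeline or ScanTimeline()
    hrf = hrf or HRFSpec()
    y = np.asarray(ts, dtype=float)
    if y.shape != (timeline.n_volumes, 4):
        raise ValueError(
            f"time series must be (n_volumes, 4); got {y.shape}"
        )
    if conv_inputs is None:
        conv_inputs = _convolved_inputs(inputs, timeline, hrf)
    a_classes = model.a_classes()
    c_classes = model.c_classes()
    dt = timeline.microtime_dt_s
    vol_idx = timeline.volume_micro_indices
    n_micro = timeline.n_microtime

    bases_forcing = np.zeros((len(c_classes), n_micro, 4))
    for b, cls in enumerate(c_classes):
        for node, k in cls:
            bases_forcing[b, :, node] += conv_inputs[model.input_names[k]]
    y_flat = y.ravel(order="F")

    def design_for(theta_a: np.ndarray) -> np.ndarray | None:
        A = model.build_A(theta_a)
        if not _is_stable(A, margin=1e-6):
            return None
        if not len(bases_forcing):
            return np.zeros((y_flat.size, 0))
        z = _integrate_batch_sampled(A, bases_forcing, dt, vol_idx)
        return np.stack([zb.ravel(order="F") for zb in z], axis=1)

    def solve_c(B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if B.shape[1] == 0:
            return np.empty(0), y_flat.copy()
        theta_c, _, _, _ = np.linalg.lstsq(B, y_flat, rcond=None)
        return theta_c, y_flat - B @ theta_c

    def residuals(theta_a: np.ndarray) -> np.ndarray:
        B = design_for(theta_a)
        if B is None:  # unstable: large flat penalty steers the search back
            return np.full(y_flat.size, 1e3)
        _, r = solve_c(B)
        return r

    if a_classes:
        sol = least_squares(
            residuals,
            x0=np.zeros(len(a_classes)),
            bounds=(-1.5, 1.5),
            xtol=1e-9,
            ftol=1e-9,
            gtol=1e-9,
            max_nfev=max_nfev,
        )
        theta_a = sol.x
    else:
        theta_a = np.empty(0)
    B = design_for(theta_a)
    if B is None:
        raise StabilityError(
            f"fitted weights for {model.name!r} are unstable"
        )
    theta_c, resid = solve_c(B)
    n = timeline.n_volumes
    sse = np.maximum(
        (resid.reshape(n, 4, order="F") ** 2).sum(axis=0),
        n * SSE_FLOOR_PER_VOLUME,
    )
    k = len(a_classes) + len(c_classes)
    log_ev = -0.5 * (float(np.sum(n * np.log(sse / n))) + k * np.log(n))
    return ModelScore(
        name=model.name,
        log_evidence=log_ev,
        sse=sse,
        k=k,
        a_weights=theta_a,
        c_weights=theta_c,
    )


def score_space(
    ts: np.ndarray,
    space: ModelSpace,
    inputs: dict[str, np.ndarray],
    timeline: ScanTimeline | None = None,
    hrf: HRFSpec | None = None,
) -> pd.DataFrame:
    """Evidence table for a whole model space (one row per candidate)."""
    timeline = timeline or ScanTimeline()
    hrf = hrf or HRFSpec()
    conv = _convolved_inputs(inputs, timeline, hrf)
    scores = [
        score_model(ts, m, inputs, timeline, hrf, conv_inputs=conv)
        for m in space.models
    ]
    ev = np.array([s.log_evidence for s in scores])
    table = pd.DataFrame(
        {
            "model": [s.name for s in scores],
            "log_evidence": ev,
            "rel_log_evidence": ev - ev.max(),
            "posterior": posterior_probabilities(ev),
            "k": [s.k for s in scores],
        }
    )
    table.attrs["process"] = space.process
    return table


def posterior_probabilities(log_evidence: np.ndarray) -> np.ndarray:
    """Posterior model probabilities under a uniform prior."""
    le = np.asarray(log_evidence, dtype=float)
    w = np.exp(le - le.max())
    return w / w.sum()


def select_model(
    table: pd.DataFrame, tie_tol: float = 1e-9
) -> tuple[str, pd.DataFrame]:
    """Best model (max posterior) plus the table; ties recorded in attrs."""
    if len(table) < 2:
        raise ValueError("model selection needs at least 2 candidates")
    best_ev = table["log_evidence"].max()
    ties = table.index[table["log_evidence"] >= best_ev - tie_tol]
    best = str(table.loc[ties[0], "model"])
    out = table.copy()
    out.attrs["n_ties"] = int(len(ties))
    out.attrs["best"] = best
    return best, out


# ---------------------------------------------------------------------------
# Ground-truth construction and model recovery
# ---------------------------------------------------------------------------

#: the reported winning structure: images/pain/state-value inputs to the
#: hippocampus pair, hippocampus->habenula connections, no
#: interhemispheric links
TRUE_BUNDLE = ("images", "pain", "state_value")
TRUE_P1_NAME = "p1|img+pain+sv|HC"
TRUE_P2_NAME = "p2|hc_to_hb"


def true_network(
    c_weight: float = 0.4,
    sv_weight: float = 0.2,
    ipsi_weight: float = 0.35,
    contra_weight: float = 0.2,
) -> NetworkModel:
    """Weighted generating model used in recovery experiments.

    Hippocampus receives image, pain and state-value inputs; positive
    hippocampus->habenula couplings (ipsilateral and crossed), matching
    the selected structure with a positive HC->Hb weight.
    """
    a_mask = np.zeros((4, 4), dtype=bool)
    for i, j in _P2_EDGES["hc_to_hb"]:
        a_mask[i, j] = True
    c_mask = np.zeros((4, len(INPUTS)), dtype=bool)
    for inp in TRUE_BUNDLE:
        c_mask[list(HC_PAIR), INPUTS.index(inp)] = True
    model = NetworkModel(
        name="true|hc_inputs|hc_to_hb", a_mask=a_mask, c_mask=c_mask
    )
    a_w = []
    for cls in model.a_classes():
        i, j = cls[0]
        a_w.append(ipsi_weight if (i % 2) == (j % 2) else contra_weight)
    c_w = []
    for cls in model.c_classes():
        _, k = cls[0]
        c_w.append(sv_weight if INPUTS[k] == "state_value" else c_weight)
    return model.with_weights(a_w, c_w)


def two_process_selection(
    ts: np.ndarray,
    inputs: dict[str, np.ndarray],
    timeline: ScanTimeline | None = None,
    hrf: HRFSpec | None = None,
) -> dict[str, object]:
    """Run Process 1 then Process 2 on one 4-region data set."""
    space1 = enumerate_process1()
    table1 = score_space(ts, space1, inputs, timeline, hrf)
    best1, table1 = select_model(table1)
    winner1 = next(m for m in space1.models if m.name == best1)
    space2 = enumerate_process2(winner1)
    table2 = score_space(ts, space2, inputs, timeline, hrf)
    best2, table2 = select_model(table2)
    return {
        "p1_winner": best1,
        "p2_winner": best2,
        "p1_table": table1,
        "p2_table": table2,
    }


def recovery_experiment(
    n_runs: int = 50,
    noise: float | str = "snr1",
    seed: int | None = None,
    timeline: ScanTimeline | None = None,
    hrf: HRFSpec | None = None,
    config=None,
    agent_params=None,
) -> pd.DataFrame:
    """Selection-frequency table over repeated simulate-and-select runs.

    Data are generated from the winning structure (``true_network``) on
    behavior simulated from a moderate Q-learning agent.  ``noise`` is a
    white-noise standard deviation, or "snr1" to match the noiseless BOLD
    standard deviation (SNR of about 1).
    """
    from .task import AgentParams, TaskConfig, simulate_session

    timeline = timeline or ScanTimeline()
    hrf = hrf or HRFSpec()
    config = config or TaskConfig()
    agent_params = agent_params or AgentParams(alpha=0.3, kappa=-3.0)
    truth = true_network()
    ss = np.random.SeedSequence(seed)
    rows = []
    for run, child in enumerate(ss.spawn(n_runs)):
        rng = np.random.default_rng(child)
        sess_seed = int(rng.integers(0, 2**31 - 1))
        session = simulate_session(
            config, agent_params, sess_seed, participant=f"run-{run}"
        )
        inputs = build_input_timecourses(session, timeline=timeline)
        clean = simulate_network(truth, inputs, timeline, hrf, noise_sd=0.0)
        if noise == "snr1":
            sd = float(clean.std())
        else:
            sd = float(noise)
        bold = clean + sd * rng.standard_normal(clean.shape) if sd > 0 else clean
        sel = two_process_selection(bold, inputs, timeline, hrf)
        rows.append(
            {
                "run": run,
                "noise_sd": sd,
                "p1_winner": sel["p1_winner"],
                "p2_winner": sel["p2_winner"],
                "p1_correct": sel["p1_winner"] == TRUE_P1_NAME,
                "p2_correct": sel["p2_winner"] == TRUE_P2_NAME,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["p1_accuracy"] = float(out["p1_correct"].mean())
    out.attrs["p2_accuracy"] = float(out["p2_correct"].mean())
    out.attrs["p2_modal_winner"] = out["p2_winner"].mode().iloc[0]
    return out
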