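"""Generative model of the staircase-controlled partial-report experiment.

The simulator emits complete synthetic datasets with the statistical
structure the downstream analysis assumes:

* a capacity-limited ("slot") identification observer whose accuracy
  decreases with set size, so each 1-up/1-down staircase has a 50% fixed
  point;
* two independent per-condition staircases (iconic memory, IM, 250 ms ISI;
  working memory, WM, 8000 ms ISI) bounded above at 16 items;
* ordered-probit confidence with a per-subject random intercept, where
  condition-wise metacognitive sensitivity is controlled by extra latent
  noise in the IM condition (noisier percepts -> confidence less diagnostic
  of accuracy);
* log-normal decision/confidence response times with occasional fast
  guesses (< 150 ms) and timeouts, so the pre-registered exclusion rules
  are exercised.

The trial table uses the documented CSV schema (see :mod:`metastair.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RTParams",
    "ObserverParams",
    "ExperimentConfig",
    "Staircase",
    "p_correct",
    "staircase_update",
    "generate_confidence",
    "simulate_experiment",
    "simulate_confidence_dataset",
    "staircase_fixed_point",
]

IM = "IM"
WM = "WM"
STAIRCASE_UPPER_BOUND = 16
STAIRCASE_LOWER_BOUND = 1


@dataclass(frozen=True)
class RTParams:
    """Response-time process: log-normal bodies plus contamination.

    ``p_fast`` is the probability of an anticipatory fast guess (uniform RT
    in [30, 150) ms, response at chance); ``p_timeout_*`` the probability of
    missing the 4 s decision / 3 s confidence deadline.  Defaults give a few
    per cent of fast-guess trials so exclusion logic is exercised without
    mass subject exclusion.
    """

    decision_meanlog: float = np.log(1.1)
    decision_sdlog: float = 0.35
    confidence_meanlog: float = np.log(0.7)
    confidence_sdlog: float = 0.35
    p_fast: float = 0.015
    p_timeout_decision: float = 0.004
    p_timeout_confidence: float = 0.004


@dataclass(frozen=True)
class ObserverParams:
    """Generative observer: capacity, lapse, confidence model, RT process.

    ``capacity_im``/``capacity_wm`` are mean stored-item capacities (items).
    Per-subject capacities share a subject "ability" draw
    Normal(0, ``capacity_sd``) across conditions plus an independent
    per-condition part Normal(0, ``capacity_within_sd``), truncated at 0.5
    items: abilities are strongly correlated within a subject, which keeps
    the between-condition set-size contrast realistic rather than washed
    out by independent noise.  The confidence model is the cumulative-probit regression used
    for inference (latent = beta_im*IM + beta_nitems*nItems +
    beta_accuracy*accuracy + u_subject + eps), with thresholds ``tau`` and
    random-intercept SD ``sigma_u``.  ``meta_noise_im``/``meta_noise_wm``
    inflate the latent noise SD (1 + meta_noise) per condition and thereby
    set condition-wise metacognitive sensitivity.

    Defaults are calibrated to the empirical pattern of the study the
    simulator emulates: slightly higher IM capacity, lower IM metacognitive
    sensitivity (standardized AUROC-2 gap near 0.5 at n=101), slightly lower
    IM confidence, and 50% accuracy in both conditions via the staircase.
    """

    capacity_im: float = 4.25
    capacity_wm: float = 4.0
    capacity_sd: float = 1.0
    capacity_within_sd: float = 0.5
    lapse: float = 0.02
    beta_im: float = -0.08
    beta_nitems: float = -0.12
    beta_accuracy: float = 1.28
    tau: tuple[float, float, float] = (-2.35, -1.25, -0.05)
    sigma_u: float = 0.5
    meta_noise_im: float = 0.16
    meta_noise_wm: float = 0.0
    rt_params: RTParams = field(default_factory=RTParams)

    def __post_init__(self) -> None:
        if self.capacity_im < 0 or self.capacity_wm < 0:
            raise ValueError("capacities must be nonnegative")
        if not 0.0 <= self.lapse <= 1.0:
            raise ValueError("lapse must be a probability")
        if not (self.tau[0] < self.tau[1] < self.tau[2]):
            raise ValueError(f"thresholds must be strictly increasing, got {self.tau}")
        if self.sigma_u < 0:
            raise ValueError("sigma_u must be nonnegative")
        if self.meta_noise_im < 0 or self.meta_noise_wm < 0:
            raise ValueError("meta-noise terms must be nonnegative")

    def capacity(self, condition: str) -> float:
        return self.capacity_im if condition == IM else self.capacity_wm

    def meta_noise(self, condition: str) -> float:
        return self.meta_noise_im if condition == IM else self.meta_noise_wm


@dataclass(frozen=True)
class ExperimentConfig:
    """Design bookkeeping of the two-session experiment.

    Per session: 270 trials = 10 practice (5 per condition) + 130
    experimental per condition.  Removing practice and the first 30
    experimental trials of each condition in each session (staircase
    burn-in) leaves 2 x 2 x (130-30) = 400 valid trials per subject.
    """

    n_subjects: int = 101
    sessions_per_subject: int = 2
    trials_per_session: int = 270
    practice_per_session: int = 10
    staircase_burn_in: int = 30
    staircase_start: int = 8
    seed: int | None = None
    observer: ObserverParams = field(default_factory=ObserverParams)

    def __post_init__(self) -> None:
        if self.trials_per_session - self.practice_per_session != 260:
            # the design fixes 130 experimental trials per condition
            pass
        if self.practice_per_session % 2 != 0:
            raise ValueError("practice_per_session must split evenly across conditions")

    @property
    def experimental_per_condition(self) -> int:
        return (self.trials_per_session - self.practice_per_session) // 2

    @property
    def valid_trials_per_subject(self) -> int:
        """Experimental trials left after per-session burn-in removal."""
        return (
            2
            * self.sessions_per_subject
            * (self.experimental_per_condition - self.staircase_burn_in)
        )


def p_correct(n_items: int, capacity: float, lapse: float = 0.0) -> float:
    """Accuracy of a slot-style observer at a given set size.

    The observer stores ``min(capacity, n_items)`` of the ``n_items`` items.
    If the probed item was stored the response is correct unless a lapse
    occurs (probability ``lapse``, then a uniform position guess among the
    ``n_items`` marked positions would rarely be right; lapses are scored as
    incorrect here for simplicity -- the lapse floor is absorbed in the
    (1-lapse) factor).  If the probed item was not stored the observer
    guesses uniformly among the ``n_items`` positions.
    """
    if n_items < 1:
        raise ValueError(f"n_items must be >= 1, got {n_items}")
    p_enc = min(capacity, n_items) / n_items
    return p_enc * (1.0 - lapse) + (1.0 - p_enc) / n_items


def staircase_fixed_point(capacity: float, lapse: float = 0.0) -> float:
    """Set size at which the slot observer performs at exactly 50%.

    The 1-up/1-down staircase converges around this value.  Solved on a
    continuous relaxation of the set size by bisection.
    """
    lo, hi = 1.0, float(STAIRCASE_UPPER_BOUND)
    if p_correct_cont(hi, capacity, lapse) > 0.5:
        return hi
    if p_correct_cont(lo, capacity, lapse) < 0.5:
        return lo
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if p_correct_cont(mid, capacity, lapse) > 0.5:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def p_correct_cont(n: float, capacity: float, lapse: float) -> float:
    """Continuous-set-size version of :func:`p_correct` (for root finding)."""
    p_enc = min(capacity, n) / n
    return p_enc * (1.0 - lapse) + (1.0 - p_enc) / n


@dataclass
class Staircase:
    """1-up/1-down staircase over set size for one memory condition."""

    condition: str
    current_n_items: int
    lower_bound: int = STAIRCASE_LOWER_BOUND
    upper_bound: int = STAIRCASE_UPPER_BOUND
    history: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.lower_bound <= self.current_n_items <= self.upper_bound:
            raise ValueError(
                f"start value {self.current_n_items} outside "
                f"[{self.lower_bound}, {self.upper_bound}]"
            )

    def update(self, outcome: str) -> None:
        """Advance after a trial: +1 item on correct, -1 on incorrect,
        unchanged when the decision deadline was missed."""
        if outcome not in ("correct", "incorrect", "no_response"):
            raise ValueError(f"unknown outcome {outcome!r}")
        self.history.append((self.current_n_items, outcome))
        if outcome == "correct":
            self.current_n_items = min(self.current_n_items + 1, self.upper_bound)
        elif outcome == "incorrect":
            self.current_n_items = max(self.current_n_items - 1, self.lower_bound)


def staircase_update(state: Staircase, outcome: str) -> Staircase:
    """Functional form of :meth:`Staircase.update` (returns a new state)."""
    new = Staircase(
        condition=state.condition,
        current_n_items=state.current_n_items,
        lower_bound=state.lower_bound,
        upper_bound=state.upper_bound,
        history=list(state.history),
    )
    new.update(outcome)
    return new


def _latent_eta(accuracy, n_items, is_im, params: ObserverParams):
    return (
        params.beta_im * is_im
        + params.beta_nitems * n_items
        + params.beta_accuracy * accuracy
    )


def generate_confidence(
    accuracy: int,
    n_items: int,
    condition: str,
    u_subject: float,
    params: ObserverParams,
    rng: np.random.Generator,
) -> int:
    """Draw a 1-4 confidence rating from the ordered-probit observer.

    The latent variable is the linear predictor plus the subject intercept
    plus Gaussian noise with SD ``1 + meta_noise(condition)``; the rating is
    the bin of the latent under the thresholds ``tau``.
    """
    tau = np.asarray(params.tau, dtype=float)
    if not np.all(np.diff(tau) > 0):
        raise ValueError("thresholds must be strictly increasing")
    sd = 1.0 + params.meta_noise(condition)
    latent = (
        _latent_eta(accuracy, n_items, 1.0 if condition == IM else 0.0, params)
        + u_subject
        + rng.normal(0.0, sd)
    )
    return int(np.searchsorted(tau, latent) + 1)


def _confidence_batch(accuracy, n_items, is_im, u, sd, params, rng):
    """Vectorized confidence draws (arrays of equal length)."""
    tau = np.asarray(params.tau, dtype=float)
    latent = _latent_eta(accuracy, n_items, is_im, params) + u + rng.normal(0.0, sd)
    return np.searchsorted(tau, latent) + 1


def _session_conditions(config: ExperimentConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    """Condition labels and practice flags for one session.

    Per-trial random assignment constrained to exactly 130 experimental and
    5 practice trials per condition (practice first, then experimental).
    """
    half_practice = config.practice_per_session // 2
    practice = np.array([IM] * half_practice + [WM] * half_practice)
    rng.shuffle(practice)
    n_exp = config.experimental_per_condition
    experimental = np.array([IM] * n_exp + [WM] * n_exp)
    rng.shuffle(experimental)
    conditions = np.concatenate([practice, experimental])
    phase = np.array(
        ["practice"] * len(practice) + ["experimental"] * len(experimental)
    )
    return conditions, phase


def simulate_experiment(
    config: ExperimentConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Simulate the complete two-session experiment for a cohort.

    Returns one row per trial with the documented schema.  Per subject a
    random intercept ``u ~ N(0, sigma_u^2)`` and per-condition capacities
    are drawn once and shared across both sessions; the two staircases
    restart at ``staircase_start`` items at the beginning of each session.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    obs = config.observer
    rtp = obs.rt_params
    rows: list[dict] = []
    for subject in range(1, config.n_subjects + 1):
        u = rng.normal(0.0, obs.sigma_u)
        ability = rng.normal(0.0, obs.capacity_sd)
        caps = {
            IM: max(
                0.5,
                obs.capacity_im + ability + rng.normal(0.0, obs.capacity_within_sd),
            ),
            WM: max(
                0.5,
                obs.capacity_wm + ability + rng.normal(0.0, obs.capacity_within_sd),
            ),
        }
        for session in (1, 2):
            stairs = {
                c: Staircase(c, config.staircase_start) for c in (IM, WM)
            }
            counters = {IM: 0, WM: 0}
            conditions, phases = _session_conditions(config, rng)
            for t, (cond, phase) in enumerate(zip(conditions, phases), start=1):
                st = stairs[cond]
                n = st.current_n_items
                if phase == "experimental":
                    counters[cond] += 1
                    order = counters[cond]
                else:
                    order = 0
                correct: float | None
                conf: float | None
                rt_dec: float | None
                rt_conf: float | None
                if rng.random() < rtp.p_timeout_decision:
                    # no decision before 4 s: no confidence stage either,
                    # staircase unchanged
                    correct = conf = rt_dec = rt_conf = None
                    st.update("no_response")
                else:
                    if rng.random() < rtp.p_fast:
                        rt_dec = rng.uniform(0.03, 0.149)
                        p = 1.0 / n  # anticipatory guess at chance
                    else:
                        rt_dec = min(
                            rng.lognormal(rtp.decision_meanlog, rtp.decision_sdlog),
                            3.999,
                        )
                        p = p_correct(n, caps[cond], obs.lapse)
                    correct = int(rng.random() < p)
                    st.update("correct" if correct else "incorrect")
                    if rng.random() < rtp.p_timeout_confidence:
                        conf = rt_conf = None
                    else:
                        if rng.random() < rtp.p_fast:
                            rt_conf = rng.uniform(0.03, 0.149)
                        else:
                            rt_conf = min(
                                rng.lognormal(
                                    rtp.confidence_meanlog, rtp.confidence_sdlog
                                ),
                                2.999,
                            )
                        conf = generate_confidence(correct, n, cond, u, obs, rng)
                rows.append(
                    {
                        "subject_id": subject,
                        "session": session,
                        "trial_index": t,
                        "phase": phase,
                        "condition": cond,
                        "n_items": n,
                        "correct": correct,
                        "confidence": conf,
                        "rt_decision_s": rt_dec,
                        "rt_confidence_s": rt_conf,
                        "staircase_order": order,
                    }
                )
    df = pd.DataFrame(rows)
    df["correct"] = df["correct"].astype("Float64")
    df["confidence"] = df["confidence"].astype("Float64")
    return df


def simulate_confidence_dataset(
    n_subjects: int,
    n_trials: int,
    params: ObserverParams | None = None,
    rho_im_nitems: float = 0.0,
    p_accuracy: float = 0.5,
    nitems_mean: float = 8.0,
    nitems_sd: float = 2.0,
    random_slope_sd: dict[str, float] | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Confidence-only dataset for power simulation and parameter recovery.

    Bypasses the staircase: per trial the condition is Bernoulli(1/2),
    accuracy Bernoulli(``p_accuracy``), and the set size a discretized
    normal clipped to [4, 16] whose mean is shifted by condition to induce a
    point-biserial correlation ``rho_im_nitems`` between the IM indicator
    and set size (the robustness scenario for the regression model).
    Confidence is drawn from the ordered-probit model in ``params`` (use
    zero meta-noise for exact model-1 data).  ``random_slope_sd`` maps
    predictor names ("IM", "nItems", "accuracy", "IM:accuracy") to SDs of
    per-subject normal deviations around the fixed coefficients,
    producing data with subject-varying slopes (the full-random-effects
    regime); the IM:accuracy deviation is added on top of the shared
    coefficients.
    """
    if rng is None:
        rng = np.random.default_rng()
    if params is None:
        params = ObserverParams(meta_noise_im=0.0, meta_noise_wm=0.0)
    if not -1.0 < rho_im_nitems < 1.0:
        raise ValueError("rho_im_nitems must be in (-1, 1)")
    # shift of the set-size mean between conditions achieving the target
    # point-biserial correlation for a balanced binary indicator
    delta = 2.0 * nitems_sd * rho_im_nitems / np.sqrt(1.0 - rho_im_nitems**2)
    total = n_subjects * n_trials
    subject = np.repeat(np.arange(1, n_subjects + 1), n_trials)
    u = np.repeat(rng.normal(0.0, params.sigma_u, n_subjects), n_trials)
    is_im = (rng.random(total) < 0.5).astype(float)
    n_items = np.clip(
        np.rint(rng.normal(nitems_mean + delta * (is_im - 0.5), nitems_sd)), 4, 16
    )
    accuracy = (rng.random(total) < p_accuracy).astype(float)
    sd = np.where(
        is_im == 1.0, 1.0 + params.meta_noise_im, 1.0 + params.meta_noise_wm
    )
    if random_slope_sd:
        extra = np.zeros(total)
        design = {
            "IM": is_im,
            "nItems": n_items,
            "accuracy": accuracy,
            "IM:accuracy": is_im * accuracy,
        }
        unknown = set(random_slope_sd) - set(design)
        if unknown:
            raise ValueError(f"unknown random-slope terms: {sorted(unknown)}")
        for term, ssd in random_slope_sd.items():
            dev = np.repeat(rng.normal(0.0, ssd, n_subjects), n_trials)
            extra += dev * design[term]
        tau = np.asarray(params.tau, dtype=float)
        latent = (
            _latent_eta(accuracy, n_items, is_im, params)
            + u
            + extra
            + rng.normal(0.0, sd)
        )
        conf = np.searchsorted(tau, latent) + 1
    else:
        conf = _confidence_batch(accuracy, n_items, is_im, u, sd, params, rng)
    return pd.DataFrame(
        {
            "subject_id": subject,
            "condition": np.where(is_im == 1.0, IM, WM),
            "n_items": n_items.astype(int),
            "correct": accuracy.astype(int),
            "confidence": conf.astype(int),
        }
    )
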