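"""A Bayesian observer of stimulus timing with recursive prior updating.

The observer carries a Gaussian prediction ("prior predicted timing") of
when the next tone in a sequence will occur.  Each tone is sensed through a
Gaussian likelihood; perception is the precision-weighted fusion of
prediction and evidence, and the posterior, shifted forward by one
inter-onset interval, becomes the prediction for the next tone — a
conjugate (Kalman-style) recursion.  Prediction uncertainty grows between
tones by ``interval_sd``, the observer's running estimate of how variable
the environment's intervals are; between sequences it is updated by
exponential smoothing of the prediction-error RMS, so the prior becomes
sharp in a temporally regular environment and broad in an irregular one.

A final tone presented slightly early or late is therefore perceived
shifted toward the predicted time point: the expected perceived anisochrony
is ``w * a`` where ``a`` is the physical anisochrony and
``w = sigma_p^2 / (sigma_p^2 + sigma_s^2)`` is the sensory weight at the
final fusion.  Two response models turn percepts into 2AFC data: a
two-noisy-criteria regularity judgment, and an audiovisual temporal-order
judgment against a flash.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import TrialCondition, StimulusSequence, realize_sequence


@dataclass(frozen=True)
class ObserverParams:
    """Noise, learning, and response parameters of the observer.

    All durations in ms.  ``interval_sd`` is the per-step growth of
    prediction uncertainty — the environment-statistics parameter;
    ``env_learning_rate`` in [0, 1] smooths it toward the observed
    prediction-error RMS between sequences (0 disables learning).
    ``criterion_early``/``criterion_late`` and their sds define the
    two-noisy-criteria regularity response; ``visual_latency_sd`` is the
    sd of visual latency noise in the order judgment; ``lapse_rate`` flips
    any response with the given probability.
    """

    sensory_sd: float = 20.0
    initial_prior_sd: float = 150.0
    interval_sd: float = 30.0
    env_learning_rate: float = 0.0
    criterion_early: float = -100.0
    criterion_late: float = 100.0
    criterion_sd_early: float = 30.0
    criterion_sd_late: float = 30.0
    visual_latency_sd: float = 40.0
    lapse_rate: float = 0.02

    def __post_init__(self) -> None:
        for name in (
            "sensory_sd", "initial_prior_sd", "interval_sd",
            "criterion_sd_early", "criterion_sd_late", "visual_latency_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.criterion_early < self.criterion_late:
            raise ValueError("criterion_early must be < criterion_late")
        if not 0.0 <= self.lapse_rate <= 0.5:
            raise ValueError("lapse_rate must be in [0, 0.5]")
        if not 0.0 <= self.env_learning_rate <= 1.0:
            raise ValueError("env_learning_rate must be in [0, 1]")

    def replace(self, **kwargs) -> "ObserverParams":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class BeliefState:
    """The observer's evolving prediction of the next tone onset."""

    predicted_onset_mean: float
    predicted_onset_sd: float
    ioi_estimate: float
    trials_seen: int = 0


def init_belief(
    first_onset: float,
    params: ObserverParams,
    ioi_estimate: float = 700.0,
) -> BeliefState:
    """Prediction for the second tone: one interval after the first."""
    return BeliefState(
        predicted_onset_mean=first_onset + ioi_estimate,
        predicted_onset_sd=params.initial_prior_sd,
        ioi_estimate=ioi_estimate,
        trials_seen=0,
    )


def fuse(
    state: BeliefState, observed_onset: float, params: ObserverParams
) -> tuple[float, float]:
    """Precision-weighted fusion of prediction and sensory evidence.

    Returns the perceived onset (posterior mean) and the posterior sd.
    Degenerate widths are honoured: a zero-sd prior pins perception to the
    prediction, a zero-sd likelihood to the observation.
    """
    sp, ss = state.predicted_onset_sd, params.sensory_sd
    if sp == 0.0 and ss == 0.0:
        raise ValueError("prior and likelihood cannot both have zero width")
    if sp == 0.0:
        return state.predicted_onset_mean, 0.0
    if ss == 0.0:
        return observed_onset, 0.0
    prec = 1.0 / sp**2 + 1.0 / ss**2
    mean = (state.predicted_onset_mean / sp**2 + observed_onset / ss**2) / prec
    return mean, prec**-0.5


def advance(
    state: BeliefState,
    posterior_mean: float,
    posterior_sd: float,
    params: ObserverParams,
    interval_sd: float | None = None,
) -> BeliefState:
    """Shift the posterior one interval forward to predict the next tone.

    Prediction uncertainty grows by the interval variability:
    ``sd' = sqrt(posterior_sd^2 + interval_sd^2)``.
    """
    isd = params.interval_sd if interval_sd is None else interval_sd
    return BeliefState(
        predicted_onset_mean=posterior_mean + state.ioi_estimate,
        predicted_onset_sd=float(np.hypot(posterior_sd, isd)),
        ioi_estimate=state.ioi_estimate,
        trials_seen=state.trials_seen,
    )


def update_environment(
    params: ObserverParams, sequence_innovations: list[float] | np.ndarray
) -> ObserverParams:
    """Smooth ``interval_sd`` toward the RMS prediction error.

    One exponential-smoothing step on the sd scale with rate
    ``env_learning_rate``; rate 0 returns the params unchanged.
    """
    rate = params.env_learning_rate
    if rate == 0.0 or len(sequence_innovations) == 0:
        return params
    rms = float(np.sqrt(np.mean(np.square(sequence_innovations))))
    return params.replace(
        interval_sd=(1.0 - rate) * params.interval_sd + rate * rms
    )


def predicted_sd_at_final(
    params: ObserverParams, n_context_tones: int = 4
) -> float:
    """Closed-form prediction sd just before the final fusion.

    The sd recursion is deterministic (independent of the observed values):
    starting from ``initial_prior_sd``, each context tone after the first
    applies a fusion and an advance.  With four context tones the prior has
    been refined twice (tones 2–4 observed, prediction advanced to tone 5).
    """
    sd = params.initial_prior_sd
    for _ in range(n_context_tones - 1):
        _, post_sd = fuse(
            BeliefState(0.0, sd, 700.0), 0.0, params
        )
        sd = float(np.hypot(post_sd, params.interval_sd))
    return sd


def shrinkage_weight(params: ObserverParams, n_context_tones: int = 4) -> float:
    """Sensory weight w at the final fusion; E[perceived anisochrony] = w*a."""
    sp = predicted_sd_at_final(params, n_context_tones)
    ss = params.sensory_sd
    if sp == 0.0 and ss == 0.0:
        raise ValueError("prior and likelihood cannot both have zero width")
    if np.isinf(sp):
        return 1.0
    return sp**2 / (sp**2 + ss**2)


@dataclass(frozen=True)
class SequencePercept:
    """Trace of one sequence pass (internal to simulation)."""

    perceived_anisochrony: float
    perceived_onset: float
    predicted_onset_mean: float
    predicted_onset_sd: float
    innovations: tuple[float, ...]
    interval_sd_after: float


def _run_sequence(
    sequence: StimulusSequence,
    params: ObserverParams,
    rng: np.random.Generator,
    interval_sd: float | None = None,
) -> SequencePercept:
    """init/fuse/advance over the context tones, then fuse the final tone.

    Each observation is the physical onset corrupted by a sensory-noise
    draw.  ``interval_sd`` (optionally the session's running estimate) is
    held fixed within the sequence: the environment statistics have a slow
    time-course and are consolidated between sequences, not within one.
    The prediction errors of the context tones are returned as innovations
    for that between-sequence update; the final (probe) tone never
    contributes to the statistics.
    """
    onsets = sequence.tone_onsets
    if len(onsets) < 2:
        raise ValueError("sequence must have at least 2 tones")
    isd = params.interval_sd if interval_sd is None else interval_sd

    state = init_belief(onsets[0], params)
    innovations = []
    for onset in onsets[1:-1]:
        observed = onset + rng.normal(0.0, params.sensory_sd)
        innovations.append(observed - state.predicted_onset_mean)
        post_mean, post_sd = fuse(state, observed, params)
        state = advance(state, post_mean, post_sd, params, interval_sd=isd)

    observed_final = onsets[-1] + rng.normal(0.0, params.sensory_sd)
    perceived, _ = fuse(state, observed_final, params)
    return SequencePercept(
        perceived_anisochrony=perceived - state.predicted_onset_mean,
        perceived_onset=perceived,
        predicted_onset_mean=state.predicted_onset_mean,
        predicted_onset_sd=state.predicted_onset_sd,
        innovations=tuple(innovations),
        interval_sd_after=isd,
    )


def _smooth_interval_sd(
    interval_sd: float, innovations: tuple[float, ...], rate: float
) -> float:
    """One between-sequence smoothing step toward the RMS innovation."""
    if rate == 0.0 or len(innovations) == 0:
        return interval_sd
    rms = float(np.sqrt(np.mean(np.square(innovations))))
    return (1.0 - rate) * interval_sd + rate * rms


def perceive_final(
    sequence: StimulusSequence,
    params: ObserverParams,
    rng: np.random.Generator | int,
) -> tuple[float, float]:
    """Perceived anisochrony and perceived onset of the final tone.

    The perceived anisochrony is the perceived onset minus the predicted
    onset; with an informative prior its expectation shrinks toward zero
    (``w * a``), the temporal-regularisation effect.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    percept = _run_sequence(sequence, params, rng)
    return percept.perceived_anisochrony, percept.perceived_onset


def respond_regular(
    perceived_anisochrony: float,
    params: ObserverParams,
    rng: np.random.Generator,
) -> str:
    """Two-noisy-criteria judgment: 'regular' iff the sensed anisochrony
    falls between criteria drawn from two independent Gaussians."""
    c_early = rng.normal(params.criterion_early, params.criterion_sd_early)
    c_late = rng.normal(params.criterion_late, params.criterion_sd_late)
    regular = c_early <= perceived_anisochrony <= c_late
    if params.lapse_rate > 0 and rng.random() < params.lapse_rate:
        regular = not regular
    return "regular" if regular else "irregular"


def respond_toj(
    perceived_tone_onset: float,
    flash_onset: float,
    params: ObserverParams,
    rng: np.random.Generator,
) -> str:
    """Order judgment: which came first, the light or the sound?

    The flash is sensed with Gaussian latency noise; exact ties resolve as
    'light_first' (a measure-zero convention).
    """
    perceived_flash = flash_onset + rng.normal(0.0, params.visual_latency_sd)
    light_first = perceived_flash <= perceived_tone_onset
    if params.lapse_rate > 0 and rng.random() < params.lapse_rate:
        light_first = not light_first
    return "light_first" if light_first else "sound_first"


def simulate_session(
    grid: list[TrialCondition],
    params: ObserverParams,
    seed: int,
    ioi: float = 700.0,
    observer_id: str = "obs",
) -> pd.DataFrame:
    """Simulate one observer through a trial grid.

    Trials are run in grid order (shuffle beforehand for interleaving).
    The regularity task answers 'regular'/'irregular'; trials with a flash
    answer 'light_first'/'sound_first'.  ``interval_sd`` evolves across
    trials when learning is enabled.  Reproducible: a pure function of
    (grid, params, seed).
    """
    if len(grid) == 0:
        raise ValueError("grid must be non-empty")
    rng = np.random.default_rng(seed)
    isd = params.interval_sd
    rows = []
    for i, cond in enumerate(grid):
        seq = realize_sequence(cond, ioi=ioi, rng=rng)
        if cond.experiment == "practice":
            # single tone, no sequence context: flat-prior perception
            perceived_tone = seq.tone_onsets[0] + rng.normal(
                0.0, params.sensory_sd
            )
            perceived_aniso = np.nan
        else:
            percept = _run_sequence(seq, params, rng, interval_sd=isd)
            isd = _smooth_interval_sd(
                isd, percept.innovations, params.env_learning_rate
            )
            perceived_tone = percept.perceived_onset
            perceived_aniso = percept.perceived_anisochrony
        if cond.experiment == "exp1":
            response = respond_regular(perceived_aniso, params, rng)
        else:
            response = respond_toj(
                perceived_tone, seq.flash_onset, params, rng
            )
        rows.append(
            {
                "trial_id": i,
                "experiment": cond.experiment,
                "environment": cond.environment,
                "jitter_level_ms": cond.jitter_level,
                "anisochrony_ms": cond.anisochrony,
                "soa_ms": cond.soa if cond.soa is not None else np.nan,
                "repetition_index": cond.repetition_index,
                "perceived_anisochrony_ms": perceived_aniso,
                "response": response,
                "observer_id": observer_id,
                "seed": seed,
            }
        )
    return pd.DataFrame(rows)
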