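"""Synthetic Matrix-test cohorts and experiments.

The generator is the statistical twin of the fitted model: participants are
drawn from group-level distributions on constrained scales (normal auditory
threshold, log-normal width and visual threshold, logit-normal lapses), stimulus
levels are individualized by inverting each participant's own psychometric
chain (standing in for the adaptive familiarization track, which estimates the
same quantities), and word counts are binomial draws from the race-model
prediction.

Default group locations are the published group-level estimates for the
normal-hearing (NH) and cochlear-implant (CI) cohorts; default cohort sizes are
14 NH and 7 CI participants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .psychometrics import (
    UNINFORMATIVE_BLUR,
    AuditoryParams,
    GuessPolicy,
    InvalidParameterError,
    LapseSet,
    Modality,
    ParticipantParams,
    StimulusCondition,
    Task,
    Variant,
    VisualParams,
    invert_auditory,
    invert_visual,
    predict_recognition,
)

WORDS_PER_SENTENCE = 5
ALTERNATIVES_PER_WORD = 10

TRIAL_COLUMNS = [
    "participant_id",
    "cohort",
    "task",
    "modality",
    "snr_db",
    "blur_px",
    "n_words",
    "n_correct",
]


@dataclass(frozen=True)
class ParamDist:
    """Location/scale of a between-participant distribution on a transformed scale.

    ``transform`` is one of ``identity`` (normal), ``log`` (log-normal, location
    given as the median on the natural scale) or ``logit`` (logit-normal,
    location given as the median probability).
    """

    loc: float
    scale: float
    transform: str = "identity"

    def __post_init__(self) -> None:
        if self.scale < 0:
            raise InvalidParameterError(f"scale must be >= 0, got {self.scale}")
        if self.transform not in ("identity", "log", "logit"):
            raise InvalidParameterError(f"unknown transform {self.transform!r}")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.transform == "identity":
            z = self.loc + self.scale * rng.standard_normal(n)
            return z
        if self.transform == "log":
            return np.exp(np.log(self.loc) + self.scale * rng.standard_normal(n))
        return expit(logit(self.loc) + self.scale * rng.standard_normal(n))


@dataclass(frozen=True)
class GroupHyperParams:
    """Group-level distributions of the participant parameters for one cohort."""

    cohort: str
    theta_a: ParamDist
    omega: ParamDist
    theta_v: ParamDist
    lam_a_focused: ParamDist
    lam_a_divided: ParamDist
    lam_v: ParamDist

    @classmethod
    def nh_defaults(cls) -> "GroupHyperParams":
        # Published NH group means: threshold -12 dB, width 7.4 dB, visual
        # threshold 18.3 px, visual lapse 0.54; auditory lapse from the 90%
        # saturation (1 - 0.80/0.9) with a +0.039 divided-task difference.
        lam_a_foc = 1.0 - 0.80 / 0.9
        return cls(
            cohort="NH",
            theta_a=ParamDist(-12.0, 1.5),
            omega=ParamDist(7.4, 0.15, "log"),
            theta_v=ParamDist(18.3, 0.2, "log"),
            lam_a_focused=ParamDist(lam_a_foc, 0.35, "logit"),
            lam_a_divided=ParamDist(lam_a_foc + 0.039, 0.35, "logit"),
            lam_v=ParamDist(0.54, 0.35, "logit"),
        )

    @classmethod
    def ci_defaults(cls) -> "GroupHyperParams":
        # Published CI group means: threshold -3.1 dB, width 10.4 dB, visual
        # threshold 17.7 px, visual lapse 0.46; auditory lapse from the 84%
        # saturation (1 - 0.74/0.9) with a +0.22 divided-task difference.
        lam_a_foc = 1.0 - 0.74 / 0.9
        return cls(
            cohort="CI",
            theta_a=ParamDist(-3.1, 2.5),
            omega=ParamDist(10.4, 0.15, "log"),
            theta_v=ParamDist(17.7, 0.2, "log"),
            lam_a_focused=ParamDist(lam_a_foc, 0.35, "logit"),
            lam_a_divided=ParamDist(lam_a_foc + 0.22, 0.35, "logit"),
            lam_v=ParamDist(0.46, 0.35, "logit"),
        )

    def group_means(self) -> ParticipantParams:
        """Participant parameters at the group locations (no between-subject noise)."""
        return ParticipantParams(
            auditory=AuditoryParams(self.theta_a.loc, self.omega.loc),
            visual=VisualParams(self.theta_v.loc),
            lapses=LapseSet.vis_shared(
                self.lam_a_focused.loc, self.lam_a_divided.loc, self.lam_v.loc
            ),
        )


def draw_participants(
    hyper: GroupHyperParams, n: int, seed: int | np.random.Generator
) -> list[ParticipantParams]:
    """Draw ``n`` participants from the cohort's group-level distributions."""
    if n < 1:
        raise InvalidParameterError(f"need at least one participant, got {n}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    theta_a = hyper.theta_a.draw(rng, n)
    omega = hyper.omega.draw(rng, n)
    theta_v = hyper.theta_v.draw(rng, n)
    lam_af = hyper.lam_a_focused.draw(rng, n)
    lam_ad = hyper.lam_a_divided.draw(rng, n)
    lam_v = hyper.lam_v.draw(rng, n)
    return [
        ParticipantParams(
            auditory=AuditoryParams(float(theta_a[i]), float(omega[i])),
            visual=VisualParams(float(theta_v[i])),
            lapses=LapseSet.vis_shared(float(lam_af[i]), float(lam_ad[i]), float(lam_v[i])),
        )
        for i in range(n)
    ]


def individualize_levels(
    params: ParticipantParams,
    targets: list[float] | np.ndarray,
    modality: Modality | str,
    policy: GuessPolicy = GuessPolicy(),
) -> np.ndarray:
    """Stimulus levels whose predicted focused-task unisensory performance hits
    ``targets`` (post-guess proportions correct).

    Inverts the participant's own guess/lapse/psychometric chain; targets above
    the lapse-limited ceiling or below the guess floor are clipped to the
    psychometric bounds, with a warning (the adaptive track in the original
    procedure runs into the same ceiling).
    """
    targets = np.asarray(targets, dtype=float)
    if np.any((targets < 0) | (targets >= 1)):
        raise InvalidParameterError("targets must lie in [0, 1)")
    g = policy.guess_rate
    modality = Modality(modality)
    if modality is Modality.A:
        lam = params.lapses.a_focused
        levels = invert_auditory(targets, params.auditory, lam, policy)
    elif modality is Modality.V:
        lam = params.lapses.v_focused
        levels = invert_visual(targets, params.visual, lam, policy)
    else:
        raise InvalidParameterError("levels are individualized per unisensory modality")
    ceiling = g + (1.0 - g) * (1.0 - lam)
    n_clip = int(np.sum((targets <= g) | (targets >= ceiling)))
    if n_clip:
        warnings.warn(
            f"{n_clip} target(s) outside the reachable band ({g:.2f}, {ceiling:.2f}) "
            "were clipped to the psychometric floor/ceiling",
            stacklevel=2,
        )
    return levels


@dataclass(frozen=True)
class DesignConfig:
    """Knobs of the experiment designs (defaults follow the published paradigm)."""

    n_focused_auditory: int = 40        # sentences in the focused auditory block
    n_focused_visual: int = 40          # sentences in the focused visual block
    n_divided_trials: int = 100         # trials in the divided block (25 combos)
    n_auditory_levels: int = 8          # individualized SNRs, 4-12 allowed
    focused_visual_blurs: tuple[float, ...] = (0.0, 6.0, 12.0, 16.0, 20.0)
    divided_auditory_targets: tuple[float, ...] = (0.0, 0.25, 0.50, 0.75)
    divided_visual_targets: tuple[float, ...] = (0.50, 0.35, 0.25, 0.15)
    words_per_sentence: int = WORDS_PER_SENTENCE
    alternatives_per_word: int = ALTERNATIVES_PER_WORD

    def __post_init__(self) -> None:
        if not 40 <= self.n_focused_auditory <= 60:
            raise InvalidParameterError("focused blocks use 40-60 sentences")
        if not 40 <= self.n_focused_visual <= 60:
            raise InvalidParameterError("focused blocks use 40-60 sentences")
        if not 80 <= self.n_divided_trials <= 120:
            raise InvalidParameterError("divided block uses 80-120 trials")
        if not 4 <= self.n_auditory_levels <= 12:
            raise InvalidParameterError("focused auditory block uses 4-12 SNRs")
        if not 5 <= len(self.focused_visual_blurs) <= 10:
            raise InvalidParameterError("focused visual block uses 5-10 blurs")

    def focused_auditory_targets(self) -> np.ndarray:
        """Post-guess performance targets spanning floor to near-ceiling."""
        return np.linspace(0.15, 0.85, self.n_auditory_levels)


@dataclass(frozen=True)
class ExperimentDesign:
    """A realized trial list for one participant and task.

    ``trials`` has one row per sentence: sentence_id (unique within the design,
    enforcing the no-repeat rule), modality, snr_db, blur_px (NaN = absent).
    """

    task: Task
    trials: pd.DataFrame
    words_per_sentence: int = WORDS_PER_SENTENCE
    alternatives_per_word: int = ALTERNATIVES_PER_WORD

    def __post_init__(self) -> None:
        object.__setattr__(self, "task", Task(self.task))

    def condition_counts(self) -> pd.DataFrame:
        return (
            self.trials.groupby(["modality", "snr_db", "blur_px"], dropna=False)
            .size()
            .rename("n_sentences")
            .reset_index()
        )


def build_design(
    task: Task | str,
    params: ParticipantParams,
    config: DesignConfig = DesignConfig(),
    seed: int | np.random.Generator = 0,
) -> ExperimentDesign:
    """Build a pseudo-random trial list for one participant.

    Focused task: one auditory-only block over individualized SNRs followed by
    one visual-only block over the common blur set.  Divided task: a balanced
    5x5 SNR-by-blur grid whose fifth SNR is "signal absent" (visual-only rows)
    and fifth blur is the uninformative 70-pixel blur (auditory-only rows),
    interleaved in pseudo-random order.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    task = Task(task)
    rows: list[dict] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # level clipping is routine here
        if task is Task.FOCUSED:
            snrs = individualize_levels(params, config.focused_auditory_targets(), Modality.A)
            per = _balanced_counts(config.n_focused_auditory, len(snrs), rng)
            for snr, k in zip(snrs, per):
                rows += [{"modality": "A", "snr_db": float(snr), "blur_px": np.nan}] * k
            rows = list(rng.permutation(rows))
            vrows: list[dict] = []
            per = _balanced_counts(config.n_focused_visual, len(config.focused_visual_blurs), rng)
            for blur, k in zip(config.focused_visual_blurs, per):
                vrows += [{"modality": "V", "snr_db": np.nan, "blur_px": float(blur)}] * k
            rows += list(rng.permutation(vrows))
        else:
            snrs = list(
                individualize_levels(params, config.divided_auditory_targets, Modality.A)
            ) + [np.nan]
            blurs = list(
                individualize_levels(params, config.divided_visual_targets, Modality.V)
            ) + [UNINFORMATIVE_BLUR]
            combos = [(s, b) for s in snrs for b in blurs]
            per = _balanced_counts(config.n_divided_trials, len(combos), rng)
            for (snr, blur), k in zip(combos, per):
                if np.isnan(snr):
                    mod = "V"
                elif blur == UNINFORMATIVE_BLUR:
                    mod = "A"
                else:
                    mod = "AV"
                rows += [{"modality": mod, "snr_db": snr, "blur_px": blur}] * k
            rows = list(rng.permutation(rows))
    trials = pd.DataFrame(rows)
    trials.insert(0, "sentence_id", np.arange(len(trials)))
    return ExperimentDesign(
        task=task,
        trials=trials,
        words_per_sentence=config.words_per_sentence,
        alternatives_per_word=config.alternatives_per_word,
    )


def _balanced_counts(total: int, n_cells: int, rng: np.random.Generator) -> np.ndarray:
    """Split ``total`` trials over ``n_cells`` as evenly as possible."""
    base, extra = divmod(total, n_cells)
    counts = np.full(n_cells, base, dtype=int)
    counts[rng.choice(n_cells, size=extra, replace=False)] += 1
    return counts


def simulate_responses(
    design: ExperimentDesign,
    params: ParticipantParams,
    truth_variant: Variant | str = Variant.TRADE_OFF,
    seed: int | np.random.Generator = 0,
    participant_id: str = "P0",
    cohort: str = "NH",
    policy: GuessPolicy = GuessPolicy(),
) -> pd.DataFrame:
    """Binomial word-recognition outcomes for every sentence of a design.

    Each sentence yields n_correct ~ Binomial(words_per_sentence, p) with p the
    race-model prediction under ``truth_variant``.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    probs = [
        predict_recognition(
            StimulusCondition(
                modality=row.modality,
                task=design.task,
                snr=None if np.isnan(row.snr_db) else float(row.snr_db),
                blur=None if np.isnan(row.blur_px) else float(row.blur_px),
            ),
            params,
            Variant(truth_variant),
            policy,
        )
        for row in design.trials.itertuples()
    ]
    n_correct = rng.binomial(design.words_per_sentence, probs)
    out = design.trials.copy()
    out["n_words"] = design.words_per_sentence
    out["n_correct"] = n_correct
    out.insert(0, "cohort", cohort)
    out.insert(0, "participant_id", participant_id)
    out.insert(2, "task", design.task.value)
    return out[TRIAL_COLUMNS + ["sentence_id"]]


def simulate_cohort(
    hyper: GroupHyperParams,
    n_participants: int,
    tasks: tuple[str, ...] = ("focused", "divided"),
    config: DesignConfig = DesignConfig(),
    truth_variant: Variant | str = Variant.TRADE_OFF,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full cohort; returns (trial table, ground-truth parameters)."""
    rng = np.random.default_rng(seed)
    participants = draw_participants(hyper, n_participants, rng)
    frames, truths = [], []
    for i, params in enumerate(participants):
        pid = f"{hyper.cohort}{i + 1:02d}"
        for task in tasks:
            design = build_design(task, params, config, rng)
            frames.append(
                simulate_responses(design, params, truth_variant, rng, pid, hyper.cohort)
            )
        truths.append(
            {
                "participant_id": pid,
                "cohort": hyper.cohort,
                "theta_a": params.auditory.threshold_db,
                "omega": params.auditory.width_db,
                "theta_v": params.visual.threshold_px,
                "lam_a_focused": params.lapses.a_focused,
                "lam_a_divided": params.lapses.a_divided,
                "lam_v": params.lapses.v_focused,
            }
        )
    return pd.concat(frames, ignore_index=True), pd.DataFrame(truths)
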