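"""Psychometric and multisensory probability computations for Matrix-test speech
recognition.

The building blocks:

* a logistic auditory psychometric function of signal-to-noise ratio with a
  threshold ``theta_a`` (50% point) and a width ``omega`` (the SNR range over
  which recognition rises from 0.1 to 0.9),
* a single-parameter exponential visual function of video blur with threshold
  ``theta_v`` (the blur at which recognition falls to exp(-1) = 36.8%),
* a multiplicative lapse probability per modality and attention task,
* a fixed 10-alternative guess floor (0.9 * psi + 0.1),
* probability summation (race model) across the auditory and visual channels,
* the multisensory enhancement index (MEI) comparing the trade-off and strict
  probability-summation variants.

All functions are pure and vectorize over numpy arrays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Union

import numpy as np

ArrayLike = Union[float, np.ndarray]

#: Slope constant of the logistic: 2*ln(9)/omega maps +-omega/2 to 0.1/0.9.
LOG9 = math.log(9.0)

#: Blur (pixel sd) that renders the video uninformative; used for the
#: auditory-only trials of the divided-attention task.
UNINFORMATIVE_BLUR = 70.0


class Modality(str, Enum):
    A = "A"
    V = "V"
    AV = "AV"


class Task(str, Enum):
    FOCUSED = "focused"
    DIVIDED = "divided"


class Variant(str, Enum):
    """Which task's auditory lapse feeds the audiovisual prediction.

    ``strict``: the divided-attention lapse (same regime as the AV trials).
    ``trade-off``: the focused-attention lapse (captures the enhancement of AV
    recognition over strict probability summation).
    """

    STRICT = "strict"
    TRADE_OFF = "trade-off"


class InvalidParameterError(ValueError):
    """Raised for psychometric parameters outside their support."""


@dataclass(frozen=True)
class AuditoryParams:
    """Logistic auditory function parameters: threshold (dB SNR) and width (dB)."""

    threshold_db: float
    width_db: float

    def __post_init__(self) -> None:
        if not self.width_db > 0:
            raise InvalidParameterError(
                f"auditory width must be positive, got {self.width_db}"
            )


@dataclass(frozen=True)
class VisualParams:
    """Exponential visual function parameter: threshold blur in pixels (> 0)."""

    threshold_px: float

    def __post_init__(self) -> None:
        if not self.threshold_px > 0:
            raise InvalidParameterError(
                f"visual threshold must be positive, got {self.threshold_px}"
            )


@dataclass(frozen=True)
class LapseSet:
    """Lapse probabilities per modality (A/V) and task (focused/divided).

    In the final model the visual lapse is shared across tasks; construct with
    ``LapseSet.vis_shared`` to enforce that.
    """

    a_focused: float
    a_divided: float
    v_focused: float
    v_divided: float

    def __post_init__(self) -> None:
        for name in ("a_focused", "a_divided", "v_focused", "v_divided"):
            lam = getattr(self, name)
            if not 0.0 <= lam <= 1.0:
                raise InvalidParameterError(f"lapse {name}={lam} outside [0, 1]")

    @classmethod
    def vis_shared(cls, a_focused: float, a_divided: float, v: float) -> "LapseSet":
        return cls(a_focused=a_focused, a_divided=a_divided, v_focused=v, v_divided=v)

    def auditory(self, task: Task) -> float:
        return self.a_focused if Task(task) is Task.FOCUSED else self.a_divided

    def visual(self, task: Task) -> float:
        return self.v_focused if Task(task) is Task.FOCUSED else self.v_divided


@dataclass(frozen=True)
class GuessPolicy:
    """Fixed guess floor of a closed-set test: p = (1 - g) * psi + g.

    g = 0.1 for the 10-alternative Matrix test.
    """

    guess_rate: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.guess_rate < 1.0:
            raise InvalidParameterError(f"guess rate {self.guess_rate} outside [0, 1)")


@dataclass(frozen=True)
class ParticipantParams:
    auditory: AuditoryParams
    visual: VisualParams
    lapses: LapseSet


@dataclass(frozen=True)
class StimulusCondition:
    """One stimulus condition: modality, attention task, SNR (dB) and blur (px).

    ``snr=None`` marks an absent acoustic signal (visual-only trials);
    ``blur=None`` marks an uninformative/absent video (focused auditory-only
    trials).  Auditory-only trials of the divided task carry ``blur=70``.
    """

    modality: Modality
    task: Task
    snr: float | None = None
    blur: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "modality", Modality(self.modality))
        object.__setattr__(self, "task", Task(self.task))
        if self.blur is not None and self.blur < 0:
            raise InvalidParameterError(f"blur must be >= 0, got {self.blur}")
        if self.modality is Modality.V and self.snr is not None:
            raise InvalidParameterError("V-only trials carry no acoustic signal")
        if self.modality in (Modality.A, Modality.AV) and self.snr is None:
            raise InvalidParameterError(f"{self.modality.value} trial requires an SNR")
        if self.modality is Modality.AV and self.blur is None:
            raise InvalidParameterError("AV trial requires a blur")
        if (
            self.modality is Modality.A
            and self.task is Task.DIVIDED
            and self.blur != UNINFORMATIVE_BLUR
        ):
            raise InvalidParameterError(
                "auditory-only trials in the divided task use the uninformative "
                f"{UNINFORMATIVE_BLUR:.0f}-pixel blur"
            )


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


def auditory_pf(snr: ArrayLike, params: AuditoryParams) -> ArrayLike:
    """Logistic recognition probability as a function of SNR (dB).

    F(x) = 1 / (1 + exp(-(2 ln 9 / omega) (x - theta))); F(theta) = 0.5 and
    F(theta +- omega/2) = 0.9 / 0.1, so omega is the 10-to-90% range.
    """
    x = np.asarray(snr, dtype=float)
    slope = 2.0 * LOG9 / params.width_db
    with np.errstate(over="ignore"):
        out = 1.0 / (1.0 + np.exp(-slope * (x - params.threshold_db)))
    return out if out.ndim else float(out)


def visual_pf(blur: ArrayLike, params: VisualParams) -> ArrayLike:
    """Exponential recognition probability as a function of blur (pixel sd).

    F(x) = exp(-x^2 / theta^2); F(0) = 1 and F(theta) = exp(-1) = 0.368.
    """
    x = np.asarray(blur, dtype=float)
    if np.any(x < 0):
        raise InvalidParameterError("blur must be >= 0")
    out = np.exp(-(x**2) / params.threshold_px**2)
    return out if out.ndim else float(out)


def apply_lapse(f: ArrayLike, lam: ArrayLike) -> ArrayLike:
    """Attenuate a psychometric value by a lapse: psi = (1 - lambda) * F."""
    f_arr = np.asarray(f, dtype=float)
    lam_arr = np.asarray(lam, dtype=float)
    if np.any((f_arr < 0) | (f_arr > 1)) or np.any((lam_arr < 0) | (lam_arr > 1)):
        raise InvalidParameterError("apply_lapse inputs must lie in [0, 1]")
    out = (1.0 - lam_arr) * f_arr
    return out if out.ndim else float(out)


def apply_guess(psi: ArrayLike, policy: GuessPolicy = GuessPolicy()) -> ArrayLike:
    """Closed-set guess correction: p = (1 - g) * psi + g, mapping [0,1] -> [g,1]."""
    psi_arr = np.asarray(psi, dtype=float)
    if np.any((psi_arr < 0) | (psi_arr > 1)):
        raise InvalidParameterError("psi must lie in [0, 1]")
    out = (1.0 - policy.guess_rate) * psi_arr + policy.guess_rate
    return out if out.ndim else float(out)


def prob_summation(psi_a: ArrayLike, psi_v: ArrayLike) -> ArrayLike:
    """Race-model (probability summation) combination of two independent channels.

    psi_sum = 1 - (1 - psi_a)(1 - psi_v) = psi_a + psi_v - psi_a * psi_v.
    """
    a = np.asarray(psi_a, dtype=float)
    v = np.asarray(psi_v, dtype=float)
    if np.any((a < 0) | (a > 1)) or np.any((v < 0) | (v > 1)):
        raise InvalidParameterError("prob_summation inputs must lie in [0, 1]")
    out = a + v - a * v
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Condition-level prediction
# ---------------------------------------------------------------------------


def _auditory_lapse_for(cond: StimulusCondition, lapses: LapseSet, variant: Variant) -> float:
    if cond.modality is Modality.AV:
        # The variant decides which task's auditory lapse predicts AV trials.
        task = Task.DIVIDED if Variant(variant) is Variant.STRICT else Task.FOCUSED
        return lapses.auditory(task)
    return lapses.auditory(cond.task)


def predict_recognition(
    cond: StimulusCondition,
    params: ParticipantParams,
    variant: Variant = Variant.TRADE_OFF,
    policy: GuessPolicy = GuessPolicy(),
) -> float:
    """Predicted probability of recognizing one word under a stimulus condition.

    Both channels are always combined by probability summation; an absent
    acoustic signal contributes psi_a = 0 and an absent video psi_v = 0 (a
    70-pixel blur contributes a numerically negligible but nonzero channel).
    The guess correction is applied last, after summation.
    """
    if cond.snr is not None:
        lam_a = _auditory_lapse_for(cond, params.lapses, variant)
        psi_a = apply_lapse(auditory_pf(cond.snr, params.auditory), lam_a)
    else:
        psi_a = 0.0
    if cond.blur is not None:
        psi_v = apply_lapse(visual_pf(cond.blur, params.visual), params.lapses.visual(cond.task))
    else:
        psi_v = 0.0
    return float(apply_guess(prob_summation(psi_a, psi_v), policy))


def mei(
    cond: StimulusCondition,
    params: ParticipantParams,
    policy: GuessPolicy = GuessPolicy(),
) -> float:
    """Multisensory enhancement index: psi_trade-off / psi_strict - 1.

    Both predictions include the guess floor, so the denominator is bounded
    below by the guess rate and the ratio is always defined.  The index is 0
    when the two tasks share one auditory lapse and positive when the divided
    task's lapse exceeds the focused one.
    """
    if Modality(cond.modality) is not Modality.AV:
        raise InvalidParameterError("MEI is defined for audiovisual conditions")
    p_trade = predict_recognition(cond, params, Variant.TRADE_OFF, policy)
    p_strict = predict_recognition(cond, params, Variant.STRICT, policy)
    return p_trade / p_strict - 1.0


# ---------------------------------------------------------------------------
# Vectorized prediction over trial tables (shared by simulation and inference)
# ---------------------------------------------------------------------------

#: integer codes used in the packed trial arrays
MOD_CODES = {Modality.A: 0, Modality.V: 1, Modality.AV: 2}
TASK_CODES = {Task.FOCUSED: 0, Task.DIVIDED: 1}


def predict_arrays(
    snr: np.ndarray,
    blur: np.ndarray,
    mod_code: np.ndarray,
    task_code: np.ndarray,
    theta_a: np.ndarray,
    omega: np.ndarray,
    theta_v: np.ndarray,
    lam_a_foc: np.ndarray,
    lam_a_div: np.ndarray,
    lam_v_foc: np.ndarray,
    lam_v_div: np.ndarray,
    variant: Variant = Variant.TRADE_OFF,
    guess_rate: float = 0.1,
) -> np.ndarray:
    """Recognition probability for packed trial arrays, broadcasting over a
    leading batch axis of the parameter arrays (used by the MCMC likelihood).

    ``snr``/``blur`` are float arrays with NaN marking an absent stimulus
    dimension. Parameter arrays broadcast against the trial axis, e.g. shape
    ``(n_walkers, n_trials)`` against ``(n_trials,)``.
    """
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        snr_safe = np.where(np.isnan(snr), 0.0, snr)
        f_a = 1.0 / (1.0 + np.exp(-(2.0 * LOG9 / omega) * (snr_safe - theta_a)))
        blur_safe = np.where(np.isnan(blur), 0.0, blur)
        f_v = np.exp(-(blur_safe**2) / theta_v**2)

    is_av = mod_code == MOD_CODES[Modality.AV]
    is_div = task_code == TASK_CODES[Task.DIVIDED]
    av_lam = lam_a_div if Variant(variant) is Variant.STRICT else lam_a_foc
    lam_a = np.where(is_av, av_lam, np.where(is_div, lam_a_div, lam_a_foc))
    lam_v = np.where(is_div, lam_v_div, lam_v_foc)

    psi_a = np.where(np.isnan(snr), 0.0, (1.0 - lam_a) * f_a)
    psi_v = np.where(np.isnan(blur), 0.0, (1.0 - lam_v) * f_v)
    psi = psi_a + psi_v - psi_a * psi_v
    return (1.0 - guess_rate) * psi + guess_rate


def invert_auditory(
    target: ArrayLike,
    auditory: AuditoryParams,
    lam: float,
    policy: GuessPolicy = GuessPolicy(),
    f_bounds: tuple[float, float] = (1e-4, 0.995),
) -> np.ndarray:
    """SNR (dB) at which the post-guess recognition probability equals ``target``.

    Targets outside the reachable band [g, g + (1-g)(1-lambda)] are clipped to
    the psychometric bounds ``f_bounds`` (floor/ceiling contract).
    """
    g = policy.guess_rate
    f = (np.asarray(target, dtype=float) - g) / ((1.0 - g) * (1.0 - lam))
    f = np.clip(f, *f_bounds)
    x = auditory.threshold_db + auditory.width_db / (2.0 * LOG9) * np.log(f / (1.0 - f))
    return np.asarray(x, dtype=float)


def invert_visual(
    target: ArrayLike,
    visual: VisualParams,
    lam: float,
    policy: GuessPolicy = GuessPolicy(),
    f_bounds: tuple[float, float] = (1e-4, 0.995),
) -> np.ndarray:
    """Blur (px) at which the post-guess recognition probability equals ``target``."""
    g = policy.guess_rate
    f = (np.asarray(target, dtype=float) - g) / ((1.0 - g) * (1.0 - lam))
    f = np.clip(f, *f_bounds)
    return np.asarray(visual.threshold_px * np.sqrt(-np.log(f)), dtype=float)
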