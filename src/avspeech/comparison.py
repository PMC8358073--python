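"""Model comparison: strict vs. trade-off probability summation.

The two variants share every parameter and differ only in which task's
auditory lapse probability feeds the audiovisual prediction, so their free
parameter counts coincide whenever both tasks contribute data and the BIC
difference reduces to the likelihood term.  The maximized binomial likelihood
is obtained by bounded quasi-Newton optimization on the transformed
participant parameters (the likelihood factorizes over participants),
multi-started and optionally initialized at hierarchical posterior means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .inference import LikelihoodEvaluator, ModelSpec, PosteriorResult, build_likelihood
from .psychometrics import (
    GuessPolicy,
    Modality,
    ParticipantParams,
    StimulusCondition,
    Task,
    Variant,
    mei,
)

_BOUNDS = {
    "theta_a": (-60.0, 60.0),
    "log_omega": (math.log(0.5), math.log(60.0)),
    "log_theta_v": (math.log(1.0), math.log(80.0)),
}
_LOGIT_BOUNDS = (-7.0, 7.0)


def bic(n: int, k: int, loglik_max: float) -> float:
    """Bayesian Information Criterion: ln(n) * k - 2 * ln(L-hat)."""
    if n < 1:
        raise ValueError(f"need at least one observation, got n={n}")
    if k < 1:
        raise ValueError(f"need at least one parameter, got k={k}")
    return math.log(n) * k - 2.0 * loglik_max


@dataclass
class MLFit:
    """Maximum-likelihood point fit of one cohort under one model variant."""

    spec: ModelSpec
    params: pd.DataFrame          # per participant, natural-scale columns
    loglik: float
    n_obs: int                    # word-level observation count
    k: int                        # free participant-level parameters
    trial_probs: np.ndarray       # fitted p per trial row (data order)


def _default_center(fam: str, ev: LikelihoodEvaluator) -> float:
    if fam == "theta_a":
        med = np.nanmedian(ev._snr)
        return float(med) if np.isfinite(med) else 0.0
    if fam == "log_omega":
        return math.log(8.0)
    if fam == "log_theta_v":
        blur = ev._blur[np.isfinite(ev._blur) & (ev._blur > 0) & (ev._blur < 60)]
        return float(np.log(np.median(blur) + 1.0)) if blur.size else math.log(12.0)
    return -1.5 if "lam_a" in fam else 0.0


def fit_ml(
    trials: pd.DataFrame,
    spec: ModelSpec = ModelSpec(),
    init: Mapping[str, float] | None = None,
    seed: int = 0,
    n_starts: int = 3,
) -> MLFit:
    """Maximize the binomial likelihood participant by participant.

    ``init`` maps layout parameter names (``theta_a[P01]``, ...) to starting
    values, typically hierarchical posterior means; additional random restarts
    guard against local optima.
    """
    rng = np.random.default_rng(seed)
    init = dict(init or {})
    trials = trials.reset_index(drop=True)
    probs = np.empty(len(trials))
    rows, total_ll, total_k = [], 0.0, 0
    for pid, sub in trials.groupby("participant_id", sort=True):
        ev = build_likelihood(sub, spec)
        fams = ev.layout.families
        idx = [ev.layout.part_slice[f].start for f in fams]
        x_full = np.zeros(ev.layout.ndim)

        def nll(z: np.ndarray) -> float:
            x_full[idx] = z
            return -ev.loglik(x_full)

        x0 = np.array([init.get(f"{f}[{pid}]", _default_center(f, ev)) for f in fams])
        bounds = [
            _BOUNDS.get(f, _LOGIT_BOUNDS) for f in fams
        ]
        best = None
        starts = [x0] + [
            np.clip(x0 + rng.normal(scale=0.7, size=len(fams)),
                    [b[0] for b in bounds], [b[1] for b in bounds])
            for _ in range(n_starts - 1)
        ]
        for start in starts:
            res = minimize(nll, start, method="L-BFGS-B", bounds=bounds)
            if best is None or res.fun < best.fun:
                best = res
        x_full[idx] = best.x
        probs[trials["participant_id"] == pid] = ev._trial_probs(x_full)[0]
        total_ll += -best.fun
        total_k += len(fams)
        row = {"participant_id": pid}
        for f, value in zip(fams, best.x):
            if f.startswith("log_"):
                row[f.removeprefix("log_")] = math.exp(value)
            elif f.startswith("logit_"):
                row[f.removeprefix("logit_")] = float(expit(value))
            else:
                row[f] = float(value)
        rows.append(row)
    return MLFit(
        spec=spec,
        params=pd.DataFrame(rows),
        loglik=total_ll,
        n_obs=int(trials["n_words"].sum()),
        k=total_k,
        trial_probs=probs,
    )


def _condition_level(trials: pd.DataFrame, probs: np.ndarray) -> pd.DataFrame:
    """Observed vs. predicted proportions per participant-level condition."""
    df = trials.copy()
    df["p_pred"] = probs
    grouped = df.groupby(
        ["participant_id", "task", "modality", "snr_db", "blur_px"], dropna=False
    )
    out = grouped.apply(
        lambda g: pd.Series(
            {
                "observed": g["n_correct"].sum() / g["n_words"].sum(),
                "predicted": np.average(g["p_pred"], weights=g["n_words"]),
            }
        ),
        include_groups=False,
    )
    return out.reset_index()


def fit_metrics(trials: pd.DataFrame, fit: MLFit, modality: str | None = None) -> dict[str, float]:
    """R-squared and mean signed error on condition-level proportions.

    ``modality`` restricts the conditions (e.g. "AV" isolates how a variant
    over- or under-predicts audiovisual performance).
    """
    cond = _condition_level(trials.reset_index(drop=True), fit.trial_probs)
    if modality is not None:
        cond = cond[cond["modality"] == modality]
    obs, pred = cond["observed"].to_numpy(), cond["predicted"].to_numpy()
    if np.ptp(obs) == 0 or np.ptp(pred) == 0:
        r2 = 1.0 if np.allclose(obs, pred) else 0.0
    else:
        r2 = float(np.corrcoef(obs, pred)[0, 1] ** 2)
    return {"r2": r2, "mean_signed_error": float(np.mean(obs - pred))}


def compare_variants(
    trials: pd.DataFrame,
    posteriors: Mapping[tuple[str, str], PosteriorResult] | None = None,
    constraint: str = "aud_free_vis_shared",
    guess_rate: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit both AV variants per cohort and tabulate BIC / dBIC / R2 / error.

    ``posteriors`` may provide hierarchical fits keyed by (cohort, variant)
    whose means initialize the likelihood maximization; each must have been
    fitted on the same participants as the trial table.
    """
    posteriors = dict(posteriors or {})
    frames = []
    for cohort, sub in trials.groupby("cohort", sort=True):
        sub = sub.reset_index(drop=True)
        per_variant = {}
        for variant in (Variant.TRADE_OFF, Variant.STRICT):
            spec = ModelSpec(lapse_constraint=constraint, variant=variant.value,
                             guess_rate=guess_rate)
            init = None
            post = posteriors.get((cohort, variant.value))
            if post is not None:
                fitted = set(post.layout.participants) if post.layout else set()
                if fitted and fitted != set(sub["participant_id"].unique()):
                    raise ValueError(
                        f"posterior for ({cohort}, {variant.value}) was fitted on "
                        "different participants than the trial table"
                    )
                init = post.mean()
            per_variant[variant.value] = fit_ml(sub, spec, init=init, seed=seed)
        for variant, fit in per_variant.items():
            metrics = fit_metrics(sub, fit)
            frames.append(
                {
                    "cohort": cohort,
                    "model": variant,
                    "n": fit.n_obs,
                    "k": fit.k,
                    "loglik": fit.loglik,
                    "bic": bic(fit.n_obs, fit.k, fit.loglik),
                    **metrics,
                }
            )
    out = pd.DataFrame(frames)
    out["delta_bic"] = out["bic"] - out.groupby("cohort")["bic"].transform("min")
    return out


def mei_surface(
    params: ParticipantParams,
    snr_grid: np.ndarray,
    blur_grid: np.ndarray,
    policy: GuessPolicy = GuessPolicy(),
) -> pd.DataFrame:
    """MEI per (blur, snr) cell for audiovisual conditions of the divided task.

    Rows are blurs, columns SNRs.  The surface is zero when the two tasks share
    one auditory lapse, grows with blur, and declines toward low SNR.
    """
    values = [
        [
            mei(
                StimulusCondition(Modality.AV, Task.DIVIDED, snr=float(s), blur=float(b)),
                params,
                policy,
            )
            for s in snr_grid
        ]
        for b in blur_grid
    ]
    return pd.DataFrame(values, index=pd.Index(blur_grid, name="blur_px"),
                        columns=pd.Index(snr_grid, name="snr_db"))
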