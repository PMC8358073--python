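"""Hierarchical Bayesian estimation of the psychometric model.

The observation model is binomial at the word level: for every sentence,
n_correct ~ Binomial(n_words, 0.9 * psi + 0.1), with psi the race-model
recognition probability built from the participant's auditory logistic,
visual exponential, and modality/task-specific lapses.

Participant parameters are drawn from group-level normal distributions on
transformed scales (threshold in dB, log width, log visual threshold, logit
lapses), with weakly informative hyperpriors (normal on the group location,
half-normal on the group scale).  One set of hyperparameters is fitted per
cohort; fit cohorts separately.

Sampling uses affine-invariant ensemble MCMC (emcee): several independent
ensembles ("chains") of walkers.  ``samples`` and ``burn_in`` count ensemble
sweeps per chain, so each chain retains ``samples * n_walkers`` posterior
draws.  Convergence is assessed with rank-normalized split-R-hat and bulk
effective sample size, treating every walker of every ensemble as a chain,
with the pass criterion R-hat < 1.1 and ESS > 1000.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln

from .psychometrics import MOD_CODES, TASK_CODES, Variant, predict_arrays

RHAT_MAX = 1.1
ESS_MIN = 1000.0

_P_EPS = 1e-12


class DataError(ValueError):
    """Trial data unusable for model fitting."""


class DiagnosticsError(ValueError):
    """Convergence diagnostics requested on an unsuitable posterior."""


@dataclass(frozen=True)
class ModelSpec:
    """Structural choices of the fitted model.

    ``lapse_constraint``: which lapses are shared across tasks.  The final
    model (``aud_free_vis_shared``) lets only the auditory lapse differ
    between the focused and divided task.  ``variant`` picks the auditory
    lapse used for audiovisual predictions (strict: divided task; trade-off:
    focused task).
    """

    lapse_constraint: str = "aud_free_vis_shared"
    variant: str = "trade-off"
    guess_rate: float = 0.1

    def __post_init__(self) -> None:
        if self.lapse_constraint not in ("aud_free_vis_shared", "all_free", "all_shared"):
            raise ValueError(f"unknown lapse constraint {self.lapse_constraint!r}")
        Variant(self.variant)


@dataclass(frozen=True)
class FamilyPrior:
    """Hyperpriors of one parameter family on its transformed scale."""

    mu0: float          # prior mean of the group location
    tau_mu: float       # prior sd of the group location
    tau_sigma: float    # half-normal scale of the group scale


def default_priors() -> dict[str, FamilyPrior]:
    return {
        "theta_a": FamilyPrior(0.0, 20.0, 10.0),
        "log_omega": FamilyPrior(np.log(8.0), 1.0, 0.5),
        "log_theta_v": FamilyPrior(np.log(15.0), 1.0, 0.5),
        "logit_lam_a_foc": FamilyPrior(-1.5, 1.5, 1.0),
        "logit_lam_a_div": FamilyPrior(-1.5, 1.5, 1.0),
        "logit_lam_a": FamilyPrior(-1.5, 1.5, 1.0),
        "logit_lam_v_foc": FamilyPrior(0.0, 1.5, 1.0),
        "logit_lam_v_div": FamilyPrior(0.0, 1.5, 1.0),
        "logit_lam_v": FamilyPrior(0.0, 1.5, 1.0),
    }


# ---------------------------------------------------------------------------
# Parameter layout and likelihood
# ---------------------------------------------------------------------------


def _lapse_families(constraint: str) -> dict[str, str]:
    """Map predict_arrays lapse slots -> family name under a constraint."""
    if constraint == "aud_free_vis_shared":
        return {
            "lam_a_foc": "logit_lam_a_foc",
            "lam_a_div": "logit_lam_a_div",
            "lam_v_foc": "logit_lam_v",
            "lam_v_div": "logit_lam_v",
        }
    if constraint == "all_free":
        return {
            "lam_a_foc": "logit_lam_a_foc",
            "lam_a_div": "logit_lam_a_div",
            "lam_v_foc": "logit_lam_v_foc",
            "lam_v_div": "logit_lam_v_div",
        }
    return {
        "lam_a_foc": "logit_lam_a",
        "lam_a_div": "logit_lam_a",
        "lam_v_foc": "logit_lam_v",
        "lam_v_div": "logit_lam_v",
    }


@dataclass
class ParameterLayout:
    """Index map of the flat parameter vector for one cohort fit.

    Layout: for every included family, a group location ``mu_<family>`` and a
    log group scale ``log_sigma_<family>``, followed by one participant-level
    value per participant per family on the transformed scale.

    Sampling runs on a non-centered parameterization (participant values as
    standard-normal offsets ``eta`` with ``value = mu + sigma * eta``), which
    avoids the location-scale funnel; the stored posterior draws are the
    centered (transformed-scale) participant values.
    """

    participants: list[str]
    families: list[str]
    slot_family: dict[str, str]      # predict_arrays lapse slot -> family (or "")
    hyper_idx: dict[str, tuple[int, int]] = field(default_factory=dict)
    part_slice: dict[str, slice] = field(default_factory=dict)
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        idx = 0
        for fam in self.families:
            self.hyper_idx[fam] = (idx, idx + 1)
            self.names += [f"mu_{fam}", f"log_sigma_{fam}"]
            idx += 2
        for fam in self.families:
            self.part_slice[fam] = slice(idx, idx + len(self.participants))
            self.names += [f"{fam}[{pid}]" for pid in self.participants]
            idx += len(self.participants)
        self.ndim = idx

    def participant_values(self, x: np.ndarray, fam: str) -> np.ndarray:
        return x[..., self.part_slice[fam]]


def build_layout(trials: pd.DataFrame, spec: ModelSpec) -> ParameterLayout:
    participants = sorted(trials["participant_id"].unique())
    has_aud = trials["snr_db"].notna()
    has_vis = trials["blur_px"].notna()
    if not (has_aud | has_vis).all():
        raise DataError("trial with both stimulus dimensions absent")
    is_av = trials["modality"] == "AV"
    is_div = trials["task"] == "divided"
    slot_map = _lapse_families(spec.lapse_constraint)
    av_slot = "lam_a_div" if Variant(spec.variant) is Variant.STRICT else "lam_a_foc"
    used = {
        "lam_a_foc": (has_aud & ~is_av & ~is_div).any(),
        "lam_a_div": (has_aud & ~is_av & is_div).any(),
        "lam_v_foc": (has_vis & ~is_div).any(),
        "lam_v_div": (has_vis & is_div).any(),
    }
    if (has_aud & is_av).any():
        used[av_slot] = True
    families: list[str] = []
    if has_aud.any():
        families += ["theta_a", "log_omega"]
    if has_vis.any():
        families += ["log_theta_v"]
    slot_family = {
        slot: (slot_map[slot] if used[slot] else "") for slot in slot_map
    }
    for slot in ("lam_a_foc", "lam_a_div", "lam_v_foc", "lam_v_div"):
        fam = slot_family[slot]
        if fam and fam not in families:
            families.append(fam)
    return ParameterLayout(participants=participants, families=families, slot_family=slot_family)


class LikelihoodEvaluator:
    """Vectorized binomial log-likelihood / log-posterior for one cohort.

    ``loglik`` and ``logpost`` accept a single parameter vector ``(ndim,)`` or
    a batch ``(n_walkers, ndim)``.
    """

    def __init__(
        self,
        trials: pd.DataFrame,
        spec: ModelSpec = ModelSpec(),
        priors: Mapping[str, FamilyPrior] | None = None,
    ):
        if trials.empty:
            raise DataError("empty trial table")
        trials = trials.reset_index(drop=True)
        self.spec = spec
        self.layout = build_layout(trials, spec)
        self.priors = dict(default_priors() | dict(priors or {}))
        pid_index = {pid: i for i, pid in enumerate(self.layout.participants)}
        self._part = trials["participant_id"].map(pid_index).to_numpy()
        self._snr = trials["snr_db"].to_numpy(dtype=float)
        self._blur = trials["blur_px"].to_numpy(dtype=float)
        self._mod = trials["modality"].map({m.value: c for m, c in MOD_CODES.items()}).to_numpy()
        self._task = trials["task"].map({t.value: c for t, c in TASK_CODES.items()}).to_numpy()
        self._n = trials["n_words"].to_numpy(dtype=float)
        self._k = trials["n_correct"].to_numpy(dtype=float)
        # binomial coefficients are parameter-free but kept so that the
        # maximized likelihood feeding the BIC is the true binomial pmf
        self._log_binom = float(
            np.sum(gammaln(self._n + 1) - gammaln(self._k + 1) - gammaln(self._n - self._k + 1))
        )
        self.n_trials = len(trials)
        self.n_observations = int(self._n.sum())
        self.n_free_params = len(self.layout.families) * len(self.layout.participants)

    # -- probability of every trial ------------------------------------
    def _trial_probs(self, x: np.ndarray, noncentered: bool = False) -> np.ndarray:
        lay = self.layout
        x = np.atleast_2d(x)

        def natural(fam: str) -> np.ndarray:
            z = lay.participant_values(x, fam)
            if noncentered:
                mu_i, ls_i = lay.hyper_idx[fam]
                z = x[:, [mu_i]] + np.exp(x[:, [ls_i]]) * z
            z = z[:, self._part]
            if fam.startswith("log_"):
                return np.exp(z)
            if fam.startswith("logit_"):
                return expit(z)
            return z

        zeros = np.zeros((x.shape[0], self.n_trials))
        theta_a = natural("theta_a") if "theta_a" in lay.families else zeros
        omega = natural("log_omega") if "log_omega" in lay.families else zeros + 1.0
        theta_v = natural("log_theta_v") if "log_theta_v" in lay.families else zeros + 1.0
        lam = {
            slot: (natural(fam) if fam else zeros)
            for slot, fam in lay.slot_family.items()
        }
        return predict_arrays(
            self._snr, self._blur, self._mod, self._task,
            theta_a, omega, theta_v,
            lam["lam_a_foc"], lam["lam_a_div"], lam["lam_v_foc"], lam["lam_v_div"],
            variant=Variant(self.spec.variant), guess_rate=self.spec.guess_rate,
        )

    def loglik(self, x: np.ndarray, noncentered: bool = False) -> np.ndarray | float:
        scalar = np.ndim(x) == 1
        with np.errstate(over="ignore", invalid="ignore"):
            p = np.clip(self._trial_probs(x, noncentered), _P_EPS, 1.0 - _P_EPS)
            out = (self._k * np.log(p) + (self._n - self._k) * np.log1p(-p)).sum(axis=-1)
        out = out + self._log_binom
        out = np.where(np.isfinite(out), out, -np.inf)
        return float(out[0]) if scalar else out

    def logprior(self, x: np.ndarray) -> np.ndarray | float:
        scalar = np.ndim(x) == 1
        x = np.atleast_2d(x)
        lay = self.layout
        out = np.zeros(x.shape[0])
        with np.errstate(over="ignore", invalid="ignore"):
            for fam in lay.families:
                pr = self.priors[fam]
                mu_i, ls_i = lay.hyper_idx[fam]
                mu, ls = x[:, mu_i], x[:, ls_i]
                sigma = np.exp(ls)
                out += -0.5 * ((mu - pr.mu0) / pr.tau_mu) ** 2
                # half-normal prior on sigma plus the log|d sigma / d log sigma|
                out += -0.5 * (sigma / pr.tau_sigma) ** 2 + ls
                z = lay.participant_values(x, fam)
                out += (-0.5 * ((z - mu[:, None]) / sigma[:, None]) ** 2).sum(axis=1)
                out += -z.shape[1] * ls
        out = np.where(np.isfinite(out), out, -np.inf)
        return float(out[0]) if scalar else out

    def logpost(self, x: np.ndarray) -> np.ndarray | float:
        return self.logprior(x) + self.loglik(x)

    # -- non-centered counterparts used by the sampler ------------------
    def _logprior_nc(self, x: np.ndarray) -> np.ndarray:
        lay = self.layout
        x = np.atleast_2d(x)
        out = np.zeros(x.shape[0])
        with np.errstate(over="ignore", invalid="ignore"):
            for fam in lay.families:
                pr = self.priors[fam]
                mu_i, ls_i = lay.hyper_idx[fam]
                mu, ls = x[:, mu_i], x[:, ls_i]
                sigma = np.exp(ls)
                out += -0.5 * ((mu - pr.mu0) / pr.tau_mu) ** 2
                out += -0.5 * (sigma / pr.tau_sigma) ** 2 + ls
                eta = lay.participant_values(x, fam)
                out += (-0.5 * eta**2).sum(axis=1)
        return np.where(np.isfinite(out), out, -np.inf)

    def _logpost_nc(self, x: np.ndarray) -> np.ndarray:
        return self._logprior_nc(x) + np.atleast_1d(self.loglik(x, noncentered=True))

    def to_centered(self, x: np.ndarray) -> np.ndarray:
        """Map non-centered draws to centered (transformed-scale) values."""
        out = np.array(x, dtype=float)
        lay = self.layout
        for fam in lay.families:
            mu_i, ls_i = lay.hyper_idx[fam]
            sl = lay.part_slice[fam]
            out[..., sl] = (
                out[..., [mu_i]] + np.exp(out[..., [ls_i]]) * out[..., sl]
            )
        return out


def build_likelihood(
    trials: pd.DataFrame,
    spec: ModelSpec = ModelSpec(),
    priors: Mapping[str, FamilyPrior] | None = None,
) -> LikelihoodEvaluator:
    """Bind a trial table to a vectorized likelihood/posterior evaluator."""
    return LikelihoodEvaluator(trials, spec, priors)


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------


@dataclass
class PosteriorResult:
    """MCMC samples: shape (n_chains, n_sweeps, n_walkers, ndim)."""

    samples: np.ndarray
    log_prob: np.ndarray                 # (n_chains, n_sweeps, n_walkers)
    param_names: list[str]
    seed: int
    layout: ParameterLayout | None = None
    spec: ModelSpec | None = None

    @property
    def n_chains(self) -> int:
        return self.samples.shape[0]

    def pooled(self) -> np.ndarray:
        """All retained draws, flattened to (n_draws, ndim)."""
        return self.samples.reshape(-1, self.samples.shape[-1])

    def pooled_df(self) -> pd.DataFrame:
        c, s, w, d = self.samples.shape
        df = pd.DataFrame(self.pooled(), columns=self.param_names)
        df.insert(0, "chain", np.repeat(np.arange(c), s * w))
        return df

    def walker_chains(self) -> np.ndarray:
        """(n_chains * n_walkers, n_sweeps, ndim): every walker as a chain."""
        c, s, w, d = self.samples.shape
        return self.samples.transpose(0, 2, 1, 3).reshape(c * w, s, d)

    def mode(self) -> dict[str, float]:
        """Draw with the highest log-posterior among retained samples."""
        flat = self.pooled()
        best = int(np.argmax(self.log_prob.reshape(-1)))
        return dict(zip(self.param_names, flat[best]))

    def mean(self) -> dict[str, float]:
        return dict(zip(self.param_names, self.pooled().mean(axis=0)))


def run_ensemble_mcmc(
    log_prob: Callable[[np.ndarray], np.ndarray],
    init: Callable[[int, np.random.Generator], np.ndarray],
    ndim: int,
    param_names: Sequence[str],
    chains: int = 3,
    samples: int = 2000,
    burn_in: int = 1000,
    seed: int = 0,
    nwalkers: int | None = None,
) -> PosteriorResult:
    """Run independent affine-invariant ensembles over a vectorized log density.

    ``init(chain, rng)`` must return (nwalkers, ndim) starting positions with
    finite density; chains are seeded independently and deterministically from
    ``seed``.
    """
    import emcee

    if chains < 1:
        raise ValueError("need at least one chain")
    nwalkers = max(nwalkers or 0, 2 * ndim + 8, 32)
    if nwalkers % 2:
        nwalkers += 1
    chain_seeds = np.random.SeedSequence(seed).generate_state(chains) % (2**31)
    all_samples, all_lp = [], []
    for c in range(chains):
        rng = np.random.default_rng(int(chain_seeds[c]))
        p0 = init(nwalkers, rng)
        lp0 = log_prob(p0)
        if not np.all(np.isfinite(lp0)):
            raise RuntimeError(
                "failed to initialize all walkers within the posterior support"
            )
        moves = [
            (emcee.moves.DEMove(), 0.8),
            (emcee.moves.DESnookerMove(), 0.2),
        ]
        sampler = emcee.EnsembleSampler(
            nwalkers, ndim, log_prob, vectorize=True, moves=moves
        )
        state = emcee.State(
            p0, random_state=np.random.RandomState(int(chain_seeds[c])).get_state()
        )
        sampler.run_mcmc(state, burn_in + samples, progress=False)
        all_samples.append(sampler.get_chain(discard=burn_in))       # (samples, nwalkers, ndim)
        all_lp.append(sampler.get_log_prob(discard=burn_in))
    return PosteriorResult(
        samples=np.stack(all_samples),
        log_prob=np.stack(all_lp),
        param_names=list(param_names),
        seed=seed,
    )


def _initializer(ev: LikelihoodEvaluator) -> Callable[[int, np.random.Generator], np.ndarray]:
    """Data-informed, chain-overdispersed starting positions."""
    lay = ev.layout
    centers = {
        "theta_a": float(np.nanmedian(ev._snr)) if np.isfinite(np.nanmedian(ev._snr)) else 0.0,
        "log_omega": np.log(8.0),
        "log_theta_v": np.log(12.0),
    }
    finite_blur = ev._blur[np.isfinite(ev._blur) & (ev._blur > 0) & (ev._blur < 60)]
    if finite_blur.size:
        centers["log_theta_v"] = float(np.log(np.median(finite_blur) + 1.0))
    chain_sd = {"theta_a": 2.0, "log_omega": 0.2, "log_theta_v": 0.2}
    walker_sd = {"theta_a": 0.5, "log_omega": 0.05, "log_theta_v": 0.05}

    def init(nwalkers: int, rng: np.random.Generator) -> np.ndarray:
        x = np.empty((nwalkers, lay.ndim))
        n_part = len(lay.participants)
        for fam in lay.families:
            c0 = centers.get(fam, -1.5 if "lam_a" in fam else 0.0)
            csd = chain_sd.get(fam, 0.5)
            wsd = walker_sd.get(fam, 0.1)
            mu_i, ls_i = lay.hyper_idx[fam]
            mu_c = c0 + csd * rng.standard_normal()
            x[:, mu_i] = mu_c + wsd * rng.standard_normal(nwalkers)
            sigma0 = max(0.3 * ev.priors[fam].tau_sigma, 0.05)
            x[:, ls_i] = np.log(sigma0) + 0.1 * rng.standard_normal(nwalkers)
            # non-centered participant offsets: standard-normal scale
            x[:, lay.part_slice[fam]] = (
                0.5 * rng.standard_normal((1, n_part))
                + 0.2 * rng.standard_normal((nwalkers, n_part))
            )
        return x

    return init


def fit_mcmc(
    trials: pd.DataFrame,
    spec: ModelSpec = ModelSpec(),
    chains: int = 3,
    samples: int = 10_000,
    burn_in: int = 10_000,
    seed: int = 0,
    nwalkers: int | None = None,
    priors: Mapping[str, FamilyPrior] | None = None,
) -> PosteriorResult:
    """Fit the hierarchical model to one cohort's trial table by ensemble MCMC.

    ``samples``/``burn_in`` are ensemble sweeps per chain; each chain retains
    ``samples * n_walkers`` draws.  Deterministic for a fixed seed.
    """
    ev = build_likelihood(trials, spec, priors)
    post = run_ensemble_mcmc(
        ev._logpost_nc,
        _initializer(ev),
        ev.layout.ndim,
        ev.layout.names,
        chains=chains,
        samples=samples,
        burn_in=burn_in,
        seed=seed,
        nwalkers=nwalkers,
    )
    post.samples = ev.to_centered(post.samples)
    post.layout = ev.layout
    post.spec = spec
    return post


# ---------------------------------------------------------------------------
# Diagnostics and summaries
# ---------------------------------------------------------------------------


@dataclass
class ConvergenceReport:
    """Per-parameter split R-hat and bulk effective sample size."""

    table: pd.DataFrame          # columns: parameter, rhat, ess
    rhat_max: float
    ess_min: float

    @property
    def passed(self) -> bool:
        return bool((self.table["rhat"] < self.rhat_max).all()
                    and (self.table["ess"] > self.ess_min).all())


def diagnose(post: PosteriorResult, rhat_max: float = RHAT_MAX, ess_min: float = ESS_MIN) -> ConvergenceReport:
    """Rank-normalized split R-hat and bulk ESS, every walker as one chain."""
    import arviz as az

    chains = post.walker_chains()                     # (n_chains*n_walkers, sweeps, ndim)
    if chains.shape[0] < 2:
        raise DiagnosticsError("convergence diagnostics require at least 2 chains")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = az.convert_to_dataset(chains)  # dims: (chain, draw, parameter)
        rhat = az.rhat(ds)["x"].to_numpy()
        ess = az.ess(ds)["x"].to_numpy()
    table = pd.DataFrame({"parameter": post.param_names, "rhat": rhat, "ess": ess})
    return ConvergenceReport(table=table, rhat_max=rhat_max, ess_min=ess_min)


def shortest_hdi(x: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``prob`` of the pooled samples."""
    x = np.sort(np.asarray(x, dtype=float).ravel())
    if x.size == 0:
        raise ValueError("empty sample array")
    m = max(1, int(np.ceil(prob * x.size)))
    if m >= x.size:
        return float(x[0]), float(x[-1])
    widths = x[m:] - x[: x.size - m]
    lo = int(np.argmin(widths))
    return float(x[lo]), float(x[lo + m])


def _group_level_derived(df: pd.DataFrame) -> dict[str, pd.Series]:
    """Natural-scale group-level quantities derived sample-wise."""
    derived: dict[str, pd.Series] = {}
    if "mu_theta_a" in df:
        derived["group_theta_a"] = df["mu_theta_a"]
    if "mu_log_omega" in df:
        derived["group_omega"] = np.exp(df["mu_log_omega"])
    if "mu_log_theta_v" in df:
        derived["group_theta_v"] = np.exp(df["mu_log_theta_v"])
    for fam, name in [
        ("logit_lam_a_foc", "group_lam_a_focused"),
        ("logit_lam_a_div", "group_lam_a_divided"),
        ("logit_lam_a", "group_lam_a"),
        ("logit_lam_v", "group_lam_v"),
        ("logit_lam_v_foc", "group_lam_v_focused"),
        ("logit_lam_v_div", "group_lam_v_divided"),
    ]:
        if f"mu_{fam}" in df:
            derived[name] = expit(df[f"mu_{fam}"])
    if "group_lam_a_divided" in derived and "group_lam_a_focused" in derived:
        derived["lam_a_task_difference"] = (
            derived["group_lam_a_divided"] - derived["group_lam_a_focused"]
        )
    return derived


def summarize(
    post: PosteriorResult,
    derived: Mapping[str, Callable[[pd.DataFrame], pd.Series] | str] | None = None,
    prob: float = 0.95,
    check_convergence: bool = True,
) -> pd.DataFrame:
    """Posterior means and shortest 95%-HDIs for raw and derived quantities.

    Derived quantities are computed sample-wise on the pooled draws, either as
    callables on the draw table or as ``DataFrame.eval`` expressions.
    Group-level natural-scale parameters (threshold, width, lapses, and the
    divided-minus-focused auditory lapse difference) are always included.
    """
    if check_convergence and post.samples.shape[0] * post.samples.shape[2] >= 2:
        report = diagnose(post)
        if not report.passed:
            warnings.warn(
                "posterior summaries requested on a non-converged fit "
                f"(max rhat {report.table['rhat'].max():.3f}, "
                f"min ess {report.table['ess'].min():.0f})",
                stacklevel=2,
            )
    df = post.pooled_df().drop(columns="chain")
    if df.empty:
        raise ValueError("posterior contains no samples")
    columns: dict[str, pd.Series] = {name: df[name] for name in df.columns}
    columns.update(_group_level_derived(df))
    for name, expr in (derived or {}).items():
        columns[name] = df.eval(expr) if isinstance(expr, str) else expr(df)
    rows = []
    for name, series in columns.items():
        x = np.asarray(series, dtype=float)
        lo, hi = shortest_hdi(x, prob)
        rows.append({"parameter": name, "mean": float(x.mean()), "hdi_low": lo, "hdi_high": hi})
    return pd.DataFrame(rows)


def write_posterior(post: PosteriorResult, path, max_rows: int = 20_000) -> None:
    """Export pooled draws (chain column + one column per parameter) as CSV.

    Ensemble chains retain sweeps x walkers draws; the export is strided down
    to at most ``max_rows`` rows to keep files reviewable.
    """
    df = post.pooled_df()
    stride = max(1, len(df) // max_rows)
    df.iloc[::stride].to_csv(path, index=False, float_format="%.6g")


def write_summary(summary: pd.DataFrame, path) -> None:
    summary.to_csv(path, index=False, float_format="%.6g")
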