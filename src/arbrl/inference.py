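"""Model fitting and comparison.

Per-subject maximum-likelihood fitting of any model variant (multi-start
bounded L-BFGS-B over the variant's free parameters), BIC-based evidence,
random-effects Bayesian model selection with exceedance probabilities
(variational Dirichlet scheme), and parameter / model recovery harnesses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .agent import ArbitrationAgent
from .config import TaskConfig
from .dataset import BehavioralDataset, DatasetError
from .likelihood_kernel import pack_params, replay_loglik
from .model_space import ModelVariantSpec
from .task_env import StateSpaceModel, build_state_space


def sequence_likelihood(
    agent: ArbitrationAgent, dataset: BehavioralDataset
) -> np.ndarray:
    """Per-choice log-likelihoods (n_trials, 2) of the recorded choices.

    Replays every session deterministically: the agent observes the recorded
    token values, conditions, transitions and rewards; the log-probability of
    each recorded choice is taken from the softmax before the trial's
    updates.  Side-effect-free with respect to the passed agent.
    """
    arrays = dataset.session_arrays()
    if np.any(arrays["a1"] < 0) or np.any(arrays["a2"] < 0):
        raise DatasetError("unmapped action name in dataset")
    logp, _ = replay_loglik(
        agent.spec, agent.params, agent.model, arrays,
        pin_pmb=agent.pin_pmb, z_override=agent.z_override,
    )
    if not np.all(np.isfinite(logp)):
        raise DatasetError("non-finite log-likelihood (recorded choice unavailable?)")
    return logp


@dataclass
class FitResult:
    """One (subject, variant) maximum-likelihood fit."""

    subject: str
    variant_id: str
    params: dict[str, float]
    nll: float                     # negative log-likelihood, nats
    n_trials: int
    n_obs: int                     # choices entering the likelihood (2/trial)
    bic: float
    log_evidence: float            # -BIC/2, the evidence fed to BMS
    n_starts: int
    converged: bool
    start_nlls: list[float] = field(default_factory=list)

    def as_row(self) -> dict:
        return {
            "subject": self.subject, "variant_id": self.variant_id,
            "nll": self.nll, "bic": self.bic, "log_evidence": self.log_evidence,
            "n_trials": self.n_trials, "n_obs": self.n_obs,
            "converged": self.converged,
            **{f"param_{k}": v for k, v in self.params.items()},
        }


def fit_subject(
    spec: ModelVariantSpec | str,
    dataset: BehavioralDataset,
    n_starts: int = 20,
    rng: np.random.Generator | int | None = 0,
    model: StateSpaceModel | None = None,
    config: TaskConfig | None = None,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    maxiter: int = 200,
    fixed: Mapping[str, float] | None = None,
) -> FitResult:
    """Fit one variant to one subject's data by multi-start L-BFGS-B.

    The first start is the bounds midpoint; the remaining ``n_starts - 1``
    are drawn uniformly within bounds from ``rng``, so a fixed seed gives a
    reproducible fit.  Parameters named in ``fixed`` are pinned at the given
    values and excluded from optimization (and from the BIC's free-parameter
    count).  The result is flagged unconverged only if every start fails.
    """
    if isinstance(spec, str):
        spec = ModelVariantSpec.from_id(spec)
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    rng = np.random.default_rng(rng)
    model = model or build_state_space(config)
    arrays = dataset.session_arrays()
    n_trials = len(arrays["a1"])
    n_obs = 2 * n_trials
    fixed = dict(fixed or {})
    unknown = set(fixed) - set(spec.param_names)
    if unknown:
        raise ValueError(f"fixed parameters not in variant: {sorted(unknown)}")
    names = tuple(n for n in spec.param_names if n not in fixed)
    all_bounds = dict(zip(spec.param_names, spec.param_bounds(bounds)))
    bnds = np.array([all_bounds[n] for n in names])

    def nll(x: np.ndarray) -> float:
        theta = pack_params(spec, {**fixed, **dict(zip(names, x))})
        logp, _ = replay_loglik(spec, theta, model, arrays)
        return -float(logp.sum())

    best = None
    start_nlls = []
    any_ok = False
    for k in range(n_starts):
        if k == 0:
            x0 = bnds.mean(axis=1)
        else:
            x0 = rng.uniform(bnds[:, 0], bnds[:, 1])
        res = optimize.minimize(
            nll, x0, method="L-BFGS-B", bounds=bnds,
            options={"maxiter": maxiter},
        )
        start_nlls.append(float(res.fun))
        any_ok = any_ok or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    k_free = len(names)
    bic = 2.0 * float(best.fun) + k_free * np.log(n_obs)
    subjects = dataset.subjects
    est = {**fixed, **dict(zip(names, map(float, best.x)))}
    return FitResult(
        subject=subjects[0] if len(subjects) == 1 else "+".join(subjects),
        variant_id=spec.variant_id,
        params={n: est[n] for n in spec.param_names},
        nll=float(best.fun), n_trials=n_trials, n_obs=n_obs,
        bic=bic, log_evidence=-bic / 2.0,
        n_starts=n_starts, converged=any_ok, start_nlls=start_nlls,
    )


@dataclass
class BMSResult:
    """Random-effects Bayesian model selection output."""

    variant_ids: list[str]
    alpha: np.ndarray              # Dirichlet concentrations
    expected_freq: np.ndarray      # E[model frequency]
    exceedance: np.ndarray         # P(model is the most frequent)
    n_subjects: int

    def as_dict(self) -> dict:
        return {
            "variant_ids": self.variant_ids,
            "alpha": self.alpha.tolist(),
            "expected_freq": self.expected_freq.tolist(),
            "exceedance": self.exceedance.tolist(),
            "n_subjects": self.n_subjects,
        }


def bms(
    log_evidence: np.ndarray | pd.DataFrame,
    variant_ids: Sequence[str] | None = None,
    alpha0: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 10_000,
    n_samples: int = 100_000,
    rng: np.random.Generator | int | None = 0,
) -> BMSResult:
    """Random-effects BMS over a (subjects x models) log-evidence matrix.

    Variational update of the Dirichlet concentrations (prior alpha0 = 1) to
    convergence, then exceedance probabilities by Monte-Carlo draws from the
    posterior Dirichlet.
    """
    if isinstance(log_evidence, pd.DataFrame):
        variant_ids = list(log_evidence.columns)
        log_evidence = log_evidence.to_numpy(float)
    lme = np.asarray(log_evidence, float)
    if lme.ndim != 2 or lme.shape[0] < 1 or lme.shape[1] < 2:
        raise ValueError("need a (subjects x >=2 models) evidence matrix")
    if not np.all(np.isfinite(lme)):
        raise ValueError("log-evidence matrix contains non-finite entries")
    n, k = lme.shape
    if variant_ids is None:
        variant_ids = [f"model{j}" for j in range(k)]
    alpha = np.full(k, alpha0, float)
    for _ in range(max_iter):
        w = lme + special.digamma(alpha) - special.digamma(alpha.sum())
        w = w - w.max(axis=1, keepdims=True)
        u = np.exp(w)
        u /= u.sum(axis=1, keepdims=True)
        alpha_new = alpha0 + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    rng = np.random.default_rng(rng)
    draws = rng.dirichlet(alpha, size=n_samples)
    exceedance = np.bincount(np.argmax(draws, axis=1), minlength=k) / n_samples
    return BMSResult(
        variant_ids=list(variant_ids), alpha=alpha,
        expected_freq=alpha / alpha.sum(), exceedance=exceedance,
        n_subjects=n,
    )


def recovery_report(
    true_params: Sequence[Mapping[str, float]],
    fits: Sequence[FitResult],
    param_names: Sequence[str],
) -> pd.DataFrame:
    """Per-parameter Pearson correlation and bias between generative and
    recovered values across agents."""
    rows = []
    for name in param_names:
        t = np.array([p[name] for p in true_params], float)
        r_ = np.array([f.params[name] for f in fits], float)
        if len(t) >= 3 and t.std() > 0 and r_.std() > 0:
            r, p = stats.pearsonr(t, r_)
        else:
            r, p = np.nan, np.nan
        rows.append({
            "parameter": name, "r": float(r), "p": float(p),
            "bias": float(np.mean(r_ - t)), "n": len(t),
            "true_sd": float(t.std()), "recovered_sd": float(r_.std()),
        })
    return pd.DataFrame(rows)


def parameter_recovery(
    spec: ModelVariantSpec | str,
    n_agents: int,
    trials_per_session: int = 100,
    n_sessions: int = 4,
    rng: np.random.Generator | int | None = 0,
    n_starts: int = 3,
    config: TaskConfig | None = None,
    params_list: Sequence[Mapping[str, float]] | None = None,
) -> tuple[pd.DataFrame, list[Mapping[str, float]], list[FitResult]]:
    """Simulate agents under known parameters, refit, and report recovery.

    Generative parameters are drawn from the cohort sampling ranges unless
    ``params_list`` is given.  Returns (report, true parameter sets, fits).
    """
    from .synthetic_data import sample_generative_params, simulate_subject
    from .model_space import instantiate

    if isinstance(spec, str):
        spec = ModelVariantSpec.from_id(spec)
    rng = np.random.default_rng(rng)
    config = config or TaskConfig()
    model = build_state_space(config)
    true_params: list[Mapping[str, float]] = []
    fits: list[FitResult] = []
    for i in range(n_agents):
        params = (dict(params_list[i]) if params_list is not None
                  else sample_generative_params(spec, rng))
        agent = instantiate(spec, params, model=model)
        ds, _ = simulate_subject(
            agent, config, f"rec{i:03d}", rng,
            n_sessions=n_sessions, trials_per_session=trials_per_session,
            model=model,
        )
        fit = fit_subject(
            spec, ds, n_starts=n_starts,
            rng=np.random.default_rng(rng.integers(2**31)),
            model=model,
        )
        true_params.append(params)
        fits.append(fit)
    return recovery_report(true_params, fits, spec.param_names), true_params, fits


def model_recovery(
    specs: Sequence[ModelVariantSpec | str],
    rng: np.random.Generator | int | None = 0,
    n_agents: int = 8,
    trials_per_session: int = 100,
    n_sessions: int = 4,
    n_starts: int = 2,
    config: TaskConfig | None = None,
) -> pd.DataFrame:
    """Exceedance confusion matrix: rows = generating variant, columns =
    exceedance probability of each candidate after refitting and BMS."""
    from .synthetic_data import CohortSpec, simulate_cohort

    specs = [ModelVariantSpec.from_id(s) if isinstance(s, str) else s for s in specs]
    if len(specs) == 1:  # degenerate subset: exceedance is trivially 1
        return pd.DataFrame([{"generating": specs[0].variant_id,
                              specs[0].variant_id: 1.0}])
    if len(specs) > 6:
        raise ValueError("model recovery expects at most 6 candidate variants")
    rng = np.random.default_rng(rng)
    config = config or TaskConfig()
    model = build_state_space(config)
    rows = []
    for gen in specs:
        cohort = CohortSpec(
            variant_id=gen.variant_id, n_subjects=n_agents,
            n_sessions=n_sessions, trials_per_session=trials_per_session,
            master_seed=int(rng.integers(2**31)),
        )
        dataset, _, _ = simulate_cohort(cohort, config, model)
        lme = np.zeros((n_agents, len(specs)))
        for i, subj in enumerate(dataset.subjects):
            sub_ds = dataset.for_subject(subj)
            for j, cand in enumerate(specs):
                fit = fit_subject(
                    cand, sub_ds, n_starts=n_starts,
                    rng=np.random.default_rng(rng.integers(2**31)),
                    model=model,
                )
                lme[i, j] = fit.log_evidence
        res = bms(lme, [s.variant_id for s in specs],
                  rng=np.random.default_rng(rng.integers(2**31)))
        rows.append({"generating": gen.variant_id,
                     **dict(zip(res.variant_ids, res.exceedance))})
    return pd.DataFrame(rows)


def fits_to_frame(fits: Sequence[FitResult]) -> pd.DataFrame:
    return pd.DataFrame([f.as_row() for f in fits])


def evidence_matrix(fits: Sequence[FitResult]) -> pd.DataFrame:
    """(subjects x variants) log-evidence table from a flat list of fits."""
    df = fits_to_frame(fits)
    return df.pivot(index="subject", columns="variant_id", values="log_evidence")
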