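"""Hierarchical Bayesian estimation of discounting preferences.

The preference-uncertainty (KU) model is fit per experimental block and
per participant group. Each subject's trialwise choices are Bernoulli
with P(LL) = Phi((x - km_i)/ku_i), where x is the pair's indifference
log10 rate; subject parameters are drawn from group-level truncated
normals (km upper-truncated at 0, ku lower-truncated at 0), whose means
carry N(0, 3) priors and standard deviations half-Cauchy(0, 2) priors.
Priors are reset for every block, and groups are fit separately with
identical priors.

Inference uses an adaptive Metropolis-within-Gibbs sampler, vectorized
over chains and subjects: subject-level (km, ku) pairs are proposed
jointly (their full conditionals are independent across subjects given
the group parameters), then each group-level parameter is updated by a
scalar random-walk step, with proposal scales adapted during warmup
only. The default configuration — 4 chains, 2,000 warmup and 2,000
retained iterations each — yields 8,000 posterior draws. Convergence is
monitored with the split-chain Gelman–Rubin statistic.

The point-preference (KT) model, used only to set each participant's
baseline rate for constructing the simulated others, is fit by exact
grid integration over (k, t) in [-4, 0] x [-1, 1] with a uniform prior.

Both models are exposed as sklearn-style estimators
(:class:`HierarchicalKUModel`, :class:`KTGridModel`); the module-level
``fit_ku_hierarchical`` / ``fit_kt_grid`` functions are thin wrappers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, log_ndtr, ndtr
from sklearn.base import BaseEstimator

from .core import LL, ChoicePair, KTParams, hyperbolic_value

__all__ = [
    "PriorSpec",
    "MCMCConfig",
    "GroupPosterior",
    "HierarchicalKUModel",
    "KTGridModel",
    "fit_ku_hierarchical",
    "fit_kt_grid",
    "rhat",
    "posterior_summary",
]


@dataclass(frozen=True)
class PriorSpec:
    """Weakly-informative group-level priors, identical across groups."""

    mu_loc: float = 0.0
    mu_scale: float = 3.0
    sigma_scale: float = 2.0  # half-Cauchy scale (location fixed at 0)

    def __post_init__(self) -> None:
        if self.mu_scale <= 0 or self.sigma_scale <= 0:
            raise ValueError("prior scales must be positive")


@dataclass(frozen=True)
class MCMCConfig:
    chains: int = 4
    warmup: int = 2000
    iters: int = 2000

    def __post_init__(self) -> None:
        if self.chains < 1 or self.warmup < 1 or self.iters < 1:
            raise ValueError("chains, warmup and iters must be positive")


@dataclass
class GroupPosterior:
    """MCMC draws for one group x one block, with diagnostics.

    ``draws`` maps parameter names to arrays: group-level parameters are
    (chains, iters); subject-level 'km' and 'ku' are (chains, iters,
    n_subjects), columns ordered as ``subjects``.
    """

    draws: Dict[str, np.ndarray]
    subjects: List
    group_label: Optional[str] = None
    block: Optional[int] = None
    rhat: Dict[str, np.ndarray] = field(default_factory=dict)
    accept_rates: Dict[str, float] = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        a = self.draws["km"]
        return a.shape[0] * a.shape[1]

    @property
    def max_rhat(self) -> float:
        vals = [np.max(v) for v in self.rhat.values()]
        return float(np.max(vals)) if vals else float("nan")


def rhat(chains: np.ndarray) -> float:
    """Split-chain Gelman–Rubin potential-scale-reduction statistic.

    ``chains`` has shape (n_chains, n_draws). Each chain is split in
    half before computing the between/within variance ratio. Chains with
    zero total variance (all draws identical) return 1.0 by convention.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need >= 2 chains with >= 2 draws each")
    n = x.shape[1] // 2
    halves = np.concatenate([x[:, :n], x[:, n : 2 * n]], axis=0)  # (2C, n)
    W = halves.var(axis=1, ddof=1).mean()
    if W == 0.0:
        return 1.0
    B_over_n = halves.mean(axis=1).var(ddof=1)
    var_plus = (n - 1) / n * W + B_over_n
    return float(np.sqrt(var_plus / W))


# ---------------------------------------------------------------------------
# Metropolis-within-Gibbs sampler


def _choice_loglik(km, ku, x, y, mask):
    """Bernoulli log likelihood per (chain, subject).

    km, ku: (C, S); x (thresholds), y (LL indicator), mask: (S, T).
    """
    z = (x[None, :, :] - km[:, :, None]) / ku[:, :, None]
    ll = np.where(y[None, :, :], log_ndtr(z), log_ndtr(-z))
    return np.where(mask[None, :, :], ll, 0.0).sum(axis=-1)


def _log_half_cauchy(sigma, scale):
    return -np.log1p((sigma / scale) ** 2)  # up to a constant


def _trunc_log_norm_km(mu, sigma):
    """log of the mass a N(mu, sigma^2) assigns to (-inf, 0)."""
    return log_ndtr(-mu / sigma)


def _trunc_log_norm_ku(mu, sigma):
    """log of the mass a N(mu, sigma^2) assigns to (0, inf)."""
    return log_ndtr(mu / sigma)


def _init_state(x, y, mask, chains, rng):
    """Overdispersed start values from crude per-subject estimates."""
    S = x.shape[0]
    frac_ll = np.array(
        [y[i, mask[i]].mean() if mask[i].any() else 0.5 for i in range(S)]
    )
    km0 = np.empty(S)
    for i in range(S):
        xi = x[i, mask[i]]
        q = np.clip(1.0 - frac_ll[i], 0.02, 0.98)
        km0[i] = np.quantile(xi, q) if xi.size else -2.0
    km0 = np.clip(km0, -5.5, -0.05)
    km = np.clip(km0[None, :] + 0.3 * rng.standard_normal((chains, S)), None, -1e-3)
    ku = 0.5 * np.exp(0.3 * rng.standard_normal((chains, S)))
    mu_km = km.mean(axis=1) + 0.2 * rng.standard_normal(chains)
    sig_km = km.std(axis=1) + 0.3
    mu_ku = ku.mean(axis=1)
    sig_ku = ku.std(axis=1) + 0.3
    return km, ku, mu_km, sig_km, mu_ku, sig_ku


def _sample_ku(x, y, mask, priors: PriorSpec, cfg: MCMCConfig, seed: int):
    """Run the sampler; returns the retained draws and acceptance rates."""
    rng = np.random.default_rng(seed)
    C, S = cfg.chains, x.shape[0]
    km, ku, mu_km, sig_km, mu_ku, sig_ku = _init_state(x, y, mask, C, rng)
    loglik = _choice_loglik(km, ku, x, y, mask)

    # adaptive proposal scales (log) — frozen after warmup
    ls_subj = np.full((C, S), np.log(0.25))
    ls_group = np.full((C, 4), np.log(0.25))
    target_subj, target_group = 0.30, 0.44

    n_iter = cfg.warmup + cfg.iters
    out_km = np.empty((C, cfg.iters, S))
    out_ku = np.empty((C, cfg.iters, S))
    out_group = {k: np.empty((C, cfg.iters)) for k in ("mu_km", "sigma_km", "mu_ku", "sigma_ku")}
    acc_subj_total = 0.0
    acc_group_total = np.zeros(4)

    def group_cond_km(mu, sigma):
        z2 = ((km - mu[:, None]) / sigma[:, None]) ** 2
        return (
            -S * np.log(sigma)
            - 0.5 * z2.sum(axis=1)
            - S * _trunc_log_norm_km(mu, sigma)
        )

    def group_cond_ku(mu, sigma):
        z2 = ((ku - mu[:, None]) / sigma[:, None]) ** 2
        return (
            -S * np.log(sigma)
            - 0.5 * z2.sum(axis=1)
            - S * _trunc_log_norm_ku(mu, sigma)
        )

    for it in range(n_iter):
        adapting = it < cfg.warmup
        gamma = min(0.05, 2.0 / np.sqrt(it + 1.0)) if adapting else 0.0

        # --- subject-level joint (km_i, ku_i) random-walk updates -------
        step = np.exp(ls_subj)
        km_prop = km + step * rng.standard_normal((C, S))
        ku_prop = ku + step * rng.standard_normal((C, S))
        valid = (km_prop < 0) & (ku_prop > 0)
        km_c = np.where(valid, km_prop, km)
        ku_c = np.where(valid, ku_prop, ku)
        loglik_c = _choice_loglik(km_c, ku_c, x, y, mask)
        dprior = 0.5 * (
            ((km - mu_km[:, None]) / sig_km[:, None]) ** 2
            - ((km_c - mu_km[:, None]) / sig_km[:, None]) ** 2
            + ((ku - mu_ku[:, None]) / sig_ku[:, None]) ** 2
            - ((ku_c - mu_ku[:, None]) / sig_ku[:, None]) ** 2
        )
        log_alpha = np.where(valid, loglik_c - loglik + dprior, -np.inf)
        accept = np.log(rng.random((C, S))) < log_alpha
        km = np.where(accept, km_c, km)
        ku = np.where(accept, ku_c, ku)
        loglik = np.where(accept, loglik_c, loglik)
        if adapting:
            ls_subj += gamma * (accept.astype(float) - target_subj)
        else:
            acc_subj_total += accept.mean()

        # --- group-level scalar random-walk updates --------------------
        hyper = priors
        for j, name in enumerate(("mu_km", "sigma_km", "mu_ku", "sigma_ku")):
            step_g = np.exp(ls_group[:, j])
            eps = rng.standard_normal(C)
            if name == "mu_km":
                prop = mu_km + step_g * eps
                la = (
                    group_cond_km(prop, sig_km)
                    - group_cond_km(mu_km, sig_km)
                    - 0.5 * ((prop - hyper.mu_loc) / hyper.mu_scale) ** 2
                    + 0.5 * ((mu_km - hyper.mu_loc) / hyper.mu_scale) ** 2
                )
                acc = np.log(rng.random(C)) < la
                mu_km = np.where(acc, prop, mu_km)
            elif name == "sigma_km":
                prop = sig_km * np.exp(step_g * eps)  # log-scale walk
                la = (
                    group_cond_km(mu_km, prop)
                    - group_cond_km(mu_km, sig_km)
                    + _log_half_cauchy(prop, hyper.sigma_scale)
                    - _log_half_cauchy(sig_km, hyper.sigma_scale)
                    + np.log(prop / sig_km)  # Jacobian of the log walk
                )
                acc = np.log(rng.random(C)) < la
                sig_km = np.where(acc, prop, sig_km)
            elif name == "mu_ku":
                prop = mu_ku + step_g * eps
                la = (
                    group_cond_ku(prop, sig_ku)
                    - group_cond_ku(mu_ku, sig_ku)
                    - 0.5 * ((prop - hyper.mu_loc) / hyper.mu_scale) ** 2
                    + 0.5 * ((mu_ku - hyper.mu_loc) / hyper.mu_scale) ** 2
                )
                acc = np.log(rng.random(C)) < la
                mu_ku = np.where(acc, prop, mu_ku)
            else:
                prop = sig_ku * np.exp(step_g * eps)
                la = (
                    group_cond_ku(mu_ku, prop)
                    - group_cond_ku(mu_ku, sig_ku)
                    + _log_half_cauchy(prop, hyper.sigma_scale)
                    - _log_half_cauchy(sig_ku, hyper.sigma_scale)
                    + np.log(prop / sig_ku)
                )
                acc = np.log(rng.random(C)) < la
                sig_ku = np.where(acc, prop, sig_ku)
            if adapting:
                ls_group[:, j] += gamma * (acc.astype(float) - target_group)
            else:
                acc_group_total[j] += acc.mean()

        if not adapting:
            i = it - cfg.warmup
            out_km[:, i, :] = km
            out_ku[:, i, :] = ku
            out_group["mu_km"][:, i] = mu_km
            out_group["sigma_km"][:, i] = sig_km
            out_group["mu_ku"][:, i] = mu_ku
            out_group["sigma_ku"][:, i] = sig_ku

    draws = {"km": out_km, "ku": out_ku, **out_group}
    accept_rates = {
        "subject": acc_subj_total / cfg.iters,
        **{
            n: acc_group_total[j] / cfg.iters
            for j, n in enumerate(("mu_km", "sigma_km", "mu_ku", "sigma_ku"))
        },
    }
    return draws, accept_rates


# ---------------------------------------------------------------------------
# Estimators


def _column(X: pd.DataFrame, *names: str) -> pd.Series:
    for n in names:
        if n in X.columns:
            return X[n]
    raise KeyError(f"trial table needs one of columns {names}")


def _trial_arrays(X: pd.DataFrame):
    """Pivot a tidy trial table into padded (S, T) arrays."""
    subj = _column(X, "subject_id", "subject")
    ss = _column(X, "ss_amount").to_numpy(float)
    ll = _column(X, "ll_amount").to_numpy(float)
    delay = _column(X, "delay_days", "delay").to_numpy(float)
    if np.any(ll <= ss) or np.any(delay < 1):
        raise ValueError("every trial needs ll_amount > ss_amount and delay >= 1")
    thresh = np.log10((ll / ss - 1.0) / delay)
    y = (_column(X, "choice").to_numpy() == LL)
    subjects = list(pd.unique(subj))
    groups = {s: np.flatnonzero((subj == s).to_numpy()) for s in subjects}
    T = max(len(ix) for ix in groups.values())
    S = len(subjects)
    xpad = np.zeros((S, T))
    ypad = np.zeros((S, T), dtype=bool)
    mask = np.zeros((S, T), dtype=bool)
    for i, s in enumerate(subjects):
        ix = groups[s]
        xpad[i, : len(ix)] = thresh[ix]
        ypad[i, : len(ix)] = y[ix]
        mask[i, : len(ix)] = True
    return subjects, xpad, ypad, mask


class HierarchicalKUModel(BaseEstimator):
    """Hierarchical Bayesian preference-uncertainty discounting model.

    Fit to a tidy trial table (one group, one block) with columns
    ``subject_id, ss_amount, ll_amount, delay_days, choice``; every
    subject needs at least one decision.

    Parameters
    ----------
    chains, warmup, draws : MCMC schedule; the default 4 x 2000/2000
        retains 8,000 posterior draws.
    priors : PriorSpec, weakly-informative group-level priors.
    seed : base seed for the sampler's generator.
    rhat_warn : warn (not fail) when the maximum split-R-hat exceeds
        this; convergence is considered clean at <= 1.01.

    Attributes
    ----------
    posterior_ : GroupPosterior with all draws and diagnostics.
    km_mean_, ku_mean_ : per-subject posterior means (pandas Series).
    summary_ : tidy per-subject summary table.
    rhat_ : dict of split-R-hat values per parameter.
    converged_ : True when max R-hat <= rhat_warn.
    """

    def __init__(
        self,
        chains: int = 4,
        warmup: int = 2000,
        draws: int = 2000,
        priors: Optional[PriorSpec] = None,
        seed: int = 0,
        rhat_warn: float = 1.05,
    ) -> None:
        self.chains = chains
        self.warmup = warmup
        self.draws = draws
        self.priors = priors
        self.seed = seed
        self.rhat_warn = rhat_warn

    def fit(self, X: pd.DataFrame, y=None, *, group_label=None, block=None):
        if len(X) == 0:
            raise ValueError("empty trial table")
        subjects, xpad, ypad, mask = _trial_arrays(X)
        priors = self.priors if self.priors is not None else PriorSpec()
        cfg = MCMCConfig(chains=self.chains, warmup=self.warmup, iters=self.draws)
        draws, acc = _sample_ku(xpad, ypad, mask, priors, cfg, self.seed)

        diags: Dict[str, np.ndarray] = {}
        for name in ("mu_km", "sigma_km", "mu_ku", "sigma_ku"):
            diags[name] = np.array(rhat(draws[name]))
        for name in ("km", "ku"):
            diags[name] = np.array(
                [rhat(draws[name][:, :, i]) for i in range(len(subjects))]
            )
        self.posterior_ = GroupPosterior(
            draws=draws,
            subjects=subjects,
            group_label=group_label,
            block=block,
            rhat=diags,
            accept_rates=acc,
        )
        self.rhat_ = diags
        self.converged_ = bool(self.posterior_.max_rhat <= self.rhat_warn)
        if not self.converged_:
            warnings.warn(
                f"max split-R-hat {self.posterior_.max_rhat:.3f} exceeds "
                f"{self.rhat_warn}; inspect chains before trusting estimates",
                stacklevel=2,
            )
        self.km_mean_ = pd.Series(
            draws["km"].mean(axis=(0, 1)), index=subjects, name="km"
        )
        self.ku_mean_ = pd.Series(
            draws["ku"].mean(axis=(0, 1)), index=subjects, name="ku"
        )
        self.summary_ = posterior_summary(self.posterior_)
        return self

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """P(choose LL) per trial row at the posterior-mean subject parameters."""
        if not hasattr(self, "posterior_"):
            raise RuntimeError("fit the model first")
        subj = _column(X, "subject_id", "subject")
        ss = _column(X, "ss_amount").to_numpy(float)
        ll = _column(X, "ll_amount").to_numpy(float)
        delay = _column(X, "delay_days", "delay").to_numpy(float)
        thresh = np.log10((ll / ss - 1.0) / delay)
        km = self.km_mean_.reindex(subj).to_numpy()
        ku = self.ku_mean_.reindex(subj).to_numpy()
        return ndtr((thresh - km) / ku)


def posterior_summary(gp: GroupPosterior) -> pd.DataFrame:
    """Tidy per-subject posterior summary: mean, sd, central 95% interval."""
    rows = []
    for pname in ("km", "ku"):
        arr = gp.draws[pname].reshape(-1, len(gp.subjects))
        lo, hi = np.percentile(arr, [2.5, 97.5], axis=0)
        for i, s in enumerate(gp.subjects):
            rows.append(
                {
                    "subject_id": s,
                    "group": gp.group_label,
                    "block": gp.block,
                    "parameter": pname,
                    "mean": arr[:, i].mean(),
                    "sd": arr[:, i].std(ddof=1),
                    "q2.5": lo[i],
                    "q97.5": hi[i],
                    "rhat": float(gp.rhat[pname][i]) if pname in gp.rhat else np.nan,
                }
            )
    return pd.DataFrame(rows)


def fit_ku_hierarchical(
    decisions: pd.DataFrame,
    priors: Optional[PriorSpec] = None,
    mcmc_config: Optional[MCMCConfig] = None,
    seed: int = 0,
    group_label=None,
    block=None,
) -> GroupPosterior:
    """Functional wrapper over :class:`HierarchicalKUModel`."""
    cfg = mcmc_config or MCMCConfig()
    model = HierarchicalKUModel(
        chains=cfg.chains, warmup=cfg.warmup, draws=cfg.iters, priors=priors, seed=seed
    )
    model.fit(decisions, group_label=group_label, block=block)
    return model.posterior_


class KTGridModel(BaseEstimator):
    """Point-preference (KT) model fit by grid integration.

    Uniform prior over k in [-4, 0] and t in [-1, 1]; exact posterior on
    the grid under the softmax choice likelihood. The posterior-mean k
    is the baseline rate from which the simulated others are built.
    """

    def __init__(self, n_k: int = 81, n_t: int = 41) -> None:
        self.n_k = n_k
        self.n_t = n_t

    def fit(self, X, y=None):
        k_grid = np.linspace(-4.0, 0.0, self.n_k)
        t_grid = np.linspace(-1.0, 1.0, self.n_t)
        if isinstance(X, pd.DataFrame):
            if len(X) == 0:
                raise ValueError("empty trial table")
            ss = _column(X, "ss_amount").to_numpy(float)
            ll = _column(X, "ll_amount").to_numpy(float)
            delay = _column(X, "delay_days", "delay").to_numpy(float)
            y_ll = (_column(X, "choice").to_numpy() == LL)
        else:  # sequence of (ChoicePair, choice)
            if len(X) == 0:
                raise ValueError("no decisions")
            ss = np.array([p.ss.amount for p, _ in X], float)
            ll = np.array([p.ll.amount for p, _ in X], float)
            delay = np.array([p.ll.delay for p, _ in X], float)
            y_ll = np.array([c == LL for _, c in X])
        K = 10.0 ** k_grid[:, None, None]
        T = 10.0 ** t_grid[None, :, None]
        v_ll = ll[None, None, :] / (1.0 + K * delay[None, None, :])
        p_ll = expit(T * (v_ll - ss[None, None, :]))
        p_ll = np.clip(p_ll, 1e-12, 1 - 1e-12)
        loglik = np.where(y_ll, np.log(p_ll), np.log1p(-p_ll)).sum(axis=-1)
        post = np.exp(loglik - loglik.max())
        post /= post.sum()
        self.k_grid_, self.t_grid_ = k_grid, t_grid
        self.posterior_grid_ = post
        self.k_mean_ = float((post.sum(axis=1) * k_grid).sum())
        self.t_mean_ = float((post.sum(axis=0) * t_grid).sum())
        return self

    @property
    def params_(self) -> KTParams:
        return KTParams(k=self.k_mean_, t=self.t_mean_)


def fit_kt_grid(decisions, n_k: int = 81, n_t: int = 41):
    """Fit the KT grid model; returns (posterior-mean KTParams, model)."""
    model = KTGridModel(n_k=n_k, n_t=n_t).fit(decisions)
    return model.params_, model
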