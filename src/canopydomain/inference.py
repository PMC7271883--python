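"""Bayesian hierarchical models of cage-level heights and survival.

Two models, mirroring the field analysis:

* **Height model** — the per-cage mean heights of grasshopper (MEFE) and
  spider (PIMI) are bivariate normal with a residual correlation; the linear
  predictor has species intercepts, year and block-within-year random
  intercepts, and warming (T), woodlouse (W) and T x W effects.  Priors are
  weakly-informative Student-t intercepts centred on the species' canopy
  heights (t3(69, 10) grasshopper, t3(60, 28) spider), informative normal
  priors for the warming effects from earlier published data
  (N(-0.13, 16.1) grasshopper, N(-12.7, 9.4) spider), flat-ish N(0, 100)
  woodlouse and interaction effects, half-t3 scales, and a uniform (LKJ(1))
  residual correlation.

* **Survival model** — survivors out of the grasshoppers stocked in each
  cage are binomial with logit(p) = intercept + year and block-within-year
  random intercepts + beta_A x (overlap-based attack rate); beta_A ~ N(0, 10),
  intercept and scales t3(0, 10).

Sampling uses the affine-invariant ensemble sampler (emcee).  In the
Gaussian height model the year/block random intercepts are marginalized
analytically, so the sampler only walks the fixed effects and
variance/correlation parameters; the binomial model samples non-centred
random-effect deviations explicitly.  Convergence is checked with
split-chain R-hat and bulk effective sample size via arviz.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .domains import fit_domain, pairwise_attack_rate, InsufficientDataError

logger = logging.getLogger(__name__)

__all__ = [
    "HeightModelSpec", "SurvivalModelSpec", "PosteriorSummary",
    "summarize_cages", "fit_height_model", "fit_survival_model",
    "sample_height_prior", "sample_survival_prior",
]


# ---------------------------------------------------------------------------
# model specifications (prior hyperparameters)

@dataclass(frozen=True)
class HeightModelSpec:
    """Priors of the bivariate height model (centres/scales in cm)."""

    alpha_mefe: tuple[float, float] = (69.0, 10.0)   # t3 centre, scale
    alpha_pimi: tuple[float, float] = (60.0, 28.0)
    sigma_mefe_scale: float = 10.0                    # half-t3 scale
    sigma_pimi_scale: float = 28.0
    beta_t_mefe: tuple[float, float] = (-0.13, 16.1)  # normal mean, sd
    beta_t_pimi: tuple[float, float] = (-12.7, 9.4)
    beta_w_sd: float = 100.0
    beta_tw_sd: float = 100.0
    tau_mefe_scale: float = 10.0                      # half-t3, year & block
    tau_pimi_scale: float = 28.0
    lkj_eta: float = 1.0                              # uniform correlation

    param_names: tuple[str, ...] = (
        "alpha_MEFE", "alpha_PIMI",
        "beta_MEFE_T", "beta_PIMI_T",
        "beta_MEFE_W", "beta_PIMI_W",
        "beta_MEFE_TW", "beta_PIMI_TW",
        "sigma_MEFE", "sigma_PIMI", "rho",
        "tau_year_MEFE", "tau_year_PIMI",
        "tau_block_MEFE", "tau_block_PIMI",
    )


@dataclass(frozen=True)
class SurvivalModelSpec:
    """Priors of the binomial survival model (logit scale)."""

    alpha: tuple[float, float] = (0.0, 10.0)   # t3 centre, scale
    beta_a: tuple[float, float] = (0.0, 10.0)  # normal mean, sd
    tau_scale: float = 10.0                     # half-t3, year & block scales


@dataclass
class PosteriorSummary:
    """Posterior means, intervals and convergence diagnostics for one fit."""

    model: str
    params: pd.DataFrame          # index: parameter; mean, sd, q2.5, q97.5, rhat, ess
    converged: bool
    n_draws: int
    draws: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    def ci(self, name: str) -> tuple[float, float]:
        row = self.params.loc[name]
        return float(row["q2.5"]), float(row["q97.5"])

    def mean(self, name: str) -> float:
        return float(self.params.loc[name, "mean"])


# ---------------------------------------------------------------------------
# cage summaries

def summarize_cages(obs: pd.DataFrame,
                    survival: pd.DataFrame | None = None,
                    min_obs: int = 2) -> pd.DataFrame:
    """Collapse an observation table to one row per cage.

    Produces mean grasshopper/spider heights, the overlap-based attack rate
    from the cage's own fitted normal domains, the treatment flags, and (when
    a survival table is supplied) survivors/stocked.  Cages missing either
    focal species (< ``min_obs`` records) are excluded with a warning.
    """
    rows = []
    for cage_id, cage in obs.groupby("cage_id", sort=True):
        heights = {sp: cage.loc[cage["species"] == sp, "z_cm"].to_numpy()
                   for sp in ("MEFE", "PIMI")}
        if any(h.size < min_obs for h in heights.values()):
            logger.warning("cage %s lacks focal-species observations; excluded",
                           cage_id)
            continue
        try:
            dom_g = fit_domain(heights["MEFE"], "MEFE", "normal")
            dom_s = fit_domain(heights["PIMI"], "PIMI", "normal")
        except (InsufficientDataError, ValueError) as err:
            logger.warning("cage %s domain fit failed (%s); excluded",
                           cage_id, err)
            continue
        overlap = pairwise_attack_rate(dom_s, dom_g)
        first = cage.iloc[0]
        rows.append({
            "cage_id": cage_id,
            "block": first["block"],
            "year": int(first["year"]),
            "W": int(first["woodlice"]),
            "T": int(first["warmed"]),
            "L_MEFE": float(np.mean(heights["MEFE"])),
            "L_PIMI": float(np.mean(heights["PIMI"])),
            "A": float(overlap.attack_rate_density),
        })
    out = pd.DataFrame(rows)
    if survival is not None and not out.empty:
        out = out.merge(survival[["cage_id", "survivors", "stocked"]],
                        on="cage_id", how="left")
    return out


# ---------------------------------------------------------------------------
# fast prior densities

_T3_CONST = math.lgamma(2.0) - math.lgamma(1.5) - 0.5 * math.log(3.0 * math.pi)


def _t3_logpdf(x, loc, scale):
    z = (x - loc) / scale
    return _T3_CONST - math.log(scale) - 2.0 * np.log1p(z * z / 3.0)


def _norm_logpdf(x, loc, sd):
    z = (x - loc) / sd
    return -0.5 * z * z - math.log(sd) - 0.5 * math.log(2.0 * math.pi)


def _sample_t3(rng, loc, scale, size):
    return loc + scale * rng.standard_t(3, size)


def _sample_half_t3(rng, scale, size):
    return np.abs(scale * rng.standard_t(3, size))


# ---------------------------------------------------------------------------
# height model: marginal likelihood over random intercepts

class _HeightPosterior:
    """Log-posterior of the height model with random effects marginalized.

    Parameter vector (15): alpha_M, alpha_P, beta_MT, beta_PT, beta_MW,
    beta_PW, beta_MTW, beta_PTW, log sigma_M, log sigma_P, atanh rho,
    log tau_year_M, log tau_year_P, log tau_block_M, log tau_block_P.
    """

    def __init__(self, summaries: pd.DataFrame, spec: HeightModelSpec):
        self.spec = spec
        self.years = sorted(summaries["year"].unique())
        self.groups = []
        for year in self.years:
            g = summaries[summaries["year"] == year]
            n = len(g)
            blocks = g["block"].to_numpy()
            same_block = (blocks[:, None] == blocks[None, :]).astype(float)
            self.groups.append({
                "y": np.concatenate([g["L_MEFE"].to_numpy(dtype=float),
                                     g["L_PIMI"].to_numpy(dtype=float)]),
                "T": g["T"].to_numpy(dtype=float),
                "W": g["W"].to_numpy(dtype=float),
                "same_block": same_block,
                "ones": np.ones((n, n)),
                "eye": np.eye(n),
                "n": n,
            })

    def log_prior(self, TH: np.ndarray) -> np.ndarray:
        s = self.spec
        ok = (np.all(np.isfinite(TH), axis=1)
              & np.all(np.abs(TH[:, :8]) <= 1e4, axis=1)
              & np.all(np.abs(TH[:, 8:]) <= 12.0, axis=1))
        TH = np.where(ok[:, None], TH, 0.0)
        lp = _t3_logpdf(TH[:, 0], *s.alpha_mefe)
        lp = lp + _t3_logpdf(TH[:, 1], *s.alpha_pimi)
        lp = lp + _norm_logpdf(TH[:, 2], *s.beta_t_mefe)
        lp = lp + _norm_logpdf(TH[:, 3], *s.beta_t_pimi)
        lp = lp + _norm_logpdf(TH[:, 4], 0.0, s.beta_w_sd)
        lp = lp + _norm_logpdf(TH[:, 5], 0.0, s.beta_w_sd)
        lp = lp + _norm_logpdf(TH[:, 6], 0.0, s.beta_tw_sd)
        lp = lp + _norm_logpdf(TH[:, 7], 0.0, s.beta_tw_sd)
        # half-t3 scales sampled on the log scale: add log-Jacobian (= log x)
        for i, scale in ((8, s.sigma_mefe_scale), (9, s.sigma_pimi_scale),
                         (11, s.tau_mefe_scale), (12, s.tau_pimi_scale),
                         (13, s.tau_mefe_scale), (14, s.tau_pimi_scale)):
            x = np.exp(TH[:, i])
            lp = lp + math.log(2.0) + _t3_logpdf(x, 0.0, scale) + TH[:, i]
        # uniform correlation on (-1, 1), sampled as atanh(rho)
        rho = np.tanh(TH[:, 10])
        lp = lp + math.log(0.5) + np.log1p(-rho * rho)
        return np.where(ok, lp, -np.inf)

    def log_likelihood(self, TH: np.ndarray) -> np.ndarray:
        B = TH.shape[0]
        alpha = TH[:, 0:2]
        beta_t = TH[:, 2:4]
        beta_w = TH[:, 4:6]
        beta_tw = TH[:, 6:8]
        sig = np.exp(TH[:, 8:10])
        rho = np.tanh(TH[:, 10])
        tau_y = np.exp(TH[:, 11:13])
        tau_b = np.exp(TH[:, 13:15])
        ll = np.zeros(B)
        for g in self.groups:
            n = g["n"]
            design = np.stack([np.ones(n), g["T"], g["W"], g["T"] * g["W"]])
            mu = np.concatenate([
                np.stack([alpha[:, i], beta_t[:, i], beta_w[:, i],
                          beta_tw[:, i]], axis=1) @ design
                for i in (0, 1)
            ], axis=1)                                   # (B, 2n)
            resid = g["y"][None, :] - mu
            cov = np.empty((B, 2 * n, 2 * n))
            for i in (0, 1):
                cov[:, i * n:(i + 1) * n, i * n:(i + 1) * n] = (
                    tau_y[:, i, None, None] ** 2 * g["ones"]
                    + tau_b[:, i, None, None] ** 2 * g["same_block"]
                    + sig[:, i, None, None] ** 2 * g["eye"]
                )
            cross = (rho * sig[:, 0] * sig[:, 1])[:, None, None] * g["eye"]
            cov[:, :n, n:] = cross
            cov[:, n:, :n] = cross
            sign, logdet = np.linalg.slogdet(cov)
            bad = sign <= 0
            if np.any(bad):
                cov[bad] = np.eye(2 * n)
            v = np.linalg.solve(cov, resid[:, :, None])[:, :, 0]
            quad = np.einsum("bi,bi->b", resid, v)
            with np.errstate(invalid="ignore"):
                ll += -0.5 * (quad + logdet) - n * math.log(2.0 * math.pi)
            ll[bad] = -np.inf
        return ll

    def __call__(self, TH: np.ndarray):
        TH = np.asarray(TH, dtype=float)
        scalar = TH.ndim == 1
        TH = np.atleast_2d(TH)
        lp = self.log_prior(TH)
        out = np.full(TH.shape[0], -np.inf)
        ok = np.isfinite(lp)
        if np.any(ok):
            ll = self.log_likelihood(TH[ok])
            out[ok] = lp[ok] + ll
        out[~np.isfinite(out)] = -np.inf
        return float(out[0]) if scalar else out

    def initial_point(self) -> np.ndarray:
        """Least-squares start for the fixed effects, moderate scales."""
        ys, Xs = [], []
        for g in self.groups:
            ys.append(np.stack([g["y"][:g["n"]], g["y"][g["n"]:]], axis=1))
            Xs.append(np.stack([np.ones(g["n"]), g["T"], g["W"],
                                g["T"] * g["W"]], axis=1))
        y = np.concatenate(ys)       # (N, 2)
        X = np.concatenate(Xs)       # (N, 4)
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        sd = np.maximum(resid.std(axis=0, ddof=4), 1.0)
        th = np.zeros(15)
        th[0:2] = coef[0]
        th[2:4] = coef[1]
        th[4:6] = coef[2]
        th[6:8] = coef[3]
        th[8:10] = np.log(sd)
        th[10] = 0.0
        th[11:15] = np.log([3.0, 6.0, 3.0, 6.0])
        return th


def _run_emcee(log_prob, x0: np.ndarray, jitter: np.ndarray, seed: int,
               n_walkers: int, n_steps: int, n_burn: int):
    import emcee

    ndim = x0.size
    rng = np.random.default_rng(seed)
    p0 = x0[None, :] + jitter[None, :] * rng.standard_normal((n_walkers, ndim))
    sampler = emcee.EnsembleSampler(
        n_walkers, ndim, log_prob, vectorize=True,
        moves=[(emcee.moves.DEMove(), 0.8),
               (emcee.moves.DESnookerMove(), 0.2)])
    sampler.random_state = np.random.RandomState(seed).get_state()
    sampler.run_mcmc(p0, n_steps, progress=False)
    chain = sampler.get_chain(discard=n_burn)          # (steps, walkers, dim)
    return np.swapaxes(chain, 0, 1)                    # (walkers, steps, dim)


def _summarize_chain(chain: np.ndarray, names, transforms, model: str,
                     rhat_limit: float = 1.01, ess_limit: float = 400.0,
                     ) -> PosteriorSummary:
    """Build a PosteriorSummary (means, 95% CI, R-hat, bulk ESS) from a chain."""
    import arviz as az

    draws = {}
    rows = []
    converged = True
    for i, name in enumerate(names):
        x = transforms[i](chain[:, :, i])
        draws[name] = x.reshape(-1)
        rhat = float(az.rhat(x))
        ess = float(az.ess(x))
        flat = x.reshape(-1)
        rows.append({
            "parameter": name,
            "mean": float(flat.mean()),
            "sd": float(flat.std(ddof=1)),
            "q2.5": float(np.quantile(flat, 0.025)),
            "q97.5": float(np.quantile(flat, 0.975)),
            "rhat": rhat,
            "ess": ess,
        })
        if not (rhat < rhat_limit) or not (ess > ess_limit):
            converged = False
    params = pd.DataFrame(rows).set_index("parameter")
    if not converged:
        logger.warning("%s fit flagged non-converged (max rhat %.3f, min ess %.0f)",
                       model, params["rhat"].max(), params["ess"].min())
    return PosteriorSummary(model=model, params=params, converged=converged,
                            n_draws=chain.shape[0] * chain.shape[1], draws=draws)


_IDENT = lambda x: x  # noqa: E731


def fit_height_model(summaries: pd.DataFrame,
                     spec: HeightModelSpec | None = None,
                     seed: int = 0,
                     n_walkers: int = 40,
                     n_steps: int = 1000,
                     n_burn: int = 500) -> PosteriorSummary:
    """Fit the bivariate height model to a cage-summary table.

    Requires at least two blocks per year and two years.  Returns posterior
    means, 95% credible intervals and convergence diagnostics; random
    intercepts are marginalized, so reported parameters are the fixed effects,
    residual scales/correlation and random-effect scales.
    """
    spec = spec or HeightModelSpec()
    if summaries["year"].nunique() < 2:
        raise ValueError("need at least 2 years for year effects")
    for year, g in summaries.groupby("year"):
        if g["block"].nunique() < 2:
            raise ValueError(f"need at least 2 blocks in year {year}")
    post = _HeightPosterior(summaries, spec)
    x0 = post.initial_point()
    jitter = np.concatenate([np.full(8, 0.5), np.full(7, 0.05)])
    chain = _run_emcee(post, x0, jitter, seed, n_walkers, n_steps, n_burn)
    transforms = [_IDENT] * 8 + [np.exp, np.exp, np.tanh] + [np.exp] * 4
    return _summarize_chain(chain, spec.param_names, transforms, "height")


def sample_height_prior(spec: HeightModelSpec | None = None, n: int = 20000,
                        seed: int = 0) -> dict[str, np.ndarray]:
    """Exact draws from the height-model priors (prior-predictive checks)."""
    spec = spec or HeightModelSpec()
    rng = np.random.default_rng(seed)
    return {
        "alpha_MEFE": _sample_t3(rng, *spec.alpha_mefe, size=n),
        "alpha_PIMI": _sample_t3(rng, *spec.alpha_pimi, size=n),
        "beta_MEFE_T": rng.normal(*spec.beta_t_mefe, size=n),
        "beta_PIMI_T": rng.normal(*spec.beta_t_pimi, size=n),
        "beta_MEFE_W": rng.normal(0.0, spec.beta_w_sd, size=n),
        "beta_PIMI_W": rng.normal(0.0, spec.beta_w_sd, size=n),
        "beta_MEFE_TW": rng.normal(0.0, spec.beta_tw_sd, size=n),
        "beta_PIMI_TW": rng.normal(0.0, spec.beta_tw_sd, size=n),
        "sigma_MEFE": _sample_half_t3(rng, spec.sigma_mefe_scale, n),
        "sigma_PIMI": _sample_half_t3(rng, spec.sigma_pimi_scale, n),
        "rho": rng.uniform(-1.0, 1.0, size=n),
    }


def sample_survival_prior(spec: SurvivalModelSpec | None = None,
                          n: int = 20000, seed: int = 0) -> dict[str, np.ndarray]:
    """Exact draws from the survival-model priors."""
    spec = spec or SurvivalModelSpec()
    rng = np.random.default_rng(seed)
    return {
        "alpha": _sample_t3(rng, *spec.alpha, size=n),
        "beta_A": rng.normal(*spec.beta_a, size=n),
        "tau_year": _sample_half_t3(rng, spec.tau_scale, n),
        "tau_block": _sample_half_t3(rng, spec.tau_scale, n),
    }


# ---------------------------------------------------------------------------
# survival model

class _SurvivalPosterior:
    """Log-posterior of the binomial survival model (non-centred REs).

    Parameters: alpha, beta_A, log tau_year, log tau_block,
    year deviations u_year (standard normal), block deviations u_block.
    """

    def __init__(self, summaries: pd.DataFrame, spec: SurvivalModelSpec):
        self.spec = spec
        self.k = summaries["survivors"].to_numpy(dtype=float)
        self.n = summaries["stocked"].to_numpy(dtype=float)
        self.A = summaries["A"].to_numpy(dtype=float)
        years = sorted(summaries["year"].unique())
        blocks = sorted(summaries["block"].unique())
        self.year_idx = summaries["year"].map({y: i for i, y in enumerate(years)}
                                              ).to_numpy()
        self.block_idx = summaries["block"].map({b: i for i, b in enumerate(blocks)}
                                                ).to_numpy()
        self.n_year = len(years)
        self.n_block = len(blocks)
        self.ndim = 4 + self.n_year + self.n_block

    def __call__(self, TH):
        s = self.spec
        TH = np.asarray(TH, dtype=float)
        scalar = TH.ndim == 1
        TH = np.atleast_2d(TH)
        ok = (np.all(np.isfinite(TH), axis=1)
              & np.all(np.abs(TH) <= 1e4, axis=1)
              & (np.abs(TH[:, 2]) <= 12.0) & (np.abs(TH[:, 3]) <= 12.0))
        TH = np.where(ok[:, None], TH, 0.0)
        alpha, beta_a = TH[:, 0], TH[:, 1]
        log_ty, log_tb = TH[:, 2], TH[:, 3]
        u_year = TH[:, 4:4 + self.n_year]
        u_block = TH[:, 4 + self.n_year:]
        tau_y, tau_b = np.exp(log_ty), np.exp(log_tb)
        lp = _t3_logpdf(alpha, *s.alpha) + _norm_logpdf(beta_a, *s.beta_a)
        for log_t, tau in ((log_ty, tau_y), (log_tb, tau_b)):
            lp = lp + math.log(2.0) + _t3_logpdf(tau, 0.0, s.tau_scale) + log_t
        lp = lp + np.sum(_norm_logpdf(u_year, 0.0, 1.0), axis=1)
        lp = lp + np.sum(_norm_logpdf(u_block, 0.0, 1.0), axis=1)
        eta = (alpha[:, None] + beta_a[:, None] * self.A[None, :]
               + tau_y[:, None] * u_year[np.arange(TH.shape[0])[:, None],
                                         self.year_idx[None, :]]
               + tau_b[:, None] * u_block[np.arange(TH.shape[0])[:, None],
                                          self.block_idx[None, :]])
        # binomial log-likelihood, stable logistic form
        ll = np.sum(self.k * eta - self.n * np.logaddexp(0.0, eta), axis=1)
        out = np.where(ok & np.isfinite(ll), lp + ll, -np.inf)
        return float(out[0]) if scalar else out

    def initial_point(self) -> np.ndarray:
        p = (self.k.sum() + 0.5) / (self.n.sum() + 1.0)
        th = np.zeros(self.ndim)
        th[0] = math.log(p / (1.0 - p))
        th[2] = th[3] = math.log(0.5)
        return th


def fit_survival_model(summaries: pd.DataFrame,
                       spec: SurvivalModelSpec | None = None,
                       seed: int = 0,
                       n_walkers: int = 64,
                       n_steps: int = 1500,
                       n_burn: int = 750) -> PosteriorSummary:
    """Fit the binomial survival model to a cage-summary table.

    Requires ``survivors``, ``stocked`` and attack-rate ``A`` columns.
    Reported parameters: intercept, attack-rate slope and random-effect
    scales (deviations are sampled but not tabulated).
    """
    spec = spec or SurvivalModelSpec()
    if summaries[["survivors", "stocked"]].isna().any().any():
        raise ValueError("survival data missing for some cages")
    if (summaries["survivors"] > summaries["stocked"]).any():
        raise ValueError("survivors exceed stocked")
    post = _SurvivalPosterior(summaries, spec)
    x0 = post.initial_point()
    jitter = np.concatenate([[0.3, 1.0, 0.2, 0.2],
                             np.full(post.ndim - 4, 0.3)])
    chain = _run_emcee(post, x0, jitter, seed, n_walkers, n_steps, n_burn)
    names = ["alpha", "beta_A", "tau_year", "tau_block"]
    transforms = [_IDENT, _IDENT, np.exp, np.exp]
    return _summarize_chain(chain[:, :, :4], names, transforms, "survival")
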