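"""Hierarchical Bayesian ANOVA of movement direction.

The observed movement direction of subject *s* (group *g*) in epoch *e* is

    y ~ Normal(mu_{s,e},  sigma_s)
    mu_{s,e} = beta0 + alpha_e + gamma_g + delta_{e,g} + u_s + v_{s,e}

with a robust hierarchical prior on the epoch-by-group interaction
(delta ~ Student-t(nu, 0, sigma_delta), represented as a scale mixture of
normals), hierarchical normal priors on the subject intercepts u_s and
subject-by-epoch terms v_{s,e} ("regress toward the mean"), a gamma prior on
the per-subject precision 1/sigma_s^2 with broad hyperpriors on its shape and
rate, and broad normal priors on beta0, alpha_e and gamma_g.

Sampling is by a conditionally-conjugate Gibbs sweep (all location and scale
parameters) with Metropolis-within-Gibbs steps for the t degrees of freedom
and the gamma shape, plus translation ("sweep") moves along the additive
ridges between fixed and random effects to keep the cell means mixing.  The
reported coefficients are recentred per draw to the sum-to-zero
parameterisation; derived cell means m_{e,g} = beta0 + alpha_e + gamma_g +
delta_{e,g} are invariant to that recentring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import gammaln

from ._rng import substream

__all__ = [
    "PriorConfig",
    "ModelSpec",
    "PosteriorSamples",
    "ConvergenceReport",
    "build_model",
    "sample_posterior",
    "diagnose",
    "cell_means",
    "group_epoch_draws",
]


@dataclass(frozen=True)
class PriorConfig:
    """Prior hyperparameters.  All priors are broad by default.

    ``scale_factor`` multiplies every prior range (normal SDs and
    inverse-gamma scales); doubling it is the standard robustness check and
    should leave the posterior essentially unchanged.
    """

    fixed_effect_sd: float = 50.0          # beta0, alpha_e, gamma_g ~ N(0, sd^2)
    delta_scale_ig: tuple[float, float] = (0.5, 0.5)    # sigma_delta^2 ~ InvGamma(a, b)
    subject_scale_ig: tuple[float, float] = (0.5, 0.5)  # sigma_u^2
    subject_epoch_scale_ig: tuple[float, float] = (0.5, 0.5)  # sigma_v^2
    tau_shape_lognorm: tuple[float, float] = (math.log(2.0), 1.5)  # prior on a_tau
    tau_rate_gamma: tuple[float, float] = (1.0, 0.1)    # Gamma(a, rate b) prior on b_tau
    nu_mode: str = "sample"                # "sample" or "fixed"
    nu_fixed: float = 4.0
    nu_prior_mean: float = 30.0            # nu - 2 ~ Exponential(mean nu_prior_mean - 2)
    include_subject_epoch: bool = True     # the v_{s,e} term
    scale_factor: float = 1.0

    def scaled(self, factor: float) -> "PriorConfig":
        return replace(self, scale_factor=self.scale_factor * factor)

    # effective (scaled) values -------------------------------------------
    @property
    def fixed_sd(self) -> float:
        return self.fixed_effect_sd * self.scale_factor

    def _ig(self, ab: tuple[float, float]) -> tuple[float, float]:
        a, b = ab
        return a, b * self.scale_factor

    @property
    def ig_delta(self):
        return self._ig(self.delta_scale_ig)

    @property
    def ig_u(self):
        return self._ig(self.subject_scale_ig)

    @property
    def ig_v(self):
        return self._ig(self.subject_epoch_scale_ig)


@dataclass
class ModelSpec:
    """Fully specified joint density for one epoched dataset.

    Data enter through per-(subject, epoch) sufficient statistics (count,
    sum, sum of squares), which is exact for the normal likelihood.
    """

    subjects: list[str]
    epochs: list[str]
    groups: list[str]
    group_of_subject: np.ndarray          # (S,) int index into groups
    n: np.ndarray                          # (S, E) trial counts
    ysum: np.ndarray                       # (S, E)
    yssq: np.ndarray                       # (S, E)
    priors: PriorConfig = field(default_factory=PriorConfig)

    @property
    def shape(self) -> tuple[int, int, int]:
        return len(self.subjects), len(self.epochs), len(self.groups)

    def log_density(self, point: dict) -> float:
        """Joint log density (likelihood + all priors) at a parameter point.

        ``point`` holds: beta0 (scalar), alpha (E,), gamma (G,), delta (E,G),
        u (S,), v (S,E), tau (S,), lam (E,G), sigma2_delta, sigma2_u,
        sigma2_v, a_tau, b_tau, nu.
        """
        S, E, G = self.shape
        pc = self.priors
        beta0 = float(point["beta0"])
        alpha = np.asarray(point["alpha"], float)
        gamma = np.asarray(point["gamma"], float)
        delta = np.asarray(point["delta"], float)
        u = np.asarray(point["u"], float)
        v = np.asarray(point["v"], float)
        tau = np.asarray(point["tau"], float)
        lam = np.asarray(point["lam"], float)
        s2d, s2u, s2v = (float(point[k]) for k in ("sigma2_delta", "sigma2_u", "sigma2_v"))
        a_tau, b_tau, nu = (float(point[k]) for k in ("a_tau", "b_tau", "nu"))

        g_of_s = self.group_of_subject
        mu = (beta0 + alpha[None, :] + gamma[g_of_s][:, None]
              + delta[:, g_of_s].T + u[:, None] + v)
        # likelihood from sufficient statistics
        n, ysum, yssq = self.n, self.ysum, self.yssq
        ll = 0.5 * np.sum(n * (np.log(tau)[:, None] - math.log(2 * math.pi)))
        ll -= 0.5 * np.sum(tau[:, None] * (yssq - 2 * mu * ysum + n * mu**2))

        def norm_lp(x, sd):
            x = np.atleast_1d(np.asarray(x, float))
            return float(np.sum(-0.5 * (x / sd) ** 2 - math.log(sd) - 0.5 * math.log(2 * math.pi)))

        def gamma_lp(x, shape, rate):
            x = np.atleast_1d(np.asarray(x, float))
            return float(np.sum(shape * math.log(rate) + (shape - 1) * np.log(x)
                                - rate * x - gammaln(shape)))

        def invgamma_lp(x, a, b):
            return float(a * math.log(b) - gammaln(a) - (a + 1) * math.log(x) - b / x)

        lp = ll
        lp += norm_lp(beta0, pc.fixed_sd)
        lp += norm_lp(alpha, pc.fixed_sd) + norm_lp(gamma, pc.fixed_sd)
        # delta | lam ~ N(0, s2d / lam); lam ~ Gamma(nu/2, nu/2)
        sd_delta = np.sqrt(s2d / lam)
        lp += float(np.sum(-0.5 * (delta / sd_delta) ** 2 - np.log(sd_delta)
                           - 0.5 * math.log(2 * math.pi)))
        lp += gamma_lp(lam, nu / 2.0, nu / 2.0)
        lp += norm_lp(u, math.sqrt(s2u))
        if pc.include_subject_epoch:
            lp += norm_lp(v, math.sqrt(s2v))
        lp += invgamma_lp(s2d, *pc.ig_delta)
        lp += invgamma_lp(s2u, *pc.ig_u)
        lp += invgamma_lp(s2v, *pc.ig_v)
        lp += gamma_lp(tau, a_tau, b_tau)
        # hyperpriors
        mu_a, sd_a = pc.tau_shape_lognorm
        lp += float(-0.5 * ((math.log(a_tau) - mu_a) / sd_a) ** 2
                    - math.log(a_tau * sd_a) - 0.5 * math.log(2 * math.pi))
        lp += gamma_lp(b_tau, *pc.tau_rate_gamma)
        if pc.nu_mode == "sample":
            rate = 1.0 / (pc.nu_prior_mean - 2.0)
            lp += math.log(rate) - rate * (nu - 2.0)
        return float(lp)


def build_model(epoched: pd.DataFrame, priors: PriorConfig | None = None) -> ModelSpec:
    """Assemble the model from an epoched trial table.

    ``epoched`` needs columns ``subject_id``, ``group``, ``epoch`` and
    ``movement_direction_deg``; rows with ``valid == False`` are dropped.
    Epoch levels keep their first-appearance order (trial order); groups and
    subjects are sorted for stable indexing.
    """
    required = {"subject_id", "group", "epoch", "movement_direction_deg"}
    missing = required - set(epoched.columns)
    if missing:
        raise ValueError(f"epoched table is missing columns: {sorted(missing)}")
    df = epoched
    if "valid" in df.columns:
        df = df[df["valid"].astype(bool)]
    if len(df) == 0:
        raise ValueError("epoched table contains no valid trials")
    if df["movement_direction_deg"].isna().any():
        raise ValueError("movement_direction_deg contains NaN")

    # keep first-appearance order (SD, MD, LD under the default generator)
    epochs = list(pd.unique(df["epoch"]))
    groups = list(pd.unique(df["group"]))
    subjects = sorted(df["subject_id"].unique())
    s_idx = {s: i for i, s in enumerate(subjects)}
    e_idx = {e: i for i, e in enumerate(epochs)}
    g_idx = {g: i for i, g in enumerate(groups)}

    S, E = len(subjects), len(epochs)
    n = np.zeros((S, E))
    ysum = np.zeros((S, E))
    yssq = np.zeros((S, E))
    si = df["subject_id"].map(s_idx).to_numpy()
    ei = df["epoch"].map(e_idx).to_numpy()
    y = df["movement_direction_deg"].to_numpy(float)
    np.add.at(n, (si, ei), 1.0)
    np.add.at(ysum, (si, ei), y)
    np.add.at(yssq, (si, ei), y * y)

    g_of_s = np.zeros(S, dtype=int)
    grp = df.groupby("subject_id")["group"].agg(lambda x: x.iloc[0])
    for s, g in grp.items():
        g_of_s[s_idx[s]] = g_idx[g]

    return ModelSpec(subjects=subjects, epochs=epochs, groups=groups,
                     group_of_subject=g_of_s, n=n, ysum=ysum, yssq=yssq,
                     priors=priors or PriorConfig())


# --------------------------------------------------------------------------
# posterior container


@dataclass
class PosteriorSamples:
    """MCMC draws, shape (chains, draws, ...) per variable.

    ``posterior['cell_mean']`` holds the derived per-draw cell means
    m_{e,g} = beta0 + alpha_e + gamma_g + delta_{e,g} for every epoch x group
    cell; coefficient draws are stored in the sum-to-zero parameterisation.
    The subject-by-epoch terms v are not stored draw-by-draw (only their
    scale sigma_v) to keep memory bounded.
    """

    posterior: dict[str, np.ndarray]
    epochs: list[str]
    groups: list[str]
    subjects: list[str]
    meta: dict

    @property
    def n_chains(self) -> int:
        return self.posterior["cell_mean"].shape[0]

    @property
    def n_draws(self) -> int:
        return self.posterior["cell_mean"].shape[1]

    def cell_mean_draws(self, epoch: str, group: str) -> np.ndarray:
        e = self.epochs.index(epoch)
        g = self.groups.index(group)
        return self.posterior["cell_mean"][:, :, e, g]

    def to_inference_data(self, var_names=None):
        import arviz as az

        post = self.posterior if var_names is None else {
            k: v for k, v in self.posterior.items() if k in var_names}
        dims = {"cell_mean": ["epoch", "group"], "alpha": ["epoch"],
                "gamma": ["group"], "delta": ["epoch", "group"],
                "u": ["subject"], "sigma_subject": ["subject"]}
        coords = {"epoch": self.epochs, "group": self.groups, "subject": self.subjects}
        return az.from_dict(posterior=post,
                            dims={k: v for k, v in dims.items() if k in post},
                            coords=coords)

    def to_frame(self, var_names=("cell_mean",)) -> pd.DataFrame:
        """Flatten draws to a long table with chain/draw indices."""
        frames = []
        for name in var_names:
            arr = self.posterior[name]
            c, d = arr.shape[:2]
            chain, draw = np.meshgrid(np.arange(c), np.arange(d), indexing="ij")
            if arr.ndim == 2:
                frames.append(pd.DataFrame({"chain": chain.ravel(), "draw": draw.ravel(),
                                            "parameter": name, "value": arr.ravel()}))
            elif name in ("cell_mean", "delta"):
                for e, en in enumerate(self.epochs):
                    for g, gn in enumerate(self.groups):
                        frames.append(pd.DataFrame({
                            "chain": chain.ravel(), "draw": draw.ravel(),
                            "parameter": f"{name}[{en},{gn}]",
                            "value": arr[:, :, e, g].ravel()}))
            else:
                flat = arr.reshape(c, d, -1)
                for j in range(flat.shape[2]):
                    frames.append(pd.DataFrame({
                        "chain": chain.ravel(), "draw": draw.ravel(),
                        "parameter": f"{name}[{j}]", "value": flat[:, :, j].ravel()}))
        return pd.concat(frames, ignore_index=True)

    def write_csv(self, path) -> None:
        scalars = [k for k, v in self.posterior.items() if v.ndim == 2]
        self.to_frame(("cell_mean", *scalars)).to_csv(path, index=False)


def read_posterior_csv(path, epochs: list[str], groups: list[str]) -> PosteriorSamples:
    """Rebuild a (cell-mean level) PosteriorSamples from :meth:`write_csv` output."""
    df = pd.read_csv(path)
    chains = int(df["chain"].max()) + 1
    draws = int(df["draw"].max()) + 1
    cm = np.zeros((chains, draws, len(epochs), len(groups)))
    post: dict[str, np.ndarray] = {}
    for name, sub in df.groupby("parameter"):
        vals = sub.sort_values(["chain", "draw"])["value"].to_numpy().reshape(chains, draws)
        if name.startswith("cell_mean["):
            en, gn = name[len("cell_mean["):-1].split(",")
            cm[:, :, epochs.index(en), groups.index(gn)] = vals
        else:
            post[name] = vals
    post["cell_mean"] = cm
    return PosteriorSamples(posterior=post, epochs=list(epochs), groups=list(groups),
                            subjects=[], meta={"source": str(path)})


# --------------------------------------------------------------------------
# Gibbs sampler


def _init_state(spec: ModelSpec, rng: np.random.Generator) -> dict:
    S, E, G = spec.shape
    n = spec.n
    with np.errstate(invalid="ignore", divide="ignore"):
        ybar = np.where(n > 0, spec.ysum / np.maximum(n, 1), np.nan)
    grand = float(np.nanmean(ybar))
    epoch_means = np.nanmean(ybar, axis=0)
    subj_means = np.nanmean(ybar, axis=1)
    group_means = np.array([np.nanmean(subj_means[spec.group_of_subject == g])
                            for g in range(G)])
    jitter = lambda shape, s=0.5: rng.normal(0.0, s, size=shape)

    state = {
        "beta0": grand + float(jitter(())),
        "alpha": np.nan_to_num(epoch_means - grand) + jitter(E),
        "gamma": np.nan_to_num(group_means - grand) + jitter(G),
        "delta": jitter((E, G), 0.2),
        "u": np.nan_to_num(subj_means - grand - np.nan_to_num(group_means)[spec.group_of_subject])
             + jitter(S, 0.2),
        "v": np.zeros((S, E)),
        "lam": np.ones((E, G)),
        "sigma2_delta": 1.0 + float(rng.random()),
        "sigma2_u": 2.0 + float(rng.random()),
        "sigma2_v": 0.5 + 0.5 * float(rng.random()),
        "a_tau": 2.0,
        "nu": 10.0,
    }
    # residual-based precision init
    nt = n.sum(axis=1)
    mu0 = grand
    rss = np.maximum(spec.yssq.sum(axis=1) - 2 * mu0 * spec.ysum.sum(axis=1) + nt * mu0**2, 1e-6)
    var = np.clip(rss / np.maximum(nt, 1), 1.0, 400.0)
    state["tau"] = 1.0 / var
    state["b_tau"] = state["a_tau"] * float(np.mean(var))
    return state


def _gibbs_chain(spec: ModelSpec, state: dict, n_sweeps: int, keep_from: int,
                 rng: np.random.Generator, store_every: int = 1,
                 store_subject_means: bool = False) -> dict[str, np.ndarray]:
    S, E, G = spec.shape
    pc = spec.priors
    n, ysum, yssq = spec.n, spec.ysum, spec.yssq
    g_of_s = spec.group_of_subject
    group_rows = [np.nonzero(g_of_s == g)[0] for g in range(G)]
    n_g = np.array([len(r) for r in group_rows], dtype=float)
    p0 = 1.0 / pc.fixed_sd**2
    use_v = pc.include_subject_epoch
    ad, bd = pc.ig_delta
    au, bu = pc.ig_u
    av, bv = pc.ig_v
    ab_tau, bb_tau = pc.tau_rate_gamma
    mu_a, sd_a = pc.tau_shape_lognorm

    beta0 = state["beta0"]
    alpha = state["alpha"].copy()
    gamma = state["gamma"].copy()
    delta = state["delta"].copy()
    u = state["u"].copy()
    v = state["v"].copy()
    tau = state["tau"].copy()
    lam = state["lam"].copy()
    s2d, s2u, s2v = state["sigma2_delta"], state["sigma2_u"], state["sigma2_v"]
    a_tau, b_tau = state["a_tau"], state["b_tau"]
    nu = pc.nu_fixed if pc.nu_mode == "fixed" else state["nu"]

    n_keep = (n_sweeps - keep_from + store_every - 1) // store_every
    out = {
        "cell_mean": np.empty((n_keep, E, G)),
        "beta0": np.empty(n_keep), "alpha": np.empty((n_keep, E)),
        "gamma": np.empty((n_keep, G)), "delta": np.empty((n_keep, E, G)),
        "u": np.empty((n_keep, S)),
        "sigma_delta": np.empty(n_keep), "sigma_u": np.empty(n_keep),
        "sigma_v": np.empty(n_keep), "nu": np.empty(n_keep),
        "a_tau": np.empty(n_keep), "b_tau": np.empty(n_keep),
        "sigma_subject": np.empty((n_keep, S)),
    }
    if store_subject_means:
        out["subject_epoch_mean"] = np.empty((n_keep, S, E))
    kept = 0

    nt_s = n.sum(axis=1)
    for sweep in range(n_sweeps):
        w = tau[:, None] * n                      # (S, E) likelihood precisions
        wy = tau[:, None] * ysum                  # w * cell mean

        gam_s = gamma[g_of_s][:, None]
        del_s = delta[:, g_of_s].T                # (S, E)

        if use_v:
            num = wy - w * (beta0 + alpha[None, :] + gam_s + del_s + u[:, None])
            prec = 1.0 / s2v + w
            v = num / prec + rng.standard_normal((S, E)) / np.sqrt(prec)
        # u
        resid = wy - w * (beta0 + alpha[None, :] + gam_s + del_s + v)
        prec_u = 1.0 / s2u + w.sum(axis=1)
        u = resid.sum(axis=1) / prec_u + rng.standard_normal(S) / np.sqrt(prec_u)
        # delta (per group, vectorised over epochs)
        base = wy - w * (beta0 + alpha[None, :] + gam_s + u[:, None] + v)
        for g in range(G):
            rows = group_rows[g]
            num_e = base[rows].sum(axis=0)
            prec_e = lam[:, g] / s2d + w[rows].sum(axis=0)
            delta[:, g] = num_e / prec_e + rng.standard_normal(E) / np.sqrt(prec_e)
        del_s = delta[:, g_of_s].T
        # alpha
        resid = wy - w * (beta0 + gam_s + del_s + u[:, None] + v)
        prec_a = p0 + w.sum(axis=0)
        alpha = resid.sum(axis=0) / prec_a + rng.standard_normal(E) / np.sqrt(prec_a)
        # gamma
        resid = wy - w * (beta0 + alpha[None, :] + del_s + u[:, None] + v)
        for g in range(G):
            rows = group_rows[g]
            prec_g = p0 + w[rows].sum()
            gamma[g] = resid[rows].sum() / prec_g + rng.standard_normal() / math.sqrt(prec_g)
        gam_s = gamma[g_of_s][:, None]
        # beta0
        resid = wy - w * (alpha[None, :] + gam_s + del_s + u[:, None] + v)
        prec_b = p0 + w.sum()
        beta0 = resid.sum() / prec_b + rng.standard_normal() / math.sqrt(prec_b)

        # translation moves along fixed/random ridges -----------------------
        # gamma_g <-> u_s (s in g)
        for g in range(G):
            rows = group_rows[g]
            prec_t = p0 + n_g[g] / s2u
            mean_t = (-gamma[g] * p0 + u[rows].sum() / s2u) / prec_t
            t = mean_t + rng.standard_normal() / math.sqrt(prec_t)
            gamma[g] += t
            u[rows] -= t
        if use_v:
            # delta_{e,g} <-> v_{s,e} (s in g)
            for g in range(G):
                rows = group_rows[g]
                prec_t = lam[:, g] / s2d + n_g[g] / s2v
                mean_t = (-delta[:, g] * lam[:, g] / s2d + v[rows].sum(axis=0) / s2v) / prec_t
                t = mean_t + rng.standard_normal(E) / np.sqrt(prec_t)
                delta[:, g] += t
                v[rows] -= t[None, :]
            # u_s <-> v_{s,:}
            prec_t = 1.0 / s2u + E / s2v
            mean_t = (-u / s2u + v.sum(axis=1) / s2v) / prec_t
            t = mean_t + rng.standard_normal(S) / np.sqrt(prec_t)
            u += t
            v -= t[:, None]
        gam_s = gamma[g_of_s][:, None]
        del_s = delta[:, g_of_s].T

        # scales -------------------------------------------------------------
        mu = beta0 + alpha[None, :] + gam_s + del_s + u[:, None] + v
        rss_s = np.maximum((yssq - 2 * mu * ysum + n * mu**2).sum(axis=1), 0.0)
        tau = rng.gamma(a_tau + 0.5 * nt_s, 1.0 / (b_tau + 0.5 * rss_s))

        lam = rng.gamma((nu + 1.0) / 2.0, 1.0 / (nu / 2.0 + delta**2 / (2.0 * s2d)))
        s2d = 1.0 / rng.gamma(ad + 0.5 * E * G, 1.0 / (bd + 0.5 * float(np.sum(lam * delta**2))))
        s2u = 1.0 / rng.gamma(au + 0.5 * S, 1.0 / (bu + 0.5 * float(np.sum(u**2))))
        if use_v:
            s2v = 1.0 / rng.gamma(av + 0.5 * S * E, 1.0 / (bv + 0.5 * float(np.sum(v**2))))

        # b_tau (conjugate), a_tau and nu (Metropolis on log scale) ----------
        b_tau = rng.gamma(ab_tau + S * a_tau, 1.0 / (bb_tau + float(tau.sum())))
        log_tau_sum = float(np.log(tau).sum())

        def a_tau_logp(a):
            return (S * (a * math.log(b_tau) - gammaln(a)) + (a - 1.0) * log_tau_sum
                    - 0.5 * ((math.log(a) - mu_a) / sd_a) ** 2 - math.log(a))

        prop = a_tau * math.exp(0.25 * rng.standard_normal())
        if math.log(rng.random()) < a_tau_logp(prop) - a_tau_logp(a_tau) \
                + math.log(prop) - math.log(a_tau):
            a_tau = prop

        if pc.nu_mode == "sample":
            sum_log_lam = float(np.log(lam).sum())
            sum_lam = float(lam.sum())
            K = E * G
            rate_nu = 1.0 / (pc.nu_prior_mean - 2.0)

            def nu_logp(x):
                h = x / 2.0
                return (K * (h * math.log(h) - gammaln(h)) + (h - 1.0) * sum_log_lam
                        - h * sum_lam - rate_nu * (x - 2.0))

            prop = 2.0 + (nu - 2.0) * math.exp(0.3 * rng.standard_normal())
            if math.log(rng.random()) < nu_logp(prop) - nu_logp(nu) \
                    + math.log(prop - 2.0) - math.log(nu - 2.0):
                nu = prop

        if sweep >= keep_from and (sweep - keep_from) % store_every == 0:
            m = beta0 + alpha[:, None] + gamma[None, :] + delta
            b0c = float(m.mean())
            alc = m.mean(axis=1) - b0c
            gac = m.mean(axis=0) - b0c
            dec = m - b0c - alc[:, None] - gac[None, :]
            out["cell_mean"][kept] = m
            out["beta0"][kept] = b0c
            out["alpha"][kept] = alc
            out["gamma"][kept] = gac
            out["delta"][kept] = dec
            out["u"][kept] = u
            out["sigma_delta"][kept] = math.sqrt(s2d)
            out["sigma_u"][kept] = math.sqrt(s2u)
            out["sigma_v"][kept] = math.sqrt(s2v)
            out["nu"][kept] = nu
            out["a_tau"][kept] = a_tau
            out["b_tau"][kept] = b_tau
            out["sigma_subject"][kept] = 1.0 / np.sqrt(tau)
            if store_subject_means:
                out["subject_epoch_mean"][kept] = (
                    beta0 + alpha[None, :] + gam_s + del_s + u[:, None] + v)
            kept += 1
    return out


def sample_posterior(spec: ModelSpec, chains: int = 4, burn_in: int = 1000,
                     draws: int = 10000, seed: int = 0, store_every: int = 1,
                     store_subject_means: bool = False) -> PosteriorSamples:
    """Sample the joint posterior by Gibbs; reproducible under (seed, chains).

    Returns all post-burn-in draws plus the derived cell means for every
    epoch x group cell.
    """
    if chains < 1 or draws < 1 or burn_in < 0:
        raise ValueError("chains and draws must be >= 1, burn_in >= 0")
    chain_outputs = []
    for c in range(chains):
        rng = substream(seed, "mcmc", index=c)
        state = _init_state(spec, rng)
        chain_outputs.append(
            _gibbs_chain(spec, state, burn_in + draws, burn_in, rng, store_every,
                         store_subject_means=store_subject_means))
    posterior = {k: np.stack([co[k] for co in chain_outputs]) for k in chain_outputs[0]}
    meta = {"seed": int(seed), "chains": chains, "burn_in": burn_in,
            "draws": draws, "sampler": "gibbs"}
    return PosteriorSamples(posterior=posterior, epochs=list(spec.epochs),
                            groups=list(spec.groups), subjects=list(spec.subjects),
                            meta=meta)


# --------------------------------------------------------------------------
# diagnostics and derived quantities


@dataclass
class ConvergenceReport:
    table: pd.DataFrame           # parameter, rhat, ess_bulk
    passed: bool | None           # None when undefined (single chain)
    rhat_threshold: float
    chain_agreement: bool | None
    notes: str = ""

    @property
    def max_rhat(self) -> float:
        return float(self.table["rhat"].max())


def diagnose(samples: PosteriorSamples, rhat_threshold: float = 1.01,
             var_names: tuple[str, ...] | None = None,
             reported_vars: tuple[str, ...] = ("cell_mean",)) -> ConvergenceReport:
    """Split R-hat and effective sample size for every stored parameter.

    The pass flag requires split R-hat <= ``rhat_threshold`` for the
    *reported* quantities (by default the derived cell means, from which all
    group summaries are computed) plus per-chain mean agreement; weakly
    identified hyperparameters may mix more slowly without invalidating the
    reported posteriors, and their R-hat/ESS are still listed in the table.
    With a single chain R-hat is undefined and the flag is ``None``.
    """
    import arviz as az

    if samples.n_chains < 2:
        names, ess_vals = [], []
        idata = samples.to_inference_data(var_names)
        ess = az.ess(idata)
        for name, da in ess.items():
            vals = np.atleast_1d(da.values).ravel()
            for j, vv in enumerate(vals):
                names.append(f"{name}[{j}]" if vals.size > 1 else str(name))
                ess_vals.append(float(vv))
        table = pd.DataFrame({"parameter": names, "rhat": np.nan, "ess_bulk": ess_vals})
        return ConvergenceReport(table=table, passed=None, rhat_threshold=rhat_threshold,
                                 chain_agreement=None,
                                 notes="single chain: split R-hat undefined")

    idata = samples.to_inference_data(var_names)
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    rows = []
    for name in rhat.data_vars:
        rv = np.atleast_1d(rhat[name].values).ravel()
        ev = np.atleast_1d(ess[name].values).ravel()
        for j in range(rv.size):
            rows.append({"parameter": f"{name}[{j}]" if rv.size > 1 else str(name),
                         "rhat": float(rv[j]), "ess_bulk": float(ev[j])})
    table = pd.DataFrame(rows)
    # per-chain mean agreement for the cell means: chain means within 4 MC SEs
    cm = samples.posterior["cell_mean"]
    chain_means = cm.mean(axis=1)
    pooled = cm.mean(axis=(0, 1))
    mcse = cm.std(axis=(0, 1)) / math.sqrt(max(samples.n_draws // 10, 1))
    agreement = bool(np.all(np.abs(chain_means - pooled[None]) <= 4 * mcse[None] + 1e-9))
    reported = table[table["parameter"].str.startswith(tuple(reported_vars))]
    passed = bool((reported["rhat"].dropna() <= rhat_threshold).all()) and agreement
    return ConvergenceReport(table=table, passed=passed, rhat_threshold=rhat_threshold,
                             chain_agreement=agreement)


def cell_means(samples: PosteriorSamples, epochs: str | list[str]) -> np.ndarray:
    """Per-draw group means over an epoch set, shape (chains, draws, groups).

    Multi-epoch summaries (e.g. the adaptation asymptote = mean of the last
    three 8-trial bins) average the per-draw cell means over the listed
    epochs.
    """
    if isinstance(epochs, str):
        epochs = [epochs]
    idx = []
    for e in epochs:
        if e not in samples.epochs:
            raise KeyError(f"unknown epoch: {e!r}")
        idx.append(samples.epochs.index(e))
    return samples.posterior["cell_mean"][:, :, idx, :].mean(axis=2)


def group_epoch_draws(samples: PosteriorSamples, epochs: str | list[str]) -> dict[str, np.ndarray]:
    """Flattened per-group draws of the epoch-set mean, keyed by group label."""
    cm = cell_means(samples, epochs)
    return {g: cm[:, :, i].ravel() for i, g in enumerate(samples.groups)}
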