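"""MCMC engine for the shared-component factor model.

The model for county i, race r, disease d (y = log mortality rate):

    y[i,r,d] = x[i,r,d]' b[r,d] + lam[r,d] * f[i,r] + kap[r,d] * g[s(i)]
               + eps[i,r,d],          eps ~ N(0, sigma[r,d]^2)

    (f[i,baa], f[i,nhw]) ~ N(0, Sigma_f),  Sigma_f from (sigma_f, rho)
    g[s] ~ N(0, sigma_g^2)
    lam[r,hd] = 1,  kap[first outcome] = 1   (identifiability)

Coefficients and latent factors have conjugate normal full conditionals
and are Gibbs-updated in closed form.  Scale parameters, loadings and the
cross-race correlation are updated by univariate slice sampling under the
*partially collapsed* likelihood: for the county-factor block (sigma_f,
rho, free lambda, residual sigmas), f is integrated out analytically —
per county the residual 4-vector is N(0, V) with V = L Sigma_f L' + D,
shared across counties — and f is redrawn from its conditional
afterwards; for the state block (sigma_g, free kappa), g is integrated
out the same way.  Collapsing removes the funnel-shaped coupling between
a variance and its latent values that makes naive Gibbs mix
pathologically slowly in hierarchical factor models.

Priors: coefficients and free loadings N(0, coef_sd^2); sds half-normal
(scale ``sigma_scale``); rho uniform on (-1, 1).  Scale parameters are
floored at 1e-6 so that noise-free (degenerate) data remain numerically
tractable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

SIGMA_FLOOR = 1e-6


def slice_sample(x0, logp, rng, w=0.25, lower=-np.inf, upper=np.inf, max_steps=50):
    """One update of the univariate stepping-out/shrinkage slice sampler."""

    def f(x):
        if x <= lower or x >= upper:
            return -np.inf
        return logp(x)

    fx0 = f(x0)
    if not np.isfinite(fx0):
        raise FloatingPointError(f"slice sampler started at logp={fx0}")
    logy = fx0 + math.log(rng.uniform())
    L = x0 - w * rng.uniform()
    R = L + w
    j = int(math.floor(max_steps * rng.uniform()))
    k = max_steps - 1 - j
    while j > 0 and L > lower and f(L) > logy:
        L -= w
        j -= 1
    while k > 0 and R < upper and f(R) > logy:
        R += w
        k -= 1
    L = max(L, lower)
    R = min(R, upper)
    while True:
        x1 = L + (R - L) * rng.uniform()
        if f(x1) > logy:
            return x1
        if x1 < x0:
            L = x1
        else:
            R = x1
        if R - L < 1e-15:
            return x0


@dataclass
class ModelData:
    """Prepared inputs for one model fit."""

    y: np.ndarray  # (n, O) log rates
    X: list  # per-outcome design (n, p_o), intercept included
    names: list  # per-outcome column names
    outcome_names: list  # e.g. ["baa_hd", "baa_st", ...]
    outcome_race: np.ndarray  # (O,) race index into races
    outcome_disease: list  # "hd"/"st" per outcome
    races: tuple  # e.g. ("baa", "nhw")
    state_idx: np.ndarray  # (n,)
    n_states: int


@dataclass
class SamplerConfig:
    chains: int = 4
    draws: int = 2000
    warmup: int = 1000
    thin: int = 1
    coef_sd: float = 10.0
    sigma_scale: float = 1.0
    fix_rho: float | None = None
    fix_sigma_g: float | None = None
    seed: int = 0


@dataclass
class ChainResult:
    scalars: dict  # name -> (draws,) array
    f_sum: np.ndarray  # (n, R)
    f_pos: np.ndarray  # (n, R) counts of draws > 0
    diff_sum: np.ndarray | None  # (n, 2) BAA-nHW log-rate difference per disease
    diff_pos: np.ndarray | None
    n_kept: int


def _hn_logp(s: float, scale: float) -> float:
    return -0.5 * (s / scale) ** 2


def run_chain(
    data: ModelData, cfg: SamplerConfig, rng: np.random.Generator
) -> ChainResult:
    n, O = data.y.shape
    R = len(data.races)
    include_state = cfg.fix_sigma_g is None or cfg.fix_sigma_g > 0
    sample_sigma_g = cfg.fix_sigma_g is None
    sample_rho = R == 2 and cfg.fix_rho is None
    rho0 = cfg.fix_rho if cfg.fix_rho is not None else 0.0

    XtX = [x.T @ x for x in data.X]
    # cross-products between outcome designs, for the joint coefficient
    # draw with the county factors integrated out
    XtX_cross = [[data.X[o].T @ data.X[q] for q in range(O)] for o in range(O)]
    p_sizes = [x.shape[1] for x in data.X]
    p_off = np.concatenate([[0], np.cumsum(p_sizes)])
    P_total = int(p_off[-1])

    # --- initialization: per-outcome ridge OLS with small jitter ---
    b = []
    sigma = np.empty(O)
    for o in range(O):
        A = XtX[o] + 1e-8 * np.eye(XtX[o].shape[0])
        bo = np.linalg.solve(A, data.X[o].T @ data.y[:, o])
        resid = data.y[:, o] - data.X[o] @ bo
        sigma[o] = max(float(resid.std()), 0.05) * math.exp(
            0.2 * rng.uniform(-1, 1)
        )
        b.append(bo + 0.01 * rng.standard_normal(bo.size))
    f = np.zeros((n, R))
    g = np.zeros(data.n_states)
    sigma_f = np.full(R, 0.2) * np.exp(0.2 * rng.uniform(-1, 1, size=R))
    rho = rho0 + (0.2 * rng.uniform(-1, 1) if sample_rho else 0.0)
    sigma_g = (
        max(cfg.fix_sigma_g or 0.0, SIGMA_FLOOR)
        if not sample_sigma_g
        else 0.15 * math.exp(0.2 * rng.uniform(-1, 1))
    )
    lam_st = np.ones(R) + (0.05 * rng.standard_normal(R))
    kappa = np.ones(O) + 0.05 * rng.standard_normal(O)
    kappa[0] = 1.0

    lam = np.ones(O)  # current loading per outcome on its race factor

    def refresh_lam():
        for o in range(O):
            lam[o] = (
                1.0
                if data.outcome_disease[o] == "hd"
                else lam_st[data.outcome_race[o]]
            )

    refresh_lam()

    Xb = np.column_stack([data.X[o] @ b[o] for o in range(O)])
    counts = np.bincount(data.state_idx, minlength=data.n_states).astype(float)

    total = cfg.warmup + cfg.draws * cfg.thin
    n_kept = cfg.draws

    scalar_names: list[str] = []
    for o, out in enumerate(data.outcome_names):
        scalar_names += [f"{out}:{c}" for c in data.names[o]]
    for r, race in enumerate(data.races):
        scalar_names.append(f"lambda:{race}_st")
    if include_state:
        for out in data.outcome_names[1:]:  # first kappa fixed at 1
            scalar_names.append(f"kappa:{out}")
    for out in data.outcome_names:
        scalar_names.append(f"sigma:{out}")
    for race in data.races:
        scalar_names.append(f"sigma_f:{race}")
    if R == 2:
        scalar_names.append("rho")
    if include_state:
        scalar_names.append("sigma_g")
    store = {nm: np.empty(n_kept) for nm in scalar_names}

    f_sum = np.zeros((n, R))
    f_pos = np.zeros((n, R))
    both_races = R == 2
    diff_sum = np.zeros((n, 2)) if both_races else None
    diff_pos = np.zeros((n, 2)) if both_races else None

    sigma_scale = cfg.sigma_scale
    coef_sd = cfg.coef_sd

    race_of = data.outcome_race
    is_st = np.array([d == "st" for d in data.outcome_disease])

    def build_V():
        """Marginal covariance of a county's residual vector, f integrated."""
        L = np.zeros((O, R))
        for o in range(O):
            L[o, race_of[o]] = lam_st[race_of[o]] if is_st[o] else 1.0
        if R == 2:
            c = rho * sigma_f[0] * sigma_f[1]
            Sig = np.array([[sigma_f[0] ** 2, c], [c, sigma_f[1] ** 2]])
        else:
            Sig = np.array([[sigma_f[0] ** 2]])
        return L @ Sig @ L.T + np.diag(sigma**2)

    def slice_update(arr, idx, prior, base_logp, w, lower=-np.inf, upper=np.inf):
        """Slice-sample arr[idx] in place under base_logp() + prior."""

        def lp(x):
            arr[idx] = x
            return base_logp() + prior(x)

        x1 = slice_sample(arr[idx], lp, rng, w=w, lower=lower, upper=upper)
        arr[idx] = x1

    kept = 0
    for it in range(total):
        g_county = g[data.state_idx]
        contrib_g = g_county[:, None] * kappa[None, :] if include_state else 0.0
        contrib_f = f[:, race_of] * lam[None, :]

        # --- coefficients: joint draw across outcomes, f integrated out ---
        # y_i - kappa g_{s(i)} ~ N(M_i beta, V), V = L Sigma_f L' + D shared
        # across counties, so the joint posterior of all coefficient
        # vectors is Gaussian with block precision W[o,q] * X_o'X_q.
        V0 = build_V()
        W = np.linalg.inv(V0)
        A_b = np.empty((P_total, P_total))
        for o in range(O):
            for q in range(O):
                A_b[p_off[o]:p_off[o + 1], p_off[q]:p_off[q + 1]] = (
                    W[o, q] * XtX_cross[o][q]
                )
        A_b[np.diag_indices(P_total)] += 1.0 / coef_sd**2
        T = data.y - contrib_g if include_state else data.y.copy()
        rhs = np.concatenate(
            [data.X[o].T @ (T @ W[:, o]) for o in range(O)]
        )
        Lb = np.linalg.cholesky(A_b)
        mean_b = np.linalg.solve(A_b, rhs)
        beta_all = mean_b + np.linalg.solve(
            Lb.T, rng.standard_normal(P_total)
        )
        for o in range(O):
            b[o] = beta_all[p_off[o]:p_off[o + 1]]
            Xb[:, o] = data.X[o] @ b[o]

        # --- scale/loading/correlation block: f AND g integrated out ---
        # With f out, county residuals are iid N(kappa g_s, V); with g out
        # as well, the marginal likelihood needs only S4 = E'E and the
        # per-state residual sums U, so every slice evaluation is O(S).
        E = data.y - Xb
        S4 = E.T @ E
        if include_state:
            U = np.column_stack(
                [
                    np.bincount(
                        data.state_idx, weights=E[:, o], minlength=data.n_states
                    )
                    for o in range(O)
                ]
            )

        def full_collapsed():
            V = build_V()
            sign, ld = np.linalg.slogdet(V)
            if sign <= 0:
                return -np.inf
            W = np.linalg.inv(V)
            val = -0.5 * n * ld - 0.5 * float(np.sum(W * S4))
            if include_state:
                Wk = W @ kappa
                t = U @ Wk
                q = 1.0 / sigma_g**2 + counts * float(kappa @ Wk)
                if np.any(q <= 0):
                    return -np.inf
                val += (
                    -data.n_states * math.log(sigma_g)
                    - 0.5 * float(np.sum(np.log(q)))
                    + 0.5 * float(np.sum(t * t / q))
                )
            return val

        for o in range(O):
            slice_update(
                sigma, o,
                lambda s: _hn_logp(s, sigma_scale),
                full_collapsed,
                w=0.1 * sigma[o] + 0.01,
                lower=SIGMA_FLOOR,
            )
        for r in range(R):
            if np.any(is_st & (race_of == r)):
                slice_update(
                    lam_st, r,
                    lambda x: -0.5 * (x / coef_sd) ** 2,
                    full_collapsed,
                    w=0.2,
                )
        for r in range(R):
            slice_update(
                sigma_f, r,
                lambda s: _hn_logp(s, sigma_scale),
                full_collapsed,
                w=0.1 * sigma_f[r] + 0.01,
                lower=SIGMA_FLOOR,
            )
        if sample_rho:
            def rho_logp(r_val):
                nonlocal rho
                rho = r_val
                return full_collapsed()

            rho = slice_sample(
                rho, rho_logp, rng, w=0.1, lower=-1.0 + 1e-9, upper=1.0 - 1e-9
            )
        if include_state:
            for o in range(1, O):
                slice_update(
                    kappa, o,
                    lambda x: -0.5 * (x / coef_sd) ** 2,
                    full_collapsed,
                    w=0.2,
                )
            if sample_sigma_g:
                def sg_logp(s_val):
                    nonlocal sigma_g
                    sigma_g = s_val
                    return full_collapsed() + _hn_logp(s_val, sigma_scale)

                sigma_g = slice_sample(
                    sigma_g, sg_logp, rng,
                    w=0.1 * sigma_g + 0.01, lower=SIGMA_FLOOR,
                )

        # Scale-group moves (generalized Gibbs with Haar correction): the
        # likelihood depends on sigma_g and the free kappas mainly through
        # their products, and on sigma_f / lambda_st likewise, so a joint
        # multiplicative rescaling mixes along that ridge where the
        # axis-aligned slice updates crawl.
        if include_state and sample_sigma_g and O > 1:
            base_sg, base_kap = sigma_g, kappa[1:].copy()

            def u_logp_state(u):
                nonlocal sigma_g
                sigma_g = base_sg * math.exp(u)
                kappa[1:] = base_kap * math.exp(-u)
                return (
                    full_collapsed()
                    + _hn_logp(sigma_g, sigma_scale)
                    - 0.5 * float(np.sum((kappa[1:] / coef_sd) ** 2))
                    + (1 - (O - 1)) * u
                )

            u = slice_sample(0.0, u_logp_state, rng, w=0.5, lower=-20, upper=20)
            u_logp_state(u)

        for r in range(R):
            if not np.any(is_st & (race_of == r)):
                continue
            base_sf, base_lam = sigma_f[r], lam_st[r]

            def u_logp_race(u, r=r, base_sf=base_sf, base_lam=base_lam):
                sigma_f[r] = base_sf * math.exp(u)
                lam_st[r] = base_lam * math.exp(-u)
                return (
                    full_collapsed()
                    + _hn_logp(sigma_f[r], sigma_scale)
                    - 0.5 * (lam_st[r] / coef_sd) ** 2
                )

            u = slice_sample(0.0, u_logp_race, rng, w=0.5, lower=-20, upper=20)
            u_logp_race(u)
        refresh_lam()

        if include_state:
            # --- state factors, f still integrated out ---
            V = build_V()
            W = np.linalg.inv(V)
            Wk = W @ kappa
            t = U @ Wk
            q = 1.0 / sigma_g**2 + counts * float(kappa @ Wk)
            g = t / q + rng.standard_normal(data.n_states) / np.sqrt(q)

            # translation move between mean(g) and the intercepts
            A_g = data.n_states / sigma_g**2 + float(
                np.sum(kappa**2) / coef_sd**2
            )
            b_g = float(g.sum()) / sigma_g**2 - float(
                np.sum(kappa * [b[o][0] for o in range(O)]) / coef_sd**2
            )
            delta_g = b_g / A_g + rng.standard_normal() / math.sqrt(A_g)
            g = g - delta_g
            for o in range(O):
                shift = kappa[o] * delta_g
                b[o][0] += shift
                Xb[:, o] += shift
            g_county = g[data.state_idx]
            contrib_g = g_county[:, None] * kappa[None, :]

        # --- county factors (conjugate, vectorized) ---
        E = data.y - Xb
        if include_state:
            E = E - contrib_g
        if R == 2:
            c01 = rho * sigma_f[0] * sigma_f[1]
            det = max(sigma_f[0] ** 2 * sigma_f[1] ** 2 - c01**2, 1e-24)
            prior_prec = (
                np.array([[sigma_f[1] ** 2, -c01], [-c01, sigma_f[0] ** 2]]) / det
            )
        else:
            prior_prec = np.array([[1.0 / sigma_f[0] ** 2]])
        P = prior_prec.copy()
        Bmat = np.zeros((n, R))
        for o in range(O):
            r = race_of[o]
            P[r, r] += lam[o] ** 2 / sigma[o] ** 2
            Bmat[:, r] += lam[o] / sigma[o] ** 2 * E[:, o]
        Pinv = np.linalg.inv(P)
        Lc = np.linalg.cholesky(Pinv)
        f = Bmat @ Pinv + rng.standard_normal((n, R)) @ Lc.T

        # Translation move: shift mass between the factor means and the
        # intercepts (likelihood-invariant; exact Gaussian conditional).
        # Removes the slow random walk between alpha and mean(f).
        A = n * prior_prec + np.zeros((R, R))
        bvec = prior_prec @ f.sum(axis=0)
        for o in range(O):
            r = race_of[o]
            A[r, r] += lam[o] ** 2 / coef_sd**2
            bvec[r] -= lam[o] * b[o][0] / coef_sd**2
        Ainv = np.linalg.inv(A)
        delta = Ainv @ bvec + np.linalg.cholesky(Ainv) @ rng.standard_normal(R)
        f = f - delta[None, :]
        for o in range(O):
            shift = lam[o] * delta[race_of[o]]
            b[o][0] += shift
            Xb[:, o] += shift
        contrib_f = f[:, race_of] * lam[None, :]

        # --- record ---
        if it >= cfg.warmup and (it - cfg.warmup) % cfg.thin == 0:
            k = kept
            for o, out in enumerate(data.outcome_names):
                for j, cname in enumerate(data.names[o]):
                    store[f"{out}:{cname}"][k] = b[o][j]
            for r, race in enumerate(data.races):
                store[f"lambda:{race}_st"][k] = lam_st[r]
            if include_state:
                for o, out in enumerate(data.outcome_names):
                    if o > 0:
                        store[f"kappa:{out}"][k] = kappa[o]
            for o, out in enumerate(data.outcome_names):
                store[f"sigma:{out}"][k] = sigma[o]
            for r, race in enumerate(data.races):
                store[f"sigma_f:{race}"][k] = sigma_f[r]
            if R == 2:
                store["rho"][k] = rho
            if include_state:
                store["sigma_g"][k] = sigma_g

            f_sum += f
            f_pos += f > 0
            if both_races:
                mu = Xb + contrib_f
                if include_state:
                    mu = mu + contrib_g
                # outcome order: baa_hd, baa_st, nhw_hd, nhw_st
                d_hd = mu[:, 0] - mu[:, 2]
                d_st = mu[:, 1] - mu[:, 3]
                diff_sum[:, 0] += d_hd
                diff_sum[:, 1] += d_st
                diff_pos[:, 0] += d_hd > 0
                diff_pos[:, 1] += d_st > 0
            kept += 1

    return ChainResult(
        scalars=store,
        f_sum=f_sum,
        f_pos=f_pos,
        diff_sum=diff_sum,
        diff_pos=diff_pos,
        n_kept=kept,
    )


def run_sampler(data: ModelData, cfg: SamplerConfig) -> list[ChainResult]:
    """Run ``cfg.chains`` independent chains; deterministic for a given seed."""
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.chains)
    return [
        run_chain(data, cfg, np.random.default_rng(s)) for s in seeds
    ]
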