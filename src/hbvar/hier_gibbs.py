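"""Parameter-expanded Gibbs sampler for the sparse hierarchical VAR posterior.

Model summary (per patient n, day t):

    y_nt = sum_i A_ni y_{n,t-i} + eps_nt,   eps_nt ~ MVN(0, Lambda^{-1})
    w_n  = vec([A_n1..A_np]) = w + v_n

with a doubly adaptive elastic-net prior on the population vector w,

    w_k | .  ~ N(0, 1 / (lam2_k + 1/(2 tau2_k)))
    2 tau2_k ~ Exponential(rate lam1_k^2 / (2 xi2_k)),

xi2_k the conditional variance of coordinate k given its trailing
coordinates under the covariance I_{Rp} (x) Lambda^{-1}, Gamma hyperpriors
on lam1_k^2 and lam2_k, Gaussian deviations v_n ~ MVN(0, Theta_v^{-1}) with
Gamma hyperpriors on the diagonal of Theta_v, and a Wishart prior on Lambda.

Sampling uses parameter expansion: an auxiliary multiplicative vector
alpha ~ MVN(0, c I) enters the likelihood through alpha * v_n (elementwise),
breaking the posterior coupling between the deviations and their precisions.
The identified patient-level deviation is v*_n = alpha * v_n.

Conditional updates, in fixed scan order:

    w      conjugate MVN (generalized ridge with diagonal penalty D)
    v_n    conjugate MVN (alpha absorbed into the regressors)
    alpha  conjugate MVN (v_n absorbed into the regressors)
    Lambda independence-Metropolis with an exactly matched Wishart proposal:
           the determinant part of the xi2-mediated prior factor telescopes
           to det(Lambda)^{Rp} (folded into the proposal dof) and the
           leading-coordinate exponential terms are linear in Lambda_11
           (folded into the proposal scale); only the remaining nonlinear
           terms enter the accept ratio, which is identically 1 when R = 1.
    2tau2  slice sampling (exact density has an extra sqrt(1 + lam2*u)
           factor relative to the inverse-Gaussian latent-scale form)
    lam1^2 conjugate Gamma
    lam2   slice sampling
    theta  conjugate Gamma

Gamma hyperpriors are specified by (mean m, degrees of freedom d), i.e.
shape d/2 and rate d/(2m); set ``gamma_mean_dof=False`` to pass shape/rate
directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .var_core import DesignEntry, build_design_set

__all__ = [
    "HyperParams",
    "ModelState",
    "PosteriorDraws",
    "compute_xi2",
    "init_state",
    "gibbs_sweep",
    "run_gibbs",
]


@dataclass(frozen=True)
class HyperParams:
    """Hyperprior settings.  Defaults are the weakly-informative choices
    used in the diary applications: lam1^2 ~ Gamma(mean 1, dof 0.001),
    lam2 ~ Gamma(1, 0.01), theta_vk ~ Gamma(1, 0.01),
    Lambda ~ Wishart((R-1) I_R, 1) (prior mean = dof * scale), and a
    MVN(0, 100 I) prior on the expansion vector alpha."""

    p: int = 1
    mu1: float = 1.0
    nu1: float = 0.001
    mu2: float = 1.0
    nu2: float = 0.01
    k_theta: float = 1.0
    s_theta: float = 0.01
    wishart_dof: float = 1.0
    K_scale: np.ndarray | None = None  # default (R-1) I_R, or I_R when R = 1
    alpha_prior_var: float = 100.0
    gamma_mean_dof: bool = True
    l1_prior_on_square: bool = True

    def gamma_shape_rate(self, mean: float, dof: float) -> tuple[float, float]:
        if self.gamma_mean_dof:
            return dof / 2.0, dof / (2.0 * mean)
        return mean, dof  # direct shape/rate entry

    @property
    def a1b1(self):
        return self.gamma_shape_rate(self.mu1, self.nu1)

    @property
    def a2b2(self):
        return self.gamma_shape_rate(self.mu2, self.nu2)

    @property
    def a3b3(self):
        return self.gamma_shape_rate(self.k_theta, self.s_theta)

    def scale_matrix(self, R: int) -> np.ndarray:
        if self.K_scale is not None:
            K = np.asarray(self.K_scale, dtype=float)
            if K.shape != (R, R):
                raise ValueError("K_scale must be R x R")
            return K
        return max(R - 1, 1) * np.eye(R)


@dataclass
class ModelState:
    """One point of the expanded parameter space."""

    w: np.ndarray          # (k,) population coefficients, k = R^2 p
    v: np.ndarray          # (N, k) unexpanded patient deviations
    alpha: np.ndarray      # (k,) expansion vector
    Lambda: np.ndarray     # (R, R) innovation precision
    two_tau2: np.ndarray   # (k,) latent elastic-net scales 2 tau_k^2
    lam1_sq: np.ndarray    # (k,) squared L1 weights
    lam2: np.ndarray       # (k,) L2 weights
    theta_v: np.ndarray    # (k,) deviation precisions diag(Theta_v)
    jitter_events: int = 0

    @property
    def lam1(self) -> np.ndarray:
        return np.sqrt(self.lam1_sq)

    @property
    def D(self) -> np.ndarray:
        """Diagonal of the population prior precision, lam2 + 1/(2 tau^2)."""
        return self.lam2 + 1.0 / self.two_tau2

    @property
    def v_star(self) -> np.ndarray:
        """Identified deviations alpha * v_n (elementwise), shape (N, k)."""
        return self.alpha[None, :] * self.v

    def validate(self) -> None:
        for name in ("two_tau2", "lam1_sq", "lam2", "theta_v"):
            arr = getattr(self, name)
            if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
                raise ValueError(f"state invariant violated: {name} must be positive")
        if not np.allclose(self.Lambda, self.Lambda.T, atol=1e-8):
            raise ValueError("state invariant violated: Lambda not symmetric")


@dataclass
class PosteriorDraws:
    """Post-warmup, thinned draws from every chain.

    ``chains`` maps parameter name -> list (one per chain) of arrays whose
    leading axis indexes draws.  Stored parameters: w, v, alpha, Lambda,
    two_tau2, lam1, lam2, theta_raw, plus the derived identified quantities
    v_star = alpha * v, w_n = w + v_star, and theta_v = theta_raw / alpha^2
    (the precision of the identified deviations v*; the raw theta and alpha
    are individually non-identified under parameter expansion).
    """

    chains: dict
    R: int
    p: int
    N: int
    patient_ids: list[str]
    sampler_config: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return len(self.chains["w"])

    def stacked(self, name: str) -> np.ndarray:
        """All chains concatenated along the draw axis."""
        return np.concatenate(self.chains[name], axis=0)

    def per_chain(self, name: str) -> list[np.ndarray]:
        return self.chains[name]


def compute_xi2(Lambda: np.ndarray, R: int, p: int) -> np.ndarray:
    """Conditional variances xi2_k of coordinate k given coordinates k+1..R^2 p
    under the covariance M = I_{Rp} (x) Lambda^{-1}.

    M is block diagonal, so xi2 depends on k only through its position
    j = ((k-1) mod R) + 1 inside its block, and equals the (j, j) entry of
    the inverse of the leading j x j block of Lambda.
    """
    Lambda = np.asarray(Lambda, dtype=float)
    if not np.allclose(Lambda, Lambda.T, atol=1e-8):
        raise ValueError("Lambda must be symmetric")
    sign, _ = np.linalg.slogdet(Lambda)
    if sign <= 0:
        raise ValueError("Lambda must be positive definite")
    block = np.empty(R)
    for j in range(1, R + 1):
        block[j - 1] = np.linalg.inv(Lambda[:j, :j])[j - 1, j - 1]
    if np.any(block <= 0):
        raise ValueError("Lambda must be positive definite")
    return np.tile(block, R * p)


def _chol_solve_sample(P: np.ndarray, b: np.ndarray, rng: np.random.Generator,
                       state: ModelState | None, component: str) -> np.ndarray:
    """Draw from MVN(P^{-1} b, P^{-1}), symmetrizing and jittering P on
    Cholesky failure (counted on the state)."""
    P = 0.5 * (P + P.T)
    scale = float(np.mean(np.diag(P))) or 1.0
    jitter = 0.0
    for attempt in range(8):
        try:
            L = np.linalg.cholesky(P + jitter * np.eye(P.shape[0]))
            break
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10, 1e-10 * scale)
            if state is not None:
                state.jitter_events += 1
    else:
        raise np.linalg.LinAlgError(
            f"conditional precision for {component!r} is not positive definite"
        )
    mean = np.linalg.solve(L.T, np.linalg.solve(L, b))
    z = rng.standard_normal(P.shape[0])
    return mean + np.linalg.solve(L.T, z)


_LOG_BOUND = 690.0  # positive scalars restricted to [~1e-300, ~1e300]


def _slice_sample(logf_raw, x0: float, rng: np.random.Generator,
                  width: float = 2.0, max_steps: int = 100) -> float:
    """Univariate stepping-out slice sampler (Neal 2003), on a log-scale
    coordinate bounded to avoid float under/overflow under nearly flat
    hyperpriors."""
    def logf(s):
        if abs(s) > _LOG_BOUND:
            return -math.inf
        return logf_raw(s)

    x0 = min(max(x0, -_LOG_BOUND + 1), _LOG_BOUND - 1)
    logy = logf(x0) - rng.exponential()
    u = rng.uniform()
    lo, hi = x0 - u * width, x0 + (1 - u) * width
    j = int(rng.integers(0, max_steps))
    k = max_steps - 1 - j
    while j > 0 and logf(lo) > logy:
        lo -= width
        j -= 1
    while k > 0 and logf(hi) > logy:
        hi += width
        k -= 1
    for _ in range(1000):
        x1 = rng.uniform(lo, hi)
        if logf(x1) > logy:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1
    return x0  # pathological shrinkage; keep current value


def _resid_matrix(entry: DesignEntry, coef: np.ndarray) -> np.ndarray:
    R = entry.R
    A_cat = coef.reshape(R, R * entry.p, order="F")
    return entry.Y - A_cat @ entry.H


def _grams(designs: list[DesignEntry]) -> list[np.ndarray]:
    return [e.H @ e.H.T for e in designs]


def _kron(G: np.ndarray, L: np.ndarray) -> np.ndarray:
    """kron(G, L) without np.kron's shape-juggling overhead (hot path)."""
    m, R = G.shape[0], L.shape[0]
    return (G[:, None, :, None] * L[None, :, None, :]).reshape(m * R, m * R)


def _krons(state: "ModelState", designs, grams) -> list[np.ndarray]:
    """Per-patient X^T Omega X = (H H^T) kron Lambda at the current Lambda."""
    return [_kron(G, state.Lambda) for G in grams]


# --- conditional updates (each exposed for oracle testing) -----------------

def w_conditional(state: ModelState, designs: list[DesignEntry],
                  krons: list[np.ndarray] | None = None):
    """Precision and linear term of the Gaussian conditional for w."""
    k = state.w.shape[0]
    P = np.diag(state.D).astype(float)
    b = np.zeros(k)
    krons = krons if krons is not None else _krons(state, designs, _grams(designs))
    for entry, XtOX, v_n in zip(designs, krons, state.v_star):
        P += XtOX
        E = _resid_matrix(entry, v_n)  # Y - mat(v*_n) H
        b += (state.Lambda @ E @ entry.H.T).reshape(-1, order="F")
    return P, b


def update_w(state, designs, rng, krons=None):
    P, b = w_conditional(state, designs, krons)
    state.w = _chol_solve_sample(P, b, rng, state, "w")


def v_conditional(state, designs, n, krons=None):
    entry = designs[n]
    XtOX = (krons[n] if krons is not None
            else _kron(entry.H @ entry.H.T, state.Lambda))
    P = XtOX * np.outer(state.alpha, state.alpha) + np.diag(state.theta_v)
    E = _resid_matrix(entry, state.w)
    b = state.alpha * (state.Lambda @ E @ entry.H.T).reshape(-1, order="F")
    return P, b


def update_v(state, designs, rng, krons=None):
    for n in range(len(designs)):
        P, b = v_conditional(state, designs, n, krons)
        state.v[n] = _chol_solve_sample(P, b, rng, state, f"v[{n}]")


def alpha_conditional(state, designs, hyper: HyperParams, krons=None):
    k = state.w.shape[0]
    P = np.eye(k) / hyper.alpha_prior_var
    b = np.zeros(k)
    krons = krons if krons is not None else _krons(state, designs, _grams(designs))
    for entry, XtOX, v_n in zip(designs, krons, state.v):
        P += XtOX * np.outer(v_n, v_n)
        E = _resid_matrix(entry, state.w)
        b += v_n * (state.Lambda @ E @ entry.H.T).reshape(-1, order="F")
    return P, b


def update_alpha(state, designs, hyper, rng, krons=None):
    P, b = alpha_conditional(state, designs, hyper, krons)
    state.alpha = _chol_solve_sample(P, b, rng, state, "alpha")


def _lambda_exponent_tail(state: ModelState, Lambda: np.ndarray, R: int, p: int) -> float:
    """Sum over coordinates with block position j >= 2 of
    -(lam1^2 * 2tau2 / 2) / xi2_k(Lambda): the part of the latent-scale prior
    that is nonlinear in Lambda and must enter the Metropolis ratio."""
    if R == 1:
        return 0.0
    xi2 = compute_xi2(Lambda, R, p)
    c = 0.5 * state.lam1_sq * state.two_tau2
    pos = np.tile(np.arange(R), R * p)  # block position of each coordinate
    mask = pos >= 1
    return float(-np.sum(c[mask] / xi2[mask]))


def lambda_proposal_params(state: ModelState, designs: list[DesignEntry],
                           hyper: HyperParams, R: int, p: int):
    """Degrees of freedom and scale of the Wishart proposal for Lambda.

    dof = wishart_dof + sum_n (T_n - p) + 2 R p  (the 2Rp from the
    det(Lambda)^{Rp} factor contributed by prod_k 1/xi2_k); inverse scale =
    K^{-1} + residual scatter + the leading-coordinate exponential terms,
    which are linear in Lambda_11.
    """
    K = hyper.scale_matrix(R)
    S = np.zeros((R, R))
    n_obs = 0
    for entry, coef in zip(designs, state.w[None, :] + state.v_star):
        E = _resid_matrix(entry, coef)
        S += E @ E.T
        n_obs += entry.n_obs
    dof = hyper.wishart_dof + n_obs + 2 * R * p
    c = 0.5 * state.lam1_sq * state.two_tau2
    pos = np.tile(np.arange(R), R * p)
    q1 = float(np.sum(c[pos == 0]))
    inv_scale = np.linalg.inv(K) + S
    inv_scale[0, 0] += 2.0 * q1
    return dof, np.linalg.inv(inv_scale)


def update_lambda(state, designs, hyper, rng, R, p):
    dof, scale = lambda_proposal_params(state, designs, hyper, R, p)
    scale = 0.5 * (scale + scale.T)
    prop = stats.wishart.rvs(df=dof, scale=scale, random_state=rng)
    prop = np.atleast_2d(prop)
    prop = 0.5 * (prop + prop.T)
    if R == 1:
        state.Lambda = prop  # accept ratio identically 1
        return
    log_ratio = (_lambda_exponent_tail(state, prop, R, p)
                 - _lambda_exponent_tail(state, state.Lambda, R, p))
    if math.log(rng.uniform()) < log_ratio:
        state.Lambda = prop


def update_two_tau2(state, hyper, rng, xi2):
    """Slice update of each latent scale u_k = 2 tau_k^2 (in log space).

    Target: f(u) propto u^{-1/2} (1 + lam2 u)^{1/2}
                       exp(-w^2/(2u) - lam1^2 u / (2 xi2)).
    """
    for k in range(state.w.shape[0]):
        w2 = state.w[k] ** 2
        lam2 = state.lam2[k]
        rate = state.lam1_sq[k] / (2.0 * xi2[k])

        def logf(s, w2=w2, lam2=lam2, rate=rate):
            u = math.exp(s)
            return (0.5 * s + 0.5 * math.log1p(lam2 * u)
                    - w2 / (2.0 * u) - rate * u)

        s0 = math.log(state.two_tau2[k])
        state.two_tau2[k] = math.exp(_slice_sample(logf, s0, rng))


def update_lam1(state, hyper, rng, xi2):
    """Conjugate Gamma update of lam1_k^2 (default), or slice update of
    lam1_k when the Gamma prior is placed on lam1 itself."""
    a1, b1 = hyper.a1b1
    tau2 = 0.5 * state.two_tau2
    if hyper.l1_prior_on_square:
        shape = a1 + 1.0
        rate = b1 + tau2 / xi2
        state.lam1_sq = np.maximum(rng.gamma(shape, 1.0 / rate), 1e-300)
    else:
        for k in range(state.w.shape[0]):
            coef = tau2[k] / xi2[k]

            def logf(s, coef=coef):
                lam = math.exp(s)
                return a1 * s - b1 * lam + 2.0 * s - coef * lam * lam

            s0 = 0.5 * math.log(state.lam1_sq[k])
            lam = math.exp(_slice_sample(logf, s0, rng))
            state.lam1_sq[k] = lam * lam


def update_lam2(state, hyper, rng):
    """Slice update of lam2_k:
    f(x) propto x^{a2-1} e^{-b2 x} (x + 1/u)^{1/2} exp(-w^2 x / 2)."""
    a2, b2 = hyper.a2b2
    for k in range(state.w.shape[0]):
        w2 = state.w[k] ** 2
        inv_u = 1.0 / state.two_tau2[k]

        def logf(s, w2=w2, inv_u=inv_u):
            x = math.exp(s)
            return (a2 * s - b2 * x + 0.5 * math.log(x + inv_u)
                    - 0.5 * w2 * x)

        s0 = math.log(state.lam2[k])
        state.lam2[k] = math.exp(_slice_sample(logf, s0, rng))


def update_theta(state, hyper, rng):
    """Conjugate Gamma update of the deviation precisions theta_vk."""
    a3, b3 = hyper.a3b3
    N = state.v.shape[0]
    shape = a3 + 0.5 * N
    rate = b3 + 0.5 * np.sum(state.v**2, axis=0)
    state.theta_v = np.maximum(rng.gamma(shape, 1.0 / rate), 1e-300)


# --- sweep and driver -------------------------------------------------------

def init_state(hyper: HyperParams, designs: list[DesignEntry], seed,
               R: int | None = None) -> ModelState:
    """Deterministic-given-seed initial state: coefficients at zero, alpha at
    one, Lambda at the (diagonally loaded) pooled sample precision, positive
    scalars drawn from their priors (clipped away from over/underflow)."""
    rng = np.random.default_rng(seed)
    if designs:
        R = designs[0].R
        p = designs[0].p
    else:
        if R is None:
            raise ValueError("R must be given when designs is empty")
        p = hyper.p
    k = R * R * p
    N = len(designs)
    if designs:
        pooled = np.hstack([e.Y for e in designs])  # R x total
        cov = np.cov(pooled) if pooled.shape[1] > 1 else np.eye(R)
        cov = np.atleast_2d(cov) + 1e-3 * np.eye(R)
        Lambda = np.linalg.inv(cov)
    else:
        Lambda = np.eye(R) / max(R - 1, 1)  # prior mean of Wishart((R-1)I, 1)
    a1, b1 = hyper.a1b1
    a2, b2 = hyper.a2b2
    a3, b3 = hyper.a3b3
    clip = lambda x: np.clip(x, 1e-6, 1e6)
    lam1_sq = clip(rng.gamma(a1, 1.0 / b1, size=k))
    lam2 = clip(rng.gamma(a2, 1.0 / b2, size=k))
    theta = clip(rng.gamma(a3, 1.0 / b3, size=k))
    xi2 = compute_xi2(Lambda, R, p)
    two_tau2 = clip(rng.exponential(1.0 / (lam1_sq / (2 * xi2))))
    return ModelState(
        w=np.zeros(k),
        v=np.zeros((N, k)),
        alpha=np.ones(k),
        Lambda=Lambda,
        two_tau2=two_tau2,
        lam1_sq=lam1_sq,
        lam2=lam2,
        theta_v=theta,
    )


def gibbs_sweep(state: ModelState, designs: list[DesignEntry],
                hyper: HyperParams, rng: np.random.Generator,
                grams: list[np.ndarray] | None = None) -> ModelState:
    """One full scan over all conditionals, in fixed order."""
    R = designs[0].R if designs else state.Lambda.shape[0]
    p = designs[0].p if designs else hyper.p
    grams = grams if grams is not None else _grams(designs)
    krons = _krons(state, designs, grams)  # Lambda fixed across these three
    update_w(state, designs, rng, krons)
    update_v(state, designs, rng, krons)
    update_alpha(state, designs, hyper, rng, krons)
    update_lambda(state, designs, hyper, rng, R, p)
    xi2 = compute_xi2(state.Lambda, R, p)
    update_two_tau2(state, hyper, rng, xi2)
    update_lam1(state, hyper, rng, xi2)
    update_lam2(state, hyper, rng)
    update_theta(state, hyper, rng)
    return state


def run_gibbs(panel, p: int = 1, hyper: HyperParams | None = None,
              chains: int = 4, iterations: int = 2000, warmup: int | None = None,
              thin: int = 1, seed: int = 0, progress=None) -> PosteriorDraws:
    """Fit the hierarchical VAR by Gibbs sampling on a preprocessed panel.

    Stored draws per chain = (iterations - warmup) // thin; warmup defaults
    to iterations // 2.  Chains use independent seed streams spawned from
    the master seed, so the run is reproducible given (seed, chains,
    iterations, warmup, thin).
    """
    hyper = hyper or HyperParams(p=p)
    if hyper.p != p:
        hyper = HyperParams(**{**hyper.__dict__, "p": p})
    warmup = iterations // 2 if warmup is None else warmup
    if not (0 <= warmup < iterations):
        raise ValueError("need 0 <= warmup < iterations")
    designs = build_design_set(panel, p)
    grams = _grams(designs)
    R = designs[0].R
    N = len(designs)
    k = R * R * p
    n_keep = (iterations - warmup) // thin
    seeds = np.random.SeedSequence(seed).spawn(chains)

    names = ["w", "v", "alpha", "Lambda", "two_tau2", "lam1", "lam2",
             "theta_raw", "theta_v", "v_star", "w_n"]
    chains_out: dict = {nm: [] for nm in names}
    for c in range(chains):
        rng = np.random.default_rng(seeds[c])
        try:
            state = init_state(hyper, designs, seeds[c].spawn(1)[0])
            store = {
                "w": np.empty((n_keep, k)), "v": np.empty((n_keep, N, k)),
                "alpha": np.empty((n_keep, k)), "Lambda": np.empty((n_keep, R, R)),
                "two_tau2": np.empty((n_keep, k)), "lam1": np.empty((n_keep, k)),
                "lam2": np.empty((n_keep, k)), "theta_raw": np.empty((n_keep, k)),
                "theta_v": np.empty((n_keep, k)),
                "v_star": np.empty((n_keep, N, k)), "w_n": np.empty((n_keep, N, k)),
            }
            kept = 0
            for it in range(iterations):
                gibbs_sweep(state, designs, hyper, rng, grams)
                if it >= warmup and (it - warmup) % thin == 0 and kept < n_keep:
                    vs = state.v_star
                    store["w"][kept] = state.w
                    store["v"][kept] = state.v
                    store["alpha"][kept] = state.alpha
                    store["Lambda"][kept] = state.Lambda
                    store["two_tau2"][kept] = state.two_tau2
                    store["lam1"][kept] = state.lam1
                    store["lam2"][kept] = state.lam2
                    store["theta_raw"][kept] = state.theta_v
                    store["theta_v"][kept] = state.theta_v / state.alpha**2
                    store["v_star"][kept] = vs
                    store["w_n"][kept] = state.w[None, :] + vs
                    kept += 1
                if progress is not None and (it + 1) % max(1, iterations // 10) == 0:
                    progress(c, it + 1, iterations)
        except Exception as exc:  # noqa: BLE001 - annotate with chain id
            raise RuntimeError(f"chain {c} failed: {exc}") from exc
        for nm in names:
            chains_out[nm].append(store[nm])
    return PosteriorDraws(
        chains=chains_out, R=R, p=p, N=N,
        patient_ids=[e.patient_id for e in designs],
        sampler_config={
            "p": p, "chains": chains, "iterations": iterations,
            "warmup": warmup, "thin": thin, "seed": seed,
            "draws_per_chain": n_keep,
        },
    )
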