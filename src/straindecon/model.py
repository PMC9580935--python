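"""Generative model of metagenotype data and its differentiable MAP objective.

Structure
---------
Latent strain genotypes ``Gamma`` (S x G, fuzzy values in (0, 1)) and
per-sample strain compositions ``Pi`` (N x S rows on the simplex)
combine into underlying alternative-allele frequencies

    P = Pi @ Gamma            (p_ig = sum_s pi_is * gamma_sg).

Measurement: with per-sample error rate eps_i the true allele is
replaced by a random allele, so the expected observed frequency is

    ptilde = p * (1 - eps/2) + (1 - p) * (eps/2),

and observed alternative counts are Beta-Binomial,
``y ~ BetaBinom(ptilde, alpha* | m)`` with concentration ``alpha*``.

Priors (all shifted-scaled Dirichlet, see :mod:`.distributions`):

    (gamma, 1-gamma) ~ SSD(1, 1, 1/gamma*)       per genotype entry
    pi_i             ~ SSD(1, rho, 1/pi*)        per sample row
    rho              ~ SSD(1, 1, 1/rho*)         metacommunity
    eps              ~ Beta                      per sample

Smaller gamma*/pi*/rho* mean stronger regularization (sparser
genotypes, fewer strains per sample, fewer strains overall).

Estimator
---------
Point estimates are MAP *in the unconstrained parameterization* (the
convention of autodiff probabilistic-programming stacks: the objective
is the log posterior density plus the log-Jacobian of the
simplex/interval transforms).  This choice is substantive, not
cosmetic.  The corner-seeking SSD priors have unbounded density at the
simplex boundary, so constrained-space MAP is degenerate: its "mode"
is full collapse of every composition onto one strain regardless of the
data (empirically the optimizer walks away from the simulation ground
truth to reach it).  The transform Jacobians vanish at the boundary at
exactly the rate needed to make the objective bounded: the genotype
prior then anneals from center-seeking (gamma* = 1) to flat
(gamma* -> 0), gradually releasing fuzzy genotypes to discretize under
likelihood pressure, and the composition prior becomes a bounded
shrinkage toward the metacommunity profile with corner-friendly heavy
tails.

A second guard concerns the hierarchy: the SSD density of pi given rho
carries a normalization factor prod_s rho_s**(-pi*) that depends on rho
but not on pi.  Summed over N samples it rewards sending rho to a
simplex vertex (with every pi row following) by ~N * pi* *
sum_s(-log rho_s), an unbounded ridge that the Jacobian term (whose
coefficient does not grow with N) cannot contain.  The objective
therefore couples pi to rho through the scale-invariant alignment term
``-S log sum_s (pi_s/rho_s)**pi*`` only; rho is estimated solely by how
well it explains the observed rows.  See docs/methods.md.

:func:`log_posterior` reports the constrained-space log density (the
quantity the priors and likelihood define); the optimizer's objective
adds the log-Jacobian terms and is exposed via
:class:`PosteriorObjective`.

The joint log posterior is fully differentiable in a log-odds /
anchored-softmax reparameterization; this module provides the value and
the analytic gradient (digamma terms for the likelihood, closed forms
for the priors) used by the optimizer in :mod:`.inference`.  MAP point
estimates are taken for the constrained-space density; the
reparameterization is purely a numerical device (no Jacobian term).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.special import betaln, digamma, gammaln

from .metagenotype import Metagenotype

_TINY = 1e-300
_EPS_INTERIOR = 1e-15
_PTIL_FLOOR = 1e-10  # keeps digamma terms finite at cornered frequencies


@dataclasses.dataclass(frozen=True)
class Hyperparameters:
    """Model hyperparameters with the defaults used throughout.

    gamma_star : genotype sparsity (smaller = fuzzier entries pushed
        harder toward 0/1)
    pi_star    : within-sample strain diversity regularization
    rho_star   : across-sample (metacommunity) diversity regularization
    alpha_star : Beta-Binomial concentration (count overdispersion)
    eps_a, eps_b : error-rate prior shapes.  With the default
        ``epsilon_prior_orientation="error-rate"`` the prior is
        Beta(eps_a * eps_b, eps_a), whose mean eps_b / (1 + eps_b) is a
        small error rate (~0.01 at the defaults).  The alternative
        orientation ``"reversed"`` uses Beta(eps_a, eps_a * eps_b),
        which concentrates near 1 and systematically inflates fitted
        error rates at shallow depth; it is provided for comparison
        only.
    """

    gamma_star: float = 1e-10
    pi_star: float = 0.3
    rho_star: float = 0.5
    alpha_star: float = 10.0
    eps_a: float = 1.5
    eps_b: float = 0.01
    epsilon_prior_orientation: str = "error-rate"

    def __post_init__(self):
        for name in ("gamma_star", "pi_star", "rho_star", "alpha_star", "eps_a", "eps_b"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.epsilon_prior_orientation not in ("error-rate", "reversed"):
            raise ValueError("epsilon_prior_orientation must be 'error-rate' or 'reversed'")

    def epsilon_shapes(self) -> tuple[float, float]:
        a, b = self.eps_a, self.eps_a * self.eps_b
        return (a, b) if self.epsilon_prior_orientation == "reversed" else (b, a)


@dataclasses.dataclass(frozen=True)
class ModelParams:
    """A full parameter point: Pi (N x S), Gamma (S x G), rho (S), epsilon (N)."""

    pi: np.ndarray
    gamma: np.ndarray
    rho: np.ndarray
    epsilon: np.ndarray

    def __post_init__(self):
        pi = np.asarray(self.pi, dtype=float)
        gamma = np.asarray(self.gamma, dtype=float)
        rho = np.asarray(self.rho, dtype=float)
        epsilon = np.atleast_1d(np.asarray(self.epsilon, dtype=float))
        N, S = pi.shape
        S2, G = gamma.shape
        if S2 != S or rho.shape != (S,) or epsilon.shape != (N,):
            raise ValueError("inconsistent parameter shapes")
        if (pi < 0).any() or (gamma < 0).any() or (gamma > 1).any():
            raise ValueError("pi must be non-negative; gamma must lie in [0, 1]")
        row = pi.sum(axis=1)
        if not np.allclose(row, 1.0, atol=1e-6):
            raise ValueError("pi rows must sum to 1 (tolerance 1e-6)")
        pi = pi / row[:, None]  # renormalize silently below tolerance
        if (rho < 0).any() or not np.isclose(rho.sum(), 1.0, atol=1e-6):
            raise ValueError("rho must be on the simplex")
        rho = rho / rho.sum()
        if (epsilon <= 0).any() or (epsilon >= 1).any():
            raise ValueError("epsilon must lie in (0, 1)")
        object.__setattr__(self, "pi", pi)
        object.__setattr__(self, "gamma", gamma)
        object.__setattr__(self, "rho", rho)
        object.__setattr__(self, "epsilon", epsilon)

    @property
    def n_samples(self) -> int:
        return self.pi.shape[0]

    @property
    def n_strains(self) -> int:
        return self.pi.shape[1]

    @property
    def n_sites(self) -> int:
        return self.gamma.shape[1]

    def permute_strains(self, order) -> "ModelParams":
        order = np.asarray(order, dtype=int)
        return ModelParams(
            self.pi[:, order], self.gamma[order, :], self.rho[order], self.epsilon
        )


# ---------------------------------------------------------------------------
# Deterministic structure
# ---------------------------------------------------------------------------

def predict_allele_freq(pi: np.ndarray, gamma: np.ndarray) -> np.ndarray:
    """Underlying alternative-allele frequencies P = Pi @ Gamma (N x G)."""
    pi = np.asarray(pi, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    if pi.shape[1] != gamma.shape[0]:
        raise ValueError(
            f"shape mismatch: pi is {pi.shape}, gamma is {gamma.shape}"
        )
    return pi @ gamma


def apply_error(p: np.ndarray, epsilon) -> np.ndarray:
    """Expected observed frequency after symmetric allele error.

    ptilde = p (1 - eps/2) + (1 - p) (eps/2); eps may be scalar or
    per-sample (broadcast along rows).  p = 1/2 is a fixed point.
    """
    p = np.asarray(p, dtype=float)
    eps = np.asarray(epsilon, dtype=float)
    if eps.ndim == 1:
        eps = eps[:, None]
    return p * (1.0 - eps / 2.0) + (1.0 - p) * (eps / 2.0)


# ---------------------------------------------------------------------------
# Log-posterior pieces (constrained space)
# ---------------------------------------------------------------------------

def _ssd_flat_log_density_2(gamma: np.ndarray, h: float) -> np.ndarray:
    """log SSD(1, 1, 1/h) density of (gamma, 1-gamma); vectorized.

    D = 2, alpha = (1, 1), reference (1/2, 1/2), scale 1/h.
    """
    g = np.clip(gamma, _EPS_INTERIOR, 1.0 - _EPS_INTERIOR)
    lg, lo = np.log(2.0 * g), np.log(2.0 * (1.0 - g))
    u, v = np.exp(h * lg), np.exp(h * lo)
    return np.log(h) + h * (lg + lo) - np.log(g) - np.log1p(-g) - 2.0 * np.log(u + v)


def _ssd_flat_log_density_2_grad(gamma: np.ndarray, h: float) -> np.ndarray:
    g = np.clip(gamma, _EPS_INTERIOR, 1.0 - _EPS_INTERIOR)
    u = np.exp(h * np.log(2.0 * g))
    v = np.exp(h * np.log(2.0 * (1.0 - g)))
    return (h - 1.0) * (1.0 / g - 1.0 / (1.0 - g)) - 2.0 * h * (
        u / g - v / (1.0 - g)
    ) / (u + v)


def _ssd_rows_log_density(x: np.ndarray, q: np.ndarray, h: float) -> np.ndarray:
    """log SSD(1, q, 1/h) density per row of x (rows on the D-simplex)."""
    x = np.clip(x, _EPS_INTERIOR, None)
    D = x.shape[-1]
    log_ratio = np.log(x) - np.log(q)
    t = np.exp(h * log_ratio)
    return (
        gammaln(D)
        + (D - 1) * np.log(h)
        + h * log_ratio.sum(axis=-1)
        - np.log(x).sum(axis=-1)
        - D * np.log(t.sum(axis=-1))
    )


def _ssd_rows_log_density_grads(x: np.ndarray, q: np.ndarray, h: float):
    """Gradients of the row-wise SSD(1, q, 1/h) log density in x and q."""
    x = np.clip(x, _EPS_INTERIOR, None)
    D = x.shape[-1]
    t = np.exp(h * (np.log(x) - np.log(q)))
    T = t.sum(axis=-1, keepdims=True)
    gx = (h - 1.0) / x - D * h * t / (x * T)
    gq = -h / q + D * h * t / (q * T)
    return gx, gq


def _community_log_kernel(pi: np.ndarray, rho: np.ndarray, h: float) -> np.ndarray:
    """Per-row log kernel coupling pi rows to the metacommunity rho.

    The SSD(1, rho, 1/h) log density with its rho-only normalization
    factor (+h * sum log rho) removed; identical in pi, but rho enters
    only through the alignment term (see the module docstring).
    """
    pi = np.clip(pi, _EPS_INTERIOR, None)
    D = pi.shape[-1]
    t = np.exp(h * (np.log(pi) - np.log(rho)))
    return (
        gammaln(D)
        + (D - 1) * np.log(h)
        + (h - 1.0) * np.log(pi).sum(axis=-1)
        - D * np.log(t.sum(axis=-1))
    )


def _community_log_kernel_grads(pi: np.ndarray, rho: np.ndarray, h: float):
    """Gradients of the community kernel in pi and rho."""
    pi = np.clip(pi, _EPS_INTERIOR, None)
    D = pi.shape[-1]
    t = np.exp(h * (np.log(pi) - np.log(rho)))
    T = t.sum(axis=-1, keepdims=True)
    gx = (h - 1.0) / pi - D * h * t / (pi * T)
    gq = D * h * t / (rho * T)
    return gx, gq


def _beta_log_density(x: np.ndarray, a: float, b: float) -> np.ndarray:
    x = np.clip(x, _EPS_INTERIOR, 1.0 - _EPS_INTERIOR)
    return (a - 1.0) * np.log(x) + (b - 1.0) * np.log1p(-x) - betaln(a, b)


def log_likelihood(params: ModelParams, mgt: Metagenotype, hyper: Hyperparameters) -> float:
    """Beta-Binomial log likelihood over all cells with observed counts."""
    from .distributions import betabinom_log_pmf_raw

    ptil = apply_error(predict_allele_freq(params.pi, params.gamma), params.epsilon)
    ptil = np.clip(ptil, _PTIL_FLOOR, 1.0 - _PTIL_FLOOR)
    mask = mgt.total > 0
    ll = betabinom_log_pmf_raw(
        mgt.alt.astype(float), mgt.total.astype(float), ptil, hyper.alpha_star
    )
    return float(ll[mask].sum())


def genotype_prior(gamma: np.ndarray, gamma_star: float) -> float:
    """Sum of SSD(1, 1, 1/gamma*) log densities over genotype entries."""
    return float(_ssd_flat_log_density_2(np.asarray(gamma, float), gamma_star).sum())


def community_prior(pi: np.ndarray, rho: np.ndarray, pi_star: float) -> float:
    """Sum over samples of the pi | rho coupling kernel (see module docstring)."""
    return float(_community_log_kernel(np.asarray(pi, float), np.asarray(rho, float), pi_star).sum())


def metacommunity_prior(rho: np.ndarray, rho_star: float) -> float:
    """SSD(1, 1, 1/rho*) log density of the metacommunity composition."""
    rho = np.asarray(rho, dtype=float)
    S = len(rho)
    return float(_ssd_rows_log_density(rho[None, :], np.full(S, 1.0 / S), rho_star)[0])


def error_prior(epsilon: np.ndarray, hyper: Hyperparameters) -> float:
    """Sum of per-sample Beta log densities of the error rates."""
    ea, eb = hyper.epsilon_shapes()
    return float(_beta_log_density(np.asarray(epsilon, float), ea, eb).sum())


def log_posterior(
    params: ModelParams, mgt: Metagenotype, hyper: Hyperparameters
) -> float:
    """Joint MAP objective value (log scale; higher is better).

    Sum of the Beta-Binomial likelihood over all cells with observed
    counts plus the genotype, community, metacommunity and error-rate
    prior terms.  Parameters on the boundary give -inf rather than
    raising.
    """
    boundary = (
        (params.gamma <= 0).any()
        or (params.gamma >= 1).any()
        or (params.pi <= 0).any()
        or (params.rho <= 0).any()
    )
    if boundary:
        return -np.inf
    return (
        log_likelihood(params, mgt, hyper)
        + genotype_prior(params.gamma, hyper.gamma_star)
        + community_prior(params.pi, params.rho, hyper.pi_star)
        + metacommunity_prior(params.rho, hyper.rho_star)
        + error_prior(params.epsilon, hyper)
    )


# ---------------------------------------------------------------------------
# Unconstrained parameterization
# ---------------------------------------------------------------------------

def _sigmoid(x):
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softmax_anchor(logits: np.ndarray) -> np.ndarray:
    """Rows of free logits -> simplex rows by appending a fixed 0 logit."""
    full = np.concatenate([logits, np.zeros((*logits.shape[:-1], 1))], axis=-1)
    full -= full.max(axis=-1, keepdims=True)
    e = np.exp(full)
    return e / e.sum(axis=-1, keepdims=True)


def _softmax_anchor_grad(p: np.ndarray, grad_p: np.ndarray) -> np.ndarray:
    """Chain rule through the anchored softmax; returns grad wrt free logits."""
    inner = (p * grad_p).sum(axis=-1, keepdims=True)
    return (p * (grad_p - inner))[..., :-1]


class ParamTransform:
    """Bijection between interior ModelParams and a flat unconstrained vector.

    Layout: [Gamma logits (S*G), Pi free logits (N*(S-1)),
    rho free logits (S-1), epsilon logits (N)].  The all-zeros vector
    maps to uniform simplex rows, gamma = 0.5 and epsilon = 0.5.
    """

    def __init__(self, n_samples: int, n_strains: int, n_sites: int):
        self.N, self.S, self.G = n_samples, n_strains, n_sites
        sg, ns1 = self.S * self.G, self.N * (self.S - 1)
        self.sl_gamma = slice(0, sg)
        self.sl_pi = slice(sg, sg + ns1)
        self.sl_rho = slice(sg + ns1, sg + ns1 + self.S - 1)
        self.sl_eps = slice(sg + ns1 + self.S - 1, sg + ns1 + self.S - 1 + self.N)
        self.size = sg + ns1 + (self.S - 1) + self.N

    def constrain(self, theta: np.ndarray) -> ModelParams:
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.size,):
            raise ValueError(f"expected vector of length {self.size}")
        gamma = _sigmoid(theta[self.sl_gamma]).reshape(self.S, self.G)
        pi = _softmax_anchor(theta[self.sl_pi].reshape(self.N, self.S - 1))
        rho = _softmax_anchor(theta[self.sl_rho].reshape(1, self.S - 1))[0]
        eps = _sigmoid(theta[self.sl_eps])
        gamma = np.clip(gamma, _EPS_INTERIOR, 1.0 - _EPS_INTERIOR)
        eps = np.clip(eps, _EPS_INTERIOR, 1.0 - _EPS_INTERIOR)
        pi = np.clip(pi, _TINY, None)
        rho = np.clip(rho, _TINY, None)
        return ModelParams(pi / pi.sum(1, keepdims=True), gamma, rho / rho.sum(), eps)

    def unconstrain(self, params: ModelParams) -> np.ndarray:
        if (
            (params.gamma <= 0).any()
            or (params.gamma >= 1).any()
            or (params.pi <= 0).any()
            or (params.rho <= 0).any()
        ):
            raise ValueError("parameters must be strictly interior")
        theta = np.empty(self.size)
        g = params.gamma
        theta[self.sl_gamma] = np.log(g / (1.0 - g)).ravel()
        pi_log = np.log(params.pi)
        theta[self.sl_pi] = (pi_log[:, :-1] - pi_log[:, -1:]).ravel()
        rho_log = np.log(params.rho)
        theta[self.sl_rho] = rho_log[:-1] - rho_log[-1]
        e = params.epsilon
        theta[self.sl_eps] = np.log(e / (1.0 - e))
        return theta


# ---------------------------------------------------------------------------
# The differentiable objective
# ---------------------------------------------------------------------------

class PosteriorObjective:
    """Unconstrained-MAP loss (and analytic gradient) for the model.

    The loss is the negative of [log posterior density + log-Jacobian
    of the sigmoid/anchored-softmax transforms] — i.e. MAP in the
    unconstrained parameterization (see the module docstring for why
    the Jacobian terms are essential).  Precomputes the count-dependent
    constants of the Beta-Binomial likelihood; per call only the
    parameter-dependent terms and their digamma-based partials are
    evaluated.  The effective gamma*/rho* are arguments so the
    annealing schedule can vary them per step.
    """

    def __init__(
        self,
        mgt: Metagenotype,
        hyper: Hyperparameters,
        n_strains: int,
        precision: int = 64,
    ):
        if precision not in (32, 64):
            raise ValueError("precision must be 32 or 64")
        self.dtype = np.float32 if precision == 32 else np.float64
        self.hyper = hyper
        self.S = int(n_strains)
        self.N, self.G = mgt.n_samples, mgt.n_sites
        self.Y = mgt.alt.astype(np.float64)
        self.M = mgt.total.astype(np.float64)
        self.mask = self.M > 0
        conc = hyper.alpha_star
        # parameter-independent part of the masked log-likelihood
        const = (
            gammaln(self.M + 1.0)
            - gammaln(self.Y + 1.0)
            - gammaln(self.M - self.Y + 1.0)
            + gammaln(conc)
            - gammaln(self.M + conc)
        )
        self.ll_const = float(const[self.mask].sum())
        self.transform = ParamTransform(self.N, self.S, self.G)

    def value_and_grad(
        self, theta: np.ndarray, gamma_star_eff: float, rho_star_eff: float
    ):
        """Return (negative log posterior, gradient wrt theta)."""
        tr = self.transform
        hyper = self.hyper
        conc = hyper.alpha_star

        gamma = np.clip(
            _sigmoid(theta[tr.sl_gamma]).reshape(tr.S, tr.G),
            _EPS_INTERIOR,
            1.0 - _EPS_INTERIOR,
        )
        pi = np.clip(
            _softmax_anchor(theta[tr.sl_pi].reshape(tr.N, tr.S - 1)), _TINY, None
        )
        rho = np.clip(_softmax_anchor(theta[tr.sl_rho].reshape(1, tr.S - 1))[0], _TINY, None)
        eps = np.clip(_sigmoid(theta[tr.sl_eps]), _EPS_INTERIOR, 1.0 - _EPS_INTERIOR)

        # --- likelihood ---
        P = pi @ gamma
        ptil = P * (1.0 - eps[:, None]) + (0.5 * eps)[:, None]
        ptil = np.clip(ptil, _PTIL_FLOOR, 1.0 - _PTIL_FLOOR)
        a1 = ptil * conc
        a2 = (1.0 - ptil) * conc
        ll_var = (
            gammaln(self.Y + a1)
            + gammaln(self.M - self.Y + a2)
            - gammaln(a1)
            - gammaln(a2)
        )
        loglik = self.ll_const + float(ll_var[self.mask].sum())
        W = conc * (
            digamma(self.Y + a1)
            - digamma(self.M - self.Y + a2)
            - digamma(a1)
            + digamma(a2)
        )
        W[~self.mask] = 0.0

        one_m_eps = 1.0 - eps
        WG = W * one_m_eps[:, None]  # d loglik / d P
        grad_gamma = pi.T @ WG
        grad_pi = WG @ gamma.T
        grad_eps = (W * (0.5 - P)).sum(axis=1)

        # --- priors ---
        lp_gamma = float(_ssd_flat_log_density_2(gamma, gamma_star_eff).sum())
        grad_gamma += _ssd_flat_log_density_2_grad(gamma, gamma_star_eff)

        lp_pi = float(_community_log_kernel(pi, rho, hyper.pi_star).sum())
        gx, gq = _community_log_kernel_grads(pi, rho, hyper.pi_star)
        grad_pi += gx
        grad_rho = gq.sum(axis=0)

        lp_rho = float(
            _ssd_rows_log_density(rho[None, :], np.full(tr.S, 1.0 / tr.S), rho_star_eff)[0]
        )
        gx_rho, _ = _ssd_rows_log_density_grads(
            rho[None, :], np.full(tr.S, 1.0 / tr.S), rho_star_eff
        )
        grad_rho += gx_rho[0]

        ea, eb = hyper.epsilon_shapes()
        lp_eps = float(_beta_log_density(eps, ea, eb).sum())
        grad_eps += (ea - 1.0) / eps - (eb - 1.0) / (1.0 - eps)

        # --- log-Jacobian of the transforms (unconstrained-space MAP) ---
        log_jac = (
            float(np.log(gamma * (1.0 - gamma)).sum())
            + float(np.log(pi).sum())
            + float(np.log(rho).sum())
            + float(np.log(eps * (1.0 - eps)).sum())
        )
        grad_gamma += 1.0 / gamma - 1.0 / (1.0 - gamma)
        grad_pi += 1.0 / pi
        grad_rho += 1.0 / rho
        grad_eps += 1.0 / eps - 1.0 / (1.0 - eps)

        # --- chain rule to unconstrained coordinates ---
        grad = np.empty(tr.size)
        grad[tr.sl_gamma] = (grad_gamma * gamma * (1.0 - gamma)).ravel()
        grad[tr.sl_pi] = _softmax_anchor_grad(pi, grad_pi).ravel()
        grad[tr.sl_rho] = _softmax_anchor_grad(rho[None, :], grad_rho[None, :]).ravel()
        grad[tr.sl_eps] = grad_eps * eps * (1.0 - eps)

        logpost = loglik + lp_gamma + lp_pi + lp_rho + lp_eps + log_jac
        return -logpost, (-grad).astype(self.dtype, copy=False)
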