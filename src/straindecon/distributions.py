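"""Probability kernels: shifted-scaled Dirichlet and Beta-Binomial.

The shifted-scaled Dirichlet (SSD) generalizes the Dirichlet with a
reference composition ``p`` (a perturbation/shift in the Aitchison
geometry of the simplex) and a positive scale ``a`` (an Aitchison
powering).  Constructively, a draw is

    Z ~ Dirichlet(alpha),    X = closure(p_i * Z_i**a),

where closure renormalizes to the simplex.  For ``a = 1`` and uniform
``p`` this is exactly Dirichlet(alpha).  Large ``a`` pushes mass toward
the simplex vertices, which is what makes the SSD useful as a
sparsity-inducing prior: the model uses scale ``1/h`` with a small
hyperparameter ``h``, so smaller ``h`` means stronger corner-seeking.

The density with respect to Lebesgue measure on the first D-1
coordinates is

    f(x) = 1/B(alpha) * a**(1-D)
           * prod_i (x_i/p_i)**(alpha_i/a) / x_i
           * (sum_i (x_i/p_i)**(1/a))**(-sum(alpha))

(the change of variables of the Dirichlet density through the
perturbation-and-powering map above).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.special import gammaln, betaln
from scipy.stats import betabinom as _scipy_betabinom


@dataclasses.dataclass(frozen=True)
class SSDParams:
    """Parameters of a shifted-scaled Dirichlet distribution.

    alpha : positive concentration vector (length D)
    p     : reference composition on the interior of the simplex
    a     : positive scale (Aitchison power)
    """

    alpha: np.ndarray
    p: np.ndarray
    a: float

    def __post_init__(self):
        alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        p = np.atleast_1d(np.asarray(self.p, dtype=float))
        if alpha.shape != p.shape:
            raise ValueError("alpha and p must have the same length")
        if (alpha <= 0).any():
            raise ValueError("alpha must be positive")
        if (p <= 0).any() or not np.isclose(p.sum(), 1.0, atol=1e-8):
            raise ValueError("p must be strictly positive and sum to 1")
        if not self.a > 0:
            raise ValueError("scale a must be positive")
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "p", p / p.sum())

    @property
    def dim(self) -> int:
        return len(self.alpha)


def ssd_log_density(x, params: SSDParams) -> float | np.ndarray:
    """Log density of the SSD at interior simplex point(s) ``x``.

    ``x`` may be a single length-D vector or an (n, D) array of points.
    Components must be strictly positive; boundary points give -inf.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != params.dim:
        raise ValueError(f"x has dimension {X.shape[1]}, expected {params.dim}")
    alpha, p, a = params.alpha, params.p, params.a
    D = params.dim
    out = np.full(X.shape[0], -np.inf)
    interior = (X > 0).all(axis=1)
    Xi = X[interior]
    log_ratio = np.log(Xi) - np.log(p)  # log(x_i / p_i)
    log_norm = (
        -(gammaln(alpha).sum() - gammaln(alpha.sum()))  # -log B(alpha)
        - (D - 1) * np.log(a)
    )
    t = np.exp(log_ratio / a)
    out[interior] = (
        log_norm
        + (log_ratio * (alpha / a)).sum(axis=1)
        - np.log(Xi).sum(axis=1)
        - alpha.sum() * np.log(t.sum(axis=1))
    )
    return out[0] if single else out


def ssd_sample(params: SSDParams, n: int, seed: int = 0) -> np.ndarray:
    """Draw ``n`` SSD samples via the constructive definition.

    Z ~ Dirichlet(alpha); X = closure(p_i * Z_i**a).  Deterministic given
    ``seed``.  Returns an (n, D) array of simplex points.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    z = rng.dirichlet(params.alpha, size=n)
    # work in logs for numerical stability at large a
    logw = np.log(params.p) + params.a * np.log(np.maximum(z, 1e-300))
    logw -= logw.max(axis=1, keepdims=True)
    w = np.exp(logw)
    return w / w.sum(axis=1, keepdims=True)


def betabinom_log_pmf(y, m, mean, concentration) -> np.ndarray:
    """Beta-Binomial log-pmf in mean/concentration form.

    Shapes are ``mean * concentration`` and ``(1 - mean) * concentration``;
    the mean of Y/m is ``mean`` and ``concentration`` controls
    overdispersion relative to Binomial(m, mean) (Binomial limit as
    concentration -> inf).  ``mean`` exactly 0 or 1 is treated as a point
    mass at y = 0 or y = m.  Broadcasts over array arguments.
    """
    y = np.asarray(y)
    m = np.asarray(m)
    mean = np.asarray(mean, dtype=float)
    concentration = np.asarray(concentration, dtype=float)
    if (mean < 0).any() or (mean > 1).any():
        raise ValueError("mean must lie in [0, 1]")
    if (concentration <= 0).any():
        raise ValueError("concentration must be positive")
    if (y < 0).any() or (y > m).any():
        raise ValueError("need 0 <= y <= m")
    mean_b, conc_b, y_b, m_b = np.broadcast_arrays(mean, concentration, y, m)
    inner = (mean_b > 0) & (mean_b < 1)
    safe_mean = np.where(inner, mean_b, 0.5)
    out = _scipy_betabinom.logpmf(
        y_b, m_b, safe_mean * conc_b, (1.0 - safe_mean) * conc_b
    )
    # point masses at the boundary
    out = np.where(mean_b == 0.0, np.where(y_b == 0, 0.0, -np.inf), out)
    out = np.where(mean_b == 1.0, np.where(y_b == m_b, 0.0, -np.inf), out)
    return out if out.ndim else float(out)


def betabinom_log_pmf_raw(y, m, mean, concentration):
    """Vectorized lgamma expression for the Beta-Binomial log-pmf.

    Identical in value to :func:`betabinom_log_pmf` on interior means;
    written out explicitly so the model can differentiate it (its partial
    derivative in ``mean`` only needs digamma terms).
    """
    a1 = mean * concentration
    a2 = (1.0 - mean) * concentration
    return (
        gammaln(m + 1.0)
        - gammaln(y + 1.0)
        - gammaln(m - y + 1.0)
        + gammaln(y + a1)
        + gammaln(m - y + a2)
        - gammaln(m + concentration)
        - betaln(a1, a2)
    )
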