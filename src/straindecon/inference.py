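"""MAP fitting of the strain-deconvolution model.

The optimizer is Adam on the unconstrained parameterization with the
analytic gradient from :mod:`.model`.  The schedule follows the
standard recipe for this model:

* initialize Pi and Gamma from an NMF factorization of the observed
  allele-frequency matrix, epsilon at its prior mean, rho uniform;
* prior annealing — hold gamma* = 1.0 and rho* = 5 for the first 2,000
  steps, then relax both geometrically (log-linearly in the step index)
  to their final values over the next 8,000 steps;
* after the annealing period, halve the learning rate whenever the
  best-seen loss has not improved for 100 consecutive steps; declare
  convergence when the rate falls below 1e-6.

Fits are bit-reproducible for a fixed seed, precision and platform.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import xarray as xr
from sklearn.decomposition import NMF

from .metagenotype import Metagenotype
from .model import (
    Hyperparameters,
    ModelParams,
    ParamTransform,
    PosteriorObjective,
    _ssd_flat_log_density_2,
    _ssd_flat_log_density_2_grad,
    _sigmoid,
)


@dataclasses.dataclass(frozen=True)
class FitSchedule:
    """Optimization schedule settings (defaults are the standard recipe)."""

    learning_rate: float = 0.05
    anneal_hold: int = 2000
    anneal_relax: int = 8000
    anneal_gamma0: float = 1.0
    anneal_rho0: float = 5.0
    patience: int = 100
    lr_factor: float = 0.5
    lr_floor: float = 1e-6
    max_steps: int = 20000
    seed: int = 0

    def __post_init__(self):
        if self.anneal_hold < 0 or self.anneal_relax <= 0 or self.patience <= 0:
            raise ValueError("schedule counts must be positive")
        if not self.lr_floor < self.learning_rate:
            raise ValueError("lr_floor must be below the initial learning rate")


@dataclasses.dataclass
class FitResult:
    """Outcome of a MAP fit."""

    params: ModelParams
    loss_trace: np.ndarray  # negative log posterior per step
    steps: int
    final_lr: float
    converged: bool  # final learning rate fell below the floor
    seed: int
    samples: np.ndarray | None = None
    sites: np.ndarray | None = None

    def strain_labels(self) -> np.ndarray:
        return np.array([f"strain_{s}" for s in range(self.params.n_strains)])

    def to_xarray(self) -> xr.Dataset:
        p = self.params
        samples = self.samples if self.samples is not None else np.arange(p.n_samples).astype(str)
        sites = self.sites if self.sites is not None else np.arange(p.n_sites).astype(str)
        return xr.Dataset(
            {
                "pi": (("sample", "strain"), p.pi),
                "gamma": (("strain", "site"), p.gamma),
                "rho": (("strain",), p.rho),
                "epsilon": (("sample",), p.epsilon),
                "loss": (("step",), np.asarray(self.loss_trace, dtype=float)),
            },
            coords={
                "sample": np.asarray(samples, dtype=str),
                "site": np.asarray(sites, dtype=str),
                "strain": self.strain_labels(),
            },
            attrs={
                "steps": self.steps,
                "final_lr": self.final_lr,
                "converged": int(self.converged),
                "seed": self.seed,
            },
        )

    def to_netcdf(self, path) -> None:
        self.to_xarray().to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "FitResult":
        with xr.open_dataset(path, engine="scipy") as ds:
            ds = ds.load()
        params = ModelParams(
            ds["pi"].values, ds["gamma"].values, ds["rho"].values, ds["epsilon"].values
        )
        return cls(
            params=params,
            loss_trace=ds["loss"].values,
            steps=int(ds.attrs["steps"]),
            final_lr=float(ds.attrs["final_lr"]),
            converged=bool(ds.attrs["converged"]),
            seed=int(ds.attrs["seed"]),
            samples=ds["sample"].values.astype(str),
            sites=ds["site"].values.astype(str),
        )

    def save_tsv(self, directory) -> None:
        """Write pi/gamma/rho/epsilon as labeled TSV tables."""
        import pathlib

        d = pathlib.Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        p = self.params
        samples = self.samples if self.samples is not None else np.arange(p.n_samples).astype(str)
        sites = self.sites if self.sites is not None else np.arange(p.n_sites).astype(str)
        strains = self.strain_labels()
        pd.DataFrame(p.pi, index=samples, columns=strains).to_csv(
            d / "pi.tsv", sep="\t", index_label="sample"
        )
        pd.DataFrame(p.gamma, index=strains, columns=sites).to_csv(
            d / "gamma.tsv", sep="\t", index_label="strain"
        )
        pd.DataFrame({"strain": strains, "rho": p.rho}).to_csv(
            d / "rho.tsv", sep="\t", index=False
        )
        pd.DataFrame({"sample": samples, "epsilon": p.epsilon}).to_csv(
            d / "epsilon.tsv", sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------

def choose_strain_number(n_samples: int, fraction: float = 0.3) -> int:
    """Number of strains to parameterize: max(1, round(fraction * N))."""
    if n_samples < 1:
        raise ValueError("need at least one sample")
    return max(1, int(np.floor(fraction * n_samples + 0.5)))


def nmf_initialize(
    mgt: Metagenotype, n_strains: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Initial (Pi0, Gamma0) from NMF of the observed allele frequencies.

    Factorizes the N x G matrix of observed alternative-allele
    frequencies (Y/M, zero where uncovered) into S components.  Sample
    loadings become Pi0 after row normalization (lightly smoothed toward
    uniform to stay interior); components are rescaled so that loadings
    and components compensate, then clipped to [0.01, 0.99] as Gamma0.
    Deterministic given ``seed``.
    """
    if n_strains < 1:
        raise ValueError("n_strains must be >= 1")
    if n_strains > mgt.n_samples * mgt.n_sites:
        raise ValueError("more strains than data cells")
    freq = np.where(mgt.total > 0, mgt.alt / np.maximum(mgt.total, 1), 0.0)
    nmf = NMF(
        n_components=n_strains,
        init="random",
        random_state=seed,
        max_iter=500,
        tol=1e-4,
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # non-convergence at max_iter is fine here
        W = nmf.fit_transform(freq)
    H = nmf.components_
    row = W.sum(axis=1, keepdims=True)
    pi0 = np.where(row > 0, W / np.maximum(row, 1e-300), 1.0 / n_strains)
    # transfer the factorization scale onto the components
    lam = W.sum(axis=0) / np.maximum(pi0.sum(axis=0), 1e-300)
    gamma0 = np.clip(lam[:, None] * H, 0.01, 0.99)
    pi0 = 0.99 * pi0 + 0.01 / n_strains  # keep strictly interior
    pi0 = pi0 / pi0.sum(axis=1, keepdims=True)
    return pi0, gamma0


# ---------------------------------------------------------------------------
# Annealing
# ---------------------------------------------------------------------------

def anneal_hyperparameters(
    step: int, schedule: FitSchedule, final: Hyperparameters
) -> tuple[float, float]:
    """Effective (gamma*, rho*) at a given optimization step.

    Held at the annealed starting values for the first ``anneal_hold``
    steps, then relaxed geometrically (log-linear in the step index) to
    the final values, reached exactly at ``anneal_hold + anneal_relax``.
    """
    if step < 0:
        raise ValueError("step must be >= 0")
    end = schedule.anneal_hold + schedule.anneal_relax
    if step < schedule.anneal_hold:
        return schedule.anneal_gamma0, schedule.anneal_rho0
    if step >= end:
        return final.gamma_star, final.rho_star
    frac = (step - schedule.anneal_hold) / schedule.anneal_relax
    g = 10.0 ** (
        np.log10(schedule.anneal_gamma0)
        + frac * (np.log10(final.gamma_star) - np.log10(schedule.anneal_gamma0))
    )
    r = 10.0 ** (
        np.log10(schedule.anneal_rho0)
        + frac * (np.log10(final.rho_star) - np.log10(schedule.anneal_rho0))
    )
    return float(g), float(r)


# ---------------------------------------------------------------------------
# Optimization
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, size: int, lr: float, b1=0.9, b2=0.999, eps=1e-8):
        self.m = np.zeros(size)
        self.v = np.zeros(size)
        self.t = 0
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps

    def step(self, theta: np.ndarray, grad: np.ndarray) -> np.ndarray:
        self.t += 1
        self.m = self.b1 * self.m + (1 - self.b1) * grad
        self.v = self.b2 * self.v + (1 - self.b2) * grad * grad
        mhat = self.m / (1 - self.b1**self.t)
        vhat = self.v / (1 - self.b2**self.t)
        return theta - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def fit(
    mgt: Metagenotype,
    n_strains: int,
    hyper: Hyperparameters | None = None,
    schedule: FitSchedule | None = None,
    precision: int = 64,
    init: tuple[np.ndarray, np.ndarray] | None = None,
) -> FitResult:
    """MAP fit of the model to a (filtered) metagenotype.

    Returns the best parameters seen after the annealing period (or the
    final iterate if optimization ends earlier).  ``init`` may supply a
    precomputed (Pi0, Gamma0) pair; otherwise NMF initialization is used
    with the schedule's seed.
    """
    if n_strains < 1:
        raise ValueError("n_strains must be >= 1")
    hyper = hyper or Hyperparameters()
    schedule = schedule or FitSchedule()
    obj = PosteriorObjective(mgt, hyper, n_strains, precision=precision)
    tr = obj.transform

    if init is None:
        pi0, gamma0 = nmf_initialize(mgt, n_strains, seed=schedule.seed)
    else:
        pi0, gamma0 = init
    ea, eb = hyper.epsilon_shapes()
    params0 = ModelParams(
        pi=pi0,
        gamma=np.clip(gamma0, 0.01, 0.99),
        rho=np.full(n_strains, 1.0 / n_strains),
        epsilon=np.full(mgt.n_samples, ea / (ea + eb)),
    )
    theta = tr.unconstrain(params0)

    adam = _Adam(tr.size, schedule.learning_rate)
    anneal_end = schedule.anneal_hold + schedule.anneal_relax
    lr = schedule.learning_rate
    best_loss = np.inf
    best_theta = None
    since_improve = 0
    converged = False
    trace = []

    step = 0
    for step in range(schedule.max_steps):
        g_eff, r_eff = anneal_hyperparameters(step, schedule, hyper)
        loss, grad = obj.value_and_grad(theta, g_eff, r_eff)
        if not np.isfinite(loss):
            if step == 0:
                raise FloatingPointError(
                    f"non-finite loss at initialization (loss={loss}); "
                    "check input counts and hyperparameters"
                )
            break
        trace.append(loss)
        if step >= anneal_end:
            # patience / learning-rate halving only after annealing:
            # during annealing the objective itself moves each step
            if loss < best_loss:
                best_loss = loss
                best_theta = theta.copy()
                since_improve = 0
            else:
                since_improve += 1
                if since_improve >= schedule.patience:
                    lr *= schedule.lr_factor
                    adam.lr = lr
                    since_improve = 0
                    if lr < schedule.lr_floor:
                        converged = True
                        break
        adam.lr = lr
        theta = adam.step(theta, grad)

    final_theta = best_theta if best_theta is not None else theta
    params = tr.constrain(final_theta)
    return FitResult(
        params=params,
        loss_trace=np.asarray(trace),
        steps=len(trace),
        final_lr=lr,
        converged=converged,
        seed=schedule.seed,
        samples=mgt.samples,
        sites=mgt.sites,
    )


# ---------------------------------------------------------------------------
# Post-hoc genotype refit
# ---------------------------------------------------------------------------

def _refit_chunk(
    Y: np.ndarray,
    M: np.ndarray,
    pi: np.ndarray,
    epsilon: np.ndarray,
    hyper: Hyperparameters,
    schedule: FitSchedule,
) -> np.ndarray:
    """Optimize Gamma for one site chunk with Pi and epsilon held fixed.

    Runs a fixed-length annealed Adam schedule (no loss-based rate
    adaptation), which makes the result exactly independent of how sites
    are chunked: with Pi fixed the objective separates per site and Adam
    updates are per-parameter.
    """
    from scipy.special import digamma

    S = pi.shape[1]
    Gc = Y.shape[1]
    mask = M > 0
    conc = hyper.alpha_star
    L = np.zeros((S, Gc))  # logits; gamma = 0.5 at start
    adam = _Adam(S * Gc, schedule.learning_rate)
    one_m_eps = 1.0 - epsilon
    for step in range(schedule.max_steps):
        g_eff, _ = anneal_hyperparameters(step, schedule, hyper)
        gamma = np.clip(_sigmoid(L.ravel()).reshape(S, Gc), 1e-15, 1 - 1e-15)
        P = pi @ gamma
        ptil = np.clip(
            P * one_m_eps[:, None] + (0.5 * epsilon)[:, None], 1e-15, 1 - 1e-15
        )
        a1 = ptil * conc
        a2 = (1.0 - ptil) * conc
        W = conc * (digamma(Y + a1) - digamma(M - Y + a2) - digamma(a1) + digamma(a2))
        W[~mask] = 0.0
        grad_gamma = pi.T @ (W * one_m_eps[:, None])
        grad_gamma += _ssd_flat_log_density_2_grad(gamma, g_eff)
        grad = -(grad_gamma * gamma * (1.0 - gamma)).ravel()
        L = adam.step(L.ravel(), grad).reshape(S, Gc)
    return _sigmoid(L.ravel()).reshape(S, Gc)


def refit_genotypes_given_pi(
    full_mgt: Metagenotype,
    pi: np.ndarray,
    hyper: Hyperparameters | None = None,
    schedule: FitSchedule | None = None,
    chunk_size: int = 500,
    epsilon: float | np.ndarray = 0.01,
    samples: np.ndarray | None = None,
) -> np.ndarray:
    """Estimate full-length genotypes conditioned on a fitted Pi.

    After fitting on a site subset, genotypes over *all* sites are
    recovered by holding Pi (and the error rates) fixed and refitting
    Gamma chunk by chunk; the chunks partition the site axis exactly
    once.  Returns the S x G fuzzy genotype matrix over every site of
    ``full_mgt``.  ``epsilon`` may be a scalar or the fitted per-sample
    error rates; ``samples``, if given, is checked against the
    metagenotype's sample set.
    """
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    hyper = hyper or Hyperparameters()
    if schedule is None:
        schedule = FitSchedule(anneal_hold=500, anneal_relax=1500, max_steps=2500)
    pi = np.asarray(pi, dtype=float)
    if pi.shape[0] != full_mgt.n_samples:
        raise ValueError(
            f"pi has {pi.shape[0]} samples but the metagenotype has {full_mgt.n_samples}"
        )
    if samples is not None and not np.array_equal(
        np.asarray(samples, dtype=str), full_mgt.samples
    ):
        raise ValueError("sample sets of pi and the metagenotype differ")
    eps = np.broadcast_to(np.asarray(epsilon, dtype=float), (full_mgt.n_samples,)).copy()
    Y = full_mgt.alt.astype(float)
    M = full_mgt.total.astype(float)
    G = full_mgt.n_sites
    out = np.empty((pi.shape[1], G))
    for start in range(0, G, chunk_size):
        stop = min(start + chunk_size, G)
        out[:, start:stop] = _refit_chunk(
            Y[:, start:stop], M[:, start:stop], pi, eps, hyper, schedule
        )
    return out
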