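"""Ground-truth world simulation for benchmarking strain deconvolution.

The generator mirrors the benchmarking protocol the model is evaluated
under: discrete strain genotypes are i.i.d. symmetric Bernoulli draws;
per-sample strain compositions are Dirichlet with symmetric
concentration 0.4 (most samples dominated by a few strains); allele
frequencies are the composition-weighted genotype mix; sequencing error
is applied at rate epsilon = 0.01; and counts are Binomial at a uniform
depth of m = 10 reads per site.

Two optional departures from that protocol exist for robustness
experiments and are off by default: Beta-Binomial (overdispersed)
counts and Poisson-distributed per-cell depth.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .metagenotype import Metagenotype
from .model import apply_error, predict_allele_freq


@dataclasses.dataclass(frozen=True)
class SimulatedWorld:
    """A simulated ground truth plus the metagenotype observed from it."""

    gamma: np.ndarray  # S x G discrete genotypes in {0, 1}
    pi: np.ndarray  # N x S compositions, rows on the simplex
    epsilon: float
    depth: np.ndarray  # N x G total counts
    metagenotype: Metagenotype
    seed: int

    @property
    def n_strains(self) -> int:
        return self.gamma.shape[0]


def simulate(
    n_strains: int,
    n_samples: int,
    n_sites: int,
    depth: int = 10,
    epsilon: float = 0.01,
    dirichlet_conc: float = 0.4,
    seed: int = 0,
    depth_overdispersion: float | None = None,
    poisson_depth: bool = False,
) -> SimulatedWorld:
    """Draw one ground-truth world and its observed metagenotype.

    Parameters
    ----------
    n_strains, n_samples, n_sites : S, N, G (all >= 1).
    depth : uniform sequencing depth m per (sample, site) cell.
    epsilon : sequencing error rate applied to all samples.
    dirichlet_conc : symmetric Dirichlet concentration for compositions.
    seed : RNG seed; the draw is fully deterministic given it.
    depth_overdispersion : if set, counts are Beta-Binomial with this
        concentration instead of Binomial (robustness option).
    poisson_depth : if True, per-cell depth is Poisson(depth) instead of
        constant (robustness option).
    """
    if min(n_strains, n_samples, n_sites) < 1:
        raise ValueError("n_strains, n_samples and n_sites must be >= 1")
    if depth < 0:
        raise ValueError("depth must be >= 0")
    rng = np.random.default_rng(seed)
    gamma = rng.integers(0, 2, size=(n_strains, n_sites)).astype(float)
    pi = rng.dirichlet(np.full(n_strains, dirichlet_conc), size=n_samples)
    p = predict_allele_freq(pi, gamma)
    ptil = apply_error(p, epsilon)
    if poisson_depth:
        m = rng.poisson(depth, size=(n_samples, n_sites))
    else:
        m = np.full((n_samples, n_sites), depth, dtype=np.int64)
    if depth_overdispersion is None:
        y = rng.binomial(m, ptil)
    else:
        conc = float(depth_overdispersion)
        q = rng.beta(
            np.maximum(ptil * conc, 1e-12), np.maximum((1 - ptil) * conc, 1e-12)
        )
        y = rng.binomial(m, q)
    mgt = Metagenotype(
        samples=np.array([f"sample_{i}" for i in range(n_samples)]),
        sites=np.array([f"site_{g}" for g in range(n_sites)]),
        alt=y,
        total=m,
    )
    return SimulatedWorld(
        gamma=gamma, pi=pi, epsilon=epsilon, depth=m, metagenotype=mgt, seed=seed
    )


def simulate_replicates(
    config: dict, n_replicates: int, base_seed: int = 0
) -> list[SimulatedWorld]:
    """Independent replicate worlds with seeds base_seed + k."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    return [simulate(**config, seed=base_seed + k) for k in range(n_replicates)]
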