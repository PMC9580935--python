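"""Metagenotype data model, I/O, filtering and per-sample summaries.

A metagenotype records, for every (sample, SNP site) pair, how many
sequencing reads support the alternative allele and how many reads were
observed in total.  Sites are biallelic: each site has exactly one
reference and one alternative allele, so the pair of integers
``(alt_count, total_count)`` fully describes the observation.

Site positions at the I/O boundary follow the usual variant-format
convention (1-based); in-memory arrays are 0-indexed.
"""

from __future__ import annotations

import dataclasses
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import xarray as xr


class MetagenotypeError(ValueError):
    """Raised for malformed metagenotype input."""


@dataclasses.dataclass(frozen=True)
class Metagenotype:
    """Dense biallelic allele-count array over samples x SNP sites.

    Attributes
    ----------
    samples : array of str, length N
        Unique sample identifiers.
    sites : array of str, length G
        Unique SNP-site identifiers.
    alt : (N, G) int array
        Reads supporting the alternative allele (``Y``).
    total : (N, G) int array
        Total reads at the site (``M``); ``alt <= total`` everywhere.
    """

    samples: np.ndarray
    sites: np.ndarray
    alt: np.ndarray
    total: np.ndarray

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=str)
        sites = np.asarray(self.sites, dtype=str)
        alt = np.asarray(self.alt)
        total = np.asarray(self.total)
        if alt.shape != total.shape or alt.shape != (len(samples), len(sites)):
            raise MetagenotypeError(
                f"shape mismatch: alt {alt.shape}, total {total.shape}, "
                f"N={len(samples)}, G={len(sites)}"
            )
        # note: zero-length axes are permitted so filters may return an
        # empty site set; I/O and model fitting require non-empty data
        for name, ids in (("sample", samples), ("site", sites)):
            if len(np.unique(ids)) != len(ids):
                raise MetagenotypeError(f"duplicate {name} identifiers")
        if not np.issubdtype(alt.dtype, np.integer):
            if not np.allclose(alt, np.round(alt)):
                raise MetagenotypeError("non-integer alt counts")
            alt = alt.astype(np.int64)
        if not np.issubdtype(total.dtype, np.integer):
            if not np.allclose(total, np.round(total)):
                raise MetagenotypeError("non-integer total counts")
            total = total.astype(np.int64)
        if (alt < 0).any() or (total < 0).any():
            raise MetagenotypeError("negative counts")
        if (alt > total).any():
            i, g = np.argwhere(alt > total)[0]
            raise MetagenotypeError(
                f"alt count exceeds total at sample {samples[i]!r}, site {sites[g]!r}"
            )
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "sites", sites)
        object.__setattr__(self, "alt", alt.astype(np.int64))
        object.__setattr__(self, "total", total.astype(np.int64))

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def ref(self) -> np.ndarray:
        """Reads supporting the reference allele."""
        return self.total - self.alt

    def allele_frequency(self) -> np.ndarray:
        """Observed alternative-allele frequency Y/M; NaN where M == 0."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.total > 0, self.alt / np.maximum(self.total, 1), np.nan)

    def select_sites(self, index: Sequence[int]) -> "Metagenotype":
        index = np.asarray(index, dtype=int)
        return Metagenotype(
            self.samples, self.sites[index], self.alt[:, index], self.total[:, index]
        )

    def select_samples(self, index: Sequence[int]) -> "Metagenotype":
        index = np.asarray(index, dtype=int)
        return Metagenotype(
            self.samples[index], self.sites, self.alt[index, :], self.total[index, :]
        )

    def to_xarray(self) -> xr.Dataset:
        counts = np.stack([self.ref, self.alt], axis=-1)
        return xr.Dataset(
            {"counts": (("sample", "site", "allele"), counts.astype(np.int32))},
            coords={
                "sample": self.samples,
                "site": self.sites,
                "allele": ["ref", "alt"],
            },
        )

    @classmethod
    def from_xarray(cls, ds: xr.Dataset) -> "Metagenotype":
        counts = ds["counts"].transpose("sample", "site", "allele").values
        ref = counts[:, :, 0].astype(np.int64)
        alt = counts[:, :, 1].astype(np.int64)
        return cls(
            ds["sample"].values.astype(str),
            ds["site"].values.astype(str),
            alt,
            ref + alt,
        )


@dataclasses.dataclass(frozen=True)
class SiteSelection:
    """Record of a site-filtering or down-sampling step."""

    kept_index: np.ndarray  # indices into the input site axis, no duplicates
    statistic: np.ndarray | None = None  # per-input-site minor-allele occurrence
    seed: int | None = None

    def __post_init__(self):
        idx = np.asarray(self.kept_index, dtype=int)
        if len(np.unique(idx)) != len(idx):
            raise ValueError("duplicate kept indices")
        object.__setattr__(self, "kept_index", idx)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_LONG_COLSETS = (
    ("sample", "site", "ref_count", "alt_count"),
    ("sample", "site", "alt_count", "total_count"),
)


def read_metagenotype(
    path, format: Literal["long-tsv", "array-container"] = "long-tsv"
) -> Metagenotype:
    """Read a metagenotype from a long-format TSV or a NetCDF container.

    The long TSV must have a header row with columns
    ``sample  site  ref_count  alt_count`` or
    ``sample  site  alt_count  total_count``.  (sample, site) pairs absent
    from the table get zero counts.
    """
    if format == "array-container":
        with xr.open_dataset(path, engine="scipy") as ds:
            return Metagenotype.from_xarray(ds.load())
    if format != "long-tsv":
        raise ValueError(f"unknown format {format!r}")

    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "site": str})
    cols = tuple(df.columns)
    if set(_LONG_COLSETS[0]) <= set(cols):
        alt = df["alt_count"].to_numpy()
        total = df["ref_count"].to_numpy() + alt
    elif set(_LONG_COLSETS[1]) <= set(cols):
        alt = df["alt_count"].to_numpy()
        total = df["total_count"].to_numpy()
    else:
        raise MetagenotypeError(
            f"unrecognized columns {cols}; expected one of {_LONG_COLSETS}"
        )
    for name, arr in (("alt", alt), ("total", total)):
        bad = ~np.isfinite(arr.astype(float))
        if bad.any():
            raise MetagenotypeError(
                f"malformed {name} count in row {int(np.argwhere(bad)[0][0]) + 2}"
            )
    if (alt < 0).any() or ((total - alt) < 0).any():
        row = int(np.argwhere((alt < 0) | (total - alt < 0))[0][0])
        raise MetagenotypeError(
            f"negative or inconsistent counts in data row {row + 2} "
            f"(sample={df['sample'].iloc[row]!r}, site={df['site'].iloc[row]!r})"
        )
    samples = pd.unique(df["sample"])
    sites = pd.unique(df["site"])
    si = pd.Categorical(df["sample"], categories=samples).codes
    gi = pd.Categorical(df["site"], categories=sites).codes
    Y = np.zeros((len(samples), len(sites)), dtype=np.int64)
    M = np.zeros_like(Y)
    if pd.DataFrame({"s": si, "g": gi}).duplicated().any():
        raise MetagenotypeError("duplicate (sample, site) rows")
    Y[si, gi] = alt
    M[si, gi] = total
    return Metagenotype(np.asarray(samples, dtype=str), np.asarray(sites, dtype=str), Y, M)


def combine_sample_tables(tables: dict) -> Metagenotype:
    """Combine per-sample SNP-count tables into one metagenotype.

    ``tables`` maps sample identifiers to file paths of per-sample TSVs
    in the style emitted by k-mer-based metagenotypers: one row per SNP
    site with columns ``site  ref_count  alt_count`` (header required).
    Sites absent from a sample's table get zero counts.
    """
    if not tables:
        raise MetagenotypeError("no sample tables given")
    frames = []
    for sample, path in tables.items():
        df = pd.read_csv(path, sep="\t", dtype={"site": str})
        missing = {"site", "ref_count", "alt_count"} - set(df.columns)
        if missing:
            raise MetagenotypeError(f"{path}: missing columns {sorted(missing)}")
        df = df.assign(sample=str(sample))
        frames.append(df)
    long = pd.concat(frames, ignore_index=True)
    samples = pd.unique(long["sample"])
    sites = pd.unique(long["site"])
    si = pd.Categorical(long["sample"], categories=samples).codes
    gi = pd.Categorical(long["site"], categories=sites).codes
    Y = np.zeros((len(samples), len(sites)), dtype=np.int64)
    M = np.zeros_like(Y)
    Y[si, gi] = long["alt_count"].to_numpy()
    M[si, gi] = long["alt_count"].to_numpy() + long["ref_count"].to_numpy()
    return Metagenotype(np.asarray(samples, dtype=str), np.asarray(sites, dtype=str), Y, M)


def write_metagenotype(
    mgt: Metagenotype, path, format: Literal["long-tsv", "array-container"] = "long-tsv"
) -> None:
    """Write a metagenotype as long TSV or a NetCDF container (scipy backend)."""
    if format == "array-container":
        mgt.to_xarray().to_netcdf(path, engine="scipy")
        return
    if format != "long-tsv":
        raise ValueError(f"unknown format {format!r}")
    si, gi = np.meshgrid(
        np.arange(mgt.n_samples), np.arange(mgt.n_sites), indexing="ij"
    )
    df = pd.DataFrame(
        {
            "sample": mgt.samples[si.ravel()],
            "site": mgt.sites[gi.ravel()],
            "ref_count": mgt.ref.ravel(),
            "alt_count": mgt.alt.ravel(),
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def minor_allele_occurrence(
    mgt: Metagenotype, mode: Literal["majority", "pooled"] = "majority"
) -> np.ndarray:
    """Per-site minor-allele occurrence statistic in [0, 1].

    ``majority`` (default): for each site, the fraction of covered samples
    (M > 0) whose within-sample majority allele is the alternative; ties
    (Y == M/2) count toward the alternative.  The minor occurrence is the
    smaller of the alternative and reference fractions.  Robust to uneven
    sequencing depth across samples.

    ``pooled``: pool read counts over samples and take the minor pooled
    allele frequency min(f, 1-f) with f = sum(Y)/sum(M).

    Sites with no covered sample get occurrence NaN.
    """
    covered = mgt.total > 0
    n_cov = covered.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        if mode == "majority":
            alt_major = covered & (2 * mgt.alt >= mgt.total)
            occ_alt = np.where(n_cov > 0, alt_major.sum(axis=0) / np.maximum(n_cov, 1), np.nan)
        elif mode == "pooled":
            tot = mgt.total.sum(axis=0)
            occ_alt = np.where(tot > 0, mgt.alt.sum(axis=0) / np.maximum(tot, 1), np.nan)
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return np.fmin(occ_alt, 1.0 - occ_alt)


def filter_minor_allele(
    mgt: Metagenotype,
    threshold: float = 0.05,
    mode: Literal["majority", "pooled"] = "majority",
) -> tuple[Metagenotype, SiteSelection]:
    """Drop sites whose minor-allele occurrence is below ``threshold``.

    A site is kept iff its minor-allele occurrence is >= threshold.  Sites
    with zero covered samples are always removed.
    """
    if not 0.0 <= threshold <= 0.5:
        raise ValueError("threshold must be in [0, 0.5]")
    occ = minor_allele_occurrence(mgt, mode=mode)
    keep = np.flatnonzero(np.nan_to_num(occ, nan=-1.0) >= threshold)
    return mgt.select_sites(keep), SiteSelection(keep, statistic=occ)


def filter_sample_coverage(mgt: Metagenotype, min_coverage: float = 0.05) -> Metagenotype:
    """Drop samples with horizontal coverage below ``min_coverage``.

    Horizontal coverage of a sample is the fraction of sites with at
    least one read.  A sample is kept iff coverage >= min_coverage
    (samples with *less than* the threshold are removed).
    """
    if not 0.0 <= min_coverage <= 1.0:
        raise ValueError("min_coverage must be in [0, 1]")
    coverage = (mgt.total >= 1).mean(axis=1)
    keep = np.flatnonzero(coverage >= min_coverage)
    if len(keep) == 0:
        raise MetagenotypeError("no samples pass the horizontal-coverage filter")
    return mgt.select_samples(keep)


def subsample_sites(
    mgt: Metagenotype, max_sites: int = 5000, seed: int = 0
) -> tuple[Metagenotype, SiteSelection]:
    """Randomly down-sample to at most ``max_sites`` sites without replacement.

    If the input already has <= max_sites sites it is returned unchanged.
    The selection is uniform, deterministic given ``seed``, and preserves
    the original site order.
    """
    if max_sites < 1:
        raise ValueError("max_sites must be >= 1")
    if mgt.n_sites <= max_sites:
        return mgt, SiteSelection(np.arange(mgt.n_sites), seed=seed)
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(mgt.n_sites, size=max_sites, replace=False))
    return mgt.select_sites(keep), SiteSelection(keep, seed=seed)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def metagenotype_entropy(mgt: Metagenotype) -> np.ndarray:
    """Depth-weighted mean allele-frequency entropy per sample, in bits.

    For sample i with observed allele frequencies p = Y/M:

        (1 / sum_g m_ig) * sum_g -m_ig [p log2 p + (1-p) log2 (1-p)]

    Zero-depth sites contribute nothing; p in {0, 1} contributes 0.
    A proxy for within-sample strain heterogeneity; 0 for a clonal
    sample, 1 when every covered site sits at frequency 1/2.  Samples
    with no covered site get NaN.
    """
    M = mgt.total.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(M > 0, mgt.alt / np.maximum(M, 1.0), 0.0)
        h = -(
            np.where(p > 0, p * np.log2(np.maximum(p, 1e-300)), 0.0)
            + np.where(p < 1, (1 - p) * np.log2(np.maximum(1 - p, 1e-300)), 0.0)
        )
    depth = M.sum(axis=1)
    out = np.where(depth > 0, (M * h).sum(axis=1) / np.maximum(depth, 1.0), np.nan)
    return out
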