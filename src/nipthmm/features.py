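"""Informative SNPs, allelic ratios and fetal-fraction estimation.

A SNP is *informative* when the mother and/or the fetus is heterozygous:
only then does the allelic depth imbalance carry fetal signal.  The allelic
ratio of a SNP is its major-allele count divided by its minor-allele count
(``max_i / min_i``, so always >= 1).

The fetal fraction of a sample is estimated from its euploid *reference*
chromosome: loci where the mother is homozygous and the fetus heterozygous
show a large allelic ratio (> 2.5 is used as the selection filter), and at
such a locus the minor-allele count is half the fetal contribution, giving

    FF = median( 2 * min_i / (max_i + min_i) )

over the selected loci.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .simulate import CfdnaSample, ChromosomeObservations

__all__ = [
    "AllelicRatioSeries",
    "FetalFractionEstimate",
    "informative_mask",
    "allelic_ratios",
    "estimate_ff",
    "estimate_ff_batch",
    "AR_FILTER_THRESHOLD",
]

#: Allelic-ratio filter used to select mother-homozygous/fetus-heterozygous
#: loci for fetal-fraction estimation.
AR_FILTER_THRESHOLD = 2.5


@dataclass(frozen=True)
class AllelicRatioSeries:
    """Allelic ratios at the informative SNPs of one chromosome.

    ``ratio`` is ``max_i / min_i`` (``inf`` where the minor count is zero);
    ``minor_fraction`` is ``2 * min_i / (max_i + min_i)``, the quantity whose
    median estimates the fetal fraction.
    """

    indices: np.ndarray
    ratio: np.ndarray
    minor_fraction: np.ndarray

    def __post_init__(self) -> None:
        if not (np.diff(self.indices) > 0).all():
            raise ValueError("locus indices must be strictly increasing")
        finite = np.isfinite(self.ratio)
        if np.any(self.ratio[finite] < 1.0):
            raise ValueError("allelic ratios are major/minor and must be >= 1")

    def __len__(self) -> int:
        return self.indices.size


@dataclass(frozen=True)
class FetalFractionEstimate:
    """Estimated fetal fraction and the number of loci it used.

    ``ok`` is False when no locus passed the allelic-ratio filter, in which
    case ``ff_hat`` is 0 by convention.
    """

    ff_hat: float
    n_loci_used: int
    ok: bool = True


def _as_chromosome(obj) -> ChromosomeObservations:
    if isinstance(obj, CfdnaSample):
        return obj.studied
    return obj


def informative_mask(obj, mode: str = "truth") -> np.ndarray:
    """Boolean mask of informative SNPs over the loci of a chromosome.

    Parameters
    ----------
    obj:
        A :class:`ChromosomeObservations` (or :class:`CfdnaSample`, whose
        studied chromosome is used).
    mode:
        ``"truth"`` uses the simulated genotypes: informative iff the mother
        and/or the fetus is heterozygous.  ``"observed"`` is for real data
        without genotypes: a locus is kept when its minor count clears a
        small absolute-plus-relative floor, ``min_i >= max(2, 0.005 * total)``,
        which rejects pure sequencing noise without discarding low-FF signal.
    """
    chrom = _as_chromosome(obj)
    if mode == "truth":
        if not chrom.has_genotypes:
            raise ValueError("truth mode requires genotype annotations")
        mother_het = chrom.m_b == 1
        fetus_het = (chrom.f_b > 0) & (chrom.f_b < chrom.f_total)
        return np.asarray(mother_het | fetus_het)
    if mode == "observed":
        total = chrom.total
        floor = np.maximum(2.0, 0.005 * total)
        return np.asarray(chrom.minor >= floor)
    raise ValueError(f"unknown mode {mode!r}")


def allelic_ratios(obj, mask: np.ndarray | None = None) -> AllelicRatioSeries:
    """Allelic ratios (major/minor) at masked loci, in chromosomal order.

    Loci with a zero minor count get ``ratio = inf``; downstream consumers
    must either tolerate or clamp them.  Loci with zero total are dropped.
    An empty mask yields an empty series.
    """
    chrom = _as_chromosome(obj)
    if mask is None:
        mask = np.ones(chrom.n_loci, dtype=bool)
    idx = np.flatnonzero(mask)
    major = chrom.major[idx].astype(float)
    minor = chrom.minor[idx].astype(float)
    covered = major + minor > 0
    idx, major, minor = idx[covered], major[covered], minor[covered]
    with np.errstate(divide="ignore"):
        ratio = np.where(minor > 0, major / np.maximum(minor, 1e-300), np.inf)
    minor_fraction = np.where(major + minor > 0, 2.0 * minor / (major + minor), 0.0)
    return AllelicRatioSeries(indices=idx, ratio=ratio, minor_fraction=minor_fraction)


def estimate_ff(
    reference: ChromosomeObservations | CfdnaSample, mode: str | None = None
) -> FetalFractionEstimate:
    """Estimate the fetal fraction from a (euploid) reference chromosome.

    Among the *informative* SNPs, selects those with allelic ratio > 2.5 —
    the mother-homozygous / fetus-heterozygous pattern.  Informative loci
    whose minor count happens to be zero (infinite ratio) are included and
    contribute 0 to the median, which keeps the estimator defined at very
    low fetal fractions.  (Restricting to informative SNPs first matters:
    a mother-hom/fetus-hom locus has a structurally zero minor count and
    would otherwise pass the ratio filter and bias the median towards 0.)

    ``mode`` selects the informativeness rule (:func:`informative_mask`);
    by default truth mode when genotypes are present, observed otherwise.
    """
    chrom = reference.reference if isinstance(reference, CfdnaSample) else reference
    if chrom.n_loci == 0:
        raise ValueError("cannot estimate fetal fraction from an empty chromosome")
    if mode is None:
        mode = "truth" if chrom.has_genotypes else "observed"
    series = allelic_ratios(chrom, informative_mask(chrom, mode))
    selected = series.ratio > AR_FILTER_THRESHOLD
    n_used = int(selected.sum())
    if n_used == 0:
        return FetalFractionEstimate(ff_hat=0.0, n_loci_used=0, ok=False)
    ff_hat = float(np.median(series.minor_fraction[selected]))
    return FetalFractionEstimate(ff_hat=ff_hat, n_loci_used=n_used)


def estimate_ff_batch(
    count_a: np.ndarray,
    count_b: np.ndarray,
    m_b: np.ndarray | None = None,
    f_b: np.ndarray | None = None,
    f_total: np.ndarray | None = None,
) -> np.ndarray:
    """Vectorised fetal-fraction estimates for a batch of reference chromosomes.

    All arrays have shape ``(n_samples, n_loci)``.  When genotype dosages
    are given, the truth informativeness rule applies; otherwise the
    observed-mode minor-count floor.  Returns per-sample estimates (0.0
    where no locus passes the filter).
    """
    major = np.maximum(count_a, count_b).astype(float)
    minor = np.minimum(count_a, count_b).astype(float)
    total = major + minor
    if m_b is not None and f_b is not None and f_total is not None:
        informative = (m_b == 1) | ((f_b > 0) & (f_b < f_total))
    else:
        informative = minor >= np.maximum(2.0, 0.005 * total)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(minor > 0, major / np.maximum(minor, 1e-300), np.inf)
        minor_fraction = np.where(total > 0, 2.0 * minor / np.maximum(total, 1e-300), np.nan)
    selected = informative & (ratio > AR_FILTER_THRESHOLD) & (total > 0)
    values = np.where(selected, minor_fraction, np.nan)
    with warnings.catch_warnings():
        # all-NaN rows (no locus passed the filter) fall back to 0.0 below
        warnings.simplefilter("ignore", category=RuntimeWarning)
        ff = np.nanmedian(values, axis=1)
    return np.where(np.isnan(ff), 0.0, ff)
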