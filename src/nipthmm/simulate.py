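"""Synthetic cfDNA sequencing data for targeted NIPT.

This module generates the inputs every other part of the package consumes:
biallelic SNP haplotypes for both parents, recombined parental chromosomes,
fetal chromosome sets under euploidy or meiosis-I maternal/paternal trisomy,
and over-dispersed per-allele read (or molecule) counts at each targeted
locus.

The count model: cfDNA is a mixture of maternal DNA (proportion ``1 - FF``)
and fetal DNA (proportion ``FF``).  At a locus, each allele's expected count
is

    mu_x = RD * [ (1 - FF) * d_m(x) / 2  +  FF * d_f(x) / 2 ]

where ``d_m(x)`` and ``d_f(x)`` are the allele's copy numbers in the maternal
(always 2 copies total) and fetal (2 or 3 copies total) genotypes.  Counts
are drawn from a negative binomial with that mean and a fixed
variance-to-mean ratio (default 3), so a trisomic locus has expected total
depth ``RD * (1 + FF/2)``.
"""

from __future__ import annotations

import dataclasses
import gzip
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "EUPLOIDY",
    "MATERNAL_TRISOMY",
    "PATERNAL_TRISOMY",
    "CONDITIONS",
    "SimulationConfig",
    "Haplotype",
    "FetalChromosomeSet",
    "LocusObservation",
    "ChromosomeObservations",
    "CfdnaSample",
    "Cohort",
    "simulate_parent",
    "recombine",
    "form_fetus",
    "draw_counts",
    "simulate_sample",
    "simulate_cohort",
    "write_samples_tsv",
]

EUPLOIDY = "euploidy"
MATERNAL_TRISOMY = "maternal_trisomy"
PATERNAL_TRISOMY = "paternal_trisomy"
CONDITIONS = (EUPLOIDY, MATERNAL_TRISOMY, PATERNAL_TRISOMY)

_ALLELES = np.array(["A", "B"])


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated condition (grid cell).

    Parameters
    ----------
    n_loci:
        Number of targeted SNPs per chromosome.
    maf:
        Minor-allele frequency shared by all loci, in [0, 0.5].
    read_depth:
        Mean reads (or UMI-collapsed molecules) per locus, ``RD``.
    fetal_fraction:
        Proportion of fetal cfDNA, ``FF``, in (0, 1).
    condition:
        Fetal chromosomal condition of the studied chromosome.
    vmr:
        Variance-to-mean ratio of the negative-binomial count noise; must
        exceed 1 (over-dispersion).
    n_train, n_test:
        Samples per condition used for model training / testing.
    seed:
        Root RNG seed; ``None`` draws fresh entropy.
    crossover:
        ``"suffix"`` exchanges a contiguous suffix at a single uniform
        breakpoint (one crossover); ``"subset"`` exchanges an independent
        random subset of positions instead.
    """

    n_loci: int = 1000
    maf: float = 0.5
    read_depth: float = 1000.0
    fetal_fraction: float = 0.10
    condition: str = EUPLOIDY
    vmr: float = 3.0
    n_train: int = 100
    n_test: int = 10_000
    seed: int | None = None
    crossover: str = "suffix"

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if not 0.0 <= self.maf <= 0.5:
            raise ValueError(f"maf must lie in [0, 0.5], got {self.maf}")
        if not 0.0 < self.fetal_fraction < 1.0:
            raise ValueError("fetal_fraction must lie in (0, 1)")
        if self.read_depth < 0:
            raise ValueError("read_depth must be non-negative")
        if self.vmr <= 1.0:
            raise ValueError("vmr must exceed 1 (negative binomial requires over-dispersion)")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.crossover not in ("suffix", "subset"):
            raise ValueError(f"unknown crossover mode {self.crossover!r}")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class Haplotype:
    """One parental chromosome copy: ordered biallelic alleles.

    Alleles are stored as int8 codes, 0 = A (designated major allele),
    1 = B (minor allele).
    """

    alleles: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.alleles, dtype=np.int8)
        if arr.ndim != 1:
            raise ValueError("haplotype alleles must be one-dimensional")
        if arr.size and not np.isin(arr, (0, 1)).all():
            raise ValueError("haplotype alphabet is exactly {A(0), B(1)}")
        object.__setattr__(self, "alleles", arr)

    def __len__(self) -> int:
        return self.alleles.size

    def to_string(self) -> str:
        return "".join(_ALLELES[self.alleles])


@dataclass(frozen=True)
class FetalChromosomeSet:
    """Fetal chromosome copies with their parental origin.

    Euploidy carries one maternal and one paternal haplotype; a meiosis-I
    trisomy carries both (post-recombination) homologs of one parent plus
    one from the other.
    """

    haplotypes: tuple[Haplotype, ...]
    origins: tuple[str, ...]
    condition: str

    def __post_init__(self) -> None:
        n_mat = sum(o == "maternal" for o in self.origins)
        n_pat = sum(o == "paternal" for o in self.origins)
        expected = {
            EUPLOIDY: (1, 1),
            MATERNAL_TRISOMY: (2, 1),
            PATERNAL_TRISOMY: (1, 2),
        }[self.condition]
        if (n_mat, n_pat) != expected:
            raise ValueError(
                f"{self.condition} requires {expected[0]} maternal + "
                f"{expected[1]} paternal haplotypes, got ({n_mat}, {n_pat})"
            )
        if len(self.haplotypes) != len(self.origins):
            raise ValueError("haplotypes and origins length mismatch")

    @property
    def ploidy(self) -> int:
        return len(self.haplotypes)

    def dosage_b(self) -> np.ndarray:
        """Copy number of the B allele per locus across fetal haplotypes."""
        return np.sum([h.alleles for h in self.haplotypes], axis=0).astype(np.int8)


@dataclass(frozen=True)
class LocusObservation:
    """Per-SNP allele counts with optional ground-truth genotypes."""

    count_a: int
    count_b: int
    maternal_genotype: str | None = None
    fetal_genotype: str | None = None

    def __post_init__(self) -> None:
        if self.count_a < 0 or self.count_b < 0:
            raise ValueError("allele counts must be non-negative")
        if self.maternal_genotype is not None and len(self.maternal_genotype) != 2:
            raise ValueError("maternal genotype must carry exactly 2 alleles")
        if self.fetal_genotype is not None and len(self.fetal_genotype) not in (2, 3):
            raise ValueError("fetal genotype must carry 2 or 3 alleles")

    @property
    def total(self) -> int:
        return self.count_a + self.count_b

    @property
    def major(self) -> int:
        return max(self.count_a, self.count_b)

    @property
    def minor(self) -> int:
        return min(self.count_a, self.count_b)


@dataclass
class ChromosomeObservations:
    """Vectorised locus observations for one chromosome of one sample.

    ``m_b`` / ``f_b`` are the B-allele copy numbers of the maternal and
    fetal genotypes; ``f_total`` is the fetal copy number (2 or 3).  The
    genotype arrays are ``None`` for real (non-simulated) data.
    """

    count_a: np.ndarray
    count_b: np.ndarray
    m_b: np.ndarray | None = None
    f_b: np.ndarray | None = None
    f_total: np.ndarray | None = None

    @property
    def n_loci(self) -> int:
        return self.count_a.size

    @property
    def total(self) -> np.ndarray:
        return self.count_a + self.count_b

    @property
    def major(self) -> np.ndarray:
        return np.maximum(self.count_a, self.count_b)

    @property
    def minor(self) -> np.ndarray:
        return np.minimum(self.count_a, self.count_b)

    @property
    def has_genotypes(self) -> bool:
        return self.m_b is not None and self.f_b is not None and self.f_total is not None

    def locus(self, i: int) -> LocusObservation:
        mg = fg = None
        if self.has_genotypes:
            mg = genotype_string(int(self.m_b[i]), 2)
            fg = genotype_string(int(self.f_b[i]), int(self.f_total[i]))
        return LocusObservation(int(self.count_a[i]), int(self.count_b[i]), mg, fg)


@dataclass
class CfdnaSample:
    """One simulated cfDNA sample: a studied and a reference chromosome.

    The reference chromosome is always euploid (same locus count, depth and
    fetal fraction) and is what the fetal-fraction estimator operates on.
    """

    studied: ChromosomeObservations
    reference: ChromosomeObservations
    condition: str
    ff_true: float
    read_depth: float
    sample_id: str = "sample"


@dataclass
class Cohort:
    """A batch of samples sharing one (condition, FF, RD) simulation cell.

    All arrays have shape ``(n_samples, n_loci)``.  ``studied`` and
    ``reference`` hold the two chromosomes of every sample.
    """

    studied: ChromosomeObservations
    reference: ChromosomeObservations
    condition: str
    ff_true: float
    read_depth: float

    @property
    def n_samples(self) -> int:
        return self.studied.count_a.shape[0]

    @property
    def n_loci(self) -> int:
        return self.studied.count_a.shape[1]

    def sample(self, i: int, sample_id: str | None = None) -> CfdnaSample:
        def row(c: ChromosomeObservations) -> ChromosomeObservations:
            return ChromosomeObservations(
                count_a=c.count_a[i],
                count_b=c.count_b[i],
                m_b=None if c.m_b is None else c.m_b[i],
                f_b=None if c.f_b is None else c.f_b[i],
                f_total=None if c.f_total is None else c.f_total[i],
            )

        return CfdnaSample(
            studied=row(self.studied),
            reference=row(self.reference),
            condition=self.condition,
            ff_true=self.ff_true,
            read_depth=self.read_depth,
            sample_id=sample_id or f"sample_{i}",
        )

    def samples(self) -> Iterable[CfdnaSample]:
        for i in range(self.n_samples):
            yield self.sample(i)


def genotype_string(n_b: int, total: int) -> str:
    """Render a genotype dosage as an allele multiset string, e.g. ``"AAB"``."""
    return "A" * (total - n_b) + "B" * n_b


# ---------------------------------------------------------------------------
# Per-sample operations
# ---------------------------------------------------------------------------


def simulate_parent(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[Haplotype, Haplotype]:
    """Draw a pair of homologous parental chromosomes.

    Each allele is independently the minor allele B with probability
    ``config.maf``, so at MAF 0.5 both alleles are equally likely.
    """
    alleles = (rng.random((2, config.n_loci)) < config.maf).astype(np.int8)
    return Haplotype(alleles[0]), Haplotype(alleles[1])


def recombine(
    hap1: Haplotype,
    hap2: Haplotype,
    rng: np.random.Generator,
    mode: str = "suffix",
) -> tuple[Haplotype, Haplotype]:
    """Chromosomal crossover between two homologs.

    ``"suffix"`` draws a single breakpoint k uniformly in [0, n_loci] and
    exchanges the suffixes from position k onward (one crossover event);
    ``"subset"`` exchanges an independent random subset of positions.
    Either way the allele multiset at every locus is conserved.
    """
    if len(hap1) != len(hap2):
        raise ValueError("homologs must have equal length")
    n = len(hap1)
    if mode == "suffix":
        k = int(rng.integers(0, n + 1))
        swap = np.arange(n) >= k
    elif mode == "subset":
        swap = rng.random(n) < 0.5
    else:
        raise ValueError(f"unknown crossover mode {mode!r}")
    a1, a2 = hap1.alleles.copy(), hap2.alleles.copy()
    a1[swap], a2[swap] = hap2.alleles[swap], hap1.alleles[swap]
    return Haplotype(a1), Haplotype(a2)


def form_fetus(
    mother_recombined: tuple[Haplotype, Haplotype],
    father_recombined: tuple[Haplotype, Haplotype],
    condition: str,
    rng: np.random.Generator,
) -> FetalChromosomeSet:
    """Assemble fetal chromosomes from recombined parental homolog pairs.

    Euploidy picks one homolog uniformly from each parent.  A meiosis-I
    nondisjunction trisomy transmits *both* recombined homologs of the
    affected parent plus one homolog of the other.
    """
    m_pick = mother_recombined[int(rng.integers(0, 2))]
    p_pick = father_recombined[int(rng.integers(0, 2))]
    if condition == EUPLOIDY:
        haps = (m_pick, p_pick)
        origins = ("maternal", "paternal")
    elif condition == MATERNAL_TRISOMY:
        haps = (*mother_recombined, p_pick)
        origins = ("maternal", "maternal", "paternal")
    elif condition == PATERNAL_TRISOMY:
        haps = (m_pick, *father_recombined)
        origins = ("maternal", "paternal", "paternal")
    else:
        raise ValueError(f"unknown condition {condition!r}")
    return FetalChromosomeSet(haplotypes=haps, origins=origins, condition=condition)


def _negative_binomial(
    mu: np.ndarray, vmr: float, rng: np.random.Generator
) -> np.ndarray:
    """Negative-binomial draws with E = mu and Var = vmr * mu.

    Parameterised as p = 1/vmr, r = mu * p / (1 - p) = mu / (vmr - 1).
    Zero means short-circuit to deterministic zero counts.
    """
    mu = np.asarray(mu, dtype=float)
    if np.any(mu < 0) or not np.all(np.isfinite(mu)):
        raise ValueError("negative-binomial means must be finite and non-negative")
    p = 1.0 / vmr
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    if np.any(pos):
        r = mu[pos] / (vmr - 1.0)
        out[pos] = rng.negative_binomial(r, p)
    return out


def draw_counts(
    maternal_genotype,
    fetal_genotype,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> LocusObservation:
    """Draw allele counts for one locus given both genotypes.

    Genotypes may be allele strings (``"AB"``, ``"AAB"``) or B-dosage
    tuples ``(n_b, total)``.  The maternal genotype must carry 2 alleles,
    the fetal genotype 2 or 3.
    """
    m_b, m_tot = _parse_genotype(maternal_genotype)
    f_b, f_tot = _parse_genotype(fetal_genotype)
    if m_tot != 2:
        raise ValueError("maternal genotype must carry exactly 2 alleles")
    if f_tot not in (2, 3):
        raise ValueError("fetal genotype must carry 2 or 3 alleles")
    ca, cb = _draw_allele_counts(
        np.array([m_b]),
        np.array([f_b]),
        np.array([f_tot]),
        config.read_depth,
        config.fetal_fraction,
        config.vmr,
        rng,
    )
    return LocusObservation(
        int(ca[0]),
        int(cb[0]),
        maternal_genotype=genotype_string(m_b, 2),
        fetal_genotype=genotype_string(f_b, f_tot),
    )


def _parse_genotype(g) -> tuple[int, int]:
    if isinstance(g, str):
        up = g.upper()
        if set(up) - {"A", "B"}:
            raise ValueError(f"genotype alphabet is {{A, B}}, got {g!r}")
        return up.count("B"), len(up)
    n_b, total = g
    if not 0 <= n_b <= total:
        raise ValueError(f"invalid genotype dosage {g!r}")
    return int(n_b), int(total)


def _draw_allele_counts(
    m_b: np.ndarray,
    f_b: np.ndarray,
    f_total: np.ndarray,
    read_depth: float,
    fetal_fraction: float,
    vmr: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised allele-count draws from the cfDNA mixture model."""
    if read_depth < 0 or fetal_fraction < 0:
        raise ValueError("read depth and fetal fraction must be non-negative")
    w_m = (1.0 - fetal_fraction) / 2.0
    w_f = fetal_fraction / 2.0
    mu_b = read_depth * (w_m * m_b + w_f * f_b)
    mu_a = read_depth * (w_m * (2 - m_b) + w_f * (f_total - f_b))
    count_b = _negative_binomial(mu_b, vmr, rng)
    count_a = _negative_binomial(mu_a, vmr, rng)
    return count_a, count_b


# ---------------------------------------------------------------------------
# Batched genotype + cohort simulation
# ---------------------------------------------------------------------------


def _simulate_genotypes(
    n_samples: int,
    n_loci: int,
    maf: float,
    condition: str,
    rng: np.random.Generator,
    crossover: str = "suffix",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Maternal/fetal genotype dosages for a batch of independent samples.

    Parents are drawn fresh for every sample.  Returns ``(m_b, f_b,
    f_total)`` with shapes ``(n_samples, n_loci)``; ``f_total`` is constant
    2 or 3 depending on the condition.
    """
    hap = lambda: (rng.random((n_samples, n_loci)) < maf).astype(np.int8)
    mh1, mh2 = hap(), hap()
    fh1, fh2 = hap(), hap()

    def cross(h1, h2):
        if crossover == "suffix":
            k = rng.integers(0, n_loci + 1, size=n_samples)
            swap = np.arange(n_loci)[None, :] >= k[:, None]
        else:
            swap = rng.random((n_samples, n_loci)) < 0.5
        return np.where(swap, h2, h1), np.where(swap, h1, h2)

    rm1, rm2 = cross(mh1, mh2)
    rp1, rp2 = cross(fh1, fh2)

    pick = lambda h1, h2: np.where(
        rng.integers(0, 2, size=n_samples)[:, None] == 0, h1, h2
    )
    if condition == EUPLOIDY:
        f_b = pick(rm1, rm2) + pick(rp1, rp2)
        ploidy = 2
    elif condition == MATERNAL_TRISOMY:
        f_b = rm1 + rm2 + pick(rp1, rp2)
        ploidy = 3
    elif condition == PATERNAL_TRISOMY:
        f_b = pick(rm1, rm2) + rp1 + rp2
        ploidy = 3
    else:
        raise ValueError(f"unknown condition {condition!r}")

    m_b = (mh1 + mh2).astype(np.int8)
    f_total = np.full((n_samples, n_loci), ploidy, dtype=np.int8)
    return m_b, f_b.astype(np.int8), f_total


def _simulate_chromosome(
    n_samples: int,
    config: SimulationConfig,
    condition: str,
    rng: np.random.Generator,
) -> ChromosomeObservations:
    m_b, f_b, f_total = _simulate_genotypes(
        n_samples, config.n_loci, config.maf, condition, rng, config.crossover
    )
    count_a, count_b = _draw_allele_counts(
        m_b, f_b, f_total, config.read_depth, config.fetal_fraction, config.vmr, rng
    )
    return ChromosomeObservations(
        count_a=count_a, count_b=count_b, m_b=m_b, f_b=f_b, f_total=f_total
    )


def simulate_cohort(
    config: SimulationConfig,
    n_samples: int,
    rng: np.random.Generator | int | None = None,
) -> Cohort:
    """Simulate a batch of cfDNA samples for one grid cell.

    Every sample gets a studied chromosome under ``config.condition`` and an
    independent euploid reference chromosome at the same depth and fetal
    fraction (used downstream for fetal-fraction estimation).
    """
    rng = np.random.default_rng(rng if rng is not None else config.seed)
    studied = _simulate_chromosome(n_samples, config, config.condition, rng)
    reference = _simulate_chromosome(n_samples, config, EUPLOIDY, rng)
    return Cohort(
        studied=studied,
        reference=reference,
        condition=config.condition,
        ff_true=config.fetal_fraction,
        read_depth=config.read_depth,
    )


def simulate_sample(
    config: SimulationConfig, rng: np.random.Generator | int | None = None
) -> CfdnaSample:
    """Simulate a single cfDNA sample (studied + euploid reference chromosome)."""
    rng = np.random.default_rng(rng if rng is not None else config.seed)
    return simulate_cohort(config, 1, rng).sample(0)


# ---------------------------------------------------------------------------
# Tab-separated output of simulated samples
# ---------------------------------------------------------------------------

_TSV_HEADER = (
    "sample_id\tchromosome_role\tlocus_index\tcount_a\tcount_b\t"
    "maternal_genotype\tfetal_genotype\tcondition\tff_true\trd\tseed"
)


def write_samples_tsv(
    samples: Sequence[CfdnaSample] | Cohort,
    path,
    seed: int | None = None,
) -> None:
    """Write simulated samples as a tab-separated table.

    One row per locus per chromosome role; gzip-transparent by file suffix.
    """
    if isinstance(samples, Cohort):
        samples = list(samples.samples())
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        fh.write(_TSV_HEADER + "\n")
        for s in samples:
            for role, chrom in (("studied", s.studied), ("reference", s.reference)):
                cond = s.condition if role == "studied" else EUPLOIDY
                for i in range(chrom.n_loci):
                    mg = fg = ""
                    if chrom.has_genotypes:
                        mg = genotype_string(int(chrom.m_b[i]), 2)
                        fg = genotype_string(int(chrom.f_b[i]), int(chrom.f_total[i]))
                    fh.write(
                        f"{s.sample_id}\t{role}\t{i}\t{int(chrom.count_a[i])}\t"
                        f"{int(chrom.count_b[i])}\t{mg}\t{fg}\t{cond}\t"
                        f"{s.ff_true:g}\t{s.read_depth:g}\t"
                        f"{'' if seed is None else seed}\n"
                    )
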