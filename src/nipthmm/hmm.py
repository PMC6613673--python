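"""Hidden Markov models over targeted loci: RC, AR and RCAR.

Three HMM variants classify consecutive targeted loci of a chromosome:

* **RC** — a 2-state model (``EUP``, ``TRI``) on per-locus total read
  counts; trisomic loci run ~``1 + FF/2`` times deeper than euploid ones.
* **AR** — a 7-state model on allelic ratios of informative SNPs.  The
  seven states are the distinct (maternal genotype x fetal genotype x
  condition) allelic patterns, each with its own noise-free expected ratio.
* **RCAR** — the combined model: 2-D observations (total count, allelic
  ratio) with diagonal Gaussian emissions over the same 7 states.

All models share uniform initial probabilities, a transition matrix built
from a stay-switch ratio (staying within the current fetal condition is 10x
more likely than switching condition), and Gaussian emissions whose means
and variances are estimated from labelled training samples.  Decoding is
log-space Viterbi, vectorised across samples.

Seven-state taxonomy (major:minor allele dosages; expected noise-free
major/minor ratio at fetal fraction ``f``):

========  ==================  =======================  =====================
state     maternal genotype    fetal genotype           expected ratio
========  ==================  =======================  =====================
``E1``    het                 het                      1
``E2``    het                 hom                      (1+f)/(1-f)
``E3``    hom                 het                      (2-f)/f
``T1``    het                 2:1                      1+f
``T2``    het                 3:0                      (1+2f)/(1-f)
``T3``    hom                 2 maternal + 1 other     2/f
``P1``    hom                 1 maternal + 2 other     (2-f)/(2f)
========  ==================  =======================  =====================

``P1`` can only arise under paternally originated trisomy (a homozygous
mother cannot transmit two non-maternal alleles), which is what lets the
7-state models separate parental origin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .simulate import (
    EUPLOIDY,
    MATERNAL_TRISOMY,
    PATERNAL_TRISOMY,
    CfdnaSample,
    ChromosomeObservations,
    Cohort,
)

__all__ = [
    "RC_STATES",
    "SEVEN_STATES",
    "StateSpace",
    "rc_state_space",
    "seven_state_space",
    "HmmModel",
    "StateFrequencyProfile",
    "EmissionFitError",
    "expected_allelic_ratio",
    "label_loci",
    "build_transitions",
    "fit_emissions",
    "viterbi_decode",
    "viterbi_decode_batch",
    "state_frequencies",
    "rc_observations",
    "seven_state_observations",
    "model_to_dict",
    "model_from_dict",
]

RC_STATES = ("EUP", "TRI")
SEVEN_STATES = ("E1", "E2", "E3", "T1", "T2", "T3", "P1")

# Group label of each state: which fetal condition it indicates.  "trisomy"
# covers allelic patterns seen under either parental origin and is
# associated with maternal origin at call time to avoid over-calling
# paternal trisomy.
_RC_CONDITIONS = ("euploidy", "trisomy")
_SEVEN_CONDITIONS = (
    "euploidy",
    "euploidy",
    "euploidy",
    "trisomy",
    "trisomy",
    "trisomy",
    "paternal_trisomy",
)

# Canonical (m_b, f_b, f_total) dosage pattern of each 7-state, with the
# major allele written as A.  Used to derive expected allelic ratios by
# dosage enumeration.
_STATE_PATTERNS = {
    "E1": (1, 1, 2),
    "E2": (1, 0, 2),
    "E3": (0, 1, 2),
    "T1": (1, 1, 3),
    "T2": (1, 0, 3),
    "T3": (0, 1, 3),
    "P1": (0, 2, 3),
}


@dataclass(frozen=True)
class StateSpace:
    """Ordered HMM states and the fetal condition each one indicates."""

    kind: str  # "RC", "AR" or "RCAR"
    states: tuple[str, ...]
    conditions: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.states) != len(self.conditions):
            raise ValueError("states and conditions must align")

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_dims(self) -> int:
        return 2 if self.kind == "RCAR" else 1

    def index(self, state: str) -> int:
        return self.states.index(state)

    def condition_groups(self) -> tuple[str, ...]:
        seen: list[str] = []
        for c in self.conditions:
            if c not in seen:
                seen.append(c)
        return tuple(seen)


def rc_state_space() -> StateSpace:
    return StateSpace(kind="RC", states=RC_STATES, conditions=_RC_CONDITIONS)


def seven_state_space(kind: str = "AR") -> StateSpace:
    if kind not in ("AR", "RCAR"):
        raise ValueError("7-state space is used by the AR and RCAR models")
    return StateSpace(kind=kind, states=SEVEN_STATES, conditions=_SEVEN_CONDITIONS)


class EmissionFitError(ValueError):
    """Raised when a state has too few labelled training loci to fit."""


@dataclass
class HmmModel:
    """A fitted HMM: state space, transitions and Gaussian emissions.

    ``means``/``variances`` have shape ``(n_states, n_dims)`` — 1-D for RC
    (total count) and AR (allelic ratio), 2-D diagonal for RCAR (count,
    ratio).  ``ratio_cap`` is the finite value infinite allelic ratios are
    clamped to before decoding (None for RC).  ``rd``/``ff`` record the
    training condition.
    """

    space: StateSpace
    startprob: np.ndarray
    transmat: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    ratio_cap: float | None = None
    rd: float | None = None
    ff: float | None = None

    def __post_init__(self) -> None:
        self.startprob = np.asarray(self.startprob, dtype=float)
        self.transmat = np.asarray(self.transmat, dtype=float)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.variances = np.atleast_2d(np.asarray(self.variances, dtype=float))
        s = self.space.n_states
        if self.transmat.shape != (s, s):
            raise ValueError("transition matrix shape mismatch")
        if not np.allclose(self.transmat.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition matrix rows must sum to 1")
        if np.any(self.variances <= 0):
            raise ValueError("emission variances must be positive")

    @property
    def kind(self) -> str:
        return self.space.kind


@dataclass(frozen=True)
class StateFrequencyProfile:
    """Proportion of decoded loci per state — the meta-classifier features.

    ``ff`` carries the fetal fraction used as a feature, with its
    provenance: ``"true"`` (simulation ground truth), ``"estimated"``
    (reference-chromosome estimate) or ``"assumed"`` (e.g. the 10% median
    convention for read-count-only data).
    """

    frequencies: np.ndarray
    n_loci: int
    rd: float
    ff: float
    ff_provenance: str = "true"

    def __post_init__(self) -> None:
        freqs = np.asarray(self.frequencies, dtype=float)
        if freqs.size and abs(freqs.sum() - 1.0) > 1e-9:
            raise ValueError("state frequencies must sum to 1")
        if np.any(freqs < 0):
            raise ValueError("state frequencies must be non-negative")
        object.__setattr__(self, "frequencies", freqs)


# ---------------------------------------------------------------------------
# State taxonomy
# ---------------------------------------------------------------------------


def expected_allelic_ratio(state: str, ff: float) -> float:
    """Noise-free expected major/minor allelic ratio of a 7-state at ``ff``.

    Derived by dosage enumeration: each allele's expected count is
    proportional to ``(1-ff) * d_m / 2 + ff * d_f / 2``.
    """
    if not 0.0 < ff < 1.0:
        raise ValueError("ff must lie in (0, 1)")
    try:
        m_b, f_b, f_total = _STATE_PATTERNS[state]
    except KeyError:
        raise ValueError(f"unknown state {state!r}") from None
    mu_a = (1 - ff) * (2 - m_b) / 2 + ff * (f_total - f_b) / 2
    mu_b = (1 - ff) * m_b / 2 + ff * f_b / 2
    hi, lo = max(mu_a, mu_b), min(mu_a, mu_b)
    return hi / lo if lo > 0 else np.inf


def label_loci(
    m_b: np.ndarray, f_b: np.ndarray, f_total: np.ndarray
) -> np.ndarray:
    """Assign each locus its 7-state index from genotype dosages.

    Returns -1 at non-informative loci (mother and fetus both homozygous).
    The state depends only on the genotype dosage pattern, not on which
    parent donated the extra chromosome.
    """
    m_b = np.asarray(m_b)
    f_b = np.asarray(f_b)
    f_total = np.asarray(f_total)
    out = np.full(m_b.shape, -1, dtype=np.int8)

    m_het = m_b == 1
    f_het = (f_b > 0) & (f_b < f_total)
    eup = f_total == 2
    tri = f_total == 3

    out[eup & m_het & f_het] = SEVEN_STATES.index("E1")
    out[eup & m_het & ~f_het] = SEVEN_STATES.index("E2")
    out[eup & ~m_het & f_het] = SEVEN_STATES.index("E3")

    out[tri & m_het & f_het] = SEVEN_STATES.index("T1")
    out[tri & m_het & ~f_het] = SEVEN_STATES.index("T2")

    # Mother homozygous, fetus heterozygous trisomic: count how many fetal
    # copies carry the maternal allele — 2 is the T3 pattern, 1 is P1.
    m_hom_tri = tri & ~m_het & f_het
    maternal_copies = np.where(m_b == 2, f_b, f_total - f_b)
    out[m_hom_tri & (maternal_copies == 2)] = SEVEN_STATES.index("T3")
    out[m_hom_tri & (maternal_copies == 1)] = SEVEN_STATES.index("P1")
    return out


def build_transitions(
    space: StateSpace, stay_switch_ratio: float = 10.0
) -> np.ndarray:
    """Row-stochastic transition matrix from the stay-switch rule.

    Transitions that keep the fetal condition (including self-transitions
    and moves between same-condition states) carry weight
    ``stay_switch_ratio``; transitions to a different condition carry weight
    1.  Same-condition moves are not penalised because the allelic pattern
    legitimately changes at nearly every informative SNP.  For the RC model
    this reduces to ``[[10/11, 1/11], [1/11, 10/11]]``.
    """
    if stay_switch_ratio <= 0:
        raise ValueError("stay_switch_ratio must be positive")
    cond = np.asarray(space.conditions)
    same = cond[:, None] == cond[None, :]
    weights = np.where(same, float(stay_switch_ratio), 1.0)
    return weights / weights.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Observation construction
# ---------------------------------------------------------------------------


def rc_observations(chrom: ChromosomeObservations) -> np.ndarray:
    """Total-count observation matrix for the RC model, shape (N, T) or (T,)."""
    return np.asarray(chrom.total, dtype=float)


def _ratio_matrix(count_a: np.ndarray, count_b: np.ndarray) -> np.ndarray:
    major = np.maximum(count_a, count_b).astype(float)
    minor = np.minimum(count_a, count_b).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(minor > 0, major / np.maximum(minor, 1e-300), np.inf)
    # zero-coverage loci carry no ratio information; treated as ratio 1
    ratio = np.where(major + minor == 0, 1.0, ratio)
    return ratio


def seven_state_observations(
    chrom: ChromosomeObservations,
    ratio_cap: float,
    with_counts: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Padded per-sample observation sequences at usable informative loci.

    Restricts each sample's loci to the informative ones (truth mask from
    genotypes) whose minor count is non-zero — a zero minor count has an
    undefined (infinite) allelic ratio, and in real data such a locus is
    indistinguishable from a homozygous one — keeps chromosomal order,
    clamps ratios to ``ratio_cap`` and pads rows to the longest sequence.

    Returns ``(obs, lengths)`` where ``obs`` has shape ``(N, T_max, D)``
    with D = 1 (ratio) or 2 (count, ratio), and ``lengths`` the number of
    usable loci per sample.
    """
    if not chrom.has_genotypes:
        raise ValueError("7-state observations require genotype annotations")
    count_a = np.atleast_2d(chrom.count_a)
    count_b = np.atleast_2d(chrom.count_b)
    m_b = np.atleast_2d(chrom.m_b)
    f_b = np.atleast_2d(chrom.f_b)
    f_total = np.atleast_2d(chrom.f_total)

    informative = (m_b == 1) | ((f_b > 0) & (f_b < f_total))
    mask = informative & (np.minimum(count_a, count_b) > 0)
    lengths = mask.sum(axis=1)
    if np.any(lengths == 0):
        raise ValueError(
            "a sample has no informative locus with both alleles observed"
        )
    t_max = int(lengths.max()) if lengths.size else 0

    # stable argsort floats informative positions to the front, in order
    order = np.argsort(~mask, axis=1, kind="stable")[:, :t_max]
    ratio = np.minimum(_ratio_matrix(count_a, count_b), ratio_cap)
    ratio_seq = np.take_along_axis(ratio, order, axis=1)
    if with_counts:
        total_seq = np.take_along_axis(
            (count_a + count_b).astype(float), order, axis=1
        )
        obs = np.stack([total_seq, ratio_seq], axis=-1)
    else:
        obs = ratio_seq[..., None]
    return obs, lengths


# ---------------------------------------------------------------------------
# Emission fitting
# ---------------------------------------------------------------------------


def _stack_training(
    training: Cohort | Sequence[Cohort] | Sequence[CfdnaSample],
) -> tuple[ChromosomeObservations, float | None, float | None]:
    """Pool the studied chromosomes of training material into 2-D arrays."""
    if isinstance(training, Cohort):
        training = [training]
    training = list(training)
    if not training:
        raise ValueError("no training material supplied")
    chroms = []
    rd = ff = None
    for item in training:
        if isinstance(item, Cohort):
            chroms.append(item.studied)
            rd, ff = item.read_depth, item.ff_true
        elif isinstance(item, CfdnaSample):
            chroms.append(item.studied)
            rd, ff = item.read_depth, item.ff_true
        else:
            raise TypeError(f"cannot train from {type(item).__name__}")
    fields = {}
    for name in ("count_a", "count_b", "m_b", "f_b", "f_total"):
        raw = [getattr(c, name) for c in chroms]
        if any(r is None for r in raw):
            raise ValueError("training samples must carry ground-truth genotypes")
        fields[name] = np.concatenate([np.atleast_2d(r) for r in raw], axis=0)
    return ChromosomeObservations(**fields), rd, ff


def _state_moments(
    values: np.ndarray, labels: np.ndarray, n_states: int, states: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    means = np.empty(n_states)
    variances = np.empty(n_states)
    for s in range(n_states):
        sel = values[labels == s]
        if sel.size < 2:
            raise EmissionFitError(
                f"state {states[s]!r} has {sel.size} training loci; need >= 2"
            )
        means[s] = sel.mean()
        variances[s] = sel.var(ddof=1)
    return means, variances


def fit_emissions(
    training: Cohort | Sequence[Cohort] | Sequence[CfdnaSample],
    model_kind: str,
    stay_switch_ratio: float = 10.0,
    rd: float | None = None,
    ff: float | None = None,
) -> HmmModel:
    """Fit per-state Gaussian emissions from labelled training samples.

    Labels come from the simulation ground truth: RC states from the fetal
    copy number, 7-states from the genotype dosage pattern at informative
    loci.  One model is fitted per training condition (RD, FF); callers
    keep a registry keyed by condition.
    """
    chrom, rd_found, ff_found = _stack_training(training)
    rd = rd if rd is not None else rd_found
    ff = ff if ff is not None else ff_found

    if model_kind == "RC":
        space = rc_state_space()
        totals = chrom.total.ravel().astype(float)
        labels = np.where(chrom.f_total.ravel() == 3, 1, 0)
        means, variances = _state_moments(totals, labels, 2, space.states)
        ratio_cap = None
        means, variances = means[:, None], variances[:, None]
    elif model_kind in ("AR", "RCAR"):
        space = seven_state_space(model_kind)
        labels2d = label_loci(chrom.m_b, chrom.f_b, chrom.f_total)
        # zero-minor loci carry no usable ratio (and are excluded from
        # decoding sequences as well)
        minor = np.minimum(np.atleast_2d(chrom.count_a), np.atleast_2d(chrom.count_b))
        mask = (labels2d >= 0) & (minor > 0)
        labels = labels2d[mask]
        ratio_all = _ratio_matrix(
            np.atleast_2d(chrom.count_a), np.atleast_2d(chrom.count_b)
        )[mask]
        if ratio_all.size == 0:
            raise EmissionFitError("no finite training allelic ratios")
        ratio_cap = 2.0 * float(np.percentile(ratio_all, 99))
        ratio = np.minimum(ratio_all, ratio_cap)
        r_means, r_vars = _state_moments(ratio, labels, 7, space.states)
        if model_kind == "AR":
            means, variances = r_means[:, None], r_vars[:, None]
        else:
            totals = chrom.total[mask].astype(float)
            c_means, c_vars = _state_moments(totals, labels, 7, space.states)
            means = np.stack([c_means, r_means], axis=1)
            variances = np.stack([c_vars, r_vars], axis=1)
    else:
        raise ValueError(f"unknown model kind {model_kind!r}")

    n = space.n_states
    return HmmModel(
        space=space,
        startprob=np.full(n, 1.0 / n),
        transmat=build_transitions(space, stay_switch_ratio),
        means=means,
        variances=variances,
        ratio_cap=ratio_cap,
        rd=rd,
        ff=ff,
    )


# ---------------------------------------------------------------------------
# Viterbi decoding
# ---------------------------------------------------------------------------


def _emission_loglik(obs: np.ndarray, model: HmmModel) -> np.ndarray:
    """Gaussian emission log-likelihoods, shape (N, T, S).

    ``obs`` has shape (N, T, D); dimensions are independent (diagonal
    covariance), so log-densities add across D.
    """
    n, t, d = obs.shape
    s = model.space.n_states
    if d != model.means.shape[1]:
        raise ValueError("observation dimensionality does not match model")
    out = np.zeros((n, t, s))
    for si in range(s):
        ll = np.zeros((n, t))
        for di in range(d):
            mu = model.means[si, di]
            var = model.variances[si, di]
            ll -= 0.5 * (np.log(2.0 * np.pi * var) + (obs[..., di] - mu) ** 2 / var)
        out[..., si] = ll
    return out


def viterbi_decode_batch(
    obs: np.ndarray,
    model: HmmModel,
    lengths: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Most likely state path for a batch of padded observation sequences.

    Parameters
    ----------
    obs:
        Shape ``(N, T, D)`` (or ``(N, T)`` for 1-D models).  Entries beyond
        a sample's length are ignored.
    lengths:
        Per-sample sequence lengths; default: all full length.

    Returns
    -------
    paths, scores:
        ``paths`` is ``(N, T)`` int8 (valid up to each sample's length);
        ``scores`` the per-sample log-probability of the decoded path.
        Ties break deterministically to the lowest state index.
    """
    obs = np.asarray(obs, dtype=float)
    if obs.ndim == 2:
        obs = obs[..., None]
    n, t, _ = obs.shape
    if t == 0:
        raise ValueError("observation sequences must be non-empty")
    if lengths is None:
        lengths = np.full(n, t, dtype=int)
    lengths = np.asarray(lengths)
    if np.any(lengths < 1):
        raise ValueError("every sequence must contain at least one observation")
    valid = np.arange(t)[None, :] < lengths[:, None]
    if not np.all(np.isfinite(obs[valid])):
        raise ValueError("observations must be finite")

    loglik = _emission_loglik(obs, model)
    s = model.space.n_states
    log_start = np.log(model.startprob)
    log_trans = np.log(model.transmat)

    delta = log_start[None, :] + loglik[:, 0, :]
    psi = np.empty((n, t, s), dtype=np.int8)
    psi[:, 0, :] = 0
    idx = np.arange(s, dtype=np.int8)
    for step in range(1, t):
        cand = delta[:, :, None] + log_trans[None, :, :]
        best_prev = cand.argmax(axis=1)
        new_delta = np.take_along_axis(cand, best_prev[:, None, :], axis=1)[:, 0, :]
        new_delta = new_delta + loglik[:, step, :]
        active = (step < lengths)[:, None]
        delta = np.where(active, new_delta, delta)
        psi[:, step, :] = np.where(active, best_prev, idx[None, :])

    paths = np.empty((n, t), dtype=np.int8)
    last = delta.argmax(axis=1).astype(np.int8)
    scores = delta[np.arange(n), last]
    paths[:, -1] = last
    rows = np.arange(n)
    for step in range(t - 2, -1, -1):
        last = psi[rows, step + 1, last]
        paths[:, step] = last
    return paths, scores


def viterbi_decode(obs: np.ndarray, model: HmmModel) -> np.ndarray:
    """Viterbi state path for a single observation sequence.

    ``obs`` has shape ``(T,)`` for 1-D models or ``(T, D)`` for RCAR.
    """
    obs = np.asarray(obs, dtype=float)
    if obs.ndim == 1:
        obs = obs[:, None]
    paths, _ = viterbi_decode_batch(obs[None, ...], model)
    return paths[0]


# ---------------------------------------------------------------------------
# State frequencies
# ---------------------------------------------------------------------------


def state_frequencies(
    path: np.ndarray,
    space: StateSpace,
    rd: float,
    ff: float,
    ff_provenance: str = "true",
) -> StateFrequencyProfile:
    """Normalised histogram of decoded states for one sample."""
    path = np.asarray(path)
    if path.size == 0:
        raise ValueError("state path must be non-empty")
    counts = np.bincount(path, minlength=space.n_states).astype(float)
    return StateFrequencyProfile(
        frequencies=counts / counts.sum(),
        n_loci=int(path.size),
        rd=rd,
        ff=ff,
        ff_provenance=ff_provenance,
    )


def state_frequencies_batch(
    paths: np.ndarray, lengths: np.ndarray, n_states: int
) -> np.ndarray:
    """Per-sample state frequencies for padded decoded paths, shape (N, S)."""
    n, t = paths.shape
    valid = np.arange(t)[None, :] < np.asarray(lengths)[:, None]
    freqs = np.stack(
        [((paths == s) & valid).sum(axis=1) for s in range(n_states)], axis=1
    ).astype(float)
    return freqs / np.asarray(lengths)[:, None]


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def model_to_dict(model: HmmModel) -> dict:
    return {
        "kind": model.space.kind,
        "states": list(model.space.states),
        "conditions": list(model.space.conditions),
        "startprob": model.startprob.tolist(),
        "transmat": model.transmat.tolist(),
        "means": model.means.tolist(),
        "variances": model.variances.tolist(),
        "ratio_cap": model.ratio_cap,
        "rd": model.rd,
        "ff": model.ff,
    }


def model_from_dict(d: dict) -> HmmModel:
    space = StateSpace(
        kind=d["kind"], states=tuple(d["states"]), conditions=tuple(d["conditions"])
    )
    return HmmModel(
        space=space,
        startprob=np.asarray(d["startprob"]),
        transmat=np.asarray(d["transmat"]),
        means=np.asarray(d["means"]),
        variances=np.asarray(d["variances"]),
        ratio_cap=d.get("ratio_cap"),
        rd=d.get("rd"),
        ff=d.get("ff"),
    )
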