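"""Targeted count-table I/O and the experimental-data RC pipeline.

Input is a tab-separated table of UMI-collapsed molecule counts per
targeted locus — columns ``sample_id``, ``chromosome_id``, ``locus_id``,
``position``, ``molecule_count`` — with a config-declared mapping of
chromosomes to *reference* (assumed euploid) or *studied* roles.

The pipeline per sample: Tukey IQR filtering of outlier loci per
chromosome, RC emission parameters anchored to the sample's own reference
chromosomes (euploid mean = mean retained reference count; trisomy mean =
euploid mean x (1 + FF/2) with FF assumed 10% by default; variances = vmr x
means), Viterbi decoding of the studied chromosome in positional order, and
a mode call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .classify import ChromosomeCall, mode_call
from .hmm import (
    HmmModel,
    build_transitions,
    rc_state_space,
    state_frequencies,
    viterbi_decode,
)

__all__ = [
    "REQUIRED_COLUMNS",
    "CountTableError",
    "MissingColumnError",
    "NegativeCountError",
    "DuplicateKeyError",
    "TargetCountTable",
    "read_count_table",
    "write_count_table",
    "iqr_filter",
    "call_experimental_sample",
    "ExperimentalCall",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    "sample_id",
    "chromosome_id",
    "locus_id",
    "position",
    "molecule_count",
)


class CountTableError(ValueError):
    """Base class for count-table validation failures."""


class MissingColumnError(CountTableError):
    pass


class NegativeCountError(CountTableError):
    pass


class DuplicateKeyError(CountTableError):
    pass


@dataclass
class TargetCountTable:
    """Validated molecule counts with chromosome role declarations.

    ``roles`` maps each chromosome id to ``"reference"`` or ``"studied"``.
    """

    data: pd.DataFrame
    roles: Mapping[str, str]

    def __post_init__(self) -> None:
        bad = set(self.roles.values()) - {"reference", "studied"}
        if bad:
            raise CountTableError(f"unknown chromosome roles: {sorted(bad)}")

    @property
    def samples(self) -> list[str]:
        return sorted(self.data["sample_id"].unique())

    def chromosomes(self, role: str) -> list[str]:
        return sorted(c for c, r in self.roles.items() if r == role)

    def sample_counts(self, sample_id: str, chromosome_id: str) -> pd.DataFrame:
        df = self.data
        sel = df[(df["sample_id"] == sample_id) & (df["chromosome_id"] == chromosome_id)]
        return sel.sort_values("position", kind="stable").reset_index(drop=True)


def read_count_table(path, roles: Mapping[str, str]) -> TargetCountTable:
    """Read and validate a tab-separated molecule-count table.

    Gzip-compressed input is handled transparently by suffix.  Raises a
    distinct, named error for missing columns, negative counts and
    duplicate (sample, chromosome, locus) keys.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise MissingColumnError(f"count table is missing columns: {missing}")
    df = df[list(REQUIRED_COLUMNS)]
    negative = df.index[df["molecule_count"] < 0]
    if len(negative):
        raise NegativeCountError(
            f"negative molecule_count at table row(s) {list(negative[:5])}"
        )
    key = ["sample_id", "chromosome_id", "locus_id"]
    dup = df.duplicated(subset=key)
    if dup.any():
        first = df[dup].iloc[0]
        raise DuplicateKeyError(
            "duplicate (sample, chromosome, locus) key: "
            f"({first['sample_id']}, {first['chromosome_id']}, {first['locus_id']})"
        )
    undeclared = set(df["chromosome_id"].unique()) - set(roles)
    if undeclared:
        raise CountTableError(
            f"chromosomes without a declared role: {sorted(map(str, undeclared))}"
        )
    return TargetCountTable(data=df, roles=dict(roles))


def write_count_table(table: TargetCountTable, path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


def iqr_filter(counts: np.ndarray, k: float = 1.5) -> np.ndarray:
    """Boolean mask of loci retained by Tukey fences.

    Retains counts within ``[Q1 - k * IQR, Q3 + k * IQR]`` with quartiles
    by linear interpolation.  Fewer than 4 loci: nothing is filtered (a
    warning is logged).  Idempotent: re-filtering retained loci removes
    nothing.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size < 4:
        logger.warning(
            "IQR filter skipped: only %d loci (need >= 4)", counts.size
        )
        return np.ones(counts.size, dtype=bool)
    q1, q3 = np.percentile(counts, [25, 75])
    iqr = q3 - q1
    return (counts >= q1 - k * iqr) & (counts <= q3 + k * iqr)


@dataclass
class ExperimentalCall:
    """RC-pipeline result for one sample of an experimental count table."""

    sample_id: str
    call: ChromosomeCall
    locus_states: pd.DataFrame  # chromosome_id, locus_id, position, count, state
    state_proportions: dict[str, float]
    reference_mean: float
    assumed_ff: float
    n_loci_retained: int


def _rc_model_from_reference(
    reference_mean: float,
    assumed_ff: float,
    vmr: float,
    stay_switch_ratio: float,
    rd: float | None = None,
) -> HmmModel:
    space = rc_state_space()
    means = np.array([reference_mean, reference_mean * (1.0 + assumed_ff / 2.0)])
    return HmmModel(
        space=space,
        startprob=np.full(2, 0.5),
        transmat=build_transitions(space, stay_switch_ratio),
        means=means[:, None],
        variances=(vmr * means)[:, None],
        rd=reference_mean if rd is None else rd,
        ff=assumed_ff,
    )


def call_experimental_sample(
    table: TargetCountTable,
    sample_id: str,
    assumed_ff: float = 0.10,
    iqr_k: float = 1.5,
    vmr: float = 3.0,
    stay_switch_ratio: float = 10.0,
) -> ExperimentalCall:
    """Run the RC pipeline on one sample of an experimental count table.

    Emissions are anchored to the data itself: the euploid mean is the mean
    retained molecule count over the sample's reference chromosomes, the
    trisomy mean is that times ``1 + assumed_ff / 2``, and variances follow
    the over-dispersion ratio ``vmr``.  Studied-chromosome loci are decoded
    in positional order and the chromosome is called by the mode rule.
    """
    ref_chroms = table.chromosomes("reference")
    studied_chroms = table.chromosomes("studied")
    if not ref_chroms:
        raise CountTableError("no reference chromosome declared")
    if not studied_chroms:
        raise CountTableError("no studied chromosome declared")

    ref_counts = []
    for chrom in ref_chroms:
        counts = table.sample_counts(sample_id, chrom)["molecule_count"].to_numpy()
        if counts.size:
            ref_counts.append(counts[iqr_filter(counts, iqr_k)])
    ref_counts = np.concatenate(ref_counts) if ref_counts else np.array([])
    if ref_counts.size == 0:
        raise CountTableError(f"sample {sample_id!r} has no reference loci")
    reference_mean = float(ref_counts.mean())

    model = _rc_model_from_reference(
        reference_mean, assumed_ff, vmr, stay_switch_ratio
    )

    frames = []
    for chrom in studied_chroms:
        df = table.sample_counts(sample_id, chrom)
        if df.empty:
            continue
        counts = df["molecule_count"].to_numpy()
        keep = iqr_filter(counts, iqr_k)
        df = df[keep].reset_index(drop=True)
        path = viterbi_decode(df["molecule_count"].to_numpy(float), model)
        df = df.assign(state=[model.space.states[s] for s in path])
        frames.append(df)
    if not frames:
        raise CountTableError(f"sample {sample_id!r} has no studied loci")
    locus_states = pd.concat(frames, ignore_index=True)

    state_idx = np.array(
        [model.space.states.index(s) for s in locus_states["state"]]
    )
    profile = state_frequencies(
        state_idx,
        model.space,
        rd=reference_mean,
        ff=assumed_ff,
        ff_provenance="assumed",
    )
    call = mode_call(profile, model.space)
    proportions = dict(zip(model.space.states, profile.frequencies.tolist()))
    return ExperimentalCall(
        sample_id=sample_id,
        call=call,
        locus_states=locus_states,
        state_proportions=proportions,
        reference_mean=reference_mean,
        assumed_ff=assumed_ff,
        n_loci_retained=int(len(locus_states)),
    )
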