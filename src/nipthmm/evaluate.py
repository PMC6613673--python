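"""Simulation experiments: accuracy grids over (condition, FF, RD).

This module runs the package's benchmark experiments end to end:
simulate cohorts for every grid cell, fit HMM emissions, Viterbi-decode,
call chromosomes by HMM mode / decision tree / SVM, and aggregate
classification accuracy per cell, per fetal-fraction band and overall.

Model configurations
--------------------
``RC_fixed``
    2-state read-count HMM with emissions trained at the expected median
    fetal fraction of 10% (read counts alone cannot reveal FF).
``RC_perfect``
    The same model trained at each cell's true FF — an upper bound.
``AR`` / ``RCAR``
    7-state allelic-ratio and combined models, emissions trained per cell;
    their meta-classifier FF feature is *estimated* from the reference
    chromosome.

Accuracy is the fraction of samples whose call equals the true condition;
an unclassified sample never counts as correct.  For the read-count models
the truth is two-class (euploidy vs trisomy, parental origin being
invisible to read counts); for the 7-state models it is three-class.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import classify as _classify
from . import hmm as _hmm
from .classify import UNCLASSIFIED, ChromosomeCall, fit_margin, fit_tree
from .features import estimate_ff_batch
from .hmm import (
    HmmModel,
    fit_emissions,
    rc_observations,
    seven_state_observations,
    state_frequencies_batch,
    viterbi_decode_batch,
)
from .simulate import (
    CONDITIONS,
    EUPLOIDY,
    MATERNAL_TRISOMY,
    PATERNAL_TRISOMY,
    Cohort,
    SimulationConfig,
    simulate_cohort,
)

__all__ = [
    "GridConfig",
    "AccuracyReport",
    "FF_BANDS",
    "accuracy",
    "run_grid",
    "loci_subsample_experiment",
    "maf_informative_experiment",
    "theoretical_informative_fraction",
]

#: Fetal-fraction aggregation bands (inclusive bounds, as proportions).
FF_BANDS = ((0.01, 0.05), (0.06, 0.10), (0.11, 0.15), (0.16, 0.20))

_DEFAULT_FF = tuple(round(0.01 * i, 2) for i in range(1, 21))
#: Desk-scale read-depth grid: an evenly spaced thinning of the full
#: 500..15000-step-500 design, so that unweighted cell averages estimate
#: the full-grid averages without over-weighting either end of the range.
_DEFAULT_RD = (1500, 4000, 6500, 9000, 11500, 14000)


@dataclass(frozen=True)
class GridConfig:
    """Configuration of one grid experiment.

    Defaults are desk-scale: the full FF range but a thinned RD grid and
    200 test samples per condition cell (the benchmark design uses 10,000).
    """

    ff_values: tuple[float, ...] = _DEFAULT_FF
    rd_values: tuple[float, ...] = _DEFAULT_RD
    conditions: tuple[str, ...] = CONDITIONS
    model_kinds: tuple[str, ...] = ("RC_fixed", "AR", "RCAR")
    n_loci: int = 1000
    maf: float = 0.5
    vmr: float = 3.0
    n_train: int = 100
    n_test: int = 200
    rc_fixed_ff: float = 0.10
    stay_switch_ratio: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        known = {"RC_fixed", "RC_perfect", "AR", "RCAR"}
        bad = set(self.model_kinds) - known
        if bad:
            raise ValueError(f"unknown model kinds: {sorted(bad)}")


@dataclass
class AccuracyReport:
    """Per-cell accuracies plus band/overall aggregation helpers.

    ``cells`` columns: model, method, condition, ff, rd, accuracy, n.
    Aggregates are unweighted means over cells (every cell carries the
    same number of samples).
    """

    cells: pd.DataFrame

    _KEY = ["model", "method", "condition", "ff", "rd"]

    def subset(self, **filters) -> pd.DataFrame:
        df = self.cells
        for col, val in filters.items():
            if isinstance(val, (list, tuple, set)):
                df = df[df[col].isin(val)]
            else:
                df = df[df[col] == val]
        return df

    def overall(self, model: str, method: str) -> float:
        df = self.subset(model=model, method=method)
        if df.empty:
            raise KeyError(f"no cells for model={model!r}, method={method!r}")
        return float(df["accuracy"].mean())

    def band(
        self,
        model: str,
        method: str,
        band: tuple[float, float],
        conditions: Sequence[str] | None = None,
    ) -> float:
        df = self.subset(model=model, method=method)
        if conditions is not None:
            df = df[df["condition"].isin(list(conditions))]
        lo, hi = band
        df = df[(df["ff"] >= lo - 1e-9) & (df["ff"] <= hi + 1e-9)]
        if df.empty:
            raise KeyError(f"no cells in band {band}")
        return float(df["accuracy"].mean())

    def band_table(self) -> pd.DataFrame:
        """Band x (model, method) accuracy table plus a total row."""
        rows = {}
        pairs = sorted(
            self.cells[["model", "method"]].drop_duplicates().itertuples(index=False)
        )
        for lo, hi in FF_BANDS:
            label = f"{int(lo * 100)}-{int(hi * 100)}%"
            row = {}
            for m, meth in pairs:
                try:
                    row[(m, meth)] = self.band(m, meth, (lo, hi))
                except KeyError:
                    row[(m, meth)] = np.nan
            rows[label] = row
        rows["total"] = {(m, meth): self.overall(m, meth) for m, meth in pairs}
        return pd.DataFrame(rows).T

    def to_tsv(self, path) -> None:
        self.cells.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path) -> "AccuracyReport":
        return cls(cells=pd.read_csv(path, sep="\t"))


def accuracy(calls: Sequence, truths: Sequence[str]) -> float:
    """Fraction of calls matching the truth; unclassified never matches."""
    if len(calls) != len(truths):
        raise ValueError("calls and truths must have equal length")
    if len(calls) == 0:
        raise ValueError("cannot compute accuracy of an empty set")
    labels = [c.condition if isinstance(c, ChromosomeCall) else c for c in calls]
    return float(np.mean([c == t for c, t in zip(labels, truths)]))


# ---------------------------------------------------------------------------
# Vectorised calling helpers
# ---------------------------------------------------------------------------


def _truth_label(kind: str, condition: str) -> str:
    if kind.startswith("RC_"):
        return EUPLOIDY if condition == EUPLOIDY else "trisomy"
    return condition


def _mode_calls_from_freqs(freqs: np.ndarray, space: _hmm.StateSpace) -> np.ndarray:
    """Vectorised mode rule over a (N, S) frequency matrix."""
    groups = space.condition_groups()
    indicator = np.array(
        [[c == g for g in groups] for c in space.conditions], dtype=float
    )
    mass = freqs @ indicator
    order = np.argsort(-mass, axis=1, kind="stable")
    top = mass[np.arange(len(mass)), order[:, 0]]
    tie = np.zeros(len(mass), dtype=bool)
    if len(groups) > 1:
        second = mass[np.arange(len(mass)), order[:, 1]]
        tie = top == second
    labels = np.array(
        [_classify._reported_condition(g, space) for g in groups], dtype=object
    )
    calls = labels[order[:, 0]]
    calls[tie] = UNCLASSIFIED
    return calls


def _cell_rng(seed: int, *tags: int) -> np.random.Generator:
    """Independent, reproducible stream per grid cell."""
    return np.random.default_rng([seed, *tags])


def _decode_cohort(
    cohort: Cohort, model: HmmModel
) -> tuple[np.ndarray, np.ndarray]:
    """Decode a cohort; returns (state frequencies (N, S), lengths)."""
    kind = model.space.kind
    if kind == "RC":
        obs = rc_observations(cohort.studied)
        obs = np.atleast_2d(obs)
        lengths = np.full(obs.shape[0], obs.shape[1])
        paths, _ = viterbi_decode_batch(obs[..., None], model)
    else:
        obs, lengths = seven_state_observations(
            cohort.studied, model.ratio_cap, with_counts=(kind == "RCAR")
        )
        paths, _ = viterbi_decode_batch(obs, model, lengths)
    freqs = state_frequencies_batch(paths, lengths, model.space.n_states)
    return freqs, lengths


def _train_rc_registry(cfg: GridConfig) -> dict[float, HmmModel]:
    """RC models trained at the fixed 10% FF convention, one per read depth."""
    registry: dict[float, HmmModel] = {}
    for rd in cfg.rd_values:
        cohorts = []
        for ci, cond in enumerate(cfg.conditions):
            sim = SimulationConfig(
                n_loci=cfg.n_loci,
                maf=cfg.maf,
                read_depth=rd,
                fetal_fraction=cfg.rc_fixed_ff,
                condition=cond,
                vmr=cfg.vmr,
            )
            rng = _cell_rng(cfg.seed, 900, int(rd), ci)
            cohorts.append(simulate_cohort(sim, cfg.n_train, rng))
        registry[rd] = fit_emissions(
            cohorts, "RC", cfg.stay_switch_ratio, rd=rd, ff=cfg.rc_fixed_ff
        )
    return registry


def nearest_rd_model(registry: Mapping[float, HmmModel], rd: float) -> HmmModel:
    """Model trained at the read depth closest to ``rd``."""
    key = min(registry, key=lambda k: abs(k - rd))
    return registry[key]


def run_grid(cfg: GridConfig) -> AccuracyReport:
    """Run the full simulation benchmark over the (condition, FF, RD) grid.

    For every cell: simulate training and test cohorts, fit per-cell
    emissions (7-state models; the fixed-FF RC model comes from a per-RD
    registry), decode, mode-call, and collect state-frequency features.
    One decision tree and one SVM per model configuration are then trained
    on the pooled training features of the whole grid and applied to every
    test sample.
    """
    kinds = cfg.model_kinds
    registry = _train_rc_registry(cfg) if "RC_fixed" in kinds else {}

    records: list[dict] = []
    meta_train: dict[str, list] = {k: [] for k in kinds}
    meta_test: dict[str, list] = {k: [] for k in kinds}

    for ff, rd in itertools.product(cfg.ff_values, cfg.rd_values):
        cohorts: dict[str, dict[str, Cohort]] = {"train": {}, "test": {}}
        for ci, cond in enumerate(cfg.conditions):
            sim = SimulationConfig(
                n_loci=cfg.n_loci,
                maf=cfg.maf,
                read_depth=rd,
                fetal_fraction=ff,
                condition=cond,
                vmr=cfg.vmr,
            )
            rng = _cell_rng(cfg.seed, 1, int(rd), int(round(ff * 100)), ci)
            cohorts["train"][cond] = simulate_cohort(sim, cfg.n_train, rng)
            cohorts["test"][cond] = simulate_cohort(sim, cfg.n_test, rng)

        train_list = list(cohorts["train"].values())
        cell_models: dict[str, HmmModel] = {}
        for kind in kinds:
            if kind == "RC_fixed":
                cell_models[kind] = nearest_rd_model(registry, rd)
            elif kind == "RC_perfect":
                cell_models[kind] = fit_emissions(
                    train_list, "RC", cfg.stay_switch_ratio, rd=rd, ff=ff
                )
            else:
                cell_models[kind] = fit_emissions(
                    train_list, kind, cfg.stay_switch_ratio, rd=rd, ff=ff
                )

        for kind in kinds:
            model = cell_models[kind]
            for split in ("train", "test"):
                for cond, cohort in cohorts[split].items():
                    freqs, _ = _decode_cohort(cohort, model)
                    n = cohort.n_samples
                    if kind.startswith("RC_"):
                        ff_feat = np.full(n, ff)
                    else:
                        ref = cohort.reference
                        ff_feat = estimate_ff_batch(
                            ref.count_a, ref.count_b, ref.m_b, ref.f_b, ref.f_total
                        )
                    features = _classify.profile_features(
                        freqs, rd=np.full(n, rd), ff=ff_feat
                    )
                    truth = _truth_label(kind, cond)
                    if split == "train":
                        meta_train[kind].append((features, truth))
                    else:
                        meta_test[kind].append((features, truth, cond, ff, rd))
                        calls = _mode_calls_from_freqs(freqs, model.space)
                        records.append(
                            {
                                "model": kind,
                                "method": "mode",
                                "condition": cond,
                                "ff": ff,
                                "rd": rd,
                                "accuracy": float(np.mean(calls == truth)),
                                "n": n,
                            }
                        )

    # meta-classifiers: one tree and one margin model per configuration,
    # trained on the pooled grid
    for kind in kinds:
        x_train = np.concatenate([f for f, _ in meta_train[kind]])
        y_train = np.concatenate(
            [np.full(len(f), t) for f, t in meta_train[kind]]
        )
        tree = fit_tree(x_train, y_train)
        margin = fit_margin(x_train, y_train)
        x_test = np.concatenate([f for f, *_ in meta_test[kind]])
        pred_tree = tree.predict(x_test)
        pred_margin = margin.predict(x_test)
        offset = 0
        for features, truth, cond, ff, rd in meta_test[kind]:
            n = len(features)
            sl = slice(offset, offset + n)
            offset += n
            for method, pred in (("tree", pred_tree), ("margin", pred_margin)):
                records.append(
                    {
                        "model": kind,
                        "method": method,
                        "condition": cond,
                        "ff": ff,
                        "rd": rd,
                        "accuracy": float(np.mean(pred[sl] == truth)),
                        "n": n,
                    }
                )

    return AccuracyReport(cells=pd.DataFrame.from_records(records))


# ---------------------------------------------------------------------------
# Targeted-loci subsampling experiment
# ---------------------------------------------------------------------------


def loci_subsample_experiment(
    n_loci_set: Sequence[int] = (50, 100, 200, 500, 1000),
    rd: float = 1000.0,
    ff_set: Sequence[float] = (0.03, 0.10),
    conditions: Sequence[str] = CONDITIONS,
    n_loci_full: int = 1000,
    n_train: int = 100,
    n_test: int = 200,
    emission_ff: float | None = None,
    vmr: float = 3.0,
    maf: float = 0.5,
    stay_switch_ratio: float = 10.0,
    seed: int = 0,
) -> AccuracyReport:
    """Accuracy of the RC model as a function of the number of targeted loci.

    Each sample keeps a uniform random subset of its loci (chromosomal
    order preserved), is decoded by the RC model trained at the full locus
    count, and is called by mode / tree / margin.  RC emissions are
    trained at each subset's own fetal fraction by default (this
    experiment isolates the effect of the locus count); pass
    ``emission_ff`` to train at one fixed fetal fraction instead.  The
    tree and margin callers are trained per locus count on the pooled
    (FF x condition) training profiles.
    """
    if max(n_loci_set) > n_loci_full:
        raise ValueError("cannot subsample more loci than simulated")

    def rc_model(train_ff: float) -> HmmModel:
        cohorts = []
        for ci, cond in enumerate(conditions):
            sim = SimulationConfig(
                n_loci=n_loci_full,
                maf=maf,
                read_depth=rd,
                fetal_fraction=train_ff,
                condition=cond,
                vmr=vmr,
            )
            cohorts.append(
                simulate_cohort(
                    sim, n_train, _cell_rng(seed, 700, int(round(train_ff * 100)), ci)
                )
            )
        return fit_emissions(cohorts, "RC", stay_switch_ratio, rd=rd, ff=train_ff)

    models = {
        ff: rc_model(ff if emission_ff is None else emission_ff) for ff in ff_set
    }

    cohorts: dict[tuple, dict[str, Cohort]] = {}
    for fi, ff in enumerate(ff_set):
        for ci, cond in enumerate(conditions):
            sim = SimulationConfig(
                n_loci=n_loci_full,
                maf=maf,
                read_depth=rd,
                fetal_fraction=ff,
                condition=cond,
                vmr=vmr,
            )
            rng = _cell_rng(seed, 701, fi, ci)
            cohorts[(ff, cond)] = {
                "train": simulate_cohort(sim, n_train, rng),
                "test": simulate_cohort(sim, n_test, rng),
            }

    records: list[dict] = []
    for k in n_loci_set:
        sub_rng = _cell_rng(seed, 702, int(k))
        train_feats, train_labels = [], []
        test_entries = []
        for (ff, cond), splits in cohorts.items():
            model = models[ff]
            truth = _truth_label("RC_fixed", cond)
            for split, cohort in splits.items():
                totals = np.atleast_2d(rc_observations(cohort.studied))
                n = totals.shape[0]
                if k < n_loci_full:
                    pick = np.argsort(
                        sub_rng.random((n, n_loci_full)), axis=1
                    )[:, :k]
                    pick.sort(axis=1)
                    obs = np.take_along_axis(totals, pick, axis=1)
                else:
                    obs = totals
                paths, _ = viterbi_decode_batch(obs[..., None], model)
                freqs = state_frequencies_batch(
                    paths, np.full(n, k), model.space.n_states
                )
                features = _classify.profile_features(
                    freqs, rd=np.full(n, rd), ff=np.full(n, ff)
                )
                if split == "train":
                    train_feats.append(features)
                    train_labels.append(np.full(n, truth))
                else:
                    calls = _mode_calls_from_freqs(freqs, model.space)
                    records.append(
                        {
                            "model": "RC_fixed",
                            "method": "mode",
                            "condition": cond,
                            "ff": ff,
                            "rd": rd,
                            "n_loci": k,
                            "accuracy": float(np.mean(calls == truth)),
                            "n": n,
                        }
                    )
                    test_entries.append((features, truth, cond, ff))

        x_train = np.concatenate(train_feats)
        y_train = np.concatenate(train_labels)
        tree = fit_tree(x_train, y_train)
        margin = fit_margin(x_train, y_train)
        for features, truth, cond, ff in test_entries:
            for method, caller in (("tree", tree), ("margin", margin)):
                pred = caller.predict(features)
                records.append(
                    {
                        "model": "RC_fixed",
                        "method": method,
                        "condition": cond,
                        "ff": ff,
                        "rd": rd,
                        "n_loci": k,
                        "accuracy": float(np.mean(pred == truth)),
                        "n": len(features),
                    }
                )
    return AccuracyReport(cells=pd.DataFrame.from_records(records))


# ---------------------------------------------------------------------------
# MAF-dependent proportion of informative variants
# ---------------------------------------------------------------------------


def theoretical_informative_fraction(maf: float, condition: str) -> float:
    """Closed-form probability that a SNP is informative.

    A SNP is informative when the mother and/or the fetus is heterozygous.
    With unrelated parents and allele B at frequency ``m``:

    * mother heterozygous: ``2 m (1 - m)``;
    * euploidy and maternal MI trisomy both add ``m (1 - m)`` for the
      mother-homozygous case (one independent non-maternal allele), giving
      ``3 m (1 - m)``;
    * paternal MI trisomy contributes two independent paternal alleles:
      ``(1-m)^2 (1 - (1-m)^2) + m^2 (1 - m^2)`` for the mother-homozygous
      case.
    """
    if not 0.0 <= maf <= 0.5:
        raise ValueError("maf must lie in [0, 0.5]")
    m = maf
    het = 2 * m * (1 - m)
    if condition in (EUPLOIDY, MATERNAL_TRISOMY):
        return het + m * (1 - m)
    if condition == PATERNAL_TRISOMY:
        return het + (1 - m) ** 2 * (1 - (1 - m) ** 2) + m**2 * (1 - m**2)
    raise ValueError(f"unknown condition {condition!r}")


def maf_informative_experiment(
    maf_set: Sequence[float] = (0.01, 0.05, 0.10, 0.20, 0.30, 0.40, 0.50),
    n_variants: int = 1000,
    n_reps: int = 100,
    conditions: Sequence[str] = CONDITIONS,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulated vs theoretical informative-SNP fractions per MAF.

    For every MAF value, ``n_reps`` chromosomes of ``n_variants`` loci are
    simulated per condition and the mean observed informative fraction is
    compared with the closed-form expectation.
    """
    from .simulate import _simulate_genotypes

    rows = []
    for mi, maf in enumerate(maf_set):
        for ci, cond in enumerate(conditions):
            rng = _cell_rng(seed, 800, mi, ci)
            m_b, f_b, f_total = _simulate_genotypes(
                n_reps, n_variants, maf, cond, rng
            )
            informative = (m_b == 1) | ((f_b > 0) & (f_b < f_total))
            rows.append(
                {
                    "maf": maf,
                    "condition": cond,
                    "simulated": float(informative.mean()),
                    "theoretical": theoretical_informative_fraction(maf, cond),
                    "n_variants": n_variants,
                    "n_reps": n_reps,
                }
            )
    return pd.DataFrame(rows)
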