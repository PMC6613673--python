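"""Chromosome-level fetal-condition calls from HMM state frequencies.

Three callers operate on a sample's :class:`~nipthmm.hmm.StateFrequencyProfile`:

* ``mode_call`` — the frequentist rule: sum decoded state frequencies
  within each fetal-condition group and call the condition with a strict
  plurality; an exact tie yields ``"unclassified"``.
* ``fit_tree`` / ``fit_margin`` — supervised meta-classifiers (a depth-3
  decision tree, and a soft-margin RBF SVM with default parameters) trained
  on features (RD, FF, state frequencies) pooled across simulation
  conditions.  These recover calls the mode rule cannot make, most notably
  paternal trisomy and low-fetal-fraction trisomies.

For the 2-state RC model the trisomy call is reported as plain
``"trisomy"`` (read counts cannot resolve parental origin); the 7-state
models report ``"maternal_trisomy"`` for the trisomy group — its allelic
patterns occur under both origins, and associating them with the maternal
origin avoids over-calling the (much rarer) paternal one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .hmm import StateFrequencyProfile, StateSpace

__all__ = [
    "UNCLASSIFIED",
    "ChromosomeCall",
    "MetaClassifier",
    "condition_mass",
    "mode_call",
    "profile_features",
    "fit_tree",
    "fit_margin",
    "predict",
]

UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class ChromosomeCall:
    """One chromosome-level call with the features that produced it."""

    condition: str
    method: str  # "mode", "tree" or "margin"
    features: dict = field(default_factory=dict)


def _reported_condition(group: str, space: StateSpace) -> str:
    if group == "trisomy" and space.kind != "RC":
        return "maternal_trisomy"
    return group


def condition_mass(profile: StateFrequencyProfile, space: StateSpace) -> dict[str, float]:
    """Total decoded frequency mass per fetal-condition group."""
    mass: dict[str, float] = {g: 0.0 for g in space.condition_groups()}
    for freq, cond in zip(profile.frequencies, space.conditions):
        mass[cond] += float(freq)
    return mass


def mode_call(profile: StateFrequencyProfile, space: StateSpace) -> ChromosomeCall:
    """Call the condition with a strict plurality of decoded loci.

    An exact tie between the top condition groups means no condition is
    prevalent and the sample is marked unclassified.
    """
    mass = condition_mass(profile, space)
    ordered = sorted(mass.items(), key=lambda kv: -kv[1])
    if len(ordered) > 1 and ordered[0][1] == ordered[1][1]:
        condition = UNCLASSIFIED
    else:
        condition = _reported_condition(ordered[0][0], space)
    return ChromosomeCall(
        condition=condition,
        method="mode",
        features={"rd": profile.rd, "ff": profile.ff, "mass": mass},
    )


def profile_features(
    profiles: Sequence[StateFrequencyProfile] | np.ndarray,
    rd: np.ndarray | None = None,
    ff: np.ndarray | None = None,
) -> np.ndarray:
    """Feature matrix (RD, FF, state frequencies) for the meta-classifiers.

    Accepts either a sequence of profiles, or a raw ``(N, S)`` frequency
    matrix together with per-sample ``rd`` and ``ff`` arrays.  Features are
    expressed in their reporting units — read depth in reads, fetal
    fraction and state frequencies in percent.  The tree caller is
    scale-invariant, but the kernel caller uses unstandardised features
    with a fixed kernel width, so the percent scale is what makes fetal
    fraction and frequency differences visible to it.
    """
    if isinstance(profiles, np.ndarray):
        if rd is None or ff is None:
            raise ValueError("rd and ff are required with a raw frequency matrix")
        freqs = np.atleast_2d(profiles)
        rd = np.broadcast_to(np.asarray(rd, dtype=float), (freqs.shape[0],))
        ff = np.broadcast_to(np.asarray(ff, dtype=float), (freqs.shape[0],))
        return np.column_stack([rd, 100.0 * ff, 100.0 * freqs])
    rows = [
        np.concatenate([[p.rd, 100.0 * p.ff], 100.0 * p.frequencies])
        for p in profiles
    ]
    return np.asarray(rows, dtype=float)


@dataclass
class MetaClassifier:
    """A fitted supervised caller over (RD, FF, state frequency) features."""

    estimator: object
    method: str
    n_features: int
    classes: tuple[str, ...]

    def predict(self, features: np.ndarray) -> np.ndarray:
        features = np.atleast_2d(np.asarray(features, dtype=float))
        if features.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got {features.shape[1]}"
            )
        return self.estimator.predict(features)


def fit_tree(
    features: np.ndarray,
    labels: Sequence[str],
    max_depth: int = 3,
    seed: int = 123,
) -> MetaClassifier:
    """Fit the depth-limited decision tree caller (Gini splits).

    Deterministic given ``seed``; a single-class training set yields a
    degenerate (constant) tree.
    """
    features = np.atleast_2d(np.asarray(features, dtype=float))
    labels = np.asarray(labels)
    est = DecisionTreeClassifier(max_depth=max_depth, random_state=seed)
    est.fit(features, labels)
    return MetaClassifier(
        estimator=est,
        method="tree",
        n_features=features.shape[1],
        classes=tuple(est.classes_),
    )


def fit_margin(
    features: np.ndarray, labels: Sequence[str], seed: int = 123
) -> MetaClassifier:
    """Fit the soft-margin kernel caller.

    RBF kernel, regularisation constant 1, kernel width 1/n_features,
    one-vs-one multiclass, no feature standardisation — i.e. default SVC
    parameters.  Requires at least two classes.
    """
    features = np.atleast_2d(np.asarray(features, dtype=float))
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("margin classifier requires at least two classes")
    est = SVC(C=1.0, kernel="rbf", gamma="auto", random_state=seed)
    est.fit(features, labels)
    return MetaClassifier(
        estimator=est,
        method="margin",
        n_features=features.shape[1],
        classes=tuple(est.classes_),
    )


def predict(model: MetaClassifier, profile_or_features) -> ChromosomeCall:
    """Call one sample with a fitted meta-classifier (never unclassified)."""
    if isinstance(profile_or_features, StateFrequencyProfile):
        features = profile_features([profile_or_features])
    else:
        features = np.atleast_2d(np.asarray(profile_or_features, dtype=float))
    label = model.predict(features)[0]
    return ChromosomeCall(condition=str(label), method=model.method)
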