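"""Structural feature extraction and the amino-acid predictor for linkers.

The linker designer must guess, for every residue position of a linker whose
backbone location is only coarsely known, which amino acid should sit there.
The signal used is the residue's structural neighbourhood: for each of the
20 amino-acid types A, the feature is the inverse-square-distance sum

    F_A(i) = Σ_a 1 / d_ia²

over residues a of type A whose Cα lies within a radius d_r (default 20 Å)
of residue i's Cα.  Because a linker's own sequence is unknown at design
time, the five sequence neighbours on either side of i are always excluded —
for training cases just as for design targets.

Prediction is a three-class problem (hydrophilic / hydrophobic / neutral): a
vote ensemble of bootstrap-trained minors (250 decision trees + 50 small
neural networks by default) outputs class probabilities as vote proportions,
and those are restored to per-amino-acid probabilities by multiplying with
the within-class compositions estimated from the training linkers:
pe(A) = pe(C) × p(A|C).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier
from sklearn.tree import DecisionTreeClassifier

from ._aa import AA_ALPHABET, AA_INDEX, CLASS_NAMES, DEFAULT_CLASS_OF_AA
from .structure import Structure

#: Default neighbourhood radius (Å) for feature extraction.
DEFAULT_FEATURE_RADIUS = 20.0
#: Sequence neighbours i±1..i±EXCLUSION_WINDOW are never counted.
EXCLUSION_WINDOW = 5


@dataclass
class FeatureVector:
    """Eq.-style 20-vector of inverse-square contact sums for one residue."""

    values: np.ndarray
    d_r: float = DEFAULT_FEATURE_RADIUS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (20,):
            raise ValueError("feature vector must have 20 entries")
        if np.any(self.values < 0):
            raise ValueError("feature values must be non-negative")


def compute_features(s: Structure, i: int,
                     d_r: float = DEFAULT_FEATURE_RADIUS) -> FeatureVector:
    """Features of residue serial ``i``: per amino-acid type, Σ 1/d².

    Only residues within ``d_r`` of i's Cα contribute; i itself and its
    sequence neighbours within ±5 positions are excluded.  Distances are
    Cα–Cα.  Features are indexed alphabetically by one-letter code.
    """
    if not 1 <= i <= len(s):
        raise ValueError(f"residue serial {i} out of range 1..{len(s)}")
    coords = s.ca_coords()
    center = coords[i - 1]
    F = np.zeros(20)
    for j, res in enumerate(s.residues, start=1):
        if abs(j - i) <= EXCLUSION_WINDOW:
            continue
        d2 = float(np.sum((coords[j - 1] - center) ** 2))
        if d2 <= d_r * d_r and d2 > 0:
            F[AA_INDEX[res.one_letter]] += 1.0 / d2
    return FeatureVector(F, d_r)


@dataclass
class ClassScheme:
    """Three-class partition of the amino acids plus per-class compositions.

    ``class_of`` maps every amino acid to exactly one of hydrophilic /
    hydrophobic / neutral; ``compositions[C]`` is the 20-vector p(A|C),
    non-zero only on members of C and summing to 1.
    """

    class_of: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_OF_AA))
    compositions: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.class_of) != set(AA_ALPHABET):
            raise ValueError("class scheme must cover all 20 amino acids")
        if set(self.class_of.values()) - set(CLASS_NAMES):
            raise ValueError(f"classes must be among {CLASS_NAMES}")
        if not self.compositions:
            self.compositions = self._uniform_compositions()
        for cname, comp in self.compositions.items():
            comp = np.asarray(comp, dtype=float)
            self.compositions[cname] = comp
            if comp.shape != (20,) or np.any(comp < 0):
                raise ValueError("composition must be a non-negative 20-vector")
            if abs(comp.sum() - 1.0) > 1e-9:
                raise ValueError(f"composition of {cname} does not sum to 1")
            outside = [a for a in AA_ALPHABET
                       if self.class_of[a] != cname and comp[AA_INDEX[a]] > 0]
            if outside:
                raise ValueError(
                    f"composition of {cname} has mass outside the class: "
                    f"{outside}")

    def members(self, cname: str) -> list[str]:
        return [a for a in AA_ALPHABET if self.class_of[a] == cname]

    def _uniform_compositions(self) -> dict[str, np.ndarray]:
        comps = {}
        for cname in CLASS_NAMES:
            comp = np.zeros(20)
            members = self.members(cname)
            for a in members:
                comp[AA_INDEX[a]] = 1.0 / len(members)
            comps[cname] = comp
        return comps

    @classmethod
    def from_linkers(cls, linker_sequences: list[str],
                     class_of: dict[str, str] | None = None,
                     laplace: float = 1.0) -> "ClassScheme":
        """Estimate p(A|C) from observed linker residues (Laplace-smoothed)."""
        scheme = cls(dict(class_of or DEFAULT_CLASS_OF_AA))
        counts = np.zeros(20)
        for seq in linker_sequences:
            for a in seq:
                counts[AA_INDEX[a]] += 1
        comps = {}
        for cname in CLASS_NAMES:
            members = scheme.members(cname)
            comp = np.zeros(20)
            total = sum(counts[AA_INDEX[a]] for a in members) + \
                laplace * len(members)
            for a in members:
                comp[AA_INDEX[a]] = (counts[AA_INDEX[a]] + laplace) / total
            comps[cname] = comp
        return cls(dict(scheme.class_of), comps)


@dataclass
class EnsemblePredictor:
    """Vote ensemble of bootstrap-trained minor classifiers.

    Class probabilities are the proportions of minors voting for each class,
    in CLASS_NAMES order.
    """

    minors: list
    scheme: ClassScheme

    @property
    def n_minors(self) -> int:
        return len(self.minors)

    def predict_class_probs_batch(self, X: np.ndarray) -> np.ndarray:
        """(n, 3) vote proportions for n feature rows."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        votes = np.zeros((X.shape[0], 3))
        for minor in self.minors:
            pred = minor.predict(X)
            for row, label in enumerate(pred):
                votes[row, CLASS_NAMES.index(label)] += 1
        return votes / self.n_minors


def _as_matrix(cases) -> tuple[np.ndarray, np.ndarray]:
    X, y = [], []
    for feat, label in cases:
        vec = feat.values if isinstance(feat, FeatureVector) else feat
        X.append(np.asarray(vec, dtype=float))
        y.append(label)
    return np.array(X), np.array(y)


def train_ensemble(cases, scheme: ClassScheme, seed: int,
                   n_trees: int = 250, n_nets: int = 50) -> EnsemblePredictor:
    """Train the bootstrap vote ensemble.

    Each minor is fit on an independent bootstrap resample (same size as the
    input, with replacement).  Decision trees are depth-capped at 8; the
    neural minors are single-hidden-layer (16 units) perceptrons with a
    capped iteration budget.  Deterministic given the seed.
    """
    if not cases:
        raise ValueError("cannot train on an empty case list")
    X, y = _as_matrix(cases)
    if len(set(y)) < 2:
        warnings.warn("training data has a single class; the ensemble will "
                      "predict it with probability 1", stacklevel=2)
    rng = np.random.default_rng(seed)
    minors = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for kind, count in (("tree", n_trees), ("net", n_nets)):
            for _ in range(count):
                idx = rng.integers(0, len(X), size=len(X))
                minor_seed = int(rng.integers(0, 2 ** 31 - 1))
                if kind == "tree":
                    minor = DecisionTreeClassifier(max_depth=8,
                                                   random_state=minor_seed)
                else:
                    minor = MLPClassifier(hidden_layer_sizes=(16,),
                                          max_iter=300, tol=1e-3,
                                          random_state=minor_seed)
                minor.fit(X[idx], y[idx])
                minors.append(minor)
    return EnsemblePredictor(minors, scheme)


def predict_class_probs(p: EnsemblePredictor,
                        f: FeatureVector | np.ndarray) -> np.ndarray:
    """Vote proportions (hydrophilic, hydrophobic, neutral) for one residue."""
    vec = f.values if isinstance(f, FeatureVector) else np.asarray(f)
    return p.predict_class_probs_batch(vec[None, :])[0]


def restore_aa_probs(class_probs, scheme: ClassScheme) -> np.ndarray:
    """Restore 3-class probabilities to the 20 amino acids.

    pe(A) = pe(C(A)) × p(A|C(A)); the result sums to 1 whenever the class
    probabilities do.  ``class_probs`` is indexed in CLASS_NAMES order.
    """
    class_probs = np.asarray(class_probs, dtype=float)
    if class_probs.shape != (3,):
        raise ValueError("class_probs must be a 3-vector "
                         "(hydrophilic, hydrophobic, neutral)")
    if np.any(class_probs < 0) or abs(class_probs.sum() - 1.0) > 1e-6:
        raise ValueError("class probabilities must be a distribution")
    pe = np.zeros(20)
    for a in AA_ALPHABET:
        cname = scheme.class_of[a]
        pe[AA_INDEX[a]] = class_probs[CLASS_NAMES.index(cname)] * \
            scheme.compositions[cname][AA_INDEX[a]]
    return pe


@dataclass
class AAProbabilityProfile:
    """Per-linker-position probability vectors over the 20 amino acids."""

    probs: np.ndarray  # (length, 20)

    def __post_init__(self) -> None:
        self.probs = np.atleast_2d(np.asarray(self.probs, dtype=float))
        if self.probs.shape[1] != 20 or np.any(self.probs < 0):
            raise ValueError("profile must be an (l, 20) non-negative array")
        if np.any(np.abs(self.probs.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("each profile position must sum to 1")

    def __len__(self) -> int:
        return self.probs.shape[0]
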