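"""The six-step termini-linker design protocol.

To engineer a circular permutant the native N- and C-termini must be joined.
When they are distant, a peptide linker is designed as follows:

1. Estimate the linker length l.  For termini closer than 20 Å a log fit to
   known CP linkers is used, l = Round(21.8·ln(b) − 52.5) clamped at 0; for
   more distant termini an iterative energy scan over candidate lengths is
   run.  Make ``t`` temporary linkers of length l (drawn from the amino-acid
   propensities of known CP linkers), insert each into the target sequence,
   build a coarse model per temporary linker, and keep the ``t′``
   lowest-energy coarse models.
2. On each kept coarse model, compute the structural features of every
   linker position and predict its amino-acid probabilities (class ensemble
   + composition restoration).
3. Sample ``k`` candidate sequences per coarse model from those
   probabilities.
4. Pool the t′·k candidates.
5. Rebuild ``m`` models per candidate and keep each candidate's lowest
   energy.
6. Rank candidates by energy and report the best ``n_report``.

Defaults follow the study conditions: t=200, t′=20, k=10, m=10, 30 reported
candidates, feature radius 20 Å.  Everything is seeded and, with a
deterministic backend, bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ._aa import AA_ALPHABET, AA_INDEX
from .linker_ml import (AAProbabilityProfile, ClassScheme, EnsemblePredictor,
                        compute_features, restore_aa_probs)
from .seqalign import Alignment
from .structure import (CPSite, Structure, cp_sequence,
                        make_pseudo_cp_template, renumber, termini_distance)

#: Eq.-3 domain bound: beyond this termini distance the log fit is invalid.
LENGTH_FIT_MAX_DISTANCE = 20.0


@dataclass(frozen=True)
class DesignConfig:
    """All protocol knobs; defaults are the study conditions."""

    t: int = 200
    t_prime: int = 20
    k: int = 10
    m_models: int = 10
    n_report: int = 30
    d_r: float = 20.0
    seed: int = 0
    backend: str = "surrogate"

    def __post_init__(self) -> None:
        if not (self.t >= self.t_prime >= 1):
            raise ValueError("need t ≥ t′ ≥ 1")
        if min(self.k, self.m_models, self.n_report) < 1:
            raise ValueError("k, m_models and n_report must be ≥ 1")


#: Scaled-down configuration for continuous testing.
CI_CONFIG = DesignConfig(t=20, t_prime=5, k=3, m_models=2, n_report=10)


@dataclass
class LinkerCandidate:
    """A designed linker with its best model and energy (lower is better)."""

    sequence: str
    energy: float
    model: Structure
    provenance: tuple[int, int]  # (coarse-model id, sample id)


@dataclass(frozen=True)
class PropensityTable:
    """Amino-acid sampling distribution for temporary linkers."""

    probs: tuple[float, ...] = field(
        default_factory=lambda: tuple([1.0 / 20] * 20))

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (20,) or np.any(p < 0):
            raise ValueError("propensity table must be a non-negative "
                             "20-vector")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("propensity table must sum to 1")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.probs, dtype=float)

    @classmethod
    def uniform(cls) -> "PropensityTable":
        return cls()

    @classmethod
    def from_sequences(cls, sequences: list[str],
                       laplace: float = 1.0) -> "PropensityTable":
        counts = np.full(20, laplace, dtype=float)
        for seq in sequences:
            for a in seq:
                counts[AA_INDEX[a]] += 1
        return cls(tuple(counts / counts.sum()))


def _round_half_away(x: float) -> int:
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def estimate_linker_length(b: float) -> int:
    """Linker length from termini distance via the CPDB log fit.

    l = Round(21.8·ln(b) − 52.5), clamped at 0, for 0 < b < 20 Å; rounding
    is half-away-from-zero.  Distances of 20 Å and beyond are outside the
    fit's domain and must use the iterative estimator.
    """
    if b <= 0:
        raise ValueError("termini distance must be positive")
    if b >= LENGTH_FIT_MAX_DISTANCE:
        raise ValueError("termini distance ≥ 20 Å: use iterative estimator")
    return max(0, _round_half_away(21.8 * math.log(b) - 52.5))


def sample_temporary_linkers(l: int, table: PropensityTable, t: int,
                             seed: int) -> list[str]:
    """Draw ``t`` random linkers of length ``l``, positions i.i.d. from the
    propensity table."""
    if l < 1 or t < 1:
        raise ValueError("need l ≥ 1 and t ≥ 1")
    p = table.array
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("degenerate propensity table")
    rng = np.random.default_rng(seed)
    letters = np.array(list(AA_ALPHABET))
    return ["".join(rng.choice(letters, size=l, p=p)) for _ in range(t)]


def sample_candidate_sequences(profile: AAProbabilityProfile, k: int,
                               seed: int) -> list[str]:
    """Draw ``k`` sequences, each position from its own probability vector."""
    rng = np.random.default_rng(seed)
    letters = np.array(list(AA_ALPHABET))
    out = []
    for _ in range(k):
        seq = "".join(
            rng.choice(letters, p=profile.probs[pos])
            for pos in range(len(profile))
        )
        out.append(seq)
    return out


@dataclass
class CPModelingTask:
    """Precomputed geometry of one CP modeling problem."""

    native: Structure
    site: CPSite
    pseudo: Structure        # pseudo-CP template
    cpm_seq: str             # permuted sequence, no linker
    junction: int            # linker slot: between cpm_seq[junction-1] and [junction]

    @classmethod
    def from_native(cls, native: Structure, site: CPSite) -> "CPModelingTask":
        native = renumber(native)
        pseudo = make_pseudo_cp_template(native, site)
        return cls(native, site, pseudo, cp_sequence(native.sequence, site),
                   len(native) - site + 1)

    def target_with_linker(self, linker: str) -> str:
        j = self.junction
        return self.cpm_seq[:j] + linker + self.cpm_seq[j:]

    def modeling_alignment(self, linker: str) -> Alignment:
        """The exact target/template alignment: everything matches except the
        inserted linker, which gaps the template row."""
        j = self.junction
        rows = (self.target_with_linker(linker),
                self.cpm_seq[:j] + "-" * len(linker) + self.cpm_seq[j:])
        return Alignment(rows, float(len(self.cpm_seq)))

    def linker_serials(self, l: int) -> list[int]:
        return list(range(self.junction + 1, self.junction + l + 1))


def _build(backend, task: CPModelingTask, linker: str):
    return backend.build_model(task.modeling_alignment(linker), task.pseudo,
                               linker)


def estimate_linker_length_long(native: Structure, site: CPSite, backend,
                                cfg: DesignConfig,
                                table: PropensityTable | None = None) -> int:
    """Iterative linker-length search for termini ≥ 20 Å apart.

    Scans l ∈ {20, 25, …, ⌊L/5⌋} (just {20} for small proteins), keeping for
    each l the minimum energy over ``t`` temporary linkers; then rescans
    l_best − 4 … l_best + 4 and returns the length with the overall lowest
    energy.  Ties go to the smallest scanned length.
    """
    table = table or PropensityTable.uniform()
    task = CPModelingTask.from_native(native, site)
    lmax = max(20, len(native) // 5)
    coarse = list(range(20, lmax + 1, 5))

    evaluated: dict[int, float] = {}

    def energy_of(l: int, sub: int) -> float:
        if l not in evaluated:
            temps = sample_temporary_linkers(
                l, table, cfg.t, seed=cfg.seed * 100003 + l * 31 + sub)
            evaluated[l] = min(_build(backend, task, tmp)[1] for tmp in temps)
        return evaluated[l]

    for l in coarse:
        energy_of(l, 0)
    l_best = min(coarse, key=lambda l: (evaluated[l], l))
    for l in range(max(1, l_best - 4), l_best + 5):
        energy_of(l, 1)
    return min(evaluated, key=lambda l: (evaluated[l], l))


def design_linkers(native: Structure, site: CPSite, cfg: DesignConfig,
                   backend, predictor: EnsemblePredictor | None = None,
                   scheme: ClassScheme | None = None,
                   propensity: PropensityTable | None = None,
                   linker_length: int | None = None,
                   return_details: bool = False):
    """Run the full design protocol; return candidates ranked by energy.

    ``predictor``/``scheme`` supply the trained amino-acid predictor; when no
    predictor is given the per-position profiles fall back to the propensity
    table.  ``linker_length`` overrides the length estimators (used when the
    length is known, e.g. from a CP-pair alignment).  Deterministic given
    the seed and a deterministic backend.  With ``return_details`` the
    intermediate protocol state (coarse-screen energies, kept model indices,
    the candidate pool) is returned alongside the ranking.
    """
    propensity = propensity or PropensityTable.uniform()
    scheme = scheme or (predictor.scheme if predictor else ClassScheme())
    task = CPModelingTask.from_native(native, site)
    b = termini_distance(task.native)
    if linker_length is not None:
        l = linker_length
    elif b < LENGTH_FIT_MAX_DISTANCE:
        l = estimate_linker_length(b)
    else:
        l = estimate_linker_length_long(native, site, backend, cfg, propensity)
    if l == 0:
        model, energy = _build(backend, task, "")
        direct = [LinkerCandidate("", float(energy), model, (-1, -1))]
        if return_details:
            return direct, {"l": 0, "pool": [], "coarse_energies": [],
                            "kept_ids": []}
        return direct

    # Step 1: temporary linkers → coarse models → keep the t′ best.
    temps = sample_temporary_linkers(l, propensity, cfg.t, seed=cfg.seed)
    coarse = []
    for idx, tmp in enumerate(temps):
        model, energy = _build(backend, task, tmp)
        coarse.append((float(energy), idx, tmp, model))
    coarse.sort(key=lambda c: (c[0], c[1]))
    kept = coarse[:cfg.t_prime]

    # Steps 2–4: per coarse model, per-position amino-acid profile → sample
    # k sequences each → pool of t′·k candidates.
    pool: list[tuple[str, int, int]] = []
    for coarse_id, (_, _, _, model) in enumerate(kept):
        serials = task.linker_serials(l)
        if predictor is not None:
            F = np.array([compute_features(model, p, cfg.d_r).values
                          for p in serials])
            class_probs = predictor.predict_class_probs_batch(F)
            rows = np.array([restore_aa_probs(cp, scheme)
                             for cp in class_probs])
        else:
            rows = np.tile(propensity.array, (l, 1))
        profile = AAProbabilityProfile(rows)
        seqs = sample_candidate_sequences(
            profile, cfg.k, seed=cfg.seed * 1009 + coarse_id)
        pool.extend((seq, coarse_id, sample_id)
                    for sample_id, seq in enumerate(seqs))

    # Steps 5–6: m models per candidate, keep its best; rank the pool.
    candidates = []
    # A deterministic backend returns identical models on every rebuild, so
    # the min over m_models equals a single build.
    m_eff = 1 if getattr(backend, "deterministic", False) else cfg.m_models
    for seq, coarse_id, sample_id in pool:
        best_model, best_energy = None, math.inf
        for _ in range(m_eff):
            model, energy = _build(backend, task, seq)
            if energy < best_energy:
                best_model, best_energy = model, float(energy)
        candidates.append(
            LinkerCandidate(seq, best_energy, best_model,
                            (coarse_id, sample_id)))
    candidates.sort(key=lambda c: (c.energy, c.provenance))
    top = candidates[:cfg.n_report]
    if return_details:
        return top, {
            "l": l,
            "pool": [seq for seq, _, _ in pool],
            # energies indexed by temporary-linker id
            "coarse_energies": [e for _, e in
                                sorted((c[1], c[0]) for c in coarse)],
            "kept_ids": [c[1] for c in kept],
        }
    return top


def ci_config(**overrides) -> DesignConfig:
    """The scaled-down test configuration, optionally tweaked."""
    return replace(CI_CONFIG, **overrides)
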