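"""Deterministic synthetic data: idealised Cα chains, CP pairs with planted
bridging linkers, separable training sets for the amino-acid predictor, and
a scaled-down multi-round independent-test harness.

Real inputs to CP modeling are experimental structures and curated CP-pair
databases; none of that is required to exercise the algorithms.  The
fixtures here are idealised Cα traces with exact 3.8 Å spacing: rings (whose
termini are adjacent, so they satisfy the direct-connection rule for
in-silico permutation), straight strands, helices and hairpins.  CP pairs
are built by actually permuting a ring and threading a known linker across
the junction, so every planted ground truth is recoverable by the analysis
code.  Ring sequences are uniform-random (mutually non-redundant, like the
curated datasets the generator emulates) while each planted linker residue
is drawn from the amino-acid class of its dominant structural neighbour —
so a linker's surroundings genuinely predict its composition, the property
the feature set relies on in real proteins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._aa import AA_ALPHABET, AA_INDEX, CLASS_NAMES, DEFAULT_CLASS_OF_AA
from .cp_transform import CPAlignment, LinkerResult
from .linker_design import (CPModelingTask, DesignConfig, PropensityTable,
                            ci_config, design_linkers)
from .linker_ml import (EXCLUSION_WINDOW, ClassScheme, compute_features,
                        train_ensemble)
from .refine import IDEAL_CA_SPACING, Junction, SurrogateBackend, _arc_points
from .seqalign import global_align, redundancy_identity, similarity_percent
from .structure import Structure, structure_from_ca

#: Class-concentrated linker alphabets: two frequent residues per class,
#: chosen so that any two draws from the same class score positively under
#: BLOSUM45 — mirrors the strong compositional bias of natural CP linkers.
LINKER_ALPHABET = {
    "hydrophilic": "KE",
    "hydrophobic": "LV",
    "neutral": "ST",
}


@dataclass(frozen=True)
class FixtureSpec:
    """Full recipe for one synthetic fixture; (spec, seed) fixes the output."""

    kind: str = "cp_pair"            # helix | strand | ring | two_domain | cp_pair
    length: int = 24
    cp_site: Optional[int] = None
    linker: Optional[str] = None
    linker_length: Optional[int] = None
    context_class: Optional[str] = None
    seed: int = 0


def _default_sequence(n: int) -> str:
    return "".join(AA_ALPHABET[i % 20] for i in range(n))


def make_ideal_chain(n: int, geometry: str = "straight",
                     sequence: str | None = None) -> Structure:
    """An idealised Cα trace with exact 3.8 Å consecutive spacing.

    Geometries: ``straight``/``strand`` (a line), ``helix`` (rise 1.5 Å,
    100°/residue), ``ring`` (closed circle, termini 3.8 Å apart) and
    ``hairpin`` (two antiparallel strands joined by a clash-free turn).
    """
    if n < 2:
        raise ValueError("need at least 2 residues")
    s = IDEAL_CA_SPACING
    if geometry in ("straight", "strand"):
        coords = np.array([[s * i, 0.0, 0.0] for i in range(n)])
    elif geometry == "helix":
        rise, turn = 1.5, np.deg2rad(100.0)
        radius = np.sqrt(s ** 2 - rise ** 2) / (2 * np.sin(turn / 2))
        coords = np.array([[radius * np.cos(turn * i),
                            radius * np.sin(turn * i),
                            rise * i] for i in range(n)])
    elif geometry == "ring":
        step = 2 * np.pi / n
        radius = s / (2 * np.sin(step / 2))
        coords = np.array([[radius * np.cos(step * i),
                            radius * np.sin(step * i), 0.0]
                           for i in range(n)])
    elif geometry in ("hairpin", "two_domain"):
        n1 = n // 2
        coords = np.zeros((n, 3))
        for i in range(n1):
            coords[i] = [s * i, 0.0, 0.0]
        a = s * (n1 - 1)
        # turn residue 3.8 Å from both strand ends (u² + 2.2² + w² = 3.8²)
        turn_pt = np.array([a + np.sqrt(5.6), 2.2, 2.0])
        if n1 < n:
            coords[n1] = turn_pt
        for j in range(n1 + 1, n):
            coords[j] = [a - s * (j - n1 - 1), 4.4, 0.0]
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    return structure_from_ca(sequence or _default_sequence(n), coords)


def _uniform_sequence(n: int, rng: np.random.Generator) -> str:
    return "".join(AA_ALPHABET[i] for i in rng.integers(0, 20, n))


def _environment_classes(model, linker_serials, n_native) -> list[str]:
    """Per linker position, the class of the dominant structural neighbour.

    The dominant neighbour is the native residue (sequence separation > 5,
    within the 20 Å feature radius) with the largest 1/d² contribution —
    i.e. the amino-acid type that tops the position's feature vector.
    """
    coords = model.ca_coords()
    out = []
    for p in linker_serials:
        F = np.zeros(20)
        for j, res in enumerate(model.residues, start=1):
            if j in linker_serials or abs(j - p) <= EXCLUSION_WINDOW:
                continue
            d2 = float(np.sum((coords[j - 1] - coords[p - 1]) ** 2))
            if 0 < d2 <= 400.0:
                F[AA_INDEX[res.one_letter]] += 1.0 / d2
        if F.sum() == 0:
            out.append("neutral")
        else:
            out.append(DEFAULT_CLASS_OF_AA[AA_ALPHABET[int(F.argmax())]])
    return out


def make_cp_pair(spec: FixtureSpec
                 ) -> tuple[Structure, Structure, CPAlignment, LinkerResult]:
    """A CP pair (Q, S) with a planted bridging linker and its ground truth.

    Q is a ring (termini adjacent); S is Q circularly permuted at the CP
    site with the planted linker threaded across the joined native termini.
    Unless an explicit linker is given, each planted linker residue is drawn
    from the class-concentrated alphabet of its structural environment's
    dominant class (``context_class`` overrides that per-position choice).
    The returned correspondence aligns every Q residue, so linker
    determination must recover exactly the planted linker.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.length
    site = spec.cp_site if spec.cp_site is not None else \
        int(rng.integers(2, n))
    q_seq = _uniform_sequence(n, rng)
    Q = make_ideal_chain(n, "ring", q_seq)
    task = CPModelingTask.from_native(Q, site)
    backend = SurrogateBackend()
    if spec.linker is not None:
        linker = spec.linker
    else:
        l = spec.linker_length if spec.linker_length is not None else \
            int(rng.integers(3, 7))
        # thread a placeholder to fix the linker geometry, then assign each
        # position from its environment (or the forced context class)
        draft, _ = backend.build_model(task.modeling_alignment("G" * l),
                                       task.pseudo, "G" * l)
        serials = task.linker_serials(l)
        if spec.context_class is not None:
            classes = [spec.context_class] * l
        else:
            classes = _environment_classes(draft, serials, n)
        linker = "".join(
            LINKER_ALPHABET[c][rng.integers(len(LINKER_ALPHABET[c]))]
            for c in classes)
    S, _ = backend.build_model(task.modeling_alignment(linker),
                               task.pseudo, linker)
    l = len(linker)
    j = n - site + 1                      # length of the permutant's N-part
    pairs = [(q, j + l + q) for q in range(1, site)] + \
            [(q, q - site + 1) for q in range(site, n + 1)]
    aln = CPAlignment(pairs, q_len=n, s_len=n + l)
    if l > 0:
        planted = LinkerResult(True, j, j + l + 1, linker, l, 0, 0)
    else:
        planted = LinkerResult(False, j, j + 1, "", 0, 0, 0)
    return Q, S, aln, planted


def make_two_domain_model(n1: int = 20, n2: int = 14, linker_len: int = 3,
                          seed: int = 0
                          ) -> tuple[Structure, Junction]:
    """A two-domain CPM-like model with a linker joining the domains.

    Domain 1 is a strand along +x; domain 2 is a strand placed at a
    seed-dependent offset and orientation; the linker is arc-threaded
    between them.  Used to exercise the hinge refinement.
    """
    rng = np.random.default_rng(seed)
    s = IDEAL_CA_SPACING
    coords1 = np.array([[s * i, 0.0, 0.0] for i in range(n1)])
    offset = coords1[-1] + np.array([4.0 + 3.0 * rng.random(),
                                     5.0 + 4.0 * rng.random(),
                                     2.0 * rng.random()])
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    coords2 = np.array([offset + direction * s * i for i in range(n2)])
    link = _arc_points(coords1[-1], coords2[0], linker_len)
    coords = np.vstack([coords1, link, coords2])
    n = n1 + linker_len + n2
    seq = _default_sequence(n)
    junction = Junction(linker_span=(n1 + 1, n1 + linker_len)) \
        if linker_len > 0 else Junction(joined_at=n1)
    return structure_from_ca(seq, coords), junction


def make_ml_training_set(n_per_class: int, separation: float, seed: int
                         ) -> list[tuple[np.ndarray, str]]:
    """Three Gaussian clusters in 20-dim feature space, one per class.

    ``separation`` shifts each class mean along its own coordinate axis;
    zero separation gives indistinguishable classes (chance-level
    prediction), large separation makes the classes linearly separable.
    Feature values are clipped at 0 to respect the non-negativity of the
    contact-sum features.
    """
    if n_per_class < 1:
        raise ValueError("need n_per_class ≥ 1")
    rng = np.random.default_rng(seed)
    cases: list[tuple[np.ndarray, str]] = []
    for ci, cname in enumerate(CLASS_NAMES):
        mean = np.full(20, 3.0)
        mean[ci] += separation
        X = rng.normal(loc=mean, scale=1.0, size=(n_per_class, 20))
        cases.extend((np.clip(x, 0.0, None), cname) for x in X)
    order = rng.permutation(len(cases))
    return [cases[i] for i in order]


@dataclass
class LinkerDBEntry:
    """One protein entry of a synthetic linker database."""

    group_id: str
    native: Structure
    site: int
    cpm: Structure                 # permutant carrying the known linker
    linker_serials: list[int]      # serials of the linker on ``cpm``
    linker_seq: str
    alignment: CPAlignment = field(repr=False, default=None)


def make_linker_db(n_entries: int = 30, seed: int = 0,
                   min_len: int = 90, max_len: int = 120
                   ) -> list[LinkerDBEntry]:
    """A grouped synthetic linker database for the independent-test harness.

    Protein sizes default to 90–120 residues: large enough that unrelated
    uniform-random sequences sit clearly below redundancy cutoffs, matching
    the non-redundant curated datasets this emulates.
    """
    rng = np.random.default_rng(seed)
    db = []
    for e in range(n_entries):
        n = int(rng.integers(min_len, max_len + 1))
        spec = FixtureSpec(kind="cp_pair", length=n,
                           seed=int(rng.integers(2 ** 31 - 1)))
        Q, S, aln, planted = make_cp_pair(spec)
        # The CP site is the Q residue aligned to the permutant's residue 1.
        site = next(q for q, s in aln.pairs if s == 1)
        j = n - site + 1
        serials = list(range(j + 1, j + planted.l + 1))
        db.append(LinkerDBEntry(f"entry{e:03d}", Q, site, S, serials,
                                planted.sequence, aln))
    return db


def run_independent_test(linker_db: list[LinkerDBEntry], rounds: int = 10,
                         split: float = 0.9, identity_cutoff: float = 15.0,
                         seed: int = 0, cfg: DesignConfig | None = None,
                         backend=None, n_trees: int = 50,
                         n_nets: int = 10) -> list[dict]:
    """Multi-round grouped train/test evaluation of the design protocol.

    Each round: split the entry groups 90/10, drop test proteins sharing at
    least ``identity_cutoff`` % sequence identity with any training protein,
    train the amino-acid ensemble (and the class compositions and propensity
    table) on the training linkers, then redesign every surviving test
    linker at its known length and record the BLOSUM45 similarity between
    the designed and the known linker plus the backend energy difference
    (designed minus known model).  Returns one record per redesigned linker.
    """
    groups = sorted({e.group_id for e in linker_db})
    if len(groups) < 2:
        raise ValueError("too few groups to split into train/test")
    backend = backend or SurrogateBackend()
    cfg = cfg or ci_config()
    by_group: dict[str, list[LinkerDBEntry]] = {}
    for e in linker_db:
        by_group.setdefault(e.group_id, []).append(e)
    records: list[dict] = []
    for r in range(rounds):
        rng = np.random.default_rng([seed, r])
        order = list(rng.permutation(groups))
        n_test = max(1, int(round((1.0 - split) * len(groups))))
        test_groups, train_groups = order[:n_test], order[n_test:]
        train = [e for g in train_groups for e in by_group[g]]
        test = [e for g in test_groups for e in by_group[g]]
        test = [
            e for e in test
            if all(
                redundancy_identity(e.native.sequence, t.native.sequence)
                < identity_cutoff
                for t in train)
        ]
        train_seqs = [e.linker_seq for e in train if e.linker_seq]
        scheme = ClassScheme.from_linkers(train_seqs)
        propensity = PropensityTable.from_sequences(train_seqs)
        cases = [
            (compute_features(e.cpm, p, cfg.d_r), scheme.class_of[aa])
            for e in train
            for p, aa in zip(e.linker_serials, e.linker_seq)
        ]
        predictor = train_ensemble(cases, scheme,
                                   seed=int(rng.integers(2 ** 31 - 1)),
                                   n_trees=n_trees, n_nets=n_nets)
        for e in test:
            if not e.linker_seq:
                continue
            round_cfg = DesignConfig(t=cfg.t, t_prime=cfg.t_prime, k=cfg.k,
                                     m_models=cfg.m_models,
                                     n_report=cfg.n_report, d_r=cfg.d_r,
                                     seed=int(rng.integers(2 ** 31 - 1)),
                                     backend=cfg.backend)
            cands = design_linkers(e.native, e.site, round_cfg, backend,
                                   predictor=predictor, scheme=scheme,
                                   propensity=propensity,
                                   linker_length=len(e.linker_seq))
            best = cands[0]
            task = CPModelingTask.from_native(e.native, e.site)
            _, e_known = backend.build_model(
                task.modeling_alignment(e.linker_seq), task.pseudo,
                e.linker_seq)
            sim = similarity_percent(
                global_align(best.sequence, e.linker_seq))
            records.append({
                "round": r,
                "group_id": e.group_id,
                "designed": best.sequence,
                "known": e.linker_seq,
                "similarity_percent": sim,
                "energy_designed": best.energy,
                "energy_known": float(e_known),
                "energy_delta": best.energy - float(e_known),
            })
    return records
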