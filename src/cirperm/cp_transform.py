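"""CP-pair linker determination, surface-fragment detection, and in-silico
circular permutant synthesis.

Two naturally related circular permutants Q and S carry, at each other's
junctions, the bridging residues ("termini linkers") that connect the native
termini.  Given a CP-aware residue correspondence between Q and S, the linker
that Q would need is read off S: it is the stretch of S residues between the
last and the first aligned S residues, trimmed by the number of unaligned Q
termini residues.  This module implements that extraction, the relative
solvent accessibility (RSA) computation and exposed-fragment scan used to
pick CP sites on protein surfaces, and the construction of synthetic
("in silico") permutants with a known excised linker — the ground truth used
to train and evaluate the linker designer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from ._aa import MAX_ASA
from .structure import (Structure, StructureError, make_pseudo_cp_template,
                        renumber, termini_distance)

#: PDB-wide average Cα–Cα distance of consecutive residues (Å); native
#: termini within 3·d of each other may be joined without a linker.
CONSECUTIVE_CA_DISTANCE = 3.36

#: RSA threshold (%) above which a residue counts as solvent-exposed.
RSA_EXPOSED_THRESHOLD = 20.0


class NotCPAlignmentError(StructureError):
    """Raised when a correspondence is not two monotone runs."""


@dataclass
class CPAlignment:
    """CP-aware residue correspondence between proteins Q and S.

    ``pairs`` holds (q_serial, s_serial) matches ordered by q.  Because of
    the circular wrap, the s serials may form at most two increasing runs.
    """

    pairs: list[tuple[int, int]]
    q_len: int
    s_len: int

    def __post_init__(self) -> None:
        if not self.pairs:
            raise NotCPAlignmentError("not a CP alignment: empty correspondence")
        qs = [p[0] for p in self.pairs]
        ss = [p[1] for p in self.pairs]
        if any(not 1 <= q <= self.q_len for q in qs) or \
           any(not 1 <= s <= self.s_len for s in ss):
            raise NotCPAlignmentError("not a CP alignment: serial out of bounds")
        if any(b <= a for a, b in zip(qs, qs[1:])):
            raise NotCPAlignmentError(
                "not a CP alignment: q serials not strictly increasing")
        breaks = sum(b <= a for a, b in zip(ss, ss[1:]))
        if breaks > 1:
            raise NotCPAlignmentError(
                "not a CP alignment: s serials form more than two runs")

    def swapped(self) -> "CPAlignment":
        """The same correspondence with the roles of Q and S exchanged."""
        pairs = sorted((s, q) for q, s in self.pairs)
        return CPAlignment(pairs, self.s_len, self.q_len)

    def to_tsv(self) -> str:
        head = f"# q_len={self.q_len}\ts_len={self.s_len}\n"
        return head + "".join(f"{q}\t{s}\n" for q, s in self.pairs)

    @classmethod
    def from_tsv(cls, text: str) -> "CPAlignment":
        q_len = s_len = None
        pairs = []
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                fields = dict(f.split("=") for f in line[1:].split())
                q_len, s_len = int(fields["q_len"]), int(fields["s_len"])
            else:
                q, s = line.split("\t")
                pairs.append((int(q), int(s)))
        if q_len is None or s_len is None:
            raise NotCPAlignmentError("missing q_len/s_len header")
        return cls(pairs, q_len, s_len)


@dataclass
class LinkerResult:
    """Outcome of linker determination for one protein of a CP pair.

    ``s_start``/``s_end`` are the exclusive serial bounds of the extracted
    span on the partner structure S; ``l``, ``m``, ``n`` are the candidate
    linker length and the counts of unaligned N-/C-terminal residues of Q.
    A linker is needed only when ``m + n < l``.
    """

    needed: bool
    s_start: int
    s_end: int
    sequence: str
    l: int
    m: int
    n: int

    def to_json(self) -> str:
        return json.dumps(self.__dict__, sort_keys=True)


@dataclass
class ExposedFragment:
    """A maximal run of consecutive solvent-exposed residues."""

    start: int
    end: int
    rsa_values: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return self.end - self.start + 1


def _forward_span(start: int, stop: int, length: int) -> list[int]:
    """Serials strictly between start and stop, walking forward with wrap."""
    out: list[int] = []
    pos = start % length + 1
    while pos != stop:
        out.append(pos)
        pos = pos % length + 1
        if len(out) > length:  # degenerate guard
            break
    return out


def determine_linker(aln: CPAlignment, seq_s: str) -> LinkerResult:
    """Extract the termini linker protein Q needs, reading it off partner S.

    With x_q/x_s the first aligned pair and y_q/y_s the last, the candidate
    linker is the S residues strictly between y_s and x_s (walking forward in
    S serial order, wrapping past the terminus — CP correspondences are
    circular).  Let l be its length, m and n the unaligned Q residues before
    x_q and after y_q.  If m + n ≥ l the termini can be joined directly;
    otherwise the linker is the span strictly between y_s + n and x_s − m.
    """
    if len(seq_s) != aln.s_len:
        raise ValueError("seq_s length does not match alignment s_len")
    x_q, x_s = aln.pairs[0]
    y_q, y_s = aln.pairs[-1]
    candidate = _forward_span(y_s, x_s, aln.s_len)
    l = len(candidate)
    m = x_q - 1
    n = aln.q_len - y_q
    if m + n >= l:
        return LinkerResult(False, y_s, x_s, "", l, m, n)
    start = (y_s + n - 1) % aln.s_len + 1
    stop = (x_s - m - 1) % aln.s_len + 1
    span = _forward_span(start, stop, aln.s_len)
    seq = "".join(seq_s[i - 1] for i in span)
    return LinkerResult(True, start, stop, seq, l, m, n)


def determine_linkers_pair(aln: CPAlignment, seq_q: str,
                           seq_s: str) -> tuple[LinkerResult, LinkerResult]:
    """Linkers for both members of a CP pair (roles swapped for the second)."""
    return determine_linker(aln, seq_s), determine_linker(aln.swapped(), seq_q)


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


#: Radius (Å) of the per-residue sphere used for Cα-only RSA.  Chosen near
#: the effective radius of an average side-chain-bearing residue.
CA_SPHERE_RADIUS = 3.4
SASA_PROBE_RADIUS = 1.4
SASA_N_POINTS = 92


def _rsa_ca_spheres(coords: np.ndarray) -> np.ndarray:
    """Shrake–Rupley on one probe-expanded sphere per residue.

    Each residue is modelled as a sphere of radius CA_SPHERE_RADIUS around
    its Cα.  RSA is the percentage of test points on the probe-expanded
    sphere not buried inside any other residue's expanded sphere, so an
    isolated residue scores exactly 100.
    """
    r_eff = CA_SPHERE_RADIUS + SASA_PROBE_RADIUS
    pts = _sphere_points(SASA_N_POINTS) * r_eff
    n = len(coords)
    rsa = np.empty(n)
    for i in range(n):
        test = coords[i] + pts
        exposed = np.ones(SASA_N_POINTS, dtype=bool)
        for j in range(n):
            if j == i:
                continue
            d2 = np.sum((test - coords[j]) ** 2, axis=1)
            exposed &= d2 >= r_eff * r_eff
        rsa[i] = 100.0 * exposed.sum() / SASA_N_POINTS
    return rsa


def _rsa_all_atom(s: Structure) -> np.ndarray:
    """All-atom Shrake–Rupley SASA (biotite) normalised by max ASA."""
    import biotite.structure as struc

    n_atoms = sum(len(r.atoms) for r in s.residues)
    arr = struc.AtomArray(n_atoms)
    idx = 0
    for ri, res in enumerate(s.residues, start=1):
        for name, xyz in res.atoms.items():
            arr.coord[idx] = xyz
            arr.chain_id[idx] = "A"
            arr.res_id[idx] = ri
            arr.res_name[idx] = res.name
            arr.atom_name[idx] = name
            arr.element[idx] = name[0]
            idx += 1
    atom_sasa = struc.sasa(arr, probe_radius=SASA_PROBE_RADIUS,
                           point_number=SASA_N_POINTS)
    rsa = np.empty(len(s))
    for ri, res in enumerate(s.residues, start=1):
        total = float(np.nansum(atom_sasa[arr.res_id == ri]))
        rsa[ri - 1] = 100.0 * total / MAX_ASA[res.one_letter]
    return rsa


def compute_rsa(s: Structure) -> np.ndarray:
    """Per-residue relative solvent accessibility (%).

    All-atom structures use Shrake–Rupley SASA normalised by per-amino-acid
    theoretical maximum areas; Cα-only structures use a documented
    sphere-per-residue approximation.
    """
    if len(s) == 0:
        raise StructureError("cannot compute RSA of an empty structure")
    if s.is_ca_only():
        return _rsa_ca_spheres(s.ca_coords())
    return _rsa_all_atom(s)


def exposed_fragments(rsa: np.ndarray,
                      threshold: float = RSA_EXPOSED_THRESHOLD
                      ) -> list[ExposedFragment]:
    """Maximal runs of consecutive residues with RSA above the threshold."""
    frags: list[ExposedFragment] = []
    start = None
    vals = list(map(float, rsa))
    for i, v in enumerate(vals, start=1):
        if v > threshold and start is None:
            start = i
        elif v <= threshold and start is not None:
            frags.append(ExposedFragment(start, i - 1, vals[start - 1:i - 1]))
            start = None
    if start is not None:
        frags.append(ExposedFragment(start, len(vals), vals[start - 1:]))
    return frags


def make_in_silico_cpm(s: Structure, frag: ExposedFragment,
                       d_consecutive: float = CONSECUTIVE_CA_DISTANCE,
                       minimize_hook=None) -> tuple[Structure, str]:
    """Build a synthetic circular permutant with a known missing linker.

    The native termini must be close enough (≤ 3·d_consecutive) to join
    directly.  The CP site is placed at the carboxyl end of the exposed
    fragment (frag.end + 1, wrapping to residue 1 when the fragment touches
    the C-terminus); the chain is reordered accordingly and the fragment
    residues are removed.  Returns the permutant and the excised sequence —
    the known linker the permutant is missing.
    """
    dist = termini_distance(s)
    if dist > 3.0 * d_consecutive:
        raise StructureError(
            f"direct connection not allowed: termini distance {dist:.2f} Å "
            f"exceeds 3·d = {3.0 * d_consecutive:.2f} Å")
    s = renumber(s)
    L = len(s)
    if not (1 <= frag.start <= frag.end <= L):
        raise StructureError("exposed fragment out of bounds")
    site = frag.end + 1 if frag.end < L else 1
    permuted = make_pseudo_cp_template(s, site)
    # Original serials, in permuted order; excise the fragment.
    original_order = list(range(site, L + 1)) + list(range(1, site))
    keep = [pos for pos, orig in enumerate(original_order)
            if not frag.start <= orig <= frag.end]
    linker_seq = s.sequence[frag.start - 1:frag.end]
    out = Structure([permuted.residues[pos].copy() for pos in keep],
                    permuted.chain_id)
    out = renumber(out)
    if minimize_hook is not None:
        out = minimize_hook(out)
    return out, linker_seq


def detect_cp_alignment(seq_q: str, seq_s: str) -> CPAlignment:
    """Sequence-level CP correspondence via alignment against doubled S.

    Convenience approximation to CP-aware structural alignment: Q is
    globally aligned against S·S and matched S positions are mapped back
    modulo len(S).  Works for clear-cut sequence-similar pairs; raises
    NotCPAlignmentError when the result is not two clean monotone runs.
    """
    from .seqalign import global_align

    aln = global_align(seq_q, seq_s + seq_s)
    pairs: list[tuple[int, int]] = []
    seen_s: set[int] = set()
    for iq, js in aln.column_pairs():
        if iq is None or js is None:
            continue
        s_mapped = (js - 1) % len(seq_s) + 1
        if s_mapped in seen_s:
            continue
        seen_s.add(s_mapped)
        pairs.append((iq, s_mapped))
    return CPAlignment(pairs, len(seq_q), len(seq_s))
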