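"""Read the bridging linker off a pair of circular permutants.

When two known structures are circular permutants of each other, the
residues one protein uses to bridge its native termini appear in the other
protein's chain.  Given the CP-aware residue correspondence, the linker is
the span between the last and first aligned partner residues, trimmed by
unaligned termini.  Here the pair is synthetic, so the planted linker is
known and must be recovered exactly.
"""

from cirperm import determine_linkers_pair
from cirperm.fixtures import FixtureSpec, make_cp_pair

Q, S, alignment, planted = make_cp_pair(
    FixtureSpec(length=30, cp_site=11, linker="GSKEG", seed=4))

result_q, result_s = determine_linkers_pair(alignment, Q.sequence, S.sequence)
print(f"planted linker          : {planted.sequence}")
print(f"recovered for Q         : {result_q.sequence!r} "
      f"(l={result_q.l}, m={result_q.m}, n={result_q.n})")
print(f"linker needed for S?    : {result_s.needed} (l={result_s.l})")
# Q needs the planted 5-residue bridge; S (which already carries it) shows
# l=0 in the reverse direction — its termini can be joined directly.
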