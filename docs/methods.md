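# Methods

This note records the models and procedures `cirperm` implements, the
defaults and their rationale, the numerical choices, and what the synthetic
fixtures do and do not establish.

## Pseudo-CP template and coarse modeling

Circular permutation preserves the fold, so the native structure is the
natural modeling template once its residue order is made to match the
permutant.  For CP site *n* (1-based, on the renumbered native chain;
*n* = 1 means no permutation), residues 1..n−1 move to the end of the
record and everything is renumbered from 1.  Insertion codes and author
numbering are deliberately discarded at renumbering — every downstream
index refers to the 1..L serials.  Parsing keeps one conformer per atom
(highest occupancy), maps modified residues with a standard parent (MSE →
MET, etc.), rejects anything else, and requires a Cα per residue: with no
external atom-restoration step in the pipeline, guessing missing alpha
carbons would silently corrupt the geometry downstream.

The coarse model is Cα-only: aligned target residues copy template Cα
coordinates; unaligned interior runs (designed linkers, insertions) are
placed on a circular arc between their flanking anchors, with the arc
radius solved by bisection so that consecutive points sit at the ideal
3.8 Å spacing (points fall back to even spacing on the straight segment
when even a straight path needs > 3.8 Å steps); unaligned termini
extrapolate along the terminal chain direction.  Side-chain placement and
loop modeling beyond this arc construction are out of scope.

## Energy backends

All model scoring goes through a backend object
(`build_model(alignment, template, linker) → (structure, energy)`,
`energy(structure)`); lower is better.  The shipped surrogate is

    E = Σ_i (d(Cα_i, Cα_i+1) − 3.8)²  +  10 · #{(i, j): |i−j| ≥ 3, d_ij < 4 Å}

— a harmonic restraint on consecutive Cα spacing plus a hard-sphere clash
count.  It is deterministic, rigid-motion invariant, and zero exactly for
an ideally spaced clash-free trace, which makes protocol logic (screening,
ranking, refinement) testable against closed-form expectations.  It is not
a statistical potential: it knows nothing about sequence, so candidate
linkers of equal length tie in energy and rank by provenance.  An external
statistical potential or force field can be plugged in through the same
contract; the weight 10 per clash simply dominates any realistic bond
strain so that clash removal is always preferred.

## Hinge refinement

The CPM model is divided at the junction where the native termini meet:
the Cα of linker residue ⌈l/2⌉ when a linker of length l ≥ 1 is present,
else the midpoint of the two joined termini Cαs.  The two native-protein
proportions are compared by residue count and the smaller one moves (ties
take the C-terminal proportion).  Axis *r* is the unit vector from the
hinge to the small proportion's Cα centroid; plane *P* passes through the
hinge and both centroids.  "Rotating on plane P" is implemented as
rotation about P's normal through the hinge.  The grid is θ ∈ {0°, 20°, …,
160°} (9 in-plane pauses covering 180° without the duplicate endpoint) ×
φ ∈ {0°, 20°, …, 340°} (18 axial snapshots covering 360°) = 162 poses,
applied as φ∘θ in the fixed initial frame; pose (0°, 0°) is the exact
identity (the input model is reused bit-for-bit, so refined energy can
never exceed the input energy).  Energy ties resolve to the
lexicographically smallest (θ, φ).  Degenerate geometry (collinear hinge
and centroids) falls back to the unit normal perpendicular to *r* with the
largest global-z component, tie-broken toward +x — deterministic and
exercised in tests.  The pseudo-bond across the hinge is allowed to
stretch; the energy function penalises it naturally, and no MD relaxation
step is included.

Centers of mass are unweighted Cα centroids, keeping the module consistent
with the Cα-only geometry used everywhere else.

## Sequence alignment and metrics

Global affine-gap alignment (gap of length k costs open + k·extend) is
provided under two penalty presets — the package default 10/0.5 and a
Stretcher-style 12/2 — both over BLOSUM62; end gaps are penalised like
internal gaps.  The multi-aligner rule selects the candidate with the most
aligned columns, ties broken by score then first occurrence.  When 3-state
secondary-structure labels are supplied for both sequences, +1 per
label-matching aligned column is added to candidate scores before
selection — a lightweight stand-in for structure-aware alignment.

Identity is identical columns over alignment length; similarity is columns
with a positive BLOSUM45 pair score over alignment length (gap columns are
never similar).  The alignment-length denominator is a documented choice;
with the shorter-sequence denominator both metrics would only grow.

**Redundancy identity.**  Dataset redundancy cutoffs in the 15–25% range
presume a conservative identity metric under which unrelated proteins
score ~5–10%.  Under permissive affine penalties, however, optimal global
alignments of *unrelated* sequences stabilise near 14% identity regardless
of length — at which point a 15% cutoff is a coin flip on noise.  The
filter primitive therefore computes identity under stiff gap penalties
(open 25, extend 2), restoring the unrelated baseline to ~5–10% while
genuinely homologous pairs still score far above any cutoff.

## Linker determination for CP pairs

Given the correspondence (q, s) pairs — strictly increasing in q, at most
two increasing runs in s — the candidate linker for Q is the S span
strictly between y_s and x_s, walked forward in S serial order *with
wrap-around* past the terminus: CP correspondences are circular, and the
wrap is the only reading that always yields the bridging region (the
flat reading would return the entire aligned body of the protein whenever
the span crosses the terminus).  With m and n the unaligned N-/C-terminal
residues of Q: if m + n ≥ l no linker is needed; otherwise the span is
trimmed to strictly between y_s + n and x_s − m.  A convenience detector
builds a sequence-level correspondence by aligning Q against the doubled
sequence of S; it is an approximation to CP-aware structural alignment and
is validated, not trusted.

## RSA and in-silico permutants

Relative solvent accessibility uses Shrake–Rupley sampling with a 1.4 Å
probe and 92 sphere points.  All-atom structures go through biotite's SASA
normalised by per-residue theoretical maximum areas; Cα-only structures
(every fixture) use a sphere-per-residue approximation — one 3.4 Å sphere
per Cα, RSA = percentage of unoccluded probe-expanded sphere points — so
an isolated residue reads exactly 100%.  Exposed fragments are maximal
runs with RSA > 20%.

An in-silico permutant requires native termini within 3·d of each other
(d = 3.36 Å, the shipped average consecutive-Cα distance; configurable,
not recomputed, since recomputing it would need a full PDB snapshot).  The
CP site goes to the carboxyl end of a chosen exposed fragment (wrapping to
residue 1 at the C-terminus), the chain is reordered, and the fragment is
excised — its sequence is the known missing linker.

## Linker length estimation

For termini distance b < 20 Å: l = Round(21.8·ln b − 52.5), clamped at 0,
rounding half-away-from-zero (the fit's own convention is unspecified;
this is the common scientific reading of "Round").  b = 20 Å is routed to
the iterative estimator, matching the fit's stated "< 20 Å" domain.  The
iterative estimator scans l ∈ {20, 25, …, ⌊L/5⌋} (just {20} for proteins
under 100 residues), keeps per l the minimum energy over t temporary
linkers, then rescans l_best ± 4; ties go to the smallest scanned length,
so a flat energy landscape returns the shortest linker — the conservative
engineering choice.

## The amino-acid predictor

Features: for residue i, F_A(i) = Σ 1/d_ia² over residues a of type A with
Cα within 20 Å, excluding sequence neighbours i±1..i±5 — applied
identically to training linkers and design targets, because at design time
a linker's own sequence neighbourhood is unknown.  Features are stored as
plain 20-vectors in alphabetical one-letter order.

Classes: the 3-class partition is hydropathy-guided — hydrophobic
{A,V,L,I,M,F,C,W}, hydrophilic {R,K,D,E,N,Q,H}, neutral {G,P,S,T,Y} — and
configurable; it is a default, not a reconstruction of any reference
partition.  Within-class compositions p(A|C) are estimated from the
training linkers with Laplace smoothing of 1 (no amino acid gets exactly
zero restored probability).

Ensemble: 250 decision-tree minors (depth ≤ 8) and 50 one-hidden-layer
(16-unit) MLP minors, each fit on an independent same-size bootstrap
resample; the MLPs run a capped iteration budget (300 iterations,
tol 1e-3) rather than validation-split early stopping, which is unstable
on bootstrap resamples where a class may have a single member.  Prediction
is one vote per minor; class probabilities are vote proportions, restored
to amino acids by pe(A) = pe(C)·p(A|C).  Everything is seeded; per-minor
seeds derive from one generator, so training is deterministic.

## The design protocol

Defaults are the study conditions: t = 200 temporary linkers, t′ = 20 kept
coarse models, k = 10 sampled sequences per coarse model, m = 10 models
per candidate, 30 reported candidates, feature radius 20 Å.  The candidate
pool is exactly t′·k sequences.  With a deterministic backend the m
rebuilds are identical, so a single build is used — the minimum over m is
unchanged.  Energy ties rank by provenance (coarse-model id, then sample
id), making the full protocol bit-reproducible given the seed.  When no
trained predictor is supplied, per-position profiles fall back to the
propensity table (uniform unless estimated from supplied linkers).
Zero estimated length returns a single "direct connection" candidate with
an empty sequence.

## Synthetic fixtures: what they emulate, and what passing does not show

Idealised chains (straight, helical, ring, hairpin) have exact 3.8 Å
consecutive spacing; rings put the termini 3.8 Å apart, satisfying the
direct-connection rule, and helices/hairpins are clash-free by parameter
choice.  CP pairs are built by actually permuting a ring and threading a
planted linker across the junction, so the determination algorithm must
recover the planted ground truth exactly.

Fixture sequences are uniform-random: mutually non-redundant, like the
curated datasets the generator stands in for.  Each planted linker residue
is drawn from a two-letter, class-concentrated alphabet (K/E hydrophilic,
L/V hydrophobic, S/T neutral — pairs chosen to score positively under
BLOSUM45 within a class) of the class of its *structural environment's*
dominant neighbour (largest 1/d² contribution among native residues
outside the ±5 window).  This plants, by construction, the correlation the
feature set exploits in real proteins — linker composition follows local
environment.  Consequently, fixture results demonstrate that the pipeline
*recovers a planted signal of this form*; they do not measure accuracy on
real CP linkers, whose environment–composition coupling is weaker and
noisier.  Likewise the surrogate energy makes "designed energy ≤ known
energy" an equality for equal-length linkers, so that harness statistic
validates protocol plumbing, not thermodynamics.

The independent-test harness groups entries (one protein per group),
splits groups 90/10 per round, discards test proteins at ≥ 15% redundancy
identity to any training protein, trains the ensemble + compositions +
propensities on the training linkers only, and redesigns each surviving
test linker at its known length (the length is observable from the CP-pair
alignment, so length estimation is evaluated separately).  Scaled problem
sizes used by the test suite and examples: databases of 15–30 entries of
90–120-residue proteins, 2–10 rounds, design config t = 20, t′ = 5,
k = 3, m = 2, ensembles of 50 trees + 10 nets — chosen as the smallest
sizes at which every code path (grouping, filtering, training, design,
reporting) is exercised with stable statistics; the full-scale defaults
remain available through the configuration objects.

## Known limitations

- Cα-only geometry throughout; no side chains, no physics-based energies,
  no MD post-optimisation (an external backend/hook is the intended route).
- Sequence-level identities and similarities, not structure-alignment
  metrics; the redundancy metric above mitigates but does not remove the
  difference.
- The in-plane rotation convention (θ measured from the initial pose over
  [0°, 180°)) is one of the two defensible readings of a 9-pause 180°
  sweep; only the pose count is fixed by construction.
- The CP-aware correspondence detector is sequence-based and fails on
  low-identity pairs where only structural alignment would succeed.
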