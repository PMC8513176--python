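"""Model a circular permutant from its native structure.

Builds a small idealised native structure (a closed Cα ring, so its termini
are adjacent), declares a CP site mid-chain, and runs the primary modeling
pipeline: pseudo-CP template construction, coarse modeling, and the
162-snapshot CP-site hinge refinement.  The permutant's new termini sit
where the native chain was cut, so the coarse model starts with one steric
clash there; the hinge search may keep the closed template pose or swing
the smaller proportion into a strain-free open pose, whichever the energy
function prefers.
"""

from cirperm import (evaluate_model, make_pseudo_cp_template, run_mode1,
                     surrogate_energy)
from cirperm.fixtures import make_ideal_chain

native = make_ideal_chain(24, "ring")
report, model = run_mode1(native, cp_site=9, seed=0)
template = make_pseudo_cp_template(native, 9)

print(f"template length       : {report.template_length} residues")
print(f"aligned columns       : {report.aligned_columns} "
      f"({report.identity_percent:.1f} % identity)")
print(f"coarse-model energy   : {surrogate_energy(template):.3f}")
print(f"snapshots evaluated   : {report.refinement['n_snapshots']}")
print(f"best pose (θ, φ)      : {tuple(report.refinement['best_pose'])}")
print(f"refined energy        : {report.refinement['best_energy']:.3f}")

metrics = evaluate_model(model, template)
print(f"RMSD vs closed pose   : {metrics['rmsd']:.2f} Å over "
      f"{metrics['n_aligned']} residues")
# Here the Cα surrogate trades the termini clash (penalty 10) for an open
# domain orientation (energy ~0), so the refined model departs from the
# closed template: the hinge search explores exactly this kind of
# domain-orientation alternative.  A colinear run (cp_site=1) skips the
# hinge and reproduces the native structure with RMSD 0.
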