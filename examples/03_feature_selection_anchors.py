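"""Iterative tICA feature selection and anchor-residue discovery.

Alternates tICA fitting with elimination of features that correlate
poorly with the two leading tICs, shrinking the unbiased all-pairs set to
a compact kinetically relevant one.  Residues recurring among the
survivors are the "anchors" of the slow motions.
"""

import loopmsm as lm
from loopmsm.selection import SelectionConfig, iterative_tica_selection

syn = lm.gen_toy_loop_trajectory(n_traj=4, n_frames=5000, seed=3)
defs = lm.enumerate_ca_pairs(syn.ensemble.topology)
fm = lm.compute_features(syn.ensemble, defs)
kept, _ = lm.prune_features(fm)

cfg = SelectionConfig(lag=5, n_tics_considered=2, target_n_features=10)
res = iterative_tica_selection(kept, cfg)

print(f"start: {kept.n_features} features, end: {len(res.selected)} "
      f"({len(res.log)} iterations, status={res.status})")
print("selected pairs:", res.labels)
print("anchor table (residue: pair count):", res.anchor_table)
print("planted loops: slow", syn.kinetics.slow_loop_residues,
      "fast", syn.kinetics.fast_loop_residues)
# -> every selected pair involves at least one planted loop residue; the
#    top anchors fall inside the planted blocks, recovering the loops
#    without any prior knowledge of where they are.
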