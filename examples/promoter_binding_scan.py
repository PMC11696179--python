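"""Scan promoter binding versus oligomeric state of the CO-NF-Y complex.

Runs the reduced coarse-grained simulator for oligomer states 1-5 (three
seeds each, desk-scale box) and reports the mean number of bound units per
promoter fragment, its rank correlation with the oligomeric state, and the
zero-affinity control against the analytic random-contact expectation.
"""

from cophase import dnasim

table, summary = dnasim.scan_oligomer_states(
    states=(1, 2, 3, 4, 5), seeds=(0, 1, 2), n_steps=400_000, progress=True
)
print("\nmean bound units per chain by oligomer state:")
for s in sorted(summary["per_state_mean"]):
    print(f"  s={s}: {summary['per_state_mean'][s]:.3f} +/- {summary['per_state_sd'][s]:.3f}")
print(f"Spearman rank correlation (state vs mean bound): {summary['spearman_rho']:.2f}")

system = dnasim.build_system(1, well_depth=0.0, nonspecific_depth=0.0, seed=0)
traj = dnasim.run_dynamics(system, n_steps=150_000, seed=5)
null = dnasim.bound_distribution(traj)
expect = dnasim.random_contact_expectation(system.n_units, system.dna_pos.shape[1], system.box_length)
print(f"binding-off control: observed {null['mean']:.4f} vs analytic {expect['mean_per_chain']:.4f}")
# A monotone increase of bound units with oligomeric state is the avidity
# signature: larger complexes bind the multi-motif fragment more effectively
# at the same per-unit affinity.
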