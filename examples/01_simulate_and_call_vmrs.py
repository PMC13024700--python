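"""Simulate an RRBS-like methylome and call VMRs by the ranked-variance knee.

Builds a 2,000-window two-group methylome (8 + 8 individuals), filters
low/extreme coverage, computes inter-individual variance in the young
group, locates the knee of the ranked variance curve, and compares the
called VMR set against the generator's ground-truth labels.
"""

from vmrkit import (
    call_vmrs,
    filter_coverage,
    generate_truth,
    simulate_counts,
    variance_threshold,
    window_variance,
)

truth = generate_truth(n_windows=2000, frac_vmr=0.1, seed=0, dispersion_contrast=5.0)
sim = simulate_counts(truth, n_per_group=8, seed=1000)
matrix = filter_coverage(sim.to_matrix(), min_cov=10)

profile = window_variance(matrix, "young")
tau = variance_threshold(profile)
vmr, non_vmr = call_vmrs(profile)

true_set = set(truth.loc[truth.is_vmr, "window_id"])
called = set(vmr)
tp = len(called & true_set)

print(f"windows after coverage filter : {matrix.n_windows}")
print(f"variance threshold (knee)     : {tau:.5f} at rank {profile.threshold_rank}")
print(f"VMRs called / labelled        : {len(called)} / {len(true_set)}")
print(f"precision / recall vs truth   : {tp / len(called):.3f} / {tp / len(true_set):.3f}")
# The knee separates the high-variance tail; precision and recall near 1
# mean the ranked-variance cut recovers the windows that were generated
# with 5x inflated beta-binomial dispersion.
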