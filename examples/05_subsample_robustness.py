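"""How stable is a differentiation call to sample-size imbalance?

Repeatedly subsamples the larger of two populations at reduced sizes,
recomputes the pairwise fixation index and its permutation p each time,
and reports the likelihood of contradicting the full-sample call.
Settings are scaled down from the reference analysis (10,000 replicates x
20,000 permutations) to stay interactive.
"""

from hapstruct import ResampleConfig, identity_matrix, subsample_robustness
from hapstruct.synthetic import spinner_count_table

ct = spinner_count_table().subset(["NSW", "South Africa"])
cfg = ResampleConfig(
    focal_pop="NSW", other_pop="South Africa",
    subsample_sizes=(150, 100, 60), n_reps=300, n_perm_per_rep=2000, seed=1,
)
rep = subsample_robustness(ct, identity_matrix(ct.haplotypes), cfg)
print(f"original F_ST = {rep.original_stat:.5f}, p = {rep.original_p:.4f} "
      f"({'significant' if rep.original_significant else 'not significant'} "
      f"at alpha {cfg.alpha})")
print(rep.to_frame().to_string(index=False))

# Interpretation: contradiction_likelihood is the fraction of subsample
# replicates whose significance call flips relative to the full-sample
# analysis; a value near 0 at every size means the call does not hinge on
# the sampling imbalance.
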