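"""Motif-level conservation in multiple alignments.

Simulates orthologous loci in four species where one planted Sox-core
motif evolves under constraint (10% of the neutral substitution rate) and
one shuffled-control motif evolves neutrally, scans the true alignments
with each matrix, and compares per-motif nucleotide conservation rates.
"""

from soxcomp import pipeline

res = pipeline.motif_conservation_study(seed=21, n_loci=400)

print(f"constrained Sox motifs: n={res['n_real']}, "
      f"mean nucleotide conservation {100 * res['mean_rate_real']:.1f}%")
print(f"shuffled-control motifs: n={res['n_control']}, "
      f"mean nucleotide conservation {100 * res['mean_rate_control']:.1f}%")
print(f"two-sided rank-sum p = {res['rank_sum_p']:.2e}")
# Motifs under selective constraint retain near-identical bases across all
# species while shuffled controls decay at the neutral rate; the rank-sum
# test quantifies that contrast over matched alignment scans.
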