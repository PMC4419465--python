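"""Call TF binding intervals from DamID fragment counts.

Simulates a single 300-kb genome with 60 planted binding sites, draws 3
fusion + 3 Dam-only replicate read sets, tests every GATC fragment for
enrichment and merges significant fragments into binding intervals.
"""

import numpy as np

from soxcomp import enrichment, pipeline, simulate
from soxcomp.gatc_quant import assemble_count_table, build_gatc_fragment_map

pwm = pipeline.sox_consensus_pwm()
dataset = simulate.simulate_genomes(pipeline.single_species_phylogeny(),
                                    length=300_000, n_genes=33, seed=7)
simulate.plant_sites(dataset, pwm, n_sites=60, class_mix={"conserved": 1.0},
                     factor_mix={"common": 1.0}, seed=8)
simulate.simulate_damid_reads(dataset, depth=60_000, seed=9)

frag_map = build_gatc_fragment_map(dataset.genomes["mel"])
table = assemble_count_table(frag_map, dataset.samples["Dichaete"])
result = enrichment.test_enrichment(table)
calls = enrichment.call_binding_intervals(result, frag_map, threshold=0.05,
                                          merge_gap=100)

print(f"{frag_map.n_fragments} GATC fragments "
      f"(mean {np.mean(frag_map.fragment_lengths()):.0f} bp)")
print(f"{int(result.tested.sum())} fragments tested, "
      f"{int((result.padj[result.tested] < 0.05).sum())} enriched at "
      "adjusted p < 0.05")
print(f"{len(calls)} binding intervals after merging gaps <= 100 bp")
for iv in list(calls)[:5]:
    print(f"  {iv.chrom}:{iv.start}-{iv.end}  "
          f"log2FC={iv.max_log2fc:.2f}  padj={iv.min_padj:.2e}")

rec = pipeline.evaluate_recovery(dataset, "Dichaete", "mel", calls)
print(f"recovered {rec['n_recovered']}/{rec['n_sites']} planted sites "
      f"({100 * rec['recovery']:.1f}%), "
      f"empirical FDR {100 * rec['fdr']:.1f}%")
# A high recovery with near-zero FDR means the NB enrichment test finds the
# planted binding sites without calling unenriched background fragments.
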