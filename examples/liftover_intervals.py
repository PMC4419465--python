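"""Translate intervals between genomes through an alignment chain.

Builds a two-block chain (an aligned region interrupted by a 30-bp
deletion on the target side) and translates intervals with the minMatch
filter, mirroring region-level liftover behaviour.
"""

import numpy as np

from soxcomp.crossmap import translate_interval
from soxcomp.io_core import Chain, ChainMap, GenomicInterval

# source [0,150) -> target [0,150); source [180,300) -> target [150,270)
chains = ChainMap([Chain(chain_id=1, score=100.0,
                         src_chrom="chr2L", src_size=1000,
                         tgt_chrom="chr2L", tgt_size=1000, orientation="+",
                         src_starts=np.array([0, 180]),
                         tgt_starts=np.array([0, 150]),
                         sizes=np.array([150, 120]))])

for start, end in ((10, 20), (100, 200), (150, 180), (140, 240)):
    entry = translate_interval(GenomicInterval("chr2L", start, end),
                               chains, min_match=0.7)
    target = (f"{entry.target.chrom}:{entry.target.start}-{entry.target.end}"
              if entry.target else "-")
    print(f"[{start},{end})  status={entry.status:15s} "
          f"fraction={entry.mapped_fraction:.2f}  target={target}")
# An interval maps only when >= 70% of its bases fall inside ungapped
# alignment blocks of exactly one chain; [150,180) sits entirely in the
# alignment gap, and [100,200) maps at exactly the 0.70 threshold.
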