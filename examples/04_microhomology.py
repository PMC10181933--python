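"""Microhomology at circle junctions.

Cuts the two 100-bp windows around a circle's start and end (50 bp
inside + 50 bp outside) and scans them with the exact ungapped
local-alignment recursion (match +1 / mismatch -2); significance is
length >= 4 and Karlin-Altschul E < 1.  A 12-bp homology planted across
the junction windows is recovered; an unrelated circle is usually not
significant -- though E < 1 is permissive (a shared ~7-mer suffices).
"""

import numpy as np

from circlescope import sim
from circlescope.io_core import GenomicInterval
from circlescope.junctions import extract_junction_windows, score_microhomology

cfg = sim.SimConfig(chrom_sizes={"chr1": 100_000, "chrM": 16_569}, seed=3)
genome = sim.make_genome(cfg)

# plant a 12-bp repeat at both junction flanks of circle [20000, 50000)
seq = list(genome["chr1"])
motif = "ACGTTGCAGGAT"
seq[20_000 - 6 : 20_000 + 6] = motif
seq[50_000 - 6 : 50_000 + 6] = motif
genome["chr1"] = "".join(seq)

circles = [
    GenomicInterval("chr1", 20_000, 50_000, "planted"),
    GenomicInterval("chr1", 60_000, 75_000, "random"),
]
windows, skipped = extract_junction_windows(circles, genome)
for w in windows:
    hit = score_microhomology(w)
    print(f"{w.circle_id:<8} length={hit.length:>3} score={hit.score:>3} "
          f"E={hit.expect:.3g} {hit.orientation} significant={hit.significant}")
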