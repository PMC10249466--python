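"""Compositional handling of a 16S count table.

Counts are closed to relative abundances, the dominant taxa are kept with a
pooled Remainder bucket, and the table is mapped to additive log-ratio (ALR)
coordinates against the Remainder — the representation every downstream
regression and distance computation uses.
"""

import numpy as np
import pandas as pd

from tmrnet import VariableGroup, alr_transform, select_top_taxa, to_relative_abundance

counts = pd.DataFrame(
    [[620, 310, 40, 20, 10], [550, 280, 90, 60, 20], [700, 150, 80, 50, 20]],
    index=["m1", "m2", "m3"],
    columns=["Akkermansia", "Lachnospiraceae", "Romboutsia", "Bacteroides", "Dubosiella"],
)
taxa = VariableGroup("16S_DNA", "measured", counts, {"compositional": True})

rel = to_relative_abundance(taxa)
print("relative abundances (rows sum to 1):")
print(rel.data.round(3))

top = select_top_taxa(rel, n=3)
print("\ntop-3 taxa plus pooled Remainder (row sums preserved):")
print(top.data.round(3))

alr = alr_transform(top, pseudocount=1e-6)
print(f"\nALR coordinates (reference = {alr.meta['alr_reference']}, natural log):")
print(alr.data.round(3))
print("each value is ln(taxon abundance / reference abundance) for that mouse")
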