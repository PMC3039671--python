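"""Scan promoter-enriched motifs in candidate regions.

Builds a synthetic 1 kb "promoter" sequence seeded with CCAAT and GC-box
motifs and an equally long neutral sequence, then reports per-motif hit
densities (hits per kb, both orientations) — the comparison used to ask
whether a region class looks like promoters.
"""

import numpy as np

from broadcall import GenomicInterval, Pwm, motif_density

rng = np.random.default_rng(4)
bases = np.array(list("ACGT"))

promoter = list(rng.choice(bases, size=1000))
for offset in (100, 400, 700):
    promoter[offset : offset + 5] = "CCAAT"
for offset in (250, 850):
    promoter[offset : offset + 8] = "GGGGCGGG"
neutral = rng.choice(bases, size=1000)

pwms = [
    Pwm.from_consensus("CAAT", "CCAAT", threshold_fraction=0.95),
    Pwm.from_consensus("GC-box", "GGGGCGGG", threshold_fraction=0.9),
]
for name, seq in (("promoter-like", promoter), ("neutral", neutral)):
    region = GenomicInterval("chr19", 0, 1000)
    densities = motif_density([(region, "".join(seq))], pwms)
    text = ", ".join(f"{k}: {v:.1f}/kb" for k, v in densities.items())
    print(f"{name:>14}: {text}")
# Planted motifs dominate the promoter-like sequence; the neutral sequence
# shows only chance hits (short degenerate motifs like CCAAT appear ~1/kb
# by chance, which is why the published analysis compares densities between
# region classes rather than testing presence).
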