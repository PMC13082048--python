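"""Classify paired 5'/3' RNA reads from a convergent two-promoter template.

Simulates reads from a template whose forward unit encodes a hairpin
that piles up 3' ends at its boundary, classifies each pair by summed
local-alignment score, applies the end-separation and start-site
filters, and profiles transcript lengths.
"""

import numpy as np

from rnapcollide import classify_pair, compare_length_distributions, length_profiles
from rnapcollide.synthetic import make_template, simulate_reads

template = make_template(seed=5, length=150, hairpin=True, hairpin_start=60)
reads, truth = simulate_reads(
    template, n=150,
    end_model={"kind": "hairpin", "fraction": 0.8, "min_len": 30, "max_len": 80},
    error_rate=0.01, seed=5,
)

classified = [classify_pair(five, three, template, read_id=rid)
              for rid, five, three in reads]
mapped = [r for r in classified if r.mapped]
agreement = np.mean([
    r.orientation == t for r, t in zip(classified, truth["orientation"])
    if r.mapped
])

profiles = length_profiles(classified, template)
fwd = profiles["lengths"]["forward"]
rev = profiles["lengths"]["reverse"]
print(f"reads mapped          : {len(mapped)}/{len(classified)}")
print(f"orientation agreement : {100 * agreement:.1f}% of mapped reads")
print(f"forward lengths       : n={len(fwd)}, median {np.median(fwd):.0f} nt")
print(f"reverse lengths       : n={len(rev)}, median {np.median(rev):.0f} nt")
print(f"hairpin drop statistic: {profiles['hairpin_drop']:.1f}")

t, p = compare_length_distributions(fwd, rev)
print(f"forward vs reverse length Welch t = {t:+.2f}, p = {p:.3f}")
print()
print("A drop statistic far above 1 means transcripts terminate at the")
print("hairpin boundary -- the signature of hairpin-positioned collisions.")
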