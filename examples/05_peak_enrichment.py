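"""SSR content of differential chromatin-accessibility peaks.

Peaks that respond to an environmental contrast (e.g. a salinity shift)
carry more SSR sequence than ordinary peaks, and the SSR content rises
with the differential-test significance.  The generator plants exactly
that structure; the stratified analysis recovers it with a bootstrap
trend test.
"""

import numpy as np

from ssrscape import (find_ssrs_genome, simulate_genome, simulate_peaks,
                      stratified_enrichment)
from ssrscape.benchmarks import scaled_config
from ssrscape.peaks import intervals_from_records
from ssrscape.simulate import PeakSpec

cfg = scaled_config(seed=15, genome_length=2_000_000)
sequences, _ = simulate_genome(cfg)
records = find_ssrs_genome(sequences)
rng = np.random.default_rng(15)

all_peaks, diff_peaks, _ = simulate_peaks(
    cfg.genome_length, [(r.start, r.end) for r in records],
    PeakSpec(n_all=2000, n_diff=600), rng=rng)

res = stratified_enrichment(all_peaks, diff_peaks,
                            intervals_from_records(records), rng=rng)
table = res["table"].copy()
table["content_%"] = (100 * table["content"]).round(2)
print(table[["stratum", "n_peaks", "content_%"]].to_string(index=False))
print(f"\nbootstrap trend p = {res['trend_p']:.4g} "
      f"(slope {res['trend_slope']:.4g})")
print("content climbs monotonically with differential significance: "
      "the most responsive regulatory regions are the most SSR-laden")
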