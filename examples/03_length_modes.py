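"""Short/long SSR length modes.

Dinucleotide SSR length distributions in shrimp genomes are bimodal: a
slippage-scale short population and an expansion-scale long one.  The
mode caller runs a KDE on log10(length) and places the short/long
threshold at the valley between the two peaks; the published manual
cuts (long (AT)n > 65 bp, long (AAT)n > 35 bp) are available as the
preset "paper-2021".
"""

from ssrscape import detect_modes, find_ssrs_genome, simulate_genome
from ssrscape.benchmarks import scaled_config
from ssrscape.modes import PRESETS, classify_short_long

cfg = scaled_config(seed=13, genome_length=2_000_000)
sequences, _ = simulate_genome(cfg)
records = find_ssrs_genome(sequences)

for motif in ("AT", "AAT"):
    lengths = [r.length for r in records if r.motif == motif]
    rep = detect_modes(lengths, motif=motif)
    print(f"({motif})n: n={rep.n}, modes={rep.n_modes}, "
          f"positions={[round(m, 1) for m in rep.mode_positions]} bp, "
          f"valley={None if rep.valley_threshold is None else round(rep.valley_threshold, 1)}")

threshold = PRESETS["paper-2021"]["AT"]
at_records = [r for r in records if r.motif == "AT"]
labels = classify_short_long(at_records, threshold)
n_long = (labels["label"] == "long").sum()
print(f"\nwith the preset cut (> {threshold:.0f} bp): "
      f"{n_long} long and {len(labels) - n_long} short (AT)n records")
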