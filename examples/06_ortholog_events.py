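"""SSR events between orthologous genes of two sister genomes.

Two descendant genomes diverge from one ancestor: lineage A doubles its
(AT)n lengths, lineage B gains extra (AAT)n copies and new intron SSR
insertions.  SSRs are matched between ortholog pairs by (feature type,
ordinal, motif class) — "the (AG)n in intron 5" — and classified as
conserved, elongated/contracted, or inserted on one side.
"""

from ssrscape import (compare_profiles, event_summary, find_ssrs_genome,
                      map_ssrs_to_features, match_ortholog_ssrs, profile,
                      simulate_species_pair)
from ssrscape.benchmarks import scaled_config

cfg = scaled_config(seed=16, genome_length=1_000_000)
res = simulate_species_pair(cfg)

records_a = find_ssrs_genome(res["sequences_a"])
records_b = find_ssrs_genome(res["sequences_b"])
len_a = res["truth_a"].genome_length
len_b = res["truth_b"].genome_length

table = compare_profiles(profile(records_a, len_a, "lineage_a"),
                         profile(records_b, len_b, "lineage_b")).table
print("genome-level species differences:")
print(table.loc[["AT", "AAT"],
                ["log2_density_ratio", "log2_length_ratio",
                 "padj"]].round(3))

inv_a = map_ssrs_to_features(records_a, res["truth_a"].genes)
inv_b = map_ssrs_to_features(records_b, res["truth_b"].genes)
print(f"\ngenes with SSRs: {inv_a['fraction_with_ssr']:.1%} (A), "
      f"{inv_b['fraction_with_ssr']:.1%} (B)")

events, skipped = match_ortholog_ssrs(inv_a, inv_b,
                                      res["ortholog_pairs"])
summ = event_summary(events)
print("\northolog SSR events:")
print(summ["by_event"].to_string())
if summ["extreme"]:
    e = summ["extreme"][0]
    print(f"\nmost extreme repeat-number change: ({e.motif})n in "
          f"{e.feature_type} {e.ordinal} of {e.pair_id}: "
          f"{e.repeats_a:.0f} vs {e.repeats_b:.0f} repeats "
          f"({e.elongation_ratio:.1f}-fold)")
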