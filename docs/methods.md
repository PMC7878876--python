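# Methods

## SSR detection

An SSR class is identified by its canonical motif: the
lexicographically smallest string among all rotations of the motif and
of its reverse complement, so that (TA)n, (AT)n and both strands of
either collapse to one class, (AT)n. Motifs that are themselves tandem
repetitions of a shorter unit (e.g. ATAT) are rejected as reducible;
their repeats are reported at the fundamental period.

**Perfect mode** (the default) finds, for each period p = 1..6, the
maximal runs of positions satisfying `seq[i] == seq[i−p]` with no
ambiguous base (N) anywhere in the run, keeps runs whose leading motif
is primitive and whose total length reaches the per-period minimum
(12 bp for periods 1–3, then 16/20/24 bp), and resolves overlapping
candidates of different classes deterministically: longest wins, ties
to the lower period, then to the leftmost start. Repeat counts are
real-valued (length/period), so a trailing partial motif is counted
fractionally. The run search is vectorised and linear in sequence
length per period; a 5 Mb genome scans in a few seconds.

**Imperfect mode** chains perfect runs of the same period and class
separated by at most `max_interruption` bp (default 3, no N in the
gap); gap bases count as mismatches, purity = 1 − mismatches/length
must exceed 0.5, and a chained record must contain at least one pure
run of `seed_min_length` bp (default 8). This emulates mismatched-mode
microsatellite miners without committing to any one tool's scoring.
The exact parameters of the mining tools used on real shrimp
assemblies are not published, so all thresholds are first-class
configuration; the defaults approximate common mismatched-mode
settings.

Compound repeats: neighbouring records closer than a configurable gap
can additionally be merged (`merge_compound`), giving the alternative
"compound = one record" counting; profiles use the unmerged counting by
default and both are available.

Coordinates are 0-based half-open internally and converted at I/O
boundaries (GFF3 and RepeatMasker are 1-based closed).

## Profiles and comparisons

Per class: count, density = count/(genome length in Mb) (exact, by
construction), mean/total/max length and genome fraction. Classes with
no records are absent rather than reported with a 0 mean length.
Between genomes, the count difference per class is tested with a χ²
two-proportion test of counts against genome lengths,
Benjamini–Hochberg adjusted across classes; log₂ density and
mean-length ratios are reported, with ±∞ sentinels and a flag when a
class exists in only one genome. Composition PCA standardises the
per-class density matrix; each component's sign is fixed so its
largest-magnitude loading is positive, making scores reproducible.

## TE ages and SSR carriage

Copy age is divergence/rate. The consensus is taken as a proxy for the
ancestral element, so the full divergence — not half — accrues on the
copy's branch; with the decapod clock this puts a 21%-diverged DNA
transposon at ~105 Myr. The divergence column of the annotation
(RepeatMasker "perc div.") is used as-is; no additional multiple-hit
correction is applied, and a pre-corrected column is accepted
unchanged. The ancient/recent epoch split is a parameter (100 Myr
default in the analysis API) because the relevant species-split age is
a per-study choice.

SSR zones: any ≥1 bp overlap with a TE body is *inside*; otherwise
overlap with the 100 bp up/downstream flank (oriented by TE strand) is
a flank zone; otherwise *outside*. Flanks are not clipped at
neighbouring TE bodies; the inside > flank precedence resolves such
overlaps. Among multiple candidate TEs the largest overlap wins, ties
to the nearest TE start, then the leftmost TE — fully deterministic and
verified against an all-pairs resolver. Harboring fractions are
reported both body-only and body+flank, since either convention is
defensible; the share of all SSRs lying in TEs of each epoch is
reported alongside.

## Length modes

Mode calling runs a Gaussian KDE on log₁₀(length) (Silverman bandwidth
by default; lengths are right-skewed so the log scale is the natural
one), takes local maxima with prominence ≥ 5% of the peak density, caps
the call at two modes (keeping the most prominent pair), and places the
short/long threshold at the density minimum between them. Records tied
exactly at a threshold are "short" (strict inequality) — an arbitrary
but documented convention. Classes with fewer than 50 records are
flagged `insufficient` and not mode-called. The manual cuts used for
the shrimp comparison (long (AT)n > 65 bp, long (AAT)n > 35 bp) are
shipped as the preset `paper-2021` so those groupings can be reproduced
without re-deriving valleys. Formal mixture fitting (EM) is
deliberately out of scope; KDE peaks suffice for this procedure and
make the threshold visible.

## Rearrangement sites

A read pair is discordant when its mates map to different sequences or
more than `max_span` apart (default 50 kb, far above any insert size).
Each discordant pair contributes evidence at **both** mapped anchors;
anchor evidence within 1 kb clusters into a site, and sites need ≥ 2
supporting pairs. Placing evidence at the anchors (rather than at the
midpoint between them) keeps window tracks symmetric and puts sites at
the junction ends, which is what the per-window counting and the
SSR-adjacency question are about; the clustering distance and support
minimum are not dictated by the underlying per-window procedure and are
exposed as configuration, with the raw per-anchor events recoverable
from the audit fields. Orientation is recorded but not used for
calling — the rule is distance-only.

Cross-sample validation merges sites from multiple samples within the
clustering distance and keeps those seen in ≥ 2 samples; a single
sample passes through with a flag.

Window tracks: per 10 kb window (last window truncated, fractions use
the actual width) — site count, merged-SSR bp fraction, merged-TE bp
fraction; Spearman correlations between the site track and each content
track. The adjacency statistic is the mean distance (in windows) from
each hotspot window (top decile of site counts, zero-count windows
excluded when the decile threshold is zero) to the nearest SSR-peak
window (top decile of SSR fraction), compared against circular shifts
of the SSR track (1000 by default, seeded); circular shifts preserve
the track's autocorrelation, which a naive shuffle would destroy.

## Peak content and stratification

Content is the bp fraction of peak sequence covered by features, with
features merged first so overlapping annotations cannot push content
above 1 — content in %, not counts, is the comparable quantity across
peak sets. Differential peaks are stratified by their (externally
computed) differential p-values at nested thresholds (10⁻³, 10⁻⁵,
10⁻¹⁰). The trend of content across strata is summarised by the slope
of content against stratum rank and tested by bootstrapping peaks
(1000 resamples, seeded): the reported p is the add-one-corrected
fraction of resampled slopes ≤ 0. On a flat null this is close to
nominal and slightly conservative, which the type-I benchmark
measures directly.

## Ortholog SSR events

One representative transcript per gene (longest CDS, exon length as
fallback); introns are derived from exon gaps when not annotated;
feature ordinals count from the 5′ end following strand. An SSR
overlapping a gene is assigned to the overlapping feature with the
largest overlap (CDS/UTR beat a co-extensive exon). Within an ortholog
pair, SSRs are matched greedily by (feature type, ordinal, motif
class) in rank order along the gene; unmatched records become
inserted_a/inserted_b events; matched records with repeat ratio ≥ 2
(configurable) are elongated/contracted, orientation relative to
genome B. Ordinal matching rather than positional alignment is the
deliberate choice: it is robust to the poor intergenic synteny of
highly rearranged genomes and matches how such events are described in comparative work ("the
(AG)n in intron 5 of gene X"). The matching guarantees that every SSR of a
paired gene appears in exactly one event, and swapping the genomes
maps the event classes onto their mirror images.

## Synthetic data

The generator assembles a genome from typed segments: background
sequence at a target GC (36%, shrimp-like), TE copies drawn from a
per-family random consensus and mutated by independent per-site
substitution to the family's target divergence (no indels by default —
downstream statistics consume substitution fractions only), SSRs as
exact motif repetitions with lengths drawn from lognormal mixtures
(log-scale draws match the right skew and bimodality of real length
distributions), and gene models with UTR/exon/intron structure whose
introns and UTRs carry SSRs. Elements are shuffled and separated by
background gaps of at least 20 bp so planted repeats never merge.
Consensus sequences are resampled until SSR-free, since a chance
repeat in a consensus would be inherited by every copy of the family
and bias harboring rates coherently. The truth ledger records every
planted SSR, TE copy (with realized divergence), gene feature,
junction and peak flag; a fixed seed reproduces every output byte.

Default study conditions (a 5 Mb single-chromosome genome; copy
numbers scale proportionally at other sizes): (AT)n planted at
3000/Mb with a 25/120 bp bimodal mixture, minor classes at 20–160/Mb,
an ancient DNA-transposon family (800 copies, divergence 0.21, SSR
carriage 0.9) and three recent retroelement families (1000 copies
total, divergence 0.02–0.05, carriage 0.5), 40 genes, ~20% SSR genome
fraction. The species-pair generator applies lineage events to a
shared ancestor: lineage A doubles (AT)n lengths, lineage B doubles
its (AAT)n planting rate and inserts new intron SSRs at 0.2 per gene,
plus 1% neutral substitution per lineage. Read-pair simulation is
coordinate-space only (170 ± 20 bp inserts, 50 bp reads, 30×
coverage, 5×10⁻⁵ chimera rate); junctions emit discordant pairs at
the local pair density. Peak simulation draws widths ~N(400, 100²),
assigns differential p-values log-uniformly within strata and makes
the SSR-overlap probability follow a configured per-stratum curve
(5% baseline rising to 50% in the strictest stratum).

What the generator does not emulate: sequencing errors and read
qualities, indel evolution within TEs, nested TE insertions,
population-level SSR polymorphism, and realistic intergenic sequence
composition. Passing recovery tests therefore demonstrates the
correctness and calibration of the algorithms under the stated
statistical structure, not detector accuracy on raw reads or on
assemblies with collapsed repeats.

## Validation experiments and problem sizes

The benchmark suite (also behind `scripts/acceptance.py`) uses desk
scales chosen so the full set runs in about a minute: detector vs
brute-force enumerator on 500 random sequences ≤ 2 kb; density and
harboring recovery on the full 5 Mb default genome; rearrangement
recall/precision over 20 seeds at 2 Mb; 100-seed mode-detection and
flat-null trend rates at 1 Mb; 20 same-parameter genome pairs at 2 Mb
for the comparison type-I rate. Classes with fewer than 5 records are
excluded from the type-I tally because the χ² approximation is
meaningless there.

## Known limitations

* Imperfect mode's chain definition counts gap bases as mismatches;
  tools that score substitutions inside an alignment will report
  slightly different purities for indel-type interruptions.
* The epoch split and the substitution-rate constant linearly rescale
  all ages; conclusions about "ancient" vs "recent" inherit the
  clock's uncertainty.
* The adjacency statistic uses decile thresholds; on very short
  sequences (< ~50 windows) the permutation null is coarse and the
  test is reported as NA below 10 windows.
* Ordinal-based ortholog matching cannot pair SSRs across features
  renumbered by exon gain/loss; such records surface as paired
  insertion/deletion events instead.
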