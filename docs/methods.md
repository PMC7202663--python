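# Methods

`tmejsig` quantifies the mutational footprint that polymerase theta-mediated
end joining (TMEJ) leaves in clonally propagated genomes: 50–500 bp deletions
with micro-homology at their junctions, occasional inserts copied from the
immediate vicinity of the breakpoints, and a lesion-anchored base at the first
deleted position. It couples those junction statistics to mutation-accumulation
(MA) rate estimation and ships a generator that produces synthetic MA cohorts
with all of these features planted, so every stage of the analysis can be
verified end to end against ground truth.

## Coordinates and allele annotation

All interfaces use 1-based inclusive coordinates. A pure insertion is anchored
at the first reference base after the insert (`end = start − 1`), keeping
`len(ref_allele) = end − start + 1` true for every record.

Deletions are annotated under **maximal 5′ conservation**: while the first
deleted base equals the first retained base after the deletion, the deleted
interval shifts one base 3′-ward. The result is the unique right-most
representation — the opposite of VCF left-alignment, for which a converter is
provided. Two consequences propagate through everything downstream:

* after normalization the first deleted base (−1 at the 5′ junction) never
  equals the first retained base after the deletion (+1 at the 3′ junction),
  so the heatmap cell (−1, +1) is structurally zero ("white square");
* the (+1, −1) cell is elevated above the background match probability,
  because any allele that was shifted k ≥ 1 steps ends with its last shift
  comparison equal by construction. The shuffled null re-applies the same
  annotation so this methodological skew appears in the null as well.

Deletions carrying an insert are never shifted — shifting across an insert
would change the junction semantics — and are flagged instead. The white
square is therefore exact only on the pure-deletion subset.

## Junction windows and micro-homology

For a deletion, four windows of width `w` (default 10) are read off the
reference: retained and lost sequence at each breakpoint, indexed by the
breakpoint position convention (+k = k-th retained base walking away from the
junction, −k = k-th lost base walking into the deletion). Windows are N-padded
past contig ends and, for the lost windows, past the deletion itself; N never
scores as a match.

Micro-homology is the largest k such that the retained 5′ suffix of depth k
equals the lost 3′ suffix. The heatmap cell (i, j) is the fraction of events
whose base at 5′ position i equals the base at 3′ position j, with events
contributing N at either position removed from that cell's denominator.

The shuffled null shuffles each of the four windows independently
(composition-preserving; pad N positions stay put), rebuilds the implied local
sequence, re-annotates it under maximal 5′ conservation, and recomputes the
heatmap; identity and coverage counts are averaged over replicates (default
10) and the whole procedure is deterministic given a seed. When the two lost
windows overlap (deletion shorter than 2w) the rebuilt deleted sequence takes
the 5′-side reading; the unobserved middle of deletions longer than 2w is
filled with N, which is inert for re-annotation because shifts terminate at N.
Observed and null cells are compared with a 2×2 chi-square (no continuity
correction) on identity-versus-not counts, starred at p < 0.001.

## Insertion origin

A deletion's insert is `simple` (none), `templated`, or `misc`. `templated`
requires length ≥ 5 (shorter matches are indistinguishable from chance) and an
exact occurrence of the full insert, on either strand, within 40 bases on each
side of either breakpoint — the search windows deliberately include the
deleted sequence adjacent to each breakpoint, since TMEJ copies from both
retained and resected DNA. Exact matching was chosen for determinism; a
mismatch tolerance would need an alignment model the data do not constrain.

## Breakpoint base composition

Each deletion contributes two junctions; at each, bases are tallied at
retained positions +1..+100 and lost positions −1..−100 (lost positions past
the deletion length are uninformative and excluded, which is why coverage
decays beyond −50 for a 50–500 bp size law). Raw frequencies f_b(p) are
normalized per base to r_b(p) = f_b(p) / c_b with c_b the mean of f_b over all
covered positions, so mean(r_b) = 1 by construction. The outlier test uses the
flat per-base bands μ_b ± k·σ_b (default k = 3) with σ_b estimated across
positions covered in at least 90% of junctions; low-coverage positions are
reported but excluded from σ estimation and flagging, because their sampling
noise would otherwise dominate the false-positive count.

Two orientations are first-class and label their outputs. `mirrored`
(default) reads the 3′ junction on the reverse-complement strand so both
junctions run retained→lost in the same molecular orientation — the natural
frame if a blocked nascent strand defines one junction border symmetrically.
`top_strand` reads the literal reference strand. Pooled A+T and C+G
frequencies are identical between the modes; only strand-specific signals
(such as cytosine marking a damaged guanine on the template) differ.

## Rates and tests

A variant is accepted as de novo when it is private to one subpopulation and
carried by both read orientations at depth ≥ 5; read-level evidence is
consumed as flags and never recomputed from alignments. When flags are absent
(synthetic input) they pass vacuously by default, configurable to fail closed.

Rates are mutations per animal generation: stratum count divided by the summed
generations of the stratum's lines, with exact Garwood (chi-square) Poisson
intervals — appropriate because per-line counts are small. Rate ratios use the
conditional-binomial construction (conditional on the total count, the first
count is binomial; a Clopper–Pearson interval for that proportion maps to an
exact interval for the ratio), with a one-sided bound when the denominator
count is zero.

The Mann–Whitney U test is permutation-exact (complete enumeration over
pooled-midrank assignments, ties included) up to n₁ + n₂ = 12 and otherwise
uses the normal approximation with tie and continuity corrections; the method
used is reported. Two-sided exact p is P(|U − n₁n₂/2| ≥ |u − n₁n₂/2|).

The lesion-frequency arithmetic converts a per-generation deletion rate into a
per-base rate of replication-blocking lesions, assuming d divisions per
generation of a genome of G bases and one deletion per unbypassed lesion:
per_base_rate = rate / (d·G), bases_per_event its reciprocal. With 0.1
deletions per generation, d = 10 and G = 10⁸ this is one lesion per 10¹⁰
bases; with 1 deletion per generation, one per 10⁹.

## Variant classification

Five classes partition any record set: SNV; microsatellite indel; deletion of
50–500 bp (with or without insert — the TMEJ size class); other
deletion / insertion; structural (inversion, tandem duplication, gross
chromosomal rearrangement, consumed as tags, never called). Absent a supplied
repeat-tract annotation, an indel is a microsatellite indel when its sequence
is a whole multiple of a unit ≤ 4 bp present in ≥ 3 adjacent tandem copies
(variant plus flanking reference); both thresholds are configurable since no
canonical definition exists.

## The G4 scanner

`scan_g4` matches the standard quadruplex-capable pattern
(G≥3 N1–7)×3 G≥3 by chaining maximal G-runs, on both strands, returning
maximal non-overlapping hits. It reports the printed qua1466 sequence
GGGAGGGCGGGCGGG as a single hit spanning all 15 bases. Motif presence only —
no thermodynamic stability scoring.

## The synthetic cohort generator

`simulate_ma_lines` emulates clonal MA propagation: independent lines, each
grown a fixed or uniform-random 40–60 generations, accumulating per-class
Poisson counts at configurable per-generation rates. Wild-type-like defaults
are 0.23 SNV, 0.04 microsatellite indel and 0.04 deletion per generation on a
GC 0.36 background; deletion sizes are log-uniform on [50, 500]; junction
micro-homology is geometric (P(k) = p(1−p)^k, p = 0.5, capped at 8);
30% of deletions carry an insert, half of those templated (length 5–12,
copied from within 40 bp of a breakpoint on either strand) and half short
simple inserts of 1–4 bp; the first deleted base is cytosine with probability
`minus1_c_bias` (default 0.5) and otherwise uniform on {A, G, T}, so the bias
parameter is the exact −1 cytosine probability and equals the background only
on a GC 0.5 reference — controlled-composition checks therefore use GC 0.5.

Implanting rewrites the local reference so that the event, in its
maximal-5′-conservation annotation, has exactly the requested micro-homology
(suffix copied, then capped with a forced mismatch one position deeper) and
−1 base, and stays right-most (first retained base after a pure deletion is
resampled away from the −1 base if needed). Each edit resamples uniformly
under a single exclusion, so a neutral configuration stays compositionally
neutral. Implant sites are kept disjoint genome-wide with 160 bp margins
(composition window plus insert search plus slack), so edits never collide;
this is stricter than biology, where hotspots recur, and clustered events are
deliberately out of scope. Ground truth (mh length, −1 base, insert origin,
lesion anchoring) is emitted per event.

What the generator does not emulate: sequencing error and read-level evidence
(flags are emitted as passing), shared ancestry between lines, selection
against deleterious events, non-uniform genomic landscapes (chromatin,
replication timing), and real microsatellite length polymorphism beyond
single-unit deletions from implanted tracts. Passing recovery tests therefore
demonstrates the correctness of the statistics, not caller performance on
real sequencing data.

## Problem sizes used in the shipped analyses

The numbered analysis scripts and the acceptance script run two cohorts: a
wild-type-like cohort of 200 lines (~3,000 variants, ~420 TMEJ-class
deletions on 6 Mb) and a TLS-dead-like cohort of 50 lines with the deletion
rate elevated 30-fold (~3,000 deletions on 12 Mb). These sizes give 3-SE
recovery bands of a few percent on every planted parameter while the whole
pipeline completes in well under a minute.

## Known limitations

* The shuffled null keeps the 5′-side reading where lost windows overlap,
  discarding half the shuffle information for deletions shorter than the
  window; with the 50–500 bp size class and w = 10 this never triggers.
* Microsatellite classification from sequence alone is heuristic; supplying
  repeat tracts overrides it.
* The VCF reader is a deliberate subset (single-ALT, `<DEL>`+INSSEQ only);
  the TSV dialect is the canonical interchange format.
* Chi-square cell comparison treats the null's averaged counts as one
  pseudo-sample; replicate-to-replicate variance of the null is not
  propagated.
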