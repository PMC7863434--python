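# Methods

## Model and assumptions

The pipeline assumes the standard chimeric-pair signature of an
integration: sequencing fragments that straddle a host/virus junction
produce pairs with one mate in host sequence and the other in viral
sequence. It further assumes that when the junction lies in a repeat, the
host mates map interchangeably to every copy, so the set of candidate loci
for one integration is the set of repeat copies — the *equivalent region*.
Everything downstream (grouping, realignment, gain) follows from treating
multi-mapping as signal to be pooled rather than noise to be filtered.

Coordinates are 0-based half-open everywhere inside the package; SAM input
is converted at the boundary and BED shares the internal convention.

## Candidate refinement

Three pure predicates, applied in a fixed order for reporting (each drop is
attributed to the first failing criterion; the surviving set is
order-independent):

1. *Complexity*: "fraction of dinucleotides" is operationalised as the
   maximum, over the 16 dinucleotides, of the fraction of read positions
   covered by at least one overlapping occurrence of that dinucleotide.
   This single definition scores both microsatellite-like repeats (AC·n)
   and homopolymers (AA covers an A-run) as 1.0 and is invariant under
   reverse complement. Keep iff coverage < 0.80 (strictly below — a read
   at exactly the threshold is dropped).
2. *Viral span*: keep iff the aligned viral length is ≥ 30 nt (boundary
   inclusive: 30 is read as the attainable minimum).
3. *Proximity*: the viral mate is locally aligned against the host genome
   restricted to ±10,000 bp around every locus of its host mate; any
   acceptable alignment (score ≥ 20, identity ≥ 0.8) explains the "viral"
   mate as nearby host sequence and drops the pair. The search is windowed,
   not genome-wide: a viral read resembling host sequence far away is not
   evidence against this junction.

A consequence worth knowing: reads that physically span the junction carry
a host segment next to the locus, so criterion 3 removes them whenever
that segment is alignable (≥ ~20 nt). Junction support in the chimeric
route therefore comes from pairs whose viral mate is (almost) entirely
viral; spanning reads re-enter through the independent LT-finder route,
which does not apply criterion 3.

## Dispersion solving

All primary and secondary host-mate placements become loci. Loci are merged
per reference with a gap tolerance (default 1000 bp, bedtools `merge -d`
semantics); one initial group forms per (merged region, viral species) with
at least 2 members, so a multi-mapping read seeds a group at every repeat
copy. Groups are then collapsed iteratively: the pair with the highest
shared-read fraction strictly above 0.80 merges first, ties broken by the
smaller combined genomic coordinate, until no pair exceeds the threshold.
The shared fraction uses the *smaller* group as denominator, so a group
contained in another always collapses — the redundancy the step exists to
remove. Termination is guaranteed (each merge removes a group) and the
outcome is independent of input order.

After the fixed point a read may still sit in two final groups that share
less than the threshold; each read is then assigned to the single group
containing most of its loci (ties to the smaller coordinate), groups
falling below the minimum size release their members, and every read ends
up in exactly one group or on the ungrouped list. Ungrouped reads are kept:
they cannot support an integration but count against the gain statistic,
and reporting them avoids wasted interpretation effort downstream.

## Realignment and junction calling

Each group is realigned against one *representative* interval of its
region, chosen as the interval holding the most members' placements (ties:
the widest). Reads touching the unique flank of the inserted copy map only
there, so this reliably picks the true copy among exact repeats and gives
the realignment the full local context; the interval is padded by 200 bp.
The region is the only reference in this step: a mate with no acceptable
local alignment to it is unmapped for flag purposes. Forward host mate +
unmapped mate supports the right end (the 73/133 flag pair); reverse host
mate + unmapped mate the left end (185/117). The right breakpoint is the
maximum end of forward host mates and the left the minimum start of reverse
host mates; when any realignment carries a soft clip of ≥ 20 nt, the modal
clip boundary overrides the mate bound (clip evidence is positionally
exact, mate bounds are fragment-length-limited). Junction micro-homology
shifts clip boundaries by the homology length; breakpoints are exact up to
that ambiguity.

## Micro-assembler

Junction consensus and LT assembly use a deterministic greedy
overlap-layout consensus: reads (both orientations) are merged into the
current contig by the longest suffix–prefix overlap of ≥ 30 nt, exact
overlaps always accepted and mismatch-tolerant overlaps down to 90%
identity otherwise; contained reads are absorbed; on overlap mismatch the
earlier base is kept. At error rate 0 every contig is therefore an exact
substring of the underlying molecule. This deliberately trades assembler
sophistication (no bubbles, no error correction) for reproducibility at the
scale of a few hundred recruited reads.

## Internal aligner

A seed-and-extend local aligner replaces external mappers so the pipeline
has no tool dependencies. Scoring: match +1, mismatch −4, gap open −6, gap
extend −1 (a gap of length L costs −6 −(L−1)); alignments below score 20 or
identity 0.8 are discarded. Small problems (≤ 2M cells) are solved by exact
affine-gap Smith–Waterman (numba kernel, rolling score rows, full pointer
matrix for traceback; ties prefer diagonal moves, the '+' strand, then the
smallest target start). Large targets are restricted to windows around
13-mer seed clusters on a common diagonal; clusters supported by a single
seed are treated as noise, which can in principle miss alignments shorter
than ~25 nt with an unluckily placed mismatch — irrelevant at the score
minimum used. Multi-copy references yield all placements within 95% of the
best score, the best marked primary, which is what the dispersion stage
consumes.

## Gain statistic

Entropy and residual information are computed in nats over the reads
surviving refinement: `l` is the locus the upstream caller assigned (the
table's host locus), `g` the final group, ungrouped reads singleton groups.
`I_res` is the conditional entropy H(L|G), hence 0 ≤ I_res ≤ I and both
gains lie in [0, 1]; an exhaustive enumeration over all assignments and
partitions with ≤ 6 reads and ≤ 4 loci certifies the bounds and the
identity NDG + SDG = 1. A sample whose reads carry a single locus has
I = 0; no dispersion existed, both gains are defined as 0 and the report
flags the sample as degenerate rather than emitting 0/0.

## Synthetic benchmark

The generator emulates the in-silico design the method is evaluated on.
Defaults: 1 Mb host genome (the evaluation uses the 1–2 Mb range; 1 Mb
keeps the full grid tractable on one CPU), 1 kb repeat units — UL ×1,
Rep10 ×10, Rep100 ×100 — placed at random non-overlapping positions, exact
copies (the worst case for dispersion; per-copy divergence is available),
an 11 kb deterministic pseudo-random viral source standing in for a real
flavivirus genome (real FASTAs can be supplied), 300/600/900 bp inserts
spliced mid-copy, 2×150 bp pairs at 700 ± 50 bp fragment length,
substitution errors at 0.001/base (the read simulator the original
benchmark used does not have its error settings on record; substitutions
at a typical Illumina-like rate suffice for the contracts tested — no
indel errors, no quality-string realism, no PCR duplicates). Pools draw
pool_coverage/pool_size expected coverage per individual with exactly one
carrier. Read counts are ceil(coverage × genome_length / (2 × 150)).

The bundled chimera scanner stands in for the upstream caller: pairs are
pre-screened with sampled viral 13-mers, candidates aligned to both
references, and a pair is emitted when one mate's best alignment is host
(full-read identity ≥ 0.9) and the other's best is viral (span ≥ 20 nt).
Because it applies no mapping-quality or clustering filters of its own, it
is somewhat *more* permissive than a full caller stack; benchmark
sensitivities at fractional carrier coverage (pools) should be read as an
upper bound on what a complete external chain would give. What passing
tests show is that the dispersion-solving machinery recovers integrations
the moment ≥ 2 refined pairs exist; they do not certify any particular
upstream caller's yield on real data, nor behaviour under structural
variation, indel errors or diverged viral strains.

## Evaluation

The evaluation unit is the sample. A carrier counts as detected when some
call's equivalent region overlaps the true insertion point ± 1000 bp (the
region-merge distance) with the right viral species — a call anchored at a
different copy of the true repeat still detects the sample, because its
region contains the true locus; that is precisely the dispersion-solving
case. A stricter locus-level outcome (a call's region must overlap the true
copy; a carrier with only wrong-locus calls scores FN+FP) is reported
alongside. Metrics with undefined denominators are reported as unavailable,
never silently zero. For the LT route, "recovery" of an event in a highly
repeated region is additionally scored as localisation: the host flank of
the junction contig is re-anchored to the genome, and an event whose flank
places equally well at many copies is unresolved even when the inserted
sequence itself assembles perfectly. Under the generator's defaults this
ambiguity rarely materialises: with 1 kb repeat units and junction contigs
whose flanks assemble out to roughly the fragment length, the flank
escapes the repeat copy into unique sequence and anchors the event
uniquely — even for the 100-copy class. Reduced recovery in highly
repeated regions should therefore be expected only when repeat units are
long relative to the assembled flanks (as for real multi-kilobase
transposons), a regime the bundled benchmark's 1 kb units do not enter.

## Known limitations

- Exact repeat copies make per-copy assignment information-free by
  construction; with real, diverged repeats the representative-interval
  choice depends on the divergence being visible within read length.
- The chimeric route cannot place breakpoints more precisely than the
  innermost mate bound (~fragment − 2×read length) unless clipped reads
  survive refinement; the LT route recovers exact junctions instead.
- Pool simulation gives every individual the same genome apart from the
  insertion; no within-pool polymorphism.
- The scanner classifies junction-spanning reads by their dominant half,
  so a read with a near-even host/virus split may be attributed to either
  reference.
- The deterministic exact-overlap assembler has no analogue of a de-Bruijn
  assembler's repeat-induced graph tangles, so assembly failures that real
  assemblers show inside high-copy repeats are not reproduced at error
  rate 0.
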