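# Methods

## The transcription model

Plastome transcription is modelled as initiation from many transcription
start sites (TSSs) combined with inefficient, stochastic termination.
Initiation sites are placed evenly (default one per 2 kb per strand, the
`uniform_tss_model` helper) or supplied explicitly with relative strengths;
a transcript starts at a TSS drawn proportionally to strength and elongates
past each base with survival probability 1 − *p*, where *p* is
`per_base_termination_prob`. Lengths are therefore geometric with mean 1/*p*
(default *p* = 5·10⁻⁴, mean 2 kb), capped at one genome lap. Optional
discrete terminator sites add a stop probability when crossed. Under these
defaults the union of overlapping precursors tiles the entire circular
genome on both strands — the property the coverage analysis measures.

Assumptions: termination is homogeneous along the genome (no sequence
dependence); initiation strengths are position-independent unless specified;
RNA processing is reduced to uniform fragmentation (no ribonuclease
specificity, no secondary structure); polyA tails can be appended but default
to length 0 and are never part of the mappable footprint.

C→U editing acts per transcript: each covered site on the transcript's own
strand is edited independently with its efficiency (a probability in (0, 1]),
and the edited base appears as T in the transcript and hence in cDNA reads.
Sites whose strand-adjusted reference base is not C are rejected.

## Reads and the error model

Fragments start uniformly along transcripts, with transcripts drawn
proportionally to their number of valid fragment starts so read coverage
tracks transcript footprint. Substitution errors are planted at a per-base
rate (default 0.1 %) and every base receives the Phred quality matching that
rate (Q30 for 0.1 %, Q40 for error-free runs); there is no quality gradient
along the read, so quality trimming is exercised by dedicated tests rather
than by the default simulation. Unstranded libraries flip each read's
orientation with probability 1/2; stranded libraries preserve transcript
strand. Small-RNA mode draws read lengths uniformly from 18–30 bp. Every
read records its expected placement (position, strand) and the edited sites
it covers.

## Mapping semantics

Reads are 3′-trimmed (trailing bases with Phred ≤ 20 removed) and dropped
unless strictly longer than 30 bases. Mapping is ungapped with at most one
substitution (`max_mismatch` ∈ {0, 1}); a read is kept only when exactly one
placement attains the minimal mismatch count — a read with one 0-mismatch
placement and further 1-mismatch placements is unique (best-stratum rule),
while ties at the minimum are discarded as multi-mapping. Mismatches are
plain Hamming counts, not quality-weighted. The index is hash-seeded: two
disjoint k-mers (k = 15 for reads ≥ 30 bp, k = 9 for small-RNA reads ≥ 18 bp)
guarantee by pigeonhole that a ≤ 1-mismatch read yields at least one exact
seed; candidates are verified by direct comparison, and the mapper is tested
against an exhaustive all-position, all-strand scan. The reference is
circular by default (placements reported modulo genome length); `--linear`
disables wrap-around.

## Coverage statistics

All statistics derive from one per-base, per-strand depth profile, which
conserves bases exactly (total depth = summed aligned read length).
"Covered" means depth ≥ 1. Zero-depth positions count toward covered
fractions but are excluded from log-scale distributions (log 0 undefined) and
tallied separately per class. CDS comprises protein-coding, tRNA and rRNA
positions; NonCDS comprises introns and intergenic space; overlapping
annotations resolve with precedence coding > intron > intergenic. The log₁₀
plotting track and the log₂ summaries are computed from the same depth
array. Repeat masking restricts the covered fraction to non-masked
positions; dispersed repeats are identical 2-kb copies (≥ 2× read length) so
they genuinely defeat unique placement, and the second copy of the
inverted-repeat pair is masked on the same grounds. Unmapped regions are
maximal zero-depth intervals in linear coordinates with a < 30 bp / ≥ 30 bp
length histogram.

## nupDNA diagnostics

Plastome-derived nuclear loci are found by k-mer-seeded (k = 16) ungapped
X-drop extension scored +1/−2, with co-linear hits chained across ≤ 8-bp
gaps into one locus (the chain junction recorded as an indel variant).
Retained loci satisfy length ≥ 500 bp, identity ≥ 95 % and a Karlin–Altschul
E-value < 10⁻¹⁰ (λ = 1.33, K = 0.621 for +1/−2 scoring); the length and
identity filters dominate in practice. Diagnostic windows are 160 bp with
the discriminating feature at 0-based offset 79 (the 80th base, "site 80"):
one window per interior SNP/indel variant with sufficient flanks, plus
junction windows at each locus edge pairing 80 bp of locus with 80 bp of
nuclear background. Reads are mapped to each window as a linear
mini-reference with zero mismatches; the homologous plastome window is
profiled identically as the comparator. Because mapping is ungapped and
mismatch-free, no read of true plastome origin can match a window across its
variant or junction, so site-80 depth is exactly zero unless the locus
itself is transcribed. The verdict threshold — transcribed iff site-80 depth
exceeds 10 % of the paired plastome-site depth — is a package choice, since
no statistical test is prescribed for the decline; it is configurable, and
the verdict is undefined (flagged) when the plastome pair has zero depth.
The negative control is run with error-free reads: a sequencing error
falling exactly on the variant position could otherwise fabricate a
window-matching read. Hits are searched on both plastome strands, but
diagnostic windows are built for forward-strand loci (all planted loci are
forward copies).

## Editing calling

Pileups count strand-adjusted bases in forward genomic space: a minus-strand
alignment contributes the complement of its read, so C→U editing on the
minus strand appears as G→A in forward space; both signatures are flagged
canonical. A site is called when depth ≥ 10, alternate count ≥ 5 and
alternate frequency ≥ 0.5, applied conjunctively (at high depth the count
and frequency rules can disagree; the frequency rule then dominates — the
ambiguity is deliberate and surfaced here rather than resolved silently).
Sites at 100 % alternate frequency are genomic SNPs, not editing. The exact
100 % rule is fragile under sequencing error — one errored read at a true
SNP drops its frequency below 1.0 — so the editing preset substitutes a
0.95 cutoff on noisy data: at ~50× depth it tolerates the ~2 error reads a
0.1 % error rate can produce while remaining far above the ~0.76 frequencies
that 80 %-efficient editing yields. The exact rule stays the default for
error-free data and the cutoff is user-configurable.

Editing detection presumes the edited (sense) strand dominates coverage at
the site, as it does in real plastomes where mRNA far exceeds antisense; the
editing preset therefore simulates with 5 % antisense initiation. Under a
symmetric antisense model the edited fraction is diluted below the 0.5
frequency threshold and sites become undetectable — a genuine property of
frequency-threshold callers on unstranded data, not an artifact. Editing
sites (and planted genomic SNPs) are spaced so that no read covers two
variant positions at once; two planted variants within one read length would
exceed the one-mismatch budget and silently delete coverage between them —
the same clustering effect would affect any strict-budget mapper.

## Problem sizes and numerical choices

The standard study condition is a 50-kb circular plastome, one TSS per 2 kb
per strand, mean transcript length 2 kb, and 200,000 100-bp reads (~400×
nominal depth) at 0.1 % error; coverage experiments run in seconds at this
scale. The editing preset lengthens transcripts (mean 10 kb) so that
per-site depth is flat at its ~50× target rather than sawtoothing between
TSSs, and uses 25,000 reads. The nupDNA experiments use 30,000 reads; the
mapper-oracle comparison uses 1,000 reads against the exhaustive scan.
Master seeds split into named per-stage child seeds through
`numpy.random.SeedSequence(master, spawn_key=(stage,))`, so any stage can be
rerun independently; identical configuration and seed reproduce every output
byte. Coordinates are 0-based half-open internally; GFF3 I/O converts to
1-based inclusive.

## What the synthetic data does and does not show

The generator reproduces the structural features the analyses depend on —
feature classes, identical repeats, an IR pair, planted nupDNA variants,
strand asymmetry, editing with partial efficiency, sequencing error — but
not realistic gene content or synteny, codon structure, promoter motifs,
quality degradation along reads, PCR duplicates, or ribonuclease processing
beyond uniform fragmentation. Passing tests therefore demonstrate that the
pipeline's logic is correct under its stated model, not that real libraries
meet the model's assumptions. In particular, IR-mapped reads: with two
identical IR copies, reads interior to the IR are discarded as multi-mapped
under the unique-placement rule, so IR coverage is reported through the
repeat-masked fraction; how IR reads should be counted (collapsed vs
duplicated) is left explicit rather than guessed.
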