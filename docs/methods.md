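# Methods

`fsgene` characterizes *fs-genes*: predicted genes whose coding region
transits between two overlapping ORFs at a frameshift position, as reported
by an HMM-based frameshift predictor whose output table is this package's
input. The package decides, per cluster of homologous fs-genes, whether the
transition looks like a programmed frameshift (ribosomal, PRF, or
transcriptional, PTR), phase variation, translational coupling, a
pseudogenizing indel, or an artifact of two adjacent genes.

## The fs-gene model

A prediction row names two overlapping ORF intervals on one strand, a
frameshift position `fs_pos` (first nucleotide of the codon at which the
transition applies, on a codon boundary of ORF1) and a direction d = ±1,
with frame(ORF2) − frame(ORF1) ≡ d (mod 3). All coordinates are 0-based,
half-open, on the coding strand; minus-strand genes are reverse-complemented
at the I/O boundary. The ORF2 interval starts at the downstream gene's
*predicted start codon*, as a gene caller reports it — this matters for the
translational-coupling feature below.

**Fusion.** The fused CDS is `s[orf1_start:fs] + s[fs+1:orf2_end]` for +1
(one nucleotide skipped) and `s[orf1_start:fs] + s[fs-1:orf2_end]` for −1
(one nucleotide decoded twice). The literature does not pin down the exact
nucleotide arithmetic of the junction; this convention reproduces the
classic dnaX (−1, A_AAA_AAG) and prfB (+1, CTT_TGA_C, reading through the
in-frame TGA) products and keeps the CDS length divisible by 3. Translation
uses the bacterial genetic code (table 11); ambiguous codons yield `X`; an
internal stop in the fused frame is an error carrying the stop's codon
index, since it indicates a wrong position or direction.

**Frameshift box.** The true shift site must lie between the stop codon
bounding ORF2's frame on the 5′ side and the stop terminating ORF1's frame
on the 3′ side. The box includes both bounding stops plus a fixed 3-nt pad
past the 3′ stop, so that phased heptamers overlapping the terminal stop
(the prfB site, and ATGA-type start/stop overlaps) remain fully inside.
Boxes wider than 100 nt are reduced to the 100-nt window centred on the
shift (frequent in high-GC genomes); missing bounding stops clip at the
gene edge with a warning. The box records a `phase_anchor` so ORF1-frame
codon starts are recoverable in box coordinates.

## Homology

BLASTp is replaced by exact Smith–Waterman (Biopython's `PairwiseAligner`,
BLOSUM62, affine gap cost 11 + L): desk-scale inputs make the exact
computation affordable and remove an external binary. E-values use the
Karlin–Altschul formula with the standard gapped constants λ = 0.267,
K = 0.041. Thresholds: 1e−10 for validation against a reference protein
set, 1e−50 for the all-against-all clustering search, 1e−3 for domain
evidence.

A frameshift is **bridged** when one hit covers ≥ 100 aa of the fs-protein
including the junction residue — the fused product has a continuous
homolog. **Split** hits (wholly 5′ and wholly 3′ of the junction, ≥ 20 aa
each; the flank minimum is this package's choice, to avoid calling split on
one off-centre hit) indicate two adjacent genes mispredicted as one
fs-gene. Domain intervals (supplied as input, standing in for a Pfam
search) bridge when an interval with E < 1e−3 strictly contains the
junction residue.

## Clustering

Nodes are fs-proteins; the best stringent hit (lowest E, ties by score then
ids) joins two nodes iff (i) both junction residues lie inside the
alignment block ≥ 10 aa from its borders, (ii) directions agree, and
(iii) the junctions are ≤ 50 aa apart *in alignment-column space* (each
residue index is projected through the aligned segments; the column metric
is robust to gaps). Connected components with ≥ 2 members are clusters,
computed with networkx and ordered deterministically by smallest member id;
criterion (ii) makes every cluster direction-pure, which is asserted.
Clusters are named by domains present in > 50 % of members (most frequent
first, joined with `/`), falling back to reference-hit transfer, then the
cluster id.

## Phased motif search

A slippery heptamer's phase relative to the ORF1 reading frame is part of
the signal: −1 sites read N_NNN_NNN (starting one nucleotide before a codon
boundary), +1 sites NNN_NNN_N. Candidate site offsets in a box are exactly
the phase-consistent positions with 7 nt remaining; windows containing
ambiguous bases are skipped, and boxes with > 10 % ambiguity are excluded.

The sampler is a one-occurrence-per-sequence Gibbs site sampler of width 7
restricted to candidate offsets: a uniform 0-order background (a
composition-matched background penalizes A-rich slippery motifs because
the poly-A site itself inflates the box's A frequency; the phase
constraint already provides specificity),
background-proportional pseudocounts (total 0.5), per-sweep resampling of
each box's site in random order, a joint phase-shift move (slide all sites
one codon and keep improvement) every five sweeps, convergence after 100
sweeps without improvement of the log-odds objective (cap 1000), a
deterministic hill-climbing polish, and a best-of-two-chains rule per run.
Exact objective ties (near-identical boxes) are canonicalized to the
leftmost common offset so reruns agree. The sampler is restarted 100 times
(random starts; clusters of ≥ 100 boxes are seeded from occurrences of the
most over-represented heptamer) and **Score(X) = fraction of runs whose
column-majority consensus is X**. Reported sites come from the
highest-objective run; sites extended ±20 nt give the 47-column positional
frequency matrix and per-column information content (bits), written as
plain text with an optional matplotlib rendering.

**Motif evidence for classification.** A cluster has a *conserved site*
when the top-scored heptamer wins ≥ 50 % of runs, occurs literally at a
phased position in ≥ 50 % of member boxes, **and** the aligned sites sit
uniformly close to the predicted shift (median distance ≤ 15 nt): a
slippery sequence is conserved *at* the frameshift, whereas a
chance-conserved window can lie anywhere in the box. In the pipeline the
presence requirement is additionally raised to the cluster's mean box
identity plus 0.15 — conservation must stand out *above background*,
because in a low-divergence cluster partially conserved windows arise
everywhere by descent alone. Two guards: a top heptamer
containing a downstream-frame start codon (AT_G for +1, A_TG for −1) marks
a suspected overlap of two adjacent genes rather than recoding; and a top
heptamer lying wholly inside a significant tandem repeat in a majority of
members counts as repeat (phase-variation) evidence — unless it is one of
the seven canonical A-rich heptamers (AAA_AAA_A, AAA_AAA_T, A_AAA_AAG,
T_AAA_AAA, A_AAA_AAC, A_AAA_AAA, G_AAA_AAA), which are bona fide slippery
sequences even though they are homopolymeric (poly-A PTR in dnaX being the
canonical case).

## Per-gene and per-cluster features

All repeat features use the ±50 nt window around the shift.

* **%AT** — members with a pure A-run or T-run ≥ 7 nt (mixed A/T tracts are
  surfaced by the tandem-repeat detector instead).
* **%R** — members with a tandem repeat other than poly-A/T. The detector
  reports *exact* tandem repeats with primitive units of 1–6 nt and total
  span ≥ 7 nt, maximal and non-nested, with fractional trailing copies
  (re-implemented exhaustively rather than wrapping the external repeat
  finder — desk-scale windows make exhaustive search trivial and exactly
  testable). Because a span of 7 at unit length 6 occurs in nearly every
  random window, the *feature* counts only significant repeats with
  span ≥ max(7, 2·unit, unit + 6); the detector itself stays permissive.
* **%S** — members whose ORF2 predicted start codon (ATG; GTG under an
  option) lies within 10 nt (configurable 20) of the last nucleotide of
  ORF1's stop. Using the *predicted* start matters: scanning for any
  phased ATG would hit internal methionine codons and overlap-ATGA motifs
  and saturate the feature.
* **%B** — members bridged by reference-set homology.
* Mean box identity from global nucleotide alignment (match 1, mismatch −1,
  gaps −2/−0.5; identity over alignment length), subsampled to 300 pairs
  in large clusters; clusters of 5–100 members with identity ≤ 80 % carry
  the published motif-search eligibility flag. By default motif search
  still runs on every cluster of ≥ 5 members (the flag is reported, and a
  strict gate is available as `gs_identity_gate`), because low-divergence
  datasets would otherwise be unclassifiable.
* RBS score: an own-design Shine-Dalgarno position-weight model (consensus
  AGGAGG, match/mismatch log-odds, spacing tolerated at 4–12 nt with a
  0.7/nt penalty outside) affinely calibrated to the published [−11, 8]
  range; a canonical SD at tolerated spacing scores 8, random 50 %-GC
  windows average below 0. Only the calibrated range and the > 2.2
  filter semantics of the upstream predictor are preserved.

## Classification

First-match cascade over cluster features:

1. suspected **overlapping pair** — conserved site whose heptamer carries a
   downstream-frame start codon;
2. **programmed frameshift** — ≥ 5 members and a conserved site;
3. **phase variation** — ≥ 5 members, repeats characteristic of the cluster
   (%AT ≥ 50 or %R ≥ 50 — at least half the members, not a chance repeat in
   one), and %AT or %R above %S;
4. **translational coupling** — %S above both %AT and %R and %S ≥ 50 (the
   floor avoids labelling on vacuous comparisons);
5. **pseudogene** — ≤ 2 genera, an annotated pseudogene member, no
   conserved site (the genus cap implements the recent-origin argument:
   clusters spanning ≥ 3 genera are excluded from pseudogene calls);
6. **hypothetical pseudogene** — ≤ 2 genera, > 50 % bridged, no annotation;
7. **uncharacterized.**

Clusters satisfying both (2) and (3) are resolved by cascade order and the
conflict is reported, keeping rule-order sensitivity visible. The manual-
verification feature of the original analysis is an input flag, never
computed. Singletons: annotated pseudogene flag → `annotated_pseudogene`;
split hits → `false_positive_pair`; a bridging hit →
`validated_error_or_indel` (strengthened, not relabelled, by domain
coverage); otherwise `orphan`.

**Mechanism.** Over programmed clusters grouped by name: two or more
same-name clusters with opposite directions → PTR (polymerase slippage is
direction-agnostic among orthologs); one ubiquitous direction → PRF;
unnamed clusters stay undetermined.

## Pipeline

Stage order: RBS filter (drop rows with downstream RBS score > 2.2, unless
disabled) → fusion → reference validation → all-against-all → graph →
clusters → boxes → motif search → features → classification. Every dropped
record is logged with a reason; all thresholds live in `PipelineConfig`
with the published values as defaults; a fixed seed makes runs
byte-identical (per-cluster sampler seeds derive from a CRC of the cluster
id).

## Synthetic data

The generator emulates the survey's inputs at desk scale with planted
truth. Members of a family share an ancestral fused protein; each member's
codons are resampled synonymously outside planted windows ("wobble",
emulating synonymous divergence among orthologs), then substituted at the
configurable per-site `noise` rate, codon-aware so the fused frame stays
open. Only the exact planted nucleotides are pinned: third positions of
codons bordering a cassette still vary, so the planted heptamer — not a
wider context — is what stays conserved. The Shine-Dalgarno stimulator is
written per member at 10–14 nt spacing: conserved in sequence, not
column-alignable, as in real orthologs. Ancestors are screened so that no
phased window away from the plants is expected to recur literally in more
than ~20 % of members and no unplanted A/T run ≥ 7 nt sits near the shift;
without this screen, invariant codons (Met/Trp, or codons pinned by a
plant) create accidental "conserved sites" that no classifier could tell
from planted ones.

Default study conditions: 8 members per clustered family (4 sequencing-
error singletons), genes of 450–750 nt at 50 % GC, noise 0.1/site (boxes at
roughly 55–75 % identity — the divergence regime in which motif
conservation is informative), six genera assigned round-robin so programmed
families span ≥ 3 genera and pseudogene families ≤ 2. Eight members rather
than the minimum five keeps majority-vote features off knife-edge ties at
the 50 % thresholds. Default cassettes: A_AAA_AAG (−1, SD stimulator) for
the PRF family; AAA_AAA_T (+1) and T_AAA_AAA (−1) as a shared-name
direction pair for PTR; AGTC×3 straddling the shift for phase variation;
member-specific stop/ATG placements within 10 nt for coupling; a 1-nt
shared indel, annotated-pseudogene flags and ≤ 2 genera for pseudogenes;
an A_TGA_AAC cassette (the classic ATGA start/stop overlap) for the
overlapping-pair family; sequencing-error singletons get their full-length
ancestor planted in the reference set. `n_per_class` for the PTR class
counts members per direction family (2n fs-genes). Some heptamers
(T_AAA_AAA) would place a stop in the fused frame at the canonical offset;
the plant then shifts upstream in whole codons, preserving phase.

What the generator does **not** emulate: realistic phylogenetic divergence
(substitutions are i.i.d.), codon-usage bias, RNA secondary structure (a
hairpin stimulator is an exact inverted repeat, not folded), multi-gene
operon context, or sequencing artifacts beyond a single indel. Passing
tests therefore show the machinery is correct under the stated statistical
structure, not that real-genome performance matches the original survey.

## Numerical choices and degenerate inputs

Identical seeds give byte-identical outputs everywhere (numpy
`SeedSequence` substreams derived by counter). Alignment-score ties break
by higher score then lexicographic ids; cluster ids by smallest member;
heptamer score ties lexicographically. A frameshift position off ORF1's
codon boundary is re-anchored upstream with a warning, never silently.
Empty post-filter inputs produce empty outputs with exit code 0. Sampler
runs on clusters with fewer than two candidate-bearing boxes raise a
clear error and the pipeline records the cluster as motif-free.

## Known limitations

The %S feature saturates when ORF2 start predictions are unavailable (the
feature is then false, never guessed). The run-consensus score is a
substitute for the original (unpublished) heptamer score formula. The
rule cascade fixes an order between programmed-frameshift and
phase-variation evidence that the original analysis resolved with manual
literature review; clusters genuinely carrying both signals (poly-A
phase-variable recoding sites) are reported as programmed with a conflict
note. Motif search on clusters of ~5 members with < 60-nt boxes is at the
edge of identifiability; scores below 0.5 should be read as "no stable
motif", not "no motif".
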