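# Methods

This note documents the models, conventions and deliberate design choices
behind `mitocomp`, in the spirit of a methods supplement: what each
computation assumes, which knobs matter, and what the synthetic-data tests
do and do not demonstrate about real data.

## Genome model and coordinates

A `MitoGenome` is a circular DNA string over {A,C,G,T,N} plus an ordered
list of typed features. Coordinates are 1-based inclusive (the GenBank
convention) everywhere, including all output tables. Circular arithmetic is
modulo the genome length; a feature segment that crosses the replication
origin is stored as two explicit segments and flagged, never as a
start-greater-than-end interval, which keeps every downstream position-set
operation simple. `rotate()` re-normalises all coordinates and is a
documented invariance: every statistic in the package (composition, skews,
partition totals, repeat content up to coordinate shift, gene order) is
unchanged by rotation, and the test suite enforces this.

Feature typing on GenBank input follows fixed rules: gene labels matching
the 15-gene core set (case-insensitive, through an extensible alias table
handling e.g. `cytb` → `cob`, `nad4l` → `nad4L`) become `core_pcg`;
`trn*` → tRNA; `rnl`/`rns`/`rrn*` → rRNA; `rnpB` → its own type; any other
CDS is an ORF, reclassified as an intron-encoded ORF when its span nests
inside an intron. Introns not explicitly annotated are derived from the
gaps of `join()` locations on CDS and rRNA features; explicit intron
features take precedence over derivation. Group I/II typing is read from
annotation qualifiers when present and otherwise left `unknown` —
structural RNA classification is out of scope, and for the clade this
package targets the annotated introns are group I.

Positions holding N are excluded from both numerators and denominators of
GC content and skews.

## Region partition

Each nucleotide belongs to exactly one of four categories with precedence
rna > coding > intronic > intergenic: tRNA/rRNA exons and rnpB paint last
(highest priority), then exons of protein genes and free-standing ORFs,
then intron spans — including the nucleotides of intron-encoded ORFs, which
count as intronic, not coding — over an intergenic background. Overlapping
coding features are counted once (position-set union). This precedence is
what makes the four percentages close to 100% exactly, reproduces the
convention in which rRNA introns are intronic rather than RNA, and is
enforced against the generator's independent bookkeeping on every synthetic
genome.

Intergenic spacers are the gaps between consecutive top-level features
around the circle (introns travel with their host gene); zero-length
spacers are reported, as is the longest spacer with its flanking genes.

## Codon usage

Codon counts cover every codon of each spliced CDS under translation
table 4; the start codon is the first annotated triplet and the stop the
last, with no re-calling of alternative starts. A CDS whose spliced length
is not divisible by three is excluded with a warning rather than silently
truncated. RSCU is count divided by the mean count of the codon's synonym
family. Percentages print at two decimals throughout the pipeline.

## Repeat detection

Interspersed repeats: an ungapped seed-and-extend self-comparison
(k-mer seeds, default k = 12; extension scores match +1 / mismatch −2 with
x-drop 20, BLASTn-like) of the doubled sequence against itself and against
its reverse-complement, reverse, and complement transforms, yielding the
four orientation classes. The trivial self-diagonal (and its circular
image at diagonal offsets ≡ 0 mod length) is excluded; hits are
deduplicated under (A,B) ≡ (B,A) symmetry and coordinate folding. Defaults
min_len = 28 nt and min_identity = 74% bracket the hit-length and identity
range reported by stringent BLASTn self-comparison of fungal mitogenomes.
Bit-exact replication of BLASTn/REPuter output is a non-goal; the detector
is validated by planted-truth recovery and by re-verifying every reported
hit's identity with a direct column-wise comparison. K-mers occurring more
than 200 times are skipped as low-complexity; this caps worst-case cost and
only suppresses seeds inside massive simple repeats, which the tandem
finder handles.

Tandem repeats: for each period p (default up to 100), positions where
`s[i] == s[i+p]` are scored +2 and mismatches −7 (the Tandem Repeats Finder
default weighting); maximal positive-scoring segments with at least one
full extra unit, total length ≥ min_total (default 24 nt) and ≥ 80% unit
match become candidate loci. Overlapping candidates of different periods
are resolved greedily by score, then smaller period, so a period-2p
harmonic never displaces the true period-p array. The consensus unit is a
per-column majority vote. The default min_total of 24 nt keeps random
AT-rich background (which is rich in short chance periodicities) from
flooding the table; the threshold is exposed and any value above 10 nt is
accepted.

## Intron position classes

The insertion point of an intron is the number of coding nucleotides
transcribed before it: offset 3k is codon k phase 0; offsets 3k+1 and 3k+2
fall inside codon k+1 with phase 1 and 2. Host coordinates are projected
onto a reference species by globally aligning the two host proteins
(BLOSUM62, gap open −11 / extend −1); a site landing in a reference gap is
assigned the nearest preceding reference column and flagged. The class key
is the exact (reference codon, phase) pair — no tolerance window — because
position classes are defined by positional identity and the alignment
projection absorbs indel drift. Clustering is a pure deterministic grouping,
independent of species input order.

Published letter / Roman-numeral class names can only be inherited from a
user-supplied reference table (host, codon, phase, name), since the anchor
introns of the published naming scheme are defined by an external reference
set; classes without a table entry are labelled UN-1, UN-2, … in site
order, and with no table at all names are synthesised from coordinates
(`cox1-c121p0`). Within-class nucleotide identity is reported when
requested but never gates clustering. A class present in ≤ 2 species is
flagged rare; in more than half the species, common.

## K2P and Ka/Ks

K2P uses the closed form d = −½·ln((1−2P−Q)·√(1−2Q)) over pairwise-kept
sites (gap/N columns deleted pairwise, matching MEGA's default); a
non-positive log argument marks the pair saturated rather than producing a
number. NG86 Ka/Ks: per-codon synonymous site fractions (each codon
contributes three sites; a change creating a stop counts as nonsynonymous)
averaged over the two sequences; difference counts average uniformly over
substitution pathways, excluding pathways that pass through a stop codon
and falling back to all pathways when every route is blocked; the
Jukes–Cantor correction −¾·ln(1−4p/3) is applied to both proportions.
Ks = 0 with Ka > 0 is reported as +inf and flagged, never dropped. Internal
stop codons are a hard error naming the codon position. Site and pathway
tables are precomputed once per genetic code, so pairwise screens over many
genes stay fast; the test suite checks the cached implementation against an
independent naive enumerator to 1e-10.

For the pairwise screen, codon alignment is protein-guided: proteins are
aligned and gaps back-threaded as codon gaps. This deviates deliberately
from nucleotide-level alignment of coding genes, which can shift frames and
invalidate synonymous/nonsynonymous bookkeeping. Equal-length CDS pairs —
the generator's regime, since it does not simulate indels — pass through
unchanged.

## Gene order and breakpoints

A gene order is the circular sequence of signed labels read by start
coordinate; duplicated labels (typically tRNA isoacceptors) are
disambiguated by anticodon, then occurrence rank, and a flag collapses
tRNAs entirely since tRNA mobility dominates fungal rearrangement signal.
Orders are compared on their common label universe through canonical signed
adjacencies: the adjacency ((x,sx),(y,sy)) and its reflected image
((y,−sy),(x,−sx)) are identified, making whole-molecule reflection an
equivalence — the strand choice of a circular GenBank record is arbitrary.
Breakpoints = common genes − shared adjacencies; zero iff the orders
coincide up to rotation and reflection. Inversion-distance computation is a
non-goal.

## Supermatrix and neighbor joining

The combined gene set (15 core PCGs + rnl + rns by default) is concatenated
with recorded per-gene partition boundaries; a species missing a gene is
gap-filled, and a species missing more than 25% of genes is excluded with a
warning. When per-gene sequences differ in length they are aligned by
reference projection — each row globally aligned to the reference species'
row, insertions relative to the reference dropped — which is exact for
indel-free data and an approximation otherwise; writers for FASTA, relaxed
PHYLIP and a plain-text partition file allow hand-off to external ML/BI
tools for full inference, which this package deliberately does not attempt.

Distances on the supermatrix are K2P with pairwise deletion (rRNA
partitions contribute as nucleotide columns). Neighbor joining is the
canonical Saitou–Nei agglomeration with ties in the Q criterion broken by
the sorted label pair, making output independent of input taxon order;
negative branch-length estimates are clamped to zero and flagged on the
node. Bootstrap support resamples alignment columns with a seeded RNG and
maps split frequencies onto the full-data tree. Support values are
resampling percentages and are reported descriptively; they are not
Bayesian posteriors, and no concordance with published support values is
asserted.

## Synthetic genomes and divergence simulation

The generator's default spec mirrors the architecture of a large
Polyporales mitogenome: a 115 kb circle with the 15 core PCGs at realistic
fungal lengths, 19 free-standing ORFs, rnl/rns, 27 tRNAs including
duplicated isoacceptors, rnpB at 329 nt, and 24 group-I introns distributed
over cox1 (12), cob (6), nad1 (2) and rnl (4), most carrying a 600 nt
intron-encoded ORF. Composition targets GC 26% with AT skew −0.03 and GC
skew +0.06 — magnitudes chosen once as realistic for an AT-rich fungal
mitogenome with negative AT and positive GC skew. Intergenic background is
i.i.d. from the target base distribution; coding genes are built from a
codon distribution derived from that distribution (renormalised over
non-stop codons of table 4), which makes TTT/AAA/TTA-type codons dominate
as they do in AT-rich mitogenomes and gives codon-usage tests a known
truth. Planted repeats (direct, palindromic, reverse, complemented, with
controllable identity) and tandem arrays occupy their own intergenic
blocks, so their coordinates are exact in the manifest. All randomness
flows from one numpy Generator keyed by the mandatory seed; identical specs
produce byte-identical GenBank output.

Divergence simulation decomposes a genome into gene components (transcript
orientation, introns attached at their codon offsets) and intergenic gaps,
evolves each down a newick tree, and reassembles leaves. Noncoding
sequence mutates per site with probability 1−exp(−rate·t); coding sequence
receives Poisson-proposed point changes with HKY-style transition bias
kappa (expected transition:transversion count ratio kappa/2), acceptance
probabilities min(1, 1/ω) for synonymous and min(1, ω) for nonsynonymous
proposals enforcing the per-gene dN/dS, stop-creating changes rejected, and
start/stop codons held fixed. Leaf assembly applies the planned intron
complement (classes share a base sequence, lightly mutated per leaf so
class members stay similar, as orthologous introns do) and gene-order moves
(segment excision/reinsertion, optionally inverted). The manifest records
realized per-branch substitution counts, per-gene syn/nonsyn counts, leaf
orders, the intron presence matrix and the generating tree.

What the generator does not emulate: indel evolution within genes,
realistic homing-endonuclease ORF sequence content, base-composition
heterogeneity along the molecule, and rate variation across sites.
Passing planted-truth tests therefore demonstrates correctness of the
bookkeeping and estimators under a clean substitution regime, not
robustness to alignment error or compositional artefacts in real data —
for real records the replication entry point (`mitocomp.accession`)
exists precisely to check the stack against published numbers.

## Validation regimes and problem sizes

The test-suite experiments run at sizes chosen for complete desk-scale
reproducibility: 50 randomized small genomes for partition conservation;
100 random 50-codon pairs for oracle equivalence (1e-10); 200 simulated
300-codon pairs per selection regime (ω = 0.2 and 1.5, kappa = 1 so the
mutation process matches NG86's unweighted site model, pairwise divergence
~0.5 proposals per site) for sign discrimination; a 12-species star with 26
cox1 and 18 cob intron classes at ≤ 20% protein divergence from the
reference for exact Pcl recovery; 10 kb i.i.d. controls for repeat false
positives; and 50 random additive 6–10-taxon matrices plus 100 six-taxon
sequence replicates for NJ correctness and sister-pair recovery. The
`scripts/acceptance.py` entry point re-runs the same experiments end to end
from a single seed.

## Known limitations

* The reader trusts annotation: it does not re-predict genes, tRNA
  structures or intron boundaries, and reports what the record contains
  even when a record's ORF inventory is internally inconsistent.
* Reference-projection alignment in the supermatrix discards insertions
  relative to the reference row; for heavily indel-divergent real data an
  external aligner should produce the per-gene alignments instead.
* NG86 underestimates Ka/Ks somewhat when the true process has transition
  bias or when stop-adjacent mutations are forbidden in the generator but
  counted as nonsynonymous sites by convention; the selection screen is a
  screen, not a likelihood test.
* The repeat finder's ungapped extension splits long indel-containing
  repeats into separate hits rather than bridging them.
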