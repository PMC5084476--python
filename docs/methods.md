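# Methods

This note records the models, algorithms, parameter choices and known
limitations behind each module, in the order data flows through the
pipeline.

## Synthetic data: what is emulated, and what is not

All generators are pure functions of a specification object that includes
the seed, so every output is reproducible and every downstream result can
be compared with planted truth.

**Plastome.** A circular genome laid out LSC + IRb + SSC + IRa with IRa the
exact reverse complement of IRb, i.i.d. bases at a configurable GC content
(default 0.37, typical of grass plastomes). The default geometry is
82,090 / 12,572 / 22,719 bp (total 140,100), the size class of a panicoid
chloroplast genome. The single-copy bases flanking the repeat junctions are
pinned so that the maximal exact repeat ends exactly at the designed
boundaries; without this a chance complementary flank extends the true IR
by a base or two and the "partition equals truth exactly" oracle would be
ill-posed.

**Reads.** Shotgun reads of fixed length, uniform circular start positions
(reads may wrap the origin), random strand, i.i.d. substitution errors only.
No indels, chimeras or quality-score modelling: the extension algorithm
relies on exact k-mer matching, so substitutions are the error mode that
actually stresses it. Read count is ceil(coverage × genome length /
read length).

**Contig seeding.** Gaps are disjoint circular intervals with length drawn
in [min_gap, 2 min_gap); the complementary arcs become contigs, optionally
with up to `end_slop` random bases appended per end to emulate misassembled
termini (the downstream trim-100 rule removes them). Gap and contig
coordinates are recorded as truth.

**Two-copy genome.** unique_bp random bases plus a duplicated_bp block
inserted exactly twice (total = unique + 2 × duplicated), used to give the
k-mer histogram a genuine second peak.

**Leaf gradients.** Five species — by default a reference C4 Andropogoneae
(Zm), a second C4 Andropogoneae (Sb), a C4 Paniceae (Sv), a C3 Paniceae
(Do) and a C3 BEP outgroup (Os) — share one base profile per gene: a
log-normal expression level (median 8 FPKM, σ=1.2) times a smooth 4-point
shape drawn from {flat, increasing, decreasing, peaked} with amplitude
a ~ U(0.4, 1.0) applied as 1 + a(shape − 1). Amplitudes are capped at 1 so
every profile stays strictly positive (the shape library's minimum is
0.25 of the mean). Replicate noise is multiplicative log-normal with
coefficient of variation `noise_cv` (default 0.2, 3 replicates); the
log-normal is mean-corrected so the expectation equals the clean value.
Planted regulators are expressed (level median 50 FPKM, σ=0.3), carry the
full-amplitude decreasing shape — high in immature basal tissue — and are
multiplied by the effect fold on segments 3–4 only in the C4 species named
by their divergence pattern, emulating tip-ward induction recruited in the
C4 lineage(s). With noise_cv → 0 the perturbed/unperturbed segment-mean
ratio equals the fold exactly. What this does *not* emulate: mapping bias,
ortholog mis-assignment beyond clean dropout, gene families, or
between-species count-scale differences — so passing screens here shows the
selection logic is sound, not that real cross-species expression is this
well behaved.

**Alignments.** A gap-free random reference and relatives at ~10 %
divergence, with optional gap columns; diagnostic residues are planted by
reference-numbered position. **A–Ci observations** are model curves (below)
plus Gaussian noise on the default nine-pressure measurement grid
(25, 19.4, 16.6, 13.5, 7.6, 4.7, 36.7, 60.4, 140.3 Pa ≡ ×10 μbar).

## Plastome finishing

Coordinates are 0-based half-open; circular positions are reported modulo
the total length. k = 20 throughout (matching, junction support, coverage),
exposed as a parameter.

*Trimming.* Both contig ends lose 100 bp before any extension, as a guard
against misassembled termini; contigs shorter than 2×trim are refused.

*Extension.* The terminal 20-mer is looked up in a sorted-array index of
every read 20-mer (forward occurrences of the k-mer, plus forward
occurrences of its reverse complement, i.e. reads from the other strand).
Matching reads are oriented onto the contig and the bases they contribute
beyond the end are combined column-by-column: a column extends the contig
only with a strict-majority base seen in ≥ `min_support` reads (default 2).
Ties, support below the minimum, or no overhanging read stop that end with
an explicit reason. This replaces interactive alignment-editor curation
with a deterministic, testable rule; ambiguity is surfaced, never guessed.

*Gap closure.* One extension round (≤ read_len − k bases per end)
alternates with a merge sweep that joins contigs whose ends agree exactly
over ≥ k bases; every junction must also be spanned by ≥ `min_support`
reads (the k-mer centred on the junction must occur in the reads). When one
contig remains, the same overlap rule applied to its own two ends closes
the circle. If a full pass makes no progress the process stops with the
surviving contig ends listed — this is the behaviour when reads are missing
over a gap.

*Quadripartite detection.* The longest pair of disjoint, exactly
reverse-complement-identical repeats ≥ `min_ir` (default 1,000 bp) is found
by anchoring 31-mer matches between the circle and its reverse complement,
chaining anchors along anti-diagonals, and extending each candidate
base-by-base around the circle. Exact matching is appropriate because IRs
are treated as identical copies; near-identical IRs with internal
differences are out of scope. The longer single-copy arc becomes LSC, the
shorter SSC; of the two strand representations the lexicographically
smaller is emitted, making the canonical form invariant to rotation and
flipping of the input.

*Coverage QC.* Every assembly position gets the strand-canonical read count
of its 20-mer. Windows (default 500 bp) are compared with an expected level
= modal single-copy depth × mean copy multiplier over the window, where the
multiplier is 2 for positions whose k-mer lies wholly inside an IR and 1
elsewhere (k-mers straddling IR boundaries are unique, hence 1). The modal
level is the median of fully-single-copy window means. Windows off by more
than a factor of 1.75 are flagged. For reads of length L at coverage C the
expected single-copy k-mer depth is C·(L−k+1)/L (≈ 40.5 at 50×, L=100,
k=20), and IR windows sit at twice that.

## k-mer genome sizing

Counting encodes bases 2 bits each and computes forward and
reverse-complement k-mer codes in one vectorized pass per k (k ≤ 32;
defaults: 20 for plastome QC, 21 for sizing — odd k avoids palindromic
self-canonicalization); the canonical code is the minimum of the two.
Windows containing non-ACGT bases are dropped; reads are processed in
~20 Mb batches, so memory stays flat.

The estimator smooths the histogram with a width-3 moving average
(edge-padded), takes the error cutoff at the first local minimum — the
first multiplicity where the smoothed series starts rising — and locates
the smoothed mode m₀ above it. The coverage peak c is the count-weighted
mean multiplicity over the first peak's support [0.5 m₀, 1.5 m₀): 1.5× the
mode is the midpoint between the single-copy and two-copy peaks, and using
the full symmetric support keeps the relative bias of c stable when
coverage changes (a ±20 % window leaves a skew-induced bias that varies
with depth and breaks the ±1 % coverage-doubling invariance). Then
total_bp = (Σ_{m>cutoff} m·n_m)/c and single_copy_bp = Σ n_m over
multiplicities in [cutoff, 1.5 c). A histogram that only decreases is
rejected as a pure error slope. No mixture-model fitting and no
heterozygosity correction are attempted: the toolkit targets the
low-heterozygosity (selfed) case.

## Gradient expression

FPKM follows the closed form counts·10⁹/(gene length · library size).
The expressed filter keeps a gene when any sample of any replicate reaches
the threshold (default 1 FPKM). Spearman correlation uses mid-ranks (ties
averaged) — essential for FPKM matrices full of zeros. Clustering is
average linkage on 1 − correlation (the linkage is a flag; the choice is a
convention, not derived from data), and the coherence report asks, per
segment, whether its replicates form a clade before any other sample joins.
Cross-species work never compares absolute FPKM between species: only
within-species 4-stage profiles leave the module, with a match table
mapping native segment grids to comparison stages (a stage may pool several
native segments when one species' base segment spans what another resolves
into base + transition).

## The C4 screens

*Induction call* (for the carbon-shuttle enzymes): TRUE requires tip FPKM ≥
50, tip/base fold ≥ 4, and a profile non-decreasing from stage 2 onward
(10 % tolerance). High-but-flat expression — the typical C3 carbonic
anhydrase pattern — therefore does not count as C4-style induction.

*TF filter.* Stage 1 takes the photosynthesis co-expression cluster TF list
as input (it comes from prior work on the reference species; the screen
does not re-derive clusters). Stage 2 keeps TFs with reference-species mean
FPKM ≥ 4 across the four stages — profiles below that are too noisy to
compare across species. Stage 3 max-normalizes each species' profile,
averages the C3 species into a consensus (requiring the C3 profiles
mutually consistent first), and flags each C4 species whose profile
diverges from that consensus. A missing ortholog makes a species
non-comparable — recorded, never flagged; a TF whose ortholog is absent in
every other species is reported as a reference-specific candidate.

*Divergence.* The default score is 1 − Pearson r of the normalized
profiles. Two safeguards address the fact that r on 4-point profiles is
heavy-tailed under replicate noise: (i) profiles with coefficient of
variation below 0.3 are flat — they carry no usable shape — and are
compared by the scale-bounded Euclidean distance ‖p−q‖/2 instead; (ii) a
divergence flag requires both 1 − r > 0.33 *and* a material normalized
difference ‖p−q‖/2 ≥ 0.28. The thresholds were calibrated on the no-signal
synthetic dataset at the default noise level (CV 0.2, 3 replicates): they
are the loosest round values at which a 200-TF decoy panel yields zero
false flags across seeds, while planted fold-4 regulators score far above
them (≈ 0.9 decorrelation, ≈ 0.4 distance). Setting `min_effect=0`
recovers a pure single-threshold rule. These are calibration choices for a
formalized surrogate of what was originally a by-eye comparison; they are
not estimates of any published judgment.

*Lineage classes.* Flags on {reference} → reference-specific; on the
reference plus every same-clade C4 species and no other → clade-shared
(named after the reference clade, e.g. Andropogoneae-shared); on all C4
species → pan-C4; anything else → none. The map is total over all flag
combinations and reduces to the 4/3/1 pattern of interest with two
Andropogoneae and one Paniceae C4 species.

## Residue scanning

Site tables give 1-based positions in the reference's ungapped sequence,
matching mutation nomenclature (A780S = Ala at reference position 780
replaced by Ser). Positions are mapped to alignment columns through the
reference row, so inserting gap columns anywhere never changes a
classification. States are C4-like (derived set), C3-like (ancestral), gap,
or other; the summary counts C4-like sites per sequence with a configurable
signature minimum (default 1). Only the PEPC A780S example table ships with
the package: the positively selected PEPCK sites and the NADP-ME/rbcL
tables are published residue sets that users supply as TSVs — they are
literature data, not constants to re-invent.

## A–Ci models

C3 (saturating light): Ac = Vcmax(Ci − Γ\*)/(Ci + Kc(1 + O/Ko)),
Aj = Jmax(Ci − Γ\*)/(4Ci + 8Γ\*), A = min(Ac, Aj) − Rd. Kinetic constants at
25 °C: Kc = 404 μbar, Ko = 248 mbar, O = 205 mbar, Γ\* = 38.6 μbar. Defaults
Vcmax = 77 and Jmax = 144 μmol m⁻² s⁻¹ describe the C3 leaf; the C4 curve
uses Vcmax = 35 for comparable maximum rates with Vp = Vpmax·Ci/(Ci + Kp),
Vpmax = 120, Kp = 80 μbar, A = min(Vp, Vcmax) − Rd. The C4 form is
deliberately the two-regime enzyme-limited simplification — no
bundle-sheath leakiness, gbs or α — because the C4 curve serves as a
qualitative contrast (steep initial slope Vpmax/Kp = 1.5 vs ≈ 0.11 for C3;
compensation point < 1 μbar vs ≈ 46 μbar). Rd defaults to 0.01·Vcmax; it is
a declared convention, not a measured value, and the compensation point is
the quantity most sensitive to it (the closed form
(Γ\* + Km·Rd/Vcmax)/(1 − Rd/Vcmax) gives 46.4 μbar at the defaults, within
the 40–55 μbar band expected for a C3 leaf). Compensation points are found
by Brent bracketing on (0, 200 μbar) to 10⁻³ μbar and cross-checked against
the algebraic root where Rubisco limits. Classification of an observed
(Ci, A) table computes the RMSE against both fixed-parameter curves and
reports the lower; no parameters are fitted to data, by design. Ci is in
μbar throughout; Pa convert at 1 Pa = 10 μbar.

## Problem sizes and numerical conventions

The test suite and the acceptance script run the plastome oracle at the
full 140 kb geometry with 50× reads, k-mer sizing on a 1.4 Mb two-copy
genome at 50× and 100×, the TF screen at 5 species × 4 stages × 3
replicates × 1,000 genes (200 TFs, 8 planted) over 20 seeds, and 100 noisy
A–Ci simulations per model — sizes chosen so each stage completes in
seconds to a couple of minutes while leaving the estimators' asymptotics
visible. Randomness always flows from explicit integer seeds through
`numpy.random.default_rng`. Known limitations worth restating: exact-match
IR detection, substitution-only read errors, no histogram mixture
modelling, thresholds in the TF screen calibrated on synthetic data, and a
C4 photosynthesis curve that is intentionally minimal.
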