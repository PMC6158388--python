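# Methods

This note documents the models, conventions and numerical choices behind
`capskit`, in the order the pipeline runs.

## Coordinates and translation

All externally reported CDS positions are 1-based from the A of the ATG
start codon; residues are 1-based from the initiator Met, so position
*p* falls in codon ⌈*p*/3⌉ (316 → 106, 908 → 303). Translation uses the
standard genetic code and **continues through internal stop codons**,
rendering them as `*`: the gene family's pseudogene member is
frame-disrupted early, and truncating at the first stop would hide the
very feature that identifies it. Trailing bases that do not fill a codon
are ignored.

## Homolog grouping and SNP calling

**Diagnostic signatures.** The panel references are placed on the
coordinate frame of the longest member via global alignment (`edlib`);
for each group, positions are scanned in ascending order and greedily
accumulated until the set distinguishes the group from every other
member (first-position tie-break). Signatures are stored in each group's
own coordinates. Two identical references abort panel construction.

**Signature matching is alignment-free.** Clone bases at signature
positions are compared at their literal ATG-anchored coordinates. A
global aligner is deliberately *not* used here: with a handful of
clustered diagnostic mismatches next to an indel, an optimal alignment
will slide a gap into the divergent island and erase exactly the
mismatches that are diagnostic. Literal coordinates are exact for any
position upstream of an indel, which is where the panel's diagnostics
live (positions 41–46). `N` never matches a signature base.

**Assignment.** A clone goes to the unique group whose full signature it
matches; with no exact match it falls back to minimum edit distance
against the references (flagged `fallback`); ties in either path yield
`unassigned`, which is data, not an error. A sequencing error that hits
a one-position signature can bump a clone into a neighbouring group or
leave it unassigned; with ~0.3% per-base error this affects roughly one
clone per 400 and is invisible to consensus-based calling.

**Consensus and the support rule.** Per group and line, A/C/G/T counts
are tallied per position (`N` excluded); the consensus is the plurality
base, with count ties giving `N` (no SNP callable there). A SNP is
emitted where the two lines' consensuses differ **and** the variant base
is carried by at least `min_support` clones in the line carrying it.
`min_support` defaults to 6, a literal reading of "more than five
occurrences". Support is counted per line, not pooled — the lines were
sequenced and grouped independently — but a `pooled` flag is provided.
Synonymous calls are emitted and flagged; filtering them is a reporting
decision. With 40–70 clones per group and independent errors, the chance
of six identical errors at one position is negligible (binomial upper
bound ≪ 10⁻⁶ per site), which the 200-replicate specificity test
confirms empirically.

## Restriction-site scanning and the digest model

Recognition sites (IUPAC-degenerate, length ≥ 4) are matched on both
strands with overlap-aware scanning. A forward match starting at 0-based
*i* cuts after base *i* + `cut_offset`; a reverse-orientation match
mirrors the offset to *i* + *L* − `cut_offset`. Windows matching in both
orientations (palindromic sites such as `GANTC`) count once, with the
forward cut. Fragments of a linear molecule are consecutive differences
of the cut positions; their sum always equals the molecule length
(asserted on every digest). Circular molecules are out of scope.

*Limitation:* the single-offset model tracks only the top-strand nick.
Enzymes cut both strands, generally asymmetrically (HinfI `G^ANTC`
leaves a 3-nt 5′ overhang), so for non-palindromic enzymes the
reverse-site cut reported here can differ from the physical top-strand
nick by up to the overhang length. Fragment patterns used in the shipped
assays place sites in forward orientation or are palindromic, where the
model is exact; Bio.Restriction agrees exactly for HinfI in the test
suite.

## CAPS design, gel model and genotype calls

The designer is single-SNP: amplicons must be equal length and differ at
exactly one position. An enzyme yields an assay only if its digest
patterns differ between alleles **and** a recognition-site occurrence
present in exactly one allele overlaps the SNP — pattern differences not
caused by the SNP are rejected. The heterozygote pattern is the multiset
union of the homozygote patterns.

Gel rendering clusters fragments greedily in ascending order: a fragment
within `min_separation_bp` (default 30) of the previous one co-migrates
into a band reported at the cluster mean, so 58/61/80 bp collapse to one
~66 bp band while 206 vs 264 bp stay distinct — the behaviour seen on
2% agarose at this size range. Fragments under `min_visible_bp`
(default 40) are flagged as possibly running off but retained. Genotype
calling matches observed bands to the rendered expectation of each class
within `tolerance_bp` (default 30) per band, returning the unique best
match or `ambiguous`. Both thresholds are configurable; the defaults are
the loosest values that keep all three expected patterns of the shipped
assays mutually distinguishable.

Allele-specific (ARMS) primers are modelled minimally: amplification
requires an exact 3′-terminal match at the aligned template position and
at most one internal mismatch. Melting temperature is out of scope.

## Genetic-effect estimators

Given the nine F2 two-locus class means, the single-locus "phenotype
value" of genotype *g* is the **unweighted** mean of the three class
means sharing *g* (marginalizing over the other locus without weighting
by class counts). Then per locus

* A = (marginal(mut hom) − marginal(WT hom)) / 2
* D = marginal(het) − (marginal(mut hom) + marginal(WT hom)) / 2
* I = [(mean(aabb) + mean(AABB)) − (marginal(aa) + marginal(bb))] / 2

The unweighted convention is a deliberate choice: it is the only one of
the conventions we tried (count-weighted marginals, per-line pooling)
that reproduces, to the printed 0.01, the published locus-1 additive
(5.38/5.53) and both dominance values (0.95/1.07, 0.65/0.72) from the
same class-mean table. The published locus-2 additive and epistasis
values are **not** reproducible from the class means under the stated
formulas with any convention tried; `capskit` reports the
formula-literal values (e.g. A-2 = 5.55, I = −3.47 for the first site)
and attaches a warning plus a `convention_note` to every result rather
than guessing at an undocumented computation. All five effects are
invariant to class ordering and to adding a constant to every class mean
(the shifts cancel in I as written).

BC1 tables lack the mutant homozygote classes, so A and I are undefined
there and the estimator refuses rather than imputing. Sample SD (n−1) is
assumed for all "±" summaries. The marginal allele contrast (e.g. aa vs
AA, +10.77 points of oleic in the first site's table) uses the same
convention, with a seeded within-class bootstrap (2,000 resamples) for
its 95% CI.

ANOVA is the classical one-way F test; the letter display runs Tukey HSD
(α = 0.05, Tukey–Kramer for unequal n) followed by the standard
insert-and-absorb algorithm, letters assigned in ascending order of
class mean. Degenerate all-identical input returns F = 0, p = 1.
Segregation is tested with Pearson chi-square against the Mendelian
ratio (df = classes − 1).

## Synthetic data: what it emulates, and what it does not

**Reference panel.** Four ~1,155-bp CDS-like sequences sharing >99%
identity, differing in a distinct 6-mer at positions 41–46, with C/C
markers at 732/735 on the second member; the third member carries a
15-bp deletion and a premature stop near position 164 (the pseudogene).
Conserved positions 313–318 spell `CACGAG` (His105-Glu106 of the first
histidine box, and a BssSI site) and 907–912 spell `GGATTC` (a HinfI
site), so the planted G316A/G908A reproduce E106K/G303E and each
destroys its site. Background codons are drawn stop-free under the seed.

**Clone libraries.** Group sizes default to 48/45/40/73 (mutant line,
206 clones) and 55/50/44/62 (wild type, 211); per-base substitution
error defaults to 0.003, an envelope for residual error after the
both-directions sequencing QC that the generator assumes has already
happened upstream. Errors are i.i.d. substitutions; chimeric PCR
products, indel errors and chromatogram-level artefacts are not
modelled, so passing tests bound performance under clean-library
conditions only.

**Amplicon fixtures.** A 731-bp pair with one BssSI site placed so the
wild type digests to [295, 436] and the mutant is uncut, and a 405-bp
pair with three HinfI sites giving [61, 80, 58, 206] wild type and
[61, 80, 264] mutant. The true amplicon sequences are not public;
fragment arithmetic, not genomic sequence, is the testable surface, so
backgrounds are rejection-sampled until neither enzyme has any
unintended site in either allele.

**Populations.** Genotypes segregate 1:2:1 per locus in the F2 and 1:1
in the BC1 (backcross to the wild-type parent, so only the four
AABB/AABb/AaBB/AaBb classes appear). The loci sit on different
chromosomes; a recombination-fraction parameter exists but defaults to
0.5 (unlinked). Oleic acid is `mu0` plus per-locus contributions
{0, a+d, 2a} for WT hom/het/mut hom, an epistasis term reaching `i` in
the double mutant, and N(0, σ²) noise — a parameterization chosen so the
class-mean estimators recover `a` and `d` exactly in expectation under
balanced classes. Defaults (`mu0` = 63.1, a₁ = 5.38, d₁ = 0.95,
a₂ = 5.55, d₂ = 0.65, i = 0, σ = 2.0, n = 232) are anchored to the
first field site's class table; the implied double-mutant mean is
63.1 + 2a₁ + 2a₂ = 84.96, consistent with the observed ~85%. The oleic
gain is drained from linoleic/linolenic in a 0.72/0.28 split
(approximating the observed trade-off across the class table), floored
at 0.5%; palmitic, stearic and oil content are genotype-independent
normals around parental values. Values are rounded to 0.01% (GC
precision) and the five-component sum is confined to [90, 100] —
trimming the polyunsaturated pool first — so every generated row
satisfies the profile invariants; maternal effects, environment × 
genotype interaction and half-seed assay error are not modelled.

**Determinism.** Every generator consumes a single `numpy` Generator
seeded from its config; identical seeds give byte-identical outputs.

## Problem sizes in the test suite

The stochastic suites run 200 replicates of the default clone libraries
(417 clones × ~1.2 kb each) for caller sensitivity/specificity, 200
simulated F2 populations of n = 300 for estimator recovery (3-SE
criterion) and segregation calibration, 1,000 random sequence/enzyme
pairs (lengths 50–2,000) against the brute-force scanner, and 50 random
fixtures against the brute-force studentized-range Tukey oracle. The
full suite completes in about a minute on one core.

## Known limitations

* Assignment trusts one verified sequence per clone; bidirectional read
  reconciliation happens upstream.
* The caller reports substitutions only; indel variants between lines
  are out of scope (clones whose length differs from their group
  reference are excluded from consensus with a report).
* The gel model is geometric (lengths only); band intensity, partial
  digestion and dCAPS mismatch-primer design are not modelled.
* The epistasis estimate is convention-sensitive and should be compared
  across studies only together with its `convention_note`.
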