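# Methods

`symbioscreen` implements the computational core of a bacteriocyte
transcriptomics study design: one RNA-seq library from dissected
bacteriocytes and one from whole insects, differential expression between
them, a homology-based screen for host genes of bacterial origin
(horizontally transferred genes, HTGs), and a reaction-level account of how
metabolic pathways are split between the host and its co-resident symbionts
(a primary symbiont with a heavily decayed genome, here *Portiera*, and a
secondary symbiont, here *Hamiltonella*). This note documents the models,
the parameters that matter, the numerical choices, and what the synthetic
data can and cannot show.

## Two-library differential expression

**Quantification.** FPKM_i = x_i · 10⁹ / (L_i · N), with x_i the fragment
count of transcript i, L_i its length in bp and N the library total. When
two assemblies are compared, ortholog pairs are first selected from a
MegaBLAST-style hit table (percent identity > 99, alignment length ≥ 200 bp,
best hit per query by bitscore, ties broken by E-value then subject id) and
the aligned region is clipped out of both transcripts; `clip_overlap`
returns the retained intervals and lengths so FPKM can be computed on the
clipped regions. Read mapping itself is out of scope: the package takes
counts-on-retained-regions as input.

**The tag-count test.** With a single library per condition the appropriate
test is the Audic–Claverie conditional statistic. Given x fragments at
depth N₁, the count y at depth N₂ has, under a common Poisson rate with a
flat prior,

    p(y | x) = (N₂/N₁)^y · (x+y)! / ( x! · y! · (1 + N₂/N₁)^(x+y+1) ),

a negative-binomial in y. The two-sided p-value is
min(1, 2·min(Σ_{k≤y} p(k|x), Σ_{k≥y} p(k|x))), with both tails inclusive of
the observed y.

*Numerics.* Terms are accumulated in log-gamma space. The upper tail is
evaluated as the complement 1 − Σ_{k<y} only while that is well-conditioned
(complement > 0.5); otherwise it is summed directly upward from k = y, which
converges geometrically (successive-term ratio → r/(1+r), r = N₂/N₁). The
complement-only form loses relative precision on small tails (≈1e−7 at
x=0, y=30); with the direct summation the implementation agrees with an
arbitrary-precision oracle to < 1e−13 relative over (x, y) ∈ [0,30]².

*Near-symmetry.* Because both tails include the observed point, swapping
(x, N₁) with (y, N₂) shifts the tails by exactly one pmf term, so the two
p-values agree only to within 2·p(y|x) (they coincide where that term is
negligible). This is a property of the inclusive-tail convention, which was
kept because it reproduces the closed-form benchmark p = 2⁻¹⁹ at
(x=0, y=20, N₁=N₂); a mid-p convention would be exactly symmetric but
changes that value.

**Calling.** p-values are Benjamini–Hochberg adjusted (delegated to
`statsmodels`; the method name is configurable) and a transcript is called
enriched/depleted when q < 0.001 and |log₂(FPKM₁/FPKM₂)| ≥ 1, both
thresholds configurable and defaulting to the published values. The log₂
ratio uses no pseudocount by default (the published fold changes reproduce
exactly from the printed FPKM pairs without one); transcripts with one zero
count get a signed infinite ratio, both-zero transcripts 0.

**Caveat: overdispersion.** The statistic models Poisson sampling of a
fixed transcriptome. If true biological replicates vary (negative-binomial
counts), the test is anticonservative: at mean 200 and NB size 10, ~13% of
null transcripts show |log₂ ratio| ≥ 1 with tiny p-values, and the
`analysis/02` driver shows exactly this on the generator's default
conditions. Type-I error control is therefore verified under the test's own
Poisson null (the generator's `dispersion=None` mode); the NB default
exists precisely to expose this limitation, which applies equally to any
single-library two-sample design.

## The HTG screen

For each transcript with at least one prokaryote (Bacteria ∪ Archaea)
protein hit, the screen computes h = B_prok − B_euk (best-hit bitscores;
a missing eukaryote hit contributes B_euk = 0 and E_euk = 1, maximising h as
the index intends) and ln(E_prok/E_euk) with E-values floored at 1e−180 so
tool-reported zeros stay finite. Retention requires FPKM > 1, no hit
lineage matching the resident symbionts, no blacklisted environmental
lineage (defaults: Lachnospiraceae, *Wallemia sebi*, *Sorangium
cellulosum*; user-extensible — the original step was manual curation), a
bacterial top hit with percent identity > 40 ("identity" is taken as
percent identity), and the three score gates h ≥ 30, B_prok ≥ 100,
ln E-ratio < −9. A functional whitelist (default bioA, bioB — biotin genes
known as HTGs in a related symbiosis) rescues candidates failing the score
gates as a unit; the per-gate flags are still recorded, so reports show
which gate failed. Hits with E > 1e−10 (the searches' reporting cutoff) are
treated as absent; the cutoff is configurable (`max_evalue_for_hit`).

Downstream checks are annotation-driven: divergence from the symbiont
homolog passes at amino-acid identity < 50% (strict), and presence calls
across related species' transcriptomes date a transfer as ancient (present
in the outgroup species), complex-wide (present in ≥ 2 non-outgroup
datasets) or recent. Genome localisation (scaffolds, flanking genes,
introns) is consumed as an annotation table, not computed, since it needs
genome assemblies.

## Pathway complementation

Each reaction of a pathway lists its gene options tagged by origin
(primary symbiont, secondary symbiont, host-insect, host-HTG). A symbiont
gene provides its reaction iff intact — pseudogenes never provide; genes
judged *en route* to pseudogenisation are encoded intact with an
`expression_reduced` flag, since the pathway maps keep them. A host gene
provides iff its transcript is bacteriocyte-enriched or flagged abundant
(mirroring the "+" convention of the published cross-symbiosis matrix; this
is why bioB, expressed but not enriched, still provides). Provider classes
follow a total precedence: unfilled → symbiont_only → shared_symbiont_pair
→ host_complement (insect vs HTG, by the host provider's origin; insect
takes precedence when both origins provide) → duplicated (host provider
beside an intact symbiont gene). A pathway is complete iff no reaction is
unfilled. The cofactor audit runs completeness per cofactor pathway and
reports the providing organism, `joint(symbiont, host)` when a reaction is
filled by host genes alone, or `gap`. FMN and FADH are encoded as separate
cofactor classes to reach the stated eight (the source enumerates seven
items with FMN/FADH printed as one).

Transcription ambiguities in the packaged fixtures are recorded in the
fixtures' own metadata rather than resolved: the stated-12 vs enumerated-7
missing EAA genes; the mealybug matrix row printing ten symbols for eleven
columns (argABCDE and PCD transcribed as "?", PRODH as the blank); the
cross-symbiosis HTG-function fixture, which encodes only the text-supported
memberships and is labelled synthetic in its filename — uniqueness
fractions computed from it describe the fixture, not the full published
four-way comparison (whose per-symbiosis HTG complements are not printed in
the main text).

## qPCR arithmetic

Amplification efficiency comes from an ordinary least-squares fit of Ct on
log₁₀ template quantity: E = 10^(−1/slope) − 1, so a perfect doubling assay
has slope −log₂10 ≈ −3.3219 and E = 1. Relative expression uses
2^(−ΔΔCt) with ΔCt = Ct_target − Ct_reference per condition; results are
reported per reference gene (no geometric-mean pooling, matching the
published presentation with RPL7 and RPL13 reported separately) as
mean ± SE of the log₂-transformed value over biological replicates, with
SE = sd/√n. Within-pathway abundance uses 2^(−ΔCt). No raw Ct values are
printed in the source, so validation of this module is property-based.

## Synthetic data

The count generator emulates the two-library design at desk scale:
library depths 524,000 / 518,000 (the published 52.4M / 51.8M fragment
totals at 1:100 — chosen so the full suite runs in seconds on one CPU while
keeping per-transcript counts in the hundreds), 2,000 transcripts of
300–3,000 bp, mean count 260 (expected totals ≈ depths), 10% enriched and
10% depleted transcripts at log₂ effect 2, negative-binomial size 10.
Truth labels are assigned by deterministic index blocks before sampling, so
class fractions are exact. `dispersion=None` selects Poisson sampling, the
test's own null. Expected library totals exceed the nominal depth by the
mass the fold changes add (they are not renormalised), which keeps null
transcripts exactly calibrated to the nominal depth ratio.

The hit-table generator plants HTGs that clear every gate by a
configurable bitscore margin and three decoy classes: ordinary insect genes
(eukaryote best hit above the prokaryote one), symbiont transcripts
(lineages matching the resident symbionts) and environmental contaminants
(blacklisted lineages); symbiont and contaminant decoys pass the score
gates so that exactly the lineage filter rejects them. Simulated E-values
derive from bitscores as E = 10⁹·2^(−B), making the bitscore and E-ratio
gates mutually consistent. With a positive margin the screen recovers
exactly the planted set on every seed (tested across 20).

What passing on this synthetic surface does **not** show: recovery of the
published genome-scale outcomes (7,900 differentially expressed transcripts
against the real libraries, phylogenetic donor assignment of each HTG) —
those need the deposited reads and the full protein database, and the
published per-gene fold changes are instead verified arithmetically from
the printed FPKM table. The generator simulates summary records, not reads
or sequences; assembly artefacts, mapping ambiguity and contamination
structure of real libraries are outside its scope.

## Problem sizes and determinism

Default verification sizes: the oracle comparison runs the full
(x, y) ∈ [0,30]² grid; type-I error uses 50,000 Poisson null transcripts;
sensitivity uses 2,000 NB transcripts with log₂ effect 3 at mean 200;
screening fixtures use 10 planted genes and 50 decoys. Every stochastic
stage draws from a single seed (sub-seeds derived via `SeedSequence`), and
identical configuration + seed reproduces byte-identical outputs; each
output file carries a provenance line with the package version, a hash of
the analysis-relevant configuration (output paths excluded) and the seed.
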