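# Methods

This note documents the models and numerical choices behind
`displaymap`: what each stage assumes, which parameters matter, what
the simulator does and does not emulate, and where the design was
genuinely open.

## The measurement model

Display-based epitope mapping reads out binding loss through selection.
A mutagenized antigen library is displayed on yeast; FACS keeps cells
that are antigen-positive (the construct is intact and displayed) but
antibody-negative (binding is lost). Substitutions that abolish binding
are overwhelmingly located at the antibody footprint, so after
selection the per-position amino-acid mutation frequency is strongly
elevated at epitope positions relative to everywhere else. The
analysis therefore needs four things: per-position mutation
frequencies per library, a between-library normalization, a calling
rule, and a structural plausibility filter.

### Counting (read level)

Fragment reads cannot be phased back to clones, so the read is the
sampling unit: `f_i = k_i / n_i`, where `n_i` counts accepted reads
that fully cover codon `i` with no ambiguous base and `k_i` those whose
codon translates to a different amino acid than the reference.
Synonymous changes are not mutations at this level; stop gains are.
Multiple substitutions on one read count independently at each
position. This per-read frequency is the only estimator available from
fragment data, and it is what downstream normalization operates on.

Alignment is by exact k-mer anchor (default k = 21, scanning anchors
left to right until one matches the ORF uniquely) plus ungapped
extension. Reads with no unique anchor, or more than `max_mismatch`
(default 10 per 150-nt read) differences, are rejected and counted by
reason. Indels are out of scope: error-prone PCR substitution loads
dominate, an indel-containing read fails the mismatch budget, and the
simulator emits none. Positions covered by fewer than `min_coverage`
(default 20) reads are flagged and excluded from scoring.

### Normalization and calling

Size factors use the median-of-ratios construction on frequencies:
over positions with strictly positive frequency in every library, the
per-position geometric mean across libraries is the pseudo-reference
and `s_j` is the median of a library's ratios to it. Positions with a
zero anywhere are excluded from the size-factor computation (their
geometric mean vanishes) but are still scored; a pseudocount is
available as a config option and defaults to 0. The median of an even
number of values is the mean of the two central values throughout.

Calling uses the within-sample median as baseline:
`e_ij = log2(f̃_ij / median_i′ f̃_i′j)`, with calls at `e ≥ 2`
inclusive. Zero frequencies score −∞ and can never be called. The
wording of the underlying rule admits a second reading — enrichment
against the unselected reference — so that ratio (`ref_delta`) is
computed and reported per position, and the run log records the
discrepancy set between the two readings, but it does not participate
in calling. A consequence of the within-sample baseline worth noting:
`e` is invariant to rescaling any library, so the size factors do not
change which positions are called; they matter for the reported
normalized frequencies and the reference deltas.

### Structural filter

A called position is removed when it is disulfide-bonded or buried:

- SASA by Shrake–Rupley sphere sampling, probe 1.4 Å, 960 lattice
  points per atom, van der Waals radii C 1.70 / N 1.55 / O 1.52 /
  S 1.80 / P 1.80 Å (fallback 1.70). Each atom is evaluated under two
  fixed rotations of the golden-spiral lattice; this suppresses the
  aliasing the deterministic lattice shows at occlusion boundaries and
  brings per-residue convergence (960 → 1920 points) under 1% on the
  bundled fixtures. Hydrogens and waters are dropped; the first model
  is kept; altlocs resolve by highest occupancy, then alphabetical id.
- RSA = SASA / max-ASA using the Tien et al. (2013) *theoretical*
  maxima; buried means RSA < 0.15. No burial threshold or reference
  scale is canonical, so both are configurable and every excluded
  position carries its reason in the output.
- Disulfides: CYS SG–SG pairs at ≤ 2.3 Å (canonical bond ≈ 2.05 Å),
  matched nearest-first so each SG bonds at most once.
- Construct-to-structure numbering: identity when author numbering and
  sequence already agree, otherwise the single best ungapped offset,
  requiring ≥ 90% identity over the overlap. Positions without a
  mapped, annotated residue are kept but flagged `unfiltered`
  (configurable to drop): an absent annotation is not evidence of
  burial.

A precomputed `(position, rsa, disulfide)` TSV can replace the
structure entirely, which is how the simulated pipeline runs without
any coordinate download.

## The simulator

The generator emulates, at desk scale: error-prone PCR at a low rate
(per-clone substitution count Poisson with mean `lambda_nt`, default 2
across a 333-nt ORF — typical of low-rate error-prone protocols;
positions uniform without replacement, alternative base uniform), FACS
selection (default 2 rounds), and tagmentation-style fragment
sequencing (fixed 150-nt reads at uniform forward-strand offsets
within the ORF, iid substitution errors at 0.001/base, constant
quality, read count = coverage × ORF length / read length).

Selection is a per-clone Bernoulli gate: clones containing a stop
codon are never captured (they do not display antigen); a displayed
clone is binding-loss if any of its amino-acid substitutions at an
epitope position registers an effect, with probability `q_effect`
(default 0.8) drawn once and held fixed — the phenotype is a property
of the genotype, not re-rolled per round. Binding-loss clones are
captured with `p_hit` (default 0.9), everything else with `p_bg`
(default 0.005, gate leakage), and each round resamples with
replacement to a fixed population size, modeling regrowth. A round
that captures nothing raises a "selection extinguished" error rather
than silently returning an empty pool.

The default scenario plants five epitope positions on a synthetic
111-residue construct numbered 22–132 (an IgV-domain span; the
sequence is an explicitly synthetic stand-in, not a real protein).
The simulated structural annotation marks the construct's two
cysteines (38, 45) as a disulfide pair and assigns exposed positions
RSA ~ U(0.2, 0.9); decoy positions — cysteine 45 and a designated
buried position — can be added to the selection so that they enrich
like true epitope residues and must be removed by the filter, which is
exactly the failure mode the structural exclusion exists for (a
substitution that breaks a disulfide unfolds the antigen and abolishes
binding without being part of the epitope).

What the simulator does **not** model: PCR amplification bias, codon
bias of the mutagenesis kit, indels, display-level expression
variation, paired-end or reverse-strand reads, and quality-score
structure. Passing end-to-end tests therefore demonstrates that the
analysis recovers planted signal under idealized sampling noise, not
robustness to those artifacts.

## Reproducibility

Every stochastic step takes an explicit seed. A pipeline run fans its
single seed out through `numpy.random.SeedSequence([seed, stage_id])`
with fixed stage ids (mutagenesis 1, selection 2, sequencing 3/4,
annotation 5), so each stage is independently reproducible and two
runs with the same config are byte-identical. Output TSVs carry
parameters in `#` header lines and contain no timestamps.

## Scale of the shipped experiments

Tests and the acceptance script run the reference scenario at 50,000
clones and 200× coverage (444 reads of 150 nt per library on the
333-nt ORF), ten independent seeds — sized so a full from-scratch
evaluation completes in well under a minute per run on one CPU while
keeping epitope-position frequencies (~0.15–0.2) an order of magnitude
above background (~0.01).

## Known limitations

- With 444 reads per library, codons within ~7 positions of either ORF
  end are covered by only ~20–150 reads (a read must fully contain the
  codon, and fragments are confined to the ORF). At those depths the
  4×-median call threshold corresponds to only a handful of mutant
  reads, and occasional false calls at edge positions are expected;
  they dominate the residual false-discovery rate of the simulated
  scenario. Real experiments with deeper sequencing do not share this
  edge effect, and raising `min_coverage` trades edge coverage for
  specificity.
- The burial threshold (RSA < 0.15), max-ASA scale, and disulfide
  cutoff are field conventions, not derived quantities; exclusions are
  annotated so users can audit which calls depend on them.
- Ungapped alignment means any indel-containing read is discarded, not
  realigned.
- The within-sample median baseline assumes mutations at most
  positions are selectively neutral; an antibody whose epitope covered
  a large fraction of all positions would shift the median and
  compress scores.
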