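# Methods

## The typing model

The centromeric KIR region is modelled as two diploid loci plus a linked
marker and a flag:

* one locus carries exactly two alleles drawn from *KIR2DL2* ∪ *KIR2DL3*
  (the two genes are allelic), so n(2DL2) + n(2DL3) = 2;
* each haplotype carries either a *KIR2DL1* allele together with
  non-variant *KIR3DP1*, or no *KIR2DL1* together with the exon-2-bearing
  *KIR3DP1V* variant, so n(2DL1) + n(3DP1V) = 2;
* *KIR2DS2* presence is carried as a per-sample flag (the kit has no
  2DS2 reactions; the flag only feeds the population-genetic analyses).

A genotype call is therefore a multiset of ≤2 *KIR2DL1* alleles, a
multiset of exactly 2 *KIR2DL2/L3* alleles, and the implied 3DP1V count.
Extra gene copies (reported in ~1–2% of individuals) are outside the
model: a sample carrying one produces either a no-call or a wrong diploid
call, and resolving it needs quantitative PCR, not a gel.

## ARMS amplification prediction

A primer binding site is scored by scanning both strands (a reverse
primer's site is the reverse complement of a plus-strand interval).
Sites are *refractory* — bound but non-productive — unless:

* the 3′-terminal base matches exactly (`k_terminal = 1`; this is the
  ARMS discrimination and is absolute by default);
* at most 1 mismatch occurs in the 5 bases 5′ of the terminal block
  (`max_3prime_window_mismatches = 1`): ARMS primers routinely carry a
  deliberate destabilizing penultimate mismatch that must not abolish
  the intended product;
* at most 3 mismatches occur over the whole footprint
  (`max_total_mismatches = 3`), an empirical bound on promiscuous
  annealing at a stringent (63 °C single-condition multiplex) anneal.

All three are exposed in `ArmsPolicy` (YAML-configurable). IUPAC codes in
templates match a primer base when the code's base set contains it (N
matches everything). A product forms for every convergent non-refractory
forward/reverse site pair, counted 5′ end to 5′ end inclusive (both primer
footprints included — the standard product definition), capped at
`max_amplicon_len = 5000` (the kit's largest product is 2322 bp).
Relaxing any policy bound can only add predicted products, never remove
one (tested as a monotonicity property).

The "Nucleotide targeted" coordinate of each kit primer is interpreted as
the 1-based position, on that gene's reference accession, of the template
base paired with the primer's 3′-terminal base; this interpretation
reproduces the published product size for 27 of the 29 reactions exactly.
The two exceptions (2DL3 reaction 3 and 2DL2 reaction 4, each 1 bp off)
are carried as explicit `position_offset` entries in the primer table
rather than silently corrected, so the published numbers remain visible.

## Knowledge base: curated and simulated

The pattern matrix (allele × reaction expected-amplification booleans) can
be built by in silico PCR from allele sequences, from a curated table, or
both — curated cells override simulated ones with per-cell provenance.
The packaged curated matrices and subgroup tables are *reconstructions*
(files named `*_synthetic.tsv`): they are built to satisfy the published
panel structure — six/three/four main-reaction subgroups for
*KIR2DL1/L2/L3*, full-panel resolvable classes
{G\*001, G\*002, G\*003, G\*004, G\*012, \*006, \*008, \*010, \*011, \*020},
{G\*001, G\*003, G\*005, \*004, \*006, \*009} and
{G\*001, G\*002, G\*005, \*003, \*006, \*009, \*010, \*014, \*015, \*017,
\*018}, with the G\*012-internal ambiguity irreducible — but the
individual matrix cells are this package's own consistent choice, not a
transcription of gel interpretation guides. An acceptance check
synthesizes allele sequences realizing each curated table and re-derives
it through the ARMS engine, demonstrating the panel structure is
realizable as actual primer chemistry.

## Interpretation

Band semantics are union-only: a reaction is expected positive iff ≥1
carried allele amplifies (gels are not quantitative; dosage information
enters only through the 3DP1V and 2DL2/2DL3 copy-number identities).
Interpretation enumerates every model-permitted genotype over the KB and
keeps those whose expected pattern equals the observation on all *valid*
reactions; a reaction whose multiplexed 813 bp control band failed is
excluded from the comparison (uninterpretable), never treated as negative.
Candidates are ordered lexicographically. Ambiguity classes (≥2 genotypes
sharing one expected pattern) are labelled deterministically with the
footnote-style symbols `*`, `#`, `$`, `&` in order of their smallest
genotype. Supplemental-reaction recommendation is an exhaustive search for
the smallest set of unrun reactions whose expected patterns pairwise
separate the candidates, lexicographic on ties; an empty recommendation
marks irreducible ambiguity. Genotypes are enumerated over KB alleles
only — an observation no KB genotype explains is reported as a no-call
rather than hypothesizing unknown alleles.

## Linkage disequilibrium

Two estimation routes:

* **Phenotype route** (carrier/non-carrier 2×2 table, HWE): absence
  haplotype frequencies by square roots of phenotype frequencies,
  p̂₀ₐ = √((c+d)/N), ĥ₀₀ = √(d/N), D̂ = ĥ₀₀ − p̂₀ₐp̂₀ᵦ, with Lewontin
  normalization of D̂ against its margin-dependent bounds. Significance
  uses χ² = 4N·D̂²/((1−p̂₀ₐ²)(1−p̂₀ᵦ²)), df 1: the denominator is the
  delta-method null variance of D̂, which makes the statistic
  asymptotically identical to Pearson's 2×2 phenotype χ² and empirically
  calibrated (measured type-I error ≈ 4–6% at α = 0.05, n = 200). A
  simpler form that divides by p̂₀ₐ(1−p̂₀ₐ)p̂₀ᵦ(1−p̂₀ᵦ) overstates χ²
  severely (measured type-I ≈ 12%) and is not used. Degenerate margins
  (an allele carried by everyone or no one) yield NaN statistics and a
  non-computable flag; the pairwise cohort matrix applies Bonferroni
  correction over computable cross-locus pairs.
* **EM route** (allele-level unphased genotypes): haplotypes are
  (2DL1-or-absence, 2DL2/L3 allele, 2DS2 flag); each sample's compatible
  unordered haplotype pairs are enumerated from the copy-number
  identities, and standard EM maximizes the HWE likelihood.
  Initialization is the deterministic product of marginal component
  frequencies; convergence when the largest frequency change < 1e-8
  (max 10 000 iterations); the log-likelihood trace is exposed and is
  non-decreasing by construction. On fully phase-certain cohorts the
  estimate equals direct haplotype counting exactly; note the 2DS2
  *presence* flag is never phase-certain (one vs two copies are
  indistinguishable), so that exactness statement applies to
  2DS2-negative data.

## Phylogeny and subgroups

Distances are uncorrected p-distances on pre-aligned protein sequences
(gapped columns excluded; no internal MSA — alignments are inputs).
Neighbor joining is the standard Saitou–Nei agglomeration with two
determinism rules: Q-criterion ties join the pair with the
lexicographically smallest (contained-leaf) key, and negative branch
lengths are clamped to zero. Curated subgroup labels are authoritative;
the nearest-seed rule (tree path distance to one designated seed allele
per subgroup, ties to the smallest group label) covers new or
low-frequency alleles only.

## Pedigree checking

A child is Mendelian-consistent iff some phase resolution of its
(2DL1, 2DL2/L3) genotype splits into one haplotype available from the
father's resolutions and one from the mother's; the search is exhaustive
(resolutions per individual are at most 2 × 2 under the model, so this is
cheap), and a unique paternal/maternal assignment is reported when it
exists. 2DS2 participates only through the necessary condition that a
positive child have a positive parent. Consanguinity is allowed; children
with an ungenotyped parent are skipped with notice.

## Synthetic data as study conditions

The generator emulates the kit's designed discrimination: all alleles of
a synthetic gene share a random backbone (length ≥ 40 per reaction so
primer sites cannot collide; a post-hoc round-trip through the ARMS
engine enforces this and raises on collision), and reaction *j*'s forward
primer ends on SNP position *j*, which carries the primer base exactly in
the alleles designated positive. Cohorts draw two i.i.d. haplotypes per
sample (HWE, random mating) from a frequency table; pedigrees transmit
one uniformly chosen haplotype per parent, with optional logged de novo
injections restricted to leaf children (an injection into a mid-pedigree
parent would corrupt already-drawn descendants). Band noise is
independent Bernoulli dropout / false-band / control-failure per band.
All generators are bit-reproducible given (design, seed).

The packaged default haplotype table (`DEFAULT_HAPLOTYPE_FREQS`) encodes
the study conditions for cohort-level checks: seven common centromeric
combinations — three cen-A (*KIR2DL1* + *KIR2DL3* + *KIR3DP1*) and four
cen-B — carrying 0.98 haplotype mass (≈96% of diploid genotypes composed
of the seven alone), including a rare *KIR2DL1\*004/KIR2DL2\*006*,
2DS2-negative haplotype at 0.012 (≈2.3% carriers). The exact values are
this package's synthetic defaults, chosen once to mirror that structure.

What the simulations deliberately omit: sequence evolution and
recombination within the block, cross-gene primer binding on real
paralogous sequence, quantitative band intensity, gel-reading error
structure beyond independent flips, and >2 gene copies. Passing tests
therefore demonstrate the *logic* of the kit — discrimination, copy-number
identities, estimator calibration — on data satisfying the model's
assumptions, not robustness to real-template artefacts.

## Problem sizes and numerical choices

Stochastic checks use: 1000 simulated cohorts of n = 200 for χ²
calibration; 100 000 / 200 000 / 600 000 multinomial replicates at
n = 100/1000/10000 for D̂ bias decay (replicate counts sized so Monte-Carlo
error is well below the O(1/n) bias being measured); 20 seeds × 50 samples
for zero-noise full-loop recovery; 50 random 8–16-leaf trees for NJ
topology recovery; 100 + 100 three-generation families for pedigree
false-positive and de novo detection rates. Floating-point guards:
EM frequencies floored at 1e-12 at initialization only; frequency-sum
tolerance 1e-9; NJ tie tolerance 1e-12 on the Q-criterion.

## Known limitations

* Diploid copy numbers are fixed by the model; triplicated regions are
  out of scope (no-call, by design).
* The curated KB is a published-structure-consistent reconstruction, not
  a figure transcription; users with the original interpretation guides
  can drop in replacement TSVs with the same column layout.
* The phenotype LD estimator assumes HWE; departures bias D̂ in ways the
  EM route (which models genotypes) partially avoids.
* Ambiguity-class symbols are deterministic labels of discovered classes,
  not identifiers matched to any external document.
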