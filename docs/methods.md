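# Methods

## Setting and model

An F1 progeny of two heterozygous, phase-unknown parents segregates, at
every site heterozygous in exactly one parent (a testcross site, TC-SNP),
1:1 for that parent's two homologous chromosomes. Within a phased
haplotype block the parent's two homologs are known site by site, so each
progeny individual inherits, per block, either homolog 0 or homolog 1 —
a two-state latent variable observed only through sparse, noisy
low-coverage calls. `lowmap` estimates that latent homolog per
(individual, block) and uses the accepted calls as backcross-style
markers for linkage mapping and scaffold anchoring.

### Observation model

Calls over one block and segregating phase form a string
X = (X₁ … Xₙ) ∈ {S, N, M}ⁿ with per-site read depths d: S — the
segregating allele was observed; N — a called genotype showing only the
constant allele; M — no data. The hidden path Z ∈ {H, N}ⁿ follows a
two-state Markov chain with switch probability T per site step and a
uniform initial distribution (the 1:1 segregation expectation).

Emissions, with depth d at the site:

| observation | state H (carrier)        | state N (non-carrier)    |
|-------------|--------------------------|--------------------------|
| S           | 1 − q_d                  | min(1, E_het + c_d)      |
| N           | q_d = min(1, 0.5^d + E_hom) | 1 − min(1, E_het + c_d) |
| M           | 1                        | 1                        |

The carrier is *heterozygous* at a TC site (segregating allele on one
homolog, the homozygous parent's constant allele on the other), so a
depth-d pile-up samples only the constant allele with probability 0.5^d.
This allele-dropout term is the dominant noise source at 0.5–1× and is
what makes per-site genotypes uninformative there; omitting it (a
depth-free P(N|H) = E_hom) makes carriers decode confidently as
non-carriers at depth 1 and collapses imputation accuracy to ~2/3, so the
depth-aware form is the default (`allele_dropout=True` on `HMMParams`;
the depth-free variant remains available and is used for symmetric-
parameterisation property tests). E_hom then covers genuine miscalls of
the constant allele on top of dropout.

On the non-carrier side, false S observations arise from read miscalls
(E_het) and from multi-mapping reads depositing the segregating allele at
the wrong locus (factor C). Two forms of the multi-mapping term are
provided: a constant c_d = C (default — the simplest reading of a fixed
C), and c_d = C·(1 − e^(−d)), the probability that a Poisson-depth
pile-up contains at least one mis-mapped read (`c_mode='poisson_depth'`).

### Decoding and acceptance

A vectorised Viterbi pass (two best partial paths kept per state and
step, which yields the exact global top-2) returns the best path Z*, the
second-best path Z², and LOD = log₁₀ P(Z*, X) − log₁₀ P(Z², X). A block
call is produced only when all of:

* at least `min_obs_len` = 6 non-missing observations (M symbols emit
  probability 1 in both states and carry no information, but still count
  as transition steps — immaterial at T = 1e-8);
* LOD ≥ `min_lod` = 2 (ambiguous decodes are rejected);
* the path is reduced to a single state by trimming: at each transition
  the two adjacent constant-state segments are compared by non-missing
  observation count (length) and by non-missing observations per bp
  (SNP density); if length ratio ≤ 0.2 **or** density ratio ≤ 0.2, the
  shorter (sparser, on a length tie) segment is reassigned to the other
  state, iterating to a fixed point. Any surviving transition rejects
  the call — one haplotype block yields one genotype.

Exact score ties in the decoder are broken toward fewer transitions, then
toward state H; they occur only for degenerate (e.g. all-M or perfectly
balanced) strings.

The transition default is T = 1e-8. (Its printed source is typographically
ambiguous between 1e-7 and 1e-8; at block scale both are far below one
expected switch per block and the choice is immaterial — the value is
taken as 1e-8 throughout.)

### Phase merging

Phase-0 and phase-1 strings of one block observe the same inheritance
through complementary site sets: carrier-of-homolog-0 is state H on the
phase-0 string and state N on the phase-1 string. `to_homolog` applies
that inversion, then per block: a phase type is eligible if ≤ 30% of
individuals are missing; with two eligible types, consensus merging
requires ≥ 50% agreement over the individuals called in both (an empty
overlap is treated as vacuous agreement), agreeing individuals keep the
shared homolog with the higher LOD, conflicting individuals take the
higher-LOD call, one-sided individuals take their only call. Below the
consensus threshold the types are not merged and the type with the higher
mean LOD passes through alone — the 0.50 value is specified only as the
gate for *initiating* consensus, so a documented fallback was needed.
With no eligible type the block is uncalled.

### Filters

Merged blocks must reach a genotyping ratio ≥ 0.70 and pass a 1-df
Pearson chi-square of h0:h1 against 1:1 at p ≥ 0.03 (no continuity
correction; at n ≈ 163 the discrete null removal rate is ≈ 0.027, close
to the nominal α). The two filters are evaluated independently on the
merged calls. No multiple-testing correction is applied across blocks —
the α is a deliberate fixed per-block screen.

### Mapping and anchoring

Two-point statistics on h0/h1 marker vectors: rf = min(D, N−D)/N over the
N individuals called in both (parental phase across scaffolds is
arbitrary, hence the min), LOD = R·log₁₀ rf + (N−R)·log₁₀(1−rf) +
N·log₁₀ 2 with the rf→0 limit N·log₁₀ 2; pairs with < 10 shared calls
are undefined. Linkage groups are connected components of the graph with
edges at LOD ≥ 10 and rf ≤ 0.20 (networkx). Markers that never disagree
at a co-called individual collapse into genetic bins (greedy,
first-seen order, consensus grown columnwise).

Within a group, bins are ordered by a deliberately naive greedy
nearest-neighbour chain on rf (seeded at the closest pair, extended at
whichever end offers the smaller rf) with cumulative Haldane distances
(−50·ln(1−2rf)) as positions. This fallback is plumbing: externally
computed orders (dedicated ordering software plus iterative error
correction) are standard for production maps and are always preferred
when supplied as a map TSV.

Scaffolds are placed at the arithmetic mean of their markers' positions
on the majority linkage group (group ties → ambiguous, unplaced;
minority markers reported), and oriented '+'/'−' when the Pearson
correlation of physical vs genetic marker position exceeds +0.50 /
falls below −0.50, else left unoriented. Map length is the sum of
per-group spans; mean inter-bin spacing divides by bins − groups (the
number of inter-bin intervals), which reproduces the printed per-map
averages exactly.

Doublet concordance compares all scaffold pairs anchored in both
parental maps, on a shared chromosome, within 5 cM of each other in the
reference map (default: either map, deduplicated; single-reference by
flag); a pair is concordant when the reciprocal order agrees. Tied
positions and pairs split across chromosomes in the other map are
skipped and counted. Because independently built maps fix each group's
direction arbitrarily, `align_group_directions` reflects anticorrelated
groups of the second map before comparison.

## Synthetic crosses

The generator emulates the study design: 17 chromosomes tiled by
scaffolds of unknown orientation; parental heterozygous SNPs confined to
SNP-dense block islands at 1 SNP/59 bp (sites snapped to one position
parity per parent so the two site sets cannot collide — a coordinate
convenience with no statistical effect); block islands of 4.8 kb by
default, matching the reported block-length scale (L50 ≈ 4.8 kb); one
parent carries a homozygous run covering 30% of each chromosome; a
configurable fraction of intercross (het × het) sites exercises the
exclusion path. Meioses follow the Haldane model (Poisson crossovers,
uniform positions, no interference); per-bp recombination is uniform.
Low-coverage calls draw depth ~ Poisson(coverage); heterozygotes split
reads Binomial(d, ½) — a single read can never yield a het call, so
allele dropout arises mechanically; each read is miscalled with
probability 0.01 and true homozygotes gain a spurious opposite-allele
read with probability 0.005 (multi-mapping). Truth tables record the
inherited homolog per (individual, block) (majority over sites, with a
within-block crossover flag), all crossover positions, the scaffold
layout and the TC-site roster. All randomness flows from one seed through
spawned sub-streams; a fixed seed reproduces every output byte for byte.

What the simulator does *not* model: alignment artifacts beyond the flat
mismap rate, indels and structural variation, depth overdispersion and
GC bias, segregation distortion, crossover interference, genotyping
batch effects. Passing recovery tests therefore demonstrates the
method's behaviour under its own noise model at realistic rates, not
performance on any particular real dataset.

## Problem sizes and numerical notes

* Parameter-recovery runs use 163 progeny at 0.5× with 1% miscalls on a
  4-chromosome genome (~190 blocks per parent, ~26,000 imputed
  (individual, block) genotypes); end-to-end anchoring uses the full
  17-chromosome default (~400 P1 blocks, ~58,000 sites). These sizes
  give tight binomial error on every rate while keeping the whole suite
  in tens of seconds.
* Accuracy against truth is scored on the majority inherited homolog;
  individuals with a real crossover inside a block have no single true
  homolog and are correctly refused by trimming.
* The simulated doublet analysis uses a denser scaffold layout
  (15 scaffolds per 60 cM chromosome) so that neighbouring scaffolds
  fall inside the 5 cM window; the default layout spaces scaffolds
  ~15 cM apart and yields no comparable doublets.
* log-domain arithmetic throughout (log₁₀); −inf emissions (e.g.
  E_hom = 0 without dropout) are handled by IEEE semantics; the
  brute-force test oracle enumerates all 2^L paths independently of the
  DP code.
* `--threads` parallelises imputation over blocks with a thread pool and
  collects results in input order, so output is identical at any thread
  count.

## Known limitations

* The exact emission parameterisation of the original finite-state
  machine is not publicly recoverable; the model above exposes exactly
  the four published parameters with documented, testable semantics, and
  both multi-mapping modes, but is not guaranteed to be byte-identical
  to the original scripts.
* The naive ordering is quadratic and unsuitable for thousands of bins;
  it exists so the pipeline runs end to end without external ordering
  software.
* MAF counts alleles from called genotypes (a depth-1 homozygote
  contributes two copies of its single observed allele), which slightly
  inflates the variance of site MAF at low coverage relative to
  read-level counting; the window is wide enough that > 99% of true TC
  sites pass at n = 163.
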