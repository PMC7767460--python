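# Methods

`cernet` re-implements, as a reusable and fully testable pipeline, the
in-silico workflow used to nominate an oncogenic lncRNA and its
competing-endogenous-RNA (ceRNA) circuitry from a tumor-only expression
cohort: decoy-gene correlation screening, sponge-triplet inference from the
intersection of expression and sequence evidence, a direct lncRNA:3'-UTR
"miRNA protector" masking analysis, TFBS-based regulator ranking, and the
qPCR 2^-ΔΔCt statistics used to validate the candidates.  Because the
original patient-level data are not public, the package ships a synthetic
cohort generator with planted ground truth; every downstream claim the test
suite makes is a statement about recovery of those plantings.

## Synthetic cohort model

Expression values are continuous log2-scale abundances drawn from a Gaussian
latent-factor model; the downstream analyses are purely correlation-based,
so count-level realism (library sizes, overdispersion) is deliberately not
modelled.  One latent "tumor activity" variable `A ~ N(0,1)` drives the two
decoy rows with opposite sign at a fixed loading of 0.95.  Each planted
sponge triplet gets its own factor `z = h·A + sqrt(1-h²)·w` with
`h = decoy_coupling / 0.95`, so the triplet lncRNA (set equal to `z` up to
scale and shift) correlates with either decoy at exactly
`±decoy_coupling`.  The miRNA and mRNA partners load on `-z` and `+z` with
loadings equal to the requested correlations, making the population
lncRNA–miRNA and lncRNA–mRNA correlations exactly `rho_lnc_mi` (< 0) and
`rho_lnc_m` (> 0); the implied miRNA–mRNA correlation is
`rho_lnc_mi·rho_lnc_m` and is negative by construction.  Non-planted
features are independent noise.  Defaults (200 samples, 30/40/100
lncRNA/miRNA/mRNA features, 5 triplets, rho = ±0.7, decoy coupling 0.8,
residual SD 1 log2 unit) are the conditions under which all recovery
properties are asserted.

A requested structure that cannot be realized (|rho| ≥ 1, or a decoy
coupling exceeding the decoy-activity loading, which would need a lncRNA
loading > 1) raises `InfeasibleCorrelationError` rather than silently
clipping.

Because all planted lncRNAs ride the same tumor-activity factor, their
sponge partners are cross-correlated between triplets.  This is realistic
for co-regulated oncogenic programs and is the main source of residual
false positives: a miRNA from triplet *j* is genuinely anti-correlated with
the lncRNA of triplet *i*, and only needs two chance seed matches to form a
cross-triplet.  At defaults this keeps planted-truth precision near 0.95
rather than 1.0.

Sequences are i.i.d. uniform A/C/G/U with seed-complementary sites
implanted at recorded, non-overlapping positions (slot placement, no
rejection sampling).  For the protector analysis the generator can paste
the reverse complement of the UTR window around each implanted site into
the lncRNA (`complement_len`), which creates a deep interaction-energy
minimum covering the site.  Features of real transcripts that are *not*
emulated: composition bias, secondary structure, repeat content,
conservation, shared seed families.  Recovery rates on this background are
therefore upper bounds on real-data performance; the chance-match
calibration (~0.6 expected 7-mer matches per 10 kb) is exact for the
uniform background only.

## Decoy screen

Every lncRNA is correlated (Pearson by default) against the upregulated and
the downregulated decoy.  Classification demands opposite signs with
|r| ≥ `r_min` (default 0.3) and raw p ≤ `p_max` (default 0.01) on both;
same-sign candidates are reported as `unclassified` rather than dropped.
Benjamini–Hochberg q-values are emitted alongside, but classification uses
raw p — matching how such screens are typically reported — and the
thresholds are CLI-exposed.  P-values come from the t transform
`t = r·sqrt((n-2)/(1-r²))`; at n = 6 this agrees with the exact permutation
p-value to within ~0.15, which is the documented tolerance of the
small-sample check.

## Site prediction and hybridization energy

Seed matching uses the canonical strict Watson–Crick site classes (8mer >
7mer-m8 > 7mer-A1 > 6mer, defined against miRNA positions 2–8 with the
opposing-A convention).  Each target start position is reported once under
its highest class, and a lower-class site wholly contained in a
higher-class site is suppressed so that one planted site yields exactly one
call.  External pattern-based or machine-learned site predictors are not
re-implemented; their role is taken by these seed classes plus a
thermodynamic filter, and none of their numeric outputs are reproduction
targets.

Duplex energies come from a nearest-neighbor dynamic program over
non-crossing intermolecular pairings (no intramolecular structure, no
accessibility term).  The stack table is a versioned package constant with
the ten standard Watson–Crick RNA stacking energies; G·U wobble stacks get
flat simplified values (−1.2 kcal/mol with one wobble pair, −0.5 with two)
— wobbles are allowed in the duplex DP but never in seed matching.
Bulges/internal loops are affine (open 3.0, extend 0.4 kcal/mol per
unpaired nt, per-strand extent capped at 8), terminal A-U/G·U pairs pay
0.45 kcal/mol, and the optimum is clamped at 0 (open state).  The DP is an
O(n·m·L²) numba kernel; windows are capped at 40 nt so profiles must scan.

Sponge ranking keeps miRNAs significantly negatively correlated with the
lncRNA, truncates to the `top_k` (default 50) most negative, then requires
≥ 2 sites on the lncRNA with mean site energy ≤ −7 kcal/mol.  The −7
default is deliberate: under the shipped stack table the weakest canonical
all-A/U 7mer seed duplex scores about −6.5 kcal/mol, so −7 admits every
strict-WC canonical seed pairing while rejecting weaker partial pairings.
A stricter cutoff (e.g. −10) silently discards genuine sites of A/U-rich
seeds and costs recall; the parameter remains config-exposed.

## Triplet assembly

Per sponged miRNA, the anticorrelation branch (mRNAs with significant
negative r vs the miRNA *and* significant positive r vs the lncRNA) is
intersected with the complementarity branch (mRNAs whose 3'-UTR carries ≥ 2
predicted sites); the branches are intersected per-miRNA, the stricter of
the two readings of "compare the two lists".  "Significant" is raw
p ≤ 0.05 by default.  Accepted triplets re-validate all six evidence
conditions and are scored by `|r_lnc_mi|·|r_lnc_m|·|r_mi_m|` (ties: total
sites, then lexicographic).  The external predictor's "highest probability
of being bound" filter maps to the duplex-energy cutoff — a semantic
substitution, not a numeric one.

Perturbation confirmation after lncRNA silencing: an mRNA is confirmed in a
cell line if it decreases significantly at ≥ 1 timepoint or correlates
significantly positively with the lncRNA in the perturbed cells; consensus
requires all cell lines.  A missing timepoint contributes no evidence (it
is never an error).

## Protector (masking) analysis

For each UTR window (default 25 nt, step 1) the profile records the best
duplex against any lncRNA subsequence of length ≤ window — realized exactly
by scanning length-25 lncRNA substrings, since duplex energy is monotone
under sequence extension.  MFE regions are the union of windows at or below
the profile's 0.25 quantile (strictly negative energies only; a constant
profile yields no regions), and masking events report every (region, site)
pair where the region covers ≥ 50% of the site.  Accessibility-aware
interaction predictors are not re-implemented: the landscape is used only
to locate overlap regions, which the pure hybridization DP preserves.  All
profile energies are reported in kcal/mol with an explicit unit field.
None of the window/quantile/fraction defaults are inherited from published
values; all are config-exposed.

## qPCR layer

ΔCt = Ct(target) − Ct(reference) per sample, technical replicates averaged
at the ΔCt level (a config flag allows per-replicate ΔΔCt);
ΔΔCt = mean ΔCt(group1) − mean ΔCt(group2); fold change = 2^−ΔΔCt, reported
both raw and in the signed convention (ratios < 1 become the negative
reciprocal, so |signed| ≥ 1 and a ratio of exactly 1 maps to +1).  Swapping
the groups inverts the raw ratio, i.e. flips the sign of the signed value.
Test selection: Shapiro–Wilk per group at alpha 0.05, then a two-sided F
test of variances (Student vs Welch t), Mann–Whitney U when either group is
non-normal or smaller than 3; three or more groups go to one-way ANOVA or
Kruskal–Wallis.  ΔCt correlations choose Pearson/Spearman by the same
normality rule; since ΔCt is inversely related to abundance the result
carries both the ΔCt-space r and the expression-space r (identical when
both inputs are ΔCts — the two flips cancel — and negated against a plain
covariate).  Fractionation percentages are 2^−Ct relative abundances
normalized per transcript.  The silencing-efficiency filter removes
replicates with knockdown efficiency `1 − 2^−ΔΔCt` below 0.75, threshold
inclusive.  No amplification-efficiency correction is applied.

The plate simulator writes the generating ΔΔCt as −log2(true ratio) with
i.i.d. normal noise on the target Ct; per-sample loading offsets are shared
with the reference well and cancel in ΔCt, so noiseless plates reproduce
the true ratio to machine precision.

## TFBS screen

Promoter windows are strand-aware (default 1 kb upstream, 200 nt
downstream — the downstream extent is this package's choice, config
exposed), clipped at zero; interval overlap is half-open on both sides.
TFs are counted per name within the window, optionally gated on overlap
with a histone-mark BED, and ranked by expression correlation with the
lncRNA (significant positive → activator candidate, negative → repressor
candidate; TFs absent from the matrix are flagged uncorrelatable).  Track
retrieval is out of scope; TFBS arrive as BED.

## Numerical and testing choices

Problem sizes in the default test and acceptance runs are chosen to keep
the whole suite under a minute of compute: 20 cohort seeds for pipeline
recovery, 10 for null calibration, ~1000 randomized cases per oracle
(brute-force site scan, exhaustive duplex enumeration at lengths ≤ 6,
threshold-and-merge region reference, position-set interval oracle, direct
product-moment formula), 300–500 Monte-Carlo plates for ΔΔCt recovery.
Determinism: every generator takes an explicit seed, each derives
independent substreams, and identical seeds give byte-identical outputs.

Known limitations: no intramolecular RNA structure or accessibility; no
batch effects, counts, or normal-tissue samples in the simulator; flat
wobble stack energies; seed classes only (no 3'-compensatory sites); the
planted-truth metrics treat biologically plausible cross-triplets (shared
tumor-activity factor) as false positives, so reported precision is
conservative with respect to the generator's own structure.
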