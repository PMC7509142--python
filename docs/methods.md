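# Methods

## Data model

The core object is a genus × sample matrix of non-negative integer counts
(`OtuTable`) with per-sample metadata carrying the aging-design factors:
cellar (FB = Priorat, ICVV = Rioja), amplicon (16S/ITS), vessel
(barrel/bottle/tank), barrel history (new/old) and aging time in months
(0/3/6/9/12). Metadata is decoded from the sample acronym grammar
(`BAO`/`BAN` = old/new barrel, `BTO`/`BTN` = bottle from old/new barrel,
`FML` = steel-tank malolactic endpoint, trailing digits = months), so a
sample's identity is never stored twice. The four packaged tables are
transcribed at genus level exactly as published, including the
"Unidentified" ITS row and the two-group superscripts, which are kept as
uninterpreted annotations (`bipartition_from_annotations` turns them into a
bipartition on request).

All four packaged tables are already rarefied; their common column sums
(30,815 / 101,243 / 2,832 / 2,381 reads) are enforced by tests.

## Rarefaction

Subsampling is WITHOUT replacement: each sample column is one multivariate
hypergeometric draw at the target depth, so rarefying a depth-d table to
depth d is the identity and per-cell expectations are
`depth × count / total`. The default depth is the minimum column sum,
which is how the quoted per-dataset thresholds arise. One global seed is
split per sample by sample index (`SeedSequence.spawn`), giving
reproducibility with per-sample independence. A single seeded draw feeds
the diversity branch; averaging over draws is available through
`rarefaction_curve` but is not the default, since a single draw is the
convention of the upstream tooling this mirrors.

## Diversity branch

*Alpha*: Shannon entropy in bits (base 2, switchable), on rarefied counts.
Factor tests are the classical equal-variance Student *t* (Welch by flag)
for two-level factors and one-way ANOVA otherwise. Degenerate inputs are
defined rather than NaN: identical values in all groups give statistic 0,
p = 1; zero within-group variance with distinct means gives an infinite
statistic, p = 0.

*Beta*: Bray–Curtis on rarefied counts (equivalently proportions, since
depths are equal). PCoA is classical MDS: Gower-center −½·J·D∘D·J,
eigendecompose, coordinates = eigenvector × √eigenvalue for positive
eigenvalues. Negative eigenvalues are reported but excluded from
coordinates and proportion-explained; no Lingoes/Cailliez correction is
applied. Axis signs are fixed so each axis's largest-magnitude coordinate
is positive, making ordinations reproducible. On Euclidean-embeddable
input the embedding reproduces the distances to < 1e-8 (tested).

*PERMANOVA*: pseudo-F from squared-distance sums,
`F = (SS_between/(g−1)) / (SS_within/(N−g))`. With ≤ 10,000 distinct label
arrangements the permutation distribution is enumerated exhaustively and
p = #{F_perm ≥ F_obs}/#arrangements (the observed arrangement counts
itself); otherwise 999 seeded Monte-Carlo permutations with
p = (1 + hits)/(1 + n). Exhaustion matters at this design's scale: the
aging-time factor has two samples per level, so the p floor is 1/35 and
Monte-Carlo noise would be comparable to the signal. Bare p-values at this
n are resolution-limited, which is why the package asserts calibration and
attainable-range properties rather than exact historical p-values.

## Compositional branch (balances)

Zero counts are imputed before any log-ratio: default is a pseudocount of
1 added to every cell (simple, reproducible, count-scale); multiplicative
replacement (zeros → δ, nonzeros rescaled to preserve the unit sum) is
available by flag. Balances are per-sample scale-invariant, so the two
scales agree downstream.

Genera are split into two groups by Ward-linkage agglomerative clustering
cut at the final merge. The clustering feature is the per-genus CLR
profile across samples, z-scored per genus. Standardization is
load-bearing: without it Ward clusters by abundance magnitude (one giant
genus against everything else) and cannot find anti-correlated
trajectories; with it, genera cluster by the shape of their temporal
profile. A correlation distance on proportion profiles (1 − Pearson r) is
available by flag. Ward merge ties follow scipy's deterministic
lowest-index convention; all-identical profiles degenerate to a
first-taxon-vs-rest split, frozen by test. The group containing the
lexicographically smallest genus label becomes the numerator — the sign of
a balance is pure convention, so determinism is the contract.

The balance is the standard two-group ILR coordinate (natural log with the
√(rs/(r+s)) normalizer). Factor tests on balances reuse the alpha-test
machinery; for a single categorical factor the OLS-summary and ANOVA
formulations coincide, which is what is implemented.

The packaged tables are rarefied, so fixture runs feed the compositional
branch the rarefied counts; the unrarefied path is exercised on synthetic
data. This is a documented deviation from the ideal of balancing on raw
counts, forced by what is published.

## Impact statistic

For each genus the statistic asks: how much does the two-group log₂ ratio
move when this genus is removed? With `S_num`, `S_den` the group sums of
the imputed values in sample j, `B_j = log₂(S_num/S_den)`, and `b_j` the
same after subtracting genus i's value from its own side,

    Impact_i = (1/n) Σ_j 2^|B_j − b_j|.

Each term is the fold change of the ratio, so `Impact_i ≥ 1`, with
equality only for a genus absent everywhere. For a numerator-side genus
the term reduces to `S_num/(S_num − c_ij)`; this closed form and a
straight-loop evaluation serve as two independent oracles the generic
implementation must match to 1e-12.

"Log₂ ratio of all counts" is read as the ratio of group SUMS, because the
defining operation — subtracting one genus's counts — is natural on sums;
a geometric-mean reading (`ratio="gmeans"`, removal from the group's
geometric mean) is offered for comparison and generally produces a
different ordering. This sums-vs-gmeans choice is the single most
consequential interpretation decision in the package. `n` is the number of
samples in the analysis subset under study, selectable by metadata filter.

On the ICVV 16S table with the printed two-group marks, the ranking is
Oenococcus (9.44) ≫ Gluconobacter (3.22) > Komagataeibacter (1.82) >
Acetobacter (1.37) > Lactococcus (1.16) > Lactobacillus (1.01) — the two
dominant genera of the dataset lead or co-lead the ranking, and every
genus of that table is among the reported drivers.

## Synthetic data generator

The generator emulates the structure the analysis assumes, not wine
chemistry. Per sample j with aging time mⱼ, the planted numerator group's
expected share q satisfies `log₂(q/(1−q)) = base_log_ratio +
time_slope·mⱼ`; within each group, genus weights follow a geometric series
(ratio `background_evenness`), echoing the strongly uneven communities of
real aging wine (one dominant genus per kingdom). Expected proportions are
perturbed with a Dirichlet draw (concentration = `dispersion` × expected
proportions — the standard overdispersed amplicon model) and counts drawn
multinomially at fixed depth, so columns sum exactly to the depth.

Defaults (the study conditions for every simulation-based check): 9
samples at months (0,0,3,3,6,6,9,9,12) mirroring the FB barrel design, 20
genera split 10/10, depth 30,000 (the 16S scale), base log-ratio 0, slope
0.3 log₂/month, dispersion 500, evenness 0.8. Dispersion 500 corresponds
to mild-to-moderate amplicon overdispersion; evenness 0.8 keeps the rarest
genus near 1.5% of its group, a regime where every genus's trajectory
carries signal. Under these defaults the planted split is recoverable
(Ward ARI = 1 in ≈ 99/100 seeds) and the null tests are calibrated —
both verified, not assumed, by the acceptance checks.

What the generator does NOT emulate: taxonomy misassignment, chimeras,
library-size variation (depth is fixed), genus-specific phylogenetic
correlation, or the extreme sparsity of real ITS tables. Passing
simulation checks therefore demonstrates correctness and calibration of
the machinery under a clean compositional drift, not robustness to every
artifact of real amplicon data.

`null_generate` zeroes the slope for type-I-error calibration. The power
check plants a drift of 2 residual SD of the balance per month (the
residual SD estimated from null simulations, converted to generator slope
via the ILR scale factor √(rs/(r+s))·ln 2).

## Pipeline and factors

`run_analysis` executes both branches per table and writes a TSV bundle
(alpha, PERMANOVA, group tests, PCoA coordinates, distance matrix,
balances, bipartition, impacts, relative abundances) plus an
effective-config echo and a structured run log (stage, parameters, input
hash, elapsed time). Outputs are byte-identical across re-runs of the same
config; changing the seed touches only rarefaction- and permutation-
derived numbers, never the balance/impact branch.

Factor definitions encode the aging design: `barrel_type` keeps barrel
samples at months where both barrel histories exist (FB: months 0–9, 4 vs
4, excluding the unpaired 12-month sample; ICVV: months 3–12, 3 vs 3);
`time` groups paired barrel months and adds the bottles as one extra group
when present (ICVV: 3-, 9-, 12-month barrels + 12-month bottles); `bottled_wine`
compares month-12 barrel vs bottle (ICVV only). A factor left with fewer
than two levels raises an error naming the factor.

## Numerical choices and limitations

* Permutation hit-counting uses F_perm ≥ F_obs − 1e-12 to make float ties
  count as ties.
* PCoA drops eigenvalues below max|λ|·1e-9 as numerically zero.
* The impact statistic has no inferential wrapper (no CIs) — it is a
  descriptive ranking by construction.
* With n = 2 per group, PERMANOVA p-values sit at the resolution floor of
  the permutation distribution; treat them as design-limited.
* Balance results depend on the imputation (pseudocount) choice for genera
  with many zeros; the dominant-genus conclusions on the packaged tables
  are insensitive to it, but rankings among near-floor genera are not.
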