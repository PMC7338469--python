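# Methods

`hhscan` tests whether a putative homoploid hybrid lineage (labelled **o**)
arose from hybridization between two parental species (**h**, the major
parent, and **m**, the minor parent), using a third congener (**s**, sister
to m) and an outgroup for phylogenetic control. This note documents the
statistical machinery, the synthetic-data generator that provides ground
truth, and the numerical choices a user should know about.

## The demographic model

All inference and simulation share one five-taxon demography. Backwards in
time: o merges into its parents at `t3`, with each lineage joining m with
probability `H` (a single admixture pulse) and h otherwise; s and m merge
into their ancestor A_sm at `t2`; A_sm and h merge at `t1`; the outgroup
joins at `t_out`. Optional continuous migration connects h and m between the
present and `t2` (the parents remain in sympatric contact — the hybrid's
existence attests to it) and h and s between `t3` and `t2` (s–h exchange is
treated as historical: s is allopatric today). A separate ancestral rate
`m_anc` connects h and A_sm between `t2` and `t1` in the barrier-testing
models.

Desk-scale defaults, chosen once for tractability while preserving the
shape of the history:

| parameter | default | rationale |
|---|---|---|
| Ne (all lineages) | 5,000 diploids | desk scale; divergence expressed in units of 2Ne below |
| `t1` | 30,000 gen (3.0 × 2Ne) | strong but incomplete lineage sorting between h and (s,m) |
| `t2` | 15,000 gen (1.5 × 2Ne) | internal branch leaves ~22% ILS, so site-pattern tests have signal |
| `t3` | 1,000 gen (0.1 × 2Ne) | recent hybrid origin |
| `t_out` | 90,000 gen | comfortably pre-dates all ingroup events |
| mutation rate | 7.5e-8 /site/gen | 5e-9 per site per year at 15 years per generation |
| recombination | 4.4e-8 /bp/gen | preserves the per-100-kb population-scaled recombination (~88 rho units) implied by a natural-population Ne of ~2e4 with r = 1e-8; per-window genealogical resolution is what windowed tests feel |
| generation time | 15 yr | used only to convert year-based inputs |

With these values nucleotide diversity is ~0.0015/bp (the real system is
~2–4× higher; the desk scale trades diversity for runtime while keeping
divergence ratios and per-window tree counts realistic).

## Windowed divergence statistics

Windows are nonoverlapping 100-kb tiles (0-based half-open; a VCF site at
position P belongs to the window with start ≤ P−1 < end). Per site,
`Dxy = pA·qB + qA·pB`; `pi = n/(n−1)·2pq`; Hudson's Fst is `1 − Hw/Hb` with
`Hw` the mean of the two within-taxon heterozygosities and `Hb` the between-
taxon expected difference. Window Fst aggregates as a ratio of sums
(`1 − ΣHw/ΣHb`), the low-bias choice; `maxFst` is the maximum raw per-site
value and equals 1 exactly when the window contains a fully-genotyped fixed
difference. Negative estimates are kept in computation and clamped only in a
display column. Per-bp values divide by the full window length by default
(invariant positions contribute zero difference); accessible-length
normalization is available where upstream filtering makes the default
misleading. A site enters a statistic only if every taxon that statistic
needs has at least `min_alleles` called allele copies there (default 40,
i.e. 20 diploids; the floor is capped at a taxon's own capacity so small
outgroup panels remain usable).

## The hhs ratio and bootstrap

For a window of sites k,

    hhs = Σ_k (p_o q_m + p_m q_o) / Σ_k (p_h q_m + p_m q_h),

the ratio of mean o–m to h–m nucleotide difference. If o is entirely
h-derived, hhs = 1; m ancestry pulls it below 1 wherever the parents
diverge (at fixed parental differences the per-site ratio is exactly
1 − γ). The genome-wide test of hhs = 1 resamples windows with replacement
(1000 replicates by default), summarizing each replicate as the mean of the
sampled windows' values (a genome-wide ratio-of-sums summary is available);
the one-sided p-value is the fraction of replicates ≥ 1 with a
(r+1)/(B+1) correction. Window resampling respects intra-window linkage.
At very small windows (few hundred sites) the per-window ratio carries a
slight Jensen bias; the test is calibrated for windows of ≥ ~50 kb at desk
scale.

## Site patterns, D and the f4-ratio

For the ordered quartet (outgroup, T1, T2, T3), frequency-weighted ABBA /
BABA / BBAA sums accumulate both allele-labelings of each site, and
D = (ABBA − BABA)/(ABBA + BABA). Significance does **not** jackknife the
ratio: the per-site mean of ABBA − BABA (an f4-type numerator, zero exactly
when D is) is jackknifed over contiguous blocks instead, because the
denominator weighting concentrates on the deepest genealogies and
underestimates variance ~1.5–1.9× under intra-window linkage. Window-scale
tests use 10 equal-site blocks and a t(9) reference; genome-scale tests use
1-Mb blocks. The block jackknife is the weighted delete-one form (block
sizes as weights), so uneven blocks are handled correctly.

The admixture proportion is the f4 ratio

    γ̂ = f4(out, s; o, h) / f4(out, s; m, h),

unbiased for the pulse fraction under the model above: o's frequencies are a
γ-mixture of the parents', so the o−h contrast is γ times the m−h contrast,
and the (out − s) projection cancels shared drift. The hybridization test
(z, p) asks whether the numerator differs from zero, with a normal reference
— the block count is small but each block aggregates hundreds of sites, so
the jackknife SE is stable; on null simulations the t reference
over-corrects (rejection ~2.5% at nominal 5%) while the normal lands on the
nominal rate. Per-window γ̂ additionally reports the jackknife z of the
*denominator*; windows where |den_z| < 2 are flagged undefined, because the
local m−h contrast can vanish (especially under migration) and the ratio is
then unbounded — without the guard single windows reach |γ̂| > 50 and ruin
any downstream regression. Per-individual estimates treat one o individual
as a two-allele-copy population. Regressions of γ̂ (and of the 0/1 barrier
indicator) on the window recombination rate are ordinary least squares via
statsmodels, reporting slope, R², F and p.

## Barrier discovery

One D test on (out, s, m, h) serves both orientations: significantly
positive D (one-sided p at α = 0.05, uncorrected) puts a window in M_hm
(excess m–h sharing), significantly negative D in M_hs. Candidates are
M_hs \ M_hm over testable windows — regions where h exchanged genes with s
(hence with the s/m ancestor) but not with m, the signature of a barrier
that arose on the m lineage after the s/m split. Untestable windows are
excluded from both sets rather than counted as non-significant. Each
candidate gets a local-ancestry call for o by testing the two nestings:
no residual signal under ((h,(o,m)),out) ⇒ MOLLISSIMA-derived, none under
((m,(o,h)),out) ⇒ HENRYI-derived, both-or-neither clean ⇒ AMBIGUOUS (the
explicit conflict category). Calls are annotated with the window's h-vs-m
maxFst; maxFst = 1 (tolerance 1e−12) flags a fixed difference.

## Joint SFS and model selection

The unfolded 2D-SFS is counted directly from called genotypes: a site is
polarized when the outgroup genotypes are non-missing and monomorphic for
one of the two alleles; derived counts are projected to fixed sample sizes
with hypergeometric weights (fractional mass per cell). This replaces
genotype-likelihood SFS estimation deliberately: the generator emits exact
genotypes, so likelihood machinery would add nothing testable.

Expected spectra are Monte-Carlo: the mean branch-mode joint allele-
frequency spectrum over `n_sims` independent non-recombining genealogies
(the infinite-sites expectation given each genealogy — no mutation-sampling
noise). The composite log-likelihood is multinomial over cells, excluding
the two monomorphic corners, with observed cells below a minimum entry
(default 5) pooled into one residual cell on both sides; expected
proportions are floored at 1e−12.

Fitting treats `n_sims` (default 20,000; production-scale fits of this kind
use hundreds of thousands) as the simulation budget per model: it is spread over a
common-random-number grid of the single free parameter (every evaluation
reuses one seed, making the profile smooth), the best grid point is refined
by a parabola, and the optimum is re-evaluated at the full budget with a
seed shared across competing models. The shared final seed matters at
boundaries: when the truth is H = 0, model3's fitted Ĥ collapses to the
grid edge and its final likelihood is *identical* to model1's, so AIC
(2k − 2lnL) resolves the tie by parsimony instead of Monte-Carlo noise.
The three hybrid-origin templates are model1 (o sister to h, H = 0), model2
(o sister to m, H = 1) and model3 (0 ≤ H ≤ 1 free); the barrier templates
are barrierA (recent h–m migration free below the ancestral rate) and
barrierB (pinned to it). Free-vs-fixed structure is declared per template;
the recovery experiments fix all parameters except the one under test to
their generating values. `fit_model_replicates` reruns a fit with different
seeds and reports the spread of the estimate.

## The synthetic-data generator

Datasets are simulated window by window (independent genealogies per
window), each window with its own recombination rate and migration regime,
through msprime with a binary mutation model (every site biallelic 0/1).
Barrier windows (`barrier_hm`) multiply the h–m migration rate by a factor
(default 0) while h–s migration persists, and can force o's ancestry in
that window to a single donor (H set to 0 or 1 locally) — emulating
post-hybridization fixation of barrier alleles; donor forcing is off unless
requested. `plant_barriers` selects windows with probability weights
`rho^-rho_bias`, concentrating barriers at low recombination when biased.
`lognormal_rho` draws a window-heterogeneous map (recombination maps in
natural populations span orders of magnitude). All randomness descends from
one seed via SeedSequence spawning; identical seeds give byte-identical
VCF/truth output. Default scale: 2 contigs × 10 Mb, 100-kb windows, 10
diploids per ingroup taxon, 4 outgroup diploids.

What the generator does *not* emulate: genotyping error and missingness,
linkage across window boundaries, selection at barrier loci (fixation is
imposed, not evolved), variable Ne through time, and real recombination-map
structure (hotspots). Passing recovery tests therefore demonstrates
correctness of the estimators under the model's assumptions, not robustness
to the full messiness of resequencing data.

## Validation experiments and their sizes

The test suite's end-to-end experiments run at sizes chosen to finish on a
single CPU in minutes; each states its conditions in the test:

* **γ̂ recovery** — 20 replicates at each H ∈ {0.1, 0.25, 0.5} on the
  default genome; observed |bias| < 0.03 and every replicate within 0.05.
* **Calibration** — 600 no-migration windows; the per-window hybridization
  test rejects within the 95% binomial band around 5%.
* **Barrier recovery** — 3 genomes, 15% planted barriers (h–m flow shut,
  historical h–s flow at 4Nm = 0.5, h–m contact at 4Nm = 2 elsewhere,
  donor coin-flipped): recall and precision ≥ 0.7, donor concordance ≥ 90%.
* **Model selection** — 20 replicates per contrast at n_sims = 20,000:
  model3 and barrierA each chosen in ≥ 90%.
* **Directionality** — 10 genomes with σ = 1.0 lognormal maps and
  rho_bias = 3 barrier placement: γ̂ increases and barrier density
  decreases with rho in ≥ 9/10.

## Known limitations

* The hhs bootstrap's per-window ratio is biased upward/downward at very
  small windows; stick to ≥ 50-kb windows at desk diversity.
* The per-window hybridization test's calibration was established at the
  default within-window recombination; with strongly linked windows
  (rho_window ≲ 20) the jackknife under-covers and rejection runs hot.
* The f4-ratio assumes no gene flow into s and no admixture older than the
  pulse; continuous h–m migration inflates γ̂ relative to the pulse
  fraction (it is genuinely extra m ancestry, but not pulse ancestry).
* AIC with composite likelihoods has no strict information-theoretic
  guarantee (sites are not independent); it is used here as a ranking
  heuristic, and the recovery
  experiments show it ranks correctly under the model.
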