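# Methods

## Model

A cohort of `m` tumors is described by `n` candidate driver events.  Each
event–sample observation is categorical: wild type (`Z`); for mutation
events hotspot (`HS`), loss (`L`), splice (`S`) or in-frame indel (`I`); for
copy-number events weak/strong amplification (`WA`/`SA`) or weak/strong
deletion (`WD`/`SD`).  Hybrid events (a gene significant both as mutated and
as copy-number altered, suffixes `-MD`/`-MA`) may carry a two-code
co-observation such as `L,WD`.  The categorical matrix **M** collapses to a
binary matrix **D** (altered / wild type) and a penalty matrix **P** whose
entries are the negative natural log of each altered observation's
passenger probability; wild-type cells carry penalty 0.  The log base is
arbitrary — any base rescales the objective uniformly — and the engine
normalizes penalties internally so that all comparisons are bit-identical
under uniform rescaling (asserted by test).

A *rule* is a set of ≥ 2 events, interpreted as a minimally sufficient
driver combination; consequently no valid rule set may contain two rules
where one strictly contains the other (*family members*).  Given a rule set,
each sample is assigned to the satisfied rule with the largest cumulative
penalty in that sample (ties: the larger rule, then the lexicographically
smallest label tuple); per-sample greedy assignment is globally optimal
because samples contribute independently.  The objective `J` is the total
penalty of assigned events; *coverage* is the assigned fraction; every rule
in a valid set must have at least `msa` assigned samples
(`msa = ceil(0.03 m)` by default — the rounding direction is our choice,
taken so the constraint never vanishes on small cohorts).

## Penalty construction

Mutation observations are classified per gene and sample with precedence
`HS > I > S > L`.  A hotspot is an amino-acid position altered by
substitutions in ≥ 3 distinct samples (a sample counts once per position;
silent and intronic variants never count).  Hotspot/loss probabilities are
sums of per-substitution rates at/away from hotspot positions (rates are an
input table, e.g. from a selection-intensity model); in-frame-indel and
splice probabilities are cohort control-gene frequencies scaled by protein
length / 480.  Splice substitutions without an amino-acid annotation cannot
enter hotspot tallies and fall through to `L`.  Patient adjustment factors
are per-sample counts of point mutations outside the candidate genes
(floored at 1, capped at 10× the 75th percentile) divided by the cohort
mean of the capped counts; the mean is taken after capping.  Copy-number
observations threshold GISTIC-style focal values at ±0.3 (neutral band) and
the per-sample strong cutoffs, combined to peak level by the extreme method
(max over peak genes for amplifications, min for deletions; the opposite
sign maps to wild type).  Copy-number rates come from control cytobands:
`μ_SD = C_SD/(n·m)`, `μ_WD = (C_SD + C_WD)/(n·m)` (weak rates pool strong
counts so weak ≥ strong), likewise for amplifications, times per-sample
factors `(C_j + 0.5)/(mean + 0.5)`.  Hybrid co-observations multiply the two
probabilities, i.e. add the two penalties.  All probabilities are clipped to
[1e-12, 0.95] before the log: the upper cap mirrors the simulator's cap and
prevents zero penalties on altered cells, the floor keeps penalties finite
on degenerate rate inputs.  Simplified penalty variants: `FC` replaces each
observation type's penalties by their cohort mean (hybrid co-observations
count as their own composite type), `FG` uses supplied global per-type
values (summed over a cell's codes), `U` sets every altered cell to
−log(0.1); downstream results under `U` are invariant to the chosen
probability.

## Four-phase search

*Phase 1* ranks the rule library by importance.  Per iteration and per
rule-set size `s` (sizes by library size: ≤ 200 rules → {3,5,8}; 201–1000 →
{5,10,15}; > 1000 → {5,10,20}), random rule sets are drawn by cycling
shuffled rule lists so every surviving rule appears in ≥ `p1_spr` sets
(default 40; 20 in the simulation settings); family members are allowed so
that related rules compete directly.  A rule's contribution to a set is the
fractional drop in `J` when it is removed (0 when J = 0); per size, mean
contributions are standardized to Z scores across rules (population SD;
all-zero when the SD vanishes) and averaged across sizes.  The lowest 25%
(`p1_cut_size`) are eliminated per iteration until ≤ 24 rules remain, which
are then ranked by a final scoring pass; eliminated rules rank below
survivors, later rounds first, ties by their last score.

*Phase 2* exhaustively evaluates, for each K = 1..10, all valid size-K
subsets of the longest ranking prefix whose valid-subset count stays within
`p2_mnrs` (200,000; half in simulation settings), counting candidates up to
`p2_max_compute` = 10 × `p2_mnrs`.  *Phase 3* refines each best-of-K set
with neighbors that swap in L = 1..3 rules from beyond the phase-2 pool (in
rank order, budget `p3_mrns` split across L) and with one-rule extensions
of the best (K−1)-set.  *Phase 4* grows K beyond 10 from the top-3 sets of
the previous size (add one rule; then swap one for two while the `p4_mrns`
budget lasts) and stops at the first K with no valid msa-satisfying
candidate.  `p3_mrns`/`p4_mrns` default to 100,000 (halved in simulation
settings); the published procedure names these budgets without printing
values, so the defaults are ours.  Throughout, rule sets are compared on
`J` quantized to 6 significant digits with ties broken by rule identity,
which makes selections deterministic and invariant to penalty rescaling.

The *core* rule set is the best set of the smallest K reaching 90% of both
the maximum objective and the maximum coverage over K.  The *generalized
core* repeats core selection on 100 random subsets (40 in simulation
settings) of 67–85% of samples, re-evaluating the stored top-100 rule sets
per K; the msa constraint applies on the subset exactly as anywhere else
(msa-failing sets score 0).  Coverage and objective thresholds are drawn
independently per iteration on 85–99% of the subset maxima; when no K meets
both (coverage need not be monotone in K), the iteration falls back to the
objective threshold alone, then to the best-J set.  Confidence of a rule,
trio, duo or event is the percentage of iterations whose subcore contains
it (duos/trios count when contained in any subcore rule); consensus items
have confidence strictly above 50, and consensus rules are family-free by
construction (asserted, not assumed).

## Simulator

The generator emulates a pan-cancer cohort at the study's stated scale: 100
events × 400 samples; `ntr` hidden rules with sizes 2–6 drawn with
probabilities (0.73, 0.19, 0.04, 0.03, 0.01); rule events drawn without
replacement from a geometric event-participation profile (decay 0.8 over
event ranks, so the top event has per-slot probability ≈ 0.2 — matching the
concentration seen in real consensus-rule tables, where a top driver can
sit in nearly half the rules); duplicate or family draws are rejected (cap
10,000).  A null fraction is drawn uniformly on [0.01, 0.20]; each rule
receives assignment probability 0.03 plus a share of the remaining mass
from uniform stick-breaking, and probabilities are realized as integer
sample counts by largest-remainder apportionment so every rule truly
receives ≥ 3% of samples.  Noise: every event gets a passenger rate from a
packaged heavy-tailed pool (quantiles of a lognormal with median 0.045,
σ = 0.9, truncated to [0.02, 0.5]) and every sample a burden factor from a
unit-mean lognormal pool (σ = 0.55); the cell-wise passenger probability is
their product capped at 0.95.  Driver cells are always altered with penalty
−log(probability); non-driver cells flip on with that probability (`Dr`), with
a single uniform rate equal to the pool mean (`Du`), or never (`Dz`).
Wild-type cells carry penalty 0 (the equivalent convention of assigning
them probability 1; the objective never reads them).

Both noise pools are synthetic surrogates: the study they emulate pooled
empirical rates and burden fractions from real cohorts, which are not
shipped here.  Passing tests on these simulations therefore demonstrate the
machinery (search, core selection, confidence estimation, baseline
comparisons) under realistic structure and heterogeneity, not agreement
with any particular cancer type; statistics that depend on the exact pool
shapes (notably the pairwise-baseline precision under heterogeneous noise)
carry that caveat.  When one ground-truth rule dominates the cohort and
many pool events co-occur with it above the msa floor, the objective
genuinely favors splitting the dominant rule into many rule+event triples
at large K, which can degrade the core assignment on such draws — the
over-fitting regime the msa constraint bounds but does not eliminate.

## Evaluation metrics

Sensitivity = fraction of ground-truth rules among the consensus rules;
precision = fraction of consensus rules that are ground truth (undefined on
an empty consensus); assignment accuracy = fraction of samples whose core
assignment equals the true assignment (null matches null).  The pairwise
baseline tests all event pairs (events with ≤ 1 carrier excluded) with a
one-sided Fisher's exact test for enrichment — computed vectorized as the
hypergeometric upper tail, which is identical to the one-sided Fisher p —
under Benjamini–Hochberg FDR 5%, scored against ground-truth duos (all
pairs co-occurring within a rule).  The phase-1 score is a normalized AUC:
`S = (AUC − AUC₀)/(AUC_max − AUC₀)` with the recovery curve summed to
`x_max = min(50, position of the last ground-truth rule in the
coverage-ordered ranking)`, `AUC₀` from that coverage ordering and
`AUC_max` from a perfect ranking; `S = AUC/AUC_max` when baseline and
maximum coincide.  Robustness metrics (retention, weighted retention,
false-positive rate) compare duo sets between a full run and an
event-excluded run; agreement between two consensus sets is
`100·|A∩B|/|A∪B|`.

## Survival associations

For each consensus rule R and member event E (auto-selected when E appears
in ≥ 2 consensus rules), samples satisfying R are compared with samples
harboring E but not satisfying R, provided both groups have ≥ 10 patients.
The statistic is a univariate Cox proportional-hazards Wald test on the
group indicator, solved by Newton iteration on the Breslow partial
likelihood specialized to a binary covariate (cross-checked against a
reference Cox implementation to < 5e-4 in z and p); positive Z means the
rule group fares better.  Multiplicity within an event is handled by
permutation: (time, status) pairs are scrambled jointly among E's carriers
(preserving carrier counts and the marginal survival distribution), the
smallest p over the event's comparisons is recorded per permutation, and
`P_adj` is the fraction of permutations strictly below the observed p — no
add-one smoothing, so a perfectly separating observed statistic reports
`P_adj = 0`.

## Scaled-down study sizes

The packaged study runs use the reduced simulation settings (20 sampling
repetitions per rule in phase 1, halved phase budgets, 40 generalized-core
iterations) with 3–5 replicates per ground-truth size at ntr ∈ {3, 5, 8}
for the full pipeline and a 5 × 5 sweep over ntr ∈ {2, 5, 10, 15, 20} for
the pairwise baseline; a full-pipeline replicate takes roughly half a
minute on one CPU.  These sizes are the package's own choice of a
desk-scale design: means stabilize near the published values while a full
190-simulation replication would add nothing methodological.

## Known limitations

* The noise pools and event-participation profile are parametric surrogates
  (swappable via `SimulationConfig`), not the empirical pools.
* Phase-3/4 budgets are not published; results at large K depend mildly on
  them (best-of-K is exhaustive-verified only for small libraries).
* The outcomes module fits no covariates and assumes proportional hazards
  within each two-group comparison.
* No parallel execution; determinism is guaranteed for a fixed seed.
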