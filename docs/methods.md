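# Methods

## Model and correction program

A protein-constrained model couples the stoichiometric network to enzyme
abundances in the GECKO style. After loading, reversible reactions are
split into irreversible forward/backward pairs (`_fwd`/`_rev` suffixes)
and each OR-branch of a GPR rule becomes its own reaction copy
(`_izN`), so every reaction copy is catalyzed by exactly one enzyme or
one complex. AND-rules give every subunit its own usage coupling on the
same reaction; subunit stoichiometry defaults to 1 (copy numbers are
rarely known) and can be overridden per enzyme. kcats are stored and
reported in s⁻¹; all constraint matrices work in h⁻¹ (×3600) so fluxes
remain in mmol gDW⁻¹ h⁻¹.

Each enzyme is assumed to operate with a **single turnover number across
all reactions it catalyzes**, its minimum reaction-specific kcat. The
capacity constraint is read per enzyme — the summed flux over all
reactions an enzyme catalyzes may not exceed (kcatᵢᵐⁱⁿ + δᵢ)·Eᵢ. A literal
per-reaction reading (one constraint per (reaction, enzyme) pair, which is
strictly looser for promiscuous enzymes) is available via
`capacity_indexing="per_reaction"`; the two coincide for single-reaction
enzymes. The per-enzyme reading is the default because the single-kcat
assumption makes the per-reaction sum redundant, and most enzymes in
curated models carry one unique kcat anyway.

The correction program is one LP spanning all conditions: per condition a
steady-state flux block with condition-specific uptake bounds, shared
non-negative corrections δ (one per enzyme measured in every condition),
and per-condition error variables ω. Enzymes *without* complete abundance
coverage keep GECKO usage variables bounded only by the protein pool row
(Ptot·f·σ); enzymes in M enter through their measured abundances directly
and are not double-counted in that pool row inside the correction LP. The
validation scenarios, by contrast, apply the pool constraint over **all**
enzymes together with abundance upper bounds on usage, which keeps the
enzyme mass fraction f unchanged between scenarios.

**Error linearization.** The natural error definition
ω = |μ_exp − v_bio| / v_bio is bilinear when both v_bio and ω are decision
variables. The LP therefore uses the surrogate
μ_exp·ω ≥ |μ_exp − v_bio| (constant denominator), which is exact at the
relevant optimum (v_bio ≈ μ_exp) and keeps the program linear. Both error
conventions are reported post hoc on every result.

### Parameters

| parameter | default | units | role |
|---|---|---|---|
| θ (error cap) | 0.6 | – | hard upper bound on each ω |
| ε (fold-change cap) | 10⁵ | – | δᵢ ≤ (ε−1)·kcatᵢᵐⁱⁿ |
| Kᵐᵃˣ | 5.75·10⁷ | s⁻¹ | absolute cap on any corrected kcat (fastest known enzyme) |
| λ grid | 10⁻¹⁴…10⁻¹ | – | one point per decade (the grid density is a choice; only the interval endpoints are prescribed) |
| feasibility tolerance | 10⁻⁹ | – | passed to HiGHS for every LP |
| default uptake | 1000 | mmol gDW⁻¹ h⁻¹ | medium nutrients without a measured rate |

## λ selection by cross-validation

3-fold cross-validation repeated 10 times: corrections are fitted on two
folds of conditions and validated on the held-out fold by FBA with the
corrected kcats under the pool constraint and measured uptake rates —
deliberately *without* abundance bounds, since the point of the selection
is to counteract overprediction in the proteomics-free regime. The score
s_λ averages, over iterations, the product of the min–max-scaled
validation error and the min–max-scaled log₁₀ total correction; both
factors are defined as 0 when the scaling is degenerate (all λ equal),
and zero totals are floored at 10⁻¹² before the log. The per-iteration
validation error is the mean over all validation conditions of the
iteration (pooled across its folds). λ\* is the grid point at the first
sign change of the second central difference of s_λ over the (uniform in
log₁₀ λ) index grid, scanning downward from the largest λ, with one-sided
differences at the endpoints and an argmin fallback when the curvature
never changes sign.

On the toy instances the generator produces, the error–parsimony
trade-off is shallow: toy kcats span 0.1–100 s⁻¹, so the marginal error
reduction per unit δ (~1/kcat) exceeds λ/|M| everywhere on the prescribed
grid and the fitted Δ is near-constant in λ; the selection then falls
back to the argmin. This is a property of the small-kcat regime, not of
the machinery — the hand-built fixture with graded per-condition demands
in the test suite exercises a genuinely non-trivial path on the same grid.

## Numerical choices

- All LPs (FBA and the correction programs) are solved with scipy's
  HiGHS interface at a primal feasibility tolerance of 10⁻⁹.
- Capacity rows are row-normalized before solving to tame the dynamic
  range of abundance-scaled coefficients (configurable off); a failed
  solve is retried once with the opposite scaling setting.
- The objective vector is rescaled so its smallest nonzero coefficient
  stays above the solver's dual feasibility tolerance; otherwise a tiny
  λ (e.g. 10⁻¹⁴/|M|) renders the correction penalty invisible to the
  solver and arbitrary ω-optimal vertices are returned. The rescaling
  does not change the argmin.
- Every returned solution is re-verified by an independent constraint
  checker that walks the model and condition objects directly (never the
  assembled matrices); violations above 10⁻⁶ are reported.
- FBA objective values are unique, so scenario error tables are
  deterministic; where a flux *pattern* is needed (synthetic data
  generation, negative-correction cuts), a parsimonious second stage with
  seeded weight jitter pins it down reproducibly.

## Variability and sampling

With the per-condition errors fixed to [0.99, 1.01]·ω_opt and the total
correction to Δ_opt ± 10⁻³, each δᵢ is minimized and maximized over the
remaining polytope. The Δ tolerance is applied in the internal correction
units (s⁻¹), consistent with Δ's definition as a sum of kcat corrections.
If the restricted polytope is numerically empty the tolerances are
widened once (×10) with a warning. Sampling draws vectors uniformly
within the per-enzyme intervals and projects each onto the polytope by
minimizing the L1 distance (split variables); projection ties are broken
by the lexicographically least vertex (enzymes in identifier order) for
reproducibility. Interval draws plus L1 projection do **not** sample the
polytope uniformly — points concentrate on its boundary — but the scheme
is reproduced as specified; a hit-and-run sampler is out of scope.

## Negative corrections (second stage)

Positive corrections cannot address *over*prediction in the pool-only
scenario. The optional second stage reduces kcats of measured enzymes —
yielding apparent catalytic rates rather than condition-independent
kcats — via a cutting-plane scheme in reciprocal-kcat space ρᵢ = 1/kcatᵢ:

1. For every condition, the scenario-(iii) optimal flux pattern under the
   positively-corrected model fixes a per-enzyme lower kcat bound (the
   pattern must stay feasible), so scenario-(iii) predictions are
   preserved *exactly* by construction.
2. Each pool-only FBA optimum that overshoots μ_exp contributes a linear
   cut: the MW-weighted usage cost per unit growth along that flux
   direction, a linear function of ρ, must reach pool-cap/μ_exp.
   Conditions at or below μ_exp contribute protective cuts keeping their
   optima feasible.
3. A small master LP over ρ (slack-minimizing, with a tiny preference for
   the smallest reductions) is alternated with re-solving the pool-only
   FBAs until no condition overshoots or the cut set stabilizes
   (≤ 15 rounds).

Positive and negative corrections are never sought in one objective: a
joint L1 objective would simply zero the negative part whenever
proteomics constraints prevent overprediction. If the master LP is
infeasible or scenario-(iii) errors drift beyond 10⁻⁶, the stage returns
the unchanged positive-correction result with a diagnostic.

## Synthetic data generator

`make_toy_network` builds an uptake → linear chain → (optional parallel
branches) → biomass topology with one enzyme per reaction, one
two-subunit complex (reaction 2) and one isozyme pair (reaction 3); kcats
are log-uniform in [0.1, 100] s⁻¹ and molecular weights uniform in
[20, 200] g mmol⁻¹ — ranges typical of central metabolism.
`simulate_conditions` draws a substrate uptake bound per condition
(uniform in [1, 10] mmol gDW⁻¹ h⁻¹), solves FBA with the true kcats, sets
μ_exp to the growth of the returned flux pattern (so abundances and
growth are exactly consistent), and sets abundances to the usage that
pattern requires times a headroom factor (default 1.2) times
multiplicative lognormal noise of a chosen CV. Abundance noise is
multiplicative because abundances are positive and span decades; headroom
> 1 puts the binding constraint on abundances rather than the pool — the
regime the correction targets. Ptot, f and σ are set so the pool holds
with slack 1.5. Enzymes unused at the optimum receive a floor abundance
of 10⁻⁶ mmol gDW⁻¹.

`deflate_kcats` divides chosen enzymes' kcats by known factors > 1; the
ground-truth correction is kcat_true − kcat_deflated. Recovery is exact
(to solver precision) for enzymes whose capacity binds in at least one
condition; enzymes that never bind are unidentifiable and only their
zero-correction sparsity is asserted. In the noisy-recovery analysis,
each seed simulates the largest condition collection once and smaller
collections are its prefixes — a growing experiment collection — which is
what makes the error trend across collection sizes comparable per seed.

**What the generator does not emulate:** genome-scale topology, realistic
growth rates (toy biomass flux equals chain flux, so μ falls in
1–10 h⁻¹), missing abundances (every toy enzyme is measured everywhere,
so the unmeasured-enzyme pool path is exercised only where tests restrict
M explicitly), measurement noise in growth/uptake rates, GAM fitting, and
condition-specific biomass composition. Passing tests demonstrate the
correctness of the optimization machinery on data whose generating model
matches the fitting model — not performance on real proteomics data.

## Enrichment statistics

The enrichment p-value is the standard hypergeometric upper tail
P(X ≥ x) for x corrected enzymes among N drawn from a background of
M measured-in-all enzymes with K annotated to the term. A variant
(`mode="as_printed"`) starting the complementary sum at i = 1 — thereby
adding P(X = 0) — is preserved for fidelity to a common misprint of the
formula; the default is the standard tail. Terms with fewer than two
corrected enzymes are excluded *before* testing, and Benjamini–Hochberg
step-up (hand-implemented, cross-checked against statsmodels in the test
suite) runs over the tested terms only, at FDR 0.05.

## Known limitations

- The correction LP omits the pool row for measured enzymes (their
  capacities use measured abundances directly); in data where measured
  enzyme mass approaches the pool cap this slightly relaxes the training
  problem relative to the validation scenarios. A warning is raised when
  measured mass exceeds the cap.
- GAM enters only as an input coefficient; the package does not fit it
  and the toy generator does not use it.
- The sampling scheme is boundary-biased (see above).
- The negative-correction stage preserves the *stored* scenario-(iii)
  optimum; alternative scenario-(iii) optima with different enzyme usage
  could in principle allow deeper reductions.
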