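# Methods

`pittaforage` implements the quantitative chain of a nestling-provisioning
study of a vermivorous forest bird (a pitta): from per-visit feeding records
to diet composition, earthworm biomass budgets, whole-breeding-event
consumption, and a predicted breeding home range compared against the
observed home-range band. This note documents the models, the constants and
their units, the synthetic-data generator, and the numerical choices.

## Observational model

The unit of observation is a **feeding visit**: one parental trip to the
nest with a beak-load of prey. Visits are grouped into **sessions** (one
nest on one observation day). Prey items are identified to one of twelve
taxonomic categories, or flagged unidentifiable/unknown; lengths are
estimated in quarter-beak units and converted at 2 cm per beak length, so
lengths live on a 0.5 cm grid. Parents sometimes cut ("sunder") long
earthworms into pieces; an item represents the reconstructed pre-sundering
worm with the piece count recorded.

Derived categoricals follow the field protocol: visit type
NoE/OnlyE/MIX by earthworm content; time of day morning/noon/afternoon on
[8,10), [10,14), [14,18] (the protocol leaves boundary assignment open; we
use half-open intervals closing the day at 18:00); rain light/heavy with
heavy strictly exceeding 4 mm/day; brood age young (1–7 d) / old (8–13 d).
The first visit of each session has no preceding inter-visit interval and
is excluded from interval-based analyses (`exclude_first_visits` removes
exactly one visit per session).

Unknown-taxon items are retained in the table but excluded from
diet-composition denominators; unmeasured items are excluded from length
summaries and biomass sums. Both exclusions are counted in the validation
report.

## Bioenergetic chain

All constants sit in `EnergeticsParams` with these defaults:

| constant | value | units | role |
|---|---|---|---|
| allometry slope / intercept | 3.19 / −15.85 | — | AFDM(g) = exp(3.19 ln L(mm) − 15.85), Megascolecidae |
| fresh : AFDM | 5.7904 | g/g | fresh mass from ash-free dry mass |
| DEE coefficient / exponent | 1092 / 0.729 | kJ d⁻¹ at 1 kg | DEE = 1092 · BM^0.729, BM in kilograms |
| adult masses | 0.109 / 0.0715 | kg | male / female |
| pair DEE (printed) | 377 | kJ d⁻¹ | rounded pair total used downstream |
| worm energy density | 16.72 | kJ g⁻¹ AFDM | |
| mean worm AFDM | 0.12258 | g | converts energy to worm counts |
| provisioning hours | 15 | h d⁻¹ | 05:00–20:00 |
| nestling / incubation / building | 12.05 / 14 / 10 | d | breeding event = 36.05 d |
| standard brood | 5 | nestlings | |

Body mass enters the DEE power law in kilograms: this is the only unit
choice under which the sex-specific masses give a pair total (376.6 kJ/day)
that rounds to the printed 377, and a regression test guards it. Downstream
consumption uses the *printed* 377 rather than the unrounded sum, because
the published consumption equation fixes that constant; with it, diet
proportions p = 0.3 and 0.7 give family totals of exactly 2,844 and 5,497
worms. Worm counts are rounded half-up to integers at the reporting step
only; intermediates keep full precision.

Brood consumption extrapolates observed rates: per nest-day, worms (and
summed AFDM) per recorded hour; per nest, the day-mean rate × 15 h ×
12.05 d; per nestling, divided by brood size; the **standardized brood** is
the cross-nest mean per-nestling value × 5. The default nest selection
drops the nest with the fewest recorded days before averaging (mirroring
the use of the three best-sampled nests), configurable to `all`. Stage-
specific energy needs (egg production, incubation) are not modelled; the
parental budget applies one DEE across the 36.05-day event.

## Home-range prediction and overlap

A consumer needing N worms in habitat with epigeic density d (0.53–8.7
worms/m²) of which a fraction a is available needs A = N/(d·a) m². Density
is an interval, so each availability maps to a predicted band
[N/(8.7a), N/(0.53a)]. The band is compared with the observed home-range
band (10–30 ha primary; 10–20 and 5–20 ha alternatives) by integrating the
intersection length over a ∈ [0.005, 0.05] with a left-endpoint Riemann sum
at step 10⁻⁵ on the linear area scale (the stated resolution; the
quadrature rule is our choice, and halving the step changes results by
<0.1%). The **relative overlap index** expresses each scenario's integral
as a percentage of the maximum over the compared set — brood-only plus the
five family scenarios (p = 0.3…0.7) — normalised within each observed-band
option. The integrand measures intersection length in m²; indices are
invariant to that global unit choice.

## Synthetic-data generator

The generator stands in for the field data: 4 nests (brood sizes 5,5,6,5),
~8 sessions per nest over a 12-day nestling period, 3–6 h sessions starting
08:00–12:00, heavy-rain days with probability 0.3. Visits arrive as a
renewal process with gamma inter-visit gaps (marginal target mean 35 min,
SD 26 min), shortened multiplicatively in the morning (×0.8) and for old
broods (×0.85). Visit types target marginal shares OnlyE/MIX/NoE =
0.648/0.305/0.047 with NoE and MIX enriched for old broods (odds ×4 and
×1.5). OnlyE loads carry 1–6 worms (truncated-geometric, marginal mean 2.6,
median 2; heavy-rain mean ×0.8); MIX loads carry 2–7 items (mean 3.4) with
at least one worm and one other item; NoE loads carry one item. Earthworm
lengths are gamma draws truncated to [0.5, 15.5] cm and quantised to 0.5 cm
(marginal mean 6.34, SD 2.5 cm), longer under heavy rain (×1.15) and
coupled to the load's worm count as n^(−1/3.19), which makes total load
AFDM approximately count-invariant under the length–mass allometry.
Non-earthworm lengths target mean 3.59, SD 2.4 cm. A small fraction of
items are unknown-taxon (4.4%) or unmeasured (2%), exercising the
validation paths.

Because the targets are *marginal* while the effects are *conditional*, the
configuration resolver solves the class-conditional parameters at
generation time: an iterative proportional fit finds young/old visit-type
shares whose visit-weighted mixture hits the marginal target; rain-class
count and length means are mixed by the expected heavy-visit weight; the
count–length coupling constant is solved over the combined OnlyE+MIX
worm-count distribution; and the base interval mean absorbs both the
expected morning/old multiplier and a renewal censoring correction — only
gaps completed inside a session are recorded, and the discarded
boundary-straddling gap is length-biased, so the recorded mean is
approximately μ(1 − cv²μ/T) for session length T, which the resolver
inverts. Residual approximation error is covered by the recovery-report
tolerances (3× the Monte-Carlo standard error at the realised n plus a
small systematic allowance).

One root RNG per dataset spawns per-nest substreams deterministically, so
identical (config, seed) reproduce a dataset byte-for-byte.

What the generator does **not** emulate: parental movement and foraging
search, earthworm population dynamics, within-day weather, between-year
variation, and the full covariate joint distribution behind the study's
mixed-model analyses. Passing recovery tests therefore show that the
pipeline measures what the generator encodes — not that the field system
satisfies those distributions.

## Statistical tests

The age-effect contingency analysis uses a two-sided Fisher exact test per
nest (the "probability ≤ observed" convention, the dominant two-sided rule)
on young/old × earthworm/other tables (item level) or young/old ×
OnlyE/other (visit level), pooled with Fisher's combined probability test
(X = −2Σln p, chi-square with 2k df). Per-nest p-values are always reported
alongside the combined value so that single-nest-driven results remain
inspectable. Nests missing one age class carry no information for the 2×2
and are excluded with a warning, reducing df. Length summaries use the
sample (n−1) SD throughout.

## Problem sizes and numerical choices

Unit tests run on handcrafted fixtures and a study-sized synthetic dataset
(4 nests, ≈260 visits); Monte-Carlo recovery checks use a 200-session
dataset (20 nests × 10 sessions, ≈1,500 visits), the smallest size at which
3×SE tolerances are meaningfully tight. The overlap integral uses the
stated 10⁻⁵ step (4,500 evaluation points), with an analytic piecewise
closed form (linear-plus-logarithmic segments between band crossings) as
the independent oracle in tests. The exact-enumeration oracle for the
Fisher test covers all 2×2 tables with margins ≤ 30 via integer
arithmetic.

## Known limitations

- The standardized-brood figure used in the published family totals (855
  worms for five nestlings) derives from per-nest daily counts that are not
  part of the main-text record; the pipeline recomputes brood consumption
  from any supplied visit table, and treats 855 as the reference input when
  reproducing the published family totals.
- The published "70–80 worms daily ≈ 910–1,040 per event" cross-check
  implies a ~13-day multiplier, inconsistent with the 12.05-day nestling
  stage used everywhere else; we use 12.05 and do not reconcile the aside.
- The overlap index compares scenarios within an assumed availability
  domain (0.5–5%) that rests on very sparse detectability evidence; indices
  are relative, not absolute measures of fit.
- Energy content, mean worm mass and densities are treated as fixed
  constants; no uncertainty propagation beyond the scenario grids.
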