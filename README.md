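# pittaforage

Nestling diet, earthworm bioenergetics, and breeding home-range prediction
for a vermivorous forest bird.

Insectivorous birds that specialise on earthworms (vermivores) tie their
breeding success to a prey resource whose availability swings with rain
and soil condition. `pittaforage` is a tested implementation of the
quantitative chain used to study one such specialist, a pitta provisioning
its nestlings: it takes parental feeding-visit records (one row per prey
item per visit), summarises diet composition and provisioning behaviour,
converts earthworm lengths to biomass, extrapolates observed provisioning
rates to the consumption of a whole breeding event, and translates that
consumption into the home-range area a breeding family would need —
compared against field-based home-range estimates.

It is aimed at ornithologists and conservation ecologists who want the
full pipeline reproducible end to end, including a seeded synthetic-data
generator that emulates the structure of a nest-camera provisioning study
so every stage is testable without field data.

## The model in brief

- **Biomass.** Earthworm ash-free dry mass from length (mm):
  `AFDM(g) = exp(3.19 · ln L − 15.85)` (Megascolecidae allometry); fresh
  mass = 5.7904 × AFDM.
- **Energy.** Adult daily energy expenditure `DEE = 1092 · BM^0.729`
  (BM in kg, kJ/day); a pair at 109 g + 71.5 g rounds to 377 kJ/day.
- **Consumption.** Brood: observed worms/hour × 15 provisioning hours ×
  12.05 nestling days, standardised to a brood of five. Parents:
  `p · 377 · 36.05 / (0.12258 · 16.72)` worms for a diet proportion `p`
  over the 36.05-day breeding event. Family = brood + parents.
- **Home range.** Area holding N available worms: `A = N / (d · a)` m²
  for density d ∈ [0.53, 8.7] worms/m² and availability fraction a.
  Predicted bands are integrated against the observed home-range band
  over a ∈ [0.5%, 5%] and ranked by the relative overlap index
  (% of the best-overlapping scenario).
- **Diet statistics.** Composition over identified items, visit types
  (NoE / OnlyE / MIX), prey-length summaries, and per-nest Fisher exact
  tests pooled with Fisher's combined probability test for the
  nestling-age effect.

See `docs/methods.md` for assumptions, parameters and limitations.

## Worked example

Run the whole pipeline on a seeded synthetic dataset:

```sh
pittaforage report --outdir out --seed 1
```

```
pittaforage pipeline report
source: synthetic

visits: 261 total, 229 after excluding first visits per session
identified prey items: 747 (5 unknown excluded); earthworms 81.5%
visit types: NoE 5.0%, OnlyE 65.1%, MIX 29.9%, YesE 95.0%
earthworm length: mean 6.17 cm (SD 2.49, n=596)
age contingency (item level): combined p = 0.366 (df=8)

pair DEE: 377 kJ/day
standardized brood consumption (brood of 5, nests nest2,nest3,nest4): 768 worms
family consumption: p=0.3: 2757, p=0.4: 3420, p=0.5: 4083, p=0.6: 4746, p=0.7: 5410

relative overlap index by observed band:
  10-30 ha: brood 7.3%, family_p0.3 58.0%, family_p0.4 72.6%, family_p0.5 84.2%, family_p0.6 93.2%, family_p0.7 100.0%
  10-20 ha: brood 11.2%, family_p0.3 69.2%, family_p0.4 84.3%, family_p0.5 93.9%, family_p0.6 99.0%, family_p0.7 100.0%
  5-20 ha: brood 19.2%, family_p0.3 81.4%, family_p0.4 91.3%, family_p0.5 97.3%, family_p0.6 100.0%, family_p0.7 99.9%
```

Reading it: the simulated nests received mostly earthworms (81.5% of
items; 95% of visits contained at least one worm). Observed provisioning
rates extrapolate to 768 worms for a standardized brood of five over the
nestling stage; adding the parents' share at diet proportions 0.3–0.7
gives family totals of ~2,800–5,400 worms per breeding event. Converted to
foraging area, the scenario assuming earthworms supply 70% of the adult
energy budget overlaps the observed 10–30 ha home-range band best (index
100%), i.e. a breeding family's energy demand alone is enough to explain
home ranges of that size.

The stages are also available separately (`simulate`, `summarize`,
`consume`, `homerange`), composing on the intermediate CSVs, and as
library functions (`pittaforage.diet`, `.energetics`, `.homerange`,
`.synthetic`).

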