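# antbiogeo

Statistical ecology of island ant communities: sample-based rarefaction with
asymptotic "active species" estimation, spatial and temporal turnover
statistics, island-biogeography tests, and a Markov model of assemblage
dynamics — built around the 2005–2009 All Taxa Biodiversity Inventory of ants
on the Boston Harbor Islands (Boston, MA, USA), whose printed summary tables
ship with the package as fixtures.

## The problem

A bounded survey region holds a finite species pool, but only a fraction of it
is *detectable* in any given week: ant colonies persist year-round while their
foraging activity switches on and off. Two questions follow. How many species
are actually active, once sampling effort is corrected for? And how does the
cast of active species change across space and time?

The package answers these with four pieces of machinery:

- **Rarefaction** (`rarefy`, `curve_summary`): repeatedly permute the pool of
  collecting events and accumulate distinct species, giving the expected
  richness E[S(N)] at every effort N with an empirical 95% envelope.
  Occurrence-based throughout — a species counts once per event regardless of
  individuals, which suits nest-centred ant ecology.
- **Active species** (`fit_asymptote`, `active_species`): fit the saturating
  curve S(N) = S·(1 − e^(−qN)) to each rarefaction trajectory; the asymptote S
  estimates the species collectible with unbounded effort in the sampled
  window. Fits of S = 0 and the top and bottom 10% of estimates are trimmed;
  the survivors give S̄ ± SD. The Chao II incidence estimator
  S_obs + ((m−1)/m)·Q₁(Q₁−1)/(2(Q₂+1)) serves as the cross-check.
- **Turnover** (`alpha_per_event`, `spatial_turnover`, `bray_curtis`,
  `weekly_temporal_turnover`): species per event (α), the spatial ratio S/α,
  and Bray-Curtis dissimilarity 1 − 2Σmin(uᵢ,vᵢ)/(Σu+Σv) between consecutive
  sampled weeks' occurrence vectors.
- **Assemblage dynamics** (`assemblage_markov` operations in
  `antbiogeo.markov`): per-plot assemblage series on ~2-week steps with
  capture–recapture gap filling, G-test merging of indistinguishable
  assemblages by species-set intersection, multi-counted transition
  tabulation, Bossert-style column merging into a reduced stochastic matrix,
  and its stable state distribution π (left eigenvector at eigenvalue 1 —
  relative persistence time, not a probability vector). A four-state
  projection onto the three dominant species (*Aphaenogaster rudis*,
  *Myrmica rubra*, *Tetramorium caespitum*) plus "all other communities"
  mirrors the headline community model.

A first-class synthetic generator (`antbiogeo.synthetic`) emulates the study
conditions — ten islands with the published geography, five seasons of
biweekly sampling, ~1,400 events, per-plot two-state activity dynamics — with
full ground truth, so every stage is testable without the unpublished field
dataset. See `docs/methods.md` for the model and its calibration.

## Worked example

```bash
python examples/active_species_estimation.py
```

```
Grape: 140 events, 31 species observed, true pool 32
annual active species S = 30.05 +/- 0.38
average week         S = 19.64 +/- 5.54 (14 weeks with >= 5 events)
Chao II              S = 31.00 +/- 0.12
```

The annual asymptote (30.1) recovers nearly the whole 32-species resident
pool and agrees with Chao II, while an average single week supports only ~20
collectible species — the same space hosts different species at different
times, here about 65% of the annual figure. The other scripts in `examples/`
walk through the inventory arithmetic on the printed tables
(`inventory_summary.py`: 51 species, 3,311 occurrences), the turnover report,
the biogeography regressions/ANCOVA, and the four-state Markov model.

A thin CLI wraps the same pipeline: `antbiogeo all --simulate --seed 1 --out
run1/`, or `antbiogeo inventory --matrix src/antbiogeo/data/island_occurrences.tsv
--out run2/` for the printed-matrix-only mode (event-level stages report
SKIPPED).

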