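# behavchain

Markov-chain analysis of scan-sampled dolphin behaviour under human
pressure.

Spinner dolphins rest by day in shallow reef lagoons, where swim-with
tourism and research vessels operate within a few hundred metres of the
resting schools. The question this package addresses is whether that
presence changes the dolphins' behaviour — specifically, whether the
states characteristic of rest (tight group cohesion, a single school, no
aerial activity) persist less when boats or swimmers are nearby, after
accounting for the natural diel rhythm and for differences between sites
and seasons. It is written for behavioural ecologists and marine-mammal
researchers who collect focal-follow scan-sampling data and want a tested,
reproducible implementation of the full analysis chain.

## The method

Field data are instantaneous scans of a focal group every 150 s: three
binary behavioural indicators (cohesion tight/loose, formation
single/multiple, aerial inactive/active) plus counts of boats and swimmers
in proximity. Clock times are normalized to the fraction of daylight
(0 = sunrise, 1 = sunset) and binned into morning, midday and afternoon.

1. **Pressure sessions and exposure.** A pressure session is a run of ≥ 5
   scans with human activity, never interrupted by more than 10 min
   without it. Exposure is the proportion of a follow's scans in a time
   category that carry activity (13 of 50 scans → 0.26).
2. **Control and pressure chains.** Consecutive scan pairs form behavioural
   transitions. A transition joins the *pressure* chain if activity is
   present at either endpoint, and the *control* chain only if no activity
   occurred at the endpoints nor during the preceding 15 min washout.
   First-order chains are checked against zero-order by BIC.
3. **Log-linear model selection.** Transitions are cross-classified into
   contingency tables (preceding, succeeding, chain, location, time; season
   within sites). Hierarchical log-linear models — each adding effect terms
   such as `Chain`, `Time + Chain` or `Time × Chain` to the
   preceding–succeeding association — are fitted by iterative proportional
   scaling and scored by `AIC = G² − 2·df`, where
   `G² = 2·Σ obs·ln(obs/fitted)`. The best model minimizes AIC and models
   within 2 units have substantial support.
4. **Stationary distributions and effect sizes.** For each chain the 2×2
   transition matrix is estimated by maximum likelihood and its stationary
   distribution π = πP solved exactly. Control and pressure proportions of
   the rest-indicative state are compared with a pooled two-proportion
   z-test and a directional Cohen's
   `h = 2·arcsin(√p_pressure) − 2·arcsin(√p_control)`
   (h < 0: less rest under pressure), both inter-site (tourism site vs a
   designated control site) and intra-site.

Because the original field observations are not deposited, the package
ships a synthetic-data generator (`behavchain.synthetic`) that simulates
the full study design — follows, sessions, diel structure, blanks — from
configured transition matrices, giving every stage an exact ground truth.

## Worked example

```bash
python analysis/01_simulate_study.py      # synthetic 3-site study, seed 1
python analysis/02_sessions_exposure.py
python analysis/03_transition_chains.py
python analysis/04_model_selection.py
python analysis/05_effect_sizes.py
```

The drivers write their tables under `results/` and print a narrative. With
the default seed the order check prints, for cohesion,

```
  cohesion: 5445 transitions, BIC order-0 5749.4 vs order-1 4873.9 -> order 1
```

— the first-order chain wins decisively, as it should for sticky
behavioural states. Model selection recovers the generating structure (a
pressure effect common to all sites and times):

```
    cohesion: best 'Chain' (AIC -47.31), 1 supported
```

and the effect report shows what that means behaviourally, e.g. intra-site
at the second tourism lagoon:

```
    cohesion   lagoon_b    midday: h -0.22 (medium), z -2.95**
```

tight cohesion is less frequent under pressure (negative h, a medium
effect, p < 0.01). Under a null configuration (pressure dynamics equal to
control) the same report shows only small, non-significant h.

The same pipeline runs from a single config, or on external data in the
documented CSV formats (see `behavchain/datamodel.py`):

```bash
behavchain all --config config.yaml --out results/run --seed 1
```

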