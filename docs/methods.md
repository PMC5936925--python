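# Methods

This note documents the statistical model, the conventions the
implementation commits to where the field protocol leaves room, the
synthetic-data generator and what it does and does not emulate, and the
numerical choices. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model and diel normalization

A scan record carries three binary behavioural indicators — cohesion
(tight/loose), school formation (single/multiple), aerial activity
(inactive/active) — any of which may be blank (group not visible at the
scan), plus boat and swimmer counts. Pressure presence is *derived* as
`n_boats + n_swimmers > 0` and never stored, so the flag and the counts
cannot disagree.

Clock time is normalized to the fraction of daylight elapsed,
`(t − sunrise)/(sunset − sunrise)`, and categorized into three equal
periods with half-open boundaries [0, 1/3), [1/3, 2/3), [2/3, 1]. The
often-quoted 0.33/0.34 boundaries are the two-decimal rendering of exact
thirds; implementing exact thirds keeps the categorization a total,
deterministic function. Scans outside daylight are rejected (they cannot
be diel-categorized); sunrise/sunset are inputs, not computed. All times
are naive local times; sun times must use the same convention.

Follows recorded at another regular interval are mapped onto the 150 s
grid: decimation when the source interval divides the target, otherwise
nearest-scan matching within half the target interval with unmatched grid
points marked as gaps. The rule is declared and configurable because the
original standardization procedure for the odd-interval site is not
recoverable.

## Sessions and exposure

A pressure session is a maximal run of pressure-present scans with at
least 5 such scans, merging across pressure-free stretches of at most
10 min. The interruption is measured net of one scan interval — elapsed
time between successive pressure scans minus 150 s — which makes the rule
exact on the scan grid: up to four consecutive missing scans merge, five
split. Session duration runs from first to last pressure scan (no
half-interval padding; the alternative is a one-line change and the choice
is recorded in the run manifest). Boat/swimmer medians are computed over
the session's pressure scans; a session's diel category is that of the
scan nearest its midpoint. Exposure in a time category is pressure scans /
total scans for the follow; a category with no scans has *undefined*
exposure, distinct from 0. Daily cumulative activity is pressure-scan
count × 150 s, which is invariant to how the day's scans are split into
follows. Sample s.d. uses n − 1; single-observation groups report 0 with a
degeneracy flag. Research and tourism activity are pooled by default, with
a purpose filter available.

## Chain construction

A transition is a pair of consecutive scans exactly one nominal interval
apart with both indicator states observed; transitions never span follow
boundaries, gaps or blanks. Labelling:

* **pressure** — activity present at either endpoint (default; `both` and
  `succeeding` conventions available and recorded in the manifest);
* **control** — no activity at the endpoints *and* at every recorded scan
  in the 15 min before the succeeding scan, *and* the follow actually
  covers that window. Absence that was not observed cannot be certified,
  so the first 15 min of every follow yield no control transitions;
* otherwise excluded (e.g. transitions shortly after a session ends).

A transition straddling a diel boundary takes the succeeding scan's
category. Zero- vs first-order chains are compared by
BIC = −2 log L + k ln n with k = 1 (i.i.d. succeeding state) vs k = 2 (one
Bernoulli per preceding state).

## Log-linear models

The scientific question is conditional — does P(succeeding | preceding)
depend on time, location/season, chain? Every model therefore contains
(i) the full interaction among the preceding state and all conditioning
factors, so the sampling distribution of conditions is fitted exactly and
never drives model comparison, and (ii) the preceding–succeeding
association. An effect term E ⊆ {time, location, season, chain} adds the
generator {preceding, succeeding} ∪ E; `Time × Chain` thus lets transition
probabilities vary freely over time-by-chain cells, while `Time + Chain`
modulates them additively on the log-odds scale. The family enumerated is
every antichain of singleton and pair terms (the empty antichain is the
null model).

Fitting is iterative proportional scaling to the generator margins,
convergence at max margin discrepancy < 1e-10, cap 10,000 cycles (the cap
has never been reached in testing; non-convergence is flagged, never
silently accepted). Degrees of freedom are cells minus parameters of the
hierarchical parametrization (sum over the downward closure of the
generators of ∏(levels − 1), plus intercept). Sampling zeros are kept;
cells forced to zero by a zero sufficient margin reduce df one-for-one; a
flattening constant (+0.5 to every cell) is available for sensitivity
analysis but off by default. `G² = 2·Σ_{obs>0} obs·ln(obs/fitted)`;
`AIC = G² − 2·df`, so the saturated model scores 0 and parsimonious
well-fitting models go negative; the support window is ΔAIC ≤ 2, ties
broken toward fewer effect terms then label. The engine is checked against
an independent Poisson-GLM maximum-likelihood fit (statsmodels) in the
test suite; the df convention for sparse tables is a declared choice
recorded with the outputs, since no universal convention exists.

## Stationary distributions and effects

Stationary distributions solve the linear fixed-point system
(Pᵀ − I)π = 0, Σπ = 1 — not matrix powering — so reducible or periodic
matrices raise a degeneracy error instead of returning a start-dependent
answer. For a 2-state chain this equals (p₁₀, p₀₁)/(p₀₁ + p₁₀), the
closed form used as the oracle in tests.

Effects compare the stationary proportion of the rest-indicative state
(tight, single, inactive) between chains. The z-test uses pooled variance
by default (unpooled available); its n is the number of transitions
supporting each stationary estimate — a declared choice, since the
stationary proportion is not literally a binomial count. Cohen's
h = 2·arcsin(√p_pressure) − 2·arcsin(√p_control) is banded |h| < 0.2
small, 0.2–0.65 medium, ≥ 0.65 large; the conventional anchors are
0.2 / ~0.5 / >0.8, and the band edges are declared midpoints. No
multiple-testing correction is applied by default (raw p-value stars at
0.05/0.01); Holm correction is available. Inter-site comparisons consume
only the control chain of the designated control site and only pressure
chains of the other sites — tourism-site "control" data are never used as
the control side of an inter-site contrast, and the pairing refuses to
fall back silently when a counterpart is missing.

## Synthetic-data generator

The generator is first-class, tested code: it defines the conditions under
which every downstream claim is verified. Per site and survey date
(school presence an independent Bernoulli per day, defaults 1.0 / 0.73 /
0.93 across the three default sites), a follow spans daylight at 150 s.
Pressure sessions are generated as intervals first — start time a
truncated normal on the daylight fraction, duration log-normal
(parameterized by mean/s.d.; defaults 75/75.1 min at the busiest tourism
site, 42/13.2 min at the research-only site, matching the right-skewed
durations typical of such operations), per-session Poisson boat and
swimmer counts held constant within the session — and scans are labelled
by membership, as in the field where pressure is recorded per scan. Each
indicator evolves as a first-order chain whose matrix is selected per scan
by (time category, pressure condition); the condition uses the same
either-endpoint convention as the extractor, so recovery tests close the
loop exactly. Default control dynamics are sticky in the rest state
(e.g. cohesion [[0.90, 0.10], [0.40, 0.60]], stationary tight proportion
5/6); default pressure dynamics halve rest persistence
([[0.75, 0.25], [0.55, 0.45]]). Blanks are inserted independently per
scan (default probability 0.05) masking all indicators while the
underlying chain keeps evolving — the real blank process is
surfacing-driven and autocorrelated, which is deliberately not modelled.

What the generator does *not* emulate: spatial movement of dolphins or
boats (pressure is a mark, not a trajectory), observer error, missing
follows within a day, state-dependent blanking, or between-day behavioural
carry-over. Passing recovery tests therefore demonstrates correctness of
the estimators under the stated generative model, not robustness to those
field realities.

## Validation studies and problem sizes

The studies in `behavchain.studies` (run by the test suite and the
acceptance script) use: 1000 random matrices for solver/closed-form
agreement; 100 random 2×2×2 tables (counts 1–5) for engine/GLM agreement;
100 replicates at 2000 transitions per chain for model recovery (null and
midday-only Time × Chain scenarios, ≥ 80 % supported-set inclusion
expected); 3000 transitions per cell for effect localization (true midday
h = −0.259 under the default scenario matrices); and 1000 replicates at
1000 transitions per chain for z-test calibration. The calibration null
uses a memoryless matrix (both rows [0.7, 0.3]) because the z-test treats
supporting transitions as independent draws; that assumption is exact for
a memoryless chain (the delta-method variance of the stationary estimate
equals the binomial variance there). For sticky chains the test is
anti-conservative — a known limitation inherited from applying a
proportion test to chain-derived proportions.

## Known limitations

* Two-state indicators and first-order chains only, matching the design.
* The df convention for sparse tables is one defensible choice among
  several; conclusions that hinge on df in near-empty cells should be
  checked with the flattening option.
* The strict washout censors the start of every follow; with short follows
  this discards a meaningful fraction of control transitions.
* Stationary-proportion z-tests ignore serial dependence (see above);
  effect sizes (h) are unaffected.
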