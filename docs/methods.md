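# Methods

## The statistic

For a community with an oldest ("founding") surname repertoire H and a
present-day repertoire P, a recruitment strategy produces a *selection*: a
multiset of units over the surnames of P. Under the low-kinship model (LK)
a unit is a surname type (one donor per surname); under the high-kinship
model (HK) every bearer of a selected surname is a unit. The
sampling-dependent bias is

    SDB = 1 − (number of units whose surname ∈ support(H)) / (total units).

It is a proportion in [0, 1]: 0 when every sampled unit bears a
historically documented surname (the founding-surnames strategy achieves
this by construction), 1 when none does. ΔSDB = SDB_LK − SDB_HK; it is
positive whenever the founding surnames hold disproportionately many
present-day bearers, which is the typical situation in stable communities.

SDB is invariant to surname relabeling and bearer order, and monotone under
unit addition (a non-shared unit can only raise it, a shared unit only
lower it); both properties are property-tested, and the statistic is checked
exhaustively against brute-force per-unit membership counting on every
repertoire with N ≤ 12 over a 4-surname alphabet.

## Strategies

- **R (random)**: with `n="all"` a deterministic census — every type (LK) or
  every bearer (HK). With numeric n, bearers are drawn uniformly without
  replacement (multivariate hypergeometric on the count vector); under LK
  the draw continues until n distinct surnames are held.
- **FQ (first quartile)**: surnames with count strictly above the 75th
  percentile of the per-surname count distribution. The percentile is
  computed by linear interpolation on the sorted counts; the estimator is
  isolated in one function since no canonical choice exists. If nothing
  lies strictly above (flat or tied spectra), the strategy falls back to
  the surnames tied at the maximum count and warns.
- **LS (locally spread)**: surnames whose annotated geographic origin equals
  the community's own province; unknown origins are excluded, and an
  optional national-bearer ceiling removes very common (likely
  polyphyletic) names. Origin annotation is an *input* (a surname →
  province table); the package never infers origins.
- **GP (grandparents)**: present-day surnames also attested in a mid-era
  repertoire (≈ two generations before the present source). Only the era
  criterion is modelled; birthplace information in the records is not part
  of the selection rule.
- **FS (founding surnames)**: present-day surnames attested in H — the
  SDB = 0 reference template.

All strategies except subsampled R are deterministic; selections satisfy
LK unit count ≤ S and HK unit count ≤ N.

## Isonymy and S/N

Random isonymy uses the unbiased (without-replacement) estimator
I = Σ nᵢ(nᵢ−1) / (N(N−1)), which equals 1 for a monomorphic repertoire and
0 for all-singletons and is well behaved at the small selection sizes the
restrictive strategies produce; the plug-in form Σ(nᵢ/N)² is available for
sensitivity checks. S/N (distinct surnames over bearers) is the crude
diversity measure used for the founding lists.

## Drift simulator

Surnames are treated as neutral alleles at a single patrilineal locus:
generation t+1 of size N_{t+1} is a multinomial draw on the surname
frequencies of generation t (Wright–Fisher). Bearer counts are treated
directly as transmitting lineages (male-only bookkeeping; surnames are
patrilineal here). Population size follows a geometric (constant-rate)
trajectory from N₀ to N_t under the growth model — only the endpoints are
known, so constant relative growth is the minimal assumption — or stays at
N₀ under the stationary model. Generation time defaults to 30 years
(roughly 14–18 generations across the studied spans); the generation count
is round(years / generation_time) and a span shorter than half a
generation is a configuration error.

Two mechanisms can inject non-founding surnames: per-birth *innovation*
(novel name, probability `innovation_rate`) and per-generation
*immigration* (binomial share `immigration_rate` of the new generation,
drawing surnames from an external pool, or founding novel lineages when no
pool is supplied). Both default to 0. Under the closed default the set of
present types is always a subset of the founding types, so the census SDB
against the founding list is **identically zero**: drift alone loses
surnames (founder retention decays) but cannot create unshared ones. The
drift comparison is therefore framed as *observed minus drift-expected*,
and any nonzero drift-expected SDB must be traced to explicit innovation or
immigration settings. Per replicate the simulator records the R/LK census
SDB and founder retention; it reports the per-iteration values, their mean
and the central 90% interval over (by default) 100 iterations.

Single-generation retention is validated against the closed form
Σᵢ(1 − (1 − pᵢ)^N) at 10,000 iterations on a three-surname toy.

## Jackknife

"Jackknife" here is delete-d style repeated random subsampling, not
leave-one-out (leave-one-out cannot produce fixed donor numbers): each of
201 replicates draws 20, 50 or (when N allows) 100 bearers uniformly
without replacement — a multivariate hypergeometric draw on the count
vector — and records 1 − SDB under both models and the subsample's S/N.
Sizes exceeding N are dropped with a warning. Under HK the mean sharing
fraction is exactly size-invariant (hypergeometric expectation); under LK
it is approximately so when shared and unshared surnames have comparable
frequency spectra, while the min–max spread shrinks with size in both
models.

## Source comparison and covariate screen

Two repertoires of the same community from different sources are compared
on per-surname counts paired over the union of supports (absent = 0):
squared Pearson correlation on the raw counts, and a chi-square homogeneity
test on a 2×K binned table in which surnames with expected counts ≥ 5 in
both sources form individual bins and the remainder is pooled — the
standard expected-count rule; the result is symmetric in the two sources.

The covariate screen regresses per-community SDB on altitude, present-day
N, foundation year and growth rate ((N_t − N_0)/N_t) by OLS simple
regression (R², slope sign, two-sided slope p). A constant response is
reported as R² = 0, p = 1 (no detectable association). Bonferroni
adjustment min(1, p·m) defaults to the full screen family m = 32
(4 strategies × 2 models × 4 covariates) even when only a subset of rows is
computed, so adjusted values do not depend on how the screen is sliced.

## Synthetic generator

`generate_founding` allocates N₀ bearers over S₀ ranked types with weights
r^(−shape) by largest remainder with a floor of one bearer per type
(S = S₀ and N = N₀ exactly); shape defaults to 1.2, a heavy-tailed but not
degenerate spectrum. `evolve_community` runs the drift chain with
descent-class bookkeeping keyed by (surname, class): children inherit the
father's class, innovators keep the father's class under a novel name, and
immigrants enter with class "immigrant".

Immigrant surnames are drawn from a finite external pool (default 400
types, same power-law weights): immigration is family- and
region-structured, so the same foreign surnames recur across events and
accumulate bearers, as in real present-day lists. Pool names never collide
with community names except through the explicit `collision_prob` knob,
which models polyphyly (identity by state): a colliding immigrant bears a
community surname while carrying immigrant descent, letting tests separate
IBS from IBD sharing.

The truth table classifies every present-day surname as founding /
immigrant-origin / innovation (a partition) and records the realized
immigrant-descent bearer fraction f. With novel (pool) immigrant surnames
and zero innovation, the census HK SDB equals f *exactly* — the identity
that turns the generator + metrics pair into a parameter-recovery problem.
For a cumulative target fraction f over G generations the per-generation
rate is m = 1 − (1 − f)^(1/G), since E[f_{t+1}] = m + (1 − m)E[f_t]
telescopes to 1 − (1 − m)^G; the recovery check at f ∈ {0.1, 0.3, 0.5}
demands the 200-replicate mean within two Monte-Carlo standard errors.

`generate_study` samples community parameters from ranges matching the
26-community design: founding totals log-uniform over 115–17,504 bearers,
founding S/N uniform over 0.08–0.45, growth rates −2.1–0.95, foundation
years 1447–1775 with a 1993 present, altitudes 0–1300 m. Its default
per-generation immigration (0.06 at sea level) decreases linearly with
altitude (`altitude_coupling`, default 0.7): isolated mountain communities
receive fewer immigrants, inducing the negative altitude–SDB association
the covariate screen is meant to recover; coupling 0 yields a null for
calibration tests. Mid-era snapshots are taken four generations (~120
years) before the present, emulating 1845–1915 marriage registers.

What the generator does **not** emulate: orthographic noise and
lemmatization errors (synthetic surnames are exact tokens), two-sex
demography and marital structure, spatially correlated migration between
communities, and the empirical frequency spectra of any real archive. Tests
passing on synthetic data therefore validate the pipeline's logic and its
estimators' calibration, not claims about any particular historical
population.

## Problem sizes and determinism

All randomness flows through `numpy.random.Generator` seeded explicitly;
reruns with the same seeds are byte-identical (asserted for the full report
bundle). The test suite uses exhaustive enumeration where feasible (1,819
count vectors × 15 historical supports for the SDB oracle), 100-iteration
drift runs over a full 26-community synthetic study, 200-replicate recovery
experiments, and 201-replicate jackknives on an N = 500 community — sizes
chosen to keep Monte-Carlo error well inside the asserted tolerances while
the whole suite runs in well under a minute.

## Known limitations

- Lemmatization is strictly rule-driven; no fuzzy variant detection is
  attempted, so unlisted orthographic variants count as distinct surnames
  (this inflates SDB slightly, mirroring archival practice where doubtful
  merges are refused).
- The drift simulator's immigration draws from a single static pool; real
  source populations drift too.
- The chi-square homogeneity test's binning rule (expected ≥ 5 per bin,
  rest pooled) is one defensible choice among several; with very sparse
  repertoires most surnames end in the pooled bin and the test loses power.
- The FQ percentile estimator and the strictly-above rule are conventions;
  alternatives (inclusive threshold, different percentile estimators) are
  easy to swap in but change selections on small tied spectra.
- Montecarlo's published growth rate (−2.09) does not equal the growth-rate
  formula applied to its own published counts (−2.19); the packaged table
  keeps the printed value verbatim and the discrepancy is asserted, not
  resolved.
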