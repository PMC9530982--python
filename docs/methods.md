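# Methods

This note documents the statistical model, the identification rules, the
synthetic-data generator, and the numerical and design choices behind
`confidnet`.

## The outcome and the model

The unit of analysis is the ordered pair: `Y_ij = 1` when participant *i*
regards participant *j* as a confidant.  Over *n* participants there are
n(n−1) ordered pairs and n(n−1)/2 unordered dyads, each dyad occupying one
of four states (null, i→j, j→i, mutual).  Density is reported on the
undirected collapse: the tie count with reciprocated duplicates merged,
divided by n(n−1)/2.

The model is an exponential-family random graph model,
P(Y = y) ∝ exp(θ·s(y)), with the statistics

* `edges` — the directed tie count (baseline propensity);
* `mutual` — the number of reciprocated dyads (reciprocity);
* `nodal_main(x)` — Σ over directed ties of (x_i + x_j), a covariate main
  effect in the sender+receiver sum convention (sender-only and
  receiver-only variants are available, since a report that prints one row
  per attribute does not distinguish them);
* `absdiff(x)` — Σ over directed ties of |x_i − x_j|.  A negative
  coefficient means less-similar pairs are less likely to be tied:
  homophily.

Every one of these statistics decomposes over dyads, so the likelihood
factorizes into a product of per-dyad four-state multinomials.  This has
three consequences the package exploits:

1. **Exact MLE** (`fit_exact`, the default): Newton iteration on the
   dyad-multinomial log-likelihood, with analytic gradient and Hessian.
   The log-likelihood is concave; standard errors come from the inverse
   observed information, p-values are two-sided Wald-normal.  For n ≤ 4
   the implementation is tested against summation over all 2^(n(n−1))
   directed graphs.
2. **Exact simulation**: each dyad's state can be drawn directly from its
   four-state distribution — a perfect, independent draw used by the
   synthetic generator and the recovery experiments.
3. **MPLE ≡ MLE without `mutual`**: with no reciprocity term the dyads'
   directed ties are independent and the pseudolikelihood *is* the
   likelihood; this equivalence is a standing test.

`fit_mple` (logistic regression of each Y_ij on its change statistic, via
statsmodels) and `fit_mcmle` (importance-sampled likelihood-ratio
maximization with networks simulated by a Metropolis–Hastings single-toggle
sampler, initialized at the MPLE, SEs from the simulated statistic
covariance) are provided for fidelity to the standard ERGM toolchain and
validated against the exact estimator.  MCMC defaults: burn-in 10·n(n−1)
toggles, thinning n(n−1), uniform ordered-pair proposals; non-convergence
is flagged in the fit object, never silent.

Odds ratios use exp(θ) with Wald 95% limits exp(θ ± z·SE) and
z = 1.959964 (not 1.96): this is what reproduces published OR/CI pairs at
two decimals from their printed coefficients.  Rounding (2 d.p. for
coefficients and ORs, 3 d.p. for density) happens only in report files;
machine outputs keep full precision.

## Instrument scoring

GDS-15 items are yes/no; an item scores 1 in the symptomatic direction.
Five positively worded items (1, 5, 7, 11, 13 in instrument order) are
reverse-keyed, i.e. score on "no".  The apathy subscale is items
{2, 9, 13}; the suicidal-ideation subscale is items {3, 7, 11, 12, 14};
the two sets are disjoint, so apathy + suicidal_ideation ≤ total.  The
keying lives in a swappable `GdsKey` table rather than in code.  A missing
item yields a missing score (the participant drops out of the analysis
set); nothing is zero-filled.

SMC is the sum of four 1–7 frequency items (range 4–28, higher = more
complaints); the severe-problem indicator is carried as metadata only.
TMIG-IC disability is coded 1 iff the 13-item sum is below the full score
of 13.  Covariates are coded against the reference categories of the
model: male, age <75 (so age exactly 75 codes 1), living alone, no
disability, and ≤9 years of education (the 10–12 and 13+ dummies; the
"other/unknown" band yields missing dummies and listwise deletion at fit
time).

## Tie identification

Step 1 (household): each household listing resolvable to a co-registered
participant (same household id, exact name match, sex agreement, age within
a 1-year tolerance) yields a directed tie, except that a respondent with
poor marital satisfaction (>6 on a 10-point scale oriented so higher = more
dissatisfied; threshold and orientation configurable) who also reports
having no confidants does not get ties to opposite-sex co-residents with an
age gap under 15 years.  This "likely-spouse" exception is implemented
literally; co-residents who are not study participants yield no tie.

Step 2 (community): a nomination carries only a name, so criteria (2)–(4)
compare the candidate to the *nominator*: same sex, age within 3 years,
same district, different address.  Criterion (1) is exact full-name
equality in the kanji rendering or the kana rendering, after Unicode NFC
normalization and whitespace trimming — no fuzzy matching, because the rule
is spelled-the-same.  Criterion (5) demands exactly one candidate; two or
more give an `ambiguous` outcome and no tie.  Every nomination receives
exactly one audit outcome in the match report.

Descriptives (components, geodesics) are computed on the undirected
collapse with isolates excluded; the mean geodesic averages shortest-path
lengths within components.  Directed-path geodesics would be an
alternative; the undirected choice matches the symmetric treatment of ties
in the density definition.

## The synthetic community

The generator emulates the survey population the pipeline is designed for:
~660 participants aged 65+ (truncated normal, mean 76.2, SD 7.3), 53.2%
women, 85.1% living with family, education bands (5/27.6/46.8/19.2/1.4%),
SMC mean 10.5 (SD 4.9), disability prevalence 0.545, GDS-15 mean 5.0
(SD 3.8) with apathy mean 1.4 and suicidal-ideation mean 1.3.

GDS items are Bernoulli draws sharing a per-person latent propensity
(logistic random effect).  Independent items with the target means would
give a total-score SD of only ~1.8; the propensity SD defaults to 1.38,
which reproduces SD ≈ 3.8, and the per-item base logits are solved by
Gauss–Hermite quadrature so the item-group means stay on target regardless
of the propensity spread.  An optional household-shared component of the
propensity is available (default off).  SMC items are generated by
splitting a clipped normal total into four 1–7 items that re-sum exactly.

Households: a fraction `p_spouse_pair` (default 0.2) of participants form
opposite-sex co-residing spouse pairs — the only source of within-roster
household ties, sized to produce roughly the observed count of
inside-household ties — while the rest of `p_live_with_family` is covered
by non-participant family members, which exercises the
unresolvable-household-member path.  Spouses share a surname; after the
surname substitution the generator re-establishes within-sex full-name
uniqueness (in both renderings), which noiseless identifiability requires.

The ground-truth network is the union of (a) household ties derived by the
same rule the tie builder applies and (b) community ties drawn from the
ERGM at θ* over the *allowed* dyad set — out-of-household pairs that are
same-sex, within 3 years of age, same district, different address — so
that every emitted nomination is re-identifiable.  The default draw is the
exact per-dyad sampler (a perfect draw from the same distribution the MH
sampler targets); `use_mcmc=True` routes through Metropolis–Hastings
instead.  The default θ* preset (`edges` −4.2, `mutual` 3.8,
`absdiff:gds_total` −0.10, on the constrained support) lands the generated
networks in the observed regime — ≈270–290 directed ties at n = 660,
collapsed density 0.001, a majority of ties reciprocated, visible GDS
homophily.  It is a documented preset, not a claim about the unobservable
truth of any real community.

Noise knobs (noisy mode only): `name_collision_rate` copies another
same-sex participant's name onto a fraction of records (creating
criterion-5 ambiguity), `out_of_roster_nomination_rate` replaces emitted
nominations with names outside the roster (criterion-1 misses), and
`age_gap_violation_rate` opens a fraction of age-incompatible dyads to tie
formation (criterion-3 losses at rebuild).

What passing the noiseless round trip shows — and what it does not: it
validates that the tie builder inverts the emission rules exactly on clean
data.  Real survey rosters have misspellings, nickname renderings,
age misreports and non-unique names; the noisy mode quantifies the loss
under such corruption, but no synthetic community certifies behaviour on a
particular real roster.

## Experiment sizes

The parameter-recovery experiment runs 100 communities of n = 100 at
θ* = (−2.2, 1.2, −0.06) and checks that the exact MLE's replicate mean is
within 3 Monte-Carlo SEs of θ* per term and that Wald 95% CI coverage lies
in [0.85, 0.99].  The preset is chosen dense enough (~110 reciprocated
dyads per community) that the MLE's finite-sample bias — which is real and
measurable in sparser regimes with ~50 reciprocation events — is
negligible against the Monte-Carlo error of 100 replicates; the recovery
experiment is a check of the estimator's asymptotic behaviour, not of
small-sample bias.  MCMC goodness-of-fit checks run on n = 3, where the
per-dyad state distribution is available in closed form.

## Known limitations

* Only dyad-separable terms are supported (`edges`, `mutual`, nodal main
  effects, `absdiff`); triangle/GWESP/degree terms, curved ERGMs and
  valued ties are out of scope.  `fit_exact` refuses non-separable models
  rather than silently approximating.
* Matching is exact-string; probabilistic record linkage is out of scope.
* The generator does not model survey nonresponse, and its
  `reports_any_confidant` flag is drawn independently of the realized
  network, so a respondent can report "no confidants" yet receive
  community ties — harmless for the pipeline (the flag only gates the
  household spouse exception) but a visible inconsistency in emitted
  surveys.
* Geodesics and components treat ties symmetrically; directed reachability
  is not reported.
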