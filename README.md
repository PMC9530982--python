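# confidnet

Confidant social networks of community-dwelling older adults: survey-based
tie identification, directed-network descriptives, and exponential random
graph modelling (ERGM) of depressive-symptom homophily.

## The problem

Surveys of older adults in a community can ask two kinds of questions that,
combined, define a *directed confidant network*: household listings
("who lives with you?") and name-only nominations ("list the people in the
community to whom you disclose your worries").  The scientific question is
whether confidant ties form preferentially between people with *similar*
depressive symptoms — homophily on the 15-item Geriatric Depression Scale
(GDS-15) and its apathy (0–3) and suicidal-ideation (0–5) subscales.

`confidnet` implements the full pipeline:

1. **cohort** — GDS-15 scoring with the standard item keying, the two
   validated subscales, subjective-memory-complaint (SMC, 4–28) and
   TMIG-IC disability (<13) coding, and covariate dummies against the
   model's reference categories.
2. **ties** — two-step tie identification: co-residing participants are
   confidants (with a likely-spouse exception for dissatisfied respondents
   reporting no confidants), and community nominations are matched by five
   criteria: exact kanji-or-kana name equality, same sex, age within
   3 years, same district but different address, and uniqueness of the
   candidate.  Every nomination gets an audit outcome.
3. **netdesc** — density with reciprocated duplicates collapsed
   (ties / n(n−1)/2), the reciprocity partition, components and mean
   geodesic distance on the undirected collapse, and per-tie score
   difference profiles.
4. **ergm** — a directed ERGM P(Y=y) ∝ exp(θ·s(y)) over the terms used for
   this design: `edges`, `mutual` (reciprocity), nodal covariate main
   effects, and `absdiff` similarity terms.  All of these decompose over
   dyads, so the package offers *exact* maximum likelihood via the per-dyad
   four-state multinomial, plus maximum pseudolikelihood (MPLE) and
   Monte-Carlo MLE with a Metropolis–Hastings sampler.  Estimates are
   reported as odds ratios with Wald 95% CIs, exp(θ ± 1.959964·SE); a
   negative `absdiff` coefficient is homophily.
5. **synth** — a synthetic community generator (roster, ground-truth
   network at a chosen θ*, emitted survey tables) so the entire pipeline is
   testable end-to-end with no external data.  In noiseless mode the
   emitted survey rebuilds the ground-truth edge set exactly.

## Worked example

Simulate a 660-person community, rebuild its network from the emitted
survey, describe it, and fit the homophily model on all 217,470 dyads:

```bash
confidnet simulate --config community.json --out sim     # {"n_participants": 660, "seed": 42}
confidnet build    --survey sim --out net
confidnet describe --edges net/edges.tsv --attrs net/node_attributes.csv --out desc
confidnet fit      --edges net/edges.tsv --attrs net/node_attributes.csv \
                   --model model.json --out fit          # terms: [edges, mutual, absdiff:gds_total]
```

which prints (seed 42):

```
built network: 307 directed ties over 660 nodes
n=660 directed=307 density=0.001

             term  coefficient   se  p_value  odds_ratio  ci_lower  ci_upper
            edges        -8.21 0.11    0.000        0.00      0.00      0.00
           mutual         9.02 0.22    0.000     8258.78   5358.08  12729.85
absdiff:gds_total        -0.04 0.02    0.019        0.96      0.94      0.99
```

Reading: the network is sparse (collapsed density 0.001, i.e. roughly one
confidant tie per thousand potential pairs), ties are overwhelmingly
reciprocated (the large positive `mutual` coefficient), and each additional
point of GDS-15 difference between two people multiplies the odds of a
confidant tie by 0.96 (95% CI 0.94–0.99) — depressive-symptom homophily.
The `fit` command writes both a rounded report table and full-precision
JSON; `describe` writes the descriptive summary (reciprocity partition,
component count and size range, mean geodesic distance) as JSON and CSV.

The same operations are available as a library:

```python
from confidnet import CommunityConfig, generate_community, build_network, fit_exact

roster, truth, survey = generate_community(CommunityConfig(seed=42))
network, report = build_network(survey)      # identical to `truth` in noiseless mode
fit = fit_exact(CommunityConfig(seed=42).model, network)
print(fit.table(round_digits=2))
```

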