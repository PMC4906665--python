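# tempoweb

Temporal structure of quantitative plant–frugivore interaction networks.

Plant–frugivorous-bird communities form bipartite mutualistic networks
whose composition and structure change within a year: migratory birds
arrive in pulses, and fruit availability trades richness (many species
fruiting) against abundance (a few species with huge crops). `tempoweb`
is a library plus analysis pipeline for asking, from a series of
per-period quantitative interaction matrices, (1) whether each period's
network is nested beyond a probabilistic null expectation, (2) whether the
generalist core and the periphery of the network turn over in species
composition between high- and low-migration periods, and (3) which
covariates — migrant proportion, fruit richness, fruit abundance — drive
the temporal variation of network-level parameters.

It is written for community ecologists who have (or want to simulate)
temporal bipartite interaction data: the package ships a synthetic
community generator whose `paper_like` preset emulates a year-long study
in a seasonal tropical site (10 sampling periods, 42 plant and 44 bird
species, ~320 distinct links, migrant peaks in January and October, and a
seasonal richness/abundance trade-off), so the entire pipeline runs and is
tested without any field data.

## What is computed

For each period's plant × bird matrix **W** (cells = estimated fruits
eaten; fecal seed counts are converted via seeds-per-fruit with a
floor of one fruit whenever seeds are present):

- **Network size** `P + A`, **connectance** `L / (P·A)`.
- **Nestedness (NODF)**: for each row (and column) pair with strictly
  decreasing marginal totals `MT_i > MT_j`, the paired overlap
  `|supp(i) ∩ supp(j)| / MT_j`; the score is 100 × the mean over all
  `P(P−1)/2 + A(A−1)/2` pairs. Significance from 1,000 replicates of the
  probabilistic null with cell probability `q_ij = (f_i + g_j)/2` (row and
  column fill proportions), one-sided, add-one estimator
  `p = (1 + #{NODF_null ≥ NODF_obs}) / (1 + R)`.
- **Specialization H2′** `= (H2max − H2) / (H2max − H2min)` where
  `H2 = −Σ p_ij ln p_ij` is the interaction-frequency entropy, `H2max` the
  entropy of the marginal-product expectation and `H2min` the entropy of a
  greedy maximally-packed table with the same marginals.
- **Interaction strength asymmetry**: per link, bird dependence
  `w_ij/c_j` minus plant dependence `w_ij/r_i`, over the larger of the
  two; averaged over links (signed; positive = birds depend more on
  plants).
- **Niche overlap**: mean pairwise Horn index of the birds'
  row-normalized interaction profiles.
- **Core/periphery**: standardized degree `Gc = (k_i − k̄)/σ_k` over the
  period's birds; `Gc > 1` is the generalist core.
- **Turnover**: per-stratum period × species membership matrices,
  Bray–Curtis dissimilarity, one-factor PERMANOVA (999 permutations)
  between the a-priori high-migration (Jan14, Mar14, Sep14, Oct14) and
  low-migration periods.
- **Drivers**: quasi-Poisson GLMs (log link, Pearson-χ² dispersion,
  t-reference inference) of each network parameter on
  `migrants + richness + migrants:richness` and on `abundance` alone.

## Worked example

```
python analysis/01_simulate_community.py --seed 1
python analysis/02_network_metrics.py
python analysis/03_nestedness_null_models.py --seed 1
python analysis/04_core_periphery_turnover.py --seed 1
python analysis/05_structure_drivers.py
```

The first script prints the community scale —

```
simulated 10 sampling periods (seed 1)
  41 plant and 44 bird species realized,
  365 distinct plant-bird links across the year
```

— and the later stages report, for this seed: 4 of 10 networks
significantly nested (`Jan14, Mar14, Sep14, Oct14`, the large
migration-season networks; the small mid-year networks carry too little
signal), significant periphery turnover between migration regimes
(pseudo-F = 4.95, p = 0.004) with a compositionally stable core
(pseudo-F = 2.17, p = 0.141), and a strong negative rank correlation
between migrant proportion and fruit abundance (Spearman r = −0.79),
reflecting the built-in seasonal trade-off. Tables land in `results/`.

The same pipeline runs from the command line on any long-format CSV
(`period,plant,bird,intensity`) with a trait table:

```
tempoweb simulate --seed 1 --out runs/sim
tempoweb metrics --series runs/sim/series.csv --traits runs/sim/traits.csv \
    --fai runs/sim/fai.csv --out runs/met
tempoweb nullm --series runs/sim/series.csv --replicates 1000 --seed 1 --out runs/null
tempoweb turnover --series runs/sim/series.csv --traits runs/sim/traits.csv --out runs/turn
tempoweb glm --metrics runs/met/metrics.csv --covariates runs/met/covariates.csv --out runs/glm
```

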