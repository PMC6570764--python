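# ecomotifs

Grade-of-membership ("mixed-membership") motif analysis for community
ecology and biogeography.

Hard clustering forces every survey site or map cell into exactly one
biogeographic unit. But real communities sit in transition zones: a
mid-elevation Himalayan forest holds both tropical and temperate birds.
`ecomotifs` decomposes a site-by-feature matrix into **K motifs** so that
each sample carries *proportional* membership in every motif — the same
model family known as ADMIXTURE in population genetics and Latent
Dirichlet Allocation in text mining. It is aimed at ecologists who want
to quantify bioregionalization, community mixing, and the turnover of
biotas along gradients, from a single modelling framework.

## The model

Each sample (row) n has a membership vector ω_n on the K-simplex; each
motif k has a feature profile θ_k. The implied per-entry probability is

    p_ng = Σ_k ω_nk θ_kg

with two observation models:

* **Bernoulli** — for presence–absence matrices (map cells × species):
  m_ng ~ Ber(p_ng), with every θ_kg ∈ [0, 1]. Motifs are clusters of
  co-occurring species; a map of ω recovers zoogeographic realms and
  their interdigitation.
* **Multinomial** — for count matrices (sites × species, sites × clades,
  or sites × map cells): row n ~ Mult(c_n+, p_n·), with θ_k on the
  G-simplex. Motifs are abundance profiles ("species abundance motifs"),
  lineage profiles after a phylogenetic time slice ("phylogenetic
  motifs"), or map-cell weightings of stacked assemblage dispersion
  fields ("geographical motifs").

Both are fit by MAP EM with non-informative priors (Dirichlet/Beta,
flat by default), restarted from many seeded initialisations; fits are
ranked — across restarts, across K, and against null-model permutations
— by an approximate log Bayes factor relative to the K = 1 fit.
Observed structure is tested against four community null models
(frequency, richness, independent swap, trial swap) by refitting on
permuted matrices and comparing Bayes-factor distributions
(empirical tail probability and Mann–Whitney U).

Supporting stages: building filtered cell × species presence matrices
from binary range grids (≥ 10 % land cover and ≥ 3 overlapping ranges
by default), constructing and stacking per-site assemblage dispersion
fields, and cutting an ultrametric phylogeny at a time slice T to
collapse species counts onto the lineages present T Myr ago.

## Worked example

```python
import ecomotifs as em

# a Himalayan-style survey: 38 sites, 120 species, two underlying motifs
counts, truth = em.simulate_gom(N=38, G=120, K=2, depth=400, separation=0.9, seed=42)
fit = em.multistart_fit(counts, 2, n_starts=10, seed=42)
print(f"K=2 fit: log BF = {fit.log_bf:.1f}, converged = {fit.converged}")

err = em.recovery_error(fit, truth)
print(f"aligned omega MAE = {err['omega_mae']:.4f}")

ens = em.null_bf_distribution(counts, 2, "richness", n_null=20, seed=42)
report = em.compare_to_null([fit.log_bf], ens)
print(f"empirical p vs 20 richness nulls = {report.empirical_p:.4f}")

top = em.top_contributors(fit, 1, n_top=3, mode="distinctiveness")
print(top[["rank", "feature", "theta", "score"]].to_string(index=False))
```

prints

```
K=2 fit: log BF = 4707.6, converged = True
aligned omega MAE = 0.0120
empirical p vs 20 richness nulls = 0.0476
 rank feature    theta    score
    1 sp_0063 0.070378 0.070157
    2 sp_0094 0.055606 0.055602
    3 sp_0103 0.046401 0.046401
```

The large positive log Bayes factor says two motifs explain the censuses
far better than one pooled community; the membership matrix ω is
recovered to ~0.01 mean absolute error; the observed fit beats every
richness-permuted null (the smallest p the 20 nulls allow); and the
distinctiveness ranking names the species that most separate motif 1
from motif 2.

The same workflow is available from the shell:

```sh
ecomotifs simulate --kind counts --n 38 --g 120 --k 2 --seed 42 --out sim
ecomotifs fit --input sim/matrix.csv --k 2 --n-starts 10 --seed 42 --out fit
ecomotifs export --fit-dir fit --mode top --out top.csv
```

plus `fit-scan` (a K range), `nulls`, `dispersion` (stack dispersion
fields), `phylo-collapse` (time-slice a tree and collapse counts), and
`export --mode structure|piemap` for Block Structure plots and GeoJSON
pie maps.

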