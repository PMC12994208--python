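# sedtaph

Analysis toolkit for **sedimentary ancient DNA (sedaDNA) taxonomic
profiles** from sediment cores: plant-guild construction from taxon
co-occurrence, guild-profile distances, taphonomy tests (stratification,
diffusion, and a sediment-influx depositional model fitted by Monte-Carlo
grid search), Simpson-diversity time series, and a clade-support SNP
counter for gap-concatenated alignments. A fully seeded synthetic-landscape
generator with known ground truth makes every stage testable without any
external data.

It is aimed at palaeoecologists working with shotgun sedaDNA read-count
tables (samples × taxa, with core/depth/sediment metadata) who need to know
*which samples can be trusted* — i.e. where the DNA reflects the local
contemporaneous environment rather than reworked, influxed sediment —
before reconstructing vegetation history.

## The core quantities

- Read-count confidence: `P = fpr^n` for a taxon supported by `n` reads
  given the assignment filter's false-positive rate (default 0.04).
- Guild construction: Pearson correlation of taxon frequencies →
  distance `d = 1 − (pmcc+1)/2` → classical MDS in 10 dimensions →
  hypercube clustering; validation by permutation tests and binomial
  enrichment `P(X ≥ x), X ~ Bin(m, p0)`.
- Guild profile distance: `∂ = √Σᵢ (p1ᵢ − p2ᵢ)²` over guild proportions.
- Stratification: overlap coefficient of Beta(1+c, t−c+1) posteriors of a
  taxon's proportion in two adjacent samples; any overlap < α ⇒ stratified.
- Diffusion bound: per-taxon `λ = −ln(p₁/p₂)/x`, a universal λ from the
  highest 1-D cluster, and `C_diff = e^{−λx}·p₂·s₁_total` expected reads.
- Depositional model: `∂1 = ∂xloc + (∂xloc/cl)·cs·(1+e1)`,
  `∂2 = ∂xloc + id·cs·(1+e2)`, scored by
  `fit = (∂1ᵢ−∂1)² + (∂2ᵢ−∂2)² + (∂2ᵢ/∂1ᵢ − ∂2/∂1)²` and minimised by
  Monte-Carlo chains over (e1, e2) with an exhaustive ~4.04-million-point
  inner grid per visited point; samples are classified secure/insecure from
  the fitted local proportion.
- Diversity: inverse Simpson `1/λ_s`, `λ_s = Σ pᵢ²`, in 1,000-year windows
  at 500-year steps over secure, dated samples.

See `docs/methods.md` for assumptions, numerical conventions and known
limitations (in particular the partial identifiability of the depositional
model and what `cl_upper` means).

## Worked example

```python
import sedtaph as st

# a synthetic landscape with known structure: 4 guild blocks over 40 taxa,
# 6 cores x 10 samples, silt (cl=0.95) above coarse sand (cl=0.4)
table, meta, truth = st.simulate_landscape(st.SimConfig(seed=1))

corr = st.pairwise_pmcc(table)
emb = st.embed_mds(st.corr_to_distance(corr), dims=10)
guilds, unassigned = st.hypercube_cluster(emb)
print(len(guilds), [len(g.members) for g in guilds])
# 4 [10, 10, 10, 10]

profiles = st.guild_profiles(table, guilds)
stats = st.sediment_pair_stats(profiles, meta)
fits = st.fit_all_sediments(stats, grid_step=0.01, n_chains=60, seed=1)
print(round(fits["silt"].cl_upper, 2), round(fits["coarse_sand"].cl_upper, 2))
# 0.89 0.85
```

The recovered groups match the four planted blocks exactly, and the fitted
local compositional proportion is higher for the fine sediment than for the
coarse one, mirroring the simulated mixing (0.95 vs 0.4 — the model sees
only two summary distances per sediment type, so the fitted value is an
upper bound on local provenance, not the mixing weight itself).

A command-line interface mirrors the library:

```sh
sedtaph simulate --seed 1 --out demo/
sedtaph guilds build --counts demo/counts.tsv --out-dir demo/guilds/
sedtaph taphonomy stratify --counts demo/counts.tsv --metadata demo/metadata.tsv --out demo/strat.tsv
sedtaph taphonomy fit --profiles demo/guilds/profiles.tsv --metadata demo/metadata.tsv --out demo/fit/
```

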