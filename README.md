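# matrikin

Tools for inferring post-marital residence patterns — matrilocality,
patrilocality or mixed residence — in ancient burial communities from
genomic kinship and uniparental haplotype data.

Cemetery samples of ancient genomes carry a readable social signal. Under
matrilocality, women remain with their maternal kin while men marry in: the
community's mitochondrial DNA collapses onto one dominant matriline (with de
novo subclades accumulating over generations), Y-chromosome diversity stays
high, women hold more and closer kinship links than men, and relatives found
*between* neighbouring sites rarely share an mtDNA haplotype. `matrikin`
implements the statistical machinery to detect and quantify that signal from
identity-by-descent (IBD) segment sharing:

- **kinship** — turns refinedIBD-style segment tables into pairwise IBD1/IBD2
  fractions, kinship coefficients φ = f<sub>IBD1</sub>/4 + f<sub>IBD2</sub>/2,
  relationship degrees (power-of-two bins, degree *d* ⇔
  φ ∈ (2^−(d+3/2), 2^−(d+1/2)]), per-individual weighted relatedness
  Σ 1/degree, ROH summaries, and Welch/Fisher tests of sex bias.
- **uniparental_stats** — per-site haplotype diversity
  h = n/(n−1)·(1 − Σp<sub>i</sub>²) (the probability two haplotypes sampled
  without replacement differ), first-degree pruning, the normalized
  relative-pair statistic, the diversity-versus-relatedness correlation
  screen, dominant-matriline reports and a Poisson minimum-births bound for
  matriline age.
- **residence_sims** — an island model of demes with sex-specific migration
  rates (m_f, m_m) and grid rejection inference of those rates from observed
  (h_mt, h_Y); and seven-generation pedigree communities under the three
  residence rules, with autosomal and X kinship-coefficient distributions
  (path counting and gene dropping) and a regime classifier.
- **ibd_network** — weighted inter-site IBD graphs and consensus Leiden
  clustering (100 seeded runs, co-assignment consensus, maximum-clade-
  credibility summary tree).
- **synthetic_data** — pedigree-backed generator for all of the above:
  residence-ruled communities, strictly matrilineal/patrilineal haplotype
  labels with infinite-alleles de novo mutation, and exact segment-level
  gene dropping emitting refinedIBD-style IBD tables.

## Worked example

Generate a six-site matrilocal community panel and analyse it:

```sh
matrikin synth --outdir fixture --seed 11 --n-sites 6 --depth 4
matrikin analyze --ibd fixture/ibd.tsv --metadata fixture/metadata.csv \
    --outdir analysis
```

From a run of the above (seed 11), `analysis/tests.json` contains

```
"welch": {"t": -6.468, "p": 9.005e-10}
"fisher": {"p": 8.188e-27, "table": [[96, 0], [34, 65]]}
```

— males hold significantly less weighted relatedness than females (Welch's
two-sided t-test on the Σ 1/degree scores), and are massively
over-represented outside their site's dominant matriline (Fisher's exact
test on the sex × matriline-membership table; in this pure matrilocal
simulation every buried female belongs to her matriline while 65 of 99
males married in from outside): the burial pattern a matrilocal community
leaves behind. The per-site table (`sites.csv`) shows depressed mtDNA
diversity (h_mt 0.45–0.71) against maximal Y diversity (h_Y = 1.0), and
`between_site.csv` lists cross-site relative pairs (> 24 cM shared), few of
which share an mtDNA haplotype.

The same machinery runs in-process. Simulating female philopatry with heavy
male migration, then asking the rejection step to recover the rates:

```python
from matrikin import DemeConfig, infer_migration, simulate_demes

sims = simulate_demes(DemeConfig(m_f=0.0, m_m=0.5, seed=5))
print(sims[["h_mt", "h_y"]].mean())   # h_mt 0.096 << h_y 0.775

grid = [round(0.1 * i, 1) for i in range(11)]
region = infer_migration(0.10, 0.78, DemeConfig(replicates=100, seed=7),
                         grid=grid)
print(region.m_f_interval, region.m_m_interval)
# (0.0, 0.0) (0.1, 1.0): female rate pinned at zero, male rate high
```

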