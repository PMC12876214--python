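# codysbiosis

Cross-kingdom gut microbiome analysis for small case-control cohorts:
alpha/beta diversity with permutation tests, biomarker effect-size scoring,
bacterium–fungus Spearman correlation networks with FDR thresholding,
random-forest discrimination, reporter-score pathway aggregation — plus a
Gaussian-copula synthetic cohort generator so the whole pipeline can be
exercised and validated without sequencing data.

**Who it is for.** Researchers with paired bacterial and fungal genus
profiles (e.g. derived from the same shotgun metagenomes) for two groups of
samples, who want to ask not only *which taxa differ* but *whether the
cross-kingdom ecology differs* — specifically, whether a community has
shifted from an antagonism-rich network toward the cooperation-dominant
state termed **co-dysbiosis**.

## The core statistic

Within each group, for every bacterial genus *b* and fungal genus *f*,
compute the Spearman rank correlation ρ(b, f) of their relative abundances
across samples, with the two-sided p-value from
t = |ρ|·√((n−2)/(1−ρ²)) on n−2 df. Benjamini–Hochberg adjust the p-values
across all cross-kingdom pairs tested in the group, and keep edges with

    |ρ| ≥ 0.6   and   q < 0.05.

The resulting signed network is summarised by its **positivity fraction**

    co-dysbiosis index = (# positive edges) / (# edges),

undefined for an empty network. A healthy-like community shows a low index
(many competitive, negative edges); a co-dysbiotic one approaches 1.

Around this core the package provides Chao1/Shannon, Bray–Curtis + PCoA,
one-way PERMANOVA (permutation or exact enumeration), Procrustes/PROTEST
(M² = 1 − (Σσ)², R = √(1−M²)), Wilcoxon/t/χ² group tests, an
LEfSe-style bootstrapped LDA effect size (log₁₀ scale, |score| ≥ 2),
cross-validated random forests with Gini and permutation importance, and
ReporterScore pathway aggregation (Σz/√k standardised against size-matched
random KO sets, |score| > 1.5). See `docs/methods.md` for the full model
descriptions and design rationale.

## Worked example

Simulate a study-shaped cohort (19 cases vs 17 controls; a control-group
latent structure with 44 negative + 7 positive couplings and a case-group
structure with 17 exclusively positive couplings), infer both networks and
compare them:

```python
from codysbiosis import (default_cohort_spec, simulate_cohort, PipelineConfig,
                         build_cross_kingdom_network, summarize_network,
                         compare_networks, t_test_from_summary)

spec = default_cohort_spec(seed=1)
table, metadata = simulate_cohort(spec)
cfg = PipelineConfig()                      # |rho|>=0.6, q<0.05, prevalence 0.25
nets = {g: build_cross_kingdom_network(table, metadata, g, cfg)
        for g in ("HC", "ARFC")}
for g, net in nets.items():
    s = summarize_network(net)
    print(f"{g}: {s.n_edges} edges ({s.n_negative} negative, "
          f"{s.n_positive} positive), co-dysbiosis index = "
          f"{s.positivity_fraction:.2f}")
report = compare_networks(nets["HC"], nets["ARFC"])
print("positivity difference (ARFC - HC):",
      round(report["positivity_difference"], 2))
ige = t_test_from_summary(285.6, 102.4, 19, 65.3, 28.7, 17)
print(f"total IgE Welch t = {ige.t:.2f}, p = {ige.p:.1e}")
```

prints

```
HC: 30 edges (25 negative, 5 positive), co-dysbiosis index = 0.17
ARFC: 4 edges (0 negative, 4 positive), co-dysbiosis index = 1.00
positivity difference (ARFC - HC): 0.83
total IgE Welch t = 8.99, p = 1.1e-08
```

Reading: at n = 17 the control network recovers 30 of its 51 planted
couplings, dominated by negative (competitive) edges; the case network keeps
only positive edges, so its co-dysbiosis index is 1.00. The last line
re-tests the groups' total-IgE contrast (285.6 ± 102.4 vs 65.3 ± 28.7 IU/mL)
from summary statistics alone.

The same workflow is available from the shell:

```bash
codysbiosis simulate --seed 1 --outdir out/
codysbiosis all --seed 1 --outdir out/        # full pipeline + manifest
codysbiosis network --abundance out/abundance.tsv --metadata out/metadata.tsv \
    --group ARFC --outdir out/                # GraphML + edge list + summary
```

Subcommands: `simulate`, `diversity`, `ordinate`, `permanova`, `procrustes`,
`diff`, `lefse`, `network`, `netsummary`, `netcompare`, `classify`,
`reporter`, `all`; shared flags `--config` (YAML), `--seed`, `--outdir`.

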