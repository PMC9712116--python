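# terraomics

Cross-environment microbe–metabolite analysis for multi-omics surveys.

Large environmental surveys profile the same samples with shotgun
metagenomics (taxon counts) and untargeted LC–MS/MS (metabolite
intensities), organised under a four-level EMPO-style environment ontology.
`terraomics` implements the statistical stack such studies need, end to
end, for microbiome and metabolomics researchers:

* **Microbial-origin annotation** — filter blank- and device-control
  artifacts, seed labels from microbial reference-database hits (Natural
  Products Atlas, MIBiG) and propagate them through molecular families
  (connected components of the spectral-similarity network).
* **Robust Aitchison PCA (RPCA)** — rclr transform
  (`ln x − mean(ln x)` over each sample's nonzero entries, zeros treated as
  missing), low-rank matrix completion, and Euclidean ("robust Aitchison")
  sample distances in the completed space.
* **Multinomial differential ranking** — per-feature, per-environment log
  fold changes `B` from `y_n ~ Mult(softmax(b0 + B[:, env(n)]))` with a
  Gaussian prior, centred so feature ranks are robust to the choice of
  reference environment.
* **Microbe–metabolite co-occurrence** — latent-factor model
  `p_n(j) = Σ_i q_ni · softmax_j(U_i·V_j + b_j)`, cross-validated pseudo-Q²
  against a pooled baseline, co-occurrence strengths `L = UVᵀ + b`, and an
  equalised biplot ordination of metabolites in microbe space.
* **Nestedness** — the NODF statistic with an equiprobable-rows /
  fixed-columns null model, standardized effect sizes and p-values.
* **Diversity & tests** — richness, Faith's PD, weighted Faith's PD,
  weighted UniFrac, PERMANOVA, Mantel (Spearman), study-adjusted multilevel
  Spearman with BH correction, Kruskal–Wallis, log-ratios, Welch t-tests.
* **Integration** — correlate co-occurrence PCs with differentials and
  ordination loadings, select focal/reference metabolite groups, and
  validate them with paired log-ratio t-tests on metabolites *and* on their
  top co-occurring microbes.
* **Synthetic data** — a generator producing coupled microbe/metabolite
  tables with EMPO-like metadata, molecular families, seeded annotations,
  contaminants and full ground truth, so the entire pipeline is testable
  without any external data.

See `docs/methods.md` for the models, conventions and calibration choices.

## Worked example

```python
import terraomics as t

res = t.run_pipeline(seed=0)   # default synthetic study: 3 environments x 20 samples

print(res.origin_precision, res.origin_recall)          # 1.0 1.0
print(round(res.permanova_microbes.statistic, 2),       # 66.35
      res.permanova_microbes.p_value)                   # 0.001
print(round(res.mantel_result.statistic, 3),            # 0.167
      res.mantel_result.p_value)                        # 0.001
print(round(res.pseudo_q2, 3))                          # 0.049
print(res.differential_recovery.round(3).to_dict())
# {'env_00': 0.767, 'env_01': 0.869, 'env_02': 0.827}
print(round(res.nestedness.nodf_observed, 1),           # 86.8
      round(res.nestedness.ses, 1))                     # 3.4
print(res.focal_environment,                            # env_01
      res.validation.metabolite_test.p_value,           # 1.1e-04
      res.validation.microbe_test.p_value)              # 2.5e-07
```

Reading the output: every feature recovered as "microbially related"
matches the generator's truth (precision = recall = 1); microbial
composition separates cleanly by environment (PERMANOVA pseudo-F 66.4,
p = 0.001 at 999 permutations); microbe and metabolite sample distances
co-vary (Mantel rho 0.167, p = 0.001); the co-occurrence model beats the
pooled baseline out of sample (pseudo-Q² 0.049, vs ≤ 0 on decoupled data);
fitted differentials rank-correlate with the planted log fold changes at
rho 0.77–0.87; the presence matrix is strongly nested against the
fixed-columns null (NODF 86.8, SES 3.4); and the focal metabolite group
discovered for `env_01` is confirmed by both log-ratio t-tests.

The same stages are available as a CLI for on-disk TSV/Newick artifacts:

```bash
terraomics simulate --seed 7 --output-dir out/
terraomics origin --table out/metabolites.tsv --metadata out/metadata.tsv \
    --network out/network.tsv --annotations out/annotations.tsv --output-dir out/
terraomics rpca --table out/microbial_metabolites.tsv --rank 3 \
    --min-sample-features 5 --output-dir out/
```

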