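# wingmorph

Landmark-based morphometrics of the developing *Drosophila* wing: a tested,
reusable pipeline for comparing wing shape and size across three
developmental stages (larval disc, 5 h pupal wing, adult wing) and
genotypes, from landmark ingestion through Procrustes alignment,
randomization MANOVA, robust outlier screening, scalar trait measures and
bootstrap ratio comparisons.

Each specimen is a 17×2 landmark configuration (8 fixed landmarks + 9
sliding semilandmarks along the anterior and posterior margin runs) with
stage / genotype / sex metadata.

## Components

| module | contents |
|---|---|
| `wingmorph.io` | TPS (tpsDig dialect) reader/writer, sidecar metadata CSV, wide landmark CSV with configurable columns, stamped CSV output |
| `wingmorph.simulate` | synthetic datasets: per-stage templates, genotype displacement fields, stage-specific shape noise, lognormal size law, outlier injection with ground truth |
| `wingmorph.superimposition` | centroid size, generalized Procrustes alignment (rotation-only, reproducible orientation), chord-tangent semilandmark sliding, Procrustes distance, tangent-space adequacy check |
| `wingmorph.shape_stats` | shape PCA, canonical variates, Type III Wilks'-Λ MANOVA, decomposition-based randomization test, mean shape-distance matrices, trajectory angles |
| `wingmorph.outliers` | Minimum-Covariance-Determinant screen on shape PCs (3 / 6 SD flags, per genotype×stage group), Grubbs' univariate test |
| `wingmorph.scalar_measures` | 28 standardized pairwise distances, margin polyline lengths, surveyor's-formula region areas, bootstrap ratio-of-means with expanded-percentile CIs, delta-method ratio SEs, Type III factorial models with Tukey-Kramer post hocs |
| `wingmorph.pipeline` / `wingmorph.cli` | end-to-end orchestration under a YAML config with mandatory seed and config-hash-stamped outputs |

## CLI

```sh
wingmorph simulate --seed 1 --out sim/                  # TPS + metadata + ground truth
wingmorph align    --tps sim/landmarks.tps --metadata sim/metadata.csv --out aligned/
wingmorph screen   --tps sim/landmarks.tps --metadata sim/metadata.csv --out outliers.csv
wingmorph pca      --tps sim/landmarks.tps --metadata sim/metadata.csv --out pcs.csv
wingmorph test     --tps sim/landmarks.tps --metadata sim/metadata.csv --seed 1 \
                   --effect genotype --out randomization.json
wingmorph scalars  --tps sim/landmarks.tps --metadata sim/metadata.csv --out scalars.csv
wingmorph compare  --scalar-table scalars.csv --seed 1 --out ratios.csv
wingmorph report   --seed 1 --out report/               # full pipeline, or --config cfg.yaml
```

Identical config + seed ⇒ byte-identical outputs; every CSV is stamped
with the config hash.

## Notes

- Semilandmark sliding minimizes Procrustes distance to the consensus
  along local chords (`mode="chord"`, default) — a deliberate, documented
  choice; `mode="none"` disables sliding. Bending-energy sliding is out
  of scope.
- The randomization MANOVA permutes the tested decomposition component
  *plus* the individual deviation (Freedman-Lane style), within stages by
  default for the genotype effect; both choices are recorded in the
  result object and are required for a calibrated test under
  stage-heteroscedastic shape variance.
- Outlier flags are reported, never auto-dropped; pass explicit
  `exclude_ids` to the pipeline to remove specimens after review.
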