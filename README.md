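# grninfer

Fast gene regulatory network (GRN) inference from heterogeneous expression
data, built around robust precision-matrix estimation:

1. **Per-gene power transforms** (Box–Cox with maximum-likelihood exponents)
   make the skewed, positive expression data more Gaussian-like.
2. **Shrinkage covariance + inversion**: the sample covariance is shrunk
   towards its diagonal (`S̄ = α·diag(S) + (1−α)·S`, default `α = 0.8`) so it
   is invertible even with fewer samples than genes; the inverse (precision
   matrix) encodes direct, conditional dependencies between genes.
3. **Bias correction**: a multiplicative row–column weighting removes
   gene-specific biases while preserving the exact zeros of the precision
   matrix; rows of genes not in the transcription-factor list are masked.
4. **Directional information**: closed-form regression-coefficient
   re-weighting, null-mutant Z-scores from single-gene knock-out
   experiments (L2-normalized, squared and fused multiplicatively), a
   hub-emphasizing row post-processing, and regulatory signs read off the
   precision matrix.

Companion modules provide a scale-free network + steady-state expression
simulator (so everything is testable offline) and ranking evaluation:
AUROC/AUPR over the candidate-edge universe, a Monte-Carlo overall score
`-½·log10(p_AUROC · p_AUPR)`, a causal-structure taxonomy of false
positives (chain / reversed chain / fork / collider / undirected /
spurious), a relevance-weighted NDCG, and a matrix-symmetry diagnostic.

## Command-line usage

```bash
# simulate a 50-gene network with a full knock-out panel
grninfer simulate --genes 50 --edges 100 --samples 300 --ko full \
    --seed 0 --outdir sim/

# infer a ranked edge list
grninfer infer --expression sim/expression.tsv \
    --annotations sim/annotations.tsv --tf-list sim/tf_list.txt \
    --alpha 0.8 --output pred.tsv

# score it against the goldstandard
grninfer eval --prediction pred.tsv --goldstandard sim/goldstandard.tsv \
    --expression sim/expression.tsv --tf-list sim/tf_list.txt \
    --k 100 --null-reps 1000 --report eval.json
```

Every subcommand writes a JSON report beside its outputs with the fully
resolved configuration. `infer` supports stage toggles (`--no-ko`,
`--no-regression-weighting`, `--no-hub-postprocess`), a
`--sign-convention {precision,partial-correlation}` switch and a
genes-in-rows `--transpose` flag. A TOML file passed via `--config` pre-sets
any option; explicit flags win.

### File formats

- **expression**: TSV, header row of gene names, one row per experiment
  (non-negative values).
- **annotations** (sidecar TSV): `row_index<TAB>kind[<TAB>genes]`, e.g.
  `12<TAB>knockout<TAB>G007`; unlisted rows are wild-type.
- **TF list**: one gene name per line.
- **goldstandard**: `regulator<TAB>target<TAB>{0,1}` (1 = verified edge,
  0 = declared negative, absent = unknown).
- **predictions**: `regulator<TAB>target<TAB>score`, descending.

## Package layout

```
src/grninfer/
  data_io.py         readers/writers, dataset + goldstandard types
  preprocess.py      per-gene Box–Cox transforms
  gaussian_core.py   covariance, shrinkage inversion, bias correction
  directionality.py  regression re-weighting, KO Z-scores, fusion, pipeline
  evaluation.py      AUROC/AUPR, overall score, FP taxonomy, NDCG, symmetry
  synthetic.py       scale-free network + expression simulator
  cli.py             simulate / infer / eval subcommands
```
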