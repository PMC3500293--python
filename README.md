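# batsig

Brown adipose tissue (BAT) in rodents contains two developmentally distinct
UCP1-positive cell types: *classical* brown adipocytes (Myf-5 lineage,
interscapular depots) and inducible *beige/brite* cells that appear in white
fat under cold or PPARγ-agonist (rosiglitazone) exposure. Deciding which of
the two a human BAT sample resembles is a classification problem on
expression data: first derive marker-gene groups that separate the cell
types, then ask which marker group a tissue panel's expression tracks.

`batsig` implements that two-stage analysis as a tested, reusable pipeline
for anyone working with bulk expression panels of adipose tissue (or any
analogous two-signature classification problem):

1. **Marker discovery.** From a three-condition experiment (white, beige,
   classical brown cultures), genes passing a fold-change + unpaired t-test
   filter (default >2-fold, *P* < 0.05) are sorted into four enrichment
   groups — white-selective, beige-selective, common brown, and
   classical-brown-selective — with the overlap fractions between the brown
   groups reported.

2. **Concordance classification.** On a tissue panel, the Pearson
   correlations *rᵢ* between an anchor gene (an established brown-fat marker,
   PRDM16/PGC1α role) and each member *i* of a marker set are integrated via
   Fisher's transform *zᵢ* = atanh *rᵢ* into a weighted mean
   z̄ = Σwᵢzᵢ/Σwᵢ (wᵢ = nᵢ − 3), giving the **gene-set correlation
   coefficient** r̄ = tanh z̄. Two competing sets are compared with
   Z = (z̄ₐ − z̄_b)/√(SEₐ² + SE_b²) against the standard normal. Genes with
   too many Tukey-whisker outlier samples (beyond quartile ± 1.5·IQR) are
   excluded beforehand, as UCP1 was in the original analysis.

Supporting modules: a ΔΔCt converter from raw qPCR Ct tables
(2^−ΔΔCt with a reference gene and optional calibrator sample), average-linkage
hierarchical clustering on 1 − r distance with Newick export, min–max heatmap
exports, 95 % density ellipses, and a seeded synthetic-data generator that
emulates both study designs with ground truth.

## Worked example

```python
import batsig as bs

# a 15-tissue panel driven by one latent beige-activity factor
panel, truth = bs.generate_tissue_panel(
    bs.TissuePanelSimConfig(n_tissues=15, beige_loading=0.9, noise_sd=0.3, seed=5)
)
screened, report = bs.filter_genes_by_outliers(panel, max_outlier_fraction=0.2)

beige = [g for g in bs.DEFAULT_MARKER_SETS["beige"] if g in screened.genes]
classical = [g for g in bs.DEFAULT_MARKER_SETS["classical"] if g in screened.genes]
a = bs.gene_set_correlation("PRDM16", beige, screened, "beige", log2=True)
b = bs.gene_set_correlation("PRDM16", classical, screened, "classical", log2=True)
v = bs.compare_set_correlations(a, b)
print(f"r̄(beige)={a.r_bar:.3f}  r̄(classical)={b.r_bar:.3f}  "
      f"Z={v.z_statistic:.2f}  p={v.p_value:.2e}  winner={v.winner}")
```

prints

```
r̄(beige)=0.857  r̄(classical)=-0.004  Z=3.15  p=1.65e-03  winner=beige
```

i.e. the anchor's correlation with the beige marker set (r̄ = 0.86) is
significantly higher than with the classical set (r̄ ≈ 0), so the panel
is classified as beige-like — the expected verdict, since the generator
drove the beige genes and the anchor from one shared factor while classical
genes sat at the detection floor.

The same flow is available from a shell:

```bash
batsig simulate tissues --seed 5 --out run/
batsig concordance --expr run/expression.tsv --meta run/metadata.tsv \
    --sets run/marker_sets.gmt --anchors run/anchors.txt --log2 --out run/
batsig run --config pipeline.yaml     # or the whole pipeline from YAML
```

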