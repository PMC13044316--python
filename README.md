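# lysoclust

Quantification of late endosome/lysosome (LE/Lys) positioning from
fluorescence microscopy, built around a per-cell **clustering index**: the
proportion of segmented vesicles in direct contact with at least one other
vesicle of the same cell,

```
index(cell) = #{vesicles with >= 1 touching neighbor} / #{vesicles in cell}
```

Dispersed cytosolic vesicles score low (incidental contacts only, ~0.4 in
the baseline regime); vesicles aggregated into perinuclear clusters score
high (~0.7).  The package is aimed at cell biologists quantifying organelle
repositioning phenotypes (e.g. GSK3-inhibition or phospho-mutant
experiments) and at method developers who need a contact statistic with an
exact, analytic ground truth to validate against.

The pipeline mirrors a standard imaging workflow:

1. **simulate** — synthetic multi-channel scenes (nuclei + vesicle
   channels): cells with one nucleus each, tens of diffraction-blurred
   circular vesicles, Gaussian PSF, Poisson-Gaussian camera noise, and an
   exact geometric record of every disk.  Two presets, `dispersed` and
   `clustered`, realize ground-truth contact fractions of 0.4 and 0.7.
2. **segment** — maximum-intensity projection, nucleus-seeded watershed
   cell territories, and vesicle detection by intensity-peak-seeded
   watershed on an Otsu foreground (classical, deterministic, weight-free).
3. **quantify** — vesicles are assigned to the cell containing their
   centroid; two labels are "touching" when their pixel supports, each
   expanded by `expand_px` (default 1), overlap — the adjacent-objects
   convention of CellProfiler's neighbor module; the per-cell index follows.
4. **coloc** — masked Pearson correlation plus a Costes-style
   auto-thresholded Pearson (orthogonal regression, threshold lowered until
   below-threshold pixels are uncorrelated).
5. **stats** — superplot summaries (per-cell values, per-experiment means,
   condition mean = unweighted mean of experiment means) and the usual test
   battery: Student's t, one-way ANOVA, Tukey HSD, and Dunnett
   (Monte-Carlo familywise adjustment, seeded).

## Worked example

```python
import pandas as pd
import lysoclust as lc

table = pd.concat([
    lc.run_condition("dispersed", "control",   n_cells=8, n_experiments=2, base_seed=0),
    lc.run_condition("clustered", "CHIR99021", n_cells=8, n_experiments=2, base_seed=0),
], ignore_index=True)
print(lc.condition_summary(table))
print(lc.compare_conditions(table.rename(columns={"index": "value"}),
                            test="anova-tukey"))
```

prints

```
condition     mean       sd  n_experiments
CHIR99021 0.696628 0.002317              2
  control 0.387969 0.005097              2

 test                 pair   statistic   df            p        adj_p stars
anova CHIR99021 vs control 2039.249026 1/30 3.822612e-29 3.822612e-29  ****
tukey CHIR99021 vs control   63.863120 2/30 3.822612e-29 0.000000e+00  ****
```

i.e. the full pipeline (render → segment → contact graph → index) recovers
the clustered regime at 0.697 and the dispersed regime at 0.388 — within a
few hundredths of the generator's exact contact fractions (0.7 / 0.4) —
and the two regimes separate decisively under one-way ANOVA with Tukey's
comparison.

The same workflow is available from the shell:

```sh
lysoclust simulate --preset clustered --n-cells 8 --seed 1 --out scenes/
lysoclust segment  --in scenes/ --out masks/
lysoclust quantify --vesicles masks/ --cells masks/ --out index.csv
lysoclust pipeline --out run/ --seed 1      # everything, with a manifest
```

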