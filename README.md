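# biofilmassay

Analysis pipeline for 96-well crystal-violet / resazurin biofilm assays, of
the kind used to screen bacterial isolates (here: cheese *Enterococcus*
collections) for biofilm production under stress conditions — temperature,
NaCl, and pH gradients at 24 h and 48 h.

It takes raw plate-reader absorbance tables plus a plate layout and produces:

- **Producer classifications** from sterility-control cutoffs
  (ODc = mean control OD + 3·SD): non / weak / moderate / strong producer
  via OD ≤ ODc < OD ≤ 2·ODc < OD ≤ 4·ODc < OD bands, with tallies,
  24 h vs 48 h cross-tabulations, and ever-producer sets.
- **Viability correction**: reduced-resazurin signal
  AR570 = (OD570 − OD600·Ro)·100 with the oxidized-substrate ratio
  Ro = OD570/OD600 measured per plate; non-detectable viability is clamped
  to 0 and flagged.
- **Biofilm per viable cell**: CV signal divided by AR570, condition
  averages, and highest-production flags (undefined "asterisk" cells
  excluded, never imputed).
- **Rank-product permutation test** on per-replicate 48 h/24 h production
  ratios: RP = geometric mean of within-replicate ranks, permutation null
  (exact enumeration for small problems), two one-sided tests reported with
  direction.
- **PCA** and a **UPGMA/Euclidean dendrogram** of the isolate ×
  (condition × timepoint × method) feature matrix, with a k-cluster cut
  ranking clusters best → worst producers, and standard Newick export.
- A **synthetic plate generator** that emulates the full study design (10
  isolates × 14 conditions × 2 timepoints × 3 biological × 3 technical
  replicates) with known latent classes, so the entire chain is testable
  without access to raw reader files.

The packaged `data/` fixtures transcribe the published producer-class tables
of a 72-isolate collection and its 10-isolate selected panel; `datasets.py`
documents two internal inconsistencies of the source tables that the
fixtures preserve as printed.

## Worked example

Simulate the default study design and run the whole pipeline:

```text
$ biofilmassay simulate --seed 7 --out sim
wrote 13860 readings over 84 plates to sim

$ biofilmassay run-all --readings sim/readings.csv --layout sim/layout.csv \
      --out results --seed 7
pipeline complete; manifest with 13 artifacts in results
```

`results/classes.tsv` holds one producer class per isolate × condition ×
timepoint with the mean OD and cutoff that produced it:

```text
isolate_id   factor  level  timepoint_h  mean_od  odc     producer_class
A1.14.2022   baseline        24.0        1.0570   0.1694  SP
A1.14.2022   baseline        48.0        0.9238   0.1544  SP
A1.14.2022   nacl     1.0    24.0        0.4828   0.1616  MP
```

i.e. isolate A1.14.2022 is a strong producer at baseline (mean OD 1.06 is
more than 4× the 0.169 cutoff) and a moderate one in 1% NaCl at 24 h. The
k = 3 cut of the UPGMA tree (`results/clusters.tsv`) isolates that dominant
producer in the "best" cluster:

```text
isolate_id   cluster  quality
A1.14.2022   1        best
A1.6.2017    3        worst
A2.48.2016   3        worst
```

and `results/rp.tsv` reports the rank-product comparison of 24 h vs 48 h
production (here e.g. A1.6.2017 dropped significantly at 48 h,
p = 0.004, direction "down"), while `results/pca.tsv` shows the first three
components explaining 69.3% + 10.9% + 6.9% of the variance of this
simulated panel. `manifest.json` records the config, seed and artifact
checksums; re-running with the same inputs and seed reproduces the
checksums bit-identically.

Library use mirrors the CLI:

```python
from biofilmassay import classify, datasets

table = datasets.load_collection_baseline()
classify.tally(table, 24.0)
# {'NP': 42, 'WP': 21, 'MP': 7, 'SP': 2}
```

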