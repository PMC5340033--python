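# rdikit

Comparing V(D)J gene-segment usage between immune repertoires is harder
than it looks: gene usage spans orders of magnitude, sequencing depth
varies wildly between samples, and the naive Euclidean distance between
frequency vectors inflates as repertoires get shallower — so two samples of
the *same* repertoire at different depths can look more different than two
genuinely different repertoires. `rdikit` implements the Repertoire
Dissimilarity Index (RDI), a non-parametric, subsampling-based distance
that controls for depth, together with a simulation framework that
calibrates raw RDI values into interpretable average fold-change units.

It is aimed at AIRR-seq analysts who already have annotated rearrangement
tables (one row per sequence or clone, with IMGT-style `v_call`/`j_call`
columns) and want to quantify how much two repertoires' gene usage differs.

## The metric

For repertoires summarized as count vectors over gene segments:

1. **Subsample** every repertoire without replacement (multivariate
   hypergeometric) to a common size *m*, by default the smallest
   repertoire's total.
2. **Count** features in the subsample.
3. **Normalize** each vector to a constant total (*n* = 500) and optionally
   apply **arcsinh**, which is linear near 0 and logarithmic above 1, so
   changes in rare genes are not drowned out by the most prevalent ones.
4. **Distance**: Euclidean (equivalently RMSD up to a constant factor)
   between every pair of transformed vectors.
5. **Repeat** 100 times and average: the mean is the RDI.

Raw RDI values depend on *m*, the number of features and the transform, so
they are only comparable within a run. The calibration module makes them
absolute: simulated repertoires with known average deviation are generated
from a baseline probability vector `p_base` perturbed on the log2 scale,

    p_fc  ∝  p_base · 2^r,     r_i ~ Normal(0, σ²),

and a monotone smoothing spline fitted to (realized mean |log2 fold
change|, mean RDI) is inverted to convert an observed RDI into the average
fold change it corresponds to. The same model yields the **RDI ladder**
(expected RDI ± local SD at chosen fold changes) and an empirical null
tail probability against the deviation-0 simulations.

## Worked example

```sh
python examples/01_tabulate_and_rdi.py
```

builds a synthetic rearrangement TSV for three repertoires — two drawn from
the same V-gene usage profile at depths 3000 and 5000, one from a perturbed
profile — parses and tallies it, and prints:

```
count table: 3 repertoires x 12 genes
subsampled all repertoires to 3000 sequences

        donor1  donor2  donor3
donor1   0.000   0.380   2.898
donor2   0.380   0.000   3.016
donor3   2.898   3.016   0.000
```

donor1 and donor2 differ only by sampling noise (RDI ≈ 0.38 on the arcsinh
scale at this depth), while donor3's genuinely shifted usage profile gives
distances ~8× larger. `examples/02_calibrate_fold_change.py` then shows the
calibration converting observed RDI values from repertoires simulated at a
true average |log2 fold change| of 1.5 back to estimates near 1.5, and
prints the reference ladder; `examples/03_null_split.py` shows that random
uneven splits of a single repertoire land on the calibrated no-change band.

The same workflow is available as a CLI for shell pipelines:

```sh
rdikit tabulate input.tsv -o counts.csv --id-column sample
rdikit rdi counts.csv -o dist.csv --seed 1
rdikit calibrate counts.csv -o model.json --seed 1
rdikit convert dist.csv --model model.json -o fold_changes.csv
```

Seeded runs are byte-reproducible, and every artifact gets a JSON sidecar
recording the parameters that produced it.

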