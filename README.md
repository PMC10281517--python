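# organoquant

Quantitative image analysis for human lung-organoid microscopy: live kinase
translocation reporter (KTR) movies, epithelial cell-shape morphometrics,
proliferation scoring and organoid morphology — together with a seeded
synthetic-data generator that produces every input with exact ground truth,
so each measurement stage can be verified end to end.

## Who this is for

Groups quantifying organoid imaging experiments of the kind used to dissect
RTK signalling in epithelial progenitor cells: time-lapse confocal movies of
ERK/AKT translocation reporters, junction-stained sections for cell-shape
measurement, EdU/KI67 proliferation assays, and brightfield silhouettes for
organoid area and budding phenotypes.

## What it computes

**KTR C/N ratio traces.** A kinase translocation reporter leaves the nucleus
when its kinase is active, so the per-cell cytoplasm/nucleus mean-intensity
ratio is a live kinase-activity readout. Nuclei are segmented from the
nuclear-dye channel; the cytoplasm of each cell is approximated by a ring of
5 pixels width grown around its nucleus (the standard proxy when no membrane
marker is imaged), and

```
C/N = mean reporter intensity in ring / mean reporter intensity in nucleus.
```

All ratios in a movie are normalised to the cohort mean at the first time
point — the cohort mean at T0 is exactly 100% — and aggregated per organoid
per time point with a 95% t-confidence band. T0-versus-Tk comparisons across
replicate organoids use one-way ANOVA on replicate means.

**Morphometrics.** Cell lateral/apical/basal lengths and length/width ratio
from annotated line segments (Euclidean endpoint distance × pixel size);
nucleus circularity `4πA/P²` from traced outlines (shoelace area, exact
vertex-chain perimeter) or masks (Crofton perimeter); per-cell marker scores
(nuclear mean + ring mean); positive-nucleus fractions (fixed or
Otsu-on-means threshold) in 2-D and 3-D; organoid areas and a
solidity-threshold budding classifier (budding iff solidity < 0.92,
calibrated so synthetic disks and lobed shapes separate with zero errors).

**Statistics.** Mann–Whitney U (exact enumeration for n ≤ 20 per group
without ties, normal approximation with tie correction otherwise), Welch's
unequal-variance t-test, and one-way ANOVA.

**Synthetic data.** The generator renders reporter movies whose C/N ratio
follows first-order relaxation toward an activity-dependent steady state
(`dr/dt = (r_inf(a) − r)/τ`, closed-form integrated), trapezoidal epithelial
cells tiling circular organoid contours in columnar/cuboidal/squamous
regimes, marker-positivity scenes with exactly `round(n·fraction)` positive
nuclei, and spherical versus multi-lobed silhouettes — each with lossless
ground truth and byte-identical output under a fixed seed.

## Worked example

```python
import numpy as np
from organoquant import synthetic as syn
from organoquant.ktr import analyze_movie, aggregate_per_organoid

times = np.arange(13) * 10.0                      # T0..T12, every 10 min
scene = syn.ktr_scene(20, times, seed=1)          # 20-cell organoid
params = syn.KineticsParams()                     # r_min=0.4, r_max=2.5, tau=15 min
stack, truth = syn.render_movie(scene, params, syn.step_activity(times),
                                r0=params.r_min)  # inhibited baseline, ligand at T0

records = analyze_movie(stack)                    # segment -> ring -> ratio -> normalise
trace = aggregate_per_organoid(records)
print(trace[["time_min", "ratio_pct", "n", "ci_lo", "ci_hi"]].round(1).head(4))
```

prints

```
 time_min  ratio_pct  n  ci_lo  ci_hi
      0.0      100.0 20   99.8  100.2
     10.0      355.8 20  355.0  356.6
     20.0      487.2 20  486.0  488.4
     30.0      554.6 20  553.7  555.4
```

The cohort mean at T0 is 100% by construction; the trace then relaxes toward
the stimulated plateau (r_max/r_min = 625% of baseline; the ground-truth
value at T12 is 624.8%), and the recovered trace tracks the ground truth to
within a fraction of a percent at the default noise level.

The same pipeline is available from the shell:

```sh
organoquant simulate --kind ktr --seed 1 --out sim/
organoquant ktr --input sim/movie.tif --out results/
```

## Layout

```
src/organoquant/
  synthetic/      scene, kinetics, epithelium, positivity, silhouette generators
  segmentation.py nuclei, ring cytoplasm, organoid areas, z-plane selection
  ktr.py          C/N ratios, T0 normalisation, tracking, per-organoid traces
  morphometrics.py cell axes, circularity, marker scores, counts, budding
  stats.py        Mann-Whitney U, Welch t, one-way ANOVA
  io.py, cli.py   TIFF/CSV/YAML I/O and the organoquant command
docs/methods.md   model assumptions, parameter choices, limitations
```
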