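# mitoboot

Quantitative analysis of dendritic mitochondrial ultrastructure in layered
neuropil, for labs that segment electron-microscopy image tiles and need
statistics that respect the nested structure of the experiment. The package
covers three stages:

1. **Morphometry** — per-object shape metrics from integer label masks
   (area, maximum Feret diameter, moment-ellipse axes, aspect ratio =
   short/long, nearest-neighbour distance within a tile), an inclusive
   size filter (default 0.01–2.1 µm²), and per-tile aggregation of count
   and total area over 100 µm² tiles.
2. **Hierarchical bootstrap** — the statistical core. Mitochondria within
   a tile, tiles within a section, and sections within an animal are
   correlated, so treating objects as independent inflates significance.
   Each bootstrap repetition resamples, with replacement, animals within a
   genotype, sections within each drawn animal, tiles (of the group's
   layer) within each drawn section, and — for per-object metrics —
   objects within each drawn tile (defaults 3 × 3 × 50 × 100, i.e. 450
   tiles and 45,000 objects pooled per repetition), then takes the median.
   Repeating (10,000×) gives a population of resampled medians per
   genotype × layer group. Two groups are compared by the joint
   distribution of their paired medians and by

   *P*<sub>boot</sub>(A > B) = proportion of repetitions with
   median<sub>A</sub> > median<sub>B</sub> (ties count ½),

   the "upper triangle" mass of the joint median plot. A sampling-size
   calibration (`sampling_size_test`) quantifies how oversampling tiles or
   objects stabilises the bootstrap.
3. **Plasticity scoring** — extracellular field-potential experiments:
   baseline stability gate (discard if OLS r² > 0.2 over the 10-min
   baseline), post/pre ratio (mean of the last 5 min post-conditioning ÷
   last 5 min pre-conditioning), classification into LTD (< 0.90, p <
   0.05), LTP (> 1.10, p < 0.05) or no change, 1-min binned time plots,
   and half-maximal input/output extraction.

A synthetic-data module generates nested datasets (negative-binomial tile
counts, truncated log-normal areas, multiplicative animal/section random
effects), rendered label masks with ground truth, and FP recordings, so the
whole pipeline runs and is validated without any raw data. Reporting
utilities add percent change, a two-sided variance-ratio F test, 10-µm
line-profile binning, and standard group-comparison columns.

## Worked example

```python
import numpy as np
from mitoboot import (
    GeneratorParams, BootstrapConfig, generate_hierarchy,
    run_bootstrap, p_boot, joint_distribution,
)

# synthetic study: 2 genotypes x 3 animals x 3 sections x 3 layers,
# per-layer median counts CTL 10/10/19 vs cKO 13/13/23 per 100 um^2
dataset = generate_hierarchy(GeneratorParams(seed=1))

config = BootstrapConfig(metric="count_per_tile", n_reps=10_000, seed=11)
results = run_bootstrap(dataset, config)

ctl = results[("CTL", "SLM")].medians
cko = results[("cKO", "SLM")].medians
print(f"P_boot(cKO > CTL, SLM count) = {p_boot(cko, ctl):.2f}")
jd = joint_distribution(cko, ctl, "count_per_tile")
print(f"joint histogram {jd.hist.shape}, mass {jd.hist.sum():.0f}")
```

prints

```
P_boot(cKO > CTL, SLM count) = 0.92
joint histogram (10, 10), mass 1
```

that is: in 92% of the 10,000 paired bootstrap repetitions the knockout's
resampled median tile count exceeded the control's — strong evidence that
mitochondria are more numerous in the knockout once animal-, section- and
tile-level variability is propagated — and the paired medians are binned
into the 10 × 10 joint probability distribution (100 bins per axis for the
area metric), normalised to total mass 1.

A command-line interface mirrors the library:
`mitoboot morphometry`, `mitoboot bootstrap`, `mitoboot ephys`,
`mitoboot simulate` (see `--help` on each).

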