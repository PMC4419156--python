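# floodmmi

Landscape floodplain condition assessment from categorical land-cover
rasters, with explicit propagation of thematic-misclassification error.

Multi-metric indices (MMIs) built from classified satellite products are a
standard tool for watershed- and regional-scale condition assessment, but
the classification error documented in those products' accuracy reports is
almost never carried through to the assessment scores. `floodmmi`
implements a floodplain MMI driven by a single thematic map and a Monte
Carlo *confusion frequency simulation* that turns the map's confusion
matrix into distributions of metric and index scores — exposing how far the
error-naive scores can be trusted, and in which direction they are biased.

It is aimed at landscape ecologists and remote-sensing analysts who score
river corridors (or any assessment unit) from NLCD-style categorical
rasters and want defensible uncertainty statements alongside the scores.

## The model

**Metrics (area-weighted cover).** Raw cover codes are binned to groups on
a disturbance gradient, each with a sub-score weight `w_Lx` in [0, 1]
(unmanaged 1.0, low-intensity agriculture 0.8, high-intensity agriculture
0.5, low-intensity urban 0.2, high-intensity urban 0.0). For an assessment
mask with `N` assessed pixels and `C_Lx` pixels of class `x`:

    Met = Σ_x (C_Lx · w_Lx) / N                                (in [0, 1])

The *perturbation* metric applies this to the five land-use groups; the
*fragmentation* metric applies it to the seven structural classes of a
morphological spatial pattern analysis (MSPA) of the binary
unmanaged/managed map — core 1.0, patch edge 0.8, loop/bridge 0.6, branch
0.4, islet 0.2, managed 0.0, with a 3-pixel (90 m at 30 m resolution) edge
width. Each metric is scored over the floodplain (F) and its surrounding
buffer (B), and combined as

    Index = ((Met_BP + Met_BF)/2 + Met_FP + Met_FF) / 3

**Error model (confusion frequency simulation).** The map's confusion
matrix, aggregated to the analysis classes, is row-normalised into a
*user's probability matrix* (UPM): `U[k, i]` is the probability that a
pixel mapped as class `k` is truly class `i`. Each Monte Carlo realization
redraws every pixel independently from its UPM row by inverse-CDF sampling.
A spatial-autocorrelation filter with total gradient `f` (default 0.10)
shifts the retention probability `U[k, k]` by +f/2 on patch-interior pixels
(full 3×3 neighbourhood same-class) and −f/2 on patch-edge pixels,
concentrating simulated error at patch boundaries. Re-running the MSPA and
the metrics on each realization yields, per site and metric, an ensemble of
scores summarised by its mean, a 95 % percentile interval, and the bias

    bias = naive score − mean simulated score,

positive when the error-naive assessment overestimates condition. Pairwise
site differences are tested with a paired Wilcoxon signed-rank on
per-realization index scores.

## Worked example

```python
import numpy as np
from floodmmi import (
    AutocorrelationFilter, RealizationRun, SyntheticLandscapeConfig,
    generate_landscape, generate_site, run_ensemble,
)
from floodmmi.metrics import structural_weight_array
from floodmmi.schemes import (
    binary_from_landuse, binary_upm, landuse_scheme, landuse_upm,
    reclassify, structural_weights,
)

# a 128x128 synthetic valley: NLCD-style codes, contiguous patches
config = SyntheticLandscapeConfig(
    class_labels=(42, 81, 82, 21, 23),   # forest, pasture, crops, low/high urban
    class_proportions=(0.55, 0.20, 0.10, 0.10, 0.05),
    patch_scale=10.0, seed=0,
)
landcover = generate_landscape(config)

scheme = landuse_scheme()
perturbation = reclassify(landcover, scheme)              # 5 weighted groups
binary = reclassify(perturbation, binary_from_landuse())  # unmanaged / managed

site = generate_site(
    landcover.shape,
    {"kind": "band", "center_row": 64, "amplitude": 12, "period": 128, "width": 14},
    buffer_width=8, site_id="S-1",
)

run = RealizationRun(n_realizations=200, master_seed=0,
                     filter=AutocorrelationFilter(total_gradient=0.10))
ensemble = run_ensemble(
    run, perturbation, binary, [site],
    {i: w for i, w in enumerate(scheme.weight_array())},
    structural_weight_array(structural_weights()),
    landuse_upm(), binary_upm(),
)
for name, d in ensemble["S-1"].items():
    print(f"{name:7s} naive={d.naive:.3f} mean={d.mean:.3f} "
          f"95% CI=[{d.ci_low:.3f}, {d.ci_high:.3f}] bias={d.bias:+.3f}")
```

Output:

```
met_bp  naive=0.677 mean=0.712 95% CI=[0.705, 0.719] bias=-0.035
met_fp  naive=0.795 mean=0.814 95% CI=[0.807, 0.822] bias=-0.019
met_bf  naive=0.313 mean=0.274 95% CI=[0.258, 0.288] bias=+0.039
met_ff  naive=0.467 mean=0.402 95% CI=[0.375, 0.424] bias=+0.065
index   naive=0.585 mean=0.570 95% CI=[0.560, 0.579] bias=+0.016
```

Reading it: misclassification inflates the apparent extent of unmanaged
cover in this mixed-use corridor (negative perturbation biases) but breaks
up contiguous habitat (positive fragmentation biases); combined into the
index the effects largely cancel, leaving a small positive bias — the
naive index slightly flatters the site — with a 95 % interval of about
±0.01 around the simulated mean.

The same pipeline runs from the shell on raster/CSV/TOML inputs:

```sh
floodmmi synth --rows 128 --cols 128 --seed 1 --out-dir demo
floodmmi run my_run.toml          # reclassify -> MSPA -> score -> simulate -> summarise
floodmmi mspa binary.asc structure.asc --edge-width 3
```

Rasters are ESRI ASCII grids or single-band TIFF; schemes, confusion
matrices and UPMs are labeled CSV; a full run is described by one TOML
config (see `floodmmi run --help`).

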