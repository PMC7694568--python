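# marshca

CA-Markov succession modelling and baseline-referenced zonation metrics for
banded coastal wetlands.

## The problem

Silty intertidal flats such as the Yancheng coastal wetlands (Jiangsu,
China) carry shore-parallel vegetation belts ordered land → sea as
*Phragmites australis* marsh → *Suaeda salsa* marsh → open mudflat, the whole
system slowly advancing seaward as the flat accretes. Since the 1980s the
invasive cordgrass *Spartina alterniflora* has inserted itself between the
*S. salsa* belt and the flats, squeezing the native belt from the seaward
side while *P. australis* advances from the landward side. Separating the
invasion's effect from natural succession requires a counterfactual: *what
would the landscape look like had the invader never arrived?*

`marshca` implements that analysis end to end for anyone working with dated
categorical land-cover rasters of a belt-structured coast:

* **Markov half** — estimate the class-transition probability matrix
  P[i → j] from a pair of dated maps by cell cross-tabulation, convert it
  between time steps with the k-th matrix root (eigendecomposition, clip,
  renormalize, residual reported), and project class areas forward:
  aₜ₊₁ = aₜ · P.
* **Cellular-automaton half** — advance the map itself one year at a time.
  The matrix prescribes integer *flows* F[i → j] ≈ nᵢ·P[i → j] (rounded so
  row margins equal current counts and column margins equal the
  largest-remainder class demands exactly), and each flow claims the source
  class's cells most suitable for the destination, where suitability is the
  destination's frequency among dynamic cells in a 5 × 5 contiguity window
  times the Markov probability. The filter is re-applied over 20 allocation
  rounds per step so fronts propagate coherently.
* **Validation** — confusion matrix, overall accuracy and Cohen's kappa
  κ = (p₀ − pₑ)/(1 − pₑ) between any two maps, plus hectare-valued
  transition cross-tabulations.
* **Zonation metrics** — the mean boundary distance L = S/D (the area S
  enclosed between a belt boundary and the seawall baseline, divided by the
  boundary's projected length D on the baseline), per-belt 1-D centroids,
  nearest/farthest boundaries, band widths, seaward-positive movement rates
  and area/proportion time series.
* **Synthetic landscapes** — a generator of banded coastal maps with ragged
  fronts and a known-parameter annual transition process, so the whole
  pipeline is testable without any satellite imagery.

## Worked example

The published annual transition matrix for the study system (estimated from
the 1985/1990 maps; rows = source class):

|              | S. salsa | P. australis | mudflat |
|--------------|---------:|-------------:|--------:|
| S. salsa     |   0.8789 |       0.1128 |  0.0083 |
| P. australis |   0.0183 |       0.9802 |  0.0015 |
| mudflat      |   0.0598 |       0.0031 |  0.9370 |

Simulate 22 years of no-invasion succession on a synthetic banded landscape
and track the *S. salsa* belt:

```python
from marshca import SimulationConfig, boundary_profile, run
from marshca import reference as R
from marshca.synthetic import SyntheticConfig, make_banded_grid

grid = make_banded_grid(SyntheticConfig(rows=200, cols=200, seed=5), date=1995)
series = run(grid, R.TRANSITION_1985_1990_ANNUAL, SimulationConfig(seed=105), 22)
for g in (grid, series[10], series[-1]):
    p = boundary_profile(g, R.SUAEDA)
    print(g.date, round(p.centroid_distance, 1), round(p.band_width, 1))
```

```
1995 1717.5 939.7
2006 3021.8 1832.2
2017 4345.4 1808.4
```

The belt centroid moves from 1717.5 m to 4345.4 m off the baseline — a
strictly year-on-year seaward drift, the qualitative signature of natural
belt succession — while per-class cell counts match the Markov demands
exactly at every step. On the published record the same arithmetic gives
the headline movement rates (`analysis/01_reference_metrics.py`):
*P. australis* centroid 877.50 m seaward over 1995–2017 (39.89 m/yr),
*S. salsa* 1281.10 m (58.23 m/yr), and an invasion-attributed *S. salsa*
area loss of 82.47 % against the no-invasion counterfactual.

The `analysis/` scripts run the stages as a narrative (reference
arithmetic, matrix recovery, CA simulation, agreement calibration), each
writing a small table under `results/`. There is also a CLI:

```bash
marshca synth --rows 200 --cols 200 --years 5 --seed 3 --out scratch/demo
marshca estimate --map-a scratch/demo/synthetic_1985.asc --map-b scratch/demo/synthetic_1990.asc \
    --date-a 1985 --date-b 1990 --scheme scheme.yaml --out matrix.csv
marshca simulate --initial scratch/demo/synthetic_1990.asc --date 1990 \
    --matrix matrix.csv --scheme scheme.yaml --years 22 --seed 42 --out scratch/sim
```

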