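# paleotrophic

Quantitative machinery for linking ecosystem productivity to the
Middle-to-Upper-Palaeolithic transition: an integrated, tested Python
implementation of the chronological, palaeoclimatic and macroecological
models used to ask whether stadial/interstadial swings in net primary
productivity (NPP) shaped where and when Neanderthal (Mousterian) groups
disappeared and modern-human (Châtelperronian, Aurignacian) groups arrived.

It is written for palaeoecologists and archaeologists who want to run these
analyses on their own date tables, pollen spectra, productivity series and
faunal lists — and for methodologists who want every step testable against
synthetic data with known ground truth.

## What it computes

**Chronology** (`paleotrophic.chronology`)
- Radiocarbon calibration against an IntCal-dialect curve: the likelihood of
  calendar age θ is N(age − μ(θ); σ_lab² + σ_curve(θ)²), normalised on a
  20-year grid; luminescence/U-series dates enter as calendar normals.
- Quality filtering (coefficient of variation ≥ 0.05, shell material,
  flagged levels), inverse-variance combination of same-level dates with a
  χ² consistency check, and summed probability distributions (SPD) per
  archaeological assemblage.
- Boundary estimation by Roberts–Solow optimal linear estimation (OLE) on
  the 5–10 most extreme calibrated medians, with date uncertainty propagated
  by 10,000-fold normal resampling.

**Palaeoclimate** (`paleotrophic.paleoclimate`)
- Weighted-averaging pollen transfer functions (taxon optima by abundance-
  weighted means, inverse deshrinking) for mean annual temperature and
  precipitation, with 500-cycle bootstrap cross-validation.
- Delta-method bias correction of simulated climate — additive for
  temperature, multiplicative for precipitation — and before/after bias
  assessment.

**Productivity dynamics** (`paleotrophic.npp`)
- dCORT dissimilarity between NPP trajectories:
  `dCORT(S1,S2) = f(CORT(S1,S2)) · d(S1,S2)` with
  `f(x) = 2/(1+exp(kx))`, CORT the first-difference correlation and d the
  Euclidean distance; with k = 2 temporal behaviour carries 76% of the
  index. Hierarchical (UPGMA) clustering, per-region cluster composition,
  Jaccard similarity of herbivore guilds, and stadial/interstadial phase
  statistics with the Wilcoxon rank-sum test.

**Carrying capacity** (`paleotrophic.carrying_capacity`)
- Total herbivore biomass from NPP by the robustly fitted log-log law
  `log10 THB = 1.401·log10 NPP − 0.642`, partitioned over a community by
  Damuth's rule `D_i = c·W_i^(−3/4)` with `c = THB / Σ W_i^(1/4)` (so
  `Σ D_i W_i = THB` exactly), size-class totals, validation against modern
  protected-area densities, minimum-census palaeocommunity assembly, and
  incidence-based rarefaction/extrapolation of species richness.

**Synthetic data** (`paleotrophic.synthetic`) generates all of the above
inputs from known ground truth, so every estimator is covered by recovery
tests. The `paleotrophic` CLI exposes each stage plus an end-to-end
`run --config run.yaml` pipeline.

## Worked example

```python
from paleotrophic.carrying_capacity import (AllometryModel, SpeciesMass,
                                            predict_thb, partition_biomass)

model = AllometryModel()          # slope 1.401, intercept -0.642
print(predict_thb(1.0, model))    # 0.228 -> THB in g m-2 at unit NPP

community = [SpeciesMass("Capra pyrenaica", 55.0),
             SpeciesMass("Cervus elaphus", 180.0),
             SpeciesMass("Equus ferus", 420.0),
             SpeciesMass("Bison priscus", 800.0)]
res = partition_biomass(2000.0, community)   # THB declared in kg km-2
```

prints (densities in ind km⁻², biomasses in kg km⁻²):

```
c = 123.218
Capra pyrenaica  W=  55 kg  D=6.101  B= 335.6  [medium]
Cervus elaphus   W= 180 kg  D=2.507  B= 451.3  [medium_large]
Equus ferus      W= 420 kg  D=1.328  B= 557.8  [medium_large]
Bison priscus    W= 800 kg  D=0.819  B= 655.3  [large]
```

The Damuth constant c sets the density of a 1-kg herbivore; heavier species
are rarer (D ∝ W^(−3/4)) but individually heavier, so their biomass share
grows as W^(1/4). The four shares sum to the declared 2000 kg km⁻² exactly.

A full synthetic run, end to end:

```sh
paleotrophic simulate --seed 5 --out data/
paleotrophic ole --dates data/dates.csv --curve data/curve.14c \
    --which youngest --iters 10000 --seed 5 --out end_boundary.json
```

With the default scenario (occupation 48,000–40,000 cal BP, 30 levels,
lab errors 150–400 yr) the resampled OLE end boundary lands within a few
hundred years of the planted 40,000 cal BP truth, with a 95% interval of
roughly ±1 kyr — e.g. seed 42 gives 39,610 cal BP (38,524–40,152).

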