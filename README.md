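# retinads

Quantitative analysis of retinal direction-selective circuit structure and
function, for physiologists and anatomists studying the starburst amacrine
cell (SAC) / ON-OFF direction-selective ganglion cell (ooDSGC) circuit — and
for anyone who needs well-tested implementations of direction-tuning
statistics, mosaic regularity indices, or laminar stratification profiling.

The package has three analysis strands, each driven end-to-end by a
synthetic-data generator with known ground truth so that every stage is
verifiable by parameter recovery and closed-form oracles:

**Spike-train direction tuning** (`retinads.tuning`, `retinads.classify`).
For a cell probed with a bar moving in 12 equally spaced directions θ_i with
spike counts n_i:

- direction selectivity index, DSI = |Σ n_i **v**_i| / Σ n_i, with **v**_i
  the unit vector along θ_i (0 = untuned, 1 = perfectly tuned);
- tuning width as the circular standard deviation σ_circ = √(−2 ln R̄),
  where R̄ is the mean resultant length of the count-weighted direction
  distribution — a nonparametric width estimate;
- a von Mises fit A·e^{κ cos(θ−μ)} / (2π I₀(κ)) for parametric summaries;
- tuning strength (P − N)/(P + N), where the preferred response P (null
  response N) is the cosine-weighted sum of the two sampled directions
  nearest the preferred (null) axis;
- ON/OFF response segmentation at the midpoint between the two temporal
  peaks of the pooled high-contrast PSTH, and the ON-OFF preferred-direction
  difference Δϕ;
- population stages: spike-sorting QC (refractory contamination > 10% or
  rate < 1 Hz excluded), DSGC gating on the bimodal DSI histogram with a
  two-Gaussian mixture (fallback threshold 0.25), ooDSGC isolation by the
  two response lobes, circular K-means subtype clustering seeded at the
  cardinal directions, and two-sample KS comparisons between genotypes.

**Mosaic regularity** (`retinads.mosaic`). The Voronoi domain regularity
index, VDRI = mean(domain area) / SD(domain area), with edge domains
excluded, compared against density-matched hard-core random arrays that
define the index expected by chance; plus per-cell "territory size" analyses
relating local crowding to binary phenotype outcomes.

**Anatomy** (`retinads.anatomy`). Primary-dendrite orientation classes
(IPL-directed / tangential / ONBL-directed at 45°/135° cuts), IPL-depth
fluorescence profiles (width-averaged, background-subtracted,
max-normalized) with plateau-aware peak calls and inter-band distances,
dendritic-tip polygon territory areas, thresholded plexus coverage,
homotypic tip-contact rates with a channel-flip chance control, and
projection-phenotype frequency tables.

## Worked example

Simulate a wild-type-like and a mutant-like ooDSGC population differing only
in null-direction spiking, and compare their tuning:

```python
from retinads.pipeline import RunConfig, PhysiologyGenotypeSpec, run_physiology_experiment

cfg = RunConfig(name="demo", seed=5)
cfg.physiology_genotypes = {
    "wildtype": PhysiologyGenotypeSpec(n_cells=50, null_rate=0.5),
    "mutant":   PhysiologyGenotypeSpec(n_cells=50, null_rate=6.0),
}
out = run_physiology_experiment(cfg, outdir="demo_out")
oods = out["metrics"][out["metrics"].is_oods]
print(oods.groupby("genotype")[["width_deg", "strength"]].median())
print(out["comparison"][["metric", "ks_statistic", "p_value"]])
```

prints

```
          width_deg  strength
genotype
mutant    78.390624  0.630884
wildtype  51.668064  0.925465
          metric  ks_statistic       p_value
0      width_deg          0.92  1.938129e-11
1       strength          1.00  1.582146e-14
2  delta_phi_deg          0.32  1.557603e-01
```

Raising null-direction firing from 0.5 to 6 spikes/trial widens the median
tuning curve by ~27° and drops tuning strength from 0.93 to 0.63 — both
shifts detected by the KS comparison at vanishing p — while leaving the
ON-OFF preferred-direction difference Δϕ unchanged, exactly the dissociation
this analysis is designed to expose. The same CLI is available as
`retinads simulate|physiology|mosaic|report`.

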