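# scassembly

Desk-scale analysis machinery for the question of how the synaptonemal
complex (SC) holds meiotic chromosomes together: specifically, whether the
transverse filament protein **SYCP1** can maintain chromosome synapsis when
its N-terminal head-to-head interface is weakened.

SYCP1 dimers from opposing chromosome axes meet at the SC midline through
the tip of their N-terminal coiled-coil (the *alphaN tip*, human residues
101-111 within the alphaN end 101-175), forming a head-to-head "dimer of
dimers". A single buried leucine (human L109, mouse L106) anchors that
interface; a neighbouring, partly surface-exposed residue (h.V105/m.L102)
matters much less. The package lets you exercise the whole quantitative
workflow around this biology on synthetic data:

* **`cg_simulator`** — a coarse-grained Brownian-dynamics model of the
  head-to-head tetramer under opposing axial steering forces, with
  genotype-dependent interface strength (WT, L102E, L106E, L102E/L106E).
* **`traj_analysis`** — Kabsch-superposition RMSD, per-residue RMSF, the
  interdimer distance between marker residues (h.L109) of opposing dimers,
  and the intact / loosened / dissociated classification with disruption
  time (an interface is intact while that distance stays below 10 Å).
* **`synth_imaging`** — synthetic superresolution-style z-stacks of two
  parallel chromosome axes with known separation, PSF blur and
  Poisson-Gaussian noise, plus overdispersed per-tubule apoptosis counts.
* **`image_quant`** — trace straightening, ten perpendicular intensity
  profiles of thickness 3, double-Gaussian peak fitting for the axis
  separation (synapsed axes sit ~150 nm apart; aligned-but-unsynapsed axes
  ~330-370 nm), and background-subtracted integrated ROI intensities on
  focal projections.
* **`stats_pipeline`** — Mann-Whitney U (exact for small tie-free samples),
  Fisher's exact test on tubule counts dichotomized at ≥ 5 apoptotic
  nuclei, the unpaired (Welch) t test, and a config-driven pipeline with a
  reproducible run manifest.

## Worked example

```python
import numpy as np
from scassembly import (
    steered_assay, AxisPairGroundTruth, synthesize_axis_pair_stack,
    measure_axis_separation, TubuleCountModel, synthesize_tubule_counts,
    compare_tunel_counts,
)

# 1. Steered dissociation assay at the middle force (0.05 kJ/mol/nm per atom)
for genotype in ("WT", "L106E"):
    r = steered_assay(genotype, force=0.05, seed=1)
    print(genotype, r.status, r.disruption_time)

# 2. Recover a known 150 nm axis separation from a synthetic SIM-like stack
mid = np.column_stack([np.linspace(12, 148, 20),
                       32 + 4 * np.sin(np.linspace(0, 2.5, 20))])
truth = AxisPairGroundTruth(true_separation_nm=150.0, midline=mid, seed=3)
stack, trace = synthesize_axis_pair_stack(truth, n_slices=9, shape=(64, 160))
out = measure_axis_separation(stack, trace)
print(round(out["mean_separation_nm"], 1), out["classification"], out["n_valid"])

# 3. Compare dichotomized apoptosis counts between two genotype scenarios
wt = synthesize_tubule_counts(TubuleCountModel(n_tubules=200, burst_fraction=0.015, seed=1))
mut = synthesize_tubule_counts(TubuleCountModel(n_tubules=200, burst_fraction=0.16, seed=2))
table, fisher = compare_tunel_counts(wt, mut)
print(table.table.tolist(), round(fisher.p_value, 8))
```

prints

```
WT intact None
L106E dissociated 11.904
149.7 synapsed 10
[[198, 2], [169, 31]] 4e-08
```

The wild-type interface survives the 100 ns steered run while the
core-mutant interface ruptures at ~12 ns; the imaging pipeline recovers the
150 nm ground truth to within a nanometre from all ten profiles and calls
the chromosome synapsed (< 250 nm); and the tubule comparison (2/200 vs
31/200 tubules with ≥ 5 apoptotic nuclei) is decisively significant by
Fisher's exact test.

A command-line umbrella mirrors the library:

```bash
scassembly simulate --genotype L102E/L106E --force 0.05 --seed 1 --out traj.xyz
scassembly analyze-traj traj.xyz --meta traj.meta.json --out results/
scassembly synth-images --separation 150 --seed 3
scassembly run --config examples/demo_config.yaml --out pipeline_out
```

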