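# corescaffold

Quantitative structural analyses for hollow multienzyme core scaffolds —
the ~10 MDa pyruvate dehydrogenase complex (PDHc) type of assembly, where a
60-subunit icosahedral transacetylase (E2) shell encloses twelve copies of
an E3-binding protein (E3BP) arranged as four trimers with tetrahedral
symmetry. The package turns the map- and model-based measurements used to
characterize such assemblies from cryo-EM data into tested, reusable
library code:

* **Density enclosure** — for a flexible element modeled into each of M
  symmetry-related subunits, count the atoms left outside the rendered
  density while sweeping the contour level over N levels (default
  0.015–0.052 in steps of 0.0005, N = 75). Across subunits a per-level
  confidence band `CI = μ ± z·σ/√M` (z = 3.291) is formed, and each
  subunit's enclosure probability is `p = n/N`, with n the number of
  levels at which its uncovered count falls strictly below the band's
  lower bound.
* **Proximity grouping** — Cα-anchor distances from each shell subunit to
  its nearest interior partner, binned into a proximal group (55–70 Å), a
  distal group (> 75 Å) and an intentionally open gap; group enclosure
  probabilities compared with a two-sided Mann–Whitney rank-sum test.
* **Interior occupancy** — solvent-excluded volumes (probe 1.4 Å) of
  interior components and disordered-chain ensembles inside a spherical
  mask (default radius 80 Å), reported as an occupancy pie.
* **Interfaces and pose screening** — Shrake–Rupley SASA, multi-body
  buried surface area, interface residues, a simplified vdW /
  electrostatic / desolvation score, steric-clash detection, and ranking
  of docking poses under a 10–25 Å lipoyllysine-reach distance restraint.
* **Kinetics** — Lambert–Beer conversion (ε = 3.07 × 10⁴ L mol⁻¹ cm⁻¹
  default) and Michaelis–Menten fits `v = V_max·S/(K_M + S)` with
  Jacobian-based standard errors.
* **Conservation** — per-column residue frequencies of an alignment at
  positions mapped through a designated reference sequence.
* **Synthetic data** — deterministic generators for toy assemblies,
  simulated maps with planted per-subunit element weights, self-avoiding
  Cα ensembles, noisy rate tables and alignments with planted
  conservation, so every stage is testable with no external downloads.

Structure and map I/O (PDB, mmCIF, MRC/CCP4) goes through
[gemmi](https://gemmi.readthedocs.io).

## Worked example

```python
from corescaffold import (AssemblyScenario, ContourSweep, MapSimulationConfig,
                          build_toy_assembly, confidence_band,
                          contour_sweep_profile, enclosure_probability,
                          simulate_map)
from corescaffold.synth import element_selections

scenario = AssemblyScenario(seed=3, element_weights=[1.0]*6 + [0.0]*6)
model = build_toy_assembly(scenario)
dmap = simulate_map(model, MapSimulationConfig(noise_sd=0.002, seed=7),
                    scenario.weight_by_chain)
profile = contour_sweep_profile(dmap, element_selections(scenario),
                                ContourSweep(), model=model)
stats = enclosure_probability(profile, confidence_band(profile))
print(stats.p_by_subunit())
```

prints (chains A–F planted with the element's density, G–L without)

```
{'A': 1.0, 'B': 1.0, 'C': 1.0, 'D': 1.0, 'E': 1.0, 'F': 1.0,
 'G': 0.0, 'H': 0.0, 'I': 0.0, 'J': 0.0, 'K': 0.0, 'L': 0.0}
```

— subunits whose element sits inside extra density have fewer uncovered
atoms than the cohort band at every one of the 75 contour levels
(p = 75/75), while element-free subunits never dip below it (p = 0).
The scripts in `examples/` walk through each capability the same way and
print what the numbers mean; a thin CLI (`corescaffold simulate|enclosure|
geometry|pipeline|kinetics|conservation`) wraps the pipeline for shell
use.

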