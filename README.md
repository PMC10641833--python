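# memmech

Trajectory-analysis toolkit linking lipid-bilayer composition to mechanical
softness and lateral organization. Given bilayer MD trajectories (or the
built-in synthetic generator), it computes:

- **geometry** — area per lipid, P–P bilayer thickness, and a
  surface-unevenness statistic from randomly sampled frames;
- **elasticity** — surface tension from the pressure-tensor anisotropy
  (γ = L_z·[P_zz − (P_xx+P_yy)/2], bar·Å → mN/m), the area compressibility
  modulus K_A fitted from a tension series with
  autocorrelation-corrected uncertainties, and a pooled two-sample t test
  between K_A estimates;
- **ordering** — per-carbon tail order parameters
  S_C = ⟨(3cos²θ−1)/2⟩ (heavy-atom i−1→i+1 vector vs. the membrane normal),
  relative-order profiles (S_mix/S_pure)·i, and terminal-methyl
  z-distributions;
- **diffusion** — lateral MSD with periodic unwrapping and drift removal,
  D from MSD = 4Dt over a configurable window, and a KS test for
  anomalous (non-Gaussian) diffusion;
- **lateral_org** — periodic 2D Voronoi cell areas per lipid,
  mixed-contact fractions, and neighbor-composition tables;
- **synthetic** — bilayer/pressure/tension generators with analytically
  known ground truth (S_C, thickness, unevenness, D, K_A), used by the
  recovery tests.

Units: Å, ps, bar, mN/m, 10⁻⁹ cm²/s (see `memmech/units.py`).
Topologies read from GRO/PDB, coordinates from XTC/DCD (via MDAnalysis), or
from a self-contained plain-text fixture format.

## CLI

```sh
# generate a synthetic system with ground truth
memmech synth --preset aa-dopc --out demo --seed 1

# analyses on the fixture trajectory
memmech apl demo/traj.fixture --n-per-leaflet 100 --out apl.csv
memmech thickness demo/traj.fixture --out thick.csv
memmech uneven demo/traj.fixture --frames 100 --seed 1 --out uneven.json
memmech order demo/traj.fixture --species LIPA --tail sn1 --out order.csv
memmech tmg demo/traj.fixture --species LIPA --bin 1.0 --out tmg.csv
memmech diffusion demo/traj.fixture --window 0.1:0.5 --out diff.json
memmech voronoi demo/traj.fixture --leaflet upper --out voronoi.csv
memmech contacts demo/traj.fixture --cutoff 11.0 --out contacts.json
memmech neighbors demo/traj.fixture --cutoff 15.0 --out neighbors.csv

# from tabular inputs
memmech tension --pressure demo/pressure.csv --out gamma.json
memmech ka --series demo/series.csv --out ka.json

# batch pipeline from a YAML config
memmech run --config run.yml --out results/
```

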