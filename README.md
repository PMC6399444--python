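# sercatools

Trajectory analysis for molecular-dynamics studies of lipid binding to
membrane pumps, built around the comparative question: *does a lipid bound
at a specific site change the structure, dynamics and solvation of the
protein?* The target system is the sarco/endoplasmic-reticulum Ca²⁺-ATPase
(SERCA), a ten-transmembrane-helix pump whose protonated E2 state binds a
single phospholipid in a nonannular cavity between helices M2 and M4 — but
every analysis is configuration-driven and applies to any
structure + trajectory pair.

The package provides, as a library plus a thin `analyze` CLI:

* **Contacts** — per-frame distances between named residue/headgroup atoms
  (min-heavy-atom, named-atom, or centre-of-geometry; minimum-image aware),
  occupancies of closed intervals ("R ≤ 0.5 nm", crystal-boundary bands),
  hydrogen-bond occupancy as a percentage of trajectory time
  (d(D···A) ≤ 0.35 nm, ∠D–H···A ≥ 150°, distance-only fallback without
  hydrogens), density histograms, and contact-vs-RMSD Pearson correlation.
* **Structure metrics** — closed-form least-squares (Kabsch-family)
  superposition; per-helix RMSD profiles (mean ± sd); RMSD time series;
  deterministic leader/medoid conformational clustering with representative
  structures.
* **Essential dynamics** — Cartesian PCA after rigid-body alignment,
  cumulative-variance accounting, per-component one-Gaussian fits whose
  r² classifies each component (essential < 0.9 ≤ partial < 0.98 ≤
  non-essential), and inner-product matrices |vᵢᴬ·vⱼᴮ| measuring
  collinearity of two trajectories' component sets.
* **Water wires** — per-frame wire/no-wire detection of hydrogen-bonded
  water chains linking a buried residue to a cytosolic site or bulk (BFS
  over the H-bond graph, ≤ 4 bridging waters by default), event
  segmentation with optional gap merging, and lifetime statistics in ps.
* **Synthetic data** — seeded generators that plant known two-state
  distance processes, covariance spectra with non-Gaussian modes, scheduled
  three-water wires and discrete headgroup states, returning the ground
  truth alongside each fixture so every stage is verifiable by parameter
  recovery without running MD.

See `docs/methods.md` for the models, conventions and their rationale.

## Worked example

Generate a paired synthetic study — a "bound" system with a planted
bimodal contact at 0.5/0.8 nm (60% contact occupancy) and two scheduled
water wires, a "free" system with a 0.3 nm contact state and three wires —
then run the full battery from one config:

```python
import yaml
from sercatools.pipeline import load_config, run
from sercatools.synth import make_demo_pair

man = make_demo_pair("fixtures", seed=1, n_frames=4000)
cfg = {
    "structure": man["systems"]["bound"]["structure"],
    "trajectories": {k: v["trajectory"] for k, v in man["systems"].items()},
    "frame_interval_ps": 20, "output_dir": "out", "seed": 1,
    "distances": [{"label": "probe", "selA": "resid 108 and name NE2",
                   "selB": "resname POPC and name P", "mode": "named-atom",
                   "occupancy_intervals": [[0.35, 0.65]]}],
    "cluster": {"sel": "resname SER and name CA", "cutoff_nm": 0.1},
    "pca": {"sel": "resname ALA and name CA", "n_components": 6},
    "wires": [{"label": "N-pathway", "source": "resid 309 and name OE1 OE2",
               "sink": "resid 101 and name ND2 OD1"}],
}
yaml.safe_dump(cfg, open("config.yaml", "w"))
summary = run(load_config("config.yaml"))
b = summary["trajectories"]["bound"]
print(b["distances"]["probe"]["occupancy[0.35,0.65]"])   # 0.606
print(b["wires"]["N-pathway"])
# {'n_events': 2, 'mean_lifetime_ps': 130.0, 'min_lifetime_ps': 120.0,
#  'max_lifetime_ps': 140.0}
print([round(p, 3) for p in b["clusters"]["populations"]])
# [0.454, 0.301, 0.17, 0.074]
print([c["class"] for c in b["pca"]["classifications"]][:4])
# ['essential', 'essential', 'non-essential', 'non-essential']
```

Reading the output: the measured contact occupancy (0.605) recovers the
planted 0.60 stationary weight; the wire detector finds exactly the two
scheduled events, with lifetimes in the planted 100–150 ps band; the
clustering recovers the four planted headgroup states including the 7%
minority orientation; and the one-Gaussian classifier marks exactly the
two planted two-well components as essential. `out/` additionally holds
per-frame TSV series, histograms, a comparative distance table with the
crystal-reference column, the inner-product matrix between the two
systems' component sets, representative-frame PDBs, and `summary.json`.

The same battery runs from a shell:

```
analyze synth --spec synth.yaml      # outdir/seed/n_frames
analyze validate --config config.yaml
analyze run --config config.yaml
```

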