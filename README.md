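# ntpchain

Conformational analysis of the triphosphate chain of Mg-ATP / Mg-GTP
complexes: geometric descriptors from MD trajectories, Mg²⁺ coordination
classification, monovalent-cation (K⁺ / Na⁺ / NH₄⁺) binding-site assignment
and occupancy, the accompanying statistics layer, and a comparative survey
of P-loop NTPase crystal structures — all exercised end-to-end on a
synthetic-trajectory generator with known ground truth.

## What it computes

* **Chain geometry** (`ntpchain.chain_model`) — five descriptors per chain:
  the PA–PG distance, the PB–O3B–PG bridge angle, and three inter-phosphate
  dihedrals (Ψ between α/β, β/γ and α/γ oxygens; 0° = eclipsed, ±60° =
  staggered; signed IUPAC convention). Also the inverse operation: embed a
  chain in 3D realising requested descriptor values to 1e-6.
* **Trajectory analysis** (`ntpchain.trajectory_analysis`) — per-frame Mg²⁺
  coordination modes (bidentate βγ, tridentate αβγ, with a *curled*
  refinement for compressed βγ chains), cation site assignment (BG / AG / G
  with species binding distances 3.2 Å for K⁺/NH₄⁺ and 2.4 Å for Na⁺),
  occupancy series, dwell-filtered state segmentation, moving averages and
  labeled atom-pair (H-bond) tracking. Reads multi-model PDB or
  topology + coordinate series via MDAnalysis.
* **Statistics** (`ntpchain.stats_reporting`) — autocorrelation-based
  decorrelated frame extraction, pooled-variance two-sample t-tests
  (dof = n+m−2, 5% level), 1-/2-term Gaussian fits of dihedral histograms,
  and normalized (d, θ) heat maps with crystal-structure overlay hulls.
* **Structure survey** (`ntpchain.structure_survey`) — screens PDB/mmCIF
  files for Mg-bound NTP-like ligands near a Lys residue, maps analogs
  (AMP-PNP/AMP-PCP/γ-S substitutions; AlF₄⁻/AlF₃/MgF₃⁻/BeF₃⁻ γ-phosphate
  mimics) onto the canonical chain, measures geometry (mimic central atom
  as the PG proxy, closest F for γ distances), finds the AG-site occupant
  (cations → water → Arg/Lys nitrogens) and superposes P-loop backbones
  (Kabsch).
* **Synthetic data** (`ntpchain.synthetic_data`) — trajectories whose
  descriptors follow configurable per-segment Gaussian statistics with
  AR(1) persistence, Mg and ions placed to realise each segment's
  coordination state and per-ion bound fractions, plus minimal fixture
  structures; everything ships with a JSON ground-truth sidecar.

## Command line

```sh
# generate a synthetic trajectory (+ ground-truth sidecar)
ntpchain synth --seed 1 --out runs/synth

# analyze a trajectory: per-frame/segment tables, occupancies, heat map
ntpchain analyze runs/synth/synthetic.pdb --dt-ps 50 --out runs/analysis

# survey structure files into a geometry/occupant table + exclusion log
ntpchain survey data/structures/*.pdb --out runs/survey

# re-render plots from an analysis directory
ntpchain report --analysis runs/analysis --out runs/report
```

Thresholds (Mg–O cutoff 2.5 Å, curled threshold 4.65 Å, Lys contact 4.0 Å,
chain-proximity radius 4 Å, species binding distances) live in a flat YAML
config (`--config`), are overridable per flag, and are echoed into every
output directory for provenance. Identical config + seed ⇒ byte-identical
JSON summaries.

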