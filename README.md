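# ntpflow

Analysis toolkit for ligand (NTP) diffusion into channel systems of large
nucleic-acid enzymes, built around three questions:

1. **How wide is a channel, and where does it narrow?**  A pathway-exploration
   algorithm grows a maximal-clearance axis from a channel mouth to a buried
   target and reports the minimal radius along the axis per trajectory frame
   (`ntpflow.pathway`).
2. **Where do ligands bind and how do they move?**  Contact-based macro-region
   occupancy per frame, time-average binding propensities per region and per
   channel, directed transition graphs, and detection of entry /
   partial-loading / complete-loading / exit events (`ntpflow.states`, with the
   MR1–MR20 region topology bundled in `ntpflow.regions`).
3. **Is the downstream DNA available for binding?**  Tri-state classification
   of base-pair association (associated / partially melted / melted) from
   hydrogen-bond distances, with time fractions optionally stratified by a
   ligand state (`ntpflow.bubble`).

Everything is testable offline: `ntpflow.synthetic` generates channel
phantoms with analytic clearance profiles, multi-ligand jump-process
trajectories with exact ground-truth timelines, and planted base-pair melting
series.

## CLI

All commands live under a single entry point:

```bash
# synthetic fixtures
ntpflow simulate phantom --shape bent --length 12 --out-pdb tube.pdb --out-truth truth.tsv
ntpflow simulate diffusion --n-ligands 8 --n-frames 1000 --out-pdb diff.pdb --out-truth states.tsv
ntpflow simulate melting --melted 0.3 --partial 0.2 --out-pdb melt.pdb --out-truth states.tsv

# channel geometry
ntpflow path tube.pdb --start 0,0,0 --target 0,0,30 --out-table axis.tsv --out-axis axis.pdb
ntpflow profile tube.pdb traj.pdb --start 0,0,0 --target 0,0,30 --out profile.tsv
ntpflow constrictions profile.tsv --out report.tsv

# ligand states (regions.yaml: per-region class, channels, residues, adjacency)
ntpflow occupancy structure.pdb traj.pdb regions.yaml --out propensity.tsv
ntpflow transitions structure.pdb traj.pdb regions.yaml --out events.json

# base-pair melting
ntpflow melting structure.pdb traj.pdb pairs.json --strata labels.txt --out fractions.tsv
```

The bundled region map (`ntpflow.regions.default_region_graph()`) carries the
MR1–MR20 names, entry/infiltration/external classes, channel memberships and
adjacency; residue lists are placeholders to be filled per structure via
`RegionGraph.with_selections` or a YAML file.

## Conventions

- van der Waals radii: Bondi by element, overridable; unknown elements get
  1.5 Å with a warning.
- Clearance is signed surface distance (centre distance minus vdW radius).
- Radius profiles use 1 Å bins by arclength from the pathway end and trim the
  first 6 Å on the entry side by default.
- Region contacts: heavy atoms within 4.0 Å (configurable).
- Base-pair bonds: donor–acceptor heavy-atom distance ≤ 3.5 Å, no angle term;
  partial melting = some but not all bonds broken.

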