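# mdcons

Analysis of protein–protein complex ensembles through the conservation of
their intermolecular residue–residue contacts.

Classical trajectory measures (RMSD, RMSF, radius of gyration) were designed
for single macromolecules and say little about what a researcher simulating a
*complex* actually cares about: whether the biological interface holds
together. `mdcons` takes an ordered ensemble of snapshots of a two-partner
complex — a multi-model PDB file or a set of single-model PDB files — and
quantifies interface dynamics directly:

* **Contacts.** Residues *k* (partner A) and *l* (partner B) are in contact
  in a frame when at least one pair of heavy atoms, one from each residue,
  is closer than 5 Å (the CAPRI convention; strict inequality).
* **Conservation rates.** Over *N* frames, each observed contact gets
  `CR_kl = nc_kl / N`, the fraction of frames containing it (1 = present in
  every frame).
* **Overall conservation coefficients.** For a threshold *t* ∈ {0.50, 0.70,
  0.90},

  `C_t = nc_t / (Σᵢ nc_i / N)`

  where `nc_t` counts the distinct contacts conserved in at least a fraction
  *t* of the frames and the denominator is the mean number of contacts per
  frame. The two counts live on different footings, so `C_t` can exceed 1
  and is not clipped.
* **Consensus map.** A residue-vs-residue map with one mark per observed
  contact, gray-scaled by `CR_kl` (black = always present).
* **Interface area.** Per frame, half the solvent-accessible surface area
  buried on complexation, `(ASA_A + ASA_B − ASA_AB) / 2`, from a
  deterministic Shrake–Rupley sampler with NACCESS-style (Chothia) radii and
  a 1.4 Å probe.
* **Characterization.** Contact typing by residue polarity
  (hydrophilic/hydrophobic/mixed, COCOMAPS-style dialect), per-residue
  percent burial, and minimum-distance monitors for chosen functional
  groups (e.g. an Asp carboxylate vs a Lys amino group).

## Worked example

Generate a synthetic 200-frame trajectory whose three interface contacts
persist with probabilities 1.0, 0.7 and 0.3, then run the full analysis:

```sh
mdcons fixtures --n-frames 200 --seed 7 \
    --slot 1,1,1.0 --slot 3,3,0.7 --slot 5,5,0.3 -o traj.pdb
mdcons run traj.pdb -a A -b B -o out
```

`out/contacts_cr.tsv` recovers the persistence of each contact from the
coordinates alone:

```text
chain_A  resnum_A  resname_A  chain_B  resnum_B  resname_B  nc_kl  CR_kl
A        2         SER        B        2         SER        200    1.0
A        4         SER        B        4         SER        138    0.69
A        6         SER        B        6         SER        58     0.29
```

and `out/summary.txt` reports the ensemble statistics:

```text
N_frames                200
mean_contacts_per_frame 1.98
C_50    1.01    nc_50   2
C_70    0.51    nc_70   1
C_90    0.51    nc_90   1
mean_interface_area_A2  41.16
sd_interface_area_A2    13.50
```

Read: on average 1.98 contacts exist per frame; two contacts are conserved
in ≥50% of frames (so `C_50 = 2/1.98 = 1.01`, slightly above 1 by
construction of the normalization), only the persistent one survives the
70% and 90% thresholds, and the mean interface area fluctuates with the
toggling contacts. The bundle also contains the grayscale consensus map
(`consensus_map.png`), the full matrix as text, per-frame areas, a
first-frame burial report, a log and a manifest echoing the configuration.

The same analyses are available one at a time (`mdcons contacts`,
`consensus`, `area`, `burial`, `distance`, `map`), and as a Python API
(`mdcons.frame_contacts`, `mdcons.conservation_rates`,
`mdcons.interface_area`, …).

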