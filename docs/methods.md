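# Methods

## Contact model

Two residues, one per binding partner, are in contact in a frame when at
least one heavy-atom pair (one atom from each residue) lies strictly closer
than the cutoff, default 5.0 Å — the convention used by CAPRI for the
fraction-of-native-contacts criterion. "Heavy" means any element other than
hydrogen or deuterium, read from the PDB element column (with a fallback to
the atom-name convention when the column is blank). The phrase "at least
two heavy atoms within 5 Å" that circulates for this criterion is read as
*one atom from each residue* — i.e. one qualifying atom pair — matching the
usual contact-map definition ("any pair of atoms belonging to the two
residues closer than a cutoff"); it is **not** read as requiring two
qualifying pairs. Ties at exactly the cutoff are non-contacts (strict
`<`); the boundary convention is fixed, documented here, and exercised by a
dedicated boundary test. Distances are computed in double precision with no
periodic-boundary imaging — snapshots are assumed whole and imaged upstream,
as is standard for PDB exports of MD trajectories.

The k-d tree neighbor search (`scipy.spatial.cKDTree`) is an implementation
detail: the test suite asserts exact set equality with an O(n²) all-pairs
scan on randomized frames, and monotonicity of the contact set in the
cutoff.

## Conservation statistics

With `nc_kl` the number of frames containing contact (k, l) and N the number
of frames, `CR_kl = nc_kl / N`. Records exist only for pairs observed at
least once; a CR of zero is representable only implicitly as an empty cell
of the consensus matrix, because the universe of never-touching pairs is the
full cross-product and carries no information.

The coefficients are `C_t = nc_t / (Σᵢ nc_i / N)` with `nc_t` the count of
distinct contacts having `CR_kl ≥ t` (inclusive threshold). Because the
numerator counts distinct pairs while the denominator is a per-frame mean,
`C_t` is not bounded by 1; values above 1 arise naturally (many transient
contacts depress the mean) and are reported as computed. Threshold
comparisons are done in exact rational arithmetic (`Fraction(nc_kl, N) ≥
Fraction("0.7")`), so a contact conserved in exactly 70% of frames counts
toward `nc_70` independent of binary floating-point representation. CR
values are printed at two decimals in tables but retained at full precision
internally. Every supplied snapshot is used; the package never subsamples.

Two invariants are asserted property-style on randomized ensembles:
`C_90 ≤ C_70 ≤ C_50`, and the double-counting identity
`Σ_records nc_kl = Σ_frames nc_i`.

## Interface area and burial

The interface area of a frame is half the solvent-accessible surface area
(ASA) buried on complexation, `(ASA_A + ASA_B − ASA_AB)/2`, with the
isolated-partner terms computed by deleting the other partner's atoms from
the same coordinates (no re-relaxation) — the standard buried-ASA
convention. Per-residue percent burial is
`100·(ASA_free − ASA_complex)/ASA_free` over the residue's heavy atoms;
residues with free ASA below 0.1 Å² are flagged rather than divided.

ASA uses Shrake–Rupley sphere sampling rather than Lee–Richards slicing:
each heavy atom's van der Waals sphere is inflated by the probe radius
(default 1.4 Å, a water) and covered with a golden-section spiral lattice
(default 960 points); a point is buried when strictly inside any
neighbour's inflated sphere, and the atom's area is the accessible fraction
of `4π(r+probe)²`. The lattice is deterministic, so areas are bit-for-bit
reproducible for fixed parameters — no random number generator is involved.
Shrake–Rupley agrees with slicing-based programs (e.g. NACCESS) to within
roughly 1–2% on protein interfaces, which is why crystal-structure area
checks carry a ±3% tolerance rather than expecting bit-exact agreement: the
exact slicing parameterization behind published reference areas is not
part of this package.

Radii follow the Chothia set NACCESS uses: N 1.65, O 1.40, S 1.85 Å;
carbons are 1.76 Å when trigonal/aromatic (backbone carbonyl, carboxamide
and carboxylate carbons, aromatic rings, Arg CZ) and 1.87 Å when
tetrahedral. Elements outside the table fall back to per-element values
(C 1.76, N 1.65, O 1.40, S 1.85, Se 1.90, P 1.80); a custom two-column
element table can be loaded as an alternative dialect. Hydrogens have no
surface and do not occlude.

Numerical notes. The sampler's error for an isolated atom is zero by
construction (no occluders); for overlapping pairs the test suite checks
the analytic two-sphere cap formula at several separations and the
convergence of the error with lattice density. Exactly coincident atom
centers are a degenerate input: every sample point of one atom lies exactly
*on* its twin's surface, where the strict-inequality burial test is a
knife-edge; such inputs are physically meaningless and are not given a
defined area. Global rotation/translation changes areas only through the
fixed lattice orientation; the suite bounds this artifact at 0.5% of the
interface area.

## Polarity dialect and distance monitors

Contact typing partitions records into hydrophilic–hydrophilic,
hydrophobic–hydrophobic and mixed, using a COCOMAPS-style dialect:
hydrophobic = {ALA, VAL, LEU, ILE, MET, PHE, PRO, TRP, GLY}, the remaining
eleven standard residues (including CYS, TYR, HIS) hydrophilic. The counts
most often quoted for protein interfaces are sensitive to the CYS/TYR/GLY
assignments, so the dialect ships as an editable two-column text config
(`mdcons/data/polarity_cocomaps.txt`) and can be swapped per run;
selenomethionine maps with methionine. Unknown residue names resolve to a
configurable default with a warning, or raise in strict mode.

Distance monitors report, per frame, the minimum heavy-atom distance
between two explicit selections (chain, residue, optional atom-name list).
Functional groups are named atom lists — Asp OD1/OD2 vs Lys NZ — never
inferred chemistry; hydrogen-bond or salt-bridge geometric criteria are
deliberately out of scope, since the contact criterion itself captures
interactions such motif detectors miss. Selections must target distinct
partners; frames where a selection is absent yield a missing value. A
cross-module test confirms that a pair's CR is positive exactly when its
distance series dips below the cutoff in at least one frame.

## Structure input

Biopython's PDB parser backs the reader. One frame per MODEL block (a file
without MODEL records is a single-frame ensemble), or an ordered list of
single-model snapshot files; the two roads are tested to produce identical
trajectories for identical content. Waters are always dropped; HETATM
records are dropped by default except MSE, which is part of the polymer.
Alternate locations resolve to the highest-occupancy conformer (ties:
first encountered). Residue identity is (chain, author residue number,
insertion code), kept verbatim from the file; residues present in only
some frames stay in the registry, and contacts involving them are simply
absent from frames lacking them — the frame count `nc_kl` only counts
frames where the contact exists. Hydrogens, common in MD-derived PDB
snapshots, are retained in the model but excluded from both contact
detection and surface areas via the heavy-atom flag. A canonical
multi-model writer (3-decimal Å) closes the round trip for fixtures and
filtered exports. Binary trajectory formats (XTC/DCD) are not read; export
snapshots to PDB upstream.

## Synthetic fixtures

The fixture generator builds two chains of single-heavy-atom
pseudo-residues (optionally 3 atoms each) on parallel lines: designated
contact slots sit at 4.5 Å (inside the cutoff), every other intermolecular
pair at ≥ 8 Å. In a trajectory each slot is set, independently per frame,
to the contact geometry with its persistence probability p, else displaced
to 9 Å. One seeded generator (`numpy.random.default_rng`) drives all
randomness and the seed is recorded in a PDB REMARK, so a fixture is
reproducible from its file. Residue names alternate ALA/SER so the
polarity classifier is exercisable synthetically.

This emulates exactly one feature of real MD ensembles — per-contact
persistence frequencies — and none of the others: no excluded volume, no
correlated contact motion, no conformational relaxation, no realistic
side-chain geometry. Passing the recovery tests therefore shows that the
pipeline measures contact persistence without bias at realistic ensemble
sizes (binomial-limited accuracy: ±0.031 at p = 0.7, N = 2000, three
standard errors); it does not validate behavior on real force-field
dynamics. Real-structure behavior is covered separately by the
crystal-structure checks when the reference PDB files are supplied.

## Problem sizes in the shipped tests

The suite runs entirely on generated inputs: randomized frames up to ~500
atoms for the contact oracle, a 2000-frame persistence fixture for
recovery, 100 random ensembles for the coefficient invariants, and toy
complexes for surface checks — together a couple of minutes on one CPU.
Ensemble sizes in the thousands of frames with full-size proteins
(hundreds of residues per partner) are the intended production scale; the
SASA step dominates there (roughly seconds per frame per thousand atoms at
960 points) and `--sphere-points` is the knob that trades area precision
for speed.

## Known limitations

* Eq.-style `C_t` normalization by the mean per-frame count, while
  implemented as defined, makes `C_t` awkward to compare across systems
  with very different interface sizes; the per-record CR table is the
  robust currency.
* No mmCIF input, no bond perception, no force-field awareness.
* Polar/apolar area decomposition and relative (Gly-X-Gly) accessibilities
  are out of scope.
* The renderer's marker size interacts with very sparse low-CR maps; the
  gamma option darkens weak contacts but is purely presentational.
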