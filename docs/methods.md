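# Methods

`liprot` quantifies lipid–protein interactions from coarse-grained (CG)
molecular dynamics trajectories along the three families of analysis the
field uses: contact-based metrics, in-plane density / depletion–enrichment,
and physical membrane properties (thickness and curvature). This note
records the model definitions, the defaults and why they were chosen, the
numerical choices, what the synthetic generators do and do not emulate, and
the known limitations.

## System model and preconditions

Input is a coordinate file (GRO or PDB) plus an optional trajectory
(XTC/TRR/DCD) containing **only protein and lipid particles**. Residues are
classified by name: the 20 canonical amino acids plus HIS protonation
variants (HSD/HSE/HSP/HID/HIE/HIP) are protein; names in the lipid database
are lipids; anything else is unknown. In strict mode (the default) the
solvent names `W, WF, NA+, CL-, ION, SOL, TIP3` abort the run — analyzing a
system with un-stripped water would silently corrupt every density and
contact statistic.

Internal units are fixed to nm and ps (the GROMACS/Martini convention); PDB
ångström values are converted on read and write. Residue indices are
0-based internally and 1-based (the file's own numbering) in all outputs.
Only orthorhombic periodic boxes are supported: the minimum-image
arithmetic used everywhere assumes a rectangular cell, so triclinic boxes
are rejected loudly rather than producing wrong distances.

The lipid database ships Martini defaults (phospholipids keyed on the PO4
phosphate bead, cholesterol on ROH, PIP-like lipids on their phosphate
beads) and is user-extensible from YAML, so unrecognized lipids require no
code change.

**Leaflets.** Each lipid molecule's leaflet is decided per frame by its mean
headgroup z against the global mean headgroup z of that frame (ties go to
the upper leaflet). This assumes a single, roughly planar bilayer with its
normal along z; vesicles, micelles and strongly curved membranes are out of
scope and not detected automatically.

## Contacts

A protein residue and a lipid molecule are *in contact* in a frame when any
selected bead of the molecule is within a cutoff distance — **inclusive**,
`d <= cutoff` — of any bead of the residue, under the minimum-image
convention. The default cutoff is **0.7 nm**: CG beads represent ~4 heavy
atoms with van der Waals radii around 0.26 nm, making 0.5–0.7 nm the
customary first-shell contact range at Martini resolution; the value is a
CLI flag (`--cutoff`). Bead selection per lipid type is either all beads
(default) or headgroup beads only (`--beads headgroup`).

The neighbor search is a periodic cell list (cell edge ≥ cutoff, 27-cell
neighborhood with wrapped indices) and is contractually identical to the
O(N²) minimum-image scan; the test suite verifies exact set equality on
randomized frames, nesting of contact sets under growing cutoff, and
invariance under rigid translation modulo the box. The cutoff must be
smaller than half the smallest box length on every analyzed frame
(minimum-image validity); otherwise the run aborts with advice.

## Metrics

From the per-frame presence series of each (residue, lipid type):

* **occupancy** — fraction of frames with ≥1 molecule in contact,
* **mean_count / sum_count** — distinct molecules in contact, averaged /
  summed over frames,
* **durations** — maximal runs of consecutive in-contact frames are events;
  a k-frame run lasts k·dt (reported in ns). `longest_duration` is the max
  over molecules, `mean_duration` the mean over all events of all
  molecules, `n_events` their count. Events truncated by the trajectory end
  still count as events; no censoring correction is applied — the simplest
  defensible convention, stated here because it biases mean durations
  downward for residence times comparable to the trajectory length.
  Kinetic residence-time model fitting (survival-curve exponentials) is
  deliberately not implemented.

**Network aggregation.** For network-graph visualization, lipid types and
residue classes become nodes: lipid node size is the type's fraction of all
lipid molecules, class node size the class's fraction of protein residues.
The default classes are hydrophobic {ALA,VAL,LEU,ILE,MET,PRO,GLY,CYS},
aromatic {PHE,TRP,TYR}, polar {SER,THR,ASN,GLN,HIS}, positive {ARG,LYS},
negative {ASP,GLU}; the mapping is YAML-configurable. Edge width is the
mean of a chosen metric over **all** residues of the class, not only the
contact-positive ones — averaging over all residues keeps widths comparable
across classes of different sizes; this was an open design choice and is
flagged here.

## Density and depletion–enrichment

The in-plane density map is the time-averaged 2D histogram of selected bead
(x, y) positions wrapped into [0, L): half-open cells [a, b), last cell
closed, counts divided by the number of frames. In count mode the map
conserves observations exactly (sum × n_frames = total bead observations);
a per-area mode (nm⁻²) is available behind a flag since either
normalization is defensible for display. Maps are not rotationally aligned
and the protein is not re-centered: the user must pre-center the protein
(standard trajectory tooling), and a warning fires if the protein centroid
drifts more than 10% of the box from the center in x/y. Contour levels for
display are fractions of the map maximum.

The **depletion–enrichment index** of a lipid type is the ratio of its
composition fraction in a shell around the protein to its bulk composition
fraction. Per frame, the shell is the set of lipid molecules with any bead
within r₀ of any protein bead (minimum image); the local fraction is the
time average of the type's share of the shell (frames with an empty shell
are skipped); the bulk fraction is the type's share of all lipid molecules.
The default shell radius is **r₀ = 1.4 nm**, twice the contact cutoff, so
the shell spans roughly the first lipid annulus; it is configurable
(`--shell-radius`). An index of 1 means no preference, >1 enrichment,
<1 depletion.

## Membrane thickness and curvature

Each leaflet's headgroup beads define a Monge-patch surface z = f(x, y) on
a regular periodic grid: the cell value is the mean z of the beads binned
to it, and empty cells are filled by synchronous iterative averaging of
their periodic 4-neighbors until none remain — a deterministic,
periodic-safe scheme chosen over spline fitting for robustness at the
sparse occupancies typical of small systems. Optional periodic Gaussian
smoothing (sigma in cells) follows. Thickness is the pointwise difference
between the upper and lower headgroup surfaces — the phosphate-to-phosphate
definition that grid-based membrane tools conventionally report; the bead
set follows the lipid database and is configurable.

Curvature uses central finite differences with periodic wrap and the
Monge-patch formulas

    H = [(1 + f_y²) f_xx − 2 f_x f_y f_xy + (1 + f_x²) f_yy] / [2 (1 + f_x² + f_y²)^{3/2}]
    K = (f_xx f_yy − f_xy²) / (1 + f_x² + f_y²)²

Sign convention: the surface normal is +z, so a crest bulging toward +z (a
dome) has H < 0 and a bowl opening toward +z has H > 0; for the test
sinusoid z = A·sin(2πx/L) the crest value is −A(2π/L)²/2. The scheme is
second-order accurate; the suite verifies the closed form within 2% on a
64×64 grid and the ~2nd-order error decay under grid refinement. By default
curvature is computed per frame and then time-averaged (curvature is
nonlinear in the surface, so the order matters); a flag computes the
curvature of the time-mean surface instead. Grids must be at least 3×3.

## Synthetic systems and what passing tests show

The generator module builds Martini-named fixtures entirely in code:

* **Bilayer + protein cylinder** — lipids on two z-offset lattices
  (headgroups at ±1.75 nm around the midplane, beads stacked at 0.3 nm)
  around a bead cylinder spanning the membrane; lattice sites keep ~0.4 nm
  clearance from the protein surface, the typical CG bead-contact gap, so
  annular contacts exist. Motion models: static, Gaussian jitter
  (σ = 0.05 nm default), per-frame re-mixing of molecules over lattice
  sites (an idealized "infinitely fast diffusion" used for mixing tests),
  and uniform re-placement (for flat-density tests).
* **Scripted contact schedules** — single-bead lipids placed at 0.7×cutoff
  from a residue in scheduled frames and parked at 3×cutoff otherwise, with
  residues spaced 5×cutoff apart so no placement can graze a neighboring
  residue; the resulting contact series equals the schedule by
  construction.
* **Planted shell composition** — per frame, a fixed number of molecules of
  each type is placed inside the enrichment shell (radial band chosen so
  the nearest protein bead is always within r₀) and the rest far outside,
  so the expected enrichment index is known exactly.
* **Analytic surfaces** — flat / tilted-plane / sinusoid point clouds for
  the surface pipeline.

All generators are deterministic functions of their spec and seed. They
emulate geometry and bookkeeping, **not** physics: there are no forces, no
realistic diffusion, no protein conformational dynamics, no membrane
undulation spectrum. Passing tests therefore demonstrate that the analysis
machinery is correct (exact neighbor search, exact metric bookkeeping,
correct surface calculus, correct normalizations) — they do not validate
biological conclusions drawn from real trajectories, which additionally
depend on sampling and force-field quality.

Problem sizes used by the tests and the acceptance script (50 random frames
of ≤500 particles for the oracle check; 120-frame mixing/enrichment runs of
48–64 molecules; 64×64 curvature grids) are chosen so every statistical
check has comfortable margin while the whole suite runs in seconds.

## Numerical choices and degenerate inputs

* Contact predicate is inclusive (`≤ cutoff`); boundary-exact cases in tests
  use binary-representable distances.
* Leaflet ties at the midplane go to the upper leaflet (deterministic).
* Density/surface binning: index = floor(x/L·n), clamped to the last cell to
  guard against floating-point x = L after wrapping.
* Empty-cell fill iterates synchronously, so the result is independent of
  sweep order.
* Zero-contact (residue, lipid type) rows report zero durations and events;
  all-gap alignment columns stay masked; an all-zero density map yields
  contour thresholds of 0.
* Degenerate inputs raise typed errors rather than producing NaNs: <2 lipid
  molecules for leaflet assignment, zero selected beads, empty enrichment
  shells on every frame, grids smaller than 3×3, cutoffs ≥ half the box.

## Known limitations

* Planar single bilayers only; the global-midplane leaflet rule fails for
  vesicles and strongly undulating membranes.
* Orthorhombic boxes only.
* No 3D volumetric densities; no rotational alignment before density
  averaging.
* No binding-site identification or ranking, and no residence-time model
  fitting — the metrics stop at descriptive statistics.
* Duration statistics are not corrected for trajectory-end truncation.
* The structure-heatmap PDB writer emits minimal single-chain records
  adequate for B-factor coloring, not a full-fidelity PDB round trip of
  arbitrary input.
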