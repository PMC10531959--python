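# Methods

## The problem

A fragment bound weakly to a protein can be located by NMR without assigning
the protein: intermolecular NOEs connect *assigned* ligand protons to
*anonymous* methyl resonances `M_n` of the receptor.  Each NOE becomes a
semi-ambiguous distance restraint — the ligand side of the pair is known,
the protein side is one of the candidate methyl carbons lining the binding
site.  Solving the complex structure then means solving two coupled
problems at once: *which* methyl each `M_n` is (a combinatorial assignment),
and *where* the rigid ligand sits (a 6-degree-of-freedom pose).  The methyl
carbons act as trilateration beacons; with at least three methyl-bearing
residues spread around the pocket, the distance network pins the pose.

## Model and algorithm

**Target function.** A pose is scored by the sum of squared violations of
the distance bounds, plus a soft steric term:

    tf = Σ_r max(0, d_r − upper_r − s, lower_r − s − d_r)²
       + w · Σ_{heavy pairs} max(0, 2.8 Å − d)²          [Å²]

with `d_r` the realized proton-to-methyl-carbon distance, `s` an optional
per-restraint slack (`methyl_slack`) and `w` the clash weight (default 1).
Distances are measured to the methyl *carbon*: anonymous methyl resonances
have no stereospecific proton positions, and carbon-referenced in-silico
distances carry a constant ≈0.7 Å offset relative to proton–proton NOEs,
which cancels from all comparisons made here.

`methyl_slack` defaults to **0**.  A per-restraint slack was considered as a
stand-in for receptor side-chain libration (±20° χ rotations move a methyl
carbon by a few tenths of an Å), but an *independent* ±0.5 Å allowance per
restraint is arithmetically the same as ~±9% distance tolerance and erases
the distinction between exact and 10%-tolerance data; coherent side-chain
motion does not act like independent padding.  Users fitting experimental
data should express uncertainty through the tolerance instead.

**Tolerance.** A fractional tolerance `f` maps a central distance `d` to
the bound pair `(d(1−f), d(1+f))`.  It is multiplicative and symmetric;
there is no absolute-Å padding option.

**Assignment enumeration.** Injective maps `M_n → site` are enumerated
depth-first in lexicographic order, honoring partial-assignment type sets
(MET/ALA/THR identifiable; VAL/LEU/ILE as a group) and same-residue
pairings.  A branch is pruned when two placed labels restrain a common
proton yet their sites are farther apart than the sum of the upper bounds
(or closer than a lower-vs-upper difference) — a triangle-inequality
argument.  Pruning carries a safety margin (default 1 Å plus twice the
slack): a pruned assignment provably has tf ≳ 0.5 Å², so pruning can never
delete a pose able to influence validation at the 0.2 threshold.  When the
entire ranked list collapses to one pose cluster, the benchmark harness
re-runs without pruning so the contrast is measured rather than reported as
the +inf sentinel.

**Pose optimization.** Per assignment the engine runs
1. an *analytic seed*: every proton restrained by ≥3 beacons is located by
   linearized multilateration (least squares on the difference equations of
   the sphere intersections), and the rigid pose is the proper Kabsch fit
   of the conformer onto those estimates;
2. `n_restarts` random restarts of simulated annealing over the 6 rigid
   degrees of freedom (geometric cooling, step sizes shrinking with
   temperature, translations confined to a search sphere around the beacon
   centroid);
3. a trust-region least-squares *polish* of every restart, using an
   active-set clash term (only near-contact atom pairs enter the residual
   vector; the set is re-checked after convergence and the final tf is
   always recomputed with the full clash sum).

The per-assignment random stream is seeded by a stable hash of
(engine seed, assignment), so an assignment is optimized bit-identically
regardless of which other assignments are enumerated next to it — this is
what makes partial-assignment comparisons exact subset comparisons.
Engine defaults are 6 restarts × 400 annealing steps; the benchmark harness
uses 4 × 100, which the analytic seed plus polish makes sufficient at the
library's problem sizes (≈25 restraints, ≤5 sites).  Restart results that
differ from each other by more than 2 Å heavy-atom rmsd are kept as separate
ranked structures (up to 4 per assignment): genuinely ambiguous landscapes
must surface as near-equal-tf alternatives, exactly as an annealing ensemble
would show them.

**Validation.** Structures from all assignments are ranked by tf.  The
target-function contrast (TFC) is `tf(first structure > 2 Å rmsd from the
best) − tf(best)`; the best pose is *validated* when TFC > 0.2.  Pose rmsd
is computed over ligand heavy atoms in the fixed receptor frame without
re-superposition — superposing would erase the binding-mode difference being
measured.  *Success* against a reference pose additionally requires
heavy-atom rmsd < 2 Å and a matching orientation (relative rotation < 90°,
an automated stand-in for visual overlay inspection; an atom-matched rmsd
< 1 Å passes outright because the rotation element of an internally
near-symmetric ligand is ill-defined).

**Topology parameters.** Over the *active* protons (those carrying at least
one restraint), `L_length` is the maximal proton–proton distance, `L_width`
the largest pair component orthogonal to the length vector (ties broken by
the lexicographically smallest proton-id pair), and `r_l = L_length/⟨d⟩`,
`r_w = L_width/⟨d⟩` with `⟨d⟩` the mean central restraint distance before
tolerance.  Empirically, calculations fail mostly when `r_l + r_w < 2`:
short ligands probed through long distances leave too much positional
freedom.  Site diagnostics implement the trilateration picture: suitable =
≥3 methyl-bearing residues and not one-sided (one-sidedness = all methyl
carbons in a closed half-space through the ligand centroid, decided by a
linear-programming membership test of the origin in the convex hull of the
beacon directions); a spread score (min/max singular value of the centered
beacon coordinates) quantifies "evenly distributed" but does not gate
suitability by default, since the half-space test already captures the
failure mode.

## The synthetic benchmark generator

Every test runs on generated ground-truth cases, not downloaded structures.
A case is: methyl beacons placed on a pocket sphere (spread / one-sided /
collinear / two-residue constellations; residue types drawn from the six
methyl types, geminal pairs 2.5 Å apart; at most 5 carbons per site so the
assignment combinatorics stay desk-scale), a rigid ligand whose proton cloud
realizes a prescribed length and width exactly (carbons ≈1 Å inside each
proton plus a central atom — enough skeleton for rmsd and sterics), a random
truth pose near the pocket center, and the restraint network extracted from
the truth geometry (every proton–carbon pair within `max_distance`, labels
shuffled by seed; restraint-free labels dropped).  The truth assignment is
returned separately and never enters the engine's inputs.

The receptor is a minimal heavy-atom point cloud, not a protein: wall atoms
behind each beacon plus a *complementary cavity wall* built from the posed
ligand's support function plus 4.0 Å (2.8 Å van-der-Waals contact + ~1.2 Å
free room, the linear margin implied by a typical pocket/ligand volume
ratio around 2.4), floored at the beacon shell and opened by a ~45° solvent
mouth in a random direction.  This confines a pocket-filling ligand the way
a real groove does while leaving a small fragment its positional freedom in
the same beacon shell.

Beacon directions are strongly jittered (σ ≈ 17°) and radii vary ±15%:
a near-regular constellation (e.g. a clean tetrahedron) is itself a
degenerate, rotation-ambiguous site, and real pockets are irregular.
Likewise the ligand's cross pair is placed off-center and interior protons
fill a 3-D disc — near-centrosymmetric or planar proton clouds carry
spurious symmetries that make the distance network ambiguous for reasons
unrelated to the phenomena under test.

Restraint networks are *complete over the binding-site methyls*: every
(proton, site-carbon) pair becomes a restraint, as in an in-silico
measurement of all site distances.  A per-pair NOE-detectability cutoff is
an experimental-data concern (`max_distance` remains available); the long
restraints matter — they are what makes swapping two beacons detectable
under wide tolerances.

Canned study conditions:

| spec | site | ligand (L × W, protons) | regime |
|---|---|---|---|
| standard | 4 residues, r = 6 Å | 6.5 × 3.2 Å, 7 | mid topology (r_l+r_w ≈ 1.6) |
| high_topology | 5 residues, r = 6 Å | 10.0 × 4.8 Å, 8 | r_l+r_w ≈ 2.2–2.5 |
| low_topology | 4 residues, r = 7 Å | 5.0 × 2.2 Å, 6 | r_l+r_w ≈ 1.0 |
| one_sided | 3 residues in a 40° cap | standard ligand | degenerate |
| two_residue | 2 residues | standard ligand | degenerate |

All cases enforce ≥12 restraints (the working floor for fragment pose
calculations) and regenerate on steric clashes at the truth pose, on
vdW-violating proton–beacon contacts, or (for spread sites) on a
constellation that fails the suitability diagnostics.  A master seed fans
out to per-case seeds through `numpy.random.SeedSequence`, so any case is
re-generable in isolation.

Degenerate-site detection is assessed at 10% restraint tolerance — the
tolerance recommended for experimental data.  At exactly 0% even an
ill-conditioned one-sided beacon cluster pins the pose (exact trilateration
has a unique solution almost surely); the practical failure of such sites is
error amplification orthogonal to the cluster, which needs a finite error
scale to express itself.

**What passing these tests does and does not show.**  The generator
emulates the *information structure* of the real experiment (semi-ambiguous
networks, tolerance, partial assignment, site topology) but not its
chemistry: no real fragment geometries, no spin diffusion, no peak overlap,
no receptor flexibility, and sterics reduced to a point-cloud wall.
Quantitative rates measured here characterize this synthetic ensemble, not
the published protein set; what transfers is the ordering of conditions
(exact > 10% > 20%; with PA > without; above the r_l + r_w boundary >
below; suitable sites ≫ degenerate sites).

## Numerical choices

- Exact in-silico restraints keep `lower = d = upper`; tolerance is applied
  as a separate step so the exact network is always recoverable.
- The NOE build-up converter uses the isolated-spin-pair approximation:
  initial slope by least squares through the origin,
  `d = d_ref (slope_ref/slope)^{1/6}`; pairs with non-positive slope are
  dropped with a warning.  Full relaxation-matrix treatment is out of scope.
- Ties in `L_length` are broken by proton-id order; `L_width` of collinear
  clouds is 0; `length_width` requires ≥2 protons.
- `compute_tfc` returns +inf (validated, with a loud log message) when no
  ranked pose differs by more than the cutoff — a situation real ranked
  lists essentially never produce, flagged rather than silently passed.
- Aggregate statistics exclude infinite TFCs from moments and report their
  count; single-row groups report sd = 0 with a flag.
- Rotations in the hot optimization path use a local Rodrigues conversion;
  poses store proper rotation matrices (det +1) throughout, so improper
  (mirror) candidates are unreachable by construction.

## Known limitations

- The ligand is rigid; internal torsions are not sampled.  Multiple
  conformers can be run independently and ranked together by tf.
- Overlapped methyl peaks (two labels on one site) are rejected, not
  modeled.
- The engine's target function is a violation score, not CYANA's energy
  function; absolute tf values are not comparable across programs, only the
  ranking and contrast logic are.
- `aggregate_report` offers no hypothesis testing; rmsd distributions are
  summarized by mean ± sd only.
- PDB input only (one ligand copy, first model); no mmCIF.
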