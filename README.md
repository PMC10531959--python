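# nmr2dock

Protein–fragment pose calculation from semi-ambiguous NMR methyl distance
restraints.

In fragment-based drug discovery, the structure of a weakly bound
protein–fragment complex is usually solved by X-ray crystallography — which
often fails for weak binders.  NMR offers an alternative that skips the
slow protein assignment step entirely: intermolecular NOEs connect
*assigned ligand protons* to *anonymous protein methyl groups* `M_n`.  Each
cross peak becomes a **semi-ambiguous distance restraint** — the ligand side
is known, the protein side is one of the methyl carbons lining the binding
site.  `nmr2dock` solves the two coupled unknowns:

1. **Assignment** — which binding-site methyl each anonymous label `M_n`
   belongs to (an injective combinatorial map, restricted by any partial
   assignment: MET/ALA/THR identified by type, VAL/LEU/ILE as a group,
   same-residue methyl pairs);
2. **Pose** — the rigid-body placement of the ligand, optimized per
   assignment against the distance bounds and ranked by a violation target
   function

       tf = Σ max(0, d − upper, lower − d)²  +  clash penalty     [Å²]

The best-ranked pose is **validated** by its *target-function contrast*
(TFC): the tf gap to the first ranked pose that differs by more than 2 Å
heavy-atom rmsd.  TFC > 0.2 means the restraint network singles out one
binding mode; TFC ≈ 0 means several poses fit equally well and the result
is ambiguous.  Ligand **topology parameters** `r_l = L_length/⟨d⟩` and
`r_w = L_width/⟨d⟩` (proton-cloud length/width over the mean restraint
distance, computed on restraint-active protons) predict convergence:
calculations mostly fail when `r_l + r_w < 2`.

The package includes structure I/O (PDB), restraint extraction and
anonymization, tolerance and partial-assignment handling, NOE build-up →
distance conversion (isolated-spin-pair approximation), the
assignment/pose engine, TFC validation and benchmark reporting, and a
seeded synthetic-case generator so the entire pipeline is testable without
downloading structures.  See `docs/methods.md` for the model and its
assumptions.

## Worked example

```python
from nmr2dock.bench import Condition, engine_config, run_case
from nmr2dock.synthetic import STANDARD_SPEC, make_case

# one synthetic ground-truth complex: 4 methyl residues around a pocket,
# a 6.5 x 3.2 A fragment, ~25 exact restraints
case = make_case(STANDARD_SPEC["site"], STANDARD_SPEC["ligand"],
                 max_distance=STANDARD_SPEC["max_distance"], seed=42)

row, result = run_case(case, Condition(tolerance=0.0, partial_assignment=False),
                       engine_config(seed=1))
print(f"TFC = {row.tfc:.2f}, rmsd to truth = {row.rmsd:.2f} A, "
      f"success = {row.success}, r_l + r_w = {row.r_l + row.r_w:.2f}")
```

prints

```
TFC = 9.12, rmsd to truth = 0.00 A, success = True, r_l + r_w = 1.67
```

With exact distances the true assignment reaches tf = 0, every wrong
assignment scores far worse (TFC 9.1 ≫ 0.2), and the top pose reproduces
the ground truth.  Re-running with `Condition(0.10, False)` widens every
bound by ±10% and shrinks the contrast; `Condition(0.10, True)` adds the
partial assignment and restores it — the central trade-off the benchmark
quantifies.

The same pipeline is available from the shell:

```bash
nmr2dock synth --n 5 --seed 7 --out-dir lib          # generate cases
nmr2dock extract lib/case000-standard/complex.pdb --ligand LIG --out-dir ex
nmr2dock run --restraints ex/restraints.tsv --methyls ex/methyls.json \
             --ligand lib/case000-standard/ligand.pdb --seed 1
nmr2dock bench --n 10 --seed 3 --out-dir bench       # five-condition matrix
```

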