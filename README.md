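# cyslock

Cysteine-anchored covalent virtual screening, and the desk-side
validation that goes with it.

Rho-family GTPases such as RhoA are molecular switches with no deep,
druggable pocket in their ground state — but RhoA carries a surface
cysteine (Cys107) found nowhere else in the Ras superfamily, next to a
cryptic groove that opens transiently in solution. `cyslock` implements
the computational workflow for exploiting such a site with covalent
Michael-acceptor ligands:

* **Pocket discovery** — cluster MD trajectory frames (multi-model PDB)
  on superposed Cα RMSD with k-medoids; report cluster occupancies and
  medoid (representative) structures.
* **Selectivity check** — map a reference residue onto a family
  alignment column and ask which homologs share it.
* **Covalent docking** — detect Michael-acceptor warheads (acrylamide,
  enone, acrylate ester, vinyl sulfone, vinyl sulfonate), apply the
  Michael addition in silico, tether the ligand to the cysteine Sγ, and
  *exhaustively* enumerate poses by stepping every rotatable torsion on
  a fixed grid.
* **Scoring and selection** — rank compounds by the best pose score

  E = w_es · Σ 332.0637 qᵢqⱼ/(ε rᵢⱼ) + w_vdw · Σ 4ε̄ᵢⱼ[(σ̄ᵢⱼ/rᵢⱼ)¹² − (σ̄ᵢⱼ/rᵢⱼ)⁶]

  (clashes positive, favorable contacts negative) and keep the top
  fraction (default 10%) for assay.
* **Adduct validation** — monoisotopic/average formula masses, in-silico
  tryptic digestion (cleave after K/R, not before P), mass-shift
  matching at ppm tolerance, and chemical-shift-perturbation analysis
  Δδ = √(Δδ_H² + (0.2 Δδ_N)²) with the standard 0.05 ppm significance
  threshold and attenuated-peak handling.

A `fixtures` module generates every input the test suite needs (toy
pockets, electrophile libraries, two-state trajectories, perturbed peak
lists) deterministically from a seed, so nothing is downloaded.

## Worked example

```python
from cyslock import fixtures, structures, screen, modcheck

pdb = fixtures.make_toy_pocket(seed=1)
struct = structures.read_structure(pdb)
anchor = structures.find_anchor(struct, "A", 107)
pocket = structures.parameterize(structures.extract_pocket(struct, anchor))

library = fixtures.make_ligand_library(seed=1, n=120, warhead_fraction=1.0)
cfg = screen.ScreenConfig(increment_deg=30.0, cap=1000, fraction=0.10)
result = screen.run_screen(library, pocket, cfg)
print(result.n_scored, len(result.selected), result.selected[:3])

print(modcheck.formula_mass("C12H10SO4"))
peps = modcheck.tryptic_digest(modcheck.rhoa_sequence())
print([p.sequence for p in peps if p.contains(107)])
```

prints

```
120 12 ['L0034', 'L0101', 'L0063']
250.02997979894
['HFCPNVPIILVGNK']
```

All 120 compounds dock (each through its single warhead, a few hundred
to a thousand conformers per compound), the 10% rule keeps exactly 12,
the C12H10SO4 adduct weighs +250.0299 Da, and trypsin releases the
14-residue peptide that carries Cys107 — the peptide on which that mass
shift would be observed.

The same operations are available from the shell:

```bash
cyslock screen --receptor pocket.pdb --anchor A:107 --library lib.smi --out results.tsv
cyslock mass C12H10SO4
cyslock cluster --trajectory traj.pdb --k 10
cyslock csp --apo apo.tsv --bound bound.tsv
```

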