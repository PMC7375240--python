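# Methods

## Scope and model

`cyslock` treats covalent ligand discovery at a nucleophilic cysteine
as four loosely coupled problems: (i) find and characterize the pocket
states a trajectory visits, (ii) establish that the anchor cysteine is
family-specific, (iii) dock a library of Michael acceptors covalently
tethered to the cysteine Sγ, and (iv) verify a covalent adduct from
mass-spectrometric and NMR evidence. Everything operates at desk
scale on plain-text formats (PDB, SMILES/SDF, aligned FASTA, TSV,
JSON); multi-model PDB doubles as the trajectory container, so no
binary trajectory readers are needed.

## Covalent docking

**Chemistry.** Five Michael-acceptor warhead classes are packaged as
SMARTS patterns (acrylamide, acrylate ester, enone, vinyl sulfone,
vinyl sulfonate); each requires a terminal CH2=CH– conjugated to the
electron-withdrawing group, with the β-carbon as the site of thiol
attack. The in-silico Michael addition reduces the C=C to C–C, adds a
hydrogen at the α-carbon and opens a single bond at the β-carbon for
the sulfur link. Because no leaving group departs, the protein mass
increases by the monoisotopic mass of the intact parent compound; this
identity (checked to 1e-6 Da against the formula-mass code) is what
ties the docking chemistry to the MS validation.

**Geometry.** Ligands are heavy-atom graphs; internal geometry comes
from a seeded ETKDG distance-geometry embedding (with an MMFF clean-up)
and is then frozen — only torsions move. The adduct's placeholder
sulfur is superposed exactly onto the pocket Sγ, the Sγ–Cβ bond is set
to 1.81 Å (a standard C–S single bond; configurable) and pointed anti
to the cysteine's own Sγ–CB bond as a tetrahedral-like start. All
scanned torsions start at 0°.

**Search.** The pose search is an exhaustive grid: every rotatable
bond (single, acyclic, both ends non-terminal; amide C–N held planar;
the Sγ–Cβ anchor bond always included and always first) takes values
{0°, inc, 2·inc, …}. The default increment of 30° (12 states per bond)
puts a typical 2–4-bond electrophile at 10²–10⁴ poses, enumerated in
lexicographic order over a breadth-first bond ordering and truncated
at a cap (default 10,000) so truncation is reproducible. Conformers
with non-bonded intramolecular contacts under 1.2 Å (1-4 pairs and
beyond; 1-2/1-3 are fixed by the frozen internal geometry) are pruned
before scoring. The receptor is rigid; no pose minimization is done —
an intentionally simple, fully deterministic search.

**Scoring.** Each pose is scored against the pocket atoms only (no
intra-ligand term): Coulomb electrostatics with the constant
332.0637 kcal·Å·mol⁻¹·e⁻² and a distance-independent dielectric ε = 4
(a common buried-pocket compromise), plus Lennard-Jones 6-12 in the
4ε[(σ/r)¹² − (σ/r)⁶] convention with Lorentz–Berthelot combining, both
cut off at 12 Å. The anchor Sγ and CB are excluded from the sums
(covalently bonded neighbors). Repulsion at short range makes clashed
poses strongly positive and favorable contacts negative, so ranking on
the per-compound minimum total needs no separate clash term. Term
weights (default 1/1), dielectric and cutoff are config knobs because
no published values exist for the original program.

**Parameters.** Protein atoms use a packaged united-atom table
(heavy atoms only, charges folded from implicit hydrogens, per-residue
sums equal to formal charges; σ/ε by element class). Ligand charges
are Gasteiger–Marsili PEOE — deterministic and dependency-free — with
implicit-hydrogen charges folded into heavy atoms for consistency;
ligand σ/ε are element-based. These choices make *absolute* energies
non-comparable to all-atom force fields; rankings within a run, which
is all the screen uses, are well defined. Total pocket charge is
reported at parameterization time as a sanity check.

**Selection.** Compounds are ranked by ascending best total (ties by
compound id) and the top ceil(fraction · n_scored) are selected;
fraction defaults to 0.10. ceil keeps small libraries non-empty and is
exact at the canonical 120-compound scale (12 selected). Compounds
without a warhead are reported but excluded from ranking; per-compound
failures never abort a screen. The whole dock path contains no random
number source, so identical inputs give byte-identical output tables.

## Trajectory clustering

Frames are evenly thinned (indices round(i·(M−1)/(K−1)), first and
last always kept), reduced to Cα coordinates, and compared by
least-squares-superposed RMSD (Kabsch fit via
`scipy.spatial.transform.Rotation.align_vectors`, proper rotation
enforced; the residual is recomputed after applying the rotation
because the solver's reported value loses ~8 digits to cancellation on
near-identical frames). Clustering is k-medoids on the full RMSD
matrix with deterministic initialization — most-central frame first,
then farthest-point — followed by PAM-style alternation. Deterministic
seeding was chosen over random restarts because it guarantees one
medoid per state whenever states are separated by more than the
within-state spread, which is exactly the regime the synthetic
trajectories construct (separation ≥ 10× noise); the `seed` argument
is accepted for API uniformity but does not influence the result.
Clusters are reported in descending occupancy with medoid frames as
representatives.

## Conservation screen

The alignment column holding the reference's Nth ungapped residue is
located by walking the reference row, then read down all rows. The
packaged family snippet uses the real RhoA 99–118 fragment; the other
rows are synthetic stand-ins for the Ras/Rab/Ran/Arf families
(labelled as such in the file) that preserve the biological point
being tested — only the Rho row carries a cysteine at that column.

## Adduct validation

Formula masses sum pyteomics' IUPAC atomic masses over Hill-notation
formulas (monoisotopic or average). Digestion cleaves C-terminal to
K/R except before P, with configurable missed cleavages; peptides
carry 1-based parent coordinates so a modification site can be located
(the packaged 193-residue human RhoA sequence yields the 14-mer
HFCPNVPIILVGNK spanning Cys107). Mass-shift matching converts a ppm
tolerance to Da on the *peptide* mass (instrument error scales with
m/z, not with the shift) and ranks candidate formulas by absolute
error.

CSP analysis combines amide shift changes as
Δδ = sqrt(Δδ_H² + (w·Δδ_N)²) with w = 0.2, the most common ¹⁵N
scaling (the threshold 0.05 ppm is standard; the weight is a knob
because conventions vary, e.g. 1/5 vs 0.14). A residue is perturbed
iff Δδ exceeds the threshold *strictly* or its peak is attenuated —
operationalized as a bound/apo intensity ratio below 0.2 or outright
absence from the bound list, since "disappeared" has no universal
numeric criterion. Perturbed residues are summarized as maximal runs
of consecutive residue numbers.

## Synthetic data

The generators mirror the shapes of a realistic campaign while running
in seconds: a toy pocket (anchor CYS with N/CA/CB/SG, Sγ at the
origin, 7 residue stubs 4–7.4 Å away with a ~70° cone left open along
the attachment direction), a 120-compound library (5 warhead cores ×
aliphatic/aromatic tails, warhead fraction configurable, one
electrophile per molecule), multi-state Cα trajectories (independent
3.8 Å-step random walks per state, amplified until every state pair
clears the requested superposed-RMSD separation, default 5 Å against
0.3 Å Gaussian noise) and apo/bound peak-list pairs whose engineered
CSP is exact by construction (0.8/0.6 split of the magnitude between
the ¹H and weighted ¹⁵N components).

What passing tests show — and what they do not: the pipelines are
algorithmically correct on inputs whose ground truth is known by
construction. The toy pocket is not a protein fold, the library is not
a vendor catalog, and trajectory states are not conformational
ensembles; no test here validates chemical accuracy of scores against
binding data, only the internal consistency, determinism and stated
selection behavior of the method.

## Numerical choices and degenerate inputs

* Coulomb/LJ sums are vectorized; a naive double-loop oracle agrees to
  1e-8 kcal/mol on random systems. r = 0 raises rather than returning
  infinities.
* Torsion rotations use Rodrigues' formula; bond lengths and
  anchor-side atom positions are preserved to 1e-9 Å, and enumeration
  is bit-for-bit reproducible.
* Score ties resolve to the lowest conformer index; ranking ties to
  the lexicographically smaller compound id; cluster-size ties to the
  smaller medoid index.
* PDB parsing keeps altloc 'A'/blank and drops others, rejects
  insertion codes, requires consistent models, and names the offending
  line in parse errors. Coordinates round-trip at the format's 0.001 Å.
* Pockets are atom-wise distance cuts (no whole-residue inclusion);
  radius defaults to 10 Å around Sγ, enough to cover a groove-sized
  site without engulfing a nucleotide pocket.

## Known limitations

* United-atom protein parameters and PEOE ligand charges are a
  pragmatic, redistributable substitute for commercial preparation
  tools; absolute energies differ from programs built on those tools.
* The receptor is rigid (no cysteine χ sampling, no induced fit);
  covalent chemistry is limited to Michael additions.
* No solvation, hydrogen-bond, strain or entropy terms; scores are a
  ranking device, not affinities.
* The conservation fixture's non-reference rows are synthetic;
  conclusions about real family selectivity require a real alignment.
* k-medoids with deterministic seeding can be suboptimal on poorly
  separated, highly anisotropic state distributions; it is exact in
  the well-separated regime it is used for here.
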