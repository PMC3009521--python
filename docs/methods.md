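# Methods

## The model

A Protein Energy Network is a complete weighted graph on the amino-acid
residues of one protein.  The weight of the edge between residues *i* and
*j* is the pairwise non-bonded interaction energy

E_ij = ⟨V_LJ(r_ij)⟩ + ⟨V_C(r_ij)⟩,

where each term is a sum over all atom pairs (a ∈ i, b ∈ j):

* Lennard-Jones: V_LJ = 4ε[(σ/r)¹² − (σ/r)⁶], with σ and ε obtained from
  per-atom values via a combining rule (Lorentz-Berthelot by default:
  arithmetic-mean σ, geometric-mean ε; pure geometric available);
* Coulomb: V_C = k·q_a·q_b/(ε_r·r), with k = 138.935485 kJ·mol⁻¹·nm·e⁻²
  and a uniform relative dielectric ε_r (default 1).

Angle brackets denote an arithmetic mean over the frames of a coordinate
ensemble.  Three weight channels are kept: the total E_ij, LJ-only, and
Coulomb-only, so networks can be built from either component alone.

Thresholding produces the unweighted graph PEN_e: edge (i,j) present iff
E_ij ≤ e, the comparison **inclusive** and taken literally in floating
point (no tolerance band; choose grid points that avoid exact ties with
integer-valued synthetic data if that matters).  Because the edge sets are
nested in e, the LCC, hub, clique and community profiles are automatically
non-increasing as e becomes more negative; the cluster count is not
monotone — it rises while the network fragments and falls to zero once all
fragments are smaller than the minimum cluster size.

Statistics follow the conventions of protein structure network analysis:
clusters are connected components counted at size ≥ 3; hubs are nodes of
degree ≥ 4; k-cliques are **all** complete k-subsets (not only maximal
cliques), k = 3 by default; communities are clique-percolation communities
(two k-cliques adjacent iff they share k−1 nodes), a community's size
being the number of distinct nodes it covers.  "High energy" summary
statistics are taken over grid points e < −20 kJ/mol, the
electrostatics-dominated regime; the dispersion-dominated regime lies
above roughly −10 kJ/mol.

## Assumptions and simplifications

* Plain pairwise sums: no periodic boundary conditions, no solvent, no
  Ewald electrostatics, no bonded terms.  The artifact consumes coordinate
  ensembles (or precomputed matrices); generating those ensembles by MD is
  outside its scope.
* Amino acids only: waters, ions and other heteroatoms are dropped when
  reading PDB files; non-standard residue names are skipped with a
  warning.  Protonation-variant names (HSD/HIE/CYX, ...) map to their
  parent residue for parameter lookup.
* Alternate locations: highest-occupancy conformer only, so each frame has
  a single topology.
* Hydrogens are used when present in the input and silently absent
  otherwise; there is no hydrogen reconstruction.  Atoms missing from the
  parameter table contribute zero energy and are tallied in one warning.
* Sequence-adjacent residues in the same chain are excluded from the
  energy matrix by default (configurable).  Their interaction is dominated
  by through-bond geometry and would otherwise thread the backbone into a
  trivially connected chain at every cutoff.  Excluded pairs are zero in
  all channels *and* carry an exclusion flag, so they never form an edge
  even at e = 0, where a bare zero would satisfy ≤ 0.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| cutoff grid | 0 → −35 kJ/mol, step 1 | the empirically observed energy range; grid points are computed as start − i·step (no accumulated drift) and reported to 3 decimals |
| k (clique size) | 3 | clique and community metrics |
| min cluster size | 3 | components below this are not counted as clusters |
| hub degree | 4 | packing-based structure-network convention |
| combining rule | lorentz-berthelot | σ, ε combination |
| relative dielectric | 1.0 | uniform screening of Coulomb term |
| distance cutoff | none | all atom pairs are summed; matrices here are small enough that exactness beats speed |
| high-energy boundary | −20 kJ/mol | start of the electrostatics-dominated regime |

## The force-field table

The bundled table (`penkit/data/forcefield.tsv`) is a self-contained,
deliberately simplified OPLS-like set covering the heavy atoms and polar
hydrogens of the 20 amino acids.  Charges are united-atom style (nonpolar
hydrogens folded into their carbons) and sum exactly to each residue's
formal charge; σ/ε come from a small set of atom classes (aliphatic C,
aromatic C, carbonyl C, N, carbonyl O, hydroxyl O, S, polar H with ε = 0).
It exists so the package works out of the box; it is **not** a validated
force field, and energy matrices computed with it will differ numerically
from any particular MD package's output.  Users with real systems should
supply their own table (same TSV columns) or import externally computed
matrices.

## The synthetic generator

`generate_synthetic_matrix` emulates the empirical shape of protein energy
landscapes with a two-component Gaussian mixture: interacting pairs draw a
weak dispersive energy (mean −5, sd 2 kJ/mol) in the LJ channel; a small
fraction of them (default 0.08) additionally draw a strong electrostatic
energy (mean −27, sd 3 kJ/mol) in the Coulomb channel; most pairs (default
0.85) do not interact at all, mirroring the sparsity of residue contact
networks; planted cliques force chosen node sets' internal pair totals to
a target energy (written to the LJ channel) so recovery is testable.
Defaults: 60 residues, mandatory seed.

What it does **not** emulate: spatial consistency (no underlying 3D
embedding, so triangle inequalities among contacts are not respected),
sequence locality of contacts, correlated fluctuation across an ensemble,
and any relation between the two channels beyond co-occurrence.  Passing
tests on synthetics therefore demonstrate algorithmic correctness and the
qualitative transition behaviour, not biological fidelity on real
proteins.

`generate_toy_ensemble` builds a poly-alanine chain (atoms N, H, CA, CB,
C, O — all parameterized in the bundled table) on an α-helix-like curve
(radius 0.23 nm, rise 0.15 nm, 100°/residue) with independent Gaussian
coordinate jitter per frame.  It exists to exercise the coordinate route
(averaging, invariances, PDB round trips) at desk scale, not to model
peptide mechanics.

## Numerical choices

* Threshold comparison is inclusive (≤) with exact floating-point
  equality, chosen as the simplest deterministic reading of "energy ≤ e".
* Matrices are validated symmetric to 1e-6 kJ/mol and symmetrized on
  read; TSV serialization uses 17 significant digits, so write→read round
  trips are exact to well under 1e-9 kJ/mol.
* total = lj + coulomb is maintained *bitwise* by reconstructing the total
  channel from its components whenever both are present.
* Clique enumeration recurses over sorted node indices (each k-subset
  produced exactly once, lexicographic output order); communities are
  found by union-find keyed on shared (k−1)-subsets, which is equivalent
  to pairwise clique adjacency but linear in the number of cliques times k.
  Components come from an iterative DFS, ordered by smallest member;
  communities are ordered by (size descending, smallest member).
  Determinism of all outputs is part of the contract; the specific
  algorithms are not.
* `transition_width` returns grid points only (no interpolation): the most
  negative cutoff with ≥ 90 % of the profile maximum and the least
  negative with ≤ 10 %.  It is an artifact-defined convenience for
  locating the LCC breakup; profiles that never fall below the lower
  fraction raise a dedicated error.  Peak ties resolve to the least
  negative cutoff.
* Degenerate inputs: an edgeless graph has LCC 1 (singleton components);
  a graph with no k-clique has largest community size 0; an all-zero
  profile has no defined transition.

## Design choices where the design was open

* The comparison report quantifies what a reader takes from overlaid
  profile plots — peak value and position, the LCC transition bracket, and
  the maximum profile value in the high-energy region e < −20 — and emits
  numbers only, never stability verdicts.  "High-energy count" was
  deliberately implemented as the *maximum* over e < −20 rather than a
  sum, matching how "more clusters at high energies" is read off a plot.
* Square-matrix TSVs carry exactly one channel per file; the long-pairs
  layout (the default) carries any subset of channels plus a `# residues:`
  header so isolated residues survive round trips; absent pairs mean zero
  energy.
* k is exposed as a parameter (default 3) for both clique and community
  metrics rather than hard-coded.
* The CLI covers fixture generation (`pen synth`), matrix computation
  (`pen build`), profile sweeps (`pen sweep`), graph export (`pen export`)
  and pair comparison (`pen compare`); all file outputs are deterministic
  text so pipelines are byte-reproducible under fixed seeds.

## Problem sizes

The test suite and the acceptance script run on synthetic matrices of
15–60 residues, random graphs of up to 20–30 nodes (100 seeds for the
oracle-equivalence checks), and toy ensembles of up to 20 residues and 10
frames — sizes at which exhaustive reference oracles (brute-force subset
enumeration, pairwise clique adjacency) are themselves fast, which is what
makes the agreement checks meaningful.  The implementation itself handles
a few hundred residues comfortably; the all-pairs energy sum is O(n²)
in residues and the clique/community metrics depend on graph density.

## Known limitations

* No weighted clique percolation, no centrality measures, no statistical
  testing of profile differences — the comparison is descriptive.
* The energy model is not a substitute for a real force field; no numeric
  agreement with MD-derived matrices is claimed anywhere.
* mmCIF and trajectory formats (XTC/DCD) are not read; convert to
  multi-MODEL PDB or export a TSV matrix instead.
* Cluster-count profiles are sensitive to the minimum-size filter near the
  fragmentation peak; compare like with like.
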