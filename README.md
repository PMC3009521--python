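# penkit — Protein Energy Networks

`penkit` builds and analyses **Protein Energy Networks (PENs)**: complete
weighted graphs over a protein's residues in which the weight of the edge
between residues *i* and *j* is their ensemble-averaged non-bonded
interaction energy

    E_ij = ⟨ V_LJ(r_ij) + V_C(r_ij) ⟩   (kJ/mol)

summed over atom pairs (12-6 Lennard-Jones plus Coulomb) and averaged over
a coordinate ensemble.  Thresholding at a cutoff *e* gives the unweighted
graph **PEN_e** with adjacency

    A_ij = 1  iff  E_ij ≤ e   (i ≠ j)

so a more negative *e* keeps only the stronger attractive contacts.  By
convention *low energy* means small negative magnitude (−5 kJ/mol,
dispersion-dominated contacts) and *high energy* large negative magnitude
(−25 kJ/mol, salt bridges).  Separate LJ-only and Coulomb-only channels
(E_ij = V_LJ or E_ij = V_C) are carried alongside the total.

Sweeping *e* over a grid (default 0 → −35 kJ/mol, step 1) and evaluating
network statistics at each cutoff produces the profiles used to compare
homologous proteins — typically a thermophile against its mesophilic
partner:

* **LCC** — size of the largest connected component (the transition
  profile: the network is coherent at low energies and breaks up across a
  transition region);
* **clusters** — number of connected components of size ≥ 3;
* **hubs** — number of nodes of degree ≥ 4;
* **cliques** — number of *k*-cliques (complete *k*-node subgraphs,
  k(k−1)/2 internal edges; default k = 3);
* **largest community** — clique percolation: two *k*-cliques are adjacent
  iff they share k−1 nodes, a community is a maximal chain of adjacent
  *k*-cliques, and its size is the number of distinct nodes it covers.

The package is aimed at structural bioinformaticians who have coordinate
ensembles (multi-MODEL PDB files) or precomputed residue-pair energy
matrices and want reproducible, scriptable network profiles instead of
one-off analyses.  Energies computed by `penkit` itself use a bundled,
deliberately simplified OPLS-like parameter table; for production
energetics, import matrices computed by your MD package as TSV.

## Worked example

Compare two synthetic 60-residue energy landscapes — a denser, deeper
"thermophile-like" one and a sparser "mesophile-like" one (the generator
emulates the empirical regimes: an LJ mode near −5 kJ/mol and an
electrostatic mode near −27 kJ/mol):

```sh
pen synth matrix --n 60 --seed 1 --background 0.80 --elec-fraction 0.12 --out thermo.tsv
pen synth matrix --n 60 --seed 2 --out meso.tsv
for M in lcc clusters hubs cliques largest_community; do
  pen sweep --matrix thermo.tsv --metric $M --out profiles_a/$M.tsv
  pen sweep --matrix meso.tsv  --metric $M --out profiles_b/$M.tsv
done
pen compare --a profiles_a --b profiles_b --label-a thermo --label-b meso --out report.tsv
```

`report.tsv` then contains (excerpt):

```
metric    statistic          a    b    a_minus_b
clusters  peak_e            -29  -9   -20
clusters  peak_value         6    4    2
clusters  high_energy_peak   6    4    2
hubs      high_energy_peak   2    0    2
lcc       high_energy_peak   21   9    12
lcc       transition_e_hi   -6   -6    0
lcc       transition_e_lo   -31  -30  -1
```

Reading it: both networks hold together down to −6 kJ/mol (`transition_e_hi`,
the most negative cutoff at which the LCC still has ≥ 90 % of its maximum
size).  The denser landscape fragments into more clusters (peak 6 vs 4),
its cluster peak sits at a much more negative cutoff (−29 vs −9), and it
retains more structure in the high-energy region e < −20 kJ/mol (LCC of 21
vs 9, 2 hubs vs 0).  The report states numbers only; whether that pattern
means "more thermostable" is up to you.

The coordinate route works the same way, starting from a PDB ensemble:

```sh
pen synth ensemble --n 12 --frames 5 --seed 3 --out toy.pdb   # or your own PDB
pen build --structure toy.pdb --out matrix.tsv
pen sweep --matrix matrix.tsv --metric lcc --grid 0:-8:0.5 --out lcc.tsv
pen export --matrix matrix.tsv -e -2 --format graphml --out pen_m2.graphml
```

Everything is also available as a library (`penkit.compute_energy_matrix`,
`penkit.build_pen`, `penkit.threshold`, `penkit.sweep`,
`penkit.compare_pair`, ...); the CLI is a thin wrapper.

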