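# flavodesc

Computational toolkit for profiling a flavanol and its circulating human
metabolites as candidate ligands of the G protein-coupled estrogen receptor
(GPER). After oral intake, (-)-epicatechin is converted into glucuronidated,
sulfated, methylated and ring-fission metabolites (E3′G, E3′S, 3′ME5S,
3′ME7S, γVL3′G, γVL3′S); whether these metabolites, rather than the parent
flavanol, carry the receptor-mediated activity is a quantitative question
about their electronic structure, their binding thermodynamics, and the
noncovalent contacts they form. `flavodesc` implements the desk-side half
of that workflow — everything downstream of the quantum-chemistry and
molecular-dynamics engines:

* **Conceptual-DFT reactivity panel** from frontier-orbital energies
  ε<sub>H</sub>, ε<sub>L</sub>: gap, I = −ε<sub>H</sub>, A = −ε<sub>L</sub>,
  μ = (ε<sub>L</sub>+ε<sub>H</sub>)/2, η = (ε<sub>L</sub>−ε<sub>H</sub>)/2,
  S = 1/2η, χ = −μ, ω = μ²/2η, the acceptor/donor powers
  ω⁺ = (I+3A)²/16(I−A), ω⁻ = (3I+A)²/16(I−A), and Δω<sup>±</sup> = ω⁺+ω⁻.
* **PCA chemical-similarity ranking** of metabolites against a reference
  molecule in standardized descriptor space.
* **MMGBSA bookkeeping** under the three-trajectory scheme:
  ΔG<sub>bind</sub> ≈ ΔE<sub>MM</sub> + ΔG<sub>sol</sub> with
  ΔE<sub>MM</sub> = ΔE<sub>internal</sub> + ΔE<sub>ele</sub> + ΔE<sub>vdw</sub>
  and ΔG<sub>sol</sub> = ΔG<sub>GB</sub> + ΔG<sub>SA</sub>, each Δ taken as
  mean(complex) − mean(receptor) − mean(ligand) over per-frame tables.
* **Trajectory post-analysis**: Kabsch superposition, RMSD series, radius
  of gyration, per-atom/per-residue RMSF, and gromos-style neighbor-count
  clustering at an RMSD cutoff.
* **Promolecular NCI analysis**: analytic ρ, ∇ρ and Hessian of a
  sum-of-exponentials promolecular density, reduced density gradient
  s = |∇ρ| / 2(3π²)<sup>1/3</sup>ρ<sup>4/3</sup>, sign(λ₂)ρ classification
  of attractive / van der Waals / repulsive voxels, Gaussian cube export.
* **QSAR**: the molecular descriptors appearing in the published binding
  models (RNCG, walk counts, Broto–Moreau autocorrelations, atom-type
  E-state sums, RDF and TDB 3D descriptors), exhaustive best-subset
  multiple linear regression ranked by adjusted R², and leave-one-out
  Q² = 1 − PRESS/TSS validation. The three published binding-energy models
  ship as built-ins.
* **Synthetic-data generators** for every input kind, with planted ground
  truth, so the full pipeline is testable without any external data.

## Worked example

The packaged fixture table carries the frontier-orbital energies
(kcal/mol) of (-)-epicatechin and its six metabolites.

```python
from flavodesc import OrbitalEnergies, compute_panel, panel_table
from flavodesc import io as fio
from flavodesc.pca import standardize, pca_fit, similarity_rank

p = compute_panel(OrbitalEnergies("EPI", -137.081, -17.724, "kcal_per_mol"))
print(f"gap={p.gap:.3f} mu={p.chemical_potential:.3f} "
      f"eta={p.hardness:.3f} omega={p.electrophilicity:.3f}")
# gap=119.357 mu=-77.402 eta=59.678 omega=50.195

panel = panel_table(fio.load_published_orbitals()).drop(
    columns=["softness", "softness_table"])
scores = pca_fit(standardize(panel), 2).scores
for mol, dist in similarity_rank(scores, "EPI"):
    print(f"{mol:8s} {dist:.3f}")
# E3'G     0.180
# 3'ME7S   0.782
# 3'ME5S   1.396
# gVL3'G   1.486
# E3'S     3.941
# gVL3'S   8.474
```

The gap of 119.357 kcal/mol marks (-)-epicatechin as kinetically stable;
the ranking says the glucuronide E3′G is the metabolite whose electronic
profile is closest to the parent flavanol (score-space distance 0.18),
while the sulfated ring-fission product γVL3′S is the least similar (8.47),
consistent with its strongly shifted HOMO.

The same analyses are available from the shell:

```bash
flavodesc reactivity --in orbitals.tsv --out panel.tsv
flavodesc pca --in panel.tsv --ref EPI
flavodesc mmgbsa --complex c.tsv --receptor r.tsv --ligand l.tsv
flavodesc traj cluster --xyz trajectory.xyz --cutoff 0.1
flavodesc nci --xyz complex.xyz --spacing 0.2 --cube-prefix out/nci
flavodesc qsar fit --in descriptors.csv
flavodesc synth energy_frames --seed 1 --out synth/
```

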