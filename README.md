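# pkfunnel

A toolkit for deep-learning + physics **virtual-screening funnels** against a
protein target with a known binding pocket — the workflow used to triage very
large compound libraries down to a handful of candidates worth testing at the
bench. It was built around screening campaigns against DNA-PKcs (the catalytic
subunit of DNA-dependent protein kinase, a DNA-damage-response drug target),
but every stage is generic.

The funnel stages, each a library module:

1. **Pocket & ligand graphs** (`pkfunnel.graphs`) — the binding pocket is the
   set of protein residues with a heavy atom within a cutoff (0.6–1.0 nm,
   stage-dependent) of the reference ligand's heavy atoms. Pocket residues
   become graph nodes with 30-dimensional embeddings (sums of chemical-group
   vectors); residue pairs in contact (min heavy-atom distance ≤ 0.5 nm)
   become edges. Ligands are parsed from SMILES into heavy-atom graphs with
   one-hot-like features (element, degree, H-count, charge, aromaticity).
2. **GCN scoring heads** (`pkfunnel.scoring`) — two graph-convolutional
   models over (pocket graph, ligand graph) pairs: **BC**, a binder/non-binder
   classifier with output in [0, 1], and **RG**, an affinity regressor on the
   pKa scale, where

   *pKa = −log₁₀ Kₓ*,  Kₓ a molar IC₅₀, Kᵢ or K_d  (pKa 9 ↔ 1 nM).

3. **Threshold funnel** (`pkfunnel.funnel`) — conjunction of inclusive
   cutoffs over a candidate score table: BC ≥ 0.99, RG ≥ 9.0, docking energy
   ≤ −7 kcal/mol by default. Docking scores are ingested from CSV, never
   computed here.
4. **MD triage** (`pkfunnel.mdstats`) — ligand RMSD series, per-entity RMSF,
   geometric hydrogen-bond counts (D–A ≤ 0.35 nm, D–H–A ≥ 150°), and the
   smooth coordination-number collective variable
   s(r) = (1 − (r/r₀)ⁿ)/(1 − (r/r₀)ᵐ).
5. **Metadynamics free-energy analysis** (`pkfunnel.metad_fes`) — reconstruct
   F(s) = −Σₖ hₖ exp(−(s−cₖ)²/2σₖ²) from hill depositions (well-tempered
   rescaling when a bias factor is present), detect basins, and apply the
   acceptance rule: a candidate passes when its **global free-energy minimum
   sits at a coordination number above a threshold** — the bound state is the
   most stable state.

A deterministic fixtures module (`pkfunnel.fixtures`) generates toy
complexes, score tables, breathing trajectories and hills files with exact
ground-truth sidecars, so the full pipeline runs and tests with no external
downloads.

## Worked example

The packaged reference table `pkfunnel/data/table1.csv` holds the 19
candidates of a deep-learning + docking screening stage. Apply the funnel and
rank by docking energy:

```python
from pkfunnel import load_reference_table, apply_funnel, FunnelConfig
from pkfunnel.funnel import rank_candidates

records = load_reference_table()
survivors = apply_funnel(records, FunnelConfig(bc_min=0.99, rg_min=9.0, docking_max=-7.0))
print(len(records), "candidates,", len(survivors), "survive")
best = rank_candidates(survivors, key="docking")[0]
print("best docking:", best.compound_id, best.docking, "kcal/mol")
print("RG range:", min(r.rg for r in records), "-", max(r.rg for r in records))
```

prints

```
19 candidates, 19 survive
best docking: L102-0385 -8.4419 kcal/mol
RG range: 9.0076 - 9.4493
```

i.e. every candidate in that stage table passes the stated cutoffs (the table
*is* the survivor set of that stage), the strongest docking pose is
L102-0385 at −8.4419 kcal/mol, and all predicted affinities sit just above
the 1 nM-equivalent pKa 9 cutoff.

The same workflow from a shell:

```sh
pkfunnel funnel src/pkfunnel/data/table1.csv --bc-min 0.99 --rg-min 9 --dock-max -7
pkfunnel fixtures make-hills --seed 1 -o fx/ && pkfunnel fes fx/hills.dat --grid -1:4:400
```

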