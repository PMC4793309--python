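# pocketfish

Proteome-scale "target fishing" for a small-molecule ligand, driven by local
binding-site similarity rather than global fold similarity.  Given one or more
protein–ligand query complexes, the pipeline

1. extracts the ligand **binding site** — every residue with a heavy atom
   within 5 Å of a ligand heavy atom;
2. searches a structure database for residue combinations whose types are
   BLOSUM62-compatible (score ≥ 1) with the site and whose **contact matrix**
   (pairwise representative-atom distances) matches it, scored by the contact
   matrix average deviation CMAD = meanᵢ<ⱼ |d_q(i,j) − d_c(i,j)| and by the
   Kabsch superposition RMSD, ranked by an empirical P-value with
   E = P × |database| and a significance gate at E < 0.01;
3. transplants the query ligand into each matched site by the match's rigid
   transform and keeps targets passing a steric/contact **docking gate**;
4. ranks surviving targets by end-point free-energy bookkeeping
   ΔG = ΔH − TΔS with ΔH = G_complex − G_receptor − G_ligand and a fixed
   entropic term TΔS = ΔH_ref + RT·ln K calibrated once from an experimental
   binding constant (K = 1.56 × 10⁵ M⁻¹ for acetylsalicylate/phospholipase
   A2: TΔS = −2.327 + 7.055 = 4.728 kcal/mol), keeping ΔG < 0;
5. summarises targets: pocket composition and acetylation-candidate (K/S/T)
   statistics, a structural-similarity network (edges at Cα RMSD < 4 Å), and
   hypergeometric pathway over-representation with Benjamini–Hochberg or
   Bonferroni adjustment from a user-supplied GMT annotation.

Because a curated human structure proteome cannot ship with the code, the
package includes a first-class synthetic-structure module: decoy backbones
with planted, noise-perturbed copies of a query site give every stage a
ground-truth benchmark that runs in seconds.

Audience: structural bioinformaticians studying off-target / polypharmacology
questions, and anyone needing a tested reference implementation of
contact-matrix site search with an honest null model.

## Worked example

```
$ python analysis/01_generate_benchmark.py
query site: 10 residues (KAITHQGSLR) within 5.0 Å
database: 110 structures, 10 planted
wrote PDB fixtures and truth table under results/benchmark/

$ python analysis/02_search_benchmark.py
10 significant hits (E < 0.01) out of 110 structures
sensitivity: 1.00 (10/10 planted recovered)
false positives: 0
top hit: SYN0001  CMAD 0.26 Å  RMSD 0.36 Å  E-value 0.0055
```

The ten structures carrying a planted copy of the query site (0.3 Å
coordinate noise, one BLOSUM62-compatible residue substitution) are all
recovered at E < 0.01 with no false positive among the 100 clean decoys; the
top hit matches the site to 0.36 Å RMSD.

```
$ python analysis/03_run_funnel.py
funnel: 110 structures -> 10 site hits -> 10 docked -> 10 with dG < 0
planted recall: search 1.00, final 1.00; false positives 0

$ python analysis/04_known_targets_table.py
entropy term: TΔS = −2.327 + 7.055 = 4.728 kcal/mol (from K = 1.56e5 M⁻¹ for phospholipase A2)
23 targets with ΔG < 0: 9 primary, 14 new
mean ΔG: primary -15.1, new -18.4 kcal/mol
range: -33.0 (strongest) to -6.0 kcal/mol
```

The funnel counts are monotone by construction (a target must be found, then
dock, then score ΔG < 0).  The reference target table ships with the package:
9 targets belong to families with established acetylsalicylate binding
("primary"); the other 14 are newly proposed, with a comparable mean binding
free energy.  `05_pocket_statistics.py` and `06_network_enrichment.py`
continue with pocket composition/acetylation statistics and the similarity
network + enrichment demonstration.

## Layout

```
src/pocketfish/     library: structures, sites, search, pose, thermo,
                    pockets, network, synth, pipeline
analysis/           numbered narrative drivers writing under results/
tests/              pytest suite with brute-force oracles
scripts/acceptance.py
docs/methods.md     model assumptions, parameters, limitations
```
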