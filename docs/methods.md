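# Methods

## Binding-site model

A binding site is the ordered set of residues whose minimum heavy-atom
distance to any ligand heavy atom is at most the extraction cutoff
(default 5.0 Å, the conventional contact-shell definition).  Hydrogens are
ignored throughout: crystal structures mostly lack them, and the synthetic
structures never carry them.  Each site residue is represented by one atom —
Cα by default, Cβ selectable — and the site is summarised by its contact
matrix, the symmetric matrix of pairwise representative-atom distances.  The
contact matrix is invariant under rigid motion, which is what makes it a
sound basis for comparing local structure across unrelated folds.

## Site search

For each database structure the engine enumerates residue combinations that
could correspond to the query site:

* **Type compatibility.**  A target residue may stand in for query residue
  *q* when BLOSUM62(q, t) ≥ 1.  A residue's own type is always admitted, even
  under a cutoff that would exclude it (relevant only for pathological
  cutoffs); non-standard codes map to X and admit all twenty types with a
  warning.
* **Geometry.**  Candidates are generated anchor-first: the query residue
  pair with the largest separation (the most discriminating distance — wide
  pairs are rarest in a compact fold) seeds the search with target pairs
  matching that distance within `pair_tol` (default 2.0 Å); remaining query
  residues are added one at a time, cheapest-compatibility first, pruning any
  partial mapping whose worst pair deviation exceeds `pair_tol`.  Enumeration
  is capped at `max_candidates` (default 50 000) with a truncation flag;
  on small instances the output is proven against exhaustive enumeration.
* **Scoring.**  Complete mappings are filtered at CMAD < 1.5 Å (CMAD is the
  mean absolute deviation between corresponding off-diagonal contact-matrix
  entries), then superposed onto the query by the Kabsch algorithm
  (closed-form SVD solution, reflection-corrected to a proper rotation), and
  the best (lowest-RMSD) mapping per structure is retained — one candidate
  match per protein.

### Statistical calibration

The published analytic form of an RMSD-based P-value for this family of
search tools is not available, so significance is calibrated empirically:
random type-compatible residue combinations are drawn from an independent
decoy set (uniform over structures, then uniform injective assignment), their
Kabsch RMSD to the query recorded, and a hit's P-value is the add-one
empirical tail (1 + #{null ≤ RMSD}) / (n + 1).  E-value = P × database size,
significance at E < 0.01 (the classical database-search convention; the
alternative "× candidate count" convention was considered and rejected as
non-standard).  With add-one smoothing the smallest achievable P is
1/(n + 1), so resolving E < 0.01 against a database of ~100 structures needs
n ≳ 11 000 null samples; the benchmark default is 20 000, which costs a few
seconds.  The null is seeded and fully deterministic.

## Docking gate

The pose stage deliberately does not re-implement a simulated-annealing
docking engine.  The contract preserved is binary: a target either accepts
the ligand or is removed.  The query ligand is transplanted into the matched
site by the match's rigid transform, then screened: protein heavy atoms
closer than `clash_dist` (2.2 Å) to any ligand atom count as clashes, atoms
within `contact_dist` (4.5 Å) as contacts, and the pose passes iff clashes ≤
0 and contacts ≥ 3.  The defaults were chosen so that transplanting a query
ligand back onto its own complex always passes while a ligand atom placed on
a Cα always fails.  Hydrogen bonds are detected by a distance-only N/O
criterion (≤ 3.5 Å); an angular term would require hydrogens.  The original
docking protocol's 10 Å search sphere has no analogue in a transplant
scheme; this divergence is intentional and recorded here.

## Free-energy bookkeeping

ΔH = G_complex − G_receptor − G_ligand is exact bookkeeping over whatever
scorer supplies the three terms.  The shipped scorer is a desk-scale pair
potential: a single-type 12-6 Lennard-Jones (well depth 0.15 kcal/mol,
minimum 3.8 Å) plus distance-dependent-dielectric Coulomb (ε(r) = 4r) over
ligand–protein heavy-atom pairs within 8 Å, with element-typed point charges
(O −0.40, N +0.35, S −0.10, C 0).  The Lennard-Jones distance is clamped at
3.2 Å (soft core): transplanted poses are rigid and never minimised, so
sub-van-der-Waals contacts reflect unrelaxed geometry, and steric rejection
is the gate's job, not the scorer's.  Full Poisson–Boltzmann solvation and
normal-mode entropy are out of scope; receptor and ligand internal energies
are set to zero so ΔH equals the interaction sum.

The entropic term is not computed per target.  Entropy changes for one
ligand binding different receptors are similar, so TΔS is calibrated once
from an experimental binding constant via −RT·ln K = ΔG = ΔH − TΔS, giving
TΔS = ΔH + RT·ln K.  For the acetylsalicylate/phospholipase A2 reference
(K = 1.56 × 10⁵ M⁻¹), ΔH = −2.327 kcal/mol and RT·ln K = 7.055 kcal/mol give
the fixed TΔS = 4.728 kcal/mol applied to every target.  Note the quoted
RT·ln K corresponds to T ≈ 297 K; at the package default T = 298.15 K
(R = 1.9872041 × 10⁻³ kcal mol⁻¹ K⁻¹) the product is 7.085, so
`entropy_from_constant` accepts an explicit `rt_ln_k` override to reproduce
the published calibration exactly.  The final filter keeps ΔG < 0 strictly;
ΔG = 0 is rejected.  Raising the fixed TΔS lowers every ΔG and can only
grow the filtered set — the property suite asserts this direction.

## Database construction

Redundancy removal follows the CD-HIT contract without reproducing its word
filter: greedy incremental clustering in descending sequence-length order,
joining a structure to the first representative with global identity ≥ the
cutoff (0.95 for a non-redundant proteome).  Identity is computed by
Needleman–Wunsch with match +1 / mismatch 0 / gap −1, traceback ties broken
diagonal > up > left for determinism, normalised by the shorter sequence
length (the CD-HIT denominator).  Whole-chain concatenated sequences are
clustered; per-chain clustering would be a caller-side variation.

## Similarity network and enrichment

Whole-chain structural similarity uses sequence-guided superposition: global
BLOSUM62 alignment (gap −5), Kabsch RMSD over aligned Cα pairs, an edge
whenever RMSD < 4 Å (strict).  This stands in for combinatorial-extension
structure alignment and is adequate for related conformers; for genuinely
homolog-free pairs a sequence-independent aligner would be required, a known
limitation.  Pathway enrichment is the hypergeometric upper tail
P(X ≥ k | N, K, n) per pathway, with N the user-supplied background, n the
targets mapping into it (also the percentage denominator), adjusted by
Benjamini–Hochberg (default, matching the usual reporting convention) or
Bonferroni, significance at adjusted p < 0.01.  No web annotation service is
called; the annotation is a local GMT file.

## Synthetic structures

The generator exists to give every stage a ground-truth benchmark:

* **Decoys** are self-avoiding Cα random walks (step 3.8 Å, non-adjacent
  pairs ≥ 4.0 Å, bounded retries) of 80 residues by default, with uniform
  residue types.  Each residue carries deterministic stub atoms — Cβ at
  1.5 Å along a local frame, plus backbone-like N and O stubs — so the
  steric gate and the polar-contact detector have atoms to act on.
* **Query complexes** place a fixed-topology 13-heavy-atom, four-oxygen
  planar ligand inside a jittered shell of 20 pocket residues at Cα radius
  8.2 Å (side chains pointing inward, ligand–protein clearance ≈ 3.1–3.6 Å,
  i.e. van-der-Waals contact) with a self-avoiding tail outside; extracted
  sites fall in the 10–26-residue range observed for real drug pockets.
* **Planting** replaces a surface cluster of decoy residues (nearest
  neighbours of the residue farthest from the centroid) with the site's
  representative coordinates plus per-coordinate Gaussian noise, rigidly
  re-posed so the pocket opening faces outward, with a chosen number of
  BLOSUM62-compatible residue substitutions (positions lacking any
  compatible neighbour, e.g. cysteine, are not substitutable and are skipped
  with a warning).  Because a planted pocket must be an actual pocket, any
  unplanted residue whose Cα would intrude into the re-posed ligand volume
  is displaced out of it.
* **Benchmarks** mix planted and clean decoys in seeded shuffled order with
  opaque identifiers and a ground-truth table.

Every generator is a pure function of its seed; all randomness flows through
explicitly passed NumPy generators.

What the synthetic data does *not* emulate: real secondary structure,
rotamers, side-chain chemistry beyond stub atoms, crystallographic noise
models, or sequence composition biases.  Passing benchmarks therefore
demonstrate the correctness and calibration of the machinery (geometry,
statistics, bookkeeping, determinism), not the discovery performance on the
human structural proteome, which depends on database coverage and real
docking energetics.  In particular the synthetic pockets form few polar
contacts, so the hydrogen-bond fraction statistic is exercised but small.

## Problem sizes and numerics

Default analysis sizes — 10 planted among 100 decoys of 80 residues, 20 000
null samples, 25 calibration decoys — keep a full benchmark-plus-funnel run
around ten seconds on one core while leaving the E < 0.01 gate resolvable.
Tolerances: rigid transforms orthogonal to 1e-8; contact matrices symmetric
to 1e-6; bookkeeping identities exact to 1e-9; degenerate rank-0 point sets
are rejected by the superposition, collinear sets are allowed.  Candidate
mappings are emitted in lexicographic target-index order, ranked hits by
(E-value, RMSD, id), making every table reproducible byte-for-byte from the
configuration hash and seed.

## Known limitations

The pose gate cannot reproduce the attrition behaviour of a
simulated-annealing docking engine, only its pass/fail contract; the scorer
is a demonstration potential, not MM-PBSA; the sequence-guided RMSD network
under-links homolog-free structural twins; enrichment p-values depend
entirely on the annotation supplied.  These boundaries are deliberate: the
contribution implemented here is the site-similarity search with its
empirical calibration and the surrounding, fully-tested funnel bookkeeping.
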