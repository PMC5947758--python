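# Methods

## Scope and model

`mrprep` covers the preparation side of molecular replacement: from scored
sequence-search hits and homologue coordinates to edited, superposed,
variance-truncated search models with per-member coordinate-error
annotations, plus copy-number estimation and triage of externally produced
MR/refinement/tracing scores. It does not run a sequence search or any MR,
refinement or density-modification program; score tables are consumed as
data.

## Sequence handling

The database preprocessor strips terminal polyhistidine purification tags,
read conservatively as a run of ≥ 4 consecutive H at either terminus, and
discards sequences shorter than ten residues — both steps exist to stop
short or tag-dominated entries flooding the hit list. Redundancy reduction
offers the levels 100/95/90/70/50 %: pairs above the level are single-linkage
clustered (transitive closure), and each cluster is represented by the entry
with the numerically smallest resolution, then the lowest R value, then the
first id. Pairwise identity uses a global alignment with match +1,
mismatch 0, gap open −10, gap extend −0.5 and free end gaps, with the
shorter sequence as denominator so fragments collapse onto their parents.
The score cutoff separating homologues from noise is 20, applied
inclusively (a hit scoring exactly 20 is kept).

Hits are grouped into numbered "domains" from their footprint on the target:
midpoint = round half-up of (first + last aligned position)/2, extent =
last − first + 1. Clustering is greedy and *seed-relative*: the
highest-scoring unassigned hit seeds a cluster and collects every unassigned
hit within ±10 residues of its midpoint and ±25 of its extent. Measuring to
the seed rather than chaining keeps the partition deterministic and
order-independent; ties in score break by id.

## Model editing

All protocols first renumber the homologue into target numbering through the
pairwise alignment (i-th chain residue ↔ i-th ungapped hit-row position);
insertions relative to the target are deleted, original numbering is kept in
`source_number`. The Cγ-mixed protocol keeps every atom of residues aligned
to an identical target residue and prunes the rest to N, CA, C, O, CB plus
the single γ-position atom of the homologue type (OG for Ser, OG1 for Thr,
SG for Cys, CG1 for Ile/Val, CG otherwise; Gly/Ala have none). Pruned
residues keep their homologue name — no renaming, no fabricated atoms — with
the target residue type recorded as an annotation. Polyalanine keeps
backbone + Cβ (no Cβ invented for glycine) and renames to ALA. Editing never
moves a coordinate or touches a B factor.

## Superposition and variance

Rigid fits use the Kabsch least-squares solution (SVD of the covariance with
reflection correction); degenerate inputs (< 3 points, collinear sets) are
rejected. A family is brought into a common frame by iterating: fit every
member's original coordinates onto the current centroid over the *core*
(positions holding a CA in every member), recompute the centroid as the
per-position mean, stop when the largest centroid shift is below 1e-6 Å or
after 100 passes. The frame is anchored on the first member, so results are
reproducible and order differences only amount to a global rigid motion.
Structural correspondence comes from the shared target numbering produced by
editing, standing in for a sequence-independent structural aligner, which is
out of scope here.

The per-position variance is the population mean (divisor n) of squared CA
deviations from the centroid, in Å²; each member's r.m.s.d. over the core is
reported alongside. These satisfy the exact decomposition
n·Σ_j var_j = Σ_i |core|·rmsd_i², which the tests assert.

## Truncation ladder

Derived ensembles keep, at level p, the `ceil(p/100 × |core|)` positions of
lowest variance — ceiling so that, e.g., 10 % of a 184-residue core retains
19 positions — with variance ties broken by ascending residue number, which
makes the levels nested. The default 5 % step gives 20 derived ensembles;
the base (untruncated) ensemble additionally keeps residues outside the
common core and is displayed as "110 %" in interactive tools, here labelled
`base`. Member r.m.s.d. annotations at each level are recomputed after
re-fitting the member onto the centroid restricted to the retained
positions, so the annotation describes the coordinates actually written.
Levels with fewer than three retained positions cannot determine a rotation
and fall back to centroid translation only.

A starting coordinate-error estimate for MR likelihood calibration comes
from sequence identity as σ = 0.4·exp(1.87·(1 − id)) Å — 0.40 Å at full
identity, ≈ 1.6 Å at 25 % — with both constants exposed as parameters.

## Copy number and triage

The Matthews coefficient is Vm = V_cell/(Z·M_asu) with the solvent fraction
1 − 1.23/Vm; V_cell uses the full triclinic volume formula. Candidate copy
numbers are scanned while solvent ≥ 0.25 and the count with solvent closest
to 0.50 wins (ties to the larger count); if even one copy leaves < 25 %
solvent the estimate is one copy with a warning. The default mean residue
mass is 110 Da; an exact sequence mass (average residue masses plus one
water) is used when a sequence is supplied. The resolution-dependent
probability refinement of the Matthews prior is deliberately not modelled.

Triage bands refined solutions by R_free: GOOD strictly below 0.35,
MARGINAL up to and including 0.5, POOR above, UNKNOWN when absent — the
boundary value 0.5 is assigned to MARGINAL, a choice the band definitions
leave open. Flags: LLG ≥ 60 (inclusive, "an increase of 60" being the
success criterion), TF/σ strictly > 8, trace success = CC strictly > 25 %
together with mean chain length ≥ 10 residues. The summary table sorts by
ascending R_free with absent values last in input order.

## Synthetic fixtures

The generator emulates the statistical structure the method exploits, not
protein physics. Targets are meanders of ideal α-helical segments (rise
1.5 Å, radius 2.3 Å, 100°/residue) joined by planar 3.8 Å-step arc turns:
consecutive Cα distances are 3.80–3.83 Å and the chain is self-avoiding by
construction; N, C, O and Cβ are placed by idealized local frames around the
trace. Families displace each residue rigidly (all atoms share the
displacement, keeping editing valid) by isotropic Gaussian noise in two
tiers: a conserved core at 0.2 Å and one contiguous mobile region at 2.0 Å
covering half the chain by default — an even split chosen so both tiers
carry enough positions for rank-based recovery statistics to be meaningful.
Sequences mutate at exactly `round((1 − identity)·n)` positions (never into
glycine, so Cβ inventories stay consistent). Optional random rigid motions
exercise the superposition. Hit-table/MSA generators lay out multi-domain
footprints with small within-tolerance jitter.

What passing tests on these fixtures show: the estimator recovers injected
variance structure, truncation preferentially retains low-noise positions,
and the bookkeeping (counts, nesting, annotations, formats) is exact. What
they cannot show: behaviour under real insertion/deletion variation between
homologues, correlated (non-isotropic) coordinate error, or MR success —
ensembles here never meet diffraction data.

## Numerical choices and limitations

- Kabsch degeneracy threshold: second singular value < 1e-8 of the largest.
- Centroid iteration: shift < 1e-6 Å, cap 100 iterations (typically < 10).
- Alt-loc resolution on PDB read: highest occupancy, ties to the
  alphabetically first conformer; HETATM, waters and hydrogens dropped.
- Stockholm '.' and '-' both read as gaps, normalized to '-'; FASTA wrapped
  at 60 columns and uppercased, so writers are byte-deterministic.
- Per-member r.m.s.d. decreases with truncation level in the mean, and no
  truncated level exceeds a member's 100 % value; strict per-member
  monotonicity between adjacent levels does not hold inside a flat-noise
  tier (ordering there is estimation noise) and is not claimed.
- Problem sizes in the tests and the acceptance script (10-member,
  200-residue families; 50-hit clustering; 1000-rep Monte Carlo) were chosen
  as the smallest sets where the statistical assertions are stable.
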