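# Methods

This note documents the models and procedures implemented in `xlorg`,
the parameters that matter, the design choices made where conventions
diverge, and what the synthetic benchmarks do and do not demonstrate.

## Cross-link tables

A cross-link identification is a pair of lysine positions, 1-based in
protein sequence space (UniProt convention). Records are canonicalized to
lexicographic endpoint order by (accession, residue), which makes
deduplication and orientation invariance trivial: A:K10–B:K20 and
B:K20–A:K10 are the same connection. Deduplication sums spectral-match
(CSM) counts across collapsed rows and keeps the best score / lowest FDR.

Choices where table dialects vary:

- **FDR filtering is boundary-inclusive** (`fdr ≤ threshold`): reporting
  "at 2% FDR" rarely specifies boundary semantics; inclusive is
  deterministic and matches common practice.
- FDR is stored as a fraction. Percent-valued columns (maximum > 1) can be
  rescaled when the `fdr_percent_autodetect` dialect flag is set; never
  silently.
- Multi-accession endpoint fields (shared peptides) take the first
  accession and are flagged in the table warnings; protein-group-aware
  ambiguity handling is out of scope.

## Structural mapping and the 35 Å restraint

The DSBSO spacer plus two lysine side chains plus in-solution flexibility
makes Cα–Cα distances of up to 35 Å conceivable for a genuine cross-link,
so 35 Å is the default maximum restraint (`max_distance`, configurable).

- **Chain assignment.** Each chain's observed residues are globally
  aligned (free end gaps) to every candidate protein sequence; the chain
  is assigned to the best protein with identity ≥ `min_identity`
  (default 0.9 — tolerant of tags and point mutants, rejecting paralogs).
  The alignment yields the residue-number reconciliation map
  (sequence position → author number); aligned mismatches are mapped,
  gaps are not. No external numbering service is used.
- **Homo-oligomer ambiguity.** A protein owning k chain copies offers k
  placements per endpoint. The mapped distance is the **minimum over all
  admissible copy-pair combinations**, including cross-copy pairings for
  intra-protein links, excluding a residue paired with itself. Minimum is
  the most permissive standard reading: a cross-link only requires some
  pair of copies to be in reach.
- **Agreement denominator.** Links whose protein has no chain
  (`protein_absent`) or whose residues never land on a present Cα
  (`endpoint_missing`) are counted separately and excluded from the
  agreement fraction, which is defined over mapped links only.
- **Satisfaction boundary is inclusive** (d = 35 Å satisfies); the exact
  bound is a measure-zero event on real data but must be deterministic.
- Altlocs: highest-occupancy Cα, ties broken by altloc identifier.
  Residues lacking a Cα are kept but flagged absent. Waters and
  heteroatoms are ignored.
- **Distance histogram**: left-closed right-open bins from 0, default
  width 5 Å; a value on an edge falls in the right bin, so counts always
  sum to the number of mapped links.

### Kabsch superposition

Closed-form least-squares rigid superposition via SVD of the cross-
covariance; the sign of the smallest singular vector is flipped when the
optimal orthogonal transform is improper, so reflections are never
returned. Inputs with fewer than 3 points or collinear geometry are
rejected (the rotation is not unique). With per-coordinate noise σ the
fitted RMSD concentrates just below σ√3 (six rigid degrees of freedom are
absorbed); the tests verify this numerically.

## Docking restraints and model ranking

Cross-links export as unambiguous restraints in the `assign` text dialect:

```
assign (segid A and resid 10 and name CA) (segid C and resid 54 and name CA) 35.0 35.0 0.0
```

i.e. target 35 Å, lower margin 35 (effective lower bound 0), upper margin
0 — "anything up to 35 Å satisfies". Docking engines require one
(chain, residue) per endpoint, so for multi-copy proteins the first chain
in sorted order is pinned and the choice is logged as a warning. The
format round-trips through `parse_restraints`.

Models are scored by evaluating every link with the same min-over-copies
mapper: satisfied count, Σ max(0, d − 35) and the largest single
violation. Ranking sorts by satisfied count (descending), total violation
(ascending), then model id — a reproducible total order; only the leading
model is usually reported, but the full order is deterministic under any
input permutation.

## Interaction network

Only inter-protein unique residue pairs create edges (it is a PPI
network; intra-protein links never form self-loops). Edge weight is the
number of unique residue pairs; CSM totals are carried as an attribute,
not the weight. Nodes are restricted to proteins with surviving edges
(`keep_isolated` reverses this). `min_links` defaults to 1 — no evidence
threshold beyond the upstream FDR filter.

## SILAC enrichment

Per protein and replicate, log2(H/L) is computed from channel
intensities; a replicate with a zero channel is non-computable for that
protein (no pseudocounts, matching disabled re-quantification upstream).
**Median normalization** subtracts the per-replicate median of log2
ratios across proteins, correcting unequal mixing of the two cultures;
the per-replicate median is exactly 0 afterwards.

The significance test is a two-tailed, equal-variance Student's t-test
(not Welch). Two groupings are implemented because the convention
varies between labs:

- `two_group` (default): log10 heavy-channel vs log10 light-channel
  intensities across replicates, df = 2n − 2;
- `one_sample`: replicate log2 ratios against 0, df = n − 1.

P-values are annotated in tiers — red p < 1e−14, orange p < 1e−4,
dark blue p < 0.05, else ns — with strict upper bounds, so the partition
is exhaustive and exclusive. Tiers use raw p-values; a Benjamini–Hochberg
q-value column is emitted for reference but never gates the tiers.
Proteins with fewer than two computable replicates get no p-value and
tier ns, flagged.

**Label swap.** Exchanging which strain is heavy-labelled flips the sign
of genuine enrichment. Concordance is Pearson r between forward log2
ratios and sign-flipped reverse ratios over shared proteins (≥ 3
required), plus the sign-agreement fraction.

## Imaging

- **Background**: rolling-ball subtraction (default radius 50 px,
  configurable; the radius must not exceed the image), clipped at zero.
- **Otsu**: between-class variance maximized over a 256-bin histogram
  scaled to the image min–max; the threshold is the chosen bin center and
  the foreground mask is strictly above it. Constant images have no
  threshold and raise. Note one discreteness consequence: inverting an
  image mirrors the histogram but the split bin changes side, so the
  class complement holds up to pixels within one bin width of the
  threshold.
- **Manders**: the thresholded (plugin-style) variant is the default —
  M1 = Σ A over (mask_A ∧ mask_B) / Σ A over mask_A, M2 symmetric; the
  plain variant (unmasked denominators) is selectable. An empty own-mask
  leaves the coefficient undefined rather than 0.
- **Line profiles**: bilinear interpolation at uniform arc-length samples
  along a polyline; per-channel min–max normalization to [0, 1] within
  the profile (a constant trace maps to zeros).
- **Membrane/cytosol ratio**: mean interpolated intensity along the
  membrane polyline divided by the average of the mean intensities of
  exactly three cytosolic disks; invariant under global intensity
  scaling.
- **Marker regions**: Otsu on the marker channel, connected components
  (8-connectivity in 2-D, 26 in 3-D), minimum size 5 pixels to suppress
  shot noise, per-region mean of the signal channel.
- 3-D stacks are thresholded per volume, not per slice.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of (parameters, seed); the seed drives
named substreams (one per generator) so stages can be regenerated
independently and bit-reproducibly.

- **Complexes** are 3-D random walks with fixed 3.8 Å Cα steps, lysine
  frequency 0.08 (typical yeast proteome frequency), chain starts
  scattered in a 60 Å box; homo-copies are rigid transforms of one
  conformation (they superpose with RMSD 0). Chains may self-intersect —
  acceptable because only pairwise distances matter downstream. Defaults
  (3 proteins × 150 residues) are sized so the satisfying/violating pools
  comfortably cover the planted-link requests across seeds.
- **Cross-link tables** plant satisfying links from lysine pairs at
  min-over-copies distance ≤ 33 Å and violating links beyond 37 Å: the
  2 Å guard bands around the 35 Å restraint keep the planted classes
  unambiguous, so the measured agreement equals the planted fraction
  exactly. Decoys reference accessions absent from the structure and must
  map as `protein_absent`.
- **SILAC tables** use log-normal baselines (log10 intensity ~
  N(6, 0.6)); per-channel log2 noise has SD `noise_sd`/√2 so the log2
  *ratio* noise SD equals `noise_sd` exactly. Enriched proteins carry the
  planted effect on the ratio, sign-flipped in the reverse orientation.
  Defaults (1000 proteins, 100 enriched, effect 2.0, ratio noise 0.25,
  3 replicates) mirror the scale of a typical pull-down experiment.
- **Images**: puncta are Gaussian-blurred impulses of equal amplitude
  (amplitude 200 over background 10, read noise SD 2, i.e. SNR 100 —
  well above the SNR ≥ 10 regime the recovery tolerances assume); equal
  amplitudes make the Manders coefficients equal the planted co-location
  fraction in the noise-free limit. The membrane image is an annulus at
  `enrichment_ratio` × background with mild blur.

Not emulated: realistic spectra or search-engine score distributions,
peptide-level ambiguity, true protein abundance distributions,
correlated replicate structure, realistic microscope PSFs (only
Gaussian), cell-to-cell variability, or segmentation. Passing the
planted-recovery tests therefore demonstrates the correctness of the
computations under known truth — not robustness to every artefact of
real data.

## Problem sizes and numerics

The test suite and the acceptance script run on deliberately small
problems — 3-protein complexes, ≤ 55 links, 1000-protein SILAC tables,
256² images, 20-model rankings — chosen as the smallest sizes at which
the statistical checks (type-I control within 3 binomial SEs, > 95%
power, ±0.05 Manders recovery) are well-powered; everything completes in
seconds. Distances are exact to ~1e−9 Å against the component-wise
formula; Kabsch recovery of planted transforms is exact to 1e−8;
pipeline reproducibility is checked at the SHA-256 level on every output
file, including TIFFs.

## Known limitations

- Chain assignment is per-chain best-hit; it does not jointly optimize an
  assignment across chains, so two near-identical paralogs both present
  in one structure could be assigned to the same accession.
- Solvent-accessible surface distances (SASD) and NZ–NZ variants are not
  implemented; Cα–Cα Euclidean distance only.
- The two-group t-test treats heavy and light channels as independent
  samples; the paired structure of replicates is not modelled.
- Conformational ensembles are out of scope: one structure, one
  distance per link.
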