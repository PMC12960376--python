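# Methods

This note documents the models, conventions, and numerical choices behind
ea2struct, and what the synthetic generators do and do not emulate.

## Variant consequence model

Variants are described in HGVS c. notation over a validated transcript
model (CDS a positive multiple of 3, terminal stop, no internal stop, no
ambiguity codes — translation must be deterministic).  The supported
subset is substitutions, deletions, duplications, delins, and intronic
substitutions at donor positions (+1/+2).  Coordinates are 1-based
inclusive throughout; the stop codon belongs to the CDS but is never
counted as a residue.  Minus-strand genes are reverse-complemented at load
time so all downstream code sees transcript-oriented sequence only.

Edits are applied to one copy of the CDS in descending coordinate order,
which keeps upstream coordinates valid and makes cis (compound) variants a
single well-defined edit.  The mutant CDS is translated from position 1
with the standard genetic code up to the first stop; a missing stop is
flagged (`no_stop_found`), not raised, and AA% is then computed on the
sequence up to the mRNA end.

**Splice-donor intron retention.**  For a donor +1/+2 substitution the
modelled product is the CDS prefix through the donor exon's last coding
base, concatenated with the (mutated) downstream intron; translation runs
into the retained intron until its first in-frame stop.  Exon skipping and
cryptic splice sites — real alternative outcomes of donor loss — are out
of scope, so retained-intron products should be read as one representative
scenario, not a prediction of the transcript pool.

**Consequence classification** diffs mutant against wild-type protein:
identical → synonymous; equal length → missense; clean prefix → stopgain;
prefix+suffix match → in-frame indel (deletions are 3'-normalized per HGVS
before naming); diverging tail → frameshift.  A truncated protein whose
tail still matches wild-type in frame (cis missense + stopgain) is
classified by the terminating event.  The frameshift convention
`p.XposYfs*N` counts the new stop as codon N of the shifted frame with the
first changed residue as codon 1, so the predicted length is
`pos + N − 2`; stopgain `p.Xpos*` gives `pos − 1`.  This is the unique
convention consistent with the per-variant AA% values the package
reproduces (e.g. p.A1837Pfs\*22 → 1857 residues → 82.1%, not 82.2%).

**AA%** is `100 · L_variant / L_wildtype` (wild type: 2261 residues for
CaV2.1).  Display values round half-up to one decimal — so the
single-residue deletion 2260/2261 prints 100.0 — but every statistic is
computed on the unrounded fraction.  This matters: the display rounding
creates spurious rank ties (four patients at "82.1") that visibly distort
Spearman correlations.

## NMD classification

A premature termination codon (PTC: stopgain, frameshift, or
retained-intron stop) is predicted to trigger nonsense-mediated decay
unless one of the canonical escape rules fires, checked in this order:
intronless transcript; PTC in the last exon; PTC within 50 nt (inclusive)
upstream of the last exon–exon junction; PTC within the first 100
(inclusive) coding bases.  The PTC position is the first base of the new
stop codon in variant-transcript coordinates: indels shift downstream
junctions by their net length, and a retained intron merges its two
flanking exons.  Consequences without a PTC (missense, in-frame) are
reported "unlikely" with rule `not_applicable`.

The 50-nt rule is deliberately implemented as distance from the *last*
junction (the boundary of the penultimate exon), the standard reading of
the rule; for PTCs inside the penultimate exon the alternative phrasings
coincide.

## Structure metrics

Models are Cα traces read with gemmi from mmCIF or PDB; per-residue pLDDT
is taken from the isotropic-B field of the Cα atom (the AlphaFold
convention), first altloc only, first chain unless specified.

**TM-score.**  TM = (1/L_norm) Σ_aligned 1/(1 + (dᵢ/d₀)²), with
L_norm = the wild-type residue count and
d₀ = max(0.5, 1.24·(L_norm−15)^⅓ − 1.8) Å.  Normalizing by the wild-type
length makes the score interpretable as "fraction of the wild-type
structure preserved": a noiseless truncation keeping fraction *f* scores
exactly *f*, and 1.0 requires every wild-type residue matched at zero
distance.

Residue correspondence is by sequence, not structural search: variant
models derive from the wild-type sequence, so the map is the longest
common prefix, extended by suffix matching across in-frame indels;
frameshift novel tails have no correspondence and contribute zero.  The
superposition maximizing TM is searched from seed fragments (sliding
windows of lengths L, L/2, L/4, half-window stride), each refined by
iterating {superpose on inliers; recompute distances; new inliers = pairs
closer than a cutoff} with the cutoff shrinking linearly from d₀ to d₀/2
over 8 iterations and a minimum inlier set of 4; TM is always scored on
all pairs under the candidate superposition, and ties between seeds break
by larger aligned count, then lower aligned RMSD.  Kabsch superposition
itself (proper rotation, det +1) is delegated to
`scipy.spatial.transform.Rotation.align_vectors`, with the RMSD
recomputed from residuals (the library's internal residual accumulates
~1e−7 cancellation noise at zero).

**Confidence.**  Mean pLDDT is the arithmetic mean (2 decimals); LCR% is
the percentage of residues with pLDDT strictly below 50.

## Cohort statistics

- **Correlations**: Pearson for TM-score (with Fisher-z 95% CI and the
  exact t test), Spearman (mean ranks on ties, t approximation) for AA%.
  The Pearson/Spearman assignment is fixed rather than driven by a
  normality test, so results are deterministic.  All ten correlation
  p-values (2 predictors × 5 indices) form a single Benjamini–Hochberg
  FDR family; the mixed-model table pools its twenty p-values the same
  way.
- **Summaries**: mean ± SD with divisor *n* (population form) — a
  deliberate compatibility choice matching the reference summary values
  (divisor n−1 would print 12.7 instead of 12.2 for FSIQ).
- **VIF** for the two predictors: 1/(1−r²), 2 decimals.

**Linear mixed model.**  y = Xβ + u_group + ε with a scalar random
intercept per family.  The variance ratio λ = σ²_family/σ²_residual is
profiled: at each λ the GLS solution is closed-form via per-group
Woodbury identities (O(n·p²) in the cohort size), and log λ is optimized
by bounded scalar minimization; a boundary fit (λ = 0) is preferred
whenever it matches the interior optimum to numerical tolerance, which
also covers the all-singleton-groups case where the likelihood is flat in
λ and the slope reduces exactly to OLS.

The default estimation is **ML** with **Satterthwaite** degrees of
freedom for t-based p-values and 95% CIs; REML is available
(`method="reml"`).  ML-plus-Satterthwaite is the convention under which
the packaged cohort's mixed-model table reproduces its reference values;
it was validated during development against lme4/lmerTest on the same
data (slopes to ≤0.05, Satterthwaite df to ≤0.1, interval bounds to
≤0.15), and the REML path is cross-checked against statsmodels MixedLM in
the test suite.  Satterthwaite df are computed as
2·f(η)² / (∇f · 2H⁻¹ · ∇f), where f(η) is the coefficient variance and H
the deviance Hessian in η = (θ, σ) — θ the family/residual SD ratio and σ
the residual SD.  That parameterization is the load-bearing choice: the
deviance is smooth and *even* in θ, so the σ²_family = 0 boundary needs
no one-sided differencing (and correctly yields df ≈ n there, because the
coefficient variance is locally insensitive to θ at 0).  In the
mixed-model table AA% enters as a fraction (0–1), the scale on which its
slope is comparable to TM-score's.

## Synthetic data: what it shows and what it does not

- **Gene generator**: a 5-exon toy gene (50 nt 5'UTR, 600 nt CDS = 199
  residues + stop, 100 nt 3'UTR, GT…AG introns) with designed codons at
  fixed positions so that one variant of every class — missense, stopgain
  (start-proximal, mid-transcript, near-junction, last-exon), frameshift
  duplication, in-frame deletion, donor+1 retention — has a hand-derivable
  p. notation, length, AA%, and NMD verdict.  Catalog expectations are
  computed inside the generator with its own codon table and rule
  arithmetic, independent of the engine under test.  Donor introns carry a
  designed in-frame TAA (one intron is cut mid-codon after "TA" so the
  retained frame stops immediately).  The random codons are redrawn (up to
  50 deterministic attempts per seed) until the duplication's shifted
  frame terminates inside the CDS.
- **Structure generator**: jittered ideal helices (rise 1.5 Å, ~100°/res,
  radius 2.3 Å → ≈3.8 Å Cα spacing; jitter SD 0.15 Å), truncated,
  rigidly moved, and/or perturbed with isotropic Gaussian noise.  The
  truncation TM-score is exact by construction; noise gives an upper
  bound.  These decoys validate the scoring machinery — they carry no
  fold, no contact topology, and no AlphaFold-like error structure, so
  passing tests certify the metric, not the realism of any predicted
  model.
- **Cohort generator**: outcome = intercept + slope·U(0,1) predictor +
  N(0, σ_family) per family + N(0, σ_residual); a target marginal
  correlation rescales the two noise SDs jointly (target 0 zeroes the
  slope instead).  Used for parameter-recovery checks (e.g. mean slope
  over 1000 simulated 13-patient cohorts within 2% of truth).

All generators are deterministic per seed, and generated GenBank/mmCIF
files round-trip exactly through the package's own readers.

## Problem sizes and runtime

The test suite and the reproduction script are sized for interactive use:
structure decoys of 40–120 residues (the brute-force TM oracle —
dense seed windows plus a coarse SO(3) grid with Kabsch polish — runs on
40-residue pairs), cohort simulations of 13×1000 and 2000×1 observations,
and the 13-patient fixture for all published-value checks.  The whole
suite completes in well under a minute; `scripts/acceptance.py` in
seconds.

## Known limitations

- Donor-site retention is the only splice outcome modelled.
- Structure correspondence assumes variant models share the wild-type
  sequence frame; unrelated structures would need a structural aligner.
- The NMD rules are transcript-geometric only; no expression data.
- LMM p-values/CIs use the Satterthwaite t approximation; with 13
  patients they are approximations, and the per-variant structural
  metrics for real patients depend on externally supplied model files.
- The splice-variant protein length in the packaged cohort (1736
  residues) is the value consistent with its published truncation ratio;
  the underlying reference intron sequence is not bundled.
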