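# Methods

This note records the models, defaults and numerical choices behind
`solstab`, and what the synthetic-data tests do and do not establish.

## PSSM and the mutation-space filters

Enrichment at column *i* for residue *a* is the log-likelihood ratio

    LL(i,a) = ln[ (n(i,a) + κ·b(a)) / (N_i + κ) / b(a) ]

with counts *n* over the mapped alignment rows, gaps excluded from the
column total *N_i*. Defaults: pseudocount κ = 1 distributed by the
background frequencies, uniform background b(a) = 1/20, no sequence
weighting (redundancy filtering is assumed to have happened upstream, e.g.
via the aligner's identity/diversity options; a weighting hook can be added
where counts are tallied). Natural log — every downstream decision is a
sign test (`LL > 0`, `ΔLL > 0`, `LL(wt) < 0`), so the base is inert.
Non-canonical letters in homologue rows are counted as gaps; in the query
they are an error.

Two consequences of the uniform background worth knowing:

- A wild type can be the *minority* residue in its column yet not be
  flagged: flagging requires its frequency to fall below 1/20, not below
  the majority residue's.
- A column containing each residue once scores exactly 0 everywhere.

The "strong" filter (default) admits a substitution only when it is both
absolutely enriched (LL > 0) and better than the wild type (ΔLL > 0); the
looser "enriched-only" mode drops the second condition and always yields a
superset. C, M and N are excluded as substitution targets by default
(chemical liabilities), configurable.

## Solvent exposure

Shrake–Rupley SASA, probe 1.4 Å, 960 sphere points per atom, hydrogens
discarded; relative exposure = SASA / theoretical residue maximum
(Tien-style Gly-X-Gly values, shipped as `data/max_sasa.tsv`,
substitutable), clipped to [0, 1].

**Orientation canonicalization.** A fixed sphere-point set is not
rotation-invariant, so before sampling, coordinates are moved to the
principal-axis frame of the atom cloud, axis signs fixed by the third
moment along each axis. Any rigid motion of the input then lands in the
same frame and SASA is reproducible to ~1e-9 relative. Limitation: for
structures with (near-)degenerate principal moments or vanishing third
moments — highly symmetric artificial geometries — the frame is arbitrary
among the degenerate choices and invariance degrades to the usual
point-sampling scatter (≲1 %). Real protein chains are generically
asymmetric.

Unresolved residues (SEQRES entries without coordinates) are excluded from
exposure and from candidate sites, with a warning. All user-facing
positions are 1-based SEQRES indices; author numbering appears only in the
numbering map.

## Solubility profiles

The packaged propensity scale (`composite-v1`) is sign-inverted
Kyte–Doolittle hydropathy plus a +1.0 bonus for D/E/K/R, re-centred to zero
mean. It is a *surrogate*: it reproduces the orderings the pipeline needs
(charged ≫ polar ≫ hydrophobic) but no published method's absolute scores,
and every output labels its provenance. Loading recentres any user scale
and enforces two invariants: zero mean, and all of D/E/K/R strictly above
all of V/I/L/F/W.

Smoothing window 7 (odd, shrinking at the termini); global score
S = mean(p), so ΔS is length-independent. ΔS for a point mutation is
computed by patching only the window means that overlap the site into a
copy of the profile and re-averaging — bit-identical to recomputing the
mutant profile, by construction (both paths share one window-summation
routine).

Structural correction:
q_i = exposure_i · Σ_{j∈N(i)∪{i}} p_j e^(−d_ij/λ) / Σ e^(−d_ij/λ), with
neighbours at Cα–Cα ≤ 10 Å and λ = 4 Å (both configurable, declared in the
report metadata). As the cutoff shrinks, q_i → p_i·exposure_i; full burial
(exposure 0) zeroes the term.

## ΔΔG handling

Positive ΔΔG = destabilizing. Replicate predictions (e.g. three runs of an
external predictor per mutation) are parsed from CSV/TSV (a tolerant mode
skips banner lines in `Dif_*.fxout`-style files); the decision statistic is
the replicate mean, the sample sd (ddof = 1, zero for a single replicate)
is carried for reporting. The built-in surrogate
ΔΔG = Δh·(2b − 0.25(1−b)) (Δh = normalized hydropathy loss, b = burial) is
deterministic, flagged `surrogate=true`, and exists so the pipeline can be
exercised without a physics predictor — it has no predictive accuracy and
its only guaranteed properties are: identity mutations give 0, and burying
a hydrophobicity loss costs more than exposing it.

## The design funnel

Site gate (all three required): relative exposure ≥ 0.15; not excluded by
the user; conservation-flagged (`LL(wt) < 0`) **or** q in the lowest 30 %
band. Sites are ordered by ascending q (worst first). The user exclusion
list defaults to empty — conservation alone usually protects functional
sites, but supplying the active site explicitly is recommended when known;
testing single mutants before combining them catches the residual risk of
a depleted-but-functional position.

Shortlist gate: ΔS > 0 and mean ΔΔG < 0 (threshold configurable). Missing
ΔΔG entries are reported as "not evaluated", never silently dropped.

Ranking: `w_sol·z(ΔS) − w_stab·z(ΔΔG)` with z-scores within the candidate
set (population sd; a constant column maps to z = 0), weights (1, 1), ties
broken by (site, substitute). Assembly is greedy in rank order, one
mutation per site, optional minimum sequence separation, budget 9 by
default; alternates force the best not-yet-used candidate first and fill
greedily; duplicates are removed; a model must have combined ΔS > 0,
recomputed on the full multi-mutant sequence so overlapping smoothing
windows interact correctly. The ranking formula and the forced-first
alternate scheme are this package's own choices — published pipelines of
this type do not specify theirs. The budget is configurable because
descriptions of comparable pipelines disagree between 9 and 12; models may
carry fewer mutations than the budget. Everything is deterministic:
identical inputs give byte-identical reports.

Paired mutations (e.g. two adjacent prolines tested jointly) are
represented as two independent candidates; grouping them is a user-level
decision, not pipeline logic.

## PEG-precipitation fitting

Normalization divides every well by the *mean* of the 0 %-PEG wells.
Fit: decreasing 3-parameter logistic on well-level fractions,
initialization a = 1, k = 1, PEG₁/₂ = the concentration whose mean fraction
is nearest 0.5; Levenberg–Marquardt least squares (maxfev 10 000). A fit is
*flagged* (not an exception) when the optimizer fails, k ≤ 0, or PEG₁/₂
leaves [0, max conc + 10] — beyond that it is extrapolation.

Bootstrap CI95: wells resampled with replacement within each
concentration, refit, percentile 2.5/97.5 over the successful refits;
failed refits are dropped and counted, > 20 % failures is an error; an
explicit seed is mandatory and makes the interval reproducible.

**Known limitation — undercoverage with quadruplicates.** Resampling only
4 wells per concentration shrinks the empirical spread
(E[σ̂] ≈ 0.80 σ at n = 4), so the percentile CI95 is systematically narrow:
in simulations at noise sd 0.05 it covers the generating PEG₁/₂ in ~82–88 %
of plates, not 95 %. The acceptance suite asserts a 90–99 % band and that
check fails, deliberately documenting the calibration gap of the percentile
method at this replicate count rather than hiding it. With ≥ 8 replicates
per concentration coverage approaches nominal; a BCa or bootstrap-t
interval would also repair it but is not the method implemented here.

## Synthetic data

Generators are seed-deterministic, write real files (FASTA/A3M/PDB/CSV) and
emit truth sidecars. The MSA generator draws homologue columns i.i.d. from
stated compositions (default: match the query w.p. 0.7) and records exact
tallies — no phylogeny, no indel process beyond decorative A3M insertions.
Structure presets are geometric toys (extended chain; Fibonacci-sphere
cages for burial) with backbone-ish atom clouds — valid PDB, not valid
stereochemistry. PEG plates are logistic truth + i.i.d. Gaussian noise at
the assay's plate layout (0–30 % in 2 % steps, quadruplicate), defaults
PEG₁/₂ = 9.4 % w/v (a typical wild-type enzyme value), k = 1, a = 1,
sd = 0.05. Green tests on these worlds establish algorithmic correctness
(oracle equivalence, contracts, determinism, calibration where attainable)
— they say nothing about predictive accuracy on real proteins, which
depends on the propensity scale, the alignment quality and the ΔΔG
predictor supplied by the user.
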