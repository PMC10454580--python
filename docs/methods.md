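# Methods

## The 1:1 binding model and what is fitted

A titration challenges a fixed concentration `P` of fluorescently labeled
protein (default 250 nM) with a serially diluted ligand `L`. Mass action for
a single site gives the fraction of protein bound,

    fB(L) = (P + L + K_D − sqrt((P + L + K_D)² − 4 P L)) / (2 P),

evaluated through the conjugate branch `2L / (b + sqrt(b² − 4PL))`,
`b = P + L + K_D`, which is numerically stable when `PL ≪ b²`. The measured
signal is the per-mille normalized fluorescence; the model is affine in fB:

    F_n(L) = F_free + (F_bound − F_free) · fB(L; K_D).

`fit_curve` minimizes the unweighted sum of squared residuals (an
sd-weighted mode exists but the default mirrors common practice of fitting
the replicate averages unweighted). For any trial K_D the two amplitudes
are an ordinary linear least-squares subproblem solved in closed form, so
the search reduces to a one-dimensional profile over log₁₀ K_D: a 161-point
log grid over [10⁻³, 10¹⁰] nM followed by a bounded scalar polish. The
reported `kd_sd` is a symmetric linearized standard error from the numerical
curvature of the profile at the optimum, scaled by the reduced chi-square.
A fit is flagged `saturated` when its predicted value at the top ligand
concentration comes within 5% of the bound-state amplitude — the practical
criterion separating informative K_Ds from runaways.

### ESP confidence intervals

`esp_interval` profiles the objective over K_D (amplitudes re-optimized at
each point) and reports the connected region around the optimum where

    χ²(K_D) ≤ χ²_min · (1 + F_crit(1, n−3; level) / (n−3)),

with `level = 0.683` by default. Boundaries are refined by bisection on
log K_D to 1% relative. If the profile stays below the threshold all the way
to a search limit, that side is unbounded (`Un`): no function minimum can be
localized and the estimate is not trustworthy. The F-based threshold is
exact only for models linear in their parameters, so the package does not
take it on faith: a Monte-Carlo experiment in the test suite (500 simulated
noisy curves) checks that the interval covers the true K_D at 68.3% ± 5%.
A perfect fit (χ²_min = 0, as with noiseless synthetic curves) is floored at
a machine-epsilon scale, which collapses the interval to a point around the
optimum rather than dividing by zero.

## MST zones

A trace is 5 s of pre-laser fluorescence, 30 s of IR heating, 5 s of
recovery, sampled at 10 Hz. Each zone is a Reference/Subject window pair and
`F_n = mean(Subject)/mean(Reference) × 1000`, means taken over samples whose
timestamps fall in the half-open window `[start, start + span)`, without
boundary interpolation. Defaults:

| zone | reference | subject |
|---|---|---|
| TJ | [2.44, 3.44) s | [5.94, 6.44) s |
| TMF_1..TMF_10 | [6.8, 7.8) s | ten 1 s windows, TMF_1 = [9, 10), TMF_10 = [34, 35) |
| InvTJ | [34.0, 35.0) s | [35.94, 36.44) s |
| BdF | [36.5, 37.0) s | [39.5, 40.0) s |

The TJ and TMF anchors are fixed by the experimental protocol being
emulated; the intermediate TMF subject starts are evenly interpolated
between the two printed anchors by default (`scheme="even"`), with a
literal 1-s-gap placement available (`scheme="gapped"`, starts at 9, 11,
…, 27 s). The InvTJ and BdF windows are not pinned by any published
coordinate; the defaults mirror the TJ construction after laser-off (a
0.94 s gap then a 0.5 s subject; a short gap before the BdF reference) and
are configurable. QC flags capillaries whose pre-laser mean lies outside
[300, 2000) counts and fails a series whose pre-laser fluorescence deviates
from the series median by more than 20%.

## The synthetic trace generator

`simulate_trace` produces
`m(t) = F0 · f_TJ(t) · f_TMF(t)` with a fast T-jump quench
`f_TJ = 1 − A_TJ (1 − e^{−Δt/τ_TJ})` and a slow thermophoretic depletion
`f_TMF = 1 − A_T (1 − e^{−Δt/τ_TMF})` during heating; after laser-off both
factors relax back toward 1, the T-jump with τ_TJ (inverse T-jump) and the
depletion with τ_BD ≥ τ_TMF (back diffusion is slower than depletion).
Each amplitude mixes linearly between free and bound values with fB
(fast-exchange, single-population approximation). Gaussian counting noise
is added per sample; every generator is a pure function of its arguments,
with per-capillary/replicate noise streams derived from
`(seed, capillary, replicate)`.

Defaults (chosen once, for realism): baseline 700 counts; T-jump amplitudes
0.05 (free) / 0.08 (bound) with τ_TJ = 0.25 s; thermophoretic amplitudes
0.10 / 0.22 with τ_TMF = 8 s; τ_BD = 12 s; noise sd 7 counts (≈1%). These
give per-mille binding-curve spans of roughly 25 (TJ) to 90 (late TMF),
comparable to typical MST experiments, and pre-laser counts comfortably
inside the QC band. The titration default is 16 capillaries, top ligand
30 µM, dilution factor 3 (span 3¹⁵ ≈ 7 orders of magnitude), 3 replicates.

### A deliberate, quantified inconsistency

Because F_n is a *ratio*, and the TMF/InvTJ/BdF reference windows sit inside
the heating or recovery phases where the signal itself depends on fB, the
zone-level F_n of these traces is a ratio of fB-affine quantities — close
to, but not exactly, the affine 1:1 model being fitted. The resulting K_D
bias is first-order in the trace amplitudes: with the defaults above,
noiseless recovery of a true 500 nM K_D is ≈1% in TJ, ≈4% in the TMF zones,
≈9% in InvTJ and ≈14% in BdF (the weakest zone). This is intrinsic: the
TMF_10 subject window *is* the InvTJ reference window, so no trace model
can make all thirteen zones simultaneously exact for an affine fit.
Shrinking the amplitudes far below realistic values would hide the bias and
was deliberately not done. The fitting machinery itself is exact — on
curves generated directly from the 1:1 model it recovers K_D to ~10⁻⁹
relative — so the residual zone bias measures model consistency of the
generator, not fitting error. Real traces carry the same structural
mismatch, which is one reason zone choice shifts K_D in practice.

What passing the synthetic tests does and does not show: the generator has
no photobleaching, no aggregation artifacts beyond Gaussian noise, no
capillary-scan spatial dimension, and no convection effects; agreement on
it validates the bookkeeping and statistics, not instrument physics.

## FCS

`model_g` is the standard single-species 3D Gaussian-volume autocorrelation;
the structure parameter S is fixed at 5 by default (typical confocal value)
and the beam waist w₀ = 0.2 µm — both must be set deliberately whenever an
absolute diffusion coefficient `D = w₀²/4τ_D` is reported, since neither is
identifiable from a single curve. Fits use bounded Levenberg–Marquardt-type
least squares with data-derived starting values (N from 1/G at short lags,
τ_D from the half-decay lag). Irregular curves are excluded when their
residual RMS exceeds 3× the batch median — a robust stand-in for the manual
rejection of aggregate-distorted curves. The competition model solves
`P_free + ΣL_i P_free/(K_D + P_free) = P_total` by bracketed root-finding
(both oligos share one K_D, since the labeled and unlabeled ligands are the
same sequence); the effective active-protein concentration is left as an
explicit argument rather than assumed.

## Motifs

CRM = `(A/G)GAT(T/C)`, ECRM = `AAGAT(T/C)TT`, scanned on both strands with
overlapping hits all reported; coordinates are 0-based half-open on the
sense strand (BED-compatible). IUPAC ambiguity codes never match. Because
every ECRM contains a CRM core, two counts are exposed: raw CRM hits, and
CRMs not contained in an ECRM (the counting under which the wild-type oligo
reads "three CRMs and one ECRM" despite four core sites). The mutation rule
replaces the invariant GA of each CRM (positions 2–3 in the motif's own
orientation) with CT — equivalently TC → AG on the ATC-bearing strand —
applied iteratively in the rare layouts where an edit juxtaposes a fresh
match, and raising when overlapping hits demand conflicting edits.

## Structures

PDB parsing (model selection, altloc resolution to blank/'A', element
fallback from atom names) is delegated to gemmi behind a flat atom-list
model. Superposition is the least-squares proper rotation over mapped
C-alpha pairs (Kabsch, via scipy's `align_vectors`); the test suite checks
it against an independent Horn quaternion implementation. Complex assembly
transforms a protein onto the protein chain of a reference complex and
borrows the reference's DNA chains unchanged, renaming on chain-id
collision. Contacts use strict `<` at the 4.0 Å threshold ("fell below"),
heavy atoms only (element not H/D, with a name heuristic when the element
column is blank), waters and non-standard HETATM residues excluded by
default. The toy-complex generator places designated contact residues with
minimum heavy-atom distance in [3.0, 3.9] Å and all others at ≥ 5.0 Å, so
recovery is exact by construction.

The experimental structures this component is meant for (an
engrailed-homeodomain–DNA co-crystal as reference complex, a GARP-domain
NMR model as mobile structure) are inputs, not bundled data; the residue
alignment between them is likewise a curated TSV input
(`AlignmentMap.from_tsv`).

## Assay arithmetic

The eGFP-vs-FITC quantification multiplies the 478–492 nm emission sums by
fixed per-fluorophore constants (FITC: window factor 0.33, ε = 76 000,
QY = 0.92; eGFP: 0.25, 56 000, 0.60), exposed as module constants; the
window factors are taken as printed, their physical provenance not being
further specified. Loading normalization sets the weakest GFP signal to 1
after optional background subtraction. Mixing arithmetic is ideal c·V
bookkeeping, which the tests close to 10⁻¹² relative.

## Problem sizes

Defaults keep everything desk-scale: a titration is 48 traces × 400
samples; the ESP coverage experiment uses 500 simulated curves; FCS
ensembles use 100 curves of 120 lags; the full test suite runs in a few
seconds and `scripts/acceptance.py` in under ten.

## Known limitations

* The trace generator's model-consistency bias (above) caps noiseless
  all-zone K_D recovery at the few-percent level in the ratio-normalized
  zones; cross-zone K_D scatter in the output is therefore expected, not a
  bug.
* No kinetics, cooperativity, Hill slopes or multi-site binding; no global
  multi-zone fitting.
* FCS omits triplet photophysics and anomalous diffusion; a one-component
  fit of a genuine mixture returns an intermediate τ_D.
* With 13 zones fitted independently at the 68.3% level, a no-binding or
  non-saturating noisy series occasionally yields one or two spuriously
  bounded intervals; judging an experiment requires the whole table, not a
  single row.
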