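# Methods

This note documents the models, numerical conventions and design choices
behind the package, in the order the pipeline runs.

## Viability simulator

The synthetic landscape assigns each drug a Hill monotherapy curve with
maximal fractional inhibition emax ∈ [0,1], slope h > 0 and midpoint ec50
(µM).  Random panels draw emax ~ U(0.55, 0.95), h ~ U(0.8, 2.5) and ec50
log-uniform on [0.5, 5] µM — the sub-µM-to-10-µM potency window typical of
kinase-inhibitor panels.  For a dose vector d the fractional effect is
f_i = emax_i·d^h/(d^h + ec50^h); the combination viability is the Bliss
product Π(1 − f_i) times an interaction factor exp(−Σ_{i<j} γ_ij f_i f_j).
The sign convention makes γ > 0 synergistic (viability below the Bliss
product), so a planted γ is recoverable as a negative fitted interaction
coefficient.  The factor acts on fractional effects, which keeps it inert
whenever either drug is absent and bounded for realistic γ.

Hormesis (low-dose growth stimulation) is a subtractive bump
s_i·(d/ec50)·exp(1 − d/ec50) on f_i, peaking at d = ec50 and vanishing at
zero dose.  Deterministic viability is clipped to [0, 1], except that the
upper clip is 1.2 when any hormesis amplitude is positive — a hormetic
well must be able to read above the untreated control or flagging it from
noise-free data would be impossible.  Assay read-outs add Gaussian noise
(default sd 0.05, the replicate scatter typical of metabolic-activity
plates) truncated to [0, 1.2].

The reference *recovery scenario* used by the seeded studies fixes, once:
10 drugs, three actives (emax = 0.9) mutually synergistic with γ = +2 on
all three pairs, seven weak drugs with emax ~ U(0.25, 0.45), noise sd
0.05, triplicate assays.  At IC20-anchored doses an active contributes
f ≈ 0.18 and a weak drug f ≈ 0.07, so single-drug activity and pairwise
synergy must both be read out of ~0.1-scale viability differences — a
deliberately non-trivial signal-to-noise regime.

## Phosphoproteome simulator

Latent kinase activities a_k (log-uniform over a 10-fold range by default)
drive Poisson spectral counts: a kinase's own phosphopeptides have mean
α·a_k·multiplicity (α = 2 counts per activity unit), each mapped substrate
site has mean β·a_k (β = 1), summed over kinases sharing the site.  Each
kinase carries three peptides, one inside its activation loop, and four
substrate relations with randomly assigned PSP/NWK/both evidence.  The
generator emulates count sparsity, replicate dispersion and shared
substrate sites; it does not emulate peptide-identification bias, missing
values from data-dependent acquisition, or serine/threonine signalling, so
passing tests demonstrate score correctness and rank recovery under
Poisson sampling, not robustness to real acquisition artefacts.

## Calibration

Monotherapy curves are fitted as viability (not inhibition):
v(d) = top − emax·d^h/(d^h + ec50^h), bounded least squares (emax ≤ 1.5,
h ∈ [0.05, 8], ec50 within 20× of the tested dose range) with a
multi-start over h ∈ {0.5, 1, 2, 4} × ec50 at the 25/50/75% dose
quantiles; best residual sum of squares wins, ties by smaller slope.
Responses with no variation yield a flat fit flagged non-informative.  The
effective dose is the closed form ED_p = ec50·(p/(1−p))^(1/h); the IC20
anchor uses p = 0.2.  Hormesis is detected (mean viability at any nonzero
dose exceeding the control mean by > 0.05), never modelled; flagged drugs
are excluded from panels only under an explicit policy, mirroring manual
practice.  When a fit is non-informative the search falls back to the
median tested dose as the anchor rather than aborting.

## Composite designs

Two-level regular fractions are built from generator words with the
resolution computed from the closure of the defining relation; resolution
< III (aliased main effects) is rejected.  The three-level catalogue holds
the 9-run and 27-run arrays constructed from GF(3) linear forms (columns
indexed by projective points, hence strength 2 by linear independence) and
the classical 18-run array as a literal table; all are verified to
strength 2 by exhaustive pair counting in the tests, as is column
truncation.

Shipped presets: k = 4 → 2^(4−1) (D = ABC) + 9-run array + 1 centre
(18 runs, 15 model terms); k = 7 → 2^(7−2) (F = ABCD, G = ABDE) + 18-run
array + 1 centre (51 runs, 36 terms); k = 10 → 2^(10−4) (G = ABC,
H = ABD, J = ADE, K = CEF) + 27-run array truncated to 10 columns + 1
centre (92 runs, 66 terms).  The fraction sizes follow from a counting
constraint: the full quadratic model needs at least as many distinct runs
as terms, which rules out 16-run fractions at k = 7 and 32-run fractions
at k = 10.  The k = 10 generators were additionally screened so that the
composite model matrix is full rank (the 27-run array must break the
two-factor-interaction aliases of the fraction); resolution and rank are
re-verified by test, not assumed.  Coded levels decode as −1 → absent,
0 → half anchor, +1 → anchor dose.

## Response-surface fitting and reduction

Replicates enter the OLS stacked, not averaged, so residual degrees of
freedom reflect replicate noise.  Estimability is checked before fitting;
rank-deficient requests fail with the inestimable terms named (QR with
column pivoting).

Backward elimination respects hierarchy (a linear term is droppable only
when no retained interaction or quadratic involves it) and drops the
least significant droppable term with p > α, deterministically (ties by
term name).  Significance is judged by the full model's partial t-tests
rather than p-values re-estimated in each submodel: re-estimation
systematically shrinks the apparent error as small-contribution terms are
pooled into the residual, inflating the null retention rate well above α
(measured ≈ 0.078 at α = 0.05), while the full-model tests are exactly
calibrated (measured 0.0496 over 1000 null simulations).  On the
near-orthogonal composite designs used here both conventions select
essentially the same terms; coefficients are refitted after every drop,
and the reported standard errors of the reduced model are referenced to
the full model's residual mean square.  With a noise-free response the
error estimate degenerates; coefficients below 1e−12 are then treated as
null so reduction remains well-defined.

## Search loop and ODC selection

Per round: preset design over the surviving panel → doses decoded from
IC20 anchors (so nothing is ever dosed above its IC20) → assay → fit →
reduce → utilities g_i = βi + ½Σβij → keep the m lowest-g drugs
(schedule default 10 → 7 → 4, ties lexicographic).  The ½ weight shares
each pairwise interaction equally between its two drugs; it is a
configurable operationalization of the qualitative rule "select for
activity and synergy, against antagonism".

After the last elimination round a confirmation stage assays the full
3^k enumeration of the final panel at absent/half/full levels (81 runs
for k = 4).  This is the stage that actually tests sub-combinations —
the composite designs never contain a single-drug or pure-triple run —
and the ODC is selected from it: among tested combinations with 1..3
active drugs whose mean viability is within 0.05 of the best such
combination, take the minimal total fractional dose (−1/0/+1 mapped to
0/0.5/1 and summed), breaking ties by the most negative sum of retained
pairwise coefficients inside the subset, then lexicographically.  The
0.05 tolerance encodes the observation that halving doses of a good
combination often preserves activity; a singleton "combination" is
admissible when one drug dominates.  The default ODC size cap is 3
drugs, the size reported for best-performing combinations in this
workflow; both cap and tolerance are configuration fields.

Seeding: one integer seed drives the whole search; per-drug calibration
assays and per-round assays draw child seeds from it, so results are
bit-reproducible and two searches with the same seed write byte-identical
combination reports.

## INKA scoring

Counts are sum-normalized per sample to the grand mean of sample totals
(the simplest scheme consistent with normalized spectral counts;
deliberately replaceable).  Arms: kinome = counts on the kinase's own
phosphopeptides; activation loop = the subset with a site inside the
annotated interval (annotation is an input table — no sequence-based
detection); PSP/NWK = counts on peptides matching a relation of that
evidence class, each peptide counted once per arm, dual-evidence sites
contributing to both.  The score sqrt(mean(kinome, loop) × mean(PSP, NWK))
is homogeneous of degree 1 in counts, so global rescaling preserves ranks
and top-N overlaps exactly; a kinase with evidence on only one side scores
zero (a known divergence point from other conventions — the arms are still
reported, and arm weighting is the obvious extension point).  Ranks break
ties alphabetically.  Treatment deltas are percent changes of the score;
a zero control score is reported as undefined rather than infinite.

Differential phosphokinase expression uses a two-sample t-test on
per-protein aggregated normalized counts with Benjamini–Hochberg control
at 0.05.  Count vectors with no within-group variance yield p = 1 (no
evidence) rather than a degenerate zero — with small Poisson means,
constant-but-unequal replicate vectors arise by chance and would
otherwise flood the discovery list.

## Residual kinases and add-on ranking

A kinase is covered when the maximum fractional inhibition over the
combination's drugs reaches 0.5 (max, not sum: one strong hit suffices;
the threshold is configurable since no principled cutoff exists).
Residual kinases are the top-N post-treatment scorers outside the covered
set; add-on candidates score Σ inhibition × INKA over residual kinases,
monotone in both factors.  The module only proposes additions — swapping
a combination drug for the add-on is empirically worse, so substitution
is deliberately unsupported.

## Study sizes and numerical conventions

The seeded studies use 100 searches for recovery rates (binomial SE ≈ 4
points near 90%), 30–40 per noise level for the monotonicity check, 200
null simulations × 10 childless terms for stepwise calibration (the
Monte-Carlo error is computed clustered by simulation, since all terms of
one fit share an error estimate), and 200 fits for calibration-error
medians.  Optimizer tolerances are 1e−14 (xtol/ftol/gtol) so noise-free
parameter recovery reaches 1e−6 relative; OLS recovery on noise-free
responses is exact to ~1e−13.  Degenerate inputs fail loudly with the
offending column, sample or term named.

## Known limitations

The simulator's interaction model is a stand-in — the true response-surface
family of any real cell line is unknown, so recovery rates certify the
search machinery, not biological generality.  Calibration fits a monotone
4PL and cannot represent biphasic curves (hormesis is flagged, not
modelled).  The phosphoproteomics side is pTyr-shaped: serine/threonine
kinases are only inferable through whatever relations the input table
supplies.  Add-on dose selection is out of scope.
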