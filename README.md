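# sfsc

Phenotypic optimization of low-dose drug combinations, coupled with
phosphoproteomic kinase-activity profiling.

Finding an effective combination of k drugs is combinatorially hopeless by
brute force: even 10 drugs at 3 dose levels span 3^10 ≈ 59k mixtures.  The
streamlined feedback-system-control (s-FSC) strategy sidesteps mechanism
entirely and treats the search as iterated design of experiments: dose a
designed subset of combinations in a cell-viability assay, fit a quadratic
response surface, keep the drugs with strong single-drug activity and
synergistic interactions, and repeat on the shrunken panel until a small
optimized drug combination (ODC) remains.  The package implements that loop
end-to-end, together with the proteomics side used to interpret and improve
the result: INKA (integrative inferred kinase activity) scoring of
phosphopeptide spectral counts, kinase-profile comparisons between
treatments, kinase–substrate evidence networks, and ranking of add-on drugs
against kinases that remain active after treatment.

Everything is testable offline: a seeded simulator generates multi-drug
viability landscapes (Hill monotherapy curves + Bliss independence +
planted pairwise synergy/antagonism + optional hormesis + Gaussian assay
noise) and Poisson spectral-count phosphoproteomes driven by latent kinase
activities through a known kinase–substrate map.

## The model

Each drug is coded at three levels, x ∈ {−1, 0, +1} = {absent, half anchor
dose, anchor dose}, with the anchor set per drug at its IC20 (the dose
giving 20% of maximal inhibition on the fitted 4-parameter logistic).  The
viability fraction y of a combination is modelled as the second-order
response surface

    y = β0 + Σi βi·xi + Σi<j βij·xi·xj + Σi βii·xi²

fitted by OLS on an orthogonal-array composite design (OACD): a
resolution-IV two-level fraction stacked on a strength-2 three-level
orthogonal array plus a centre run.  Because y is viability, βi < 0 means
single-drug activity, βij < 0 synergy, βij > 0 antagonism; βii measures
dose sensitivity.  After hierarchical backward elimination (α = 0.05),
drugs are scored by

    g_i = βi + ½ Σj≠i βij        (lower is better)

and the panel shrinks along the schedule 10 → 7 → 4.  A confirmation stage
enumerates all absent/half/full combinations of the final panel, and the
ODC is the lowest-total-dose combination whose mean viability lies within a
tolerance (default 0.05) of the best observed.

On the proteomics side, a kinase's INKA score combines kinase-centric
evidence (spectral counts on the kinase's own phosphopeptides and its
activation loop) with substrate-centric evidence (counts on phosphosites
attributed to it by curated PSP or predicted NWK relations):

    INKA = sqrt( mean(kinome, loop) × mean(PSP, NWK) )

Kinases that stay in the post-treatment top-N but are not inhibited ≥50% by
any ODC drug are residual targets; candidate add-on drugs are ranked by
Σ (fractional inhibition × residual kinase's INKA score).

## Worked example

```python
from sfsc import fsc_search as fs

land = fs.recovery_landscape(seed=42, noise_sd=0.05)   # 3 synergistic actives among 10 drugs
result = fs.run_search(fs.SimulatedAssay(land), seed=42)
for rr in result.rounds:
    print(f"round {rr.index} ({rr.stage}): panel={len(rr.panel)} drugs, "
          f"R2={rr.model.r2:.3f}, eliminated={sorted(rr.eliminated)}")
odc = result.odc
print("ODC:", odc.drugs, f"viability {odc.mean_viability:.3f} +/- {odc.sem:.3f}")
```

prints

```
round 0 (search): panel=10 drugs, R2=0.845, eliminated=['D08', 'D09', 'D10']
round 1 (search): panel=7 drugs, R2=0.867, eliminated=['D04', 'D05', 'D06']
round 2 (search): panel=4 drugs, R2=0.831, eliminated=[]
round 3 (confirmation): panel=4 drugs, R2=0.881, eliminated=[]
ODC: ('D01', 'D02', 'D03') viability 0.498 +/- 0.032
```

The simulator planted mutual synergy among D01–D03; three elimination
rounds and the confirmation stage recover exactly that triple at full
anchor doses, cutting viability to ~0.50 while seven inactive drugs are
discarded.  The same loop is available from the shell
(`sfsc search --simulate --seed 42 --out results/`), along with
`simulate`, `calibrate`, `design`, `fit`, `inka`, `target-gap` and
`report` subcommands.

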