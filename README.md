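# btpcorr

Linear vs. nonlinear correlation analysis of protein **backbone
torsional pairs** (BTPs) — pairs of φ/ψ dihedral angles observed along
a conformational ensemble (e.g. an MD trajectory).

Correlated backbone motions underlie allosteric communication, but the
standard tools disagree about what "correlated" means: circular linear
correlation coefficients capture only one linear relationship, while
mutual information captures any statistical dependence and is directly
an entropy (hence free-energy) contribution. `btpcorr` implements both
measures and the machinery that connects them, for structural
bioinformaticians analyzing torsion time series from simulation or any
other source of backbone conformational ensembles.

## The measures

For torsions x and y sampled over M snapshots:

- **Circular correlation** (Fisher–Lee):
  `r = Σ sin(x_i − x̄) sin(y_i − ȳ) / √(Σ sin²(x_i − x̄) Σ sin²(y_i − ȳ))`,
  with x̄ the circular mean. Unstable for antipodal two-state torsions
  (the package flags these records).
- **Mutual information**: `MI = S_x + S_y − S_xy` in nats, from plug-in
  entropies of 60-bin (6°) marginal and joint histograms.
- **The MPMI contour**: across protein data sets, the maximum possible
  MI attainable at a given |r| follows
  `f(r) = −a·ln(1 − |r|^b)`, with (a, b) calibrated so that
  f(0.4) − f(0.1) = 0.08 and f(0.7) − f(0.4) = 0.23 nats. A pair with
  `MI − f(r) > 0.02` is classified **nonlinear**; `fit_contour` refits
  (a, b) on your own MI-vs-r scatter.
- **Torsional states**: peaks of the 1D distributions (cyclic
  collective-bin rule, 0.1 weight floor) classify pairs as DSP / SMP /
  DMP (neither / one / both torsions multi-state); joint-distribution
  peaks use a strict toroidal 8-neighbor test with a 3-bin merge.
  Heterogeneous linear correlation — different linear relationships in
  different states, the mechanism behind nonlinear pairs — is diagnosed
  from the collinearity of the positive peaks of
  `Δp(x,y) = p(x,y) − p(x)p(y)`.

Diagnostics cover distribution convergence (pairwise K-L over three
trajectory thirds, 0.2 nat threshold), a permutation null for
finite-sampling spurious correlation, trajectory-subset analysis, and
snapshot thinning. A seeded synthetic generator (multi-state von Mises
marginals, Markov state switching, per-state Gaussian-copula coupling)
provides ground truth for all of it. See `docs/methods.md` for details.

## Worked example

Simulate an 8-residue "protein" (two helix, four loop, two strand
residues → 14 torsions) with two planted couplings: a heterogeneous
pair (opposite-sign per-state ρ, torsions 6 and 11) and an ordinary
within-state copula pair (ρ = 0.5, torsions 3 and 14); then analyze:

```sh
btpcorr simulate --n-residues 8 --snapshots 50000 --ss HHLLLLEE \
    --couple 6:11:heterogeneous --couple 3:14:copula:0.5 \
    --dwell 200 --seed 7 --out-prefix demo
btpcorr analyze --torsions demo_torsions.tsv --pdb demo.pdb \
    --dssp demo_dssp.tsv --out report --seed 1
```

The per-pair records for the two planted pairs (`report/records.tsv`):

```
 i  j         r       MI   MPMI_r   excess linearity transition pair_type  distance
 3 14  0.498114 0.142282 0.137444 0.004838    linear        DSP     ab-ab  22.25520
 6 11 -0.075937 0.493737 0.003293 0.490444 nonlinear        DMP       L-L   8.72556
```

The copula pair carries r ≈ 0.50 and MI ≈ 0.14 nats — right on the
contour (MPMI_r 0.137, excess < 0.02): a genuinely linear pair, however
strong. The heterogeneous pair has near-zero r yet MI ≈ 0.49 nats,
0.49 above the contour: its two states carry opposite linear
relationships that cancel in r but not in MI. The contingency table
(`report/contingency.tsv`) shows exactly one nonlinear pair among 91,
in the DMP class; `report/convergence.tsv` reports all 14 torsions
converged (max pairwise K-L < 0.2), and the permutation nulls in
`report/permutation.tsv` bound spurious MI at ≈ 0.01 nats, far below
the planted signal.

The same analysis runs on real data: `btpcorr extract traj.pdb
torsions.tsv` computes φ/ψ series from a multi-model PDB, and `analyze`
accepts any torsion table in degrees (TSV, one indexed torsion per
column) plus optional reference structure and DSSP code files for
distance and secondary-structure stratification.

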