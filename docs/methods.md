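# Methods

`btpcorr` analyzes pairwise correlations between protein backbone
torsions (φ/ψ dihedrals) from conformational-ensemble time series,
separating the part of a pair's statistical dependence that a single
linear relationship can carry from genuinely nonlinear coupling. This
note records the models, the defaults and why they hold, the numerical
choices, and what the synthetic generator does and does not emulate.

## Torsion universe and geometry

A chain of N residues contributes 2N−2 analyzable torsions: φ of the
N-terminal and ψ of the C-terminal residue are undefined. Torsions are
indexed 1..2N−2 in sequence order ψ(1), φ(2), ψ(2), …, φ(N); all
correlation-matrix axes follow this order, so it is worth stating
prominently. Dihedrals follow the IUPAC sign convention (checked
against MDAnalysis and mdtraj in the test suite) and the (−180°, 180°]
range; all angles in the package are degrees.

Each torsion's spatial position is the midpoint of its central bond
(N–Cα for φ, Cα–C for ψ); the inter-torsion distance is the Euclidean
distance between midpoints evaluated in a user-designated reference
structure (typically the structure used to initiate sampling). A mean
structure over frames would be an alternative reference; since
ensembles here are analyzed through one designated structure anyway, a
single reference keeps distances reproducible, and the choice only
shifts pairs near the cutoff. Pairs at distance ≤ 8 Å are "spatially
local", others "long-range" — the boundary is inclusive.

Secondary structure comes from DSSP codes: H → α, E → β, everything
else (B, G, I, T, S, coil) → L. With several input structures each
residue takes the majority class; ties break toward L, the
conservative call, and residues missing from a DSSP table count as L
with a warning. Pair types pool α and β (α/β–α/β, α/β–L, L–L) because
torsions in either stable secondary structure behave alike: they rarely
leave their torsional state.

## Distributions and torsional-state peaks

Marginals use 60 bins of 6°; joint distributions use the 60×60 toroidal
grid. Binning is fixed rather than adaptive so that entropies,
mutual information and K-L divergences across subsets and proteins are
directly comparable.

1D peak counting follows a cyclic neighbor-difference rule:
δ_n = p(n) − p(n−1) with wraparound; ignoring zero differences, a bin
with δ < 0 whose next nonzero difference is positive is a boundary;
bins between consecutive boundaries form collective bins, and a
collective bin with probability > 0.1 is a peak. The 0.1 weight floor
makes the count a proxy for *occupied* torsional states rather than for
every density ripple. A distribution with no boundaries (uniform, or a
single basin) is one collective bin, hence one peak.

2D peaks are bins strictly greater than all 8 neighbors, with toroidal
wrap (angles are circular; the 1D rule is explicitly cyclic, so the 2D
neighborhood wraps too). Two tentative maxima whose cyclic index
differences are ≤ 3 on **both** axes are the same basin — a 24° split
is not a state transition — and merging is closed transitively, so a
chain of pairwise-mergeable maxima is one peak. Strictness matters:
exact plateaus have no strict maximum and are reported with a
degenerate flag instead of an arbitrary count.

The distribution difference Δp(x,y) = p(x,y) − p(x)p(y) vanishes
identically for independent torsions. Its positively-signed peaks
locate where the joint density exceeds independence; if those peak
centers fall on one straight line the pair's linear coupling is
homogeneous, while an L-shape or multiple slopes indicate
*heterogeneous* linear correlations — different linear relationships in
different regions of the joint distribution, which is what makes a pair
nonlinear. The implementation detects positive Δp peaks with the 2D
peak rule, requires peak cells to exceed a noise floor of
5·√(1/(n_bins²·M)) (five times the Poisson noise scale of a uniformly
occupied cell — above the expected maximum over ~3600 noise cells,
~4σ, and well below any real state-occupancy excess), unwraps the
centers around their circular mean, and fits one total-least-squares
line. The verdict is homogeneous when the RMS perpendicular residual is
≤ 1.5 bins (sub-peak-width collinearity); the raw residual is always
reported so the verdict is auditable. No positive peak above the floor
means "independent". Both the floor and the tolerance are parameters.

## Circular correlation and its instability

Linear association between two angles uses the Fisher–Lee circular
correlation

r = Σ sin(x_i − x̄) sin(y_i − ȳ) / √(Σ sin²(x_i − x̄) · Σ sin²(y_i − ȳ)),

with x̄ the circular mean. When a torsion occupies two antipodal states
of similar weight, the sine and cosine sums both nearly vanish, the
circular mean is dominated by noise, and r becomes unreliable —
subsets of the same trajectory can give strongly positive, negligible
and strongly negative r. There is no clean fix within circular
statistics, so the package flags records whose resultant length
R < 0.05 rather than dropping them; a strict mode excludes them from
counts. Constant series make r undefined; it is reported as 0 with a
degenerate flag so pipelines complete.

## Mutual information and the MPMI contour

MI = S_x + S_y − S_xy from plug-in entropies of the binned
distributions, in nats: multiplied by k_B, MI is an entropy
contribution (the second-order term when a joint ensemble's entropy is
expanded into mutual-information orders; higher orders are out of
scope), so the natural log is the natural unit. No pseudocounts: empty
cells contribute zero. Entropies are summed with `math.fsum`, making
them independent of summation order and bit-reproducible against naive
reference implementations; marginal entropies are computed from the
per-series integer-count histograms for the same reason.

Empirically, the upper envelope of MI attainable at a given |r| — the
maximum possible MI, MPMI_r — is well described by

f(r) = −a · ln(1 − |r|^b),

the simplest form that is symmetric in the sign of r, zero at r = 0,
and divergent as |r| → 1. The shipped constants
(a, b) = (0.446594, 1.906044) are calibrated by solving the two
envelope increments f(0.4) − f(0.1) = 0.08 and f(0.7) − f(0.4) = 0.23
nats (a two-equation root problem; the ratio eliminates a, leaving a
1-D Brent solve in b). `fit_contour` refits (a, b) from any MI-vs-r
scatter: |r| is cut into 0.05-wide intervals; within each interval the
points in the most populated 0.02-nat MI histogram bin (the modal
density — the dense ridge of the scatter, robust to a minority of
above-contour points) contribute one sample at their mean (|r|, MI),
and (a, b) are least-squares fitted through the samples.

A pair is **nonlinear** when MI − f(r) > 0.02 nats (strict), linear
otherwise. Pairs are independently classed by their torsions' 1D peak
counts: DSP (both single-peak), SMP (exactly one multi-peak), DMP
(both multi-peak).

## Diagnostics

**Convergence.** Each torsion's trajectory is cut into three contiguous
equal subsets; for every subset pair the K-L divergence is computed in
both directions and the larger taken (K-L is asymmetric and no
direction is canonical; the maximum is the conservative call — both
directions are recoverable from the API). A torsion converges when the
maximum over the three pairs is < 0.2 nats, with the same 60-bin
binning as the MI calculation. Zero cells of the reference distribution
are regularized by ε = 1/(10·M_subset) — a tenth of one count — added
to every cell and renormalized, and only when actually needed, so
identical subsets give exactly 0.

**Permutation null.** Spurious correlation from finite sampling is
bounded by recomputing r and MI after drawing the two series' snapshot
indices independently, uniformly with replacement over 1..M (matching
the literal per-snapshot resampling loop), n_rounds times with a seeded
generator; the maxima over rounds are reported.

**Subset analysis.** The trajectory is cut into n contiguous equal
blocks (default 20) and (MI, r, joint-peak count) computed per block
with the full-set values attached. Contiguous rather than interleaved
blocks preserve the time-scale interpretation: a pair coupled through
slow state transitions shows its correlation only in blocks containing
a transition.

**Thinning.** Stride mode keeps every k-th snapshot; uniform-count mode
keeps n evenly spaced snapshots including the first and last.

## Synthetic generator

The generator emulates exactly the features the analysis assumes:

- per-torsion marginals: 1–3 von Mises states with stationary weights;
- slow state dynamics: a Markov state process, parameterized either by
  an explicit per-snapshot transition matrix (validated against the
  stationary weights) or by a mean dwell time with geometric dwells;
- state-coupled pairs: a joint stationary table over state pairs whose
  marginals are the torsions' weights, driven by one joint Markov
  process (redraw from the table at rate 1/dwell);
- within-state coupling: a Gaussian copula — a bivariate standard
  normal with the state pair's ρ, pushed through the normal CDF to
  uniforms and through the numeric inverse von Mises CDF to angles, so
  rank correlation is controlled without distorting the marginals.
  Opposite-sign per-state ρ realizes heterogeneous linear correlation,
  the generative mechanism of nonlinear pairs;
- whole "proteins": H/E residues get single-state torsions at canonical
  basin centers (κ = 15), loop residues two states 120° apart (κ = 20)
  with slow switching; planted couplings replace chosen torsion pairs;
  pseudo-geometry is a straight chain with 3.8 Å Cα spacing and 0.3 Å
  Gaussian jitter plus DSSP-style code files, so distance and
  secondary-structure stratification run end to end. A planted pair's
  realized distance follows from its index separation (~1.9 Å per index
  step); planting a long-range pair means choosing distant indices.

The inverse von Mises CDF has no closed form; it is inverted
numerically from a dense tabulated CDF (2^16 grid points, ~1e−4 rad
spacing — three orders of magnitude below the 6° analysis bins) by
monotone interpolation, cached per concentration.

When state emissions are well separated, the analytic state-level MI
Σ p ln(p/(p_x p_y)) over the joint state table is the large-sample
limit of the binned MI and is recorded as ground truth, together with
expected peak counts (valid when modes are separated and weights exceed
the 0.1 floor) and expected linearity labels.

What the generator does **not** emulate: physically realistic backbone
geometry, Ramachandran-accurate basin placement, side chains,
autocorrelated within-state motion beyond the state process, and
rugged multi-basin landscapes. Passing tests therefore demonstrate that
the estimators and classification rules recover known generative
structure of the assumed form — not that real trajectories satisfy
those assumptions.

## Problem sizes and verification conditions

The package's own verification suite uses:

- estimator-recovery checks at M = 2×10^5 snapshots over 20 seeds. For
  the two-state coupled pair with joint table [[0.4, 0.1], [0.1, 0.4]]
  (analytic MI 0.1927 nats), the state process uses mean dwell 10
  snapshots: the empirical state table carries an effective sample of
  ~M/(2·dwell), and across-seed MI dispersion grows as √dwell (measured
  sd 0.0014/0.005/0.021 nats at dwell 1/10/100), so a fast-mixing
  process is the condition under which a ±0.02 recovery check tests the
  estimator rather than the generator's own sampling noise;
- a six-pair planted benchmark (two single-state copula pairs, ρ = 0.4
  and −0.5; two state-coupled pairs with a non-monotone 3-state/2-state
  arrangement; two heterogeneous-ρ pairs, ρ = ±0.8, dwell 1000) checked
  through the full pair-universe pipeline. The non-monotone arrangement
  matters: symmetrically placed 2-state/2-state coupled pairs induce
  |r| ≈ 0.6 whose contour value equals their state MI — they genuinely
  sit on the contour and are correctly labeled linear, so they are not
  usable nonlinear plants;
- peak-counting verification on 50 randomized designed constructions
  per dimensionality, plus exact rotation/translation invariance;
- convergence and permutation checks at M = 3×10^4 and 10^5.

## Known limitations

- The contour constants are a reconstruction calibrated from the two
  envelope increments; refitting on your own data (`fit_contour`,
  `--contour refit`) is preferable when the scatter is dense.
- Plug-in MI is biased upward by ~occupied_cells/(2M); at M below ~10^4
  with 3600 cells the bias approaches the 0.02 nonlinearity threshold,
  so classification needs large M or fewer bins. The permutation null
  quantifies this bias per pair.
- The heterogeneity verdict depends on the noise floor and residual
  tolerance; both are reported alongside the verdict rather than
  hidden.
- Circular r instability near antipodal two-state torsions is flagged,
  not repaired; MI is the robust measure for such pairs.
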