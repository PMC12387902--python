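# Methods

`inkmap` analyzes a small two-group clinical cohort table — subjects coded on
the Rorschach inkblot test, labeled either AD (Alzheimer dementia) or INPH
(idiopathic normal pressure hydrocephalus) — with four unsupervised stages:
descriptive validation, planar projection, self-organizing-map clustering, and
contractive-map association learning with spanning-tree extraction. This note
records the models, the parameters that matter, the numerical conventions, and
the design choices that were genuinely open.

## Cohort model and preprocessing

A cohort is a subjects × variables matrix of non-negative integer codings:
localization counts (G, D, Dd, DG), determinants (F, F±, movement, color,
shading), contents (A, Ad, H, Hd, objects, …), popular/original response
counts, resonance types (TRI I/II), the reality index (IR), and a block of 0/1
"particular phenomena" flags (perseveration, refusal, confabulation, …). The
bundled reference cohort has 19 subjects (8 AD, 11 INPH) and 45 variables.

Three structural coding rules are checked as soft diagnostics, never as
gates: the response count must equal the localization sum (G+D+Dd+DG) and the
determinant sum (F+M+FM+m+CF+FCho+CHO), and F must split into F⁺+F⁻. On the
reference cohort exactly one subject violates exactly one rule (a determinant
total of 10 against 11 responses), which is reported and retained. Content
categories intentionally have no sum rule: one response can carry several
contents.

Descriptive statistics use the sample (n−1) standard deviation; this is the
convention under which the reference cohort's published summary reproduces.
The writer rounds to 2 decimals.

All downstream stages consume the min–max scaled matrix: per variable,
x → (x − min)/(max − min). A constant column maps to 0 (not 0.5) so that it
stays inert in the signal-driven association learning. The (min, max) pairs
are stored, so integer data round-trips exactly through the inverse
transform.

For association learning, two binary indicator columns (INPH, DEMENZA — 1 for
group membership) are appended after the last variable, giving the reference
cohort 47 variables. The groups thereby become ordinary network units and
group–variable links can be read off the learned weights.

## Planar projection and separation counting

Subjects are embedded in 2-D by classical metric MDS (Torgerson): square the
pairwise distance matrix of scaled rows, double-center to recover a Gram
matrix, and scale the top two eigenvectors by the square roots of their
eigenvalues. Negative eigenvalues are clipped; a rank-deficient configuration
zero-pads the second axis. The method is deterministic up to axis sign; each
axis is oriented so the first subject's coordinate is non-negative. The
default row metric is Euclidean (Manhattan is a config option, and an
iterative SMACOF mode with fixed seed is available); on the reference cohort
the Euclidean default already reproduces the published separation, so it
stays the documented default.

Group separation is quantified exactly: candidate separator normals are the
two axes plus, for every pair of embedded points, their difference vector and
its perpendicular; every threshold between consecutive projections is swept;
the reported count is the minimum number of subjects on the wrong side of the
best line. This candidate family is exhaustive for the minimum —
any optimal separator can be rotated until it is supported by two points
without changing its error. Among minimum-error separators, ties break toward
fewer misplaced INPH subjects (the majority group stays clean), then toward
the lexicographically smallest misplaced-id list. On the reference cohort two
single-misplacement solutions exist ({Demenza 1} and {INPH 3 pr}); the
tie-break selects Demenza 1, matching the published account of the one
out-of-place subject. The count is invariant under rotation, reflection and
uniform scaling of the plane.

## Self-organizing map

A 5×5 rectangular Kohonen map (25 units, codebook dimension = number of
variables) is trained online: for each record the best-matching unit (BMU,
nearest codebook vector in Euclidean distance, ties to the lowest row/col) and
its Gaussian grid neighborhood are pulled toward the record. Defaults:

| parameter | default | note |
|---|---|---|
| grid | 5 × 5 | fixed by the analysis design |
| epochs | 1000 | |
| learning rate | 0.5 → 0.02 | exponential decay |
| neighborhood radius (σ, grid units) | 1.5 → 0.02 | exponential decay |
| init | uniform [0,1] per weight, seeded | PCA-plane init by flag |

The schedule was chosen so that the map actually resolves individual
subjects: with 19 records on 25 units, a coarse final radius leaves clusters
of near-neighbors sharing units, while this anneal ends in per-unit
competitive refinement — across seeds the modal outcome on the reference
cohort is exactly one shared class, occupied by the two cell-for-cell
identical INPH records (which share a BMU under any seed, a data property,
not a training property). Gentler textbook schedules (fewer epochs, linear
decay, final radius ≥ 0.5) were measured to leave 3–4 shared classes and were
rejected for this data regime. Quantization error is recorded per epoch
(entry 0 is the untrained codebook).

Classes are named "row.col", 1-based. Component planes (the codebook values
of one variable across the grid) come with a concentration score, max −
mean: near zero for variables spread over the whole map (e.g. the form count
F), large for variables that peak in a few classes only (e.g. original
responses).

## Auto Contractive Map

The association learner is a three-layer contractive network with one unit
per variable in every layer. For a scaled record s ∈ [0,1]^N, contraction
constant C, mono-connection weights v (input→hidden) and weight matrix w
(hidden→output):

    h_i   = s_i (1 − v_i/C)
    net_i = Σ_j h_j (1 − w_ij/C)
    o_i   = h_i (1 − net_i/C)

    Δv_i  = λ (s_i − h_i)(1 − v_i/C)
    Δw_ij = λ (h_i − o_i)(1 − w_ij/C) h_j,   with h_i − o_i = h_i · net_i/C

applied after every record. The v_i rise monotonically toward C, shutting the
hidden signal down; training stops when max_i (C − v_i) ≤ 10⁻⁶ C (or at the
10 000-epoch cap, returning a non-converged flag — an all-zero column never
saturates). The frozen w encodes associations: pairs that were strongly and
jointly active while signal lasted accumulated the most weight.
`net` can transiently exceed C, driving o negative; that is part of the
dynamics, and weights are clipped to [0, C] purely as a numerical safeguard.
The association matrix is a = (w + wᵀ)/(2C), clipped to [0,1], diagonal 1,
reported at 2 decimals.

Defaults: C = 1 with [0,1] inputs, ε₀ = 0.01 initial weights, λ = 0.01,
online updates in a per-epoch seeded shuffle. The learning rate is the one
genuinely consequential choice. Two measurable failure modes bound it from
above: at λ = 0.1 single updates overshoot the contraction bound for strongly
co-active pairs, clipping dozens of weights at exactly C — which flattens the
top of the association scale into 1.00-ties and scrambles the spanning tree —
and the learned associations become order-sensitive (max difference ≈ 0.34
between two record orderings). λ = 0.01 is the largest rate in a scanned
decade with no clipping and order-robustness ≤ 0.01 (measured ≈ 0.005); below
it the associations change only in the third decimal, indicating the values
are near their small-λ limit. Convergence on the 47-variable reference table
takes ≈ 1800 epochs (a few seconds).

Two properties of the method worth stating plainly:

- **Associations track joint activation magnitude, not correlation.** Two
  variables that are both large in many records associate strongly even if
  uncorrelated. Consequently the guarantee "a duplicated column attains the
  maximal off-diagonal association" holds among columns with comparable
  marginals (by the rearrangement inequality), and the test battery
  constructs its toys that way; with wildly different column magnitudes the
  duplicate can be out-accumulated.
- **The top of the scale is compressed.** All strong links on the reference
  cohort land between 0.98 and 1.00, so 2-decimal rounding separates levels
  only coarsely. Under these equations and defaults the dementia–perseveration
  link comes out 0.993 (stable as λ → 0), slightly above its published 0.98;
  the corresponding check is left failing rather than tuned, since no
  principled parameter choice reproduces it while preserving the 0.99 links.

## Graph extraction

Distances d = 1 − a feed a Kruskal MST with fully deterministic tie-breaking
(weight, then lexicographic node pair), so graph outputs are byte-stable. The
maximally-regular-graph step iterates non-tree edges in decreasing strength
and adds an edge iff a pluggable regularity functional strictly increases;
the default functional accepts nothing, so the default MRG is the MST — the
published variable graphs are trees. An edge budget caps additions.
Serialization: GraphML (primary), DOT and edge-list CSV, with full-precision
`strength` attributes, 2-decimal `label` renderings and a `category="group"`
attribute on the indicator nodes; all three formats re-import losslessly.

## Synthetic cohorts and recovery

The generator emulates the cohort's statistical shape: per-variable,
per-group parameters — Poisson means for counts (negative binomial when a
dispersion is set), Bernoulli probabilities for 0/1 flags — with group sizes
8/11 by default when calibrated from the reference cohort. Calibration
classifies a variable as binary iff its observed maximum is 1, and plants a
variable as discriminative when its group means differ by ≥ 1.0 (counts) or
≥ 0.3 (binaries). Variables are independent by default; an optional
common-factor mode multiplies all count means by a per-subject lognormal
severity, reproducing the coupling of every count to the subject's overall
response rate. What the generator does **not** emulate: the deterministic
coding-sum rules (localization/determinant/form sums hold only in
expectation, not per row) and any finer inter-variable dependence; passing
recovery tests therefore shows sensitivity to planted marginal effects, not
fidelity to full protocol structure.

`recovery_eval` samples cohorts, runs scale → (projection, separation) and
indicator-append → AutoCM → MST, and reports per-planted-variable
indicator-adjacency fractions, the misplacement distribution, and parameter
error. Under a strong single-variable effect (mean 0 in AD vs 8 in INPH,
n = 19) the planted variable is MST-adjacent to the INPH indicator in ≥ 90%
of runs; under a zero-effect spec the 2-D separation stays at chance level
(mean misplacement ≥ 2 over 50 runs, measured ≈ 4.6). Problem sizes in the
test battery (10–15 record toys, 50-run Monte Carlos) are chosen as the
smallest at which these contrasts are stable.

## Degenerate inputs and conventions

Empty tables, single-group tables (for indicator construction), sub-3-subject
projections and non-finite inputs are rejected with specific errors; truncated
trailing CSV cells are filled with 0 under a logged warning (the one known
truncated row in the published 47-variable table is 0 in its complete
duplicate); identical records always share an SOM class and coincide in the
embedding. The pipeline derives per-stage seeds from one global seed by fixed
offsets, so any stage can be reproduced in isolation.

## Known limitations

- The projection stands in for a proprietary mapping algorithm whose exact
  distance and scaling variant is unpublished; only separation behavior, not
  coordinates, is comparable.
- The SOM schedule is tuned for ~20-subject cohorts on a 5×5 grid; larger
  cohorts will need a larger grid and a re-examined anneal.
- AutoCM association values depend (weakly, at the default λ) on learning
  rate and record order; comparisons should use the same config.
- The regularity functional of the published maximally-regular graph is not
  specified; the default reproduces tree-shaped output, and other functionals
  are pluggable but not calibrated against any reference.
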