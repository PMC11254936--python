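# Methods

`netsde` learns explicit stochastic differential equations (SDEs) for
networked systems from a single trial of node-activity snapshots plus the
known interaction topology. This note records the model, the estimation
procedure, the numerical choices, and the limits of what the synthetic
benchmarks demonstrate.

## Model class

Each of `n` nodes carries a `d`-dimensional state `x_i(t)`. The dynamics are

    dx_i = ( F(x_i) + Σ_j A_ij G(x_i, x_j) ) dt + Φ(x_i) dW_t,

with `A_ij` the (directed, possibly signed or weighted) influence of node `j`
on node `i`, `F` the self-dynamics, `G` the pairwise interaction aggregated
element-wise over sending nodes, `Φ` the state-dependent diffusion amplitude,
and `W_t` a `d`-dimensional Wiener process. On signed networks one
interaction map is used per link type (excitatory/inhibitory, inherited from
the source node). The integrator is Euler–Maruyama throughout; the one-step
transition is therefore Gaussian,

    x_i(t+dt) ~ N( x_i + (F + Σ_j A_ij G) dt ,  Φ² dt ).

## Stage 1: likelihood-trained component models

Three compact fully-connected networks (tanh, two hidden layers, width 32 by
default) represent `f ≈ F`, `g ≈ G` (per link type) and `φ ≈ Φ`. They are
composed by message passing over the adjacency into the per-node transition
mean and variance and trained by minimizing the Gaussian negative
log-likelihood of all consecutive snapshot pairs,

    L = mean_{t,i,k} [ (x_next − μ̃)² / σ̃² + log σ̃² ],
    μ̃_i = x_i + (f(x_i) + Σ_j A_ij g(x_i, x_j)) dt,    σ̃²_i = φ(x_i)² dt.

State-independent constants of the Gaussian density are dropped. Variance
positivity is enforced by a softplus on the diffusion net's raw output; the
distillation target is the positive amplitude `φ` itself (the transition
standard deviation rescaled by 1/√dt). A full-covariance form of the loss is
implemented for completeness (scaled so a diagonal covariance reduces to the
diagonal expression term by term); training uses the diagonal mode.

Training details (all configurable via `TrainingConfig`): z-scoring per state
dimension with a stored inverse transform, so every component can be queried
in original units; Adam on random minibatches of time steps (default batch
128, learning rate 1e-2) with cosine learning-rate decay — without decay the
drift estimate random-walks at the minibatch-noise floor instead of settling;
the last 10 % of transitions are held out and the best held-out state is
returned; gradients are hand-derived (the backprop is exact; it is verified
against finite differences in development). Optimizer, schedule and split are
engineering choices — the objective is the likelihood above.

Because autodiff frameworks are not part of this package's dependency set,
the networks and their backprop live in a small internal module (`_mlp`);
they are ordinary MLPs, seeded and deterministic.

## Stage 2: two-phase sparse distillation

Pre-constructed libraries `L_F`, `L_G`, `L_Φ` of elementary scalar terms
(canonical grammar: `xi1..xid`, `xj1..xjd`, and the pairwise distance `r`)
are evaluated on states sampled from the training trajectory, giving design
matrices Θ; the Kronecker lift Θ ⊗ I_d attaches one coefficient per output
component to each scalar term. The lifted problem is block diagonal across
output components, so the regressions are run per output dimension.

Default composition: `L_F` = monomials of total degree ≤ 3 (trigonometric
terms are available via `include_trig` but off by default: on O(1) data
ranges `sin x` differs from `x − x³/6` by less than any realistic training
error, which makes support identification ill-posed); `L_G` = monomials of
degree ≤ 2 in the state pair, pairwise differences `xj_k − xi_k`, sigmoidal
synaptic gates of the sending components (matching the canonical synaptic
coupling of the built-in neuron model), and distance kernels; `L_Φ` =
constant plus monomials of degree ≤ 2. Libraries are user-extensible through
a plain-text manifest.

**Phase 1 (global relevance).** LASSO over a 50-point, four-decade λ grid
with shuffled seeded 5-fold cross-validation (standardized columns, centered
target). Relevance = |standardized coefficient| at the CV-optimal λ. Terms
inactive there are ranked strictly below the active ones by their largest
coefficient anywhere on the λ path — a term that the optimal penalty shrank
away entirely must still be reachable in phase 2. A constant column cannot be
standardized; its relevance is the standardized intercept |ȳ|/σ_y.

**Phase 2 (minimal support).** Terms are added in relevance order with
unpenalized least-squares refits on each nested support, scored by
κ² = 1 − RSS/TSS. Three refinements over a strict one-by-one walk, each
motivated by near-collinear libraries:

- *Lookahead*: at each step the best-gaining of the next 8 ranked candidates
  is added (ties within 5 % of the best gain resolve by relevance order), so
  a decoy cannot block a needed term.
- *Pair step*: if no single candidate passes the threshold, pairs from the
  window are tried — strongly correlated groups such as {x, x³} on a narrow
  range often help only jointly.
- *Stopping*: a new term must improve κ² by more than
  max(tolerance, (1 − κ²)/8) (pairs: max(2·tolerance, (1 − κ²)/4)), with
  tolerance = 1e-3. Near the plateau the remaining misfit is approximator
  noise, and a term explaining only a small fraction of it is rejected; an
  exactly representable target still proceeds to κ² = 1.

After the walk, backward elimination removes any term whose removal costs
less than the stopping scale (a term admitted early can be made redundant by
later ones), and terms contributing less than 4 % of the target RMS are
pruned. Identically zero targets give empty parts; exactly constant targets
(κ² undefined) resolve to the constant term.

**Joint drift distillation.** The likelihood constrains only the aggregated
sum `f + Σ_j A_ij g`, so regressing `f` and `g` separately on the trained
nets inherits a flat direction: a receiver-only piece of `g` can trade
against `f` almost freely when in-degrees are similar. `distill_networked`
therefore regresses the *total* drift on the concatenation of self-library
columns and topology-aggregated pair-library columns (per link type);
in-degree heterogeneity then separates the parts as part of the sparse
regression itself.

Its default drift target is the raw one-step increments `(x(t+dt) − x(t))/dt`
rather than the trained drift surface. The reason is statistical: the
increments' error is white transition noise, which perturbs least-squares
coefficients only at the O(σ/√(N·dt)) scale, whereas the trained surface
carries smooth approximation error of a few per cent that the library can
partially express — far more damaging to support identification. Against
increment targets κ² saturates at the drift's share of the transition
variance, so the remaining-misfit fraction carries no information and the
stopping rule falls back to the absolute gain tolerance, with the
contribution prune referenced to the fitted signal's RMS.
`drift_target="model"` retains the smoothed-surface regression for data
whose noise exceeds the intrinsic diffusion. The per-component route
(`distill`) remains the right tool when the pair function itself is the
object of interest (e.g. separating excitatory from inhibitory synaptic
responses), and is exact for oracle components.

An output dimension whose component values have RMS below a few per cent of
the part's largest dimension is treated as absent (`component_floor`): with
trained approximators a truly missing component is pure approximation noise.

**Metrics.** κ² as above (1 = perfect, 0 = mean predictor, can be negative).
Equation discrepancy is the symmetric mean absolute percentage error over the
union of (part, link type, term, output dimension) slots with nonzero
coefficient on either side: mean of |I − R|/(|I| + |R|), so a term present in
only one equation contributes exactly 1/k. sMAPE is symmetric, lies in
[0, 1], and is 0 iff the equations agree.

## Built-in ground-truth systems

The cited equation forms live in `models.py`; all coefficients are exposed as
parameters.

- `hindmarsh_rose`: three-variable bursting neuron (a=1, b=3, c=1, h=5,
  r=0.006, s=4, x_rest=−1.6, I=3.2) with sigmoidal synaptic coupling
  k_syn (V_syn − x1_i) / (1 + exp(−10 (x1_j − 1))), V_syn = +2 on links from
  excitatory nodes and −1.5 from inhibitory nodes. The default pair library
  contains the same canonical gate.
- `rossler`: a=b=0.2, c=5.7 with diffusive coupling in the first component;
  for weighted benchmarks the link weights are uniform on (0, 1).
- `lorenz_network`: Lorenz-63 (10, 28, 8/3) per node, diffusive x-coupling;
  the stochastic intensity is 1/√γ and the second component's diffusion
  depends linearly on the third, φ₂ = (1/√γ)(1 + 0.02 x₃) — a representable
  cross-component diffusion.
- `linear_cubic_test`: the recovery oracle. Its (x1, x2) pair is a
  Liénard-form relaxation oscillator (f1 = x1 + x2 − x1³, f2 = −x1 − 0.3 x2)
  with a driven third dimension (f3 = −0.5 x3 + 0.3 x1 x2), diffusive
  coupling in the first two components (0.3, 0.4) and constant diffusion 0.1.
  Every term is in the default libraries. Two properties matter: the limit
  cycle covers the state range by dynamics rather than by noise, and the
  noise is ~10 % of the drift scale — with noise of order the drift, the
  nonparametric drift-estimation floor at 5·10³ snapshots exceeds 40 % and no
  method recovers support. Diffusive coupling is used because its Jacobian
  contribution has nonpositive real spectrum (Gershgorin), so no random
  topology can destabilize the simulation.

The end-to-end benchmark optionally trains a small ensemble of independent
initializations and distills the averaged components (`n_ensemble`);
with the increment-target distillation the single-model default suffices.

## Second-order flocking

The acceleration-level model is

    dv_i = [ S(|v_i|²) v_i/|v_i| + Σ_{j≠i} ( C(r_ij) r_ij + A(r_ij) v_ij ) ] dt
           + ε dW_t,         dr_i = v_i dt,

with r_ij = r_j − r_i, v_ij = v_j − v_i. The scalar self-propulsion strength
acts along the unit velocity (speed regulation); interactions are all-to-all.
The parametric kernel forms are A(r) = a1(exp(−r/3) + a2) + a3,
C(r) = c1((r/2−1)³/(r/2+1)⁶ + c2) + c3, S(u) = s1(u + s2) + s3 with u = |v|².
Since a1·a2 + a3 is a single degree of freedom (likewise c, s), results are
reported in the canonical normalization a2 = c2 = s2 = 0.

Each strength function is a scalar function of a scalar, so the fitted
approximators are radial-basis networks (Gaussian bumps at data-quantile
centers plus a linear trend) — linear in their coefficients. The composite
loss β₁L_nl + β₂L_r + β₃L_v + β₄L_a (likelihood of the velocity transition
plus squared two-step displacement, velocity and acceleration errors) is
quadratic in the predicted acceleration and hence in the coefficients, so the
fit is an exact weighted least squares; the likelihood channel's weight
depends on ε, which is re-estimated from the transition residuals in one
reweighting pass. Gradient-trained MLPs were rejected for this module after
profiling: their spectral bias resolves the sharp short-range cohesion kernel
orders of magnitude more slowly than the convex fit, whose solution is the
statistical optimum by construction.

Kernel distillation is least squares of the two-parameter forms (amplitude,
offset) on the fitted strengths over quantiles of the *observed* distances
and squared speeds — the fit and its κ² are weighted by where the data live;
outside the observed support the strengths are extrapolation.

Default simulation kernels (amplitudes are this package's choices; the forms
are fixed): a=(0.5, 0, 0), c=(8, 0, 0), s=(−0.5, 0, 0.5), ε=0.3, dt=0.01.
ε=0.3 keeps speeds and pairwise distances fluctuating over a realistic band
(which is what makes all three kernels identifiable); the flock still orders
(polarization ≈ 0.99 from disordered initial velocities).

Track preprocessing for empirical 2-D/3-D recordings: per-individual cubic
(optionally smoothing) splines resampled on a common fixed-dt grid (default
0.01), velocities and accelerations from the spline derivatives; individuals
whose speed deviates from the flock median by more than 3.5 median absolute
deviations in more than 5 % of frames are dropped and reported; optional
cruising-window extraction (explicit window or longest run above a speed
threshold); normalization to zero initial centroid and unit spatial scale;
rotation of the horizontal plane so the mean initial heading points along +x.
The pipeline is idempotent up to spline tolerance.

## Pathology spreading on a connectome

The region-level model maps a binary seeding vector x(0) to the fraction of
each region occupied by pathology at month t:

    y_i(t) = ( b0_i x_i(0)
             + b1_i Σ_j Ã_ij x_j(0)/(1+e^{−A_ij})      [retrograde]
             + b2_i Σ_j Ã_ji x_j(0)/(1+e^{−A_ji})      [anterograde]
             + b3_i Σ_j D̃_ij x_j(0) e^{D_ij} ) · T(t), [spatial]
    T(t) = c_t + 1.5 t,   D_ij = 1/log(E_ij²) (entries < 0.11 zeroed).

`A` is anatomical connectivity in retrograde orientation (anterograde is its
transpose), `E` the Euclidean distance matrix (the transform presumes
distances above 1 in the data's units; smaller entries map to zero, or raise
in strict mode), and Ã, D̃ are binary supports. σ is treated as i.i.d.
residual noise during fitting.

Identifiability: with a single seeding vector, (b0..b3)_i enter predictions
only through the scalar loading u_i = Σ_k b_ki m_ki (m = pathway features);
because T(t) has a pinned slope of 1.5/month, the overall scale *is*
identified, so (u, c_t) are the identifiable coordinates. Fits report them
exactly and decompose b as the minimum-norm solution u_i m_i/|m_i|²; recovery
statements are about (u, c_t). The directional-preference readout (mean |b1|
vs |b2|) still works through the minimum-norm decomposition because
generation with dominant retrograde coefficients makes u correlate with the
retrograde feature.

Fitting is least squares in log space by default (linear space available):
for fixed c_t the optimal log-loading is closed form per region, leaving a
smooth 1-D profile objective in c_t solved by bounded scalar minimization
(c_t > −1.5 keeps T positive over the first observed month). The homogeneous
("every region equal") variant constrains each b to a shared scalar per
pathway — a 4+1-parameter nonlinear least squares in the same space, so the
two variants' errors are comparable; on heterogeneous data it is strictly
worse. The seed-specificity null refits the heterogeneous model from random
seed sets and compares per-timepoint squared Pearson correlations;
specificity arises because the reachable-region support of a wrong seed set
mismatches the observed pathology support.

The synthetic connectome generator draws a sparse nonnegative directed `A`
(exponential weights, density 0.15), region coordinates in a 200-unit box
(so the D-threshold removes the far tail), heterogeneous b vectors from
uniform ranges with adjustable retrograde/anterograde scales, c_t = 0.5, and
observations at months {1, 3, 6, 9} with optional multiplicative lognormal
noise.

## What the synthetic benchmarks do and do not show

The generators produce data from exactly the model class the estimators
assume (Euler-consistent transitions, Gaussian intrinsic noise, known
topology, stationary dynamics). Passing tests therefore demonstrate correct
identification and implementation at realistic noise-to-signal ratios — not
robustness to model misspecification: measurement (extrinsic) noise,
unobserved nodes, topology errors, non-Gaussian or state-correlated noise,
and nonstationary empirical recordings are all outside what the suite
establishes. Preprocessing (splines, windowing) is exercised on synthetic
tracks only.

## Problem sizes and tolerances

The validation suite runs at scaled-down study sizes chosen for a single CPU:
cubic-oscillator recovery at 10 nodes × 5·10³ steps (dt = 0.01), signed
bursting-neuron sign recovery at 20 nodes × 2·10³ steps, flocking at 20
individuals × 5·10³ steps, pathology recovery at 40 regions with 100-draw
nulls, and transition-moment checks at 10⁵ samples (4 standard errors; OU
stationary variance within 5 %, where the Euler discretization itself
contributes ~θ·dt/2 = 2.5 % at the test's step size). Stochastic recovery
criteria are majority-of-seeds statements (at least 4 of 5 fixed seeds).

## Known limitations

- Drift estimation error scales like σ/√(m·dt) per resolvable state-space
  cell; with noise of order the drift, support recovery fails for any
  method at these data sizes (this bounds what "one trial" can deliver).
- Greedy-with-lookahead selection is robust to the collinearity patterns we
  observed, but it is not best-subset selection; adversarial libraries can
  still defeat it.
- The per-component distillation of `g` can carry a receiver-only offset out
  of the likelihood's flat direction; use the joint route or contrast-based
  readouts when the offset matters.
- The tau model's per-region coefficient vectors are not individually
  identifiable from one seeding experiment (only their loadings are); the
  minimum-norm decomposition is a convention, not an inference.
- No extrinsic-noise deconvolution, no latent/partially observed nodes, no
  higher-order (triplet) interactions, no adaptive or higher-order SDE
  integrators, and no network-topology inference.
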