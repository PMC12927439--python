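# Methods

## The problem

A first-order saddle point on a potential-energy surface (PES) — a
stationary point whose Hessian has exactly one negative eigenvalue — is the
transition state of harmonic transition-state theory. The dimer method
finds such points from a single starting geometry: it estimates the
softest Hessian eigenvector `tau` from finite differences between a
displaced replica `R0 + dR*tau` and the midpoint `R0`, inverts the force
component along `tau`,

    F_eff = F - 2 (F . tau) tau ,

and follows `F_eff`, climbing the softest mode while relaxing every
orthogonal direction. When each force call is an electronic-structure
calculation, the dominant cost is the number of PES evaluations, which
motivates an on-the-fly Gaussian-process (GP) surrogate: the walker relaxes
cheaply on the GP posterior mean and consults the true PES only to verify
and to extend the training set.

## The surrogate

Energies and gradients enter a joint GP with the inverse-distance squared
exponential kernel

    k(x, x') = sigma_c^2 + sigma_f^2 exp( -1/2 sum_{i<j}
                 ((1/r_ij(x) - 1/r_ij(x')) / l_phi(i,j))^2 ),

one length scale per unordered element-pair type. The 1/r features are a
physical prior: the kernel varies fastest exactly where the PES does (short
range), and is rotation/translation invariant by construction. Gradient
observations require the energy–gradient and gradient–gradient covariance
blocks; these are the analytic first and mixed second derivatives of `k`
through the chain rule over the inverse pair distances, assembled in
`kernel.kernel_blocks` and validated against central finite differences in
the test suite (a mandatory check: a silent sign error here corrupts
everything downstream).

Training energies are centered on their mean before fitting, so the signal
variance works on O(1) residuals — the regime the barrier bound
`sigma_f^2 < 2` assumes. Observations are deterministic calculator output,
so the noise model is a fixed nugget pair (1e-8 eV^2 on the energy channel,
1e-8 (eV/A)^2 on gradients), with geometric jitter escalation
(1e-8 → 1e-4 relative to the mean covariance diagonal) if a factorization
fails, e.g. for near-duplicate geometries. Prediction always conditions on
the full observation history; the subset below is used only to fit
hyperparameters. Frozen fixture anchors contribute pair distances to the
kernel but no gradient observations or prediction outputs.

## Hyperparameter control

Fitting hyperparameters on the whole history costs
O((M_data * 3N + M_data)^3) per objective evaluation and quickly dominates
wall time. Instead the marginal likelihood is evaluated on a farthest-point
subset: seeded with the two most recent observations (path continuity),
grown greedily by max–min distance under the intensive Earth Mover's metric
(below), starting at 10 members and hard-capped at 30. Candidates whose
energy exceeds the subset median by more than 3 interquartile ranges are
deferred — strained outliers degrade the conditioning of the covariance —
but are admitted if the target size cannot otherwise be reached. Ties break
to the lowest index, which makes selection deterministic.

The objective is MLL + log-prior + barrier:

* **Prior.** Independent Student-t densities on each log-parameter,
  location 0, scale 1, degrees of freedom `max(28, n_interaction_types)`.
  The floor keeps the shape near-Gaussian; the growth with interaction-type
  count regularizes chemically complex systems harder. Which parameters
  carry the prior and its scale were open choices; all optimized
  log-parameters carry it at scale 1.
* **Barrier.** The likelihood has a shallow ridge along the signal
  variance; unbounded growth of `sigma_f^2` flattens the posterior mean and
  inflates the predictive variance until the walker is steered into
  unphysical geometries. The maximized objective therefore includes the
  interior-point term `+mu * log(lambda_max - w0)` with `w0 = log sigma_f^2`
  and `lambda_max = log 2`; it diverges to -inf at the bound, so the
  optimizer cannot cross it (for the equivalent minimized objective this is
  the textbook `-mu log(C - w0)` penalty with gradient `mu/(C - w0)`). The
  strength schedule `mu(N) = min(mu0 + alpha*N, mu_max)` with
  `mu0 = 1e-4`, `alpha = 1e-3`, `mu_max = 0.5` keeps the model flexible
  while data is scarce and tightens as it accumulates.
* **Oscillation detection.** Over a trailing window of W = 6 optimizer
  iterates, the fraction of parameter updates whose consecutive signs
  alternate is computed; if it exceeds p_osc = 0.5 the subset grows by 5
  (capped at 30) and the optimization reruns, at most three times, after
  which the best parameters seen are kept and the run is flagged unstable.
  W and p_osc are package choices (no published values exist): a single
  sign flip never triggers growth, sustained alternation does.

The optimizer is bounded L-BFGS-B in log space with central-difference
gradients (`jac="3-point"`, step 1e-5): the ridge is so flat that
forward differences at machine-epsilon steps return noise, which
manifested as premature convergence wherever the start happened to be.
Because the objective is multimodal — a collapsed length scale acts as a
delta-kernel local optimum that fresh data cannot undo from inside — each
fit runs from the warm start, from the prior location, and from two seeded
random draws, keeping the best optimum. Bounds are [-5, 5] on every
log-parameter (the upper bound on `w0` is `lambda_max - 1e-6`). The
constant offset `sigma_c^2` is fixed at 1 eV^2 by default; the paper-level
description lists it in the kernel but never among the optimized
parameters.

## Configuration metrics and the trust radius

The legacy trust metric, the maximum absolute log-ratio of interatomic
distances, is rotation invariant but not permutation invariant: relabeling
two identical atoms (a methyl rotation, a proton transfer) looks like a
huge step. The replacement is an intensive Earth Mover's distance: per
element type, an exact linear assignment (Hungarian algorithm, never a
greedy matching — the quantity is a minimum over permutations) matches the
atoms of the two configurations; the per-type mean matched displacement is
taken, and the overall distance is the maximum over types. Averaging within
a type makes the measure intensive — spectator atoms do not dilute it — and
taking the worst type keeps a small moving group visible inside a large
molecule. No rotational pre-alignment is applied: along a search
trajectory, rigid motion has already been projected out of every step, and
the metric is used only there.

A surrogate relaxation step is accepted only if the EMD from the candidate
to its nearest training configuration is at most

    Theta = min( T_min + dT_explore * (1 - 2^(-N_data/N_half)),
                 max(a_floor, a_atoms / N_atoms) ),

an earned-exploration schedule (more data, larger permitted moves, saturating
at `T_min + dT_explore`) capped by a size-aware physical ceiling. On
rejection the true PES is evaluated at the current midpoint, the
observation is added, and the relaxation resumes from the last accepted
midpoint with an enlarged Theta. Defaults `T_min = 0.1 A`,
`dT_explore = 0.4 A`, `N_half = 10`, `a_floor = 0.2 A`,
`a_atoms = 5 A*atoms` are package choices, exposed in the config.

## Rigid-body purification

The force inversion breaks Newton's third law, so uncorrected steps can
translate and rotate the whole frame; the kernel is rigid-motion invariant,
but the trust metric and the training inputs are not, and frame drift
shows up as spurious novelty. Each translation step `s` is therefore
projected onto the internal subspace, `s - sum_k (s.u_k) u_k`, where the
`u_k` are three exact translations plus up to three Gram–Schmidt
orthonormalized infinitesimal rotation generators about the geometric
centroid (unit masses — this is a symmetry projection, not dynamics; drop
tolerance 1e-8 for collinear geometries, where the rank falls to 5). When
any atom is frozen, constraints already pin the frame and the basis is
empty.

## The dimer engine

Rotation uses the two-point Fourier method: along the great circle through
`tau` and the normalized rotational force, the curvature is a harmonic in
`2*phi` fixed by `C(0)`, `C'(0)`, and one trial rotation; each iteration
costs two gradient calls and returns the minimizing angle directly.
Steepest-descent orientation updates (rather than conjugate-gradient ones)
keep the implementation simple; rotation tolerances are exposed, not
asserted. Translation uses a limited-memory BFGS recursion on the effective
force, with history reset whenever `tau` turns by more than 30 degrees
(curvature information across a mode switch is misleading). While the
curvature along `tau` is still positive — the walker is inside a convex
basin — only the reversed parallel force is followed, straight up the
softest mode. Every step is purified, then clipped so no atom moves more
than `0.5 * (1 - ratio_at_limit) * d_min` (half the gap to the nearest
neighbour, modulated by the cautious/aggressive knob) nor more than an
absolute cap. Convergence is declared when the root-mean-square atomic
force over movable atoms falls below 0.01 eV/A; on the surrogate the same
test uses predicted forces, and the outer loop re-verifies on the true PES.

## The outer loop

Evaluate the true PES at the current midpoint; append the observation;
refit hyperparameters (every iteration, warm-started — they change little
once data accumulates); factorize the surrogate over the full history;
relax the dimer on the surrogate until its own convergence or a
trust-radius rejection; evaluate the true PES at the resulting midpoint;
declare success only when the *true* RMS force is below tolerance. If the
covariance cannot be factorized even at maximum jitter, or the relaxation
is rejected three times in a row without moving, the controller falls back
to one plain-dimer cycle on the true PES. Budgets (300 true-PES calls, 10^4
surrogate steps per relaxation, 100 outer iterations by default) make every
failure mode a flagged, non-converged result rather than an exception; a
calculator error aborts with the trajectory retained. A `gpdimer` baseline
mode — legacy log-ratio trust metric, full-history hyperparameter fits, no
barrier, no oscillation control — exists for paired comparisons, and a
`dimer` mode runs the engine directly on the true PES.

## Synthetic fixtures: what they emulate and what they do not

`surfaces` provides closed-form calculators so the whole stack is testable
without any electronic-structure engine; every fixture's gradient is
checked against finite differences before anything else runs, and all
generators are seed-deterministic.

* **Morse clusters** (pairwise Morse, default depth 1 eV, width 1.5 1/A,
  r0 = 1.5 A, alternating two element labels so pair-type machinery is
  exercised). The relaxed 4-atom tetrahedron and its rearrangement saddle
  drive the paired call-count comparison: ten starts perturbed by 0.12 A
  from the minimum, both search modes, median true-PES calls compared.
  The soft parameterization is deliberate — curvatures of a few eV/A^2
  keep the GP well inside the `sigma_f^2 < 2` regime that the barrier
  assumes for centered energies.
* **2D Gaussian wells** embedded as one movable pseudo-atom plus two frozen
  anchors (so the kernel has pairs to work with). Curvatures are given
  molecular scale (depths 3–4 eV, widths ~0.4 A): at the 0.01 eV/A force
  criterion a walker sits within |g|/lambda of the saddle, so soft toy
  surfaces would not support a meaningful position-accuracy statement. A
  weak harmonic confinement (0.05 eV/A^2) removes the zero-force plateau of
  bare Gaussian tails, where any force-based test would otherwise
  "converge" far from anything — bound molecules have no such plateau.
  Saddles are pre-solved by Newton's method on the analytic gradient from
  ridge-midpoint guesses and kept only if genuinely index-1; that oracle is
  independent of the dimer machinery it later judges.
* **Quadratic PES** with an arbitrary Hessian, for exact eigenpair checks
  of the rotation routine.

None of these fixtures have the dimensionality, anharmonic coupling, or
multi-fragment pathologies of real molecular benchmarks; passing here shows
the algorithmic contracts (metric exactness, barrier hardness, projection,
acceleration direction, saddle index) hold, not that production success
rates transfer.

Search starts in the tests are displaced from the minimum toward the
barrier, as in standard practice (production runs initialize along a
cheaply estimated softest mode): at an isotropic well bottom the minimum
mode is degenerate and the initial uphill direction is undetermined, which
is an initialization property, not a property of the searcher.

## Numerical choices

* Jitter: start 1e-8, grow ×10 to at most 1e-4 (relative to the mean
  covariance diagonal), then fail loudly.
* Gram–Schmidt drop tolerance 1e-8 (relative) for rotation generators.
* Dimer separation 1e-2 A on analytic surfaces (1e-3 in eigenpair unit
  tests of the rotation, where the quadratic surface makes smaller better).
* Degenerate geometries (coincident atoms) raise immediately in the kernel
  and the Morse evaluator; the engines convert this into a structured
  `pes_error` stop.
* FPS tie-break: lowest index. Trust acceptance at the boundary: accept
  (the inequality is non-strict).
* The subset size persists (monotone non-decreasing) across outer
  iterations once oscillation control has grown it.

## Known limitations

* Exact linear assignment is O(Nt^3) per element type per distance; fine at
  benchmark scale (tens of atoms), not tuned for thousands.
* The acceptance/rejection bookkeeping assumes a fixed element multiset
  along a search; systems that change identity mid-search are out of scope.
* No sparse/inducing-point approximations: in the few-dozen-observation
  regime they cost more than they save, and the full-history posterior is
  exact.
* The legacy baseline shares the adaptive trust schedule (in its own metric
  units) rather than a hand-tuned fixed radius, which is the closest
  like-for-like comparison this codebase can make.
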