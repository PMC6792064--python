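# Methods

## The simulation-kernel idea

Kernelized learners (SVMs, kernel nearest neighbour, similarity-feature
forests) need only a similarity score between pairs of samples, not the
samples' feature vectors.  When a mechanistic but *approximate* simulation
of the system is available, that similarity can be computed by simulation:
run every sample through the model many times under different plausible
parameter settings, and score a pair of samples highly if their simulated
behaviour agrees across that whole family of models.

Formally, let `x_i` be sample `i`'s feature vector and `theta` the vector
of simulation parameters we are uncertain about, with an independent
marginal distribution attached to each entry (Gaussian multipliers around
a nominal rate, a discrete set of candidate values, or a uniform choice
among structurally different model variants).  For trials `r = 1..R` one
instantiation `theta_r` is drawn and **shared by every sample in that
trial**; the simulation output `S(x_i, theta_r)` may be a set of time
courses or a class label.  A bounded pairwise similarity
`z(i, j, r) in [0, 1]` is computed per trial and the kernel is the
entrywise average

    K(i, j) = (1/R) * sum_r z(i, j, r),

so `K(i, i) = 1` and `0 <= K(i, j) <= 1` by construction.  Trials in
which a sample's integration diverges are excluded pairwise: each pair is
averaged over the trials where both samples simulated successfully, and a
pair with no successful common trial is an error rather than a guess.

Two similarity variants are built in:

* **indicator similarity** for categorical outputs (`z = 1` iff the two
  labels agree).  Each trial's matrix is a sum of one-hot Gram matrices,
  so the averaged kernel is automatically positive semidefinite.
* **trajectory similarity** for ODE outputs: each selected state
  variable's series is rescaled to [0, 1] by the trial population's
  (min, max); the per-variable similarity is one minus the mean absolute
  difference of the rescaled series; the result is the mean over selected
  variables.  A variable that is constant across the whole trial
  population contributes similarity 1.  Before rescaling, concentrations
  are mapped through `log1p` (a model-level choice): levels span orders
  of magnitude across genotypes, and on the raw scale a handful of
  overexpression samples dominate the population bounds and wash out the
  similarity signal.  Trajectory kernels need not be PSD; when the
  smallest eigenvalue is below -1e-8 the kernel is repaired by clipping
  negative eigenvalues at zero, renormalizing the diagonal to 1 and
  clipping off-diagonals back to [0, 1], with the clipped spectral mass
  recorded in the kernel's provenance.

Kernel convergence in `R` is tracked through running averages
`K^(r)` (emitted from `r = 3` by default; earlier averages are too noisy
to be worth writing) and the Frobenius norms `||K^(r) - K^(r-1)||_F`,
which decay like `1/r` for bounded similarities.

## The four bundled systems

All data are synthetic: each model has a ground-truth simulation that
labels the samples (never seen by the kernel pipeline) and an approximate
SimKern variant that only produces outputs for similarity scoring.
Kinetic constants are this package's own and were chosen for qualitative
class structure, not biochemical realism; they live in YAML files under
`simkern/models/data/` and every generator is bit-reproducible for a
fixed seed.

**Radiation cell fate** (classification, 4 classes, 39 features).  A
34-state ODE network: DSBs activate ATM, which drives p53
phosphorylation and tetramerization against the MDM2/WIP1 feedbacks; p53
targets fan out into repair (GADD45, repair complex), arrest (p21,
14-3-3sigma, Reprimo), apoptosis (PUMA/BAX/BCL2, cytochrome c,
apoptosome, caspases, cleaved PARP) and cycling (CDC25, cyclins, RB/E2F)
blocks.  Samples vary 33 rate constants (log-normal multipliers,
sigma 0.6) and six knockout flags (ARF, BAX, SIAH, Reprimo, p53, APAF1;
each Bernoulli(0.3)).  End-of-horizon readouts are thresholded in a
fixed priority order — apoptosis (cleaved PARP), mitotic catastrophe
(mitotic-damage integrator), repaired-and-cycling (cycling readout high,
residual DSBs low), quiescence otherwise — making the rule total and
deterministic.  Thresholds (12 / 6 / 0.5 / 2) were fixed once so that all
four fates occur with frequency >= 2% in a 2000-sample population.  The
SimKern variant marks 87 of the 127 parameters uncertain with Gaussian
multipliers (mean 1, sd 0.2) and outputs all 34 time courses; the
"more knowledge" kernel restricts similarity to the readout variables the
classifier actually uses, the "less knowledge" kernel uses all 34.

**Flowering time** (regression, 35 raw / 53 coded features).  Six ODEs
for the floral-integrator circuit (FT, FD, SOC1, AGL24, LFY, AP1) with
saturating activation kinetics, an FT-FD complex input onto SOC1 and
AP1, and the LFY-AP1 positive feedback that makes flowering a switch.
The outcome is the first time AP1 exceeds a fixed threshold, linearly
interpolated between grid points; trajectories that never cross are
censored at the horizon (100 time units).  Samples combine one of 19
genotypes (wild type, six knockouts, six overexpression lines, six
double knockouts; knockout zeroes a gene's production terms,
overexpression multiplies them by 8) with log-normal multipliers
(sigma 0.3) on 34 of the 36 rate parameters.  Two constants were revised
during calibration: AGL24's repression of AP1 was weakened (K_P3 10) and
the direct FT-FD -> AP1 route softened (v_P2 0.08) because the original
values put whole genotypes on a knife edge where flowering time jumped
between ~30 and the censoring horizon under tiny rate perturbations — no
approximate simulation can resolve such samples, and the published
behaviour this package reproduces (every noise level yielding a
*sufficient* kernel) presumes the model instance is not pathological.
The SimKern variants perturb the same 34 rates with multiplicative
Gaussian noise (sd 0.1 / 0.2 / 0.4) or, for a biased variant, uniform
discrete multipliers {0.01, 1, 5, 10}, and output all six time courses.

**Boolean cancer model** (classification, 3 classes, 37 features).  A
32-node synchronous Boolean network wiring damage inputs (DNA damage,
ECM, growth factor) through Notch/TGF-beta, AKT/ERK/NF-kB and Wnt
signalling, the p53/p63/p73 tumour suppressors, their microRNAs, the
SNAI/TWIST/ZEB EMT regulators and adhesion genes into phenotype nodes.
A sample is the 32 initial states (ECM on with probability 0.3, DNA
damage 0.6, all else 0.5) plus five mutation flags (p53 forced off;
AKT1, AKT2, NICD, TGF-beta forced on; each Bernoulli(0.12)).  Synchronous
updates run with cycle detection until a fixed point or limit cycle; a
marker counts as "on" in a limit cycle if on in at least half its
states, and the class is apoptotic (Apoptosis marker), metastasizing
(Metastasis marker) or other, in that priority.  The SimKern variant is
a modular reduction to 11 module nodes with coarse rules; because it is
ambiguous which member node's initial value a module should inherit,
each trial chooses the mapping uniformly at random per module — that
mapping is the uncertainty, and the reduction's information loss is what
makes this kernel deliberately *biased*.

**Network flow** (classification, 3 classes, 12 features).  A layered
acyclic network (source, layers of 6/6/4 nodes, a 3-node final layer,
sink; exactly 80 arcs after dropping one, so that every path uses
exactly one of the 3 final arcs).  A unit of flow takes the cheapest
source-to-sink path (layered dynamic program; equal-cost ties go to the
lexicographically smallest arc sequence, making the optimizer exactly
reproducible); the class is the final arc used.  Samples vary 12 arc
costs (log-normal multipliers, sigma 0.5); the three final-arc costs
were balanced by a small iterative loop so all classes occur >= 2%.  The
better SimKern variant perturbs 23 arcs (the 12 varied plus 11 more)
with sd 0.15 multipliers; the worse variant perturbs 44 arcs with
sd 0.5.

## Benchmark protocol

Each repetition draws a fresh 50/25/25 train/validation/test permutation
split (sizes floor(N/2), floor(N/4), remainder).  Learning curves
restrict training to a fraction s of the training set
(default s in {0.05, 0.1, 0.2, 0.5, 1.0}; ceil(s * |train|) indices
without replacement, redrawn with a shifted seed if a classification
subsample has fewer than two classes).  For SVMs and nearest neighbour,
features are min-max scaled to [0, 1] with the rule fitted on the
training subsample only (zero-range columns map to 0; validation/test
values are deliberately not clipped) and categorical features are
dummy-coded with level sets fixed from the dataset schema; random
forests see the raw columns.  Hyperparameters are tuned by validation
score and the winner is refit on the training subsample (not
train+validation) and scored once on the test set.  Grids: SVM penalty
C in 10^{-2..3} (6 log-spaced values, for the linear, RBF and
precomputed-kernel SVMs), RBF width gamma in 10^{-3..2}, forests over
{100, 500} trees x {unbounded, 10} depth with mtry sqrt(p) for
classification and p/3 for regression (the classic randomForest
convention).  Kernelized algorithms consume kernel submatrices: the SVM
takes the Gram matrix directly, the kernelized forest uses each sample's
similarity-to-training-samples row as its feature vector (forests have
no native kernel mode; this is the standard kernel-as-features
construction), and kernelized 1-NN predicts the outcome of the
argmax-similarity training sample with ties to the lowest index.
Metrics are exact-match accuracy (the multiclass generalization of
(TP+TN)/(TP+TN+FP+FN)) and R^2 = 1 - SSE/SST; both are medianed over 10
repetitions.  Internal estimator randomness is seeded from the
repetition seed, so a rerun with the same seed reproduces the result
table bit for bit.

Summaries follow the usual box-plot conventions (quartiles by linear
interpolation; outliers strictly outside q1/q3 -/+ 1.5 IQR).  The "best"
algorithm of a group is the one that most often has the highest median
across the subsample fractions, excluding the nearest-neighbour
algorithms; ties break by mean median, then by a fixed algorithm order.

## What the synthetic data does and does not show

The generators emulate populations of mechanistically distinct samples
whose outcome is a deterministic function of their features through a
known dynamical system.  Real applications add measurement noise,
unmodelled heterogeneity, and — crucially — a much larger gap between the
approximate simulation and reality than the controlled perturbations
used here.  Passing tests therefore demonstrate that the pipeline
extracts the similarity structure a family of approximate simulations
encodes, not that any particular real-world simulation is good enough;
the Boolean model's biased kernel is the bundled illustration of what a
structurally wrong simulation does (early advantage, early plateau,
eventually overtaken by feature-based forests).

## Numerical choices and limitations

* ODE integration is fixed-step classical Runge-Kutta (radiation dt
  0.05, horizon 48; flowering dt 0.1, horizon 100) with
  non-negativity clamping — adequate for these smooth saturating
  kinetics and fully reproducible; there is no adaptive error control,
  so grossly perturbed parameter draws can diverge, which is handled as
  a per-sample trial failure and masked pairwise in the kernel average.
* Trajectory similarity subsamples nothing: it uses the full output
  grid (101 points flowering, 97 radiation).
* Kernel CSV round trips are exact to 12 significant digits; files with
  asymmetric or out-of-range entries are rejected on read.
* Problem sizes in the tests and the acceptance script (n = 600
  flowering, n = 1000 Boolean, R = 10 trials, 10 repetitions) are the
  package's standard desk-scale study; the full four-model figure
  replication is a longer run driven by the same CLI configs.
* The sharpest known limitation is the flowering model's censoring:
  about a quarter of samples never flower within the horizon, so R^2 is
  partly driven by predicting the censored mass; this mirrors the
  bounded-outcome convention described above rather than a survival
  treatment of censoring.
* Multiple-kernel combination, correlated theta entries and using
  simulation outputs directly as features are deliberately out of scope.
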