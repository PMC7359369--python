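# Methods

This document describes the statistical model and the sampling machinery
implemented by `gpgrn`, in the order the code composes them.

## Model

Expression of $n$ genes is modelled as a continuous-time stochastic process
$x(t) \in \mathbb{R}^n$ observed at a sparse set of measurement times:

- **Measurement model.** Observations are noisy snapshots
  $y_k = x(t_k) + \varepsilon_k$, with independent Gaussian noise
  $\varepsilon_{k,i} \sim \mathcal N(0, r_i)$ per gene. Missing entries are
  simply dropped from the likelihood.
- **Dynamics.** Between measurements the state follows a stochastic
  differential equation $dx_i = f_i(x)\,dt + \sqrt{q_i}\,dw_i$ with process
  noise $q_i$ and a drift $f_i$ that is a priori a Gaussian process.
- **Drift prior.** $f_i \sim \mathcal{GP}(m_i, k_i)$ with affine mean
  $m_i(x) = b_i - a_i x_i$ (basal transcription $b_i$, degradation $a_i$)
  and squared-exponential ARD covariance
  $k_i(x, z) = \gamma_i \exp\big({-\sum_j \beta_{ij} (x_j - z_j)^2}\big)$.

The inverse length scale $\beta_{ij}$ measures how strongly $f_i$ varies
along coordinate $j$: $\beta_{ij} = 0$ means regulator $j$ has no influence
on gene $i$. Network inference is therefore inference over the sparsity
pattern of $\beta$.

### Spike-and-slab links

Each $\beta_{ij}$ decomposes as $S_{ij} H_{ij}$: a binary indicator
$S_{ij}$ (the adjacency entry of interest) times a persistent slab
magnitude $H_{ij} > 0$ that is retained while a link is switched off, so
link re-activation proposals resume from a plausible magnitude. A priori
each link is present independently with probability $\eta/(\eta+1)$; the
slab magnitudes carry exponential priors at all times (so an indicator
flip changes the prior by exactly $\log \eta$), $\gamma_i, q_i, r_i$ carry
noninformative inverse-Gamma priors, and $a_i, b_i$ exponential priors.

### Marginal trajectory density

The grid refines the measurement times so that no step exceeds a quarter
of the median measurement interval. On the grid, an Euler discretisation
turns the SDE into increments
$\Delta x_i^{(k)} = \delta\tau_k f_i(x^{(k)}) + \sqrt{q_i \delta\tau_k}\, \xi_k$.
Because $f_i$ is a GP evaluated at the grid states, it can be marginalised
in closed form: the stacked increments of gene $i$ are jointly Gaussian
with mean $\delta\tau \odot (b_i - a_i x_i)$ and covariance

$$\Sigma_i = \mathrm{diag}(\delta\tau)\, K_i \,\mathrm{diag}(\delta\tau) + q_i\,\mathrm{diag}(\delta\tau),$$

where $K_i$ is the kernel Gram matrix over the grid states (plus a
relative jitter of $10^{-8}\gamma_i$). The density factorises over genes.
When several series are modelled jointly their grids are concatenated; no
increment crosses a series junction.

### Steady states, external inputs, normalization

- A steady-state measurement $x_{ss}$ is encoded as a noisy observation
  that the drift vanishes there, $f(x_{ss}) \approx 0$; the increment
  density is conditioned on this pseudo-observation (block-Gaussian
  conditioning with a small observation variance).
- A known external input (e.g. a drug on/off signal) enters as an extra
  kernel coordinate with its own column of $S$ and $H$; its inferred
  outgoing links identify direct targets. Input columns are excluded from
  benchmark scoring.
- Expression data are normalized to a unit scale before inference so the
  default hyperpriors (order-one rates and magnitudes) apply.

## Sampling

The posterior over trajectories and hyperparameters is explored by
Metropolis–Hastings within Gibbs. One sweep runs, in order:

1. **Trajectory block** — five preconditioned Crank–Nicolson (pCN)
   substeps. The Gaussian reference is the zero-drift random walk
   ($q_i$ Brownian increments); a pCN proposal
   $x' = \sqrt{1-s^2}\,x + s\,\zeta$ mixes the current path with a
   reference draw, and the acceptance ratio only involves the
   non-Gaussian part of the posterior. Acceptance is therefore stable
   under grid refinement. Measured columns are informed by the
   measurement likelihood; the step size adapts toward 20–30% acceptance
   during burn-in and is frozen afterwards.
2. **Per gene:** an indicator flip (birth/death of a link), a random-walk
   update of each active slab magnitude, and random-walk updates of
   $\gamma_i$, $q_i$, $r_i$, $a_i$, $b_i$ (log-scale proposals for scale
   parameters). Proposal scales adapt during burn-in only.

Multiple independent chains (distinct derived seeds) can be run and their
post-burn-in, thinned indicator samples pooled. The **confidence matrix**
is the posterior mean of $S$: entry $(i, j)$ estimates the probability
that regulator $j$ acts on gene $i$. Edges ranked by confidence feed the
AUROC/AUPR evaluation (self-loops excluded).

## Pseudo-input acceleration

Evaluating the dense $N \times N$ trajectory covariance for every
proposal is the dominant cost on refined grids. For grids above 64
increments the sampler therefore switches (by default, `n_pseudo="auto"`)
to a low-rank approximation built on $m$ pseudo-inputs: representative
points $P$ in regulator space, chosen as k-means centroids of the current
grid states. With $K_{nm}$ the cross Gram matrix and $K_{mm}$ the
pseudo-point Gram matrix, the kernel is approximated as

$$K \approx K_{nm} K_{mm}^{-1} K_{mn} + \mathrm{diag}(d), \qquad
  d_k = \gamma - [K_{nm} K_{mm}^{-1} K_{mn}]_{kk},$$

which is exact on the diagonal and exact everywhere when $m = N$ with
$P$ equal to the grid states. The Gaussian density is evaluated with the
Woodbury identity in whitened form: with $V = L_m^{-1} K_{nm}^\top$
(where $K_{mm} = L_m L_m^\top$), diagonal
$a = q\,\delta\tau + \delta\tau^2 (d + \text{jitter}\,\gamma)$ and
$G_a = V \,\mathrm{diag}(\delta\tau/\sqrt{a})$, the capacitance is
$C = I + G_a G_a^\top$ — identity plus a Gram matrix, whose Cholesky
factorization is stable regardless of how ill-conditioned the raw
covariance becomes. Cost per evaluation drops from $O(N^3)$ to
$O(N m^2)$.

Three exact reuse identities keep the per-sweep cost low:

- a trajectory move leaves $P$ (hence $L_m$) unchanged, so only $V$ is
  rebuilt;
- all kernel blocks scale exactly with $\gamma$
  ($V \propto \sqrt{\gamma}$, $d \propto \gamma$), so $\gamma$ and $q$
  proposals reuse them and refactorize only $C$;
- a mean-parameter ($a_i$, $b_i$) move changes only the residual.

Pseudo-inputs are refreshed from the visited states at each burn-in
adaptation and frozen after burn-in, so the post-burn-in chain targets a
fixed density. Caches are rebuilt from scratch every 100 sweeps to keep
floating-point drift bounded on long runs.

## Synthetic benchmark circuits

The `synthetic` module generates ground-truth networks with Hill-kinetics
dynamics (activating or repressing edges, multiplicative regulation),
integrates them with Euler–Maruyama under process noise, and samples
noisy measurements under configurable protocols, including a
perturbation–relaxation design: the simulation starts from a perturbed
state with transcription rates transiently multiplied in the first half
of the recording, mimicking a stimulus followed by relaxation. The
stimulus indicator can be exposed to inference as an external input.
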