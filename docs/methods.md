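# Methods

`kinseq` learns and generates kinetically faithful state-to-state sequences of
physicochemical systems. The pipeline is: Brownian-dynamics simulation →
feature/collective-variable (CV) extraction → K-means discretization into
integer token sequences → autoregressive sequence-model training (a
decoder-only transformer, with LSTM and Markov-state-model baselines) →
multinomial generation of future tokens → kinetic and thermodynamic
validation of the generated sequences against the source dynamics.

## Brownian-dynamics simulators

Both simulators integrate overdamped Langevin dynamics with the
Euler–Maruyama scheme

    r ← r + (dt/γ)·F(r) + sqrt(2·kT·dt/γ)·η,   η ~ N(0, 1) per component,

so the discrete noise realizes the fluctuation–dissipation relation
⟨ξ·ξ′⟩ = 4 kT γ⁻¹ δ(t−t′) in 2D. Noise is drawn chunk-wise from a seeded
`numpy.random.Generator` outside the numba-jitted kernels; a trajectory is a
bit-reproducible function of (system spec, integrator spec, seed).

### Multi-well toy potentials

V_p(x, y) = W·(x^p + y^p) − Σᵢ G(x, xᵢ)·G(y, yᵢ), with p = 6 (three wells)
or p = 4 (four wells), W = 10⁻⁴, and G the unnormalized Gaussian
exp(−(u−u₀)²/(2σ_G²)) with σ_G = 0.8. Well centers: (0,0), (±1.5, ±1.5) for
the three-well system; (0,0), (2,−1), (0.5,2), (−0.5,−2), (−2,1) for the
four-well one. Integration uses dt = 0.01 τ_BD.

Two free parameters are not fixed by the model definition and are our
calibration:

* **γ = 1** — τ_BD-unit dynamics are invariant up to a global time rescaling,
  so γ only sets the clock.
* **kT = 0.08** — the Gaussians overlap, so although the wells are ≈1 energy
  unit deep, the inter-well saddles lie only ≈0.2 units above the minima
  (numerically: minima −1.059/−1.032, diagonal saddle −0.831). kT = 0.08
  places adjacent-well barriers at ≈2.5–3 kT, which yields clear
  metastability with several hundred inter-well transitions per 10⁵ saved
  frames — enough statistics for commit-time curves. The direct path between
  the two *distant* outer wells runs through a ≈12 kT ridge, so direct
  distant hops are absent from the dynamics, reproducing the qualitative
  structure of the multi-well reference systems. At kT ≈ 1 the same
  landscape supports no metastable states at all (the particle diffuses over
  the whole confining basin), which is why the temperature matters.

The default initial condition is a well center chosen uniformly with the
integrator seed.

### Active worm-like polymer chain

A 2D chain of N = 32 beads (diameter σ = 1) with:

* harmonic bonds, V = (k₀/2)(|rᵢ₊₁−rᵢ|−d₀)², d₀ = 0.5 σ, k₀ = 10⁴ kT/σ²
  (stiff-spring choice; bond-length fluctuations ≪ d₀);
* harmonic bending about θ₀ = π at every interior bead,
  V = (k_ang/2)(θ−θ₀)², k_ang = 45 kT (the θ → π limit of the force is
  taken analytically to avoid the sin θ → 0 singularity);
* Hertzian excluded volume V = E(1−r/σ)^{5/2} for r < σ with E = 10⁴ kT/σ³,
  applied between beads at contour separation |i−j| ≥ 2 (bonded neighbours
  overlap by construction at d₀ = σ/2 and are governed by the bond term);
* tangential self-propulsion: each bond contributes a force f_m·t̂ (t̂ the
  unit vector from bead i to i+1) split equally onto its two beads;
  f_m = 5 kT/σ is the active chain, f_m = 0 the passive one.

Integration: dt = 10⁻³ τ_BD, γ = 200 kT·τ_BD/σ², kT = 1.

**Metastable states and desk-scale sampling.** The chain has two long-lived
conformational families: a wound spiral (compact, Rg ≈ 2) and a bent/extended
state (Rg ≈ 4.5). Starting from the spiral, breakup into the extended state
occurs on a ~3×10³ τ_BD timescale (measured over seeds: 0.5–4×10³ τ_BD,
roughly exponential); the reverse event — spontaneous spiral nucleation —
was never observed in 10⁵ τ_BD and is beyond desk-scale budgets. The default
study condition is therefore an **ensemble of spiral-initialized members**
(24 members × 3,000 τ_BD, saved every 0.1 τ_BD; member seeds spawned from a
master seed). A majority of members convert, so both basins are sampled and
the one-way spiral→extended conversion provides a clean detailed-balance
violation signal with ~15 expected events (pooled z ≈ √15 ≈ 3.9). The spiral
initial condition winds the propelled head *inward* (activity then stabilizes
the spiral), which is what makes the state metastable rather than instantly
unwinding.

What this emulates — and does not: the ensemble reproduces the two-state
structure and the irreversibility of the active dynamics, but not repeated
back-and-forth conversions; forward/backward commit-time statistics at large
commit times are therefore dominated by the one-way conversion events, and
curve shapes beyond the breakup scale carry few events.

## Features and collective variables

* Pairwise distances: C(k,2) Euclidean distances between selected particles,
  ordered lexicographically; the polymer uses 8 beads in arithmetic
  progression with step 4 → 28 features; 20 particles → 190 features.
* Radius of gyration: equal-mass Rg(t).
* For the polymer, the Rg series used as a 1D CV is smoothed with a 1 τ_BD
  (10-frame) moving average before discretization. Raw threshold crossings
  during a breakup flicker on sub-τ_BD scales; smoothing makes one physical
  conversion one token-level transition. (Unsmoothed discretization inflates
  both transition counts symmetrically and erases the commit-time asymmetry.)

### Autoencoder

Symmetric MLP: widths [F, max(16, F), 16, L, 16, max(16, F), F] with tanh on
hidden layers, linear latent and output layers; Adam (lr 10⁻³), mini-batches
of 256, feature-wise z-scoring before training. The quality score is the
fraction of variation explained,

    FVE = 1 − Σᵢ‖X(i) − Y(i)‖² / Σᵢ‖X(i) − X̄‖²,

computed on the standardized scale (scale-free; 1 = perfect reconstruction,
0 = mean prediction, negative = worse than the mean). Training is full
backpropagation on numpy — the package deliberately carries no deep-learning
framework dependency; at these widths (≤ 200 units) numpy on one CPU covers
every training run in seconds to minutes.

## Discretization

K-means (scikit-learn, squared Euclidean, 10 restarts, seeded) on the CVs.
Cluster labels are arbitrary, so clusters are renumbered by descending
population (ties broken by ascending first-CV coordinate of the center),
making runs comparable. Defaults for k mirror the systems: 3 (three-well), 4
(four-well), 2 (polymer), with a fine-grained k = 20 mode. A uniform-binning
mode along a 1D CV (default 30 bins) supports 1D free-energy reconstruction.

Training segments: n_s random contiguous segments (seeded), each split
train/validation (default 60/20 of the segment, with the trailing 20% share
of the source sequence serving as held-out continuation); the generation
prompt is the trailing block (default 64 tokens) of the segment.

## Decoder-only transformer

Token embedding (d-dimensional) plus fixed sinusoidal positional encoding
PE(k, 2i) = sin(k/10000^{2i/d}), PE(k, 2i+1) = cos(k/10000^{2i/d}); N_b
residual blocks of masked multi-head self-attention (Q = XW_q, K = XW_k,
V = XW_v; scores QKᵀ/√d_h per head, d_h = d/N_h, strictly causal mask) and a
4d-wide ReLU feed-forward layer; pre-norm residual placement (post-norm
available); final layer norm and a linear head whose softmax gives the
next-token distribution. Loss is the autoregressive cross-entropy
−(1/T)Σₜ log p(O(t+1)|O(≤t)).

Numerical choices: Adam with gradient clipping at global norm 1; per-head
√(d/N_h) scaling (the literal √d reading is a config option); dropout 0 by
default (tiny vocabularies, long training). One "epoch" of the trainer is
one Adam step on a batch of windows (block_size+1 tokens) sampled
length-weighted from the training segments — the appropriate unit at these
data sizes; epoch counts in presets are chosen so the validation loss has
saturated. Forward and backward passes are hand-written numpy; a
finite-difference gradient check runs in the test suite for every
norm-placement × ablation variant.

Desk-scale presets (d = 32, N_h = 4, N_b = 2, block 16–32, 1500–2000 steps,
batch 32–64) are sized so every end-to-end run fits single-CPU budgets; for
rare-transition data the step budget matters: the cross-entropy equilibrium
calibrates P(rare transition) to its empirical frequency only after the
optimizer has seen enough transition examples (~2000 steps for rates of
order 5×10⁻⁵ here; at 500 steps the rate is overestimated several-fold).

The attention-ablated variant removes the attention sublayer (norms and
feed-forward retained), severing every cross-token path: logits at position
t then depend on token t only, which the tests verify by perturbation.

Attention maps for analysis are the raw pre-softmax masked scores averaged
over heads, blocks, and sampled sequence chunks; masked entries are reported
as zero.

## Generation

Pure multinomial sampling at temperature 1 from the model's next-token
distribution at the end of the context, with a sliding window capped at
block_size. Ensembles: one continuation per (model, prompt), member seeds
spawned from a master seed via `SeedSequence`. A batched path generates many
continuations from one model in lockstep at nearly the cost of one. A
structural property (asserted in tests): generated tokens can never leave
the training vocabulary.

## Kinetic validation

* **State probabilities**: occupancy frequencies per ensemble member, then
  mean ± standard error over members.
* **Commit-time transition counts**: the token sequence is decomposed into
  maximal constant runs; a transition i→j is counted at commit time τ when a
  run of i immediately precedes a run of j and min(Lᵢ, Lⱼ) ≥ τ (symmetric
  dwell rule; the pre-dwell-only rule is a config option, and the choice is
  recorded in curve metadata). Curves are non-increasing in τ, and at τ = 1
  the counts over all ordered pairs sum to the number of token changes. The
  commit grid defaults to 1…99th percentile of run lengths. When curves from
  sequences of different lengths are compared they are rescaled to counts
  per 10⁴ frames.
* **Curve agreement** (`compare_curves`): fraction of grid points with
  |actual − generated| ≤ 3 pooled standard errors, plus the maximum z.
* **Detailed balance**: per unordered pair, z(τ) = (F−B)/√(F+B) with F, B
  the total forward/backward counts pooled over members (the Skellam/Poisson
  z-score for a flux imbalance); a pair is flagged above |z| = 3. A
  member-scatter standard error is *not* used: it reports false certainty
  from the deterministic ±1 run-pairing artifact of alternating sequences
  and diverges when every member shows the same single one-way event.
* **1D free energy**: histogram → probability → F = −kT ln P, shifted so
  min F = 0; empty bins are masked, never interpolated. For a driven system
  this is an effective (occupancy) free energy, not a thermodynamic one.

## Baselines

* **Markov state model**: sliding-window transition counts at lag τ,
  restricted to the largest strongly connected state set (dropped states
  reported); non-reversible estimate is row-normalized counts; reversible
  estimation by iterative proportional fitting is optional (default off — the
  detailed-balance assumption is exactly what the active-system comparison
  interrogates). Implied timescales tᵢ(τ) = −τ/ln λᵢ(τ) with non-real or
  non-positive eigenvalues flagged rather than dropped; automated lag
  selection picks the smallest τ whose slowest timescale changes < 10% on
  doubling. The Chapman–Kolmogorov test compares [T(τ)ᵏ]ᵢᵢ with directly
  estimated [T(kτ)]ᵢᵢ under block-bootstrap bands. Generated sequences carry
  dt_per_frame = lag × source dt — an MSM at lag > 1 cannot emit
  finer-grained sequences, which is exactly its handicap in the comparison.
* **LSTM**: single recurrent layer (hidden width = the transformer's d),
  same embedding size, same window-sampling trainer, and the same
  forward/generate contract, so every kinetics metric applies unchanged.

## Synthetic fixtures with known ground truth

* `markov_chain`: tokens from a known T (oracle for parameter recovery).
* `periodic`: zero-entropy cyclic source (oracle for the loss → 0 limit).
* `second_order`: xₜ = (xₜ₋₁ + xₜ₋₂) mod 3 with probability p (default 0.9),
  else uniform. Its lag-1 conditionals are exactly uniform, so any
  context-blind model (ablated transformer, lag-1 MSM) is capped at ln 3
  nats while a two-token context makes the source nearly deterministic —
  the maximally discriminating fixture for the attention ablation. A caveat
  discovered while testing: the additive structure also makes *all* lag-k
  marginals uniform, so the Chapman–Kolmogorov self-transition test cannot
  detect this particular non-Markov process; the CK violation test uses a
  semi-Markov (deterministic dwell) process instead.
* `toy_traj`: a short three-well BD trajectory.

## Known limitations

* Desk-scale active-chain sampling is one-way (spiral→extended); statements
  about the reverse flux rest on its absence, not on measured rates.
* The transformer and LSTM trainers are numpy-based and single-threaded; the
  presets are sized for minutes-per-model, not for the larger vocabularies
  (k = 20) at full trajectory lengths.
* MSM bootstrap bands use contiguous-block resampling, which underestimates
  uncertainty when dwell times approach the block length.
* Passing tests on the synthetic systems demonstrates the machinery end to
  end; real molecular trajectories bring featurization and CV-quality
  questions (e.g. low FVE on disordered systems) the toy systems do not.
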