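# Methods

## The model

`selfishherd` implements an agent-based rendering of Hamilton's selfish-herd
hypothesis in which the motional strategy is *learned* rather than imposed.
N disk-shaped agents of diameter σ (the length unit) move on an unbounded
plane. The predation risk of agent *i* is taken proportional to the area
A_i of its Voronoi cell — the *domain of danger* (DOD) — bounded by a disk
of cutoff radius δ around the agent, so an isolated agent has the maximal
area A_max = πδ² and the smallest conceivable cell is the body area
A_min = π(σ/2)².

Each time step Δt every agent chooses one of four actions: move straight
forward (0.25 σ), turn left or right along an arc of radius 0.8 σ through
18° (the arc length again ≈ 0.25 σ), or stand still. Motile actions carry
multiplicative Gaussian noise (s.d. 20 % of the action magnitude); standing
still is noise-free. All agents move synchronously; afterwards hard-disk
overlaps are removed by iterative symmetric projection of overlapping pairs
back to contact distance (an overdamped, parameter-free collision step).

The agent's only input is a five-component observable: a 180° vision cone
ahead of the heading split into five 36° sectors; every visible neighbour j
adds σ/|r_ij| to the sector holding the bearing of its centre. A neighbour
is invisible when the sight line to its centre passes within σ/2 of a
strictly nearer agent's centre (binary, full-disk occlusion), or when it is
outside the cone. Bearings exactly on a sector boundary go to the more
counter-clockwise sector; the cone is closed at ±90°.

The per-step reward is

    r = r_SHH + r_prox,
    r_SHH(A) = (A_max − A)/(A_max − A_min)           (linear in the DOD),
    r_prox(d) = −c [1 − tanh((d − d0)/w)]            (proximity penalty),

with d the nearest-neighbour distance, weight c = 0.375, threshold d0
(1.0 σ or 1.5 σ — the switch between strongly and weakly rotating groups)
and crossover width w = 2 σ. The printed form of the tanh argument is
ambiguous between (d−d0)/2 and 2(d−d0); we adopt the smooth, wide reading
(d−d0)/2 and expose w as a configuration knob so the narrow reading is one
line away. r_SHH is clipped to [0, 1] because transient overlap resolution
can momentarily produce A < A_min. Totals are bounded in [−2c, 1].

## Exact cutoff-Voronoi geometry

No installed geometry library computes the area of a Voronoi cell
intersected with a *true* disk, so the package computes it in closed form:
each agent's cell is built by Sutherland–Hodgman clipping of a bounding
square with the perpendicular-bisector half-planes of all neighbours closer
than 2δ (neighbours beyond 2δ cannot affect the disk), and the area of that
convex polygon intersected with the cutoff disk is evaluated by Green's
theorem — triangle contributions for boundary pieces inside the disk,
circular-sector contributions outside. This is exact to floating-point
round-off, is robust for collinear configurations that break general-position
Voronoi constructions, and costs O(k²) per agent for k in-range neighbours.
Adjacency holds for pairs whose shared bisector edge has positive length
inside both cutoff disks (a formally shared edge far outside δ is not a
behavioural neighbourhood). Tests cross-check the areas against a
Monte-Carlo rejection-sampling oracle and an independent polygonal
approximation built with shapely.

Geometric tolerances: polygon clipping uses an absolute tolerance of 1e−9 σ;
pairwise distances below 1e−9 σ raise a degenerate-tessellation error.

## Learning algorithm

Training follows centralized training / decentralized execution: a single
actor network (5 → 64 → 64 → 4, tanh hidden layers, softmax head) maps each
agent's own observable to action probabilities, and one critic of the same
shape provides a state-value baseline. Networks, backpropagation and the
Adam optimiser are implemented in numpy; the networks are small enough that
a full training run is a single-CPU job.

Training is episodic. Each episode starts from a fresh random configuration
(positions uniform in a box with pairwise distance ≥ σ, headings uniform)
and runs the observe → policy → sample → step → reward loop for every agent.
The pooled batch of (observable, action, discounted return) tuples over all
agents and steps is then revisited for a few epochs of minibatch Adam
updates. Because the batch becomes off-policy after the first update, the
policy gradient uses the proximally clipped importance-ratio surrogate
(ratio clip 0.2); with a fresh batch the ratio is one and the update reduces
to the plain advantage policy gradient. Advantages (return − baseline) are
standardised per minibatch; gradients are clipped to global norm 1; an
entropy bonus (weight 0.01) discourages premature collapse. Defaults:
γ = 0.99, learning rate 1e−3, minibatch 8192, 4 epochs per episode. The
full-scale schedule is 30 episodes × 3000 steps × 100 agents = 9×10⁶
individual actions.

A two-armed-bandit check (one action pays 1) verifies the policy gradient
end to end: the rewarded arm exceeds probability 0.99 within 500 updates.

## Analysis statistics

* **MSD**: time-averaged mean squared displacement per agent and ensemble,
  optionally after removing the per-frame group centroid (isolating
  intra-group motion). Saturation onset is the smallest lag reaching 95 % of
  the long-lag plateau (mean over the last decade of lags).
* **Rotational order** O_R = |Σ_i (r̂_i × û_i)·ẑ| / N with r̂ the unit
  vector from the group centroid and û the heading. The per-agent-absolute
  variant (mean of |r̂ × û|, baseline 2/π for random headings) is exposed as
  an option; the signed-sum form, whose random baseline is ~1/√N, is the
  primary definition because only it makes "weak rotation ≈ 0.1"
  distinguishable from noise.
* **Spatial rotation map** O*_R(r): the signed cross product averaged per
  square grid cell in the centroid-centred frame over a trailing window;
  cells with fewer than 5 visits are missing. Being centroid-relative, the
  map resolves a central vortex at full magnitude but shows off-centre
  vortices with the correct sign at reduced magnitude.
* **Cumulative DOD** Ā_i(τ): prefix mean of each agent's DOD series; its
  across-agent interquartile range divided by the ensemble mean
  (`risk_spread`) is the risk-sharing statistic — it decays towards zero
  when time-averaged predation risk equalises.
* **DOD autocorrelation**: each agent's series is mean-removed and
  normalised by its own sum of squares (ACF(0) = 1), then averaged over
  agents. This is the standard windowed (biased) estimator, carrying the
  (1 − τ/T) envelope; agents whose DOD is constant to ~1e−9 relative are
  excluded. The correlation time is the first lag below 1/e.
* **Neighbour persistence** p_NN(τ): mean fraction of an agent's
  cutoff-Voronoi neighbours still adjacent after lag τ; agents with empty
  neighbour sets at the reference time are skipped; p_NN(0) = 1.

## What the fixtures emulate

Deterministic generators (lattice, tangential ring, rigidly rotating mill,
re-scattered gas, mirrored two-vortex pair) provide known-answer inputs for
these statistics. A rigidly rotating *circular* mill has constant DODs — its
ACF is deliberately undefined — so the rigid-versus-mixing discrimination
test uses a uniformly breathing rotating ring, which keeps the Voronoi
topology exactly (p_NN ≡ 1) while its periodic DOD signal recurs to the
estimator envelope without decay. None of the fixtures emulate learned
behaviour; they validate the measurement code, not the learning.

## Problem sizes

The default configuration reproduces the full study scale and takes on the
order of an hour of single-CPU time per training run via the CLI. The test
suite and the acceptance script run a scaled-down rendition chosen as the
smallest herd that still aggregates and mixes: 10–20 agents, 300–800-step
episodes, 5–12 episodes, box side scaled to keep the initial density
comparable (box ∝ √N), γ = 0.95 (horizon matched to the shorter episodes)
and 8 update epochs per episode. At this scale training reliably beats the
random-policy baseline and the group forms a compact, dynamically mixing
cluster, but the sharp strongly/weakly-rotating distinction of the
full-scale system (O_R ≈ 0.6 vs ≈ 0.1) is only partially developed; the
scaled-down numbers reported by the acceptance script are therefore
qualitative cousins, not replicas, of the full-scale values.

## Known limitations and open choices

* The noise model is multiplicative on the action magnitude, with an extra
  heading wobble of s.d. 0.2 × 18° on forward moves so that all motile
  actions have a rotational noise component; standing still is noise-free.
* Collisions are resolved by hard projection, not a force law; dense
  transients may need several sweeps and are capped at 100 (a warning, not
  an error).
* Occlusion is binary (full-disk blocking of the centre line); no partial
  visibility.
* The update cadence, network size, γ and learning rate are free
  hyperparameters of the method; the defaults above are logged into every
  artifact via the config hash.
* Boundary conditions are an unbounded plane; there are no walls or
  predators.
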