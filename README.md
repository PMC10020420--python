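# selfishherd

Multi-agent reinforcement learning for Hamilton's selfish herd: disk agents
on a plane learn — by shared-experience policy gradient — to minimise their
Voronoi **domain of danger** (DOD), and the package quantifies the collective
states that emerge (cohesive rotating groups) and the long-time sharing of
predation risk among selfish individuals.

## The problem and who this is for

The selfish-herd hypothesis proposes that animal aggregations form because
each individual selfishly reduces its own predation risk, measured by the
area A of its Voronoi cell: a predator is assumed to strike the nearest
prey, so a small cell means a small danger zone. Classic agent-based studies
impose hand-written movement rules; here the behaviour is *learned* as the
(approximately) optimal policy of a reinforcement-learning problem, so the
emergent group dynamics is an unbiased consequence of risk minimisation.
The package is aimed at researchers in collective behaviour and active
matter who want a reproducible, single-CPU testbed for selfish-herd
dynamics with a full analysis toolchain.

## The model in brief

* N agents, disks of diameter σ, unbounded plane. Actions per step Δt:
  forward 0.25 σ, turn left/right along an arc of radius 0.8 σ through 18°,
  or stand still; 20 % multiplicative Gaussian action noise; hard-disk
  overlaps projected back to contact.
* Observable: a 180° vision cone split into five 36° sectors; each visible
  neighbour j adds σ/|r_ij| to its sector; nearer agents occlude
  (full-disk sight blocking).
* Reward: r = r_SHH + r_prox with
  r_SHH = (A_max − A)/(A_max − A_min), A_max = πδ² (cutoff δ = 10 σ),
  A_min = π(σ/2)², and r_prox = −c[1 − tanh((d − d0)/w)] penalising
  nearest-neighbour distances d below d0 (c = 0.375, w = 2 σ).
* Learning: centralized training, decentralized execution — one shared
  actor (5→64→64→4 MLP, softmax) and critic baseline trained per episode on
  the experience pooled over all agents; proximally clipped policy-gradient
  updates in numpy. Defaults: 30 episodes × 3000 steps × 100 agents.
* Analysis: MSD, rotational order O_R = |Σ r̂×û|/N and its spatial map,
  median DOD, cumulative per-agent DOD, DOD autocorrelation, neighbour
  persistence p_NN(τ).

With d0 = 1.0 σ the trained herd forms a strongly rotating single vortex;
with d0 = 1.5 σ a weakly rotating group with transient local vortices. In
both, individuals keep trading places between centre and edge until their
time-averaged DODs — their predation risks — equalise.

## Worked example

```python
import numpy as np
from selfishherd import RunConfig, SelfishHerd

cfg = RunConfig(n_agents=20, steps_per_episode=600, n_episodes=12,
                box_side=18.0, gamma=0.95, minibatch=512, epochs=8, d0=1.0)
res = SelfishHerd(cfg).fit(seed=2)
print(res.summary())
traj = res.simulate(n_steps=800, seed=3)
stats = res.ness_statistics(traj, burn_in=200)
print({k: round(v, 3) for k, v in stats.items()})
```

prints (a few minutes on one CPU; numbers vary with the seed):

```
Selfish-herd MARL fit
==========================================================
agents:    20    episodes:    12    steps/episode: 600
reward: c=0.375, d0=1.0 sigma, delta=10.0 sigma
kinematics: step 0.25 sigma, turn 18.0 deg @ R=0.8 sigma, noise 20%
seed: 2    config hash: 1d0afeb58fe8
----------------------------------------------------------
mean reward:  first episode +0.3421   final episode +0.5607
median DOD :  first episode   270.13   final episode     5.37  (sigma^2)
final entropy of policy: 1.209 nats
==========================================================
{'mean_reward': 0.56, 'median_dod': 6.814, 'rotational_order': 0.291,
 'rotational_order_se': 0.005, 'acf_correlation_time': 18.0,
 'pnn_half_lag': 36.0, 'risk_spread_initial': 1.678,
 'risk_spread_final': 0.312}
```

Reading the output: the median DOD collapses from ~270 σ² (scattered start)
to ~5 σ² (compact group) as training proceeds; the rollout's rotational
order ~0.29 indicates a collectively rotating group at this reduced scale;
the risk spread — the across-agent IQR of cumulative mean DODs over the
ensemble mean — decays from 1.68 to 0.31, i.e. time-averaged predation risk
converges across individuals.

The same pipeline is available from the shell:

```bash
selfherd train   --config cfg.yaml --seed 1 --out run/
selfherd rollout --config cfg.yaml --policy run/policy.npz --seed 2 --steps 3000 --out roll/
selfherd analyze --trajectory roll/trajectory.npz --out stats/
selfherd sweep   --seed 1 --c-values 0.375 --d0-values 1.0,1.5 --out sweep/
```

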