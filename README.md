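# paraspec

Tools for tracing how a duplicated bacterial two-component signaling
system evolves interaction specificity.

Two-component systems pair a sensor histidine kinase (HK) with a cognate
response regulator (RR): the kinase autophosphorylates and passes the
phosphoryl group to its partner, and a handful of residues at the
HK–RR interface decide which partner that is.  When an HK–RR operon
duplicates, the two daughter systems start out fully cross-reactive and
must accumulate mutations that insulate them from each other.  `paraspec`
implements the computational arc of studying such an event — exemplified
by the EnvZ–OmpR duplication in the α-proteobacteria — as a reusable,
fully tested pipeline:

* **pairing** — match cognate HK–RR pairs from genome gene order
  (adjacent genes pair; ambiguous HK/RR clusters and orphans are
  dropped) and merge each pair into one concatenated record;
* **phylo_likelihood** — Felsenstein pruning on a fixed tree with the
  empirical LG or Poisson amino-acid models, discrete-gamma rate
  heterogeneity, AIC model comparison, and outgroup rooting;
* **ancestors** — marginal (empirical-Bayes) ancestral sequence
  reconstruction: per-site posteriors at internal nodes, MAP ancestors
  with mean-posterior confidence, ambiguous sites (two residues with
  posterior > 0.2), and "AltAll" alternative ancestors that swap in the
  second-most-likely residue at every ambiguous site;
* **paralog_profiles** — per-clade residue frequencies, calls of
  paralog-specific positions (a residue or chemical class ≥ 90 % in one
  clade and ≤ 10 % in the other), occupancy/conservation trimming,
  reference-numbering maps, and mutation bookkeeping (`R27Q`, …);
* **kinetics** — phosphotransfer time-course analysis: normalization to
  t = 0, the two-point initial-rate window estimator (30 s for cognate
  pairs, 5 min otherwise), a log-linear decay estimator, and
  specificity-constant ratios.  With regulator in excess, phospho-HK
  decays roughly as `exp(-(k_cat/K_M)[RR] t)`, so rate ratios under
  matched conditions estimate k_cat/K_M ratios — the per-protein
  fold-preference;
* **synthetic_data** — generators for every input: sequence evolution
  along trees with known ancestral truth, duplication scenarios with
  planted clade-diagnostic residues, genome gene tables, and mass-action
  phosphotransfer curves with lognormal gel noise.

## Worked example

```python
import numpy as np
import paraspec as ps

# simulate a duplication: two 48-leaf paralog clades separated by a long
# stem, with diagnostic residues planted at columns 27 and 29
tree = ps.duplication_tree(n_leaves_per_clade=48, mean_branch_length=0.1,
                           stem_length=0.25, seed=7)
scenario = ps.DuplicationScenario.at_root(
    tree, [(27, {"R"}, {"Q", "E", "S"}), (29, {"D", "E"}, {"A"})])
model = ps.lg_model(gamma_shape=1.0, n_categories=4)
sim, clades = ps.plant_duplication(scenario, model, n_sites=300, seed=7)

# reconstruct the pre-duplication ancestor at the root
post = ps.marginal_posteriors(tree, sim.leaf_alignment, model, [tree.root_id])[0]
anc = ps.map_ancestor(post)
truth = sim.ancestral_truth[tree.root_id]
accuracy = np.mean([a == b for a, b in zip(anc.map_sequence, truth)])
print(f"root ancestor: mean posterior {anc.mean_pp:.3f}, "
      f"true-state accuracy {accuracy:.3f}")

# which columns distinguish the paralog clades?
clade1 = [l for l, c in clades.items() if c == 1]
clade2 = [l for l, c in clades.items() if c == 2]
calls = ps.paralog_specific_positions(
    ps.position_frequencies(sim.leaf_alignment, clade1),
    ps.position_frequencies(sim.leaf_alignment, clade2))
print("paralog-specific columns:",
      sorted(c.position for c in calls if c.is_specific))

# kinetic fold-preference of the post-duplication kinase
courses = []
for pair, kt in [("HK2:RR1", 2.0e-4), ("HK2:RR2", 5.6e-3)]:
    params = ps.KineticParameters(transfer_rate_constant=kt,
                                  phosphatase_rate_constant=0.0,
                                  noise_sd=0.05, seed=1)
    times = np.array([0, 10, 30, 60, 120, 300, 600, 1200, 1800], float)
    courses.append(ps.simulate_phosphotransfer(params, times, pair=pair))
rates = [ps.fit_decay_rate(tc) for tc in courses]
ratio = ps.specificity_ratio(rates[1], rates[0])
print(f"HK2 prefers {ratio.direction.split(':')[1]} "
      f"{ratio.fold:.1f}-fold (planted: 28)")
```

prints

```
root ancestor: mean posterior 0.803, true-state accuracy 0.783
paralog-specific columns: [27, 29, 290]
HK2 prefers RR2 26.5-fold (planted: 28)
```

The mean posterior of ~0.8 is typical for an ancestor this deep, and
note it tracks the realized accuracy — the posteriors are calibrated.
Profiling recovers both planted diagnostic columns; the extra call at
column 290 is a residue that drifted to fixation on the long
post-duplication stem, the irreducible background such scans have.  The
kinase's 26.5-fold measured preference recovers the planted 28-fold
k_cat/K_M ratio from noisy simulated gel quantifications.

A command-line interface mirrors the library
(`paraspec simulate|pair|lnl|modelselect|asr|profile|trim|mutate|kinetics|run`);
`paraspec run config.yaml --outdir out/` executes the whole pipeline
from a strict YAML config and writes a reproducibility manifest.

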