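# snailguild

Comparative life-history analysis for guilds of parasitic castrators
sharing one host.

A parasitic castrator (a trematode in a snail, say) takes over its
host's body: the host's residual reproductive value is zero, and
selection on how the stolen body is allocated between growth and
reproduction acts on the castrator. Where many castrator species
exploit the *same* host species, every species runs the same
physiological machinery in the same environment — a rare natural
setting for testing whether extrinsic mortality drives among-species
differences in allocation: higher mortality should select for less
growth and greater reproductive effort.

`snailguild` implements that analysis end to end for mark-recapture
shell-growth data, and ships a synthetic-data generator with exact
latent ground truth so every estimator can be validated against worlds
where the answer is known.

## What it computes

* **Shell geometry** — new-growth volume from aperture area
  (radius = width/4) times degrees-of-coiling/360; initial volume from
  a cone approximation; length ↔ volume via the cube-root scaling
  `volume^(1/3) = 0.326·length + 0.497` (refittable by OLS).
* **Growth model** — quasi-Poisson GLM of individual growth (mm³) with
  log link: group × initial size plus estuary, habitat[estuary],
  site[estuary, habitat] and growing-time[estuary] as fixed factors;
  per-term quasi-likelihood-ratio χ²; per-group size-specific growth
  curves, growth at the mean-sized snail, total growth allocation
  (∫ curve between common size limits), and all pairwise contrasts
  with Benjamini–Hochberg FDR control.
* **Differential extrinsic mortality** — for each species at each
  site, its prevalence among snails free of its dominants is applied to
  the snails carrying a dominant; minus observed co-infections, over
  total recruits: the fraction of recruits killed by dominant species
  (negative values flag facilitation). Pooled across sites weighted by
  observed prevalence. For uninfected snails: gender-specific
  castration risk.
* **Allocation indices** — gonadosomatic index (GSI), the combined
  female GSI (ovary + accessory reproductive tissue), and relative
  reproductive allocation RRA = GSI / proportional growth at the mean
  size ≡ reproductive mass / new-growth mass.
* **Inference** — permutation correlation tests (two-tailed,
  B = 100,000 by default), a two-stage permutation guard against the
  growth-in-the-denominator artifact, standard major axes, regression
  through the origin, a site-level plasticity F-test, and Felsenstein
  independent contrasts on a user-supplied unit-branch Newick tree.

## Worked example

```python
from snailguild import synthetic_data as sd, pipeline as pl

config = sd.default_config(n_snails_per_site=120, seed=42)
world = sd.generate_world(config)
manifest, out = pl.run_pipeline(world.records, config.hierarchy,
                                config.gsi, seed=7, iterations=10_000)

for key in ("species:growth_vs_mortality", "species:rra_vs_mortality",
            "species:rra_two_stage"):
    s = manifest.statistics[key]
    print(f"{key}: r = {s['r']:+.2f}, p = {s['p']:.4f} (n = {s['n']})")
```

prints (seed 42 world, seed 7 tests):

```
species:growth_vs_mortality: r = -0.90, p = 0.0012 (n = 10)
species:rra_vs_mortality:    r = +0.84, p = 0.0064 (n = 10)
species:rra_two_stage:       r = +0.84, p = 0.0009 (n = 10)
```

Total growth allocation falls with differential mortality (r = −0.90):
groups whose recruits are more often killed by dominant species — or,
for uninfected snails, castrated — allocate less to growth. Relative
reproductive allocation rises with mortality (r = +0.84), and the
two-stage guard confirms the positive relationship is not an artifact
of growth appearing in the RRA denominator. The plain GSI shows no such
relationship (r = +0.22, p ≈ 0.54) — standing-stock indices misrank
reproductive effort when growth allocation varies. The site-level
plasticity test on the same run (F₉,₁₂₈ = 0.89, p = 0.53) finds no
within-group growth response to local risk: the group differences
behave as fixed species differences, which is how the generator built
them.

The allocation table behind those tests (`out["allocation_table"]`)
carries one row per group: total growth allocation, growth at the
mean-sized snail (mm³), GSI, RRA and differential mortality — e.g. the
top dominant (`hime`: mortality 0.00, growth 15.2 mm³) versus uninfected
males (mortality 0.30, growth 5.4 mm³) in the run above.

A command-line interface wraps the same chain:

```bash
snailguild simulate --seed 42 --out-dir scratch/world
snailguild pipeline scratch/world/records.csv --seed 7 --out-dir scratch/run
```

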