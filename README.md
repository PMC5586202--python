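# sitefid

Site-centric detection of site fidelity in bounded animal habitats.

Animals confined to a small arena — the motivating case is ants moving
inside a flat 50 × 35 mm nest cavity, tracked at 10-minute intervals — tend
to return to particular places: the brood pile, the nest entrance, a
favourite wall. The classical way to test for such fidelity is *reductive*:
collapse the whole trajectory into one summary (the area it covers, here the
number of distinct grid cells visited, N_i) and compare that against
unbiased-movement expectation. Inside a bounded arena this fails badly,
because a walk that strongly prefers a few sites can still wander over a
normal-looking total area.

`sitefid` implements the *site-centric* alternative, aimed at movement
ecologists and social-insect researchers:

1. **Constrained random-walk (RW) null model.** Each trajectory is
   re-simulated by resampling its own empirical step-length and turn-angle
   distributions, starting from its first observed fix, rejecting steps that
   leave the nest, and re-imposing its exact missing-fix pattern. An
   ensemble of such replicates is an absolute "no spatial preference"
   standard that preserves everything else about the walk. (A
   location-shuffling null, which destroys the step/turn structure, is
   included as a baseline.)
2. **Per-site visitation statistics.** The nest is gridded into cells
   ("sites", default 3 × 3 mm). For each ant *i* and visited site *s* the
   package measures the number of uninterrupted visits n_is, the mean dwell
   time D̄_is, and the typical first return time R̄T_is. Return times are
   right-censored (the return after the last visit is never seen), so they
   are summarised by the restricted mean — the area under the Kaplan–Meier
   survival curve up to the largest observation.
3. **Significance testing.** Observed statistics are compared to their null
   ensemble distributions as z-scores, tested with two-tailed permutation
   p-values ((r+1)/(R+1) form), and corrected per ant and per metric with
   the Benjamini–Hochberg FDR procedure; sites are classified attracted /
   avoided / neutral / untestable. The reductive N_i test is provided for
   comparison.
4. **Spatial-overlap networks.** Pairwise space-use similarity is the
   volume of intersection VI_ij = Σ_s min(p_i(s), p_j(s)) between
   normalized visit distributions (1 = identical use, 0 = disjoint).
   Spin-glass modularity partitioning of the VI-weighted colony graph
   yields communities with distinctive space use; the community containing
   the queen is labelled "nurse".
5. **Return-dynamics survival model.** A Cox proportional-hazards model of
   the (censored) time to return to a site, with the previous visit's dwell
   time, caste, community and the site's brood counts as predictors. A
   dwell hazard ratio above 1 — long stays followed by fast returns — is
   the statistical signature of a self-attracting walk, i.e. history-
   dependent, non-Markovian movement. Cluster-robust and shared-frailty
   (mixed-effects) variants are built in, with AIC-based selection.
6. **Simulators.** Unbiased correlated walks, centre-biased walks, and
   self-attracting lattice walks, assembled into whole synthetic colonies
   (queen + workers, missing fixes, brood censuses) with ground-truth
   labels for benchmarking the detectors.

## Worked example

A single centre-biased walker (bias weight w = 0.3) analysed against 4,000
RW-null replicates:

```python
import numpy as np
import sitefid as sf

geometry = sf.NestGeometry(width=50, height=35, entrance_xy=(25, 0))
grid = sf.make_grid(geometry, cell_size=3.0)

rng = np.random.default_rng(2)
spec = sf.WalkerSpec(model="biased", w=0.3, attractor=(25.0, 17.5))
traj = sf.simulate_biased_walk(spec, geometry, rng, ant_id="W01")

stats, tests, reductive = sf.analyse_trajectory(
    traj, geometry, grid, n_reps=4000, seed=7
)
```

Output:

```
sites visited (N_i):      64
reductive class:          neutral (null 2.5-97.5%: 59-107)
attracted sites (visits): 8
strongest site:           cell (8,5), n=15 visits vs null mean 0.9, z=12.5, q=0.0160
```

The walker covers 64 distinct cells — squarely inside the null range
(59–107), so the area-based reductive test calls it *neutral*. The
site-centric tests nevertheless flag 8 cells as significantly over-visited
after FDR correction; the strongest, the cell at the attractor, received 15
visits against a null expectation of 0.9 (z = 12.5). This is exactly the
false-negative mode of area-based testing that the site-centric framework
repairs.

## Command line

```bash
sitefid simulate --colonies 2 --workers 15 --seed 1 data/
sitefid all --reps 10000 --seed 1 --brood data/brood.csv data/traj.csv out/
```

`out/` then contains `site_tests.csv` (per ant × site × metric), per-ant
`summary.csv` (N_i, n̄_i, D̄_i, R̄T_i, reductive class, attracted/avoided
counts), one GraphML network per colony, `community_map.csv`,
`cox_table.csv` (predictor, HR, SE, z, p) and a `manifest.json` recording
seeds, parameters and output checksums. `sitefid nulls`, `fidelity`,
`network` and `returns` expose the individual stages.

Input format: long CSV with columns `colony,ant,tick,x_mm,y_mm,caste`
(empty x/y = missing fix); brood censuses as
`colony,census_tick,stage,x_mm,y_mm`.

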