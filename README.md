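# cisweep

Discrete-generation frequency dynamics, inference and field statistics for
maternally inherited endosymbionts (e.g. *Wolbachia*) that combine imperfect
maternal transmission, host-fitness effects and cytoplasmic incompatibility
(CI).

The package covers:

- **`cisweep.dynamics`** — one- and two-strain recursions for the three
  cytoplasm classes (uninfected, non-CI strain A, CI strain R), interior
  equilibria with stability classification (Fisherian / bistable /
  no-invasion regimes), and rare-invasion conditions.
- **`cisweep.inference`** — scalar root-solves for the relative fecundity
  implied by an observed frequency change, (mu, F) sensitivity grids, the
  minimal CI-strain fecundity needed to displace a resident strain within a
  time horizon, and year/generation conversion.
- **`cisweep.field_stats`** — exact (Clopper–Pearson) binomial confidence
  intervals, pooled frequency estimates, log-likelihood-ratio (G) tests of
  heterogeneity, and transmission-leakage estimation with a line-level
  percentile bootstrap.
- **`cisweep.hitchhike`** — joint infection/mtDNA-haplotype recursions
  demonstrating hitchhiking sweeps of infection-associated haplotypes
  through the uninfected class.
- **`cisweep.wave`** — a minimal 1-D deme-lattice simulator contrasting
  bistable and Fisherian spatial spread (deterministic local dynamics,
  nearest-neighbour migration, optional seeded long-distance jumps).
- **`cisweep.synth`** — synthetic survey tables (multinomial sampling from
  model trajectories) and isofemale-line tables (beta-binomially
  overdispersed leakage), fully seeded.

## CLI

The console script `cisweep` exposes five subcommands:

```bash
# two-strain trajectory (flags or a key=value --config file)
cisweep simulate --FA 1.061 --muA 0.023 --FR 1.08 --muR 0.045 --H 0.55 \
    --p0A 0.54 --p0R 0.09 --gens 45 --out traj.csv

# fit F from the first/last rows of an observations CSV (p,year[,n,site])
cisweep fit --observations obs.csv --gens-per-year 20 --mu 0.023

# survey statistics
cisweep stats --mode ci --x 8 --n 350
cisweep stats --mode gtest --survey survey.csv
cisweep stats --mode mu --lines lines.csv --boot 10000 --seed 1

# 1-D lattice spread, per-generation snapshots as CSV
cisweep wave --FA 1.0 --muA 0 --FR 1.1 --muR 0.045 --H 0.55 \
    --demes 60 --m 0.1 --gens 300 --out wave.csv

# synthetic datasets (CSV plus a JSON sidecar recording design and seed)
cisweep synth --what survey --seed 1 --out-prefix survey \
    --FA 1.061 --muA 0.023 --FR 1.08 --muR 0.045 --H 0.55
cisweep synth --what lines --seed 1 --out-prefix lines --mu 0.023 --rho 0.1
```

Trajectory CSVs have header `generation,p_A,p_R,p_O`; lattice CSVs
`generation,deme,p_A,p_R,p_O`.

## Notes

- Published-figure comparisons round half-away-from-zero at the printed
  precision (3 dp for frequencies/fecundities, 2 dp for equilibria).
- The sensitivity-grid labelling of the three (mu, F) combinations follows
  the order in which they are introduced in the source analysis; the
  original figure does not label its curves explicitly.
- The unstable equilibrium at (F=0.95, mu=0.045, H=0.55) computes to
  ≈0.232; the widely quoted rounded figure is 0.22. The package reports
  the computed value.
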