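# Methods

## The model

`lvcoex` analyses two-species competition microcosms — the motivating
system is the bactivorous ciliates *Colpidium striatum* (species 1) and
*Paramecium aurelia* (species 2) feeding on *Bacillus subtilis* — with the
classical Lotka-Volterra competition model

    dN1/dt = r1 N1 (1 − (N1 + a12 N2)/K1)
    dN2/dt = r2 N2 (1 − (N2 + a21 N1)/K2)

where state is **total biovolume per microcosm** (µm³). Biovolume, not
numbers, is the biomass proxy throughout: the two ciliates differ roughly
1.7-fold in per-cell volume, so cell counts alone misstate resource use.
Carrying capacity K is the monoculture steady state; a12 is the per-unit
effect of species 2's biovolume on species 1. Neutral (ecologically
equivalent) competition is a12 = a21 = 1.

At an interior equilibrium the zero-growth conditions are linear,

    N1* + a12 N2* = K1,     N2* + a21 N1* = K2,

so with monoculture steady states for K1, K2 and coexistence steady states
(C1, C2) the coefficients invert in closed form:

    a12 = (K1 − C1)/C2,     a21 = (K2 − C2)/C1.

This inversion is exact whenever the observed state lies on the focal
species' zero-growth line; it does not require the interior equilibrium to
be unique or even attracting. That matters here: with a12·a21 near 1 the
two nullclines are nearly parallel, the interior equilibrium (when it
exists) is approached along a very slow manifold, and the community
observed on days 8–14 is best understood as a quasi-steady state *on* the
nullclines whose position along them still reflects initial conditions.
The coefficient estimates are insensitive to that position, which is why
near-neutral systems remain estimable at a 15-day horizon.

These coefficients lump exploitation (niche overlap) and interference
competition into a single number; no decomposition is attempted.

## Relative-yield-total geometry

Normalizing each species' coexistence biovolume by its monoculture value,
y_i = C_i/K_i, maps both monoculture states to 1; the segment y1 + y2 = 1
(the RYT line) connects them. Regions, tested in this order:

1. **positive_interaction** — some y_i > 1 (a species does better with a
   competitor than alone). With bootstrap CIs available the rule is
   conservative: the yield's lower 95% bound must exceed 1 (a
   point-estimate mode is provided, and is the default for bare
   literature values).
2. **on_ryt** — |y1 + y2 − 1| ≤ band half-width.
3. **overyield_area_A** — y1 + y2 > 1 with both y_i ≤ 1, the triangle that
   resource partitioning is expected to reach.
4. **below_ryt** — otherwise.

The band half-width is the half-width of the 95% bootstrap interval of
y1 + y2 − 1, i.e. the uncertainty of the RYT perimeter implied by the four
steady-state SEs. For symmetric competition (K1 = K2, a12 = a21 = a < 1)
the equilibrium yields are 1/(1+a) each, so RYT = 2/(1+a) — the closed
form used as an oracle in the tests. At a = 1 the equilibrium is
degenerate (a line of fixed points); the code signals this explicitly
rather than classifying silently.

## Steady-state extraction

Replicate-first averaging: each replicate's observations inside the window
are time-averaged, then the cross-replicate mean and SE (SD of replicate
means / √n) are reported. The SE therefore measures replicate-level
variation — the level at which treatments are randomized — not
within-replicate sampling noise. The default window is days 8–14;
whether the published ±-values for Table-style summaries are replicate- or
sample-level is rarely stated, and replicate-level is the defensible
default for experiments with repeated measures. The window is a plain
parameter (the oxygen measurements of the motivating study, for example,
started on day 10).

## Uncertainty: the parametric bootstrap

Each steady-state mean is drawn from its sampling distribution, both
coefficients (or yields) are recomputed per draw, and 2.5/97.5 percentiles
give the CI (n_boot = 10,000, seeded). Draws with non-positive
denominators are rejected and redrawn; the rejection count is reported and
a warning is emitted above 1% of draws.

Three draw schemes are available; the choice matters at n = 6 replicates:

- `normal` — Gaussian with the plug-in SE. Treats the SE as known; with
  SEs estimated from 5 df this undercovers (≈87–88% measured against the
  generator at the default design).
- `t` — each quantity drawn as mean + SE·t₅. Overcorrects, because the
  target statistic combines three (or four) independent uncertain
  quantities, and by the CLT their combination needs less tail inflation
  than each component alone (≈99% measured).
- `welch` (default) — Gaussian draws whose deviations are expanded by
  t_{df_eff}(0.975)/z(0.975), with df_eff from the Welch–Satterthwaite
  rule applied to the delta-method variance decomposition of the target.
  Measured coverage 95.4% over 500 synthetic experiments.

A first-order delta-method CI is provided as an independent cross-check;
it agrees with the `normal` bootstrap to ~2% when SEs are small relative
to means.

## The synthetic experiment generator

The generator emulates the design of the motivating experiment: four
treatments (each ciliate alone, both together, bacteria only) × 6
replicates, 5 mL microcosms, 15 days, sampling and medium exchange
(0.2 mL of 5 mL, a ×0.96 dilution) on a Mon/Wed/Fri pattern
(days 1, 3, 5, 8, 10, 12, 15), inocula of 5 individuals per species.
Samples are recorded immediately *before* each exchange, since the
extracted aliquot is what gets counted.

Latent dynamics are the deterministic LV model integrated with adaptive
RK45 (rtol/atol 10⁻⁸) between instantaneous dilution events; there is no
process noise, so all replicates of a treatment share one latent
trajectory and differ only in observation noise. Observation noise has two
parts: (i) counting noise — Poisson on the number of cells in the counted
aliquot, using the density-scaled protocol (whole dish ≤ 10 cells/mL,
0.2 mL for 10–50/mL, 0.1 mL above); (ii) per-cell-volume noise — the
factor converting counts to biovolume is drawn from a lognormal with the
species' mean cell volume and the SE of that mean.

Calibration. Monoculture and coexistence biovolumes are anchored at
K₁ = 8.44×10⁷ µm³ and (C₁, C₂) = (3.53×10⁷, 4.09×10⁷) µm³, and per-cell
volumes at 5.04×10⁴ (n = 81) and 8.56×10⁴ µm³ (n = 86) — the scale of the
study system. Quantities the data cannot pin down were fixed once at
realistic values:

- growth rates r1 = r2 = 1.5 day⁻¹ — typical for well-fed ciliates and
  sufficient to reach steady state by day 8 from a 5-cell inoculum;
- a21 = 0.8 (the Colpidium-on-Paramecium coefficient is not identified by
  the published monoculture values); K₂ := C₂ + a21·C₁ = 6.92×10⁷ µm³ then
  places a stable interior equilibrium exactly at (C₁, C₂). The implied
  a12 = (K₁−C₁)/C₂ = 1.2;
- the printed ± values for cell volumes are read as SEs of the mean
  (despite an "(SD)" label in the source summaries) because only that
  reading reproduces the t ≈ 10 group contrast; the SD reading gives
  t ≈ 93. Both readings are selectable (`dispersion_is`).

Bacterial prey are generated as a separate observable, not a dynamically
coupled resource: the LV carrying capacities already absorb resource
supply (fresh bacterized medium was replenished at every exchange), and
prey size is analysed as an outcome. Each treatment gets an invented but
realistic mean density (ungrazed control 5×10⁶ cells/mL; grazed cultures
1–2×10⁶, lowest under Colpidium) with 10% lognormal noise, and a size
spectrum over 1–10 µm ESD bins whose mean drifts linearly after a 5-day
lag: +0.055 µm/day under Colpidium (which removes small cells), −0.055
under Paramecium, no drift in the mixed and control treatments — about
1 µm of separation by day 14, none before the lag. Cell volume for a bin
is the sphere (π/6)d³; ciliate cells measured individually use the prolate
spheroid (π/6)·length·width².

What the generator does **not** emulate: demographic stochasticity and
extinction at low inoculum sizes, process noise in the dynamics,
evolutionary or successional change in the prey, size-class demography of
the bacteria (prey size is an outcome, not a driver), and between-replicate
variation in latent parameters. Passing tests therefore show that the
estimators recover truth under counting-type observation noise at the
study design — not that the LV model is a correct description of any
particular real microcosm.

## Numerical choices

- RK45 with rtol 10⁻⁸, atol 10⁻⁸·min(K); logistic-type systems are not
  stiff. Negative excursions beyond −10⁻¹²·K abort with an error; smaller
  round-off is zeroed.
- Equilibria solved in closed form from the 2×2 linear system;
  a12·a21 = 1 raises a dedicated degenerate-case error.
- Exact-neutrality tolerance in `classify_outcome` is 10⁻⁹ (relative for
  K); data-driven neutrality judgments always go through CIs instead.
- Percentile CIs are closed intervals; a zero-width CI at exactly 1 counts
  as including 1.
- p-values are reported at machine precision.

## Simulation sizes

The packaged checks use 100 runs for monoculture-K recovery, 200 for the
neutral-geometry classification rate, and 500 for CI coverage, with
n_boot = 4,000–10,000; these sizes give Monte-Carlo SEs of about 1–2
percentage points on the reported rates while keeping the whole suite
around half a minute.

## Known limitations

- The convergence guarantee "interior starts reach the coexistence
  equilibrium by t ≈ 50/min(r)" holds for moderately conditioned
  parameters; as a12·a21 → 1 the slow-manifold time diverges and no fixed
  horizon suffices (the estimators, as noted above, do not depend on this).
- Mixed-effects contrasts with day nested in replicate are out of scope;
  replicate-mean Welch contrasts are the implemented analogue.
- The literature table ships synthetic illustrative coordinates (the
  original figures print none) and supports the classification machinery,
  not quantitative claims about those studies.
- `one_way_anova` and the flux passthrough accept any numeric function
  measurements; no instrument model is attempted.
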