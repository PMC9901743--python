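# Methods

## Model

The model reduces ferritin iron handling to four reactions over four
species — labile ferrous iron (LIP), the diferric-peroxo intermediate
(DFP, two iron atoms per molecule), mineralized core iron (core, counted
as the concentration it would have if every crystal were solubilized),
and 24-subunit ferritin cages (FT). All concentrations are molar and time
is in seconds; constants quoted in mM in the source literature are stored
converted to M.

Assumptions worth stating explicitly:

* **One homogeneous cage pool.** H (heavy subunits per cage, 0–24) is a
  population-average composition, not a per-cage distribution, and APC =
  core/FT is the population-mean load. Per-cage stochastic filling is out
  of scope.
* **Event-count convention.** Each rate law counts reaction events; the
  stoichiometric multipliers (2 LIP per oxidation, 2 DFP → 4 core per
  nucleation, 1 DFP → 2 core per mineralization) live in the derivative
  assembly. This makes conservation of LIP + 2·DFP + core exact by
  construction.
* **Empirical nucleation/mineralization laws.** The molecular mechanism of
  crystal formation is not resolved; the laws are phenomenological (mass
  action in DFP² for seeding, Langmuir-type hyperbolic growth, Hill-type
  product inhibition, and a capacity shut-off at 4300 atoms/cage) with
  constants estimated from initial-rate data.
* **Turnover.** Optional zero-order cage synthesis (`ft_ksyn`, M/s,
  producing apo cages) and first-order degradation (`ft_kdeg`, 1/s). The
  degraded cages carry their mean share of the core, so degradation also
  moves iron core → LIP at `ft_kdeg·core`. Iron is conserved with turnover
  on. Chelator- or autophagy-receptor-specific release mechanisms are not
  modelled; degradation is a lumped first-order proxy.

### Parameters (defaults)

| name | meaning | default | units |
|---|---|---|---|
| ox_kcat | ferroxidase turnover | 591 | s⁻¹ |
| ox_Km | Hill half-saturation in LIP | 3.5e-4 | M |
| ox_n | Hill coefficient | 1.3 | – |
| H | heavy subunits per cage | 4 | – |
| rO | L-homopolymer oxidation offset | 2 | – |
| red_kdeg | DFP reduction constant | 0.2605 | s⁻¹ |
| nuc_kcat | nucleation constant | 5e7 | M⁻² s⁻¹ |
| nuc_Ki | nucleation core inhibition | 4.615e-4 | M |
| nuc_n | inhibition Hill coefficient | 4 | – |
| rN | L-subunit nucleation offset | 50 | – |
| min_kcat | mineralization turnover | 0.101564 | s⁻¹ |
| min_Km | DFP half-saturation | 5e-6 | M |
| min_Ki | core inhibition | 4.6458e-3 | M |
| min_n | inhibition Hill coefficient | 4 | – |
| min_m | capacity Hill coefficient | 8 | – |
| capacity | max atoms per cage | 4300 | – |
| ft_ksyn | cage expression rate | 0 (off) | M s⁻¹ |
| ft_kdeg | cage degradation constant | 0 (off) | s⁻¹ |

Two unit choices are interpretations: `nuc_kcat` is taken as M⁻²s⁻¹ (the
only assignment that makes DFP²·FT·k a concentration flux), and `ft_ksyn`
as M·s⁻¹ (a zero-order synthesis; with degradation at 1.203e-5 s⁻¹ the
cage concentration relaxes to ksyn/kdeg, e.g. 6.015e-14 / 1.203e-5 =
5 nM). The subunit factor (H+rO)/(24+rO) with rO = 2 gives an L-only cage
1/13 of the H-homopolymer oxidation rate; the source literature describes
this ratio loosely as "10-fold", and the formula is implemented as
printed. The default composition H = 4 is the hepatocyte-like value used
in calibration; the cell-scale scenario library keeps it, since those
experiments restate only concentrations, not composition.

## Numerics

* **Integration.** LSODA with rtol 1e-8, atol 1e-12 by default. The
  system is stiff: after a dose, ferroxidase flux equilibrates DFP in
  fractions of a second while turnover acts over days. Tiny negative
  excursions within tolerance are clipped to zero inside the right-hand
  side; the public rate-law API instead rejects negative concentrations.
* **Events.** Dosing events (set/add/scale a species) partition the run
  into segments; the integrator is stopped, the state modified exactly,
  and integration restarted. No interpolation crosses a discontinuity. The
  external iron each event introduces or removes is accumulated so the
  conservation identity LIP + 2·DFP + core = const + cumulative dose is
  checkable on every trajectory. At an output point coinciding with an
  event, the post-event state is recorded.
* **Degenerate states and clamps.** The capacity factor
  (1 − (APC/4300)^m) is clamped to zero for APC ≥ 4300 (it is an empirical
  shut-off, not a reverse rate), and the clamp is applied before
  exponentiation so extreme APC cannot overflow. If FT = 0 while core > 0
  (possible transiently with turnover), APC is defined as the capacity:
  no cages, no mineralization surface.
* **Steady states.** Integration in doubling epochs (starting at 1e4 s, up
  to 1e7 s) until every derivative is below 1e-17 M/s. The tolerance is
  deliberately far below the turnover flux scale (~6e-14 M/s) so the
  ferritin steady state is resolved to ≪1%; at looser tolerances the
  stop condition triggers a few percent short of ksyn/kdeg.
* **Output grids.** 0.01 s for the ≤25 s in-vitro scenarios, 0.1–1 s for
  cell-scale runs, 500 s for the multi-day turnover runs; all
  configurable. Halving the grid and tightening tolerances tenfold moves
  reported states by <0.01%.

## Calibration

`fit_core_parameters` reproduces the estimation procedure for the
nucleation/mineralization constants: unweighted nonlinear least squares of
predicted versus observed initial mineralization rates as a function of
initial APC. The predicted rate at each APC pre-loads the cages
(core₀ = APC·FT), applies the iron dose to the LIP, integrates a short
window and averages the mineralization flux over it. The default window is
0.1 s, chosen so core growth stays below 2% of its starting value across
the APC range under the reference assay conditions (2.32 µM FT, H = 4,
470 atoms/cage dose) — long enough for DFP to equilibrate, short enough
that the readout reflects the initial state. With the shipped constants
the predicted curve is unimodal with its maximum near APC ≈ 1525, inside
the empirically reported 1500–2000 band.

Optimization runs in log10 parameter space: a seeded differential-
evolution global stage followed by trust-region least-squares refinement,
with best-so-far bookkeeping so the hand-off never worsens the objective.
The original estimation used a commercial-grade combination of global
optimizers; standardizing on one seeded population algorithm keeps results
bit-reproducible. The local stage uses a relative finite-difference step
of 1e-3 (in log10 units) — large enough that gradients are not drowned by
ODE truncation-error noise in the objective. Default bounds span ±3
decades around the shipped values, hard-limited by the chemical
constraints that min_Km stays in the plausible DFP concentration range
and min_kcat below the oxidation turnover.

### Synthetic data and what recovery tests show

`generate_synthetic_dataset` multiplies the model-predicted curve by
unit-mean lognormal factors of a chosen coefficient of variation —
multiplicative noise, the natural model for strictly positive rate
readouts digitized from absorbance assays. It emulates measurement scatter
only: no APC-dependent bias, no baseline drift, no correlated errors, and
the generating model is by construction the fitted model. Recovery tests
therefore certify the estimation machinery (identifiability under the
design, optimizer convergence, seeding), not the model's adequacy to real
assay data.

The recovery study design spans both informative regimes: near-zero APC,
where the readout is dominated by nucleation seeding the first crystals
(this is the only region carrying information on `nuc_kcat`), and loaded
cages, where core-catalyzed mineralization dominates. For the
three-parameter study the readout window is lengthened to 5 s so the
nucleation-seeded signal at APC ≈ 0 rises to within an order of magnitude
of the largest rates; with a 0.1 s window it sits four decades below them
and is invisible to an unweighted objective. Noise-free data are recovered
to ≪1%; at 5% noise the median error over 20 replicate studies is ~2% for
min_kcat, ~2% for min_Ki and ~11% for nuc_kcat (the last is the sloppiest
direction: the APC≈0 rate constrains roughly the product of seeding and
early growth).

## Scenario library

Built-in scenarios carry the published experiment conditions: the
in-vitro APC sweep (2.32 µM FT, 1.09 mM dose, 25 s), cell-scale buffering
(5 nM FT, 1 µM then 2 µM LIP steps at 400 s), LIP depletion (zeroed at
400 s), a 2.5 µM addition with APC tuning, the subunit-composition sweep
(H = 0…24), and three turnover parameterizations (expression rates
3.075e-14 / 6.015e-14 / 1.203e-13 M/s against degradation 1.203e-5 1/s,
equilibrating at 2.56 / 5 / 10 nM cages) dosed with 0.5 µM iron every
1e5 s. The turnover scenarios run 40 doses (~46 days) — long enough for
the low-expression pool to fill to capacity and visibly lose buffering,
which a shorter course does not reach. The cytosolic volume (1.4e-12 L)
is scenario metadata used for SBML export; no rate law depends on it.

## SBML export

Scenarios export as SBML Level 3 documents: one compartment, the four
species, all constants as global parameters, APC as an assignment-rule
parameter (piecewise-guarded for FT = 0), and kinetic laws written as
explicit MathML with the capacity clamp as a piecewise term. Kinetic laws
are multiplied by the compartment so they are in substance/time as SBML
semantics require. With turnover on, three reactions are added —
synthesis, cage degradation, and core release (core → LIP at
ft_kdeg·core). The release flux is proportional to core, not FT, so it
cannot share a fixed-stoichiometry reaction with cage degradation; it is
its own mass-action reaction. Round-trip fidelity is tested by
re-simulating the document with a generic SBML interpreter that uses only
the document's contents.

## Limitations

* Nucleation and mineralization constants are phenomenological; the
  subunit offsets rO and rN in particular are order-of-magnitude settings,
  and predictions that hinge on L-subunit nucleation enhancement should be
  treated as qualitative.
* The mean-field APC cannot represent heterogeneous cage populations
  (e.g. a mix of full and empty cages behaves differently from uniformly
  half-full ones in reality).
* Early-time (<20 s) mineralization detail is known to be imperfect at
  high iron loads; the model targets cellular timescales of minutes and
  beyond.
* No spatial transport, no chelators, no regulated ferritinophagy; iron
  enters and leaves only through the explicit events and turnover fluxes.
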