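# Methods

`onecarbon` is a deterministic kinetic model of hepatic one-carbon
metabolism built to study how a liver cell regulates five competing
methyltransferases (MTs) that all draw methyl groups from the same donor,
S-adenosylmethionine (SAM).  This note records the model, its assumptions,
the calibration procedure, the numerical choices, and the limits of what
the simulations show.

## The model

Thirteen concentrations (all μM, well-mixed cytosol) evolve by mass
balance, d[X]/dt = inflows − outflows:

* methionine cycle: Met, SAM, SAH, Hcy;
* folate cycle: THF, CH2-THF, CH=THF, 10f-THF, DHF, free 5mTHF;
* GNMT species: free GNMT, 5mTHF–GNMT, 5mTHF–GNMT–5mTHF.

Twenty-two reactions connect them.  The SAM equation is exactly

    d[SAM]/dt = V_MATI + V_MATIII − V_GNMT − V_AS3MT − V_PEMT − V_GAMT − V_DNMT.

Methionine enters at a prescribed rate (constant 50 μM/hr, or a daily meal
profile averaging 50); the only exit for the homocysteine backbone is
transsulfuration (CBS), so at any constant-input steady state the CBS flux
equals the input exactly.  The transsulfuration fraction `frac` is the CBS
flux divided by the net SAH→Hcy flux (the flux around the methionine
cycle); at the reference state this is 50/100.25 ≈ 0.50.

All rate laws are Michaelis–Menten forms modified for product inhibition,
cooperativity or allosteric control.  The five MTs use the measured
constants: GNMT is cooperative in SAM (Hill n = 2) with competitive SAH
inhibition (Ki 35 μM); AS3MT (Km 50, Ki 10), GAMT (Km 49, Ki 16) and DNMT
(Km 1.4, Ki 1.4) are competitive; PEMT (Km 18.2, Ki 3.8) is
noncompetitive.  Each MT's co-substrate (glycine, arsenite/GSH,
phosphatidylethanolamine, guanidinoacetate, DNA) is held constant and
folded into a cell-effective Vmax, so the in-vitro Vmax values and the
cellular ones differ (see Calibration).  AS3MT substrate inhibition by
very high SAM is omitted as negligible at hepatic SAM levels.

### GNMT–5mTHF binding

GNMT is both an enzyme and a folate-binding protein with two sequential
5mTHF sites, modelled as mass action with k1 = 50 μM⁻¹hr⁻¹, k2 = 1 hr⁻¹,
k3 = 1 μM⁻¹hr⁻¹, k4 = 1.6 hr⁻¹ (KD1 = 0.02 μM, KD2 = 1.6 μM; units chosen
so KD = k_off/k_on is in μM).  No statistical site factors are added; the
rate constants are used as given.  Catalysis is carried by the weighted
occupancy `w_free·[GNMT] + w_single·[5mTHF-GNMT] + w_double·[doubly bound]`
with default weights (1, 0.5, 0) — free enzyme fully active, singly bound
half active, doubly bound inactive.  The alternative all-or-nothing
hypothesis (1, 0, 0) is supported for comparison; against the published
inhibition summary (15 % inhibition at 0.1 μM total 5mTHF, 50 % at 1 μM,
90 % at 10 μM, with 1 μM enzyme) the half-activity weights fit an order of
magnitude better (SSE 0.013 vs 0.132), which is the computational argument
for the 50 %-activity conclusion.

Equilibrium species are computed by reducing the two binding equilibria
plus the two conservation laws to a single residual in the free ligand,
which is strictly increasing, and bisecting (Brent, xtol 1e-14).  This is
robust for any KD ratio; the test-suite checks it against the closed-form
cubic root and against long-time integration of the mass-action ODEs.

### Long-range interactions (lri)

Three allosteric actions let SAM influence distant parts of the network:
SAM activates CBS, inhibits BHMT, and inhibits MTHFR.  They are modelled
as Hill factors on the respective velocities:

* CBS:    · SAM³/(Ka³ + SAM³), Ka = 15 μM
* BHMT:   · Kb³/(Kb³ + SAM³), Kb = 60 μM
* MTHFR:  · Ki²/(Ki² + SAM²), Ki = 15.5 μM

The `lri` toggle replaces SAM in these three factors (and only there) by
the baseline steady-state SAM, frozen beforehand from a baseline solve.
The clamp is a no-op at the baseline itself; under perturbations it
reproduces the expected signature that free 5mTHF, bound GNMT and `frac`
do not move at all unless GNMT itself is perturbed.

### Remaining reactions

MAT-I carries soft exponential SAM inhibition (0.23 + 0.8·e^(−0.0026·SAM));
MAT-III is activated by SAM and roughly quadratic in methionine at low
methionine, which produces the "substrate switch" at high input.  SAHH,
SHMT, MTD and MTCH are net-reversible two-term forms; MS is bilinear in
5mTHF and Hcy saturation terms (Km 25 and 0.1 μM); TS/DHFR, FTS/FTD and
the two purine steps (PGT, AICART) close the folate cycle; a small
nonenzymatic THF↔CH2-THF interconversion is included.  Gross exchange
fluxes of the reversible steps at the reference state (e.g. SHMT reverse
10 μM/hr, MTD/MTCH 40/30) set how stiffly those steps are coupled; they
are not observable from net balances and were fixed once at plausible
magnitudes.

Two quantities are conserved exactly by construction: total GNMT protein,
and the folate pool counted as free folates + one 5mTHF per singly bound +
two per doubly bound GNMT.  Bound folate must count toward the folate
total because the binding terms appear in the 5mTHF equation; the free
folate sum alone is not conserved.

## Calibration

The model is anchored at its reference operating point — the normal liver
steady state at methionine input 50 μM/hr and total folate 20 μM: Met
17.97, SAM 23.97, SAH 3.89, Hcy 2.27, free 5mTHF 5.35 μM; cycle flux
100.25 μM/hr, V_GNMT 43.97, V_DNMT 2.05, V_GAMT 25.42, V_PEMT 27.53,
V_AS3MT 1.28, V_MS 23.65, V_BHMT 26.60, V_CBS 50 μM/hr, frac 0.50.  These
published values are internally consistent (every node balances to
100.25), and every Vmax is derived as `reference flux / rate-shape at the
reference state`, which makes the reference point an *exact* equilibrium
of the assembled system (max |RHS| ~ 1e-14 μM/hr).  Folate-cycle internal
pools not fixed by the operating point (THF 6.7, CH2-THF 0.94, CH=THF
1.15, 10f-THF 4.05 μM, DHF closing the balance) and the folate-cycle flux
split (SHMT net 34, MTD/MTCH 10, TS 1, FTS 3, purine steps 1.5 each) were
chosen once at hepatic magnitudes.

The strengths of the three allosteric constants, the MTHFR Hill
coefficient, and the cellular GNMT half-saturation were then estimated by
fitting the model's steady-state responses to the published perturbation
panel (PEMT knockout: SAM +25 %, 5mTHF −14 %; DNMT ×20: SAM −22 %, 5mTHF
+18 %, frac −10 %; GNMT knockout: GAMT +55 % with the interactions, +121 %
without).  The fitted model reproduces all seven within 2 percentage
points (worst case 1.7).

A note on the cellular GNMT constant: flux bookkeeping at the reference
state shows that a GNMT half-saturation of 100 μM would give the GNMT flux
a SAM-elasticity near 1.9, which cannot reproduce the panel — under PEMT
knockout GNMT would then absorb more than the entire freed flux before SAM
could rise 25 %.  The panel requires an elasticity of roughly 1 that
*rises* as SAM falls and *falls* as SAM rises, i.e. a Hill curve with its
half-saturation near the operating SAM.  The cellular form therefore uses
Km_cell = 20 μM (co-substrate context folded in, like the cellular Vmax
values), while the in-vitro constants remain available in the standalone
rate-law functions.

## Virtual experiments

* **Perturbation panel** — multiply one MT's cellular Vmax by a factor
  (0 = knockout, 20 = the DNMT upregulation case) and compare steady
  states.  A GNMT knockout zeroes the *total protein*, removing catalysis
  and folate buffering together, and releases the ~1.77 μM of bound folate
  into the free pool — this release is why GAMT rises further (+122 %)
  without the long-range interactions than naive bookkeeping suggests.
* **Input sweep** — steady-state SAM over methionine input 10–100 μM/hr,
  both toggles.
* **Folate sweep** — steady-state SAM and total methylation (sum of the
  five MT fluxes) over total folate, with an optional sensitivity
  envelope: each replicate multiplies the 11 methionine-cycle Vmax values
  by independent draws from [0.9, 1.1] (default 10 replicates, one seeded
  RNG stream, replicate index = draw order).
* **Meal simulation** — 24-h cyclic input (33.33 μM/hr fasting, 66.67 for
  3 h after breakfast 07:00 and lunch 12:00, 100 for 3 h after dinner
  18:00; clock times are a modelling choice and configurable; the daily
  mean is exactly 50).  The first simulated day is discarded as a
  transient.  Flux variability is summarized as peak-to-trough amplitude
  over the mean.

## Numerics

Stiff integration uses LSODA with rtol 1e-8 and atol 1e-10 μM; piecewise
constant input is integrated segment by segment so the solver never steps
across a discontinuity.  Steady states are found by integrating 800 model
hours (extended 4× on failure) and polishing with a hybrid-Powell root
solve in which two redundant rows (the system has two exact conservation
laws, so the raw Jacobian is singular) are replaced by the conservation
constraints and two binding rows by the binding-equilibrium relations;
convergence requires max |RHS| < 1e-8 μM/hr.  The steady state is treated
as a unique attractor; randomized-start tests support this in the explored
regime, but no multistability search is performed.  Concentrations below
1e-12 μM are treated as zero inside the rate laws to avoid round-off sign
flips.  Simulation sizes throughout (sweep grids of ~10 points, 2-day meal
runs, 10-replicate envelopes) are chosen to resolve the reported curves;
everything here runs in seconds.

## Limitations

* The folate-cycle interior (pools and gross fluxes) is calibrated, not
  measured; conclusions should be read at the level of the reported
  steady-state responses, not individual folate-cycle fluxes.
* Co-substrates are constant, so the model cannot describe regulation
  through substrate availability (e.g. guanidinoacetate control of GAMT)
  except by externally scaling a cellular Vmax.
* Mitochondrial one-carbon metabolism, compartmentation, stochastic
  fluctuations and whole-body transport are out of scope; the meal
  experiment is purely deterministic.
* The lri-off model is a diagnostic construct (regulatory terms clamped at
  baseline), not a biological mutant.
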