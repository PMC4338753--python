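# Methods

## Model overview

The package simulates a cerebellar Purkinje cell as a branched tree of
cylindrical compartments obeying, per compartment,

    C_m dV/dt = −[ Σ_i g_i (V − E_i) + g_leak (V − E_leak) ] + I_axial + I_inj

with axial coupling through cylindrical axoplasm resistances
(Ra = 122 Ω·cm) and fifteen voltage- and calcium-dependent conductances
placed by region. Spikes initiate in the axon initial segment (AIS),
back-propagate into the soma, and propagate through three nodes of Ranvier
toward the deep cerebellar nuclei; the dendrites carry the
calcium/KCa machinery that shapes pacemaking and high-drive responses.

## Morphology

The axon is fully specified: AIS 17 × 0.97 µm, paraAIS 4 × 0.97 µm, four
100 × 0.73 µm myelinated internodes alternating with three 4 × 0.73 µm
nodes, and a two-section 100 × 0.6 µm collateral leaving the second node
(11 axonal sections). The soma is a single 29.8 × 29.8 µm cylinder
(lateral area ≈ 2790 µm²; membrane areas everywhere are lateral cylinder
areas π·d·L).

The source dendritic reconstruction is not available as coordinates, so a
seeded generator builds a surrogate tree with three branch orders (trunk
sections attached to the soma, principal > 8 µm thresholds, terminal
< 3.5 µm), outward-tapering diameters inside the 0.67–9.22 µm range, and
section lengths scaled to a common factor so the cell's total area is
70,000 µm² within 0.2%. At full scale (1599 sections) lengths stay inside
the biological 1–10 µm range; at desk scale (default 48 sections, the
configuration used by the test-suite and the acceptance script) each
section stands for a cluster of branchlets and its length is allowed to
exceed 10 µm — total area, the quantity that controls the passive
aggregates, is preserved exactly. Identical seeds give identical trees.

Sections are discretized by the standard rule (compartment length
≤ 0.1 λ at 100 Hz; single-compartment myelin), giving ~225 compartments at
desk scale.

## Passive calibration

Somatic specific capacitance is 0.77 µF/cm². Dendritic membrane is spiny;
its specific capacitance (2.045 µF/cm²) and leak (1.367·10⁻⁴ S/cm²) were
calibrated once — `scripts/calibrate_passive.py` reproduces the
procedure — so that the somatically measured passive input resistance and
capacitance of the surrogate cell are ≈ 14 MΩ and ≈ 1090 pF. Myelin uses
0.06 µF/cm² and 2·10⁻⁶ S/cm² (wrapped membrane); nodes, paraAIS and the
collateral carry a higher leak (10⁻⁴–5·10⁻³ S/cm²) that holds the thin
axon at rest. The leak reversal, −54 mV, is a calibration parameter of
the pacemaker operating point (it sits just above the spike
afterhyperpolarization, supplying part of the interspike depolarizing
drive). Rin is measured as the steady ΔV/ΔI for a −10 pA somatic step
solved exactly on the passive tree; Cin as the integrated capacitive
charge over the charging transient divided by the somatic voltage step,
evaluated in closed form from the two steady states.

## Channels

Kinetics follow the published source model of each channel; where the
printed forms are ambiguous the implementation states its reading:

* **Nav1.6** — the 13-state resurgent scheme (5 closed, 6 inactivated,
  open, open-blocked; activation ladder α = 150·e^(V/20) ms⁻¹,
  β = 3·e^(−V/20), γ = 150, δ = 40, ε = 1.75, ζ = 0.03·e^(−V/25),
  Con/Coff = 0.005/0.5, Oon/Ooff = 0.75/0.005, allosteric factors
  (Oon/Con)^¼ and (Ooff/Coff)^¼). Placed in AIS, nodes, collateral, soma
  and the dendritic trunk (the trunk reading follows the text; spreading
  sodium over the entire tree would make the dendrites spike-generating,
  which the cell type is not).
* **Kv1.1, Kv3.3** — n⁴ delayed rectifiers with symmetric exponential
  rates (half-activation −45 and −16 mV).
* **Kv3.4** — m³h with the fast activation/deactivation and partial
  inactivation (floor 0.31) of the TEA-sensitive somatic current; the
  principal spike-repolarizing conductance and, in the nodes, the
  transmission-frequency filter.
* **Kv1.5** — n³ with fast and slow inactivation (slow τ 6.8 s).
* **Kv4.3 / Kir2.x** — granule-cell A-type (a²b) and inward rectifier.
* **KCa1.1 (BK)** — a 10-state Monod–Wyman–Changeux Markov scheme: five
  closed and five open states indexed by bound Ca (0–4), binding ten-fold
  tighter in the open tier (K_d 3 µM closed / 0.3 µM open, k_on
  100 mM⁻¹ms⁻¹), opening equilibrium e-folding every 19 mV with base rates
  6/300 ms⁻¹ at 0 mV. These constants are this package's calibration
  (pinned as regression fixtures): the scheme is silent at the 45 nM
  resting point, restrains the dendritic membrane above ~−50 mV once
  submembrane Ca exceeds ~0.1 µM, and activates strongly during spikes.
* **KCa2.2 (SK2)** — the 6-state scheme (4 closed, 2 open) with
  Ca-driven forward rates (200/160/80 mM⁻¹ms⁻¹), half-activation
  ≈ 0.35 µM.
* **KCa3.1** — single gate whose opening rate is the product of a
  saturating Ca term and an e-fold/27 mV voltage term.
* **Cav2.1 (P-type)** — half-activation −29.5 mV, slope 8.5 mV, bell
  τ_m ≈ 0.27 ms. Implemented with a single activation gate so that the
  stated half-activation describes the conductance; this preserves the
  P-type window current that, together with persistent sodium and the
  T-type window, drives the interspike depolarization.
* **Cav3.1/3.2/3.3 (T-type)** — m²h each with staggered activation
  voltages and time constants. The printed recovery branch of the
  thalamic variant is typographically unreadable; the canonical
  thalamic-relay form (exp((V+467)/66.6) below −80 mV,
  28 + exp(−(V+22)/10.5) above) is used instead.
* **HCN1** — single gate, α/β = 0.0018·e^(∓(V+58.7)/22, /7.14) ms⁻¹.
* **TRP** — a voltage-independent cationic leak (E = 0 mV), off in the
  canonical cell; 6·10⁻⁵ S/cm² in the dendrites reproduces the ~100 Hz
  high-basal-rate firing phenotype.

Rates are expressed at each source's experimental temperature and scaled
to 37 °C with Q10 = 3 (α and β scale together, so steady states are
temperature-invariant and time constants shrink). Reversal potentials:
Na +60, K −88, HCN −34.4, TRP 0 mV. The calcium reversal is updated every
step from the GHK relation using the outermost-shell free Ca; the
extracellular concentration (1.324 mM) is back-solved so the initial
reversal at 45 nM is exactly +137.5 mV.

At simulation start all gates and Markov chains are set to their steady
state at −65 mV and 45 nM Ca, and a 500 ms settling window is discarded
before any measurement.

## Calcium dynamics

Each compartment carries up to four concentric shells (outer depth
0.1 µm; thin axonal compartments collapse to a single pool). Calcium
enters the outer shell from the compartment's Ca currents, diffuses
radially (D = 0.233 µm²/ms), binds calbindin (0.16 mM sites,
k_f 43.5 mM⁻¹ms⁻¹, K_d ≈ 2 µM effective) and parvalbumin (0.08 mM,
k_f 10 mM⁻¹ms⁻¹, K_d 0.1 µM), and is extruded by a generic saturable pump
(Michaelis constant 0.2 µM; maximum flux 3·10⁻³ mM·µm/ms per unit regional
density, region weights 0.4 dendrites / 1 soma,AIS / 10 nodes). The
saturable form matters: near rest the pump clears the standing P-type
window influx and keeps the interspike submembrane Ca near 0.1 µM, while
during spikes the influx exceeds the pump's ceiling and submembrane Ca
rises into the KCa operating range (~1 µM at the dendritic membrane).

Numerics conserve mass exactly in a closed system: radial diffusion is a
flux-form backward-Euler tridiagonal solve (factorized once per Δt) and
buffer binding uses the closed-form positive root of the implicit binding
step, updating bound Ca as the exact complement.

## Integration

One Δt = 0.025 ms step performs: (1) exponential-Euler updates of all HH
gates (kinetics tabulated on a 0.05 mV grid and advanced in one fused
array operation; the tables are generated from the channel specifications
themselves, so the fast path cannot drift from the reference kinetics);
(2) backward-Euler master-equation solves for the Markov channels (rate
entries decomposed as A(V) + B(V)·Ca, states permuted by reverse
Cuthill–McKee so the linear systems are banded with half-bandwidth 2);
(3) one backward-Euler voltage solve over the branched tree with
conductances frozen at their post-update values (leaf-to-root elimination,
root-to-leaf back-substitution); (4) the calcium update and GHK refresh.
A |V| ≥ 200 mV guard aborts divergent runs with a diagnostic. The inner
loops are JIT-compiled with numba when available, with identical pure
NumPy/Python fallbacks.

Backward Euler is first-order: halving Δt shifts individual spike times
by ~0.05 ms near the start of a run, but the ~1% period error of the
limit cycle accumulates linearly across a long stretch (≈ 2% of each
interspike interval). The test-suite asserts the convergence order;
applications needing phase-accurate long trajectories should reduce Δt.

## What the surrogate reproduces — and what it does not

All protocol measurements in the test-suite and the acceptance script run
at desk scale (48 dendritic sections, ~225 compartments, seconds-long
runs), which keeps the full battery within minutes on one core. With the
printed conductance table and the calibrations above, the surrogate cell
reproduces:

* passive aggregates (area 70,000 µm², Rin ≈ 13.7 MΩ, Cin ≈ 1080 pF);
* regular pacemaking near 30 Hz (reference 35.5 Hz) with spike half width
  ≈ 0.26 ms, AHP ≈ −68 mV and trough-to-peak amplitude ≈ 85 mV, always
  below the 75 Hz admissibility ceiling;
* abolition of firing by dendritic P-type knockout, acceleration and
  spike growth after dendrite removal, silence after total Na knockout,
  preserved/accelerated firing after KCa or Kv1 knockouts, and
  near-indifference to HCN1 knockout;
* spike initiation in the AIS ahead of the soma on every spike, 1:1
  axonal transmission at spontaneous rates, and sharpened K-dependent
  filtering of fast somatic drive at the third node;
* the ~100 Hz high-basal-rate variant (dendritic TRP), and the
  continuously-firing / pausing variants as conductance edits.

Known deviations, with their diagnosed causes (kept, not patched over):

* **AIS-restricted Na knockout does not silence the cell.** With the
  printed somatic density (0.214 S/cm² on ≈ 2790 µm², ≈ 6 µS) the soma is
  an autonomous oscillator; removing the 0.26 µS AIS conductance barely
  perturbs it. The same somatic density also makes the somatic peak
  essentially coincident with the AIS peak (median lead ≈ 0.006 ms
  against the reference 0.1 ms).
* **Conduction is faster than the reference** (≈ 1.1 vs 0.73 m/s): with
  0.03 S/cm² of nodal Na on 9 µm² nodes the regenerative safety factor is
  marginal, and much of the wave at the third node is electrotonic, which
  travels fast. Myelin capacitance was set (0.06 µF/cm²) at the edge that
  still lets the third node regenerate.
* **The sustained full-spike rate saturates near 60–130 Hz** instead of
  ~300 Hz, and the ramp-evoked instantaneous maximum of full-blown spikes
  is ≈ 65 Hz (reference 296 Hz): under strong drive spikes shrink into
  spikelets as sodium availability falls — the Ca-dependent K restraint
  that stabilizes the dendrites in this reconstruction also brakes the
  interspike recovery. For analysis purposes a "full-blown" spike is one
  peaking above −10 mV.
* **Somatic step currents do not evoke complex bursting** (the 6 /s
  Ca-spike-terminated bursts of the reference). The burst cycle requires
  the dendrites to escape regeneratively once somatic firing fades; the
  same BK restraint that keeps pacemaking stable prevents that escape at
  every step amplitude tested (up to 4 nA the response stays tonic and
  then fades). Direct dendritic injection (3 nA into the trunk) does
  evoke a spike burst. This is the largest behavioral gap of the
  surrogate reconstruction and is reported as such, not masked.

## Design choices made where the design was open

* The section count of the reduced tree (≈ 50) and all desk
  durations are runtime choices; the generator accepts the full 1599.
* The pump-density table row is read as a regional scale factor on a
  single generic pump, since buffers are species with concentrations.
* The burst classifier discards the first 400 ms of a step response: the
  onset adaptation notch would otherwise split a tonic train in two.
* Knockouts are expressed as conductance scalings to zero; every protocol
  operates on a copy and asserts afterwards that the pristine model's
  channel-table hash is unchanged.
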