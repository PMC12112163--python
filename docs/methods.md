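# Methods

This note documents the models, the coupling scheme, the parameter choices
and their rationale, the numerical decisions, and what the bundled
synthetic populations do and do not represent.

## 1. Electrophysiological model

Each neuron is a single isopotential compartment with Hodgkin–Huxley-type
currents at 34 °C:

    C dV/dt = −(I_Na + I_Kd + I_M + I_Ca + I_KCa + I_D + I_leak + I_NaLeak
               + I_pump) + I_stim / A

* transient Na⁺ (m³h) and delayed-rectifier K⁺ (n⁴) with a threshold-shift
  parameter `v_t` (−55 mV), the classic cortical rate functions;
* slow non-inactivating M-type K⁺ current (gate p, `tau_max_m` up to 12 s)
  producing spike-frequency adaptation;
* high-voltage-activated Ca²⁺ current (q²) feeding a first-order
  intracellular Ca²⁺ pool, and a Ca²⁺-activated K⁺ current whose slow
  build-up/clearance cycle (`tau_ca` ≈ 200 ms) produces stuttering;
* a slowly inactivating D-type K⁺ current (fast activation d1, slow
  inactivation d2, τ ≈ 600 ms) producing delayed firing onset;
* unspecific leak plus a small Na⁺-specific leak that the pump balances at
  rest.

Intracellular Na⁺ and K⁺ are dynamic; their Nernst reversals are
recomputed every step. Extracellular [K⁺]=5 mM and [Ca²⁺]=1.1 mM are fixed.
Cl⁻ and Ca²⁺ relax first-order to rest (Ca²⁺ additionally receives channel
influx); they are reported in validation but do not gate the pump.

**Na⁺/K⁺-ATPase.** The sole electro-metabolic sink. Cycle rate (in mM of
ATP per ms, referred to the cell volume):

    rate = v_max (Na_i/(Na_i+K_na))³ (K_o/(K_o+K_k)) (ATP/(ATP+K_atp)) f(V)

with the canonical 3 Na⁺ : 2 K⁺ : 1 ATP stoichiometry and a net +1 charge
per cycle contributing an outward current. `K_atp` = 0.2 mM keeps the pump
near-saturated at the 1.38 mM operating point, so ATP-gating matters only
when energy actually runs low. The voltage factor is a mild sigmoid
operated on its lower tail (`v_half` = +40 mV, slope 20 mV): consumption
then grows ~exponentially with depolarisation — about tenfold over a spike
excursion relative to quiet periods — while varying only ~1.6× across the
subthreshold range, which leaves resting ion homeostasis undisturbed.
`v_max` is fixed so the resting cycle rate (−70 mV, 10 mM Na⁺, 1.38 mM
ATP) equals the metabolic model's reference resting demand, 2×10⁻⁵ mM/ms.
Because pump sites live in the membrane, `v_max` scales with each cell's
surface-to-volume ratio (like every other transmembrane flux after current
→ concentration conversion); with log-normal surface areas this gives the
population a realistic spread of per-volume energy turnover.

**Integration.** Semi-implicit scheme at a fixed 0.025 ms step: gates by
exponential (cnexp-style) update, the voltage implicitly against the
instantaneous conductances, then explicit updates of the slow ion/ATP
pools. ATP is floored at 10⁻⁶ mM with a logged clamp rather than an error.
Spike times are taken at the −20 mV upward crossing (2 ms refractory) with
sub-step linear interpolation, so interspike-interval trends are not
quantised to the grid. The inner loop is compiled with numba; a pure-numpy
reference implementation of the identical update is kept and the two are
held together by a unit test at 10⁻¹² tolerance. Halving the step leaves
spike counts unchanged and moves final Na⁺ by <1 % on the adapting probe
(tested at 1.5 s; the property degrades only through benign phase drift of
late spikes at longer horizons).

**Stimulus.** Ornstein–Uhlenbeck current, Euler–Maruyama at the membrane
step: x' = x + (μ−x)·dt/τ + σ√dt·ξ, τ = 3 ms; stationary variance σ²τ/2
(verified against the closed form). "Relative" parameterisation: each
archetype defines an operating drive as a fraction of its baseline current
(a near-rheobase characterisation level that scales with area), with noise
amplitude 15–45 % *of the mean drive* depending on firing class. Per-layer
calibration multiplies all archetype drives of a layer by a common gain,
bisected until the layer's mean rate over a 1.5 s fixed-ATP probe (first
500 ms discarded: onset bursts of adapters, silent periods of delayed
cells) lies in the target band, default 1–10 Hz.

## 2. Reduced NGV metabolic model

One NGV unit per neuron; ~15 states over three compartments (mM):

* neuron: glucose, pyruvate, lactate, cytosolic and mitochondrial NADH,
  ATP, phosphocreatine, O₂;
* astrocyte: glucose, lactate, ATP;
* capillary: glucose, lactate, O₂, β-hydroxybutyrate, exchanging with
  fixed arterial concentrations at rate blood_flow/blood_volume.

Twelve lumped saturable fluxes: symmetric glucose carriers, lumped
glycolysis (2 ATP + 2 pyruvate + 2 NADH per glucose; activated by ADP,
limited by cytosolic NAD⁺), reversible lactate dehydrogenase (mass
action), astrocyte→neuron and capillary→neuron monocarboxylate transport,
O₂ transport, oxidative phosphorylation (13 ATP and 2.5 O₂ per pyruvate,
scaled by `etc_efficiency`·`mito_density_scale`), a cytosol→mitochondria
NADH shuttle whose delivered NADH is oxidised for 2.5 ATP each,
β-hydroxybutyrate oxidation (10 ATP), a fast reversible creatine-kinase
buffer, and housekeeping ATPases (neuronal rate 2×10⁻⁵·MM(ATP) mM/ms,
roughly a quarter of active consumption — the non-signalling overhead that
production must cover). Within this module ADP = A − ATP.

**Regulatory regime.** Glycolysis keeps a strong ADP sensitivity
(K = 0.5 mM: ~9× headroom at rest), while oxidative phosphorylation runs
near ADP-saturation (K = 0.02 mM) and is therefore limited by its Vmax and
by pyruvate supply. Consequences: (i) demand tracking — pump activity
lowers synchronised ATP, the liberated ADP accelerates glycolysis and
pyruvate supply, and production follows consumption; (ii) mitochondrial
capacity is *felt* — because all NGV units start from a common reference
state, a layer with denser mitochondria genuinely runs more oxidative flux
during the transient, and an ETC efficiency cut removes an amount of
production proportional to that capacity. This is what makes the densest
layer lose the most ATP under ageing. (Had each layer been pre-equilibrated
to its own steady state, the operating flux would be demand-pinned and the
ETC cut would bite identically everywhere.)

**Vascular constants.** Blood flow is fixed at 0.0001 ml/min against a
0.023 ml blood volume (the source prints the volume with inconsistent
units; both the printed string and the interpretation are emitted by
`--dump-params`). These are whole-tissue-scale quantities: the capillary
reservoir is ~10⁶ × one neuron's volume, so per-unit drain is scaled onto
capillary concentrations by a tissue/capillary volume ratio (default
10⁻⁶) and the capillary is effectively a large slowly-refreshed reservoir
on the 3 s horizon.

**Calibration.** `v_gly_n` (and the OXPHOS/ketone Vmax split) is fixed so
the resting steady state under the reference demand 2×10⁻⁵ mM/ms sits at
ATP = 1.380 mM, the fixed-ATP reference level. The steady state is found
by long LSODA relaxation plus Newton polish (residual <10⁻¹²). Removing
demand raises steady ATP (to ≈1.44·0.995); doubling it lowers ATP;
steady states under each individual ageing factor lie strictly below the
calibrated rest.

**Integration.** LSODA at rtol 10⁻⁶ / atol 10⁻⁹ per 100 ms segment
(self-convergence verified at 10× tighter tolerances). The segment
integrator advances cumulative production and cumulative sinks as states
and reconstructs ATP algebraically from them, so the per-segment energy
identity ATP(t) = ATP(0) + produced − sinks − demand·t holds to round-off
by construction. Concentrations are guarded non-negative inside flux
evaluation and clamped-and-logged at segment output.

## 3. Coupling scheme

Per coupling interval (100 ms, the smallest common multiple of the 0.025 ms
membrane step and the 100 ms metabolism macro-step): the electrophysiology
of all neurons advances first (consuming ATP), then each neuron's NGV unit
advances over the same window, then ATP is merged by the additive splitting
rule and ADP overwritten in both simulators from the AK closure.

Two design points deserve emphasis:

* **Consumption information flows through the synchronised state, not
  through a demand forcing.** If the pump's consumption were additionally
  forwarded to metabolism as a −demand term, the additive merge would
  subtract it twice (the electrophysiology side already debited it). With
  demand = 0 inside coupled-mode metabolism, Eq.-1 exactness, the
  degenerate single-simulator equivalences, and per-neuron energy closure
  to 10⁻⁹ mM all hold identically; production still upregulates because
  the synchronised ATP/ADP carry the demand signal. The demand argument
  remains for standalone metabolism runs and calibration.
* **Merge exactness.** The merge is evaluated branch-wise so that when one
  side did not move, the other side's value passes through bit-exactly;
  the lower clamp (10⁻⁶ mM) and the adenine-pool cap (applied by the
  orchestrator before injecting the value into the simulators) are logged
  sanity events, as are any species outside the configured bounds at a
  synchronisation.

The AK convention adopted is q_AK = ADP²/(ATP·AMP) = 0.92 — the one under
which the printed closed form is the positive root of the equilibrium
quadratic; the alternative convention differs by <1 % in ADP at
physiological ATP. The closure is non-monotone over the whole pool (ADP→0
at both ends); it decreases strictly on the physiological branch.

Per-neuron work within an interval is independent (no synaptic coupling in
scope); every neuron draws noise from its own counter-based stream keyed on
(run seed, neuron id), so results are bit-identical regardless of worker
count or scheduling.

In the fixed-ATP reference mode metabolism is skipped and ATP held at
1.38 mM exactly while consumption is still tallied.

## 4. Synthetic populations and the ageing protocol

`fixture_population` provides pinned-seed populations (smoke: 5 neurons;
small: 60/6 layers; medium: 300 neurons, all 11 archetypes, 6 layers).
Layer fractions and e-type mixtures are configuration, not measured
values; the medium fixture deliberately over-represents inhibitory types
(~15–25 cells each) so per-archetype statistics are estimable at desk
scale. Surface areas are log-normal (σ = 0.25) around archetype templates,
standing in for morphological diversity. Mitochondrial density scales are
monotone with a layer-4 maximum (L1 0.90 … L4 1.10 … L6 0.95),
configurable.

The Aged profile multiplies: ETC efficiency ×0.85, arterial and
intracellular glucose ×0.8, β-hydroxybutyrate ×0.7, total NAD pool ×0.7,
NADH shuttle ×0.75, glutamate drive of astrocytic glycolysis ×0.8, and
initial neuronal lactate ×1.2 (an initial-condition shift, not a sustained
source). The directions are the constraint from the ageing literature; the
magnitudes are this package's choices, validated by direction tests and by
the qualitative layer ordering only. Stimulus, seeds and electrophysiology
are identical between arms.

What these fixtures do **not** emulate: synaptic connectivity and
morphologically detailed neurons, so absolute circuit-scale statistics
(e.g. specific per-e-type Spearman coefficients, absolute layer deficits)
are outside what passing tests demonstrate; the tests certify the coupling
physics, the exactness contracts, directions, and orderings.

## 5. Analysis definitions

* Resting potential: mean voltage over the final 100 ms of the last
  spike-free stretch (≥20 ms from any spike); AP amplitude: mean over
  spikes of (peak within 3 ms) − (−20 mV threshold); max voltage: global
  trace maximum.
* AP-vs-rest consumption: mean consumption rate in 5 ms windows centred on
  spikes ÷ mean rate in samples ≥25 ms from every spike; absolute
  molecule counts via volume × Avogadro. Undefined cases are reported as
  NaN, not raised.
* Supply–demand: Pearson r of cumulative produced vs pump-consumed ATP per
  e-type; Spearman ρ of production vs spike count. Groups under 3 (or a
  configurable minimum) and zero-variance groups are flagged.
* Group statistics: Shapiro–Wilk per group; Dunn's rank-sum z with tie
  correction, Bonferroni-adjusted (implemented in `emcosim.stats`;
  cross-checked against the Kruskal–Wallis statistic for two groups).
* Young/Aged spike differences: greedy nearest-time pairing within 5 ms
  (well below typical interspike intervals, well above numerical jitter).
* Physiological bands (end-of-run ATP, ADP, Na⁺, K⁺, Ca²⁺, Cl⁻ and
  EXC/INH rates) are configurable defaults.

## 6. Problem sizes and known limitations

The test suite runs the medium fixture (300 neurons, 3000 ms) once per
condition and shares it across tests; coupling-interval robustness uses a
20-neuron, 1 s population, and step-halving a single neuron at 1.5 s —
sizes chosen to keep the default suite fast while exercising every claim.

Known limitations:

* Production lags consumption by the supply-chain response time (~seconds),
  so neurons whose spiking concentrates late in a 3 s run have produced
  less by the final sample than equally-consuming early spikers. With only
  ~15 cells per inhibitory archetype the *minimum* per-archetype
  supply–demand correlation is therefore sensitive to the stimulus
  realisation (≈0.96–0.97 at the pinned study conditions; dips toward
  ≈0.8 for unlucky draws in small irregular-firing groups). Larger groups
  average this out.
* The Aged–Young ATP deficits are millimolar-per-mille scale, smaller than
  circuit-scale reports: with a single reduced supply chain per neuron,
  ADP feedback compensates much of the capacity loss at steady state, and
  the 3 s transient captures only the uncompensated, mitochondria-scaled
  part (which carries the layer ordering).
* No synapses: firing statistics are drive-calibrated, not
  network-generated; the excitatory/inhibitory distinction affects only
  composition and reporting.
* Resting potentials of the archetypes sit near −58 to −65 mV under zero
  drive (depolarised by the Na⁺ leak/window currents that give the pump a
  resting load), at the depolarised end of the physiological range.
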