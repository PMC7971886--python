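# Methods

## Model

The package models batch and continuous cultures of *E. coli* engineered to
produce 3-hydroxypropionate (3-HP) and acrylic acid (AA), as deterministic
mass-action/enzyme-kinetic ODE systems: `d[S]/dt = Σ_r ν_{S,r} v_r` over
non-fixed species, concentrations in mM, rates in mM/s, time in seconds
(hours and g/L only in reporting).  Boundary species (buffered phosphate
and ammonium, the vitamin-B12 coenzyme, extracellular sinks in continuous
mode) are clamped and carry zero derivative.

A *variant* model is chassis + nine native extension reactions + six synth
drains + one heterologous route (+ the shared 3-HP→AA trio for AA end
products).  Glucose-fed variants omit GlyD and DhaPT: with those two
reactions present under glucose, newly made glycerol is deflected straight
back into central metabolism instead of feeding the route, so only
glycerol-fed variants carry them.

### Rate laws

All mechanisms are closed forms with strictly positive denominators on the
non-negative orthant, except the substrate-inhibited ping-pong form whose
removable singularity at the origin is defined as rate 0.  Each law
factorises as `v = capacity × F`, where the capacity is `Vmax`, or
`[E]_T · k_cat` for the heterologous enzymes, or the mass-action `k`; `F`
is the dimensionless saturation factor that Method-1 estimation divides
by.  Reversible laws (glycerol-3-phosphate dehydrogenase, K_eq = 900;
aspartate aminotransferase, K_eq = 3.2) vanish exactly on the equilibrium
manifold `A·B = P·Q/K_eq`.

Four of the transcribed formulas were canonicalised to the standard closed
form of their named mechanism (rapid-equilibrium random bi-bi, ordered
bi-bi with product inhibition, reversible ping-pong bi-bi, two-substrate
Hill); the intact rows of the same tables follow these forms, which fixes
the reading of the mangled ones.

### Key parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| `E_total` (heterologous) | 100 | mM | enzyme deliberately in surplus so the route itself is never the artificial bottleneck; 1/10/100 mM reruns supported per reaction |
| B12 coenzyme | 1 (fixed) | mM | saturating versus the dehydratase's K_a = 0.008 mM |
| DhaPT mass-action `k` | 0.05 | mM⁻¹s⁻¹ | no printed source exists; explicit configuration, logged at build time |
| synth drain `k` | 0.002 | s⁻¹ | fallback before `synth_constants` recomputes them from a stoichiometric flux distribution (`k_M` = consuming flux / [M]_ss, [M]_ss = 1 mM for new metabolites) |
| export `k` (3-HP/AA) | 0.1 | s⁻¹ | first-order export stand-in; the transport step is otherwise unspecified |
| FVA pin width | 0.01 | mM/s | pins shared reactions to the kinetic flux distribution |
| 50× bound | 50 | fold | capacity-edit band of the design loop |

Native Vmax defaults (mM/s): G3pD 0.0309, AccC 0.284, AspAT 2.549738 are
the pre-overexpression values implied by the published mutant edits
(1.392/45, 0.568/2, 127.4869/50); AspC 57 is the k_cat·[E]_T estimate.
G3pP 0.05, GlyK 0.02, GlyD 10, GluD 0.02 have no printed source and are
package defaults scaled to the synthetic chassis (GlyK and GluD small
enough that the glycerol futile cycle and glutamate synthesis do not
out-compete ~10⁻² mM/s carbon fluxes); all are overridable and
recomputable via Method 1.

## Synthetic chassis

The chassis is a ~16-reaction lumped CCM: PTS uptake (glucose + PEP →
hexose-P + pyruvate), upper/lower glycolysis lumps, pyruvate
dehydrogenase, a two-step TCA loop, PEP carboxylase, pyruvate overflow,
two anabolic drains (OAA- and acetyl-CoA-consuming), oxidative
phosphorylation, ATP maintenance, adenylate kinase, transhydrogenation and
CO₂/bicarbonate interconversion.  Design constraints that shaped it:

* **Conserved moieties** — NAD/NADH, NADP/NADPH, ATP/ADP/AMP and the CoA
  thioester pool are exactly conserved, so the control-analysis
  link-matrix reduction is exercised.  Every reaction that consumes a
  pooled cofactor also binds it kinetically (otherwise a pool can be
  driven negative), and every drain of a CoA thioester returns free CoA.
* **Carbon closure** — CO₂ and bicarbonate are free carbon-bearing
  species, and the synth drains deposit carbon into a one-carbon biomass
  proxy, so a batch variant conserves total carbon to machine precision —
  the package's stoichiometry audit.
* **No uptake deadlock** — pyruvate kinase capacity is kept below the
  PTS's; otherwise PEP is drained to zero and glucose uptake halts
  irreversibly.  The pyruvate overflow lump guarantees a pyruvate outlet
  when PDH is CoA-throttled.
* **Continuous mode** (`make_continuous`) adds a constant feed (default
  30 % of the uptake Vmax — comfortably inside the sustainably absorbable
  range), first-order drains for glycerol, malonyl-CoA, β-alanine and AA
  (k = 0.01 s⁻¹), a CO₂ vent, and clamps consumer-less sinks.  These
  choices pin down what the continuous configuration only loosely
  specifies; FCC magnitudes depend on them, rank order is the robust
  output.
* The stoichiometric twin is built from the kinetic reactions themselves,
  so the kinetic steady-state flux lies in its feasible cone by
  construction.  Jittered instances (seeded log-normal, σ = 0.1, on the
  chassis capacities) support robustness studies.

What the chassis does **not** emulate: real *E. coli* flux maps, pathway
regulation (allostery, transcription), intermediate toxicity, growth
dilution, or realistic pool sizes.  Green tests on this chassis certify
the pipeline's numerics and logic — estimation identities, conservation,
control-coefficient theorems, optimisation behaviour — not quantitative
titers of the organism; quantitative replays require the deposited
BioModels entries, which the SBML loader accepts unchanged.

## Numerics

* **Integration**: scipy `solve_ivp`, BDF by default.  With [E]_T =
  100 mM the heterologous capacities (up to ~10⁴ mM/s against µM-scale
  pools) make the system permanently stiff; the classic stiff/non-stiff
  switching solver (LSODA, selectable) produces the same trajectories at
  ~100× the step count.  Defaults rtol 1e-8 / atol 1e-10; trajectories are
  invariant to tolerance halving to < 1e-6 relative.
* **Steady states**: integrate towards equilibrium, then Newton (hybr) in
  log-concentration space on the conservation-reduced coordinates: the
  link matrix `L` (exact rational row-reduction of `Nᵀ`) eliminates the
  singular directions, and the dependent species follow affinely with the
  conserved totals fixed by the start state.  Acceptance residual
  ‖rhs‖∞ ≤ 1e-8 mM/s (default target 1e-10); a failed warm start is
  re-approached by integration before the verdict "no steady state".
  Stability = all reduced-Jacobian eigenvalues with Re < 1e-9; unstable
  states are refused for control analysis.
* **FCC**: structural route `C^J = I + ε C^S`, `C^S = −L (N_R ε L)⁻¹ N_R`,
  scaled by `v_i/J`; finite-difference route re-solves the steady state
  under ±1 % enzyme-activity modulation (central, logarithmic).  Both are
  reported; they agree to < 1 % relative on the chassis and the summation
  theorem holds to < 1e-3 (typically 1e-7).
* **Capacity search**: Brent's bounded minimiser on log₁₀(fold) with
  xatol 2e-4 (≈ 5e-4 relative on Vmax), plus explicit evaluation of both
  band edges so bound-active optima are returned exactly.  Candidates
  whose simulation diverges are rejected and scored zero.
* **Method-1 closed loop**: the consistency check pins at 1e-5 mM/s
  rather than the operational ±0.01 default — the synthetic chassis
  carries ~5e-3 mM/s fluxes, so a ±0.01 pin admits maxima the kinetics
  cannot reach and the identity `v = Vmax·F` is then tested far from the
  reference state.  With tight pins the re-simulated flux reproduces the
  FVA value to < 1 %.
* **Flux-unit bridge**: kinetic mM/s are taken as stoichiometric model
  units directly (scale factor 1.0, configurable and logged).

## Open choices made

* Acetyl-CoA carboxylase's second substrate role is bound to bicarbonate
  (not ATP): the carboxylation co-substrate must appear in the rate law or
  continuous operation drives bicarbonate negative.  ATP hydrolysis is
  treated as non-limiting.
* Glycerol-3-phosphate dehydrogenase is modelled NADPH-linked as printed,
  although the *E. coli* enzyme is usually NADH-linked; the stoichiometry
  follows the source model.
* Knock-outs are represented as the 1/50 floor of the search band, not
  true deletion (available separately), keeping the search space compact.
* The design loop's "feed-limited" stop fires when the carbon source is
  exhausted before the horizon and relaxing the last capacity bound by 1 %
  improves the titer by < 1e-4 relative.

## Limitations

Replays of the published model sizes, titers and FCC rank orders require
the deposited BioModels SBML files; the corresponding tests fail with an
explicit diagnostic when the files are absent rather than silently
passing.  The finite-difference FCC route is noisy when the target flux is
near zero (β-alanine variant at its continuous steady state).  Problem
sizes throughout (chassis size, 10 jitter instances, single-iteration
design replays) are the package's test-scale defaults; all are parameters.
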