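# Methods

## Model

The package simulates a 17-state compartment model of the osteosarcoma
microenvironment: ten cell populations (naive/mature macrophages,
naive/helper/regulatory/cytotoxic T cells, naive/activated dendritic cells,
cancer, necrotic cells), four cytokine pools (IFN-γ, μ1 = TGF-β/IL-4/IL-10/
IL-13, μ2 = IL-6/IL-17, HMGB1), and three drug concentrations. Time is in
days; cell states are counts, cytokines are in arbitrary abundance units,
drugs in mg per liter of body volume.

Assumptions inherited from the model family: activation of a mature cell
from its naive pool follows the mass-action law (rate λ·[activator]·[naive]);
cytokine levels are proportional to the populations producing them; tumor
growth is logistic with carrying capacity C0, promoted by μ1/μ2; a fraction
α_NC of dying cancer cells becomes necrotic; necrotic cells release HMGB1,
which matures dendritic cells, which in turn activate helper and cytotoxic
T cells — the feedback loop that makes chemotherapy *increase* dendritic and
T-cell activity in the model.

Chemotherapy enters as an exponential kill term K·(1 − e^{−βA}) per drug:
nearly linear at low concentration, saturating at high concentration. The
kill bracket is shared across populations; only the multiplier K differs
(0.9/day for cancer, 0.6/day for every immune population — chemotherapy
preferentially kills fast-cycling cells, so immune kill rates may not exceed
the tumor's). Methotrexate is cell-cycle specific: its term carries the
phase factor φ = f − τ/a + 1/(24a), with f = 0.5 the initial vulnerable
fraction, a = 0.6667 d the cell-cycle time, and τ = min(T, f·a) the capped
exposure clock (τ and a in days; 24 = hours per day). The factor lives in
`model.cycle_phase_factor` so an alternative convention is a one-line swap.
The cisplatin enhancement of cytotoxic killing is
δ_CTc·(1 + δ_CTcA3·(1 − e^{−β3A3})), parameterized so that δ_CTcA3 = 1 with
saturating drug exactly doubles the cytotoxic kill rate. The exposure clock
T restarts at the start of each infusion event of a drug and keeps running
after the event ends — an interpretation choice: clinical schedules consist
of discrete infusions, while τ is defined only through the exposure time.

Parameter provenance: drug efficacies per µmol (MTX 1.126, DOX 1.063, CDDP
0.044 L/µmol) are converted to L/mg via molar masses (454.4, 580, 300
g/mol), giving β = 2.4780, 1.8328, 0.1467 L/mg; decay rates come from
elimination half-lives (11.5 h, 2 h, 25 min) as δ = ln2/t½ = 1.4466, 8.3178,
39.9253 day⁻¹; δ_CTcA3 = 1 and α_NCA = 0.8 are assumption-class values whose
influence the sensitivity stage quantifies. Doses in mg/m² convert to mg/L
through a reference adult male (BSA 1.9 m², volume 59.7 L). A tumor cell is
modeled as a *cube* of side equal to the cell diameter: a 275 mL tumor of
35 µm cells then holds ≈6.4×10⁹ cells, which is the figure the fraction
scale α_dim = 1.765×10⁸ was calibrated to; a sphere model would not
reproduce it.

## Regimens and integration

Treatment schedules are ordered infusion events within repeating cycles. A
bolus is modeled as a 1-hour infusion (bounded ODE source), a "continuous
24-h infusion" as a 1-day event. The infusion source v_A(t) is piecewise
constant and discontinuous at event boundaries, and φ has a kink where τ
saturates at f·a, so the integrator (LSODA, rtol 1e-6 / atol 1e-9 by
default) is restarted at every event start, event end, and τ-saturation
time; within a segment the rates are constant and τ is affine, which the
engine exploits. All solves run on the non-dimensional system — states
divided by their untreated steady-state values X∞, drugs scaled by
Ā = A·δ_A/v*, with v* the first-injection-day amount — for numerical
stability; dimensional quantities appear only at the interface. A drug
absent from a regimen gets scale 1. Small integrator-induced negatives
(below 1e-9 of state scale) are zeroed; larger negatives abort the run.

The untreated steady state is found by long-horizon integration followed by
hybrid-Newton root polishing, and doubles as the "large tumor" initial
condition.

## Synthetic cohort

The study conditions are three tumor clusters with distinct immune
compositions: one fast-growing cluster and two slower ones, the second
carrying the largest tumors. The cluster-specific base-model rates were
fitted to deconvolved patient expression data in prior work and are not
available as numbers, so the cohort module *constructs* them: a profile declares
compartment-level immune fractions (the 22 deconvolution cell types are
aggregated straight to the model's eight immune compartments), tissue
percentages, and per-capita turnover knobs; the back-solver then chooses
naive-source rates and own-death/decay rates so the untreated system is
exactly at equilibrium at the declared state. Equilibria that would require
a negative rate raise an error naming the offending equation.

Choices a reader should know, made once at design time:

* **Populations.** Immune populations are fractions × α_dim; cancer and
  necrotic populations follow the tissue-percentage ratios. Large-tumor
  cancer populations are 1.34/1.6/1.34 ×10¹⁰ for clusters 1/2/3, and the
  small/medium variants use the corresponding reference cohort values
  (e.g. 2.7×10⁸ and 6.9×10⁹ for cluster 1); these are quoted at the default
  α_dim and scale with it, keeping the whole construction homogeneous of
  degree 1 — which is exactly why α_dim cannot affect scaled dynamics, a
  property the tests assert.
* **Growth rates.** Total logistic coefficients 0.035 / 0.022 / 0.018 day⁻¹
  for clusters 1/2/3 with C∞/C0 = 0.5. Back-solving makes the net
  small-tumor growth rate about half the coefficient, i.e. ~1%/day for the
  fast cluster — the scale implied by the reference delay outcomes
  (a 6-month delay inflates the post-treatment small tumor several-fold)
  and by two-cycle MAP reductions of roughly five- to seven-fold.
* **Timescales.** Slow macrophage turnover (δ_M ≈ 0.01/day), naive pools
  recovering within days, cytotoxic/helper T-cell turnover of order
  0.1–0.2/day, necrotic clearance 1/day, cytokine equilibration within
  hours (δ = 4–10/day). Dendritic activation is dominated by HMGB1 (85%)
  and HMGB1 production by necrotic release (80%); helper/cytotoxic T-cell
  activation is dominated by dendritic presentation. These weights encode
  the necrosis→HMGB1→dendritic→T-cell axis the model is built around; with
  macrophage-dominated activation instead, helper T cells would *fall*
  during therapy because macrophages crash, contradicting the reference
  behavior the cohort is meant to reproduce.
* Per-tumor fraction tables are Dirichlet draws (concentration 200) around
  cluster means with truncated-normal tissue percentages, behind a single
  seeded generator.

What the generator does **not** emulate: gene expression or deconvolution
noise, correlations between immune composition and growth rate across
patients, inter-patient variation in chemotherapy parameters, and any claim
that the synthetic fractions estimate the real clusters' compositions. A
passing suite therefore shows the pipeline's machinery is correct and its
qualitative treatment responses are reproducible — not that the synthetic
clusters match any patient population quantitatively.

## Sensitivity analysis

Forward sensitivities s_i = ∂X̄/∂θ_i obey ds_i/dt = ∂F/∂θ_i + (∂F/∂X̄)s_i
and are integrated jointly with the state (RK45, rtol 1e-8) for all 18
chemotherapy parameters; the cell-cycle time a is excluded as a direct
measurement rather than an estimated parameter. The Jacobian and parameter
gradients are vectorized central differences (relative steps 1e-6); the
non-dimensional scales are frozen at the nominal parameter point so that
perturbing a decay rate probes dynamics, not the scale definition.
Relative sensitivities s̄_i = s_i·θ_i/X̄ mask points where X̄ falls below
1e-9 of its trajectory maximum. Time averages use trapezoidal quadrature.

Neighborhood averaging evaluates the time-averaged scores on a node set
over a ±10% box ("small neighborhood") built as the level-2 nested star
stencil (center plus one symmetric pair per dimension at the box faces,
2d+1 nodes) with a seeded Sobol fill when more nodes are requested. Both
the raw node sum (the source formulation) and the node mean are reported;
the ranking is invariant to that normalization. Verification is by central
finite differences on fully re-solved trajectories; agreement is within
0.5% relative for every parameter, and parameters with no active pathway
(e.g. methotrexate efficacy under a methotrexate-free regimen) come out
exactly zero.

On the synthetic clusters the dominant parameters are K_C, the doxorubicin
pair (β2, δ_A2), and the methotrexate pair (f, δ_A1); the assumed
parameters α_NCA and δ_CTcA3 rank near the bottom, which is the property
that matters for trusting their assumed values.

## Dose optimization

The loss is L(v, t) = (Ĉ(v,t) − C_target)² + κ·Σ|v_i| subject to
0 ≤ v_i ≤ U_i, with one dose variable per drug scaling that drug's
per-infusion dose uniformly across cycles, and default per-infusion-day
bounds 20,000 / 45 / 75 mg/m² (MTX/DOX/CDDP). The L1 penalty (not L2)
keeps the high-dose methotrexate from dominating the regularization.
Because the feasible set is the nonnegative box, Σ|v_i| = Σv_i is linear
and smooth there, so no smoothing of the absolute value is needed and
bound-constrained L-BFGS-B applies directly; gradients are finite
differences. Internally the objective is divided by C_target² — same
argmin, conditioned for ~10⁹-cell magnitudes; the reported loss is also
given on the raw scale. Multi-start (default 8 starts: zero dose, nominal
doses, box midpoint, seeded uniform draws, plus optional warm starts) makes
the search deterministic under a fixed seed; the returned loss is
recomputed from scratch at the optimum. κ defaults to 0 (pure least
squares); note that on the raw scale a κ of order C_target²/Σv is needed
before the penalty influences the optimum.

## Problem sizes and tolerances used in the shipped experiments

Tests and the acceptance run use two MAP cycles (85-day horizon) for
dynamics and non-dimensional equivalence, one cycle (45 days) for
sensitivity oracles and optimizer identities, and delay sweeps out to a
182-day start; solver tolerances are 1e-6/1e-9 for production runs,
1e-10–1e-11 for oracle comparisons. Sensitivity-vs-finite-difference checks
use relative step 1e-4 and compare at 0.5%; the monotonicity identities for
κ and C_target chain warm starts between optimizations so each solve
refines, not re-randomizes, its predecessor.

## Known limitations

* The base-model rate constants are synthetic constructions, not estimates;
  absolute populations and doses are illustrative even though they land in
  clinically plausible ranges by design of the conditions.
* Immune equations share the cancer phase factor (f, a) for methotrexate;
  separate immune cell-cycle parameters are not modeled.
* No spatial structure, no additional drugs (e.g. ifosfamide), no adjuvant
  (post-surgery) phase, no toxicity constraints beyond box bounds.
* The weekly single-agent methotrexate preset uses a 10 mg/m² dose; single-agent high-dose methotrexate is usually quoted in g/m²
  elsewhere, so that regimen's absolute effect sizes should be treated with
  caution.
* Resistance scenarios are expressed by overriding β2/β3; resistant-cell
  efficacy values are not bundled.
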