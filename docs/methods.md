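# Methods

## Model

`fuzzypolar` studies the continuous limit of Boolean regulatory networks.
A network is a directed, signed graph over two node classes: extracellular
inputs (cytokines, immune complexes, metabolic signals) that are only ever
set exogenously, and internal nodes (transcription factors and secreted
mediators) each governed by one AND/OR/NOT rule. The continuous model keeps
the rule structure and replaces the connectives with the probabilistic
fuzzy operators — conjunction `q*p`, disjunction `q+p-q*p`, negation
`1-p` — applied by structural recursion over the rule tree. Because both
binary operators are associative and commutative, the fold order of n-ary
clauses is immaterial (property-tested). The resulting fuzzy truth value
`omega_i(q)` is a polynomial mapping the unit box to [0, 1] that agrees
exactly with the Boolean rule on 0/1 states.

Dynamics: `dq_i/dt = phi[omega_i(q)] - alpha_i q_i` with the sigmoid
characteristic `phi[w] = 1/(1+exp(-b (w - omega_thr)))`. With
`omega_thr = 0.5` and `alpha_i = 1` a node's stationary level is exactly
`phi` of its rule's degree of truth. Since `phi` is confined to (0, 1), the
flow points inward on every face of the unit box: trajectories started in
[0,1]^n remain there. At any synchronous Boolean fixed point the RHS
residual is bounded by `exp(-b/2)` (each omega is exactly 0 or 1 and each
state coordinate is 0 or 1), which is the quantitative sense in which the
continuous model contains the Boolean one; the test suite asserts this
bridge for the vendored network and for 50 seeded random networks against
an exhaustive synchronous-attractor oracle.

Inputs are carried as state components with zero derivative rather than
eliminated, so the assembled system has one equation per node (29 for the
macrophage network). Unclamped inputs simply hold their initial value;
the alternative (decaying inputs) was rejected because every experiment in
scope sets inputs exogenously.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `b` | 30 | – | sigmoid steepness: small = gradual commitment, large = switch-like |
| `omega_thr` | 0.5 | – | rule-truth level giving half-maximal drive |
| `alpha` | 1 | 1/time | decay rate; sets the relaxation timescale to 1 |
| activation / inactivation | 0.75 / 0.25 | – | steady-state labeling thresholds (inclusive) |
| grid step | 0.025 | – | clamp-value resolution of scans |

Choice of `b`: the steepness is the one genuinely free parameter of the
transformation. For a node driven directly by a single clamped input, the
steady level is `phi(v)`, so the labeled "uncertainty band" has half-width
`ln(3)/b` around 0.5 and activation occurs at `0.5 + ln(3)/b`. `b = 30`
places these at 0.463–0.537 and 0.537 respectively, which on the 0.025 grid
yields NoLabel rows at 0.475–0.525 and first activation at 0.55 — the
behavior the macrophage model is calibrated to show for interferon. Values
of `b` below ~22 smear single-input transitions across most of the dose
axis and cannot produce a narrow uncertainty band; values above ~44
collapse the band to a single grid point. `b` is exposed everywhere and
recorded in all result artifacts; the Boolean-limit test suite runs at
b ∈ {10, 20, 50} independently of the default.

## The vendored macrophage network

The fixture has 29 nodes (15 extracellular, 14 internal) and 60 signed
interactions derived from its rules. The rule set is a **reconstruction**:
the original publication distributes the full rule list through
supplementary material, so the vendored file was rebuilt from the
mechanisms its text states — STAT6 silencing NFkB and STAT1 through SOCS1;
TGFB activating HIF1a while inactivating STAT1; immune complexes plus
glucocorticoids driving ERK; adenosine, TLR4 engagement and hypoxia driving
HIF1a (with glucocorticoids suppressing NFkB); IL-6's anti-TNF action
gating the autocrine NFkB–TNFA loop that makes the M1 state
self-sustaining; STAT6-driven IL-10/TGFB secretion feeding STAT3 —
constrained to the published node/edge counts and calibrated against the
two printed dose thresholds (interferon-γ activation at 0.55 with
uncertainty band 0.475–0.525; IL-6 jump at 0.45) before any other result
was inspected. Two inputs (LPS, IL13) complete the extracellular inventory
beyond the nodes named in the text and are flagged as reconstructed in the
network file header.

Known deviations of the reconstruction from the published qualitative
results, left uncorrected rather than tuned post hoc:

- TNFAe polarizes the monocyte to M1 near 0.5 (published: roughly 0.6).
- The IL1B scan reaches the M1M2b hybrid from ~0.55 (published: > 0.75).
- IL10e and MCSF scans settle in M2cM2d rather than M2aM2cM2d (the
  reconstruction has no IL-10 → STAT6 arm).
- The pro-M2a microenvironment converts M1 to M2aM2cM2d above ~0.5
  (published: M2d; same threshold region).
- Under the NFkB-on/HIF1a-off perturbation, the IL10e+TGFB environment
  yields M1M2c (published: M2a). With NFkB clamped fully active the M1
  marker can never deactivate, so any label there necessarily retains the
  M1 tag; the published labeling of that condition is not reproducible
  under the stated clamp and marker scheme.

Only the interferon and IL-6 thresholds are asserted quantitatively; all
other landscape content is covered by property-based tests.

## Labeling scheme

Markers: NFkB → M1, STAT1 → M1a, STAT6 → M2a, ERK → M2b, STAT3 → M2c,
HIF1a → M2d (configurable; ERK was chosen over AP-1 as the M2b marker, the
alternative being a table edit away). Any marker strictly inside
(0.25, 0.75) makes the whole state `NoLabel`; otherwise active tags are
concatenated in canonical order. When NFkB and STAT1 are active together
the tag collapses to plain `M1`, reflecting that the two factors jointly
define the classical pro-inflammatory macrophage; the collapse is a
labeling convention, exposed as a flag. Distance readouts are Euclidean
over transcription-factor nodes only (inputs are clamped, so their
displacement reflects the protocol, not the dynamics); per-node difference
vectors are exported so any other metric can be recomputed.

## Numerics

Integration uses LSODA with rtol 1e-8 / atol 1e-10 in windows of 5 time
units up to t_max = 200, declaring a fixed point when the RHS infinity
norm falls below 1e-6; converged states satisfy |q - phi(omega(q))| within
10x that tolerance on unclamped nodes. Clamped coordinates are re-imposed
bit-exactly after every solver window. If the horizon is exhausted, an
extra 40-unit probe window with dense output is searched for a genuine
excursion followed by a return to the terminal state within 1e-4 (the
return time refined on the interpolant, so limit cycles with any period
are recognized); such runs are classified `cyclic`, others
`undetermined`. No scan condition of the vendored network exercises the
cyclic branch; it exists because NOT-loop networks (e.g. a three-node
repressilator) genuinely oscillate and are part of the tested surface.

Scan protocol: every grid point restarts from the same initial state, so
rows are order-independent and the protocol introduces no hysteresis; a
continuation mode (warm-starting from the previous point) exists but is
off by default. Transition thresholds are reported as the first grid value
carrying the new label, with intervening NoLabel rows attached to the
transition as its uncertainty band.

## Initial states

`M0` is the all-zero vector. Named phenotype states are reconstructed 0/1
core vectors — each phenotype's marker TF plus its canonical secretory
partners under the vendored rules (e.g. M1 = {NFkB, TNFA, IL12, IL6}); the
published attractor table is supplementary material not vendored here, so
these are synthetic stand-ins, and only the M1 core is a self-sustaining
Boolean fixed point of the reconstruction at zero inputs. Hybrid names
(`M1M2b`, …) are unions of the pure cores. Arbitrary vectors and
node→value mappings are accepted everywhere a name is.

## Synthetic networks

The generator draws, per internal node, k' ≤ k distinct regulators folded
left-associatively with random AND/OR connectives and literals negated
with probability p_not, using an integer-only sampling path so a seed
reproduces the same network on any platform. It emulates the structural
class of the macrophage network (clamp-only inputs, one rule per internal
node); it does not emulate biological degree distributions, autocrine
feedback motifs, or marker semantics. Passing the property suites on such
networks therefore certifies the *machinery* (transformation, integration,
labeling, scanning) — not the biological fidelity of any particular rule
set, which is exactly why the macrophage rules ship as data that can be
replaced by any conforming file.

## Limitations

- The model is qualitative: concentrations and time are normalized, so
  thresholds are comparable within the model but not in physical units.
- No stochasticity, delays, or spatial diffusion; secretion is represented
  only through network feedback, not as an extracellular field.
- Exhaustive Boolean analysis is limited to 20 internal nodes (2^n states).
- The reconstructed rule set is faithful to the documented mechanisms and
  the calibrated thresholds, but it is not the authors' supplementary rule
  list; analyses downstream of rule details beyond the tested anchors
  should treat it accordingly.
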