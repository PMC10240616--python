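# fuzzypolar

Continuous fuzzy-logic dynamics of Boolean regulatory networks, built
around a macrophage-polarization pipeline.

## The problem

Macrophages polarize from circulating monocytes (M0) into a spectrum of
phenotypes — pro-inflammatory M1/M1a and regulatory M2a, M2b, M2c, M2d —
depending on the cytokines, immune complexes and metabolic signals in their
microenvironment. Boolean models of the underlying transcriptional
regulatory network capture the phenotype repertoire as attractors, but they
cannot ask *quantitative* questions: at what interferon concentration does
a monocyte commit to M1? How wide is the window in which no phenotype can
be assigned? Which hybrid phenotypes appear between the pure states?

`fuzzypolar` answers such questions by transforming any Boolean regulatory
network into a system of ODEs and scanning it. It is aimed at systems
biologists working with logical models who want dose-response and
phenotype-landscape readouts without hand-deriving kinetic models.

## The model

Each node $i$ carries a normalized expression level $q_i(t)\in[0,1]$. Its
Boolean update rule is made continuous with the probabilistic fuzzy
operators

$$q \wedge p \to q\,p, \qquad q \vee p \to q + p - q\,p, \qquad \neg p \to 1-p,$$

giving a fuzzy truth value $\omega_i(q)\in[0,1]$ that coincides with the
Boolean rule on $\{0,1\}$ states. The activation drive is the sigmoid
characteristic

$$\phi[\omega_i] = \frac{1}{1+\exp\!\big(-b\,(\omega_i-\omega_{thr})\big)},$$

with steepness $b$ (default 30) and threshold $\omega_{thr}=0.5$, and the
dynamics are

$$\frac{dq_i}{dt} = \phi[\omega_i(q)] - \alpha_i q_i, \qquad \alpha_i = 1,$$

so a node's stationary expression is the sigmoid-transformed degree of
truth of its rule. Extracellular nodes carry no rule; they are clamped
state components with zero derivative. At a steady state, a marker
transcription factor with $q\ge 0.75$ counts as active and $q\le 0.25$ as
inactive; the label is the concatenation of active marker tags (M1 < M1a <
M2a < M2b < M2c < M2d), with anything strictly inside $(0.25, 0.75)$
producing `NoLabel` — the range of uncertainty.

The package vendors a 29-node, 60-interaction macrophage network
(15 extracellular inputs, 14 internal nodes; the rule set is a documented
reconstruction — see `docs/methods.md`) plus a random-network generator and
an exhaustive synchronous Boolean-attractor oracle, so every stage is
testable on networks of any origin.

## Worked example

```python
import fuzzypolar as fp

network = fp.macrophage_network()
markers = fp.macrophage_markers()
system = fp.build_ode_system(network)          # b=30, omega_thr=0.5, alpha=1

scan = fp.dose_scan_1d(
    system,
    fp.ScanSpec1D(scan_nodes=["IFNG"], grid=fp.make_grid(), q0="M0"),
    markers,
)
for row in scan.rows[16:24]:
    print(f"IFNG={row.value:5.3f}  STAT1={row.state['STAT1']:.3f}  "
          f"label={row.label.label:8s}  distance={row.distance:.3f}")
```

prints

```
IFNG=0.400  STAT1=0.047  label=M0        distance=0.047
IFNG=0.425  STAT1=0.095  label=M0        distance=0.095
IFNG=0.450  STAT1=0.182  label=M0        distance=0.182
IFNG=0.475  STAT1=0.321  label=NoLabel   distance=0.321
IFNG=0.500  STAT1=0.500  label=NoLabel   distance=0.707
IFNG=0.525  STAT1=0.679  label=NoLabel   distance=1.205
IFNG=0.550  STAT1=0.818  label=M1a       distance=1.292
IFNG=0.575  STAT1=0.905  label=M1a       distance=1.348
```

Reading: as the clamped interferon-γ concentration rises, the monocyte
stays M0 up to 0.45, passes through the range of uncertainty (STAT1 between
0.25 and 0.75) over 0.475–0.525, and commits to the STAT1-specific M1-type
phenotype at 0.55. `distance` is the Euclidean displacement of the
transcription-factor state from the initial monocyte. The derived
transition record is available directly:

```python
>>> scan.transitions
[{'value': 0.55, 'label_before': 'M0', 'label_after': 'M1a',
  'uncertainty_band': [0.475, 0.5, 0.525]}]
```

The same machinery runs joint microenvironment scans from any phenotype
state (`microenvironment_scan`, with presets such as `"pro-M2a"` or the
breast-cancer combinations), scans under the constant NFkB-on/HIF1a-off
perturbation (`tgem_scan`), and two-axis phenotype-space maps
(`phenotype_map_2d`). From the shell:

```
fuzzypolar scan1d IFNG --out results/
fuzzypolar envscan --preset pro-M2a --q0 M1 --out results/
fuzzypolar tgem --preset bc-IgG-A2a --out results/
```

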