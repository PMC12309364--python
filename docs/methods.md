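# Methods

This note documents the models and procedures `g4tune` implements, the
defaults it ships, and what its synthetic-data generator does and does not
emulate.

## Motif model and library enumeration

A G4 motif is `G{t} L1 G{t} ... G{t}`: `c` G-tracts of `t` guanines each,
separated by `c − 1` loops of length ≥ 1 over {A, T/U, C} (loops never
contain G, so tract boundaries are unambiguous and a loop can never extend a
tract). Constructors enforce `t ≥ 2`, `c ≥ 4` and the loop-count arithmetic;
invalid specs are rejected rather than repaired.

Two full-factorial design strategies are enumerated:

- **(i)** fixed tract number `c = 4`; `t ∈ {2..6}` × uniform loop length
  `∈ {1..5}` → 25 specs per level;
- **(ii)** fixed loop length 2; `t ∈ {2..6}` × `c ∈ {4..7}` → 20 specs per
  level.

The strategies overlap at `c = 4`, loop length 2 (5 specs), and duplicates
are removed once, giving 40 specs per level and 80 across DNA + RNA. This
deduplication is required for the library total to come out at 80 and is the
interpretation adopted here. Within strategy (i) all loops of a motif share
one length; heterogeneous loop lengths are representable but not enumerated
by default.

**Loop realization.** The `balanced` policy cycles A → T/U → C across the
concatenated loop positions 5′→3′, which makes the composition invariant
(max count − min count ≤ 1, exact equality when the total loop length is
divisible by 3) hold by construction and is deterministic; when the total is
not divisible by 3, earlier alphabet letters receive the extra copies. The
`fixed` policy repeats one permutation over {A, T, C} in every loop; for
3-nt loops the 27 permutations form the loop-composition panel. Any
externally measured library with its own loop strings can be loaded from a
manifest CSV and overrides these conventions.

**Reference architecture.** The `(G4N3)3G4` motif with ATC loops renders as
`GGGGATCGGGGATCGGGGATCGGGG` (25 nt). A G3-tract rendering
(`GGGATCGGGATCGGGATCGGG`) of the same architecture circulates in the
literature; both are constructible here, and the formula-faithful G4-tract
form is the default.

**Disabled mutants** carry the minimum number of G→A substitutions that
makes the detector (at the parent's tract length as `min_tract`) report no
hit. The search is exhaustive over substitution counts k = 1, 2, … (cap 6 by
default; exceeding the cap raises rather than returning a partial mutant),
with candidate position sets tried in lexicographic order so ties resolve to
the 5′-most set. Minimality is verified in the tests by independent
brute-force search over all smaller substitution sets.

**Naming.** Components are named `<LEVEL>.<R>REU` with R the measured REU
rounded to the nearest 5 (half rounds up); label collisions within a
registry gain `.2`, `.3`, … suffixes in registration order.

## PQS detection and propensity score

A hit is a chain of ≥ `min_tracts` all-G windows of one tract length
`t ≥ min_tract`, consecutive windows separated by 1..`max_loop` nt. The
scanner reports every **maximal** chain (extendable chains are not reported;
overlapping maximal chains all are) for every feasible `t`, via depth-first
traversal of the window-successor graph; the positive/negative predicate
uses a longest-chain dynamic program instead, so mutant search stays fast on
G-dense inputs. Equivalence of the scanner with a from-definition
brute-force enumerator is part of the test suite (1,000 random sequences
≤ 60 nt, plus G-rich stress cases).

The propensity score is the linear form
`2·tract_length + 0.75·tract_count − 0.25·mean_loop_length`: strictly
increasing in tract length and number, strictly decreasing in mean loop
length, which reproduces the observed ordering of inhibitory strength
(> 90% pairwise rank agreement with the generator's ground truth over the
default library). It is a design gate and ranking aid only — it is **not**
a G-score, a thermodynamic stability estimate, or a topology predictor, and
its absolute values have no physical units. Detector defaults
(`min_tract 2, max_loop 7, min_tracts 4`) match the smallest designed tract
and are configurable; mutant design overrides `min_tract` with the parent's
tract length so that breaking any single tract below the designed length
suffices.

## Chassis and coordinates

The chassis fuses a 41-bp minimal human CMV-IE1 core promoter to a 57-nt
5′UTR (98 bp total). The packaged core promoter is the canonical published
CMV-IE1 core region (TATA box through +1). The packaged UTR is a clearly
flagged **synthetic placeholder**: the authentic bioproduction UTR is
proprietary, so the stand-in is guanine-free (inert to both PQS formation
and AUG creation) and licensed users should pass their own sequence to
`assemble_bpcu`. The bundled reporter CDS is likewise a minimal synthetic
stand-in for examples and tests.

Coordinates are TSS-relative with no position 0: +1 is the first UTR
nucleotide, −1 the last promoter nucleotide, and insertion at coordinate p
places the motif immediately 3′ of nucleotide p. This convention makes the
two validated optima sit directly upstream of the TSS (−1) and 6 nt into the
UTR (+6). DNA-level motifs are inserted into the coding strand as their
reverse complement (the G-rich strand is the template strand); RNA-level
motifs verbatim. The default candidate panel is 7 DNA + 6 RNA sites; only
−1/+6 are validated optima, the other coordinates are an editable screening
grid shipped as configuration, not as asserted biology.

Upstream-start screening reports every AUG strictly upstream of the intended
start codon in the transcript. Only AUG is screened (the flagged loop
variants — AAU, UAU, CAU, each completed to AUG by the following G-tract —
all create canonical starts); near-cognate starts are out of scope.

## Activity model and statistics

`REU ~ β₀ + β₁·tract_length + β₂·tract_count + β₃·mean_loop_length`, fitted
per level by OLS through the normal equations (explicitly, not via a
wrapped model object; agreement with brute-force least squares is tested).
Mean loop length is used as the loop summary because designed motifs have
uniform loops, making the mean equal the designed value; the feature triple
is a constructor argument, so an alternative summary can be supplied.
Rank-deficient designs raise an error naming a collinear feature.
Predictions are clipped to [0, 120] REU (observed activities reached 107% of
control; 120 leaves headroom). R² and the overall F-test p-value are
reported; p-values are never used for automated decisions.

Pearson correlations use the product-moment definition with two-sided
p-values from the t-transform (n − 2 df). The outlier screen fits a simple
regression, computes internally standardized residuals
`e_i / (s·√(1 − h_ii))`, and flags |z| > 2.5 (the threshold is a package
choice; the procedure, not the cutoff, is the documented method).
Components are classified structure-acting when their expression reduction
strictly exceeds 20 REU, the upper edge of the generic insertional effect
observed for disabled motifs.

## Synergy and ratio design

The two-level prediction `REU_combined = REU_DNA × REU_RNA / 100` is treated
as exact: panels report deviations and a ±12 REU agreement flag
(configurable), and no interaction term is ever refitted. The HC:LC design
space is the Cartesian product of strength levels (default 10, 30, 50, 70,
100 REU for both chains; 25 points), with encoded ratio REU_HC / REU_LC at
equal gene copy number — copy-number rebalancing is out of scope, and the
"~1:2 optimum" is read as encoded ratio 0.5 on this grid. Optimum finding is
deterministic under ties (lowest HC REU, then lowest ratio) and extracts two
rule families: titer-vs-LC correlations within fixed-HC rows, and the
titer-peak HC location within fixed-LC columns.

## Synthetic-data generator

The generator defines the study conditions under which the pipeline is
tested; its defaults are fixed and are not tuning knobs.

- **Truth model**: REU = clip(140 − 12·tract_length − 9·tract_count +
  4·mean_loop_length + level_offset, [0, 110]), with level offsets 0 (DNA)
  and −8 (RNA). These values were chosen once so the default library spans
  roughly 13–100 REU at the DNA level and 5–92 at the RNA level, matching
  the designed two-orders-of-magnitude tuning range; no default-library spec
  reaches the clip bounds, so OLS recovery is unbiased there.
- **Replicates**: observations are means of n = 3 Gaussian draws (SD 5 REU,
  truncated to [0, 110]). No numeric replicate SD is published for the
  measurements being emulated; 5 REU is a package choice, exposed as a
  parameter.
- **Context shifts**: +7 (HEK) and +17 (HepG2) REU added to the source true
  value, re-measured with the same replicate structure. Using replicate
  means (rather than a single draw) mirrors the triplicate design and
  tightens the shift estimator; at 40 components the estimate lands within
  ±2 REU of the planted shift.
- **Dual controllers**: observed = prediction + Uniform(−10, 10), clipped at
  0. Bounded uniform noise (not Gaussian) makes the ±12 REU agreement
  property provable by construction; a Gaussian alternative would make it
  only probable.
- **Titer surface**: titer = scale · (REU_LC/100)^1.0 ·
  exp(−tent(log ratio)), an asymmetric log-ratio tent (slope 1.3 above the
  0.5 peak, 0.8 below), normalized so the unengineered control point
  (100, 100) reads 100%. This is the simplest multiplicative family that is
  simultaneously strictly increasing in LC at every fixed HC, unimodal in
  the encoded ratio with the peak planted at 0.5, and well-separated at the
  design grid points. Measurement noise is multiplicative lognormal
  (fractional SD 0.05), typical of titer assays and strictly positive; at
  the peak it corresponds to ~5% of peak titer, under which the optimum is
  recovered at every seed in a 100-seed suite.

**What passing tests show — and don't.** The generator reproduces the
*statistical structure* of the measurements (monotone feature-activity
relationships, replicate noise, context offsets, bounded synergy deviations,
a unimodal titer surface), so green tests demonstrate that the pipeline
correctly recovers planted structure at realistic noise. They do not
validate the biology: real G4 activities saturate and interact in ways a
three-feature linear model only approximates, real loop-composition effects
are not exactly zero, and real titer surfaces need not be separable. The
generator also omits single-cell variability (population means only),
REU-dependent noise, and any product-specific processing kinetics.

## Numerical choices and limitations

- Deterministic orderings everywhere: enumeration (strategy i before ii,
  lexicographic), scanner output (by start), mutant ties (5′-most),
  optimum ties (lowest HC, then ratio).
- REU label rounding: nearest 5, half up.
- Seeds: one integer seed drives each simulation; identical (seed, config)
  gives byte-identical tables.
- The mRNA-context worked panel (nominal 90/70/50/35 vs observed
  75/55/35/25) gives r = 0.997, p = 0.003 — consistent at two decimals with
  the published correlation for that comparison.
- Not implemented by design: QGRS G-scores and G4Hunter scores, folding
  topology and thermostability prediction, near-cognate start codons,
  vector-backbone modelling, ANOVA/post-hoc replicate statistics, and
  mechanistic kinetic models of why the multiplicative synergy rule holds.
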