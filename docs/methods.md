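# Methods

## Scope and intent

`nfkbcoupling` implements a reduced deterministic model of the coupled
canonical/noncanonical NF-κB pathways with discrete translational delays,
the delay-scan simulation experiments built on it, and the qPCR
expression-analysis computations that accompany such studies (comparative
Ct, Z-score transformation, average-linkage clustered image maps,
genomic-DNA standard curves and ChIP fold enrichment). A synthetic-data
module emulates the study designs so every stage runs without access to
raw measurements.

## The delay model

### State and mechanisms

Fourteen species: active IKK; IκBα mRNA/protein; the cytoplasmic
RelA·IκBα complex and free nuclear RelA (their sum is conserved); a
canonical reporter mRNA (the NFKBIA/TNFAIP3/IL8 class); TRAF1 mRNA and
protein; free NIK; the TRAF1·NIK complex; p100 mRNA and protein; p52; and
TNIP1 mRNA as the noncanonical reporter. Mechanisms: TNF steps the IKK
activation rate; IKK liberates RelA from the IκBα complex; RelA drives
IκBα (negative feedback), the reporter, and seed-level TRAF1 and p100
transcription; TRAF1 protein captures constitutively synthesized,
fast-turnover NIK into a stable complex; the complex processes p100 to
p52 by saturable (Michaelis) kinetics; p52 drives TNIP1 and — crucially —
feeds back on TRAF1 and p100 transcription. TRAF1 and p100 translation
read their mRNA at fixed lags τ₁ and τ₂ (nominally 120 and 90 min),
making the system a constant-delay DDE integrated by the method of steps
with the pre-stimulus steady state as constant history.

### Why the dual delayed feedback and saturable processing

Three timing facts must hold simultaneously: the p52 onset (coupling
interval, θ = 0.10 of the nominal plateau rise) is ~360 min at delays
(120, 90); it collapses to ≤ 15 min when both delays are removed; and
reducing either delay *alone* hits a plateau (for the TRAF1 axis, exactly
at 90 min — the other protein's delay). A pure feed-forward cascade
cannot do this: every run is, to leading order, a time-shift of one ramp,
so removing the delays can shorten the onset only by about max(τ₁, τ₂).
A positive feedback through *one* delayed step paces the onset with that
delay alone and produces no plateau on the other axis. The structure that
reproduces all three facts is an AND-gated loop through *both* delayed
steps: p52 production requires an amplified complex (TRAF1 branch, paced
by τ₁) *and* amplified p100 supply (paced by τ₂), with saturable
processing capping what either branch can do alone. Onset then proceeds
in ignition waves that each cost roughly the larger delay — nominally
whiff at ~max(τ₁, τ₂), amplification waves at multiples of it, and
threshold crossing on the second wave (≈ 3·max), while the undelayed
system ignites continuously within minutes. Steep transcriptional
activation (Hill coefficient 4, plausible for promoters with multiple κB
sites) and distinct activation thresholds for the p100/TNIP1 promoters
(`hill_K_p52`) versus the TRAF1 promoter (`hill_K_p52_traf1`) keep the
wave count robust across the delay grid; with a Hill coefficient of 2 the
plateau structure could not be realized within tolerance anywhere in an
extensive (≈2500-candidate) parameter search.

### Parameters

All rates are per minute, abundances in arbitrary units; the shipped
defaults (`src/nfkbcoupling/data/default_params.cfg`) are the calibrated
nominal set. The ones that matter most:

| parameter | default | role |
| --- | --- | --- |
| `tau_traf1_min`, `tau_nfkb2_min` | 120, 90 | translational delays (min) |
| `txn_max_traf1`, `txn_max_p100` | 0.124, 0.134 | RelA-driven seed transcription |
| `txn_fb_traf1`, `txn_fb_p100` | 218, 1425 | p52-driven autoregulatory transcription |
| `hill_K_p52`, `hill_K_p52_traf1`, `hill_h` | 0.66, 3.08, 4 | p52 activation thresholds and steepness |
| `proc_rate`, `proc_K` | 1.0, 0.0247 | saturable p100→p52 processing |
| `deg_p52` | 0.214 | p52 turnover; saturates the plateau within the 600-min horizon |
| `ikk_act_rate` … | 2.0 … | canonical arm; gives a reporter-mRNA first peak at ~4 min |

Calibration (`calibrate_nominal`) is a deterministic coordinate search on
a shrinking multiplicative grid over the feedback/threshold parameters,
accepting only strict improvements of the residual against three targets:
nominal interval 360 ± 15 min, zero-delay interval ≤ 15 min, canonical
reporter first peak ≤ 60 min. A start that already meets the targets is
returned unchanged, so re-calibrating from the shipped configuration is
bit-stable. With the shipped set the computed facts are: nominal interval
345.4 min; zero-delay interval 11.9 min (the grid minimum, at (0, 0));
TRAF1-axis plateau flat to within 7.3 min on [0, 90] and broken by
+26.5 min at 105 (threshold exactly 90); an NF-κB2-axis plateau over
[0, 30]. The margins against the 15-min/7.5-min tolerances are small but
exactly reproducible: the whole computation is deterministic.

### Numerics

Fixed-step classical RK4 with step 0.05 min; the two lagged mRNA reads
use linear interpolation of a per-step history buffer (zero lag reads the
current stage value, so the τ = 0 model is exactly the pure ODE). Halving
the step changes every species by < 1e-4 of its dynamic range. Negative
round-off excursions are clamped to zero and logged; any clamp beyond
1e-8 a.u. aborts the run. The pre-stimulus steady state is solved
analytically (nuclear RelA is zero without stimulus, the TRAF1/NIK pair
and the p52 feedback reduce to scalar root finds; the smallest p52 fixed
point is taken) and certified by residual derivatives < 1e-8 a.u./min,
with a relaxation fallback. The inner loop is numba-compiled with a
pure-Python fallback. Scans reuse the steady state across runs (it does
not depend on the delays); 1681 simulations take ~10 s compiled.

### Scan conventions

Scans cover 0–600 min in 15-min steps. Single-axis scans run the 41
lattice points plus one nominal baseline run (42 simulations per
protein); the combinatorial scan runs the full 41 × 41 = 1681 grid, with
the θ anchor still taken from a nominal reference run. The onset
threshold θ·(nominal plateau rise) is frozen per scan so intervals are
comparable. Runs that never cross the threshold within 600 min carry a
NO_ONSET sentinel, are written as NA, and are excluded from minima and
plateau statistics; under the calibrated max-of-delays pacing this covers
the large-delay corner of the grid (onset ≈ 3·max(τ₁, τ₂) exceeds the
horizon once max(τ₁, τ₂) ≳ 200 min). The plateau threshold readout walks
the axis upward and reports the largest lattice value below which all
intervals lie within 7.5 min (half the grid step) of each other.

The three-row regime table (fast / near-nominal / delayed) is implemented
literally with first-match precedence. It is a conceptual decision rule:
the ODE scan is only required to agree with its unambiguous corners
(both delays below nominal → never slower than nominal; both at or above
with one strictly above → never faster), which the tests assert. Full
row-3 agreement is not asserted — the table's asymmetric third row is not
a property any single smooth onset function can reproduce everywhere.

### Delay recovery

`DelayRecovery(times, p52, params).fit()` grid-searches the 15-min
lattice for the least-squares match to an observed p52 series (600 min,
1-min sampling), using a cached library of simulated series. SSE ties
within a relative tolerance of 1e-9 resolve to the lexicographically
smallest (τ₁, τ₂) pair. At 5% multiplicative noise the true pair
(240, 180) is recovered to within one lattice step in all of 20 seeded
trials.

## Expression pipeline

* **ΔΔCt** — replicates are averaged on the Ct scale (geometric mean on
  the linear scale); ΔCt is taken against the reference assay per
  (condition, time) column; ΔΔCt subtracts the control column (control
  condition at the earliest time), so that column is 1 by construction.
  Efficiency is fixed at 100% (2-fold per cycle). Columns lacking a
  reference Ct are emitted as missing with a logged warning; missing
  inputs propagate.
* **Z-scores** — per-row over observed entries with the sample (n−1)
  standard deviation; constant rows map to zeros; rows with fewer than
  two observations become missing. The transform is applied jointly
  across all 2 × 6 condition–time columns (configurable by subsetting the
  matrix first).
* **Clustering** — UPGMA on Euclidean row distances; missing data are
  handled pairwise-complete with a √(p_total/p_observed) rescaling; rows
  comparable with nothing are excluded and reported. Ties break toward
  the smallest cluster-index pair and leaf order puts the smaller cluster
  index left, making the tree fully deterministic. The implementation is
  in-package because these conventions are part of its contract; scipy's
  average linkage is used as an independent cross-check on matrices with
  unique distances, and a brute-force oracle (cross-pair means recomputed
  from the original matrix) checks 60+ random instances.
* **Standard curves / ChIP** — ordinary least squares of Ct on log10
  mass over a ≥ 1-decade dilution series (1–100 ng by default);
  efficiency = 10^(−1/slope) − 1; ChIP enrichment is (IP/input)
  normalized to the unstimulated ratio, with template masses recovered by
  inverting the curve.

## Synthetic data

The generator emulates the study's structures, not its numbers: 50 panel
genes (the shipped primer table) × 6 time points (0, 1, 3, 6, 12, 24 h —
a declared choice; the source figures span 1–24 h) × EMT/control × 3
replicates. Cluster archetypes encode the qualitative biology: interferon
genes induced in control but shut down under EMT; NF-κB/growth-factor
genes amplified by EMT; TRAF1/NFKB2/TNIP1 peaking at 12 h with ~20-fold
EMT versus ~3-fold control induction; the mesenchymal program
constitutively up in EMT. Noise is additive Gaussian on the Ct scale
(default SD 0.25 cycles — the natural scale of qPCR error); missing cells
are injected at a default rate of 4%; Cts are built by inverting the
ΔΔCt formula so the zero-noise round trip is exact. Everything is a pure
function of (plan, seed).

What passing tests on these data do **not** show: the generators contain
no amplification-efficiency variation, no condition-dependent reference
drift, no correlated replicate error, and the planted clusters are
cleaner than biological ones, so pipeline performance here is an upper
bound on real-data performance.

## Problem sizes and limitations

Default experiment sizes: 600-min horizon at 1-min output; 42-run
single-axis and 1681-run combinatorial scans; 20-seed recovery and
planted-partition experiments; 8 × 6 matrices for the clustering oracle.
Known limitations: A20-mediated IKK feedback is omitted (A20 appears only
within the reporter class); RelA·p52 dimer bookkeeping is not modeled
(p52 acts directly); stimulus programs are step inputs (poly I:C is
represented by the same step); the model's arbitrary units are anchored
only by the timing calibration, so absolute abundances are not
interpretable; and the large-delay corner of the combinatorial grid is
reported as NO_ONSET rather than extrapolated beyond the 600-min horizon.
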