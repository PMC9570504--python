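# Methods

## Gating model and simulator

Each gap-junction channel is a continuous-time three-state Markov chain —
main open (conductance γ_main), residual (γ_res) and fully closed (0 pS) —
gated by the absolute transjunctional voltage |V_j| with polarity-specific
half-deactivation voltage V_0 (mV) and sensitivity A (1/mV). Real GJ
channels carry two hemichannel gates in series; because macroscopic
Boltzmann fits treat each polarity independently, the simulator collapses
them to one effective gate per polarity. This reproduces the fitted
observable; it is a modelling convenience, not a claim about contingent
hemichannel gating.

The opening and closing rates split the Boltzmann exponent symmetrically:

    α(V_j) = k0 · exp(−A(|V_j| − V_0)/2)
    β(V_j) = k0 · exp(+A(|V_j| − V_0)/2)

so the stationary open probability α/(α+β) = 1/(1 + exp[A(|V_j| − V_0)])
is exactly the two-state Boltzmann law, with both rates equal to k0 at
|V_j| = V_0. Published data constrain only the stationary curve, not the
kinetics; k0 is therefore a calibration choice: 2 s⁻¹ in the macroscopic
regime (relaxation completes well before the last 500 ms of a 5 s step)
and 0.5 s⁻¹ in the single-channel regime, where slow gating leaves the
first ~2 s of a step dominated by the initial open level, matching the
appearance of published unitary records.

A closing transition enters the fully closed state with probability
p_fullclose (default 0.2, chosen once as a realistic full-closure
fraction; both residual and fully closed levels are observed in real
records) and the residual state otherwise; both gated states reopen at
rate α, which preserves the Boltzmann open probability when the gated
states are lumped. Consequence for macroscopic analysis: the stationary
*conductance* floor is (1 − p_fullclose)·γ_res/γ_main, slightly below the
tabulated G_min used to set γ_res. With p_fullclose = 0.2 the fitted G_min
of simulated wild-type pairs sits ≈0.04 below the preset, within one
published SD.

Simulation is discrete-time at the sampling interval (10 kHz default),
guarded by dt·max(α, β) ≤ 0.1; rates above 10⁴ s⁻¹ are clamped with a
warning. Internally, sojourns are drawn geometrically (the exact law of
per-sample stepping; memorylessness makes re-sampling at voltage-segment
boundaries exact), so cost scales with the number of gating events rather
than samples. Channels start from the stationary distribution at the
holding potential (0 mV, i.e. predominantly open). Recording noise is
white Gaussian (σ = 2 pA at 10 kHz) low-passed at the 1 kHz acquisition
cutoff with the same Gaussian filter used in analysis, leaving ≈0.9 pA
r.m.s. stored and ≈0.4 pA after the 200 Hz analysis filter. Traces are
written as UTF-8 text blocks (`## trace i` separators, `# key = value`
headers, one pA sample per line, 4 decimals).

## Macroscopic analysis

Per step: I_peak is the baseline-subtracted mean over a 10 ms window
starting 5 ms after step onset (the blank skips the capacitive transient
and is shorter than any plausible gating relaxation); I_ss is the mean of
the last 500 ms of the step; conductances are G = I/V_j and
G_j,ss = G_ss/G_peak with per-step (per-trace) peak normalization. The
pair conductance G_j comes from the ±20 mV steps; pairs above 0.01 nS
(≈3× the noise-limited conductance resolution at the default noise) count
as coupled, and pairs at ≥9 nS are flagged as excluded from gating
analysis. That exclusion limits voltage-clamp error on real rigs; the
simulator does not model clamp error, so simulation-based recovery tests
fit the flagged pairs anyway.

The Boltzmann fit is bounded least squares (0 ≤ G_min, G_max ≤ 1.5,
0 ≤ V_0 ≤ 150 mV, 0 ≤ A ≤ 1 /mV) with multistart over
V_0 ∈ {20, 40, 60, 80} mV, unweighted across V_j points, reporting the
best converged start; G_max is free even though published tables omit it —
this absorbs the small peak-normalization bias (a few % of channels are
gated at holding, so G_peak slightly underestimates the true maximum)
without disturbing V_0 or G_min. Fits pinned at A ≈ 0 or with an
essentially flat span are flagged degenerate rather than trusted.

## Single-channel analysis

Traces are filtered with a Gaussian low-pass at 200 Hz. The cutoff
convention is the −3 dB point: kernel σ_t = 0.1325/f_c, 10–90% rise time
0.3321/f_c — stated explicitly because "200 Hz" alone does not fix the
kernel.

The all-point histogram covers the first 2.0 s of the step (configurable).
Bin width follows Freedman–Diaconis clipped to [0.05, 0.2] pA: the floor
avoids empty-bin noise, and the cap corrects Freedman–Diaconis's
overestimate on multimodal amplitude distributions, whose IQR spans the
full baseline-to-open range (≈0.6 pA bins otherwise, coarser than the
0.4 pA filtered noise sd). The amplitude-estimation pipeline
(`estimate_amplitude`) also prepends 0.3 s of pre-step baseline so the
zero-current level is always represented; without it, windows lacking a
full closure make the residual level the component nearest 0 pA and
corrupt the baseline assignment.

Histograms are decomposed into K ∈ {2, 3, 4} Gaussian components sharing
one width (recording noise is level-independent), fitted by
Poisson-weighted least squares and selected by BIC; unweighted fitting
lets high-count bins drive the objective and splits true peaks. The
baseline is the component nearest 0 pA; the main open level is the
component farthest from baseline carrying ≥5% of the samples; remaining
components are reported as subconductance states and excluded from γ_j.
Unimodal histograms yield a "no events" result, not an error.

γ_j is the ordinary least-squares slope (free intercept) of i_j magnitude
against |V_j|, polarities pooled. Per pair, replicate amplitudes at the
same |V_j| are averaged after discarding values below 0.6× the largest
replicate: a sweep in which the channel deactivated before the histogram
window resolves only the ~24% residual level, and including it as the
main open state biases the slope by tens of percent — the filter mirrors
the manual identification of the main open level across a trace gallery.
Both the pooled regression on pair-averaged points and the per-pair
slope mean ± SD are reported.

Idealization uses half-amplitude threshold crossing on the 200 Hz-filtered
step portion, with events shorter than the dead time (2× the filter rise
time, ≈3.3 ms at 200 Hz) merged into the flanking sojourn, shortest
first — merging never increases the event count. The residual and fully
closed levels both fall below the half-amplitude threshold and are lumped
as "closed". Dwell statistics report the arithmetic mean open duration
and event count per V_j; a V_j with no open events is absent, not zero.

## Group statistics

Kruskal–Wallis (tie-corrected H, chi-square reference with k−1 df),
Dunn's post hoc z-tests restricted to variant-vs-reference comparisons
(pooled mid-ranks, tie correction, Bonferroni over performed comparisons
by default, raw p selectable), Mann–Whitney U (exact two-sided p by
enumeration of the U null distribution when there are no ties and
n_a·n_b ≤ 400, otherwise normal approximation with tie and continuity
correction) and pooled-variance Student's t. Only distribution tail areas
come from scipy.special; degenerate inputs follow the p = 1 convention
(all values identical, or zero variance with equal means).

Calibration note: the exact Mann–Whitney test at n = 6 per group is
discrete; its attainable two-sided level at α = 0.05 is 38/924 ≈ 0.0411.
Monte-Carlo calibration checks therefore need ≥10⁵ replicates for the
standard error to resolve a [0.04, 0.06] acceptance band. Dunn's
Bonferroni-adjusted per-comparison rejection rate targets family-wise
error and is by design below α; it is checked for internal consistency
(adjustment factor, antisymmetry, permutation-oracle agreement in mid-p
convention) rather than against the per-test band.

## Steric-clash screening

PDB files are parsed with gemmi after a fixed-column validation pass that
reports truncated or unparsable ATOM/HETATM records with their line
number; waters are skipped, the highest-occupancy alternate conformer is
kept, and unknown elements fall back to a 1.70 Å radius with a warning.
Heavy-atom pairs between two residue selections are enumerated with a
uniform cell grid (5 Å cutoff), so cost scales with contacts. Pairs
within two covalent bonds are excluded; bonds are inferred from covalent
radii + 0.4 Å slack. A pair clashes when d < r₁ + r₂ − 0.4 Å and is a
contact when d < r₁ + r₂ + 0.5 Å; radii and tolerance follow common
clash-screening practice, since no numeric criterion is recoverable from
visual inspection in a molecular viewer. The interface profile tabulates
minimal heavy-atom distances for NT (4–17) × TM2 (85–95) residue pairs
per subunit, intra-subunit and with the cyclically adjacent chain;
unmodelled residues are flagged missing, not fatal. Mutant side chains
are not built — the module scans supplied coordinates only, as side-chain
placement would require a rotamer library and is a separate modelling
problem.

## What the synthetic data do and do not show

The generator reproduces: Boltzmann-distributed stationary gating per
polarity, three conductance levels, exponential dwell times, Gaussian
recording noise shaped by a 1 kHz acquisition filter, and the ±20…±100 mV
step protocol at 10 kHz. It does not emulate series-resistance or
space-clamp error (the 9 nS rule is therefore a flag, not an active
filter, on synthetic data), contingent gating of the two hemichannel
gates, slow chemical gating, multi-exponential or voltage-dependent
residual kinetics, baseline drift, or capacitive transients. Passing
recovery tests therefore demonstrates that the analysis chain is
unbiased under the stated model at realistic noise, not that it is robust
to every artifact of real recordings.

## Problem sizes used in tests

Gamma-recovery runs use 3 synthetic pairs × 3 sweeps × 6 voltages per
conductance preset (2.5 s steps); macroscopic recovery uses 6 pairs of
150 channels on 5 s steps; simulator-law checks use a single noise-free
channel for 2500 s at 1 kHz (≈5×10⁴ transitions); statistical calibration
uses 10⁵ null replicates; clash-oracle comparisons use 300–500-atom toys.
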