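# Methods

## Trajectory metrics

**Helix axis and A/B angle.** A helix axis is the first principal component of
the helix's Cα coordinates (SVD of the centred set), sign-oriented from the
N-terminal to the C-terminal Cα; fewer than 4 Cα atoms or a fully degenerate
point set is an error. The A/B interhelix angle is the arccos of the dot
product of the two oriented unit axes, so it lives in [0°, 180°] and is
symmetric in its arguments. PCA is used because it is exactly testable (the
axis of collinear points is the line itself) and is the standard construction
when no explicit fitting convention is published for a system. The helix A/B
residue ranges, hinge domains and pivot residue are configuration values
(shipped defaults use canonical cNTnC assignments mirrored by the synthetic
scaffold: helix A = chain C 14–28, helix B = 38–48, N-lobe = 1–85, pivot = 89,
ITC domain = 93–161); they must remain user-overridable because helix
assignments differ between numbering conventions.

**Hinge angle and interdomain distance.** The hinge angle is measured at the
pivot centroid between the vectors to the Cα centroids of the two quasi-rigid
domains; the interdomain distance is the distance between those centroids.
Both are invariant under global rigid transforms (tested to 1e-6).

**Salt bridge.** D159–R83 occupancy is the fraction of frames in which the
minimum distance between the Asp carboxylate oxygens and the Arg guanidinium
nitrogens is below 4.0 Å — the conventional ionic-contact threshold, exposed
in configuration since no published cutoff fixes it. For wild-type troponin
position 159 is glycine: the carboxylate selection is empty and the occupancy
is 0 by definition rather than an error.

**Contacts.** A ligand contacts a residue when the minimum distance over all
ligand-atom × residue-atom pairs is *strictly* below 2.5 Å; "2.5 Å exactly" is
not a contact. All atoms participate, hydrogens included when present
(`heavy_only` switches to heavy atoms). Hotspots are residues with contact
probability strictly above 0.10, sorted by probability (ties by chain and
residue number). Attachment applies the same criterion against the whole
protein and segments the raw per-frame bound state into maximal episodes with
no smoothing (an optional debounce window exists, default 0). No
periodic-boundary imaging is applied: coordinates are assumed pre-imaged,
which holds for the synthetic data and for typical post-processed MD output.
On small instances every contact output is checked against a brute-force
all-pairs scan.

## Distribution summaries and the recoupling call

Each pooled metric series reports the sample mean and std, the percentage of
samples strictly above a boundary (110° for the A/B angle, the open-state
edge), and the FWHM of a Gaussian-kernel density estimate (Scott bandwidth,
1024-point grid extended 3 bandwidths past the sample range, half-height
crossings of the *global-maximum peak* found by linear interpolation). The
main-peak convention matters for multimodal cases (the EGCG hinge
distribution); the %>110° figure is computed on samples, not KDE area, because
it is estimator-free. Frames from the 5 runs of a condition are concatenated
before summarizing; per-run summaries remain available for dispersion
reporting. Fewer than 10 samples, or an all-identical series, is an error.

The phosphorylation delta is mean(P) − mean(uP) (same convention for FWHM and
%>110°). A candidate condition is classified *restored* when its delta has the
same sign as the wild-type delta and its magnitude exceeds a dead-band
(defaults 0.5° for angles, 0.25 Å for distances, 1 percentage point for
%-above). The dead-band keeps near-zero shifts (e.g. ECG's −0.2°) from
counting as restoration; it is a declared package convention, not an inferred
property of the source data.

## Motility

The Hill model f = f_min + (f_max − f_min)/(1 + (EC50/[Ca])^n_H) is fitted by
bounded least squares on log₁₀[Ca²⁺] with all four parameters free;
initialisation takes the half-activation crossing for EC50 and n_H = 2. A
curve whose activation range is below 0.05 cannot constrain the model and is
rejected; a fitted EC50 outside the measured span warns but does not fail.
Standard errors come from the covariance via the delta method. The coupling
call uses the mean of per-pair EC50(P)/EC50(unP) ratios (matching how
single-replicate ratios are conventionally quoted), SEM for n ≥ 2, and a
two-tailed paired t-test on log EC50 (ratios are multiplicative) for n ≥ 3;
coupled = mean ratio > 1.5 and, when testable, p < 0.05. The 1.5 threshold
separates the observed coupled (≥ 1.73) from uncoupled (≤ 1.33) conditions and
is configurable. Single-pair calls carry an explicit
`significance_available = False` flag. The fixed-[Ca²⁺] screen takes the
concentration as an input (published protocol text is ambiguous about the
value) and is positive when phosphorylation significantly lowers the paired
fraction motile.

## Myocyte transients

Beats are segmented at threshold crossings of the smoothed (5-sample centred
moving average) negative length derivative, at most one onset per stimulus
period; onset-interval CV > 20% raises an arrhythmia warning. Within a beat,
the onset is refined to the 10%-of-amplitude crossing on the shortening phase
— instrumentation vendors do not publish an onset convention, so it is
configuration. L₀ is the pre-onset median length; amplitude is
100·(L₀ − min)/L₀; ttp90 runs from onset to the interpolated 90%-of-peak-
shortening crossing; ttb90 from the peak to recovery of 90% of the shortening
amplitude toward L₀ (a beat that never recovers inside its window reports
ttb90 as missing). Per-cell features are medians over accepted beats, robust
to one bad beat. Lusitropy is 1 − ttb90(+dob)/ttb90(−dob) per cell; group
statistics are means ± SEM of per-cell deltas with two-tailed paired t-tests
and two-level star coding (* p < 0.05, ** p < 0.01).

## Synthetic data

The trajectory generator emulates the structure of long troponin-core MD runs
— 5 runs × 3750 frames at 0.4 ns/frame by default — on an abstract Cα-level
scaffold (chain C, residues 1–161, pseudo-Cα spacing 2 Å) built so the default
region definitions apply unchanged. Per frame it realizes *exactly*: a sampled
A/B angle (rigid rotation of the helix-B arm), a sampled hinge angle and
interdomain distance (the N-lobe centroid is placed at the polar position
about the pivot that solves the triangle with the static ITC centroid), a
Bernoulli salt-bridge state (carboxylate oxygens placed at 3.0/8.0 Å from the
guanidinium nitrogens), and a two-state Markov ligand with stationary bound
fraction p_on/(p_on + p_off) (bound frames pin a ligand atom 2.0 Å from its
target residue along a collision-checked direction; unbound frames place it
beyond the protein's bounding sphere + 20 Å). Angle realization being exact
means recovery tests isolate metric-code error from generator error; every
per-frame value is recorded in a JSON manifest. All randomness derives from
one seed through spawned per-run substreams.

Default distribution parameters are the wild-type apo unphosphorylated
condition (A/B N(101.81°, 9.15°), hinge N(121.61°, 7.24°), distance
N(30.18 Å, 1.34 Å), salt-bridge occupancy 0); mixtures of Gaussians are
supported for multimodal conditions. What the generator does **not** emulate:
force-field physics, solvent, frame-to-frame autocorrelation of the angles
(samples are i.i.d., so passing recovery tests shows the measurement chain is
correct, not that the analysis is robust to slowly-decorrelating MD data),
ligand chemistry, or multi-residue binding footprints (each bound episode
touches one target residue).

Activation curves use the Hill form with defaults from the native condition
(EC50 0.059 µM, ratio 2.24, n_H = 2, f_min 0.05, f_max 0.80 — cooperativity
and plateaus are field-typical choices since only EC50s and ratios are
published), 8 log-spaced concentrations spanning EC50/20 to EC50·ratio·20, and
additive Gaussian noise. Transients use a raised-cosine two-phase beat
template whose rise/decay durations are solved numerically so the *measured*
ttp90/ttb90 (analyser conventions above) equal the requested values; defaults
are L₀ 120 µm, amplitude 8%, ttp90 0.15 s, ttb90 0.45 s at 250 Hz sampling
with ~1%-of-depth noise, slow sinusoidal drift, and 5% cell-to-cell parameter
spread (truncated at 2σ so timing jitter cannot make a beat infeasible);
combinations whose rise+decay exceed the stimulus period are rejected.

## Pipeline and problem sizes

The pipeline replays every reference condition (shipped CSVs of
condition-level statistics under `tncoupling/refdata/`) through
generate-and-re-measure, producing study-shaped tables and a per-ligand
cross-level summary whose agreement score is the fraction of tiers matching
the majority call. Externally computed MMPBSA binding energies are echoed from
a side input, never computed. Report assembly defaults to 2 runs × 1500 frames
per trajectory condition, 3 curve replicates at noise 0.03, and 12 cells per
myocyte condition — sizes chosen so a full 14-condition report builds in
seconds while each statistic's sampling error stays well inside the dead-bands
used for classification; single-condition analyses and the acceptance script
use the full 5 × 3750 frames. Reports are deterministic given (config, seed)
and carry the package version and a hash of analysis-relevant configuration.

## Known limitations

* FWHM from a KDE is biased slightly upward (bandwidth convolution), visibly
  so for sharp multimodal densities; the main-peak convention can halve the
  reported width when modes are well separated.
* The recoupling dead-bands and the 1.5 coupling-ratio threshold are package
  conventions; condition calls within a dead-band's width of the boundary
  should be read as borderline.
* Hill fits with all four parameters free need concentrations on both sides
  of the EC50; heavily one-sided designs fit but warn.
* Beat features assume one contraction per stimulus period; alternans or
  spontaneous activity will trigger the arrhythmia warning and may corrupt
  per-cell medians.
* PDB parsing intentionally rejects insertion codes; renumber first.
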