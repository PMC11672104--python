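# tncoupling

Analysis of **phosphorylation coupling in cardiac troponin** at three levels:
molecular-dynamics trajectory metrics, in vitro motility Ca²⁺ sensitivity, and
cardiomyocyte relaxation.

## The scientific problem

β-adrenergic stimulation activates PKA, which phosphorylates cardiac troponin I
at Ser22/Ser23. In healthy thin filaments this lowers the Ca²⁺ affinity of
troponin 2–3 fold and speeds myocyte relaxation (**lusitropy**). Many
cardiomyopathy mutations (TnC G159D, TnT R92Q, ACTC E99K, Tm E180G, …) make
Ca²⁺ sensitivity independent of phosphorylation (**uncoupling**) and blunt
lusitropy; some small molecules — silybin B, EGCG, resveratrol — restore the
response (**recoupling**), while close analogues (silybin A, ECG) do not.

The package quantifies that coupling, for people who analyse MD trajectories of
the troponin core, motility-assay activation curves, or IonOptix/CytoCypher
shortening records:

* **Trajectory tier** (`io`, `geometry`, `contacts`, `diststats`): per-frame
  TnC helix A/B interhelix angle θ_AB (first-principal-component axes, N→C
  oriented; θ_AB > 110° marks the open hydrophobic patch), NcTnC–ITC hinge
  angle at a linker pivot, interdomain centroid distance, D159–R83 salt-bridge
  occupancy (cutoff 4 Å), and ligand contact occupancy (min atom distance
  < 2.5 Å), summarized as mean/std/FWHM/%>110°. The phosphorylation shift
  Δ = mean(P) − mean(uP) is compared in sign and magnitude with the wild-type
  shift to call recoupling.
* **Motility tier** (`motility`): four-parameter Hill fits
  f = f_min + (f_max − f_min)/(1 + (EC50/[Ca²⁺])^n_H) to fraction-motile
  curves; the coupling statistic is the EC50(P)/EC50(unP) ratio (coupled when
  mean ratio > 1.5 with a significant paired t-test on log EC50), plus a
  fixed-[Ca²⁺] paired screen.
* **Myocyte tier** (`transients`): beat segmentation of 10 s / 1 Hz
  cell-shortening records; %L₀ amplitude, ttp90 (onset → 90% peak shortening)
  and ttb90 (peak → 90% recovery); **lusitropy = 1 − ttb90(+dob)/ttb90(−dob)**
  with paired t-tests.
* **Synthetic data** (`synthetic`): generators that plant every statistic with
  exact per-frame ground truth (manifests), so each tier has recovery tests.
* **Pipeline** (`pipeline`, `cli`): runs all tiers against the shipped
  reference conditions and assembles study-shaped tables plus a cross-level
  restored/not-restored summary per ligand.

## Worked example

```bash
python examples/03_motility_coupling.py
```

```
EC50 (P)   : 0.138 uM   EC50 (unP): 0.059 uM
mean ratio : 2.30 +/- 0.03 (n=6, p=2.9e-08)
coupled    : True
```

Paired activation curves are generated at the native thin-filament condition
(EC50 0.059 µM unphosphorylated, 2.24-fold shift) with measurement noise,
refit, and called: the recovered ratio ≈ 2.3 reproduces the native 2–3-fold
desensitisation, so phosphorylation and Ca²⁺ sensitivity are coupled. The
other examples cover trajectory metrics (`01`), ligand contacts and the
salt bridge (`02`), lusitropy (`04`) and the full cross-level report (`05`).

A thin CLI wraps the same functions:

```bash
tncoupling simulate traj --out bundle --frames 3750 --runs 5 --seed 1
tncoupling analyze-traj --topology bundle/topology.pdb --traj bundle/run1.pdb \
    --metric ab_angle --out ab
tncoupling report --out report_dir --seed 1
```

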