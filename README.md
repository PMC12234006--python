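# protongate

Quantitative analyses of proton-leak gating in small multidrug-resistance
(SMR) transporters such as EmrE — an *E. coli* homodimer that couples
proton import to drug export and, when its C-terminal gate is
compromised, leaks protons down their gradient. The package implements,
as a tested pipeline with synthetic ground-truth data for every stage:

- **Water-wire connectivity.** Each water oxygen in an MD frame is a node
  of a weighted graph with edge cost w(r) = 1 + exp(α·(r − r₀)), r₀ = 3 Å
  (the O–O distance of hydrogen-bonded waters). The shortest path *S* from
  the donor glutamate's carboxylate oxygens to the open-face destination
  (Dijkstra) measures wire connectivity; log *S* separates leak-competent
  (wet) from dry frames.
- **Hydrophobic-gate distances.** Exact and softmin
  (β/ln Σᵢ exp(β/dᵢ)) minimum H–H distances between side-chain pairs
  across a trajectory, with Welch two-sided t-tests and star labels.
- **ZZ-exchange NMR.** For symmetric two-site alternating access at rate
  *k*, the composite ratio I_AB·I_BA/(I_AA·I_BB − I_AB·I_BA) = k²t²
  cancels initial intensities and relaxation; pooling residues and
  fitting yields *k* directly.
- **Global pKa titrations.** Fast-exchange shift curves
  δ(pH) = δ_end + Σⱼ Δδⱼ·10^(pKaⱼ−pH)/(1+10^(pKaⱼ−pH)) fitted globally
  with one or two shared pKa values, F-test/AIC model selection, and
  per-residue pKa-sensitivity classification.
- **Umbrella sampling → PMF → pKa.** Self-consistent WHAM over harmonic
  windows along the excess-charge-center (CEC) projection coordinate,
  5-block error analysis, and conversion of the PMF to a site pKa via
  K = C°·π·r_cyl²·∫ exp(−ΔW/kT) dx.
- **Proteoliposome assays.** Pyranine F/F₀ normalization, no-gradient
  baseline subtraction, burst + A·(1 − e^(−rate·t)) leak fits; SSME
  current baseline correction and charge integration; replicate
  statistics.

Every input class has a seeded generator (`protongate.synth`) that
records its ground truth in metadata, so all fits are testable without
external data.

## Worked example

Generate a synthetic ZZ-exchange dataset in the slow-exchange (low-pH)
condition and fit the alternating-access rate, then run a global 2-pKa
titration fit:

```bash
$ protongate simulate zz --preset zz_low_pH --out run/zz_data
$ protongate zzfit --in run/zz_data/quartets.csv --out run/zz_fit
k = 4.07 ± 0.015 1/s (20 points)

$ protongate simulate titration --out run/titr_data
$ protongate titrate --in run/titr_data/shifts.csv --npka 2 --out run/titr_fit
pKa = 5.60 ± 0.02, 7.11 ± 0.01
```

The `zz_low_pH` preset generates quartets at a true rate of 4 s⁻¹ with
2% multiplicative noise; the fitted 4.07 ± 0.015 s⁻¹ recovers it (the
quoted uncertainty is the fit covariance; a residue-level bootstrap SD
is also reported in `exchange_fit.json`, and "20 points" counts the
(residue, delay) ratios surviving the k·t ≤ 0.5 validity cap). The
titration preset encodes true pKa values 5.6 and 7.1 across 12 residues
(H and N shifts); the global fit recovers both within its uncertainty.

Water-wire analysis over a mixed wet/dry synthetic trajectory:

```bash
$ protongate simulate wire --seed 3 --out run/wire_data
$ protongate waterwire --traj run/wire_data/wire.pdb --out run/wire
{
  "n_frames": 100,
  "logS_min": 2.269,
  "logS_max": 16.886,
  "logS_mean": 8.998,
  "best_hydrated_frame": 28,
  ...
}
```

log S near 2.3 is a fully hydrogen-bonded wire (6 edges of weight
≈ 1.4); log S near 17 is a chain broken by one ~6 Å gap. The bimodal
histogram (`logS_histogram.csv`) mirrors the wet/dry ground-truth labels.

## Layout

```
src/protongate/
  synth.py      seeded generators + presets (ground truth in metadata)
  frames.py     Frame container + atom-selection mini-language
  io.py         PDB/GRO/XYZ readers (MDAnalysis), CSV + JSON sidecars
  waterwire.py  weighted water graph, shortest path, wire profiles
  gates.py      hard-min/softmin H–H distances, Welch comparisons
  nmr.py        ZZ-exchange rate fit, global titration fit, sensitivity
  pmf.py        CEC projection, WHAM, block errors, PMF → pKa
  assays.py     pyranine/SSME trace processing, group statistics
  cli.py        `protongate` subcommands with provenance JSON
```

See `docs/methods.md` for the models, parameter conventions, numerical
choices and known limitations.
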