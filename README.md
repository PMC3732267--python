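# uremiq

Quantitative ¹H-NMR analysis of uremic retention solutes in deproteinized
plasma.

## The problem

In chronic kidney disease (CKD), failing renal clearance lets small organic
solutes ("uremic toxins") accumulate in blood. One-dimensional ¹H-NMR of
plasma can quantify a panel of these solutes in a single acquisition — but
only after the proteins are removed, and no single deproteinization method
shows the whole panel: a 10 kDa ultrafilter passes only the protein-unbound
fraction (strong binders such as hippuric acid and *p*-cresyl sulphate
vanish), acetonitrile precipitation releases the bound solutes but loses
citrate, and perchloric-acid extraction degrades spectral quality too far to
quantify from. `uremiq` implements the complete workflow for this kind of
study, aimed at spectroscopists and nephrology researchers who want a
reproducible, testable version of it:

1. **Metabolite library** — resonance positions, multiplicities, proton
   counts, protein-binding behaviour, control reporting limits and
   literature normal concentrations for a panel of 14 uremic solutes plus
   citric acid and the TSP internal standard, shipped as editable YAML.
2. **Simulator** — ground-truthed 500 MHz spectra (6002 Hz spectral width,
   32K points) of patient and control cohorts under each preparation.
3. **Peak fitting** — chemical-shift referencing to the TSP singlet,
   joint baseline + Lorentzian deconvolution of library-initialized
   regions with hard within-multiplet area-ratio constraints.
4. **Quantification** — concentrations from the area ratio to the
   9-proton TSP singlet of known concentration, with detection limits and
   the preparation-merging rule (bound solutes from the acetonitrile
   extract, everything else from the ultrafiltrate).
5. **Retention statistics** — cohort mean C_u ± SD, hypothetical maximum
   C_max, the M/N retention index with banding, and eGFR correlation
   (exact small-sample Spearman p, log-scale regression with 95% CI).

## The model

A multiplet of metabolite *m* carries total area

    A_m = k · n_m · c_m

with proton count `n_m` and in-tube concentration `c_m`, each line being a
Lorentzian `L(δ) = (2A/π)·w / (4(δ−c)² + w²)`. Referencing against the TSP
spike (20 µl of 20.2 mM in a 670 µl tube → 603 µM, nine equivalent protons)
cancels the unknown response `k`:

    c_m = (A_m / A_TSP) · (9 / n_m) · c_TSP · d

where `d` maps the tube back to plasma (1 for neat ultrafiltrate, 700/500
for the acetonitrile resuspension). Cohort statistics follow the reporting
conventions of uremic-toxin surveys:

    C_max = C_u + 2·SD        M/N = C_u / N

with bands *high* (M/N > 10), *moderate* (4 ≤ M/N ≤ 10) and *low* (M/N < 4).

## Worked example

Simulate the default study (10 CKD patients, 4 controls, ultrafiltration +
acetonitrile) and analyse it end to end:

```bash
uremiq run-all --seed 1 --out demo_run --n-patients 10 --n-controls 4
```

prints the cohort summary table (concentrations in µM, rounded for
reporting):

```
              metabolite  n_detected  C_u_uM  SD_uM  C_max_uM  N_uM   MN     band
              creatinine          10     546    188       922  72.0  7.6 excluded
       1-methylhistidine           9      34     21        76   4.0  8.5 moderate
       3-methylhistidine          10      42     19        81   2.7 15.7     high
           hippuric acid           9     183    114       411   3.0 60.9     high
       p-cresyl sulphate          10     297     95       487  15.0 19.8     high
       dimethyl sulphone           9      53     19        90   9.0  5.9 moderate
2-hydroxyisobutyric acid          10      23     13        49   7.0  3.3      low
     N,N-dimethylglycine          10      21      6        33   2.6  8.0 moderate
            trigonelline          10      30     19        69   NaN  NaN excluded
           pseudouridine          10      49     19        87   3.2 15.4     high
                 betaine           6      96     16       127  34.6  2.8      low
            myo-inositol          10     538     98       735  30.0 17.9     high
           dimethylamine          10      17      0        17   3.3  5.1 excluded
  trimethylamine N-oxide          10     104     39       182  38.0  2.7      low
panel solutes elevated in >=1 patient: 14
```

Reading the output: `C_u` is the mean over the patients in whom the solute
was detected (undetected values are excluded, not zero-imputed, which is
why `n_detected` can be below 10 — betaine's 50 µM control reporting limit
hides its lower tail). `C_max = C_u + 2 SD` is the hypothetical maximal
uremic level. `MN` compares the uremic mean with the literature normal `N`;
trigonelline has no reference value and dimethylamine and creatinine are
conventionally excluded from the retention index, leaving 11 indexed
solutes. All 14 panel solutes are detected above their control thresholds
in at least one patient. The run directory also receives the full
per-preparation concentration table, merged per-patient values, M/N chart
data, eGFR correlation results, per-line fit diagnostics and a recovery
report against the simulator's ground truth — every file carrying the seed
and configuration hash that reproduce it.

The same steps are available individually (`uremiq simulate`, `uremiq fit`,
`uremiq quantify`, `uremiq summarize`), and as library functions for
scripted use. Real spectra are accepted as two-column ppm/intensity text
files with `# key: value` header lines.

## Layout

```
src/uremiq/
  library.py     metabolite panel, TSP standard, YAML round-trip
  lineshapes.py  Lorentzian profile, first-order and AB multiplet patterns
  spectrum.py    ppm/intensity container + text format
  simulate.py    cohort and spectrum generator (three preparations)
  fitting.py     referencing, baselines, region deconvolution (lmfit)
  quantify.py    TSP calibration, detection limits, preparation merging
  retention.py   C_u/C_max/MN statistics, exact Spearman, regression
  pipeline.py    orchestration + report files
  cli.py         click command-line interface
docs/methods.md  modelling assumptions, defaults, limitations
```
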