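# timsdda

Desk-scale processing of DDA-PASEF proteomics data: an in-memory timsTOF
data model, peptide chemistry, a fragment-indexed database search with
X!Tandem-style scoring, mass / collision-energy / retention-time /
ion-mobility calibration, 21-feature LDA rescoring, and target-decoy
competition FDR control — plus a seeded synthetic-run generator with full
ground truth, so every stage of the pipeline is testable end to end without
vendor raw files.

**Who is it for?** Method developers who want an executable, fully
inspectable reference for how a timsTOF DDA identification pipeline fits
together (preprocessing → search → calibration → rescoring → FDR), and who
need ground-truth data to validate each stage. It reads the project MGF
dialect and plain FASTA; Bruker `.tdf` binaries are out of scope.

## The method

- **Data model.** A *frame* is one retention-time point holding peaks across
  the ion-mobility scan dimension; splitting a frame by scan number yields
  mobility-resolved spectra (reduced inverse mobility 1/K0 in Vs/cm²).
  Frames support filtering, binning/vectorization on a rounded m/z grid,
  addition, and scalar multiplication — the operators needed to aggregate
  refragmented spectra.
- **Search.** Peptides from an in-silico digest (trypsin with up to 2 missed
  cleavages, or unspecific 7–25 mers), with fixed/variable modifications and
  reversed decoys (C-terminus fixed), are expanded into a flat b/y fragment
  table sorted by fragment m/z. Candidates are retrieved by precursor
  neutral mass (±15 ppm tryptic / ±20 ppm HLA preset, isotope errors −1..+2)
  and scored with the hyperscore
  `ln(N_b!) + ln(N_y!) + ln(1 + Σ matched intensity)` (factorials capped at
  10), fragments matched at ±20 ppm.
- **Calibration.** The median of per-PSM average fragment ppm errors gives a
  global mass correction; the top-scoring 4096 PSMs calibrate a
  collision-energy offset by maximizing the median normalized spectral
  contrast angle `1 − 2·arccos(cosθ)/π` against a CE-dependent fragment
  intensity model; RT and ion-mobility baseline predictors are fine-tuned on
  PSMs at q ≤ 0.01 with a peptide-level 80/20 split.
- **Rescoring.** 21 scalar descriptors per PSM (search statistics, ppm
  errors, RT/IM prediction deltas, intensity similarity) feed a linear
  discriminant trained per held-out peptide batch (5 nonoverlapping batches,
  all decoys + targets at q ≤ 0.01); the new score is the signed distance
  from the decision boundary.
- **FDR.** Target-decoy competition at PSM level, peptide level, and
  peptide-level double ("picked") competition where each target competes
  against its own reversed decoy. Estimated FDR at cutoff c is
  `(D(c)+1)/max(T(c),1)`; q(s) is the minimum estimated FDR over cutoffs
  at or below s.

## Worked example

```bash
timsdda simulate --seed 7 -o run/            # synthetic DDA-PASEF run
timsdda run --fasta run/proteome.fasta --mgf run/run.mgf -o out/ --seed 7
```

or, through the library, the equivalent of `scripts/acceptance.py --seed 1`:

```text
precursors: 2000
PSMs accepted at q<=0.01 (rescored): 2000
PSMs accepted at q<=0.01 (hyperscore): 2000
ground-truth peptide recall: 1.000
first-pass median ppm: -0.009
second-pass median ppm: +0.001
collision-energy offset: +0.0
```

All 2,000 simulated precursors are identified at 1% FDR (the synthetic
spectra are clean single-peptide spectra, so full recall is expected — see
`docs/methods.md` for what this does and does not establish); the estimated
global mass error is ~0 ppm, as generated, and the collision-energy grid
search returns the generating offset. Filtered reports land in
`out/results_psm.csv` and `out/results_peptide.csv` (decoys removed), with
the complete scored PSM set in `out/psms.jsonl.gz` and the 21-column feature
matrix in `out/features.tsv`.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

generates a fresh 2,000-precursor synthetic run from the given seed, executes
all ten pipeline stages (read-in, refragmentation merging + top-150
preprocessing, search-space generation, scorer configuration, first search,
mass + CE calibration, predictor fine-tuning, second search, LDA rescoring,
target-decoy competition + reports), prints the summary above, and writes the
result JSON to `--out`.
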