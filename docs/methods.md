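# Methods

This note documents the models, numerical choices, and open design decisions
behind `timsdda`, and states precisely what the synthetic-data tests do and
do not establish. No number quoted here is asserted anywhere except where a
test or the acceptance script computes it.

## Data model

`TimsFrame` stores one retention-time point as parallel peak arrays
(scan, 1/K0, m/z, intensity), kept sorted by (scan, m/z), with the
constraint that a scan index maps to exactly one inverse-mobility value.
Grid operations (frame addition, vectorization, refragmentation merging)
round m/z with round-half-to-even at a configurable number of decimals;
this rule is platform-deterministic, and intensity is conserved exactly
under every grid operation (asserted by property tests). Scaling by zero
keeps zero-intensity peaks so peak counts stay predictable; a separate
`prune_zero_intensity` removes them. The scan↔mobility mapping in synthetic
data is linear (`1/K0 = a − b·scan`); vendor calibration functions are out
of scope, as is any binary raw format.

## Chemistry

Monoisotopic element masses are CODATA/NIST values; modification deltas are
Unimod-consistent (carbamidomethyl +57.021464, oxidation +15.994915,
N-terminal acetyl +42.010565, cysteinylation +119.004099). Trypsin cleaves
after K/R but not before P. Isotope envelopes are convolutions of
per-element natural-abundance distributions over the peptide's elemental
composition, truncated and renormalized; for molecules up to 30 atoms they
match an exhaustive isotopologue enumeration to 1e-9. Decoys reverse the
sequence keeping the C-terminal residue (preserving tryptic termini and
mass); decoys colliding with any target sequence are dropped before
indexing. Variable modifications expand to all combinations of up to 3
sites (a common engine default; the source pipelines do not state one).
Only primary b/y series are generated — no neutral losses, a/c/x/z ions, or
internal fragments.

## Search

The fragment index is a flat structure-of-arrays of every b/y ion of every
(modified) target and decoy peptide within the configured fragment m/z
bounds, sorted by fragment m/z. Candidate retrieval by precursor neutral
mass uses binary search over the sorted peptide-mass array rather than
fixed 1-Da bins; the two layouts answer identical queries and binary search
is simpler and exact (tolerance queries are verified against a naive linear
scan). Unknown precursor charge enumerates charges 2..5; isotope
mis-assignment offsets of −1..+2 neutrons are tried and recorded per PSM.

The hyperscore is `ln(N_b!) + ln(N_y!) + ln(1 + Σ matched intensity)` with
factorial arguments capped at 10 to prevent overflow (X!Tandem practice);
the +1 keeps the score defined at zero matched intensity. Each theoretical
ion matches its nearest observed peak within the ppm tolerance; matched
intensity sums over distinct peaks. Ties are broken by smaller |ppm error|
and then lexicographic peptide sequence; top-N intensity ties keep the
lower m/z. ppm errors are signed as (observed − theoretical)/theoretical.

Database splitting (the HLA preset uses 6 chunks) assigns proteins to
chunks with a seeded RNG, searches chunks sequentially, merges PSMs per
spectrum, re-ranks, and trims to the configured report depth; with one
chunk this is exactly the plain search.

## Calibration

**Mass.** The global correction is the median of per-PSM mean fragment ppm
errors over confident (q ≤ 0.01) first-pass PSMs; spectra are corrected
multiplicatively by (1 − median·1e-6). The first-pass search runs at twice
the configured fragment tolerance: with a ±20 ppm window and an injected
shift near ±20 ppm, matching at the configured tolerance censors the error
distribution at the window edge and biases the median toward zero; the
widened window removes that censoring, and the second search on corrected
spectra uses the configured tolerance. Recovery of injected shifts in
{−20, −10, 0, +10, +20} ppm is within ±1 ppm on generator defaults.

**Collision energy.** Deep fragment-intensity predictors are replaced by a
closed-form baseline: intensity = base(series) · exp(−λ(series, CE) ·
ordinal) · charge factor, with λ linear in CE (floored at 0.005 to stay
positive). The calibration grid-searches an offset over −10..+10 eV
maximizing the median normalized spectral contrast angle
(1 − 2·arccos(cosθ)/π over L2-normalized matched-ion intensity vectors)
on the 4096 highest-scoring PSMs. When observed intensities come from this
model the generating offset is recovered exactly; with the generator's
default 10% multiplicative intensity noise the argmax can shift by one to
two 1-eV grid steps, so the exact-recovery test generates noise-free
intensities.

**RT / ion mobility.** Baselines are closed-form: additive per-residue
retention coefficients + intercept fit by ridge-regularized least squares
(α = 1e-2), and a per-charge linear model 1/K0 = a_z + b_z·(m/z)
(defaults a₂ = 0.45, b₂ = 5.5e-4 — plausible trapped-ion-mobility
magnitudes, not a biological claim). Fine-tuning keeps the stated protocol:
confident PSMs reduced to one per peptide, split 80/20 at peptide level
(disjoint by construction, seeded), refit on the training part, and the
returned model is never worse than the input on the validation part. The
learning-rate schedule fields (start 1e-3, floor 1e-6, patience 5, 10× per
trigger) are carried in the config and the validation report; for these
closed-form models a single refit replaces the epoch loop. Runs with fewer
than 20 distinct confident peptides skip fine-tuning with a warning.

## Rescoring

The 21 descriptors are: hyperscore, rank, delta to next rank,
ln(1+matched intensity), matched intensity fraction, matched b, matched y,
longest consecutive b run, longest y run, signed and absolute mean fragment
ppm error, precursor ppm error, isotope error, charge, peptide length,
missed cleavages, signed and absolute RT delta, ion-mobility delta,
spectral angle, and cosine similarity. Feature definitions are identical
for targets and decoys. Peptides are split into 5 nonoverlapping seeded
batches; each batch is scored by an LDA (lsqr solver, automatic shrinkage
of the within-class covariance — 21 features can exceed the confident
target count in small runs) trained on the other batches with all decoys
and targets at initial hyperscore q ≤ 0.01. Features are z-scored on the
training fold; non-finite values (missing predictors) impute to 0 after
scaling. Class priors are fixed uniform because the target/decoy balance of
the training fold is an artifact of the q filter; this also makes the
degenerate all-constant-feature case score identically everywhere. Score
orientation is flipped if training targets do not score above training
decoys. A training fold with a single class raises an error with a
diagnostic; the pipeline catches it on small runs (where the +1 pseudocount
floors attainable q-values above the training threshold) and falls back to
the hyperscore with a warning.

## FDR

All three competition levels use the conservative estimator
FDR(c) = (D(c)+1)/max(T(c),1) and q(s) = min over cutoffs c ≤ s, clipped to
[0,1]. Target/decoy score ties resolve in favor of the decoy at every
competition. Peptide-level analysis treats modified sequences as distinct
peptides (grouping by bare sequence is available via a flag). Double
competition pairs each target with the decoy generated from it (pairing by
generating target; the inverse of the reversal reconstructs the source),
keeps the higher-scoring pair member, and runs the q machinery over
survivors; a decoy that is its own source (palindromic body) indicates a
bookkeeping bug and raises. All three procedures are verified against an
O(n²) all-cutoffs brute force on random instances.

## Synthetic data

The generator emulates DDA-PASEF structure: a seeded random proteome with
UniProt-average residue frequencies (120 proteins of 150–400 residues by
default), tryptic digest, 2,000 sampled precursors with charges drawn from
{1: 2%, 2: 58%, 3: 30%, 4: 10%}, retention times from the additive-
coefficient model mapped onto a 20-minute gradient with 5 s Gaussian
jitter, mobilities from the per-charge linear model with 0.008 Vs/cm²
jitter, a linear CE ramp (20–60 eV over m/z 300–1700), fragment peaks from
the baseline intensity model with 10% lognormal noise and multiplicative
ppm error ~ Normal(shift, 1.5 ppm), 15 uniform noise peaks per spectrum,
and refragmentation of 15% of precursors with Dirichlet intensity splits.
Where no value was externally stated these defaults were chosen once as
field-plausible magnitudes and are not tuned against test outcomes.

What it does **not** emulate: chimeric/co-isolated spectra, MS2 isotope
envelopes, detector saturation or baseline noise spectra, real peptide
retention behavior, or vendor raw encodings. A green end-to-end test
therefore establishes that the machinery (merging, indexing, scoring,
calibration, rescoring, FDR bookkeeping) is correct on clean
single-peptide spectra — including 100% recall at 1% FDR, which is expected
in this regime — not that identification performance transfers to real
instrument data.

## Limitations

- No protein-level FDR or protein inference; no LFQ; no DIA.
- Baseline predictors are linear stand-ins for deep RT/IM/intensity models;
  calibration machinery is exercised, predictive accuracy is not
  state of the art.
- MGF and frame-TSV are the only spectrum inputs; the MGF dialect's
  PASEF headers (ION_MOBILITY, PRECURSOR_ID, COLLISION_ENERGY,
  ISOLATION_WINDOW, SCAN_WINDOW) are project-defined.
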