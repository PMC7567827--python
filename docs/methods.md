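# Methods

## Scope and model

`swathqc` treats a spectral assay library as an ordered list of assays,
each an atomic record of one precursor ion — modified peptide sequence,
charge, q1 m/z, retention time (or iRT), protein mappings — with its
selected fragment (q3) ions. Duplicate precursor occurrences are
deliberately preserved on read: redundant ("raw") libraries must be
observable as such, and only the explicit `merge_redundant` operation
collapses them. Three tab-separated dialects (OpenSWATH, PeakView,
Spectronaut/Prosit-generic) are identified by required-column
fingerprints; unknown m/z cells are collected as rejected rows rather
than dropped, so `file rows = stored fragments + rejected rows` holds.

## Mass calculus

Monoisotopic masses use the standard residue table with
m(proton) = 1.007276466 Da and m(H₂O) = 18.010565 Da. Theoretical ions
are restricted to the b and y series:

    b_i = (Σ_{k≤i} m_k + z·m_p) / z
    y_i = (Σ_{k>n−i} m_k + m_H₂O + z·m_p) / z

where m_k includes any modification delta at position k. Fragments in
other series, or carrying neutral-loss labels, are classed "other" in the
series composition and excluded from delta-mass averaging; whether such
ions should be verified against theory is an open modelling question and
they are conservatively left unverified. Unannotated fragments are
assigned to the nearest theoretical b/y ion within 0.1 Da (ties: smaller
|Δ|, then y over b, then lower charge); unmatched ones are skipped.

Modified sequences are parsed from UniMod (`C(UniMod:4)`), bracket-name
(`C[Carbamidomethyl (C)]`), bracket-delta (`C[+57.0214]`) and vendor
short (`C[CAM]`) notations into one canonical form, which also serves as
precursor identity. Labels resolve by name first, then by delta-mass
match within 0.001 Da; built-ins are carbamidomethyl-C (57.021464 Da)
and oxidation-M (15.994915 Da). An unresolvable label or non-standard
residue (B, Z, X, …) marks the assay *unverifiable*: it is never a crash,
passes through repair unchanged, and is counted into problem assays.

## The 62-criterion registry

The registry is fixed at 6 complexity + 28 characteristics +
6 modifications + 8 completeness + 14 correctness = 62 criteria. The
correctness category folds the per-ion precursor/fragment error counts
into a single "assays with ≥1 mass error" criterion to keep the category
at 14; `DeltaMassStats` still exposes both counts programmatically.
Criteria whose optional input (SWATH scheme, proteome FASTA) is absent
are reported with status `not_evaluated`, never omitted, so the report
surface is always 62 rows in a fixed order — which also makes repeated
assessments byte-identical.

Key conventions, chosen where the design was genuinely open:

* **Average delta mass is a signed mean** (not absolute): a library built
  from observed masses shows its systematic offset directly, and an
  injected constant +δ is recovered as exactly δ.
* **Mass-error tolerance** for counting an ion as erroneous is 0.01 Da
  (strictly greater-than), configurable via `AssessParams`; the average
  is reported regardless.
* **Problem assays** = assays with ≥1 mass error + unverifiable assays +
  precursors outside every isolation window (each assay counted once).
* **Isolation windows are half-open [start, end)**: schemes with 1 Th
  overlaps would otherwise double-assign boundary values. A precursor may
  legitimately sit in several overlapping windows; a fragment conflicts
  if it falls in *any* window containing its precursor.
* **RT fit** pairs peptides by modified sequence observed at both 2+ and
  3+ (first occurrence wins on duplicates) and fits RT(3+) on RT(2+) by
  ordinary least squares; it needs ≥3 pairs and non-zero 2+ spread,
  otherwise `not_evaluated`.
* **Target/decoy**: a dialect decoy flag wins; otherwise accessions are
  classed by prefix (`DECOY_`, `decoy_`, `rev_`, `reverse_`,
  configurable) with the proteome index's classes as fallback; an assay
  mapping to both classes is *mixed*. Percentages sum to 100.
* **Digestion** is trypsin with K/R-P suppression (toggleable), I/L kept
  distinct; proteotypic = peptide mapping to exactly one target protein.

## Repair

`correct_masses` rewrites in-scope m/z to theory (fragment-only by
default; precursor correction is offered but off, since precursor m/z is
usually already computed, not observed) and is idempotent: annotations
inferred for unannotated fragments are persisted so a second pass
recomputes identical values. `filter_conflicts` removes whole assays (the
problem library is an assay-level artifact for inspection); a
fragment-level drop mode exists as an option. Corrected-then-filtered
libraries are a fixed point: zero average delta, zero conflicts, zero
problem assays — *provided the scheme covers the library's precursor
range*, as it does for any library built from that acquisition;
precursors outside the scheme are unverifiable by definition. Replicate
merging sums intensities per fragment identity (series, ordinal, charge,
loss) before top-N selection; top-N ties keep the lower m/z.

## Synthetic data

The generator emulates a consensus tryptic library built with theoretical
masses: random proteins over the 20 residues (uniform, hence ~10% K/R and
realistic peptide lengths), fully tryptic peptides of 7–25 residues at 2+
and 3+, fixed carbamidomethyl on C, all b/y 1+ ions in 200–1800 Th as
candidates, and the top 6 by a decreasing geometric intensity profile
(base 0.7, ×U(0.9, 1.1) jitter) — the jitter makes top-N selection and
tie cases exercisable. iRT is a Kyte–Doolittle hydropathy proxy mapped
into (−50, 100), identical across charge states of a peptide, because
only cross-charge equality matters for the RT-fit diagnostic. Defaults:
30 proteins of 150–400 residues, ≤10 peptides per protein — a few hundred
assays, which keeps every test and the reproduction script in seconds;
larger libraries are produced by raising `n_proteins` (the 10,000-assay
decoy-accounting run uses 700 proteins, ≤20 peptides each).

Defect injectors mirror how real libraries go wrong: a constant q3 offset
of 0.01/0.02/0.05 Da (observed-mass libraries), decoy assays at a small
fraction built by shuffling a peptide until it is absent from the
proteome index, one fragment per selected assay rewritten into its
precursor's DIA bin, and r-fold replicate duplication with intensity
jitter. Every generator is a pure function of its seed.

What the generator does **not** model: chimeric/noisy spectra, neutral
losses and non-b/y series, intensity prediction accuracy, RT
non-linearity between charge states, shared-peptide protein inference
ambiguity at realistic rates, and empirically calibrated m/z error
distributions (errors are injected as exact constants). Passing tests
therefore demonstrate that the diagnostics recover known injected
defects exactly; they do not certify behaviour on vendor exports beyond
the dialect conventions implemented.

## Numerical notes

Window membership, m/z comparison and delta averaging are plain float64;
report values are serialized at 6 significant digits. Written libraries
carry 6 decimal places of m/z (≥0.000001 Th), 4 of intensity/RT. The
equal-width scheme generator pins the final window edge to the requested
range end to cancel accumulated float error; the variable-width mode
draws widths from a Dirichlet(5·1) profile with every width strictly
greater than the overlap. Decimal parsing is '.'-radix only.

## Known limitations

Only b/y fragment theory is generated; libraries dominated by other
series will show large "other" fractions and sparse mass verification.
Dialect column sets are a pragmatic reconstruction of common vendor
exports, not a full grammar of every export option. FDR estimation and
entrapment analysis are out of scope — decoys are counted, not modelled.
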