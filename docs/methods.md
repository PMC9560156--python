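# Methods

## Pathway-completeness audit

The audit operates entirely offline on two tables: a pathway catalog and an
organism's EC-number complement. The catalog encodes each biosynthetic route
as an ordered chain of reaction steps whose substrate/product names must link
(validated at parse time); alternative routes to the same amino acid are
separate variants, and an organism is complete for an amino acid when any one
variant has every step satisfied. A step is satisfied by an exact four-field
EC match, or — when a step's EC carries the serial wildcard `x` — by any
annotated EC in the same sub-subclass. The wildcard exists because databases
resolve activities to different depths; it is a matching policy of this
package, not a property of the EC system. Reports pick the variant with the
fewest missing steps, breaking ties by lexicographic variant id so results
are order-independent, and amino acids absent from the catalog are reported
`undefined` rather than incomplete.

The packaged catalog covers all twenty canonical amino acids with textbook
E. coli routes (ilv/leu operons for the branched-chain family, the
diaminopimelate route to lysine, the shikimate trunk shared by the aromatic
pathways, the his operon, and single- or few-step routes for the eleven
nonessential amino acids, including both the sulfate-assimilation and
transsulfuration routes to cysteine and both the prephenate and
phenylalanine-hydroxylase routes to tyrosine). Host-native bypass steps —
e.g. the terminal transamination of 2-oxoisovalerate by Bcat1/2 — are
ordinary steps whose EC a host annotation can supply; no special-casing. The
union of gene symbols across the nine essential-amino-acid pathways is 54;
since the catalog approximates a larger mined inventory, tests treat the
count only as exceeding 40. The catalog is data (TSV), user-replaceable.

The three annotation profiles are constructed set-theoretically from the
catalog: `complete` is the union of all catalog ECs; `metazoan_like` removes
every EC that occurs exclusively in essential-amino-acid variants (so shared
activities like chorismate mutase, which also serves the tyrosine route,
survive); `cho_like` additionally restores the branched-chain
aminotransferase (2.6.1.42, which hosts retain) and deletes the two P5CS
activities (2.7.2.11, 1.2.1.41), making the profile a proline auxotroph as
CHO cells are. These are idealized profiles: real genome annotations carry
partial, missing and spurious ECs that the profiles do not emulate, so
passing audits here demonstrate the audit logic, not annotation quality.

## Isotopologue model

Labeling assumes U-¹³C tracers: each precursor unit is drawn independently
from a well-mixed pool and is either fully heavy (probability p) or fully
light. The product MID is the convolution of these two-point distributions —
for valine's 3+2 pyruvate scheme the support is {0, 2, 3, 5} for any
p ∈ (0, 1). The ¹³C₃-pyruvate arriving from ¹³C₆-glucose via glycolysis and
any spiked pyruvate are treated as one pool with a single effective p;
compartmentation is out of scope. Natural ¹³C abundance (1.07%) is off by
default — the tracing design reads the sparse support directly and the study
regime annotated spectra manually — but a binomial convolution over the
remaining light carbons is available via `natural_abundance=True`.

Mass arithmetic uses monoisotopic masses from the NIST table shipped with
pyteomics (¹²C 12.000000, ¹H 1.007825, ¹⁴N 14.003074, ¹⁶O 15.994915;
¹³C−¹²C = 1.003355, ¹⁵N−¹⁴N = 0.997035, proton 1.007276 Da). Adducts add or
subtract bare protons (not hydrogen atoms); charge is 1 in all packaged
uses. Fragment ions support two conventions: `adduct` applies the same
protonation arithmetic as the precursor, while `intrinsic` treats the written
formula as the charge-carrying ion (immonium-style) and adjusts only the
electron mass. The predicted ¹³C₅-valine [M+H]⁺ is 123.1030 Da; observed
instrument peaks differ at the sub-millidalton level depending on calibration.

Pool-fraction estimation inverts only one-unit schemes (p = 1 − P(0 labels));
for multi-unit products the unlabeled fraction alone does not identify p
without assuming the full model shape, so the function refuses rather than
guess.

## Peak assignment and quantification

Assignment takes a centroided peak table (peak heights; areas behave
identically), computes theoretical m/z per label count, and takes the single
most intense unused peak within a ppm window (default 5 ppm, Orbitrap-class;
the window check refuses configurations where adjacent windows would
overlap). Chromatographic integration and raw-file parsing are upstream of
this package. Quantification is a single ratio: total pmol = target
intensity / internal-standard intensity × spiked pmol, scaled to 10⁶ cells;
the labeled amount uses intensities at ≥1 label. The packaged standard is
¹³C₅/¹⁵N-valine; its spiked amount per sample is the spike concentration
times extraction volume (500 nM × 1 mL/10⁶ cells ⇒ 500 pmol default).
Replicate and timepoint averages are arithmetic means.

## Growth analytics

Doubling time is total elapsed days divided by total PDL gained over the
window (not the mean of per-passage rates, which overweights short
passages; the per-passage estimator is available via a flag for
comparison). Replicates are aggregated by averaging per-replicate PDL before
dividing into days; percent change averages counts across replicates before
the ratio. A window gaining no doublings yields an explicitly undefined
doubling time rather than a negative one. Counts of zero are rejected by
validation; generated series never produce them.

## qPCR

RQ = E^(−ΔΔCq) with mean Cq per technical-replicate group and SDs combined
in quadrature across the four groups; efficiency defaults to E = 2.0 (no
standard curves are modeled — fitting them is out of scope) with a per-run
override. Copy number multiplies RQ by the calibrator's known copies; the
single-copy landing-pad integration justifies the default of 1. "x-fold
increase" is reported as RQ − 1 (a 0.54-fold increase means RQ = 1.54); the
alternative reading RQ = x is selectable via `convention="ratio"`.

## Synthetic scenarios

Generators emit data plus a ground-truth sidecar, and identical seeds give
byte-identical output. Noise models are standard choices: lognormal
multiplicative for cell counts and peak intensities (mean-one
parameterization), Gaussian for Cq. Background peaks are placed at least
three tolerance-widths from every target m/z, so assignment tests isolate
window logic by construction. Packaged growth scenarios mirror the study
conditions they emulate: `pMTIV_ilvD_plus` (3.2-day doubling, ten 3.9-day
passages = 39 days), `pMTIV_valfree` (4.3-day doubling, five 3.8-day
passages = 19 days), and `pCtrl_valfree` (1.96-day half-life, the decline
matching an 88% six-day loss); all use 10% count noise, 10⁵ cells re-seeded
per passage, three replicates, fixed seed 42. These sizes keep the full test
suite and the acceptance script each within a few seconds on one CPU while
leaving the doubling-time estimator's sampling error well inside the ±0.2-day
recovery tolerance (the 39-day scenario's estimator SD is ≈0.07 day with
replicate averaging).

What the generators do not emulate: chromatographic drift and co-elution,
detector saturation, isotopic fine structure, plate-position effects in
qPCR, or density-dependent growth. Green round-trip tests therefore validate
the estimators against their own model assumptions, not against instrument
artifacts.

## Limitations

- The audit is annotation-based: it cannot detect enzymes present but
  unannotated, nor assess expression or flux feasibility.
- The MID model ignores exchange fluxes and compartment-specific pools; it
  is a labeling bookkeeping model, not flux analysis.
- Absolute quantification assumes equal ionization response of analyte and
  heavy standard (the standard co-elutes, so this is the usual practice).
- The packaged catalog is an approximation of a database-mined inventory;
  counts derived from it are lower bounds.
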