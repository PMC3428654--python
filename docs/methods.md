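# Methods

## Repeat model and detection

A simple sequence repeat (SSR, microsatellite) is a tandem repetition of a
1–6 bp motif. The detector scans each transcript once per unit size *k* by
comparing the sequence with itself at lag *k* (`seq[t] == seq[t+k]`); a
maximal stretch of equalities is a repeat region, anchored at its first
position, with copy number ⌊region/k⌋. Only primitive motifs are reported
(an (AGAG)ₙ run is an (AG)ₙ locus), `N` matches nothing, and for a perfect
locus tract length = copies × unit size exactly, so a reported run can
never be extended by a unit-aligned base on either side. Coordinates are
0-based half-open internally; GFF3 export converts to 1-based inclusive.

Motifs are equivalent under cyclic rotation and reverse complement, since a
tandem tract has no intrinsic phase or strand. The canonical representative
is the lexicographic minimum of the closure; the display label is
`REP/REVCOMP(REP)`. Some families are conventionally printed by a
non-minimal member (CA/TG rather than AC/GT); `canonical_label` maps any
member label onto the canonical one, and class membership — not the label —
is what the tests assert.

### Classification taxonomy

The catalogue partitions loci into four disjoint classes with precedence
compound > imperfect > perfect; every base belongs to at most one reported
locus. The length threshold (default 18 bp; 15 supported) applies to the
*total span* of joined loci.

* **Imperfect**: ≥ 2 runs of the same canonical family (mono/di/tri only),
  each with ≥ 2 copies spanning ≥ 8 bp, separated by interruptions of
  1–4 bp. Chaining is done per family, so a chance micro-repeat of another
  family inside an interruption does not split a chain; runs interleaved
  within an accepted chain are consumed by it.
* **Compound**: adjacent members within ≤ 10 bp, either of different
  families (each member ≥ 12 bp) or of the same family when each member
  independently passes the full threshold. A member that is itself an
  interrupted chain makes the locus `compound_imperfect`. Subtypes are
  labelled by the sorted component unit sizes (mono-mono … di-tri).
* Overlaps between runs of different unit sizes are resolved before
  joining: the longer tract wins, ties go to the smaller unit.

### Why the two extra floors

Two parameters beyond the classic rule set are deliberate design choices:

* `imperfect_min_run_bp = 8`. With a copies-only rule (≥ 2 copies per run),
  any two chance `AA` pairs within 4 bp constitute an "imperfect SSR";
  random 40 %-GC sequence then contains one every few hundred bases, which
  is inconsistent with imperfect loci being a small minority (~3 %) of real
  genic-SSR catalogues. Eight bp (8 mono copies, 4 di, 3 tri) keeps joined
  runs substantial while admitting classic interrupted tracts such as
  A₈-G-A₉.
* `compound_min_component_bp = 12`. Different-family compound members may
  be sub-threshold (two 16 bp runs 2 bp apart form a valid ≥ 18 bp
  compound), but without any floor a chance 2–3 bp repeat inside a spacer
  would convert a genuine locus into a compound. Twelve bp — two thirds of
  the default threshold — separates members from background noise. Runs
  below this floor are *transparent*: they neither join nor break a chain,
  and being sub-threshold they are never reported.

Both are exposed in `MiningConfig`, as are the gap (4 bp) and spacer
(10 bp) limits, so alternative operational definitions are one flag away.

## Catalogue statistics

All counts are exact integers; percentages are rounded half-up to two
decimals only at presentation, matching how survey tables are printed.
Density is (total bp / 1000) / n_loci in kb per SSR. Incidence is
100 × n_loci / n_transcripts — a count ratio ("SSRs per 100 transcripts"),
not the fraction of transcripts containing a locus; the two differ whenever
a transcript carries several loci, and the ratio is what published survey
arithmetic uses. Copy-number threshold filtering keeps copies *c* with
*c* × unit ≥ the target threshold; copy-number modes rank copy numbers by
total count across unit sizes, ties broken by copy number ascending.

Published count tables (classification × subtype, per-unit copy-number
histograms, headline totals, top motif families) ship as commented TSV
fixtures under `ssrmine/data/` and are loaded with `load_fixture`; tests
read them rather than hard-coding counts.

## Primer filtering

Candidates are every window of 18–24 nt lying wholly in a flank and within
the maximum product distance of the tract. A window passes with G/C between
40 and 70 % and Tm between 54 and 63 °C, where
Tm = 64.9 + 41 (n_GC − 16.4)/L °C — the simple GC-count model, chosen
because the published protocol states only the acceptance window, not its
thermodynamic engine. It depends only on length and G+C count and is
deliberately swappable; nearest-neighbour Tm, salt correction and
dimer/hairpin screening are out of scope, so primer *yields* are not
comparable with Primer3-based counts. Ambiguity characters disqualify a
window rather than raising. Pairs must bracket the tract with product
length in [100, 400] bp (maximum configurable); they are ranked by
|ΔTm|, then product length, and the top 3 returned by default.
`audit_primer_pair` re-validates every constraint from the template with
independent arithmetic (Biopython's `gc_fraction`, a re-derived Tm
expression) and shares no code with the enumerator.

## Marker diversity

Alleles are the distinct band sizes a marker shows among amplifying
accessions; non-amplification is missing data, not a null allele. Allele
frequency pᵢ is the fraction of allele observations, and
PIC = 1 − Σ pᵢ² (0 for monomorphic markers, at most 1 − 1/k for k
alleles). Jaccard similarity uses binary (marker, band) presence —
dominant scoring, the convention for PAGE band matrices; band sizes match
by exact integer equality in synthetic data (a tolerance hook exists for
real gel data). Pairs with an empty band union get similarity 0 with a
warning.

UPGMA merges the most similar pair of clusters, with the merged cluster's
similarity to others the size-weighted mean of its members' (equivalently
the mean over all leaf pairs). Node height is the merge similarity, so
heights fall monotonically from leaves (height 1) to the root; ties break
on the lexicographically smallest pair of cluster labels (a cluster is
labelled by its smallest accession id), making trees reproducible. Tests
cross-check merge heights against SciPy's average linkage. Newick export
is on the distance scale d = 1 − S with node heights d/2, so the cophenetic
distance between two leaves equals one minus their merge similarity; two
leaves merged at S = 0.8 serialize as `(A:0.1,B:0.1);`.

## Synthetic data

`generate_transcripts` emulates a transcriptome-scale SSR survey:

* transcript lengths are lognormal (σ = 1, median ≈ 684 bp) tuned to a mean
  of ≈ 1,127 bp, the scale of assembled uni-transcripts;
* planted loci per transcript are Poisson with mean 0.104 (the published
  loci-per-transcript ratio at the 18 bp threshold);
* motif families follow the published ≥ 18 bp spectrum (AG/CT 34.51 %,
  CA/TG 7.65 %, AT/AT 5.85 %, GAA/TTC 3.57 %, mono 0.57 %, tetra 2.12 %,
  penta 2.97 %, hexa 25.37 %), with the residual tri and hexa mass spread
  over plausible families;
* copy numbers are drawn from the packaged per-unit histograms;
* the classification mix is 82.75 / 4.53 / 12.72 % perfect / imperfect /
  compound, with 60.2 % of compounds carrying an interrupted member.

Background sequence (40 % GC) is rejection-sampled in ≤ 400 bp chunks so it
contains no run that could be reported or could chain with a planted locus;
planted tracts get ≥ 30 bp of clean flank, interruptions and spacers are
built from characters that cannot seed or extend a run, and junction bases
are repaired so flanks never extend a tract's period. Finally each
transcript is re-classified and regenerated until the detected catalogue
equals the planted one — so detection recall and precision against ground
truth are exactly 100 % *by construction*, and the closure test verifies
the construction rather than estimating an error rate. Everything is
deterministic per seed.

What this does **not** emulate: real transcripts are not SSR-free outside
planted loci (UTR composition bias, low-complexity regions), lengths are
not independent of SSR content, assembly and sequencing errors are absent,
and motif spectra within a family are uniform over rotations/strands.
Passing closure tests therefore demonstrates correctness of the detector
and classifier on well-posed inputs, not field performance on noisy
assemblies.

`generate_genotypes` draws one allele per accession per marker from given
frequency vectors (dominant single-band view), with distinct band sizes per
allele, and records exact frequencies and PIC for recovery tests.

## Numerical and testing conventions

Rounding is half-up via `Decimal` (2.3125 → 2.31). Detector equivalence is
checked against an independent brute-force position scan: exhaustively over
a two-letter alphabet to 12 bp and the full alphabet to 7 bp (enumeration
over four letters beyond that is combinatorially out of reach), plus 200
seeded random 60 bp sequences with planted repeats — thresholds lowered so
short sequences contain loci. The standard validation sizes are 1,000
simulated transcripts (~1,500 planted loci) for detection closure and 5,000
genotype draws for PIC recovery; property tests (hypothesis) are
derandomized for reproducibility.

## Known limitations

* Imperfect/compound operational rules vary across the literature; the
  published catalogue's exact rule set is not recoverable, so real-data
  imperfect/compound *counts* are not reproduction targets — only the
  taxonomy, arithmetic and printed shares are.
* Primer yield depends on the Tm model; only the constraint windows are
  faithful.
* `incidence_pct` reproduces the count-ratio convention (see above), which
  can exceed 100 %.
* UPGMA assumes a constant divergence rate (ultrametricity); with strongly
  rate-heterogeneous markers, neighbour-joining (out of scope) would be
  more appropriate.
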