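# Methods

This note records the model behind `uorfkit`, its assumptions, the defaults
that matter, and the design decisions taken where more than one reasonable
choice existed.

## Model and procedure

The quantity of interest is the ribosome-occupancy balance between a
transcript's main ORF and each upstream ORF (uORF) in its leader, and how
that balance shifts between two conditions. The procedure has four stages.

**Annotation reduction.** Real annotations carry many transcript variants
per gene; uORF coordinates are only well defined against a single model. Per
gene we keep one protein-coding transcript: among those with Gencode
confidence level 1 (validated) or 2 (manually annotated), the one with the
greatest *mature* length (sum of exon lengths). Mature length, not CDS
length, is the criterion because the leader content is what determines which
uORFs exist. Ties break on the lexicographically smallest transcript id so
runs are reproducible. Transcripts lacking a `level` attribute are treated
as level 3 and excluded — fail-closed on unknown provenance. Transcripts
whose CDS length is not a multiple of 3 occur in real annotations
(selenoproteins, frameshifts, incomplete models); they are kept but flagged,
with a strict mode to drop them.

**uORF discovery.** A uORF is a maximal in-frame span from a start codon
(default ATG; alternative starts are opt-in) to the *first* in-frame stop
(TAA/TAG/TGA), lying fully inside the leader. Span length includes the stop
codon and must be within [9, 400] nt: 9 nt is the smallest ORF with one
coding codon besides start and stop, and 400 nt is the conventional upper
bound for calling an ORF "short". A span of L nt encodes L/3 − 1 residues
(stop excluded, initiator Met counted). All distinct start positions are
reported, including nested starts sharing a stop, because transcripts with
several uORFs are biologically common and each start is scored
independently. Codons containing N match nothing — conservative on
ambiguous sequence. uORFs overlapping the CDS are excluded by default (an
off switch exists for exploratory use, in which case starts must still
precede the CDS). Discovered candidates can be filtered by evidence —
summed raw counts across all libraries ≥ 1 by default; a threshold of 0
reproduces the behaviour of a pre-built comprehensive annotation in which
uncovered uORFs are retained.

**P-site counting.** Each read is reduced to a single genomic point: the
inferred ribosomal P-site, at a fixed offset (default 12 nt, the classical
value for ~28–30-nt fragments) from the read's 5' end, walked through the
aligned blocks so junction gaps are skipped. Point assignment — rather than
overlap counting — guarantees a read cannot count to both a uORF and the
downstream CDS. Reads outside the 25–35-nt length window, and secondary or
supplementary alignments, are ignored; there is no offset auto-calibration
from metagene profiles, but a per-read-length offset table can be supplied.
Libraries are assumed stranded in the forward sense (read strand equals
transcript strand); this is configurable.

**Ratio statistic.** Libraries are made comparable by median-of-ratios size
factors computed on the CDS table only (CDS features are long and stable;
uORF counts are sparse) and applied to both tables:
s_j = median over all-positive features of K_ij / g_i, where g_i is the
feature's across-sample geometric mean. The median is taken over linear
ratios as the definition states. For each uORF the per-condition ratio is

    R_c = (mean of normalized CDS counts + ψ) / (mean of normalized uORF counts + ψ)

with pseudocount ψ = 1 so that ratios stay defined for uncovered uORFs, and
the readout is log2FC = log2(R_treatment / R_control). Condition
aggregation is the ratio of per-condition means of normalized counts — the
simplest defensible aggregation; per-replicate ratio averaging would weight
low-count replicates erratically. Records are ranked by |log2FC|, two-sided,
since both directions (relieved and tightened repression) are of interest;
the top and bottom round-half-up(0.05 × N) records are flagged
`strongest_change` and `least_change`. uORFs with zero raw counts in every
library are excluded from the ranking (their log2FC is pure pseudocount
artefact) but remain in the output. The method is a ranking: no dispersion
estimation, no tests, no multiple-testing correction.

## Numerical notes

- Round-half-up is used for the flag-set size, so 939 eligible records give
  47 flags and 1878 give 94.
- Size-factor scale behaviour: multiplying one library's counts by c
  multiplies every size factor by a common c^(1/S) beyond the intended
  per-library factor, because the geometric-mean reference moves. This
  global constant cancels exactly in every ratio when ψ = 0 (verified to
  1e-9) and to first order when ψ = 1; normalized tables agree up to that
  one constant.
- Ties in |log2FC| break on uorf_id; all orderings in the package
  (transcripts, samples, flags) are deterministic, so identical inputs give
  byte-identical outputs.
- Degenerate inputs: a leader of length 0 hosts no uORFs and is valid; a
  count matrix with no all-positive feature has undefined size factors and
  is a hard error; a uORF whose transcript lacks a CDS feature is skipped
  and logged.
- Coordinates are 0-based half-open internally; GTF I/O is 1-based closed;
  BED output is 0-based half-open.

## Synthetic worlds

The simulator builds complete test inputs: a toy genome, a Gencode-style GTF
with multi-exon genes on both strands (plus a shorter decoy transcript per
gene so annotation reduction is exercised), and per-library alignments. Its
defaults are the reference study conditions used by the test suite: 200
uORF-bearing genes, 4 control + 4 treatment libraries, negative-binomial
read totals with mean 200 per transcript and dispersion 0.1, 30% of a
transcript's reads allocated to its uORFs at baseline, and 10 genes whose
CDS:uORF allocation ratio is shifted by ±2 log2 units in treatment. Leaders
are 120–260 nt with 1–2 planted uORFs of 9–36 nt (typical of the ~40-nt
mean length of human uORFs); 4 replicates per condition mirror a standard
stress-stimulation design.

Background leader sequence is scrubbed of spurious ATGs, so the discoverable
uORF set equals the planted set exactly and discovery is checked for
identity rather than statistically. Reads are placed so the default P-site
offset lands uniformly inside the intended feature, and they span exon
junctions when the placement walk crosses one. The simulation deliberately
omits sequencing errors, soft-clipping, multimappers, UMI structure,
off-target reads (3'UTR or intronic), uneven codon-level occupancy, and
leaders where real scanning ribosomes would produce overlapping signal.
Passing tests therefore demonstrate the correctness of coordinate handling,
counting and the ratio statistic under the stated noise model — not
robustness to alignment artefacts or to annotation error in real data.

With these defaults the end-to-end check asks that all planted uORF
coordinates are recovered exactly and that at least 9 of the 10 shifted
genes land in the strongest-change flags; problem sizes (200 genes, 8
libraries, ~320k reads) were chosen so the whole suite represents the study
design faithfully while remaining quick to run on a laptop.

## Known limitations

- Only ATG-frame uORFs with standard stops are modelled; no stop-codon
  readthrough, no CDS-overlapping (oORF) classes, no translation-initiation
  statistics — candidate uORFs are defined by sequence plus simple read
  evidence, not by initiation-site inference.
- The two-condition design is fixed; multi-condition contrasts are out of
  scope.
- `least_change` flags identify stable ratios only; calling a uORF
  "translation-supportive" would need additional information (e.g.
  translation efficiencies), which the method deliberately does not compute.
- GFF3 input is not supported; Gencode-dialect GTF only.
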