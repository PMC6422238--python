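# Methods

## Scope and model

`lossscan` operationalizes a comparative argument about gene loss: a gene is
called a pseudogene only on positive evidence of an inactivating defect, and
functional only on complete positive evidence of integrity. Three evidence
channels are modeled.

**Splice sites.** Only canonical GT–AG introns are accepted. A donor is the
first two intron bases; an acceptor is the two bases preceding the first exon
base. Acceptor context is scored as the pyrimidine (C/T) fraction over a
window immediately 5′ of the AG (`ppt_window`, default 20 nt). Dinucleotides
containing N are *ambiguous*, never canonical and never defects — incomplete
assemblies (ancient-genome reads, draft assemblies) must not masquerade as
mutations. GC–AG introns are reported non-canonical: the analysis reasons only
about canonical sites, and a flagged GC donor is visible in the call rather
than silently accepted.

**Terminal-exon rescue.** Candidate acceptors are every position preceded by
AG within a search span (default 10 kb, truncated at the locus end with a
logged warning) downstream of the penultimate exon's donor. Each candidate is
translated in the frame fixed by the upstream coding sequence (`frame` =
bases to skip after the acceptor, the GFF phase convention; all candidates
share it because they share the donor). Scoring is

    total = w1·ppt_score + w2·(profile_matches / |profile|) + w3·frame_ok

with defaults w1 = w2 = 1.0, w3 = 0.5, `min_codons` = 30 for `frame_ok`. The
weights implement a minimal ranking consistent with how a true terminal exon
differs from a decoy: a strong tract, the expected C-terminal protein features
(binding-site tripeptide, conserved cysteines), and an open frame. `min_codons`
= 30 reflects that a terminal CRD exon encodes roughly the C-terminal third of
a ~130-residue domain. Ties break toward the smaller (more 5′) position, the
order in which a scanner would encounter them. ORF length and profile matching
deliberately translate past the span end — a real exon's reading frame does
not stop at a scan window — so the candidate *set* and tract scores are
invariant to sequence beyond the span, while ranking may respond to it.
Branch-point modeling and position-weight-matrix splice scores are out of
scope; the tract fraction is the only context statistic.

Offset conventions: all coordinates are 0-based half-open internally, with
GFF3 conversion at the I/O boundary; any offset reported between a decoy and a
true acceptor is the difference of their first-exon-base coordinates, and
output tables carry the positions themselves so alternative conventions can be
recomputed.

**Junction evidence.** Support for a candidate terminal exon is the total
count of intron-spanning reads whose acceptor coordinate matches; donors are
not matched because competing terminal-exon models share the donor. The winner
must reach `min_reads` (default 2 — one spanning read can be a mapping
artifact, two consistent ones are treated as confirmation) and strictly exceed
the runner-up; ties are AMBIGUOUS (no preference is fabricated), and all-below-
threshold is UNSPLICED. Raw per-junction counts are reported; no efficiency
normalization is attempted.

**CRD classification.** Exactly two tripeptides at the principal Ca²⁺ site are
valid: QPD (galactose/GalNAc class) and EPN (mannose/GlcNAc class); everything
else is INVALID, and any middle residue other than proline is disqualifying
because the proline must adopt the *cis* configuration. Only the tripeptide is
hard-coded; other binding-site residues are checked through the user-supplied
C-terminal profile, because their identities vary by family and should not be
invented. The conserved-cysteine check counts C residues against an expected
minimum (default 4 for a full CRD; the count is a floor, not an exact match,
since sequences may carry additional non-conserved cysteines). The neck
heptad score is the best over the 7 register phases of the hydrophobic
fraction at a/d positions, with hydrophobic = {L,I,V,M,F,A} and no window
smoothing — the simplest detector of coiled-coil character.

**Status call.** Defects are counted as: each supplied non-canonical,
non-ambiguous splice call, plus an INVALID motif, plus a failed cysteine
check. Two or more → PSEUDO_MULTIPLE; one → PSEUDO_SPLICE or
PSEUDO_BINDING_SITE; none → FUNCTIONAL_GAL/FUNCTIONAL_MAN only when evidence
is complete (at least one splice call, all canonical, valid motif, intact
cysteines), otherwise INDETERMINATE. A lone observed defect suffices for a
pseudogene call even when other channels are missing (the partially covered
ancient-genome case); missing evidence never upgrades. Defects are reported
side by side without ranking their severity, since the relative sufficiency of
individual substitutions is not modeled.

**Pipeline verdict.** FUNCTIONAL iff the status is FUNCTIONAL_*, PSEUDOGENE
iff PSEUDO_*, else INDETERMINATE; additionally a FUNCTIONAL status with
contradicting transcript evidence (UNSPLICED/AMBIGUOUS splicing call) is
downgraded to INDETERMINATE rather than letting one channel overrule another.
When the annotated model lacks the expected terminal exon and the rescue scan
finds no *credible* candidate (credible = full profile match with an open
frame), the report carries a DELETED_EXON annotation with an INDETERMINATE
verdict — absence of a locatable exon is treated as missing evidence, not as a
demonstrated mutation. Minus-strand models are mirrored onto the reverse
complement before any splice-site arithmetic.

## Glycan-array analysis

IUPAC-condensed structures (CFG dialect: reducing end rightmost, branches
parenthesized before their parent, spacer suffixes like `-Sp8`) are parsed
into rooted trees; spacers are metadata, never nodes. Epitope classes:

- LEWIS: a GlcNAc bearing Gal β1-4 plus Fuc α1-3 (Lewis-x) or Gal β1-3 plus
  Fuc α1-4 (Lewis-a), with the Gal terminal;
- GALNAC / GAL: a terminal GalNAc / Gal whose ring positions 3 and 4 are both
  unsubstituted ("terminal" = no residue children on ring positions 2–6; an
  unknown attachment position is conservatively treated as blocking);
- OTHER: none of the above.

Precedence for multi-antennary glycans carrying several epitope types is
LEWIS > GALNAC > GAL > OTHER (fucosylated epitopes first; GalNAc before Gal,
matching the monosaccharide affinity order GalNAc > Gal for this receptor
family). Sulfate/phosphate modifiers on a position count as substitution —
"free OH" is read literally — so 3-O-sulfation demotes a Gal terminus to
OTHER while 6-O-sulfation does not. Both the 3- and 4-OH must be free
simultaneously. Spot statistics drop exactly one maximal and one minimal
replicate (one instance each under ties; six replicates always leave four)
and report mean and sample SD (ddof = 1) of the remainder; a three-replicate
spot leaves a single value and SD 0. Ranking is by trimmed mean descending,
ties by glycan id.

## Alignment and trees

Global pairwise alignment uses Biopython's `PairwiseAligner` with BLOSUM62,
gap open −10 and gap extend −1 under the convention that a gap of length L
scores `open + (L−1)·extend`; scores are verified against exhaustive
enumeration on short sequences. Percent identity counts identical columns over
columns with no gap in either row — one convention had to be fixed, and the
positions are available in the result so alternatives can be recomputed.
Distances are `1 − identity/100`. Neighbor joining is implemented in-package
with the standard Q-criterion, deterministic tie-breaking by the
lexicographically smallest pair of clade labels (each clade keyed by its
smallest leaf name), negative branch lengths clamped to zero and flagged, and
the final edge split at an arbitrary midpoint (tip-to-tip path lengths are
independent of the split). On additive input the tree reproduces the input
distances exactly; scikit-bio's `nj` serves as an independent cross-check in
the tests. Dendrogram shapes are interpreted qualitatively (who is whose
nearest neighbor), not as exact branch lengths.

## Synthetic data: what it emulates and what it does not

`make_locus` builds a seven-exon locus (defaults: exon lengths 120, 81, 72,
150, 141, 131, 121 nt; introns 280–400 nt; 30/90 nt UTRs) whose coding
sequence is random sense codons with implants: the binding-motif tripeptide at
codon offset 3 of the terminal exon's translation, conserved cysteines at
terminal-exon offsets 10 and 25 and at CRD offsets 9 and 59. Introns are
GT + body + 20-nt pyrimidine tract + AG; the tract is drawn from {C,T} only,
which saturates the acceptor consensus and makes recovery properties exact
rather than probabilistic. The final intron optionally carries a decoy: a
purine-biased window, an AG, and 32 in-frame stop-free codons — an in-frame
acceptor that is exactly the trap that misleads annotation, but with a weak
tract and no profile features. Mutations implant ACCEPTOR_GG, DONOR_AT, motif
codon swaps (e.g. QPD→QSD), or delete the terminal exon and its acceptor
region entirely. Ground truth (expected status, expected spliced exon,
implanted coordinates, frame, CRD protein) is recorded alongside.

Junction simulation draws zero-truncated Poisson(depth) counts at every
spliced junction of a functional locus — a junction present in the transcript
is observed at least once, which is what makes "recovery with probability 1"
well-posed — and, for unspliced truths, no reads at the final junction and at
most one background read elsewhere. Recovery tests use depth 20, at which the
default `min_reads` = 2 threshold is cleared except with probability ≈ 4·10⁻⁸
per locus. Array simulation draws six replicates per glycan from a Gaussian
centered on `background + class_signal[class]` (murine-like profile: Lewis ≈
GalNAc ≫ Gal ≫ other; bovine-like: Lewis ≫ GalNAc ≈ Gal ≫ other; noise SD 500
RFU), clipped at zero since scanner intensities are non-negative. Expression
tables realize three archetypes: liver-restricted (liver 2500–3500 against
others ≤ 2, guaranteeing a ≥ 1000-fold ratio), spleen-dominant, and absent
(all below a declared background of 1). All generators are pure functions of
(spec, seed).

What the generators do **not** emulate — and therefore what passing recovery
tests do not show about real data: alignment and mapping errors in junction
tables, splice-site variation beyond the GT–AG consensus, compositional
structure of real introns (the synthetic tract/decoy contrast is sharper than
a typical real one), paralogous read attraction, array spatial artifacts and
glycan-density effects, and cross-tissue normalization issues in expression
tables. The recovery rates measure the internal consistency of the pipeline's
logic under its own noise model, not its error rate on genomes.

## Sizes and thresholds used in validation

The acceptance script and tests run: 200 loci across the six mutation classes
(intact, acceptor AG→GG, donor GT→AT, motif→QSD, motif→RPD, acceptor+motif)
at junction depth 20; 50-locus splicing-recovery sets for the intact and
doubly mutated archetypes; the 8000-tripeptide enumeration; the 25-structure
hand-labeled glycan panel plus 1000 random replicate vectors against a
drop-min/drop-max oracle; 100 seeded arrays for top-10 recovery under the
bovine-like profile; alignment-score checks against exhaustive enumeration on
sequences of 4–8 residues; and neighbor joining on a fixed additive 5-leaf
matrix (tolerance 1e-9). These sizes keep the full validation under a few
seconds while leaving the statistical claims (e.g. ≥ 99/100 seeds) meaningful.

## Known limitations

- Single-transcript gene models; no isoform graphs or alternative promoters.
- The rescue scan scores acceptors only; donor-side re-annotation and 5′ exons
  are out of scope.
- The motif classifier is binary-by-design (QPD/EPN); lineage-specific
  variant motifs with retained activity would be called INVALID.
- Identity distances ignore alignment uncertainty; no bootstrap support is
  computed for NJ trees.
- The glycan grammar covers the CFG condensed dialect used on printed arrays
  (named residues, a/b anomerics, parenthesized branches, numeric sulfate/
  phosphate modifiers, spacer suffixes); GlycoCT/WURCS and repeat units are
  not supported.
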