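# lossscan

Comparative genomics of gene loss: given a gene locus, its exon model,
transcript evidence and protein-level features, `lossscan` decides whether the
gene still encodes a functional product or has been pseudogenized by
inactivating mutations. It was built around the biology of C-type lectin
receptors such as the Kupffer cell galactose receptor (CLEC4F), where the
question "is this gene functional in this species?" decomposes into a small
set of independently checkable facts:

- **Splice-site integrity.** Introns must begin with GT (donor) and end with
  AG (acceptor); an acceptor mutated to GG or a donor mutated to AT cannot be
  spliced. Acceptor strength is summarized by the pyrimidine fraction of the
  polypyrimidine tract in a window 5′ of the AG.
- **Terminal-exon rescue.** Automated annotations sometimes splice the final
  intron to a fortuitous in-frame acceptor ("exon X") instead of the true
  terminal exon further along the chromosome. The rescue scan enumerates every
  AG downstream of the penultimate exon's donor and scores each candidate by
  `w1·ppt + w2·(profile matches / profile size) + w3·frame_ok`, where the
  profile lists expected residues of the translated terminal exon (the
  binding-site tripeptide, conserved cysteines).
- **Transcript evidence.** Intron-spanning RNA-seq reads are tallied at the
  acceptor positions of competing terminal exons; a winner needs a minimum
  read count and a strict majority, otherwise the locus is UNSPLICED or
  AMBIGUOUS.
- **Binding-motif class.** The tripeptide at the principal Ca²⁺ site of a
  C-type carbohydrate-recognition domain (CRD) determines specificity:
  Glu-Pro-Asn (EPN) → mannose/GlcNAc, Gln-Pro-Asp (QPD) → galactose/GalNAc.
  Any other tripeptide — in particular any non-proline middle residue, since
  the proline must be in the *cis* configuration — is invalid. Conserved
  cysteine counts and the heptad-repeat character of the coiled-coil neck are
  checked alongside.
- **Glycan-array analysis.** Array structures in IUPAC-condensed text are
  parsed into trees and classified by terminal epitope: Lewis-a/x
  (red), other galactose (green) or GalNAc (blue) with free 3- and 4-OH
  groups, or none of these (black). Replicate intensities are summarized by a
  trimmed statistic (drop one max, one min; mean ± sd of the rest) and ranked.
- **CRD relatedness.** Pairwise global alignments (BLOSUM62, affine gaps) give
  percent identities; `1 − identity/100` distances feed neighbor joining, with
  Newick output.

A per-species run combines these stages into a verdict — FUNCTIONAL,
PSEUDOGENE or INDETERMINATE — where two or more independent defects are
reported as PSEUDO_MULTIPLE and missing evidence always degrades toward
INDETERMINATE rather than guessing. A seeded synthetic-data module generates
loci with implanted mutations, junction tables, glycan arrays and tissue
expression tables with recorded ground truth, so every classifier is tested by
recovery.

## Worked example

```python
from lossscan import (ACCEPTOR_GG, LocusSpec, make_locus, consensus_profile,
                      rescue_terminal_exon)

spec = LocusSpec(seed=5)                      # intact seven-exon locus
locus, model, truth = make_locus(spec)
candidates = rescue_terminal_exon(locus, truth.donor_pos, truth.frame,
                                  consensus_profile(spec))
print(candidates[0])
```

prints

```
AcceptorCandidate(acceptor_pos=2675, ppt_score=1.0, frame_ok=True,
                  orf_len=39, profile_matches=5, total_score=2.5)
```

i.e. the top-ranked acceptor is the implanted terminal exon at locus offset
2675: a saturated pyrimidine tract (1.0), all five expected protein features
(QPD tripeptide plus two cysteines) and an open reading frame of 39 codons.
The in-frame decoy acceptor upstream scores 0.8 (tract 0.30, no profile
matches, open frame) and ranks well below it. The `examples/` directory has one narrative
script per capability (rescue, mutation calls, junction evidence, array
ranking, phylogeny, species panel); each prints its numbers with a line of
interpretation.

A thin CLI mirrors the library:

```
lossscan simulate locus --seed 5 --out sim/
lossscan rescue-exon --locus sim/locus.fasta --gff sim/model.gff3 \
    --profile profile.tsv --out candidates.tsv
lossscan splice-evidence --junctions j.tsv --candidates c.tsv --out call.json
lossscan glycan-array --table array.tsv --top 100 --out report.tsv
lossscan phylo --proteins crds.fa --out-tree t.nwk --out-matrix d.tsv
lossscan run --config panel.yaml
```

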