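# lrrscan

Degenerate leucine-rich-repeat (LRR) consensus scanning for channel
C-termini, built around the putative LRR motifs of the Pannexin 1
(Panx1) intracellular C-terminal tail, plus the quantitative assay
computations used to characterize trafficking phenotypes.

## The problem

Panx1 is a four-transmembrane channel protein whose intracellular
C-terminus (Panx1CT, residues ~299 to the end) controls whether the
channel reaches the cell surface.  The proximal Panx1CT contains a
putative LRR motif: single LRR units carry an 11–12 residue *highly
conserved segment* (HCS) fitting

```
L x x L x L x x N x L        (11-mer)
L x x L x L x x C x x L      (12-mer)
```

where the anchor classes are degenerate: **L** is Leu/Ile/Val/Phe (the
internal L anchors tolerate any hydrophobic residue), **N** is
Asn/Thr/Ser/Cys, **C** is Cys/Ser/Asn, `x` is any residue, and the
first and last L positions may relax to relatively hydrophilic
residues.  Two or more LRR units in close proximity form solenoidal
LRR domains that mediate protein–protein interactions and subcellular
targeting.

`lrrscan` implements this consensus as an explicit, configurable
residue-class matcher (`ResidueClassConfig`) and provides:

* **scanning** — every start position of a protein is tested for both
  window lengths; 11- and 12-mer hits at the same start merge into one
  hit with both variants, and per-anchor evidence records which class
  (core, hydrophobic extension, terminal relaxation) admitted each
  residue;
* **motif / domain assembly** — each HCS gains a putative trailing
  variable segment (VS, default up to 7 residues), and hits whose
  starts lie within 30 residues chain into putative LRR domains;
* **a null model** — closed-form per-window match probabilities and
  expected chance-hit counts for an i.i.d. residue background, for
  calibrating scan output;
* **conservation** — hits are lifted through a user-supplied multiple
  sequence alignment (aligned FASTA or Clustal) into ortholog rows and
  re-tested in the ortholog's own residues;
* **annotation overlap** — closed-interval intersection of hits with
  functional-site intervals; the five published Panx1CT HCS segments
  and their annotated sites (endocytic motifs, caspase-cleavage site,
  membrane-interacting region, …) ship as packaged TSVs;
* **assay quantification** — two-channel colocalization (Pearson's r
  over a foreground mask and colocalization rate), lane densitometry
  (per-band percent of declared lane signal), growth-curve doubling
  time (DT = Δt·ln2 / ln(N_later/N_earlier), two-point or log-linear
  regression), dead-cell fraction and MTT percent-of-control;
* **synthetic data** — seeded generators for sequences with planted
  consensus windows, ortholog sets, ring/disc two-channel images,
  exponential growth series and Gaussian-band lane profiles, each with
  a ground-truth record.

All coordinates are 1-based and inclusive, so literature positions
such as S328-K348 address residues directly.

## Worked example

Re-derive the published Panx1CT evidence table (packaged segments,
default consensus):

```bash
$ lrrscan table1
hcs     discovery          span     variant  window        match  relaxations
HCS1    visual_inspection  305-315  11       LKVYEILPTFD   yes    4:Y:hydrophobic_ext;11:D:terminal
HCS2    scanprosite        329-340  11       LYNLFLEENIS   yes    11:S:terminal
HCS2    scanprosite        329-340  12       LYNLFLEENISE  yes    12:E:terminal
HCS3    visual_inspection  344-355  12       YKCLKVLENIKS  yes    1:Y:hydrophobic_ext;12:S:terminal
HCS4    visual_inspection  360-371  12       IDPMLLLTNLGM  yes    4:M:hydrophobic_ext;12:M:hydrophobic_ext
HCS5    visual_inspection  376-387  12       IIDGKIPTSLQT  yes    4:G:hydrophobic_ext;12:T:terminal
...
```

Every printed variant matches; the `relaxations` column is the anchor
evidence (window position : residue : relaxation used), e.g. HCS5
needs the hydrophobic extension for G at anchor position 4.

From Python, scanning a sequence with the five published windows
joined by proline spacers:

```python
>>> from lrrscan import *
>>> from lrrscan.resources import load_table1_segments
>>> windows = [s.longest_window for s in load_table1_segments()]
>>> seq = ProteinSequence(id="demo", residues=("P" * 10).join(windows))
>>> hits = scan_sequence(seq)
>>> [(m.start, m.variants) for m in hits]
[(1, (11,)), (22, (11, 12)), (44, (11, 12)), (66, (11, 12)), (88, (11, 12))]
>>> infer_domains(hits)[0].span
(1, 99)
>>> null = null_match_probability(uniform_frequencies())
>>> round(null.p11, 4), round(null.expected_hits(len(seq)), 2)
(0.05, 4.45)
```

Five hits, one five-member putative domain.  The uniform-background
null model says a random 99-mer would produce ~4.4 chance hit starts
under the permissive default classes — the calibration context for any
scan report.

Doubling time from a synthetic growth series (true DT 20 h, 5%
multiplicative noise, five counts 24 h apart):

```python
>>> from lrrscan.synthetic import gen_growth
>>> series, truth = gen_growth(dt_hours=20.0, noise_sigma=0.05, seed=13)
>>> doubling_time(series, (0, 4), mode="regression").doubling_time_hours
19.75...
```

The CLI exposes the same operations as subcommands: `scan`, `table1`,
`conserve`, `coloc`, `lane`, `growth`, `simulate`, `annotations`
(`lrrscan <cmd> --help`).

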