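# isoclone

Medium-throughput heterologous expression campaigns clone dozens to
hundreds of candidate genes in parallel into *Escherichia coli* expression
vectors and screen them for soluble protein. `isoclone` implements the
in-silico side of one such strategy: every insert is flanked by a
BamHI-family site upstream and an EcoRI-family site downstream, so a single
PCR product per gene can be ligated into **both** a His6-tag vector (pFO4)
and a GST-tag vector (pGEX-4T-1) that are always opened with BamHI + EcoRI.
Genes that carry an internal BamHI or EcoRI site are rescued by the
**isocaudomers** BglII and MfeI — enzymes with different recognition sites
but identical 5' overhangs (GATC and AATT respectively) — giving four
cloning strategies: BamHI/EcoRI, BamHI/MfeI, BglII/EcoRI, BglII/MfeI.
A cross-junction such as BamHI×BglII ligates into a hybrid 6-mer
(`G^GATCC` + `A^GATCT` → `GGATCT`) cut by neither enzyme, and — because the
vector's `GGATCC` sits at phase 0 of the tag ORF — still reads Gly-Ser, so
the scar is silent at the protein level.

The package covers, as importable modules and a CLI:

- **triage** — restriction-site screening and strategy assignment
  (preference BamHI > BglII, EcoRI > MfeI), signal-peptide/transmembrane
  detection by Kyte–Doolittle hydropathy (window 19, mean ≥ 1.6) with
  trimming or elimination, and predicted-mass bounds (7–140 kDa);
- **primer_design** — tailed primers
  `5'-G6-[BamHI|BglII]-[hyb]-3'` / `5'-C6-[EcoRI|MfeI]-[stop anticodon]-[hyb]-3'`
  with hybridization regions chosen so every target shares one Wallace-rule
  melting temperature, Tm = 2(A+T) + 4(G+C) (default 60 ± 2 °C);
- **clone_sim** — in-silico digestion, sticky-end ligation (including
  isocaudomer scars), fusion reading-frame validation and colony-PCR size
  prediction;
- **plate_layout** — 96-well cloning / 24-well expression plate arraying
  and picklists;
- **screening_report** — aggregation of per-target per-vector outcomes
  (soluble / insoluble / no expression / no clone) into domain-of-life ×
  vector count and integer-percentage tables, a best-outcome combined
  column, and pipeline-funnel efficiencies;
- **fixtures** — deterministic synthetic CDS and screen generators
  (controlled GC, implanted sites, hydrophobic stretches, per-domain
  outcome probabilities) so everything is testable without downloads.

## Worked example

Generate a synthetic 192-target three-domain campaign and run the whole
pipeline:

```bash
isoclone fixtures table2-like --seed 1 --outdir fx
isoclone run fx/targets.fasta --sidecar fx/targets.tsv \
    --screen-tsv fx/screen.tsv --outdir out
```

which prints

```
192 synthetic targets written to fx
INFO isoclone: config 25dcfad8064c: 192 targets read
INFO isoclone: triage: 192 assigned, 0 eliminated
INFO isoclone: design/clone: 192 primer pairs, 384 constructs
targets=192 assigned=192 constructs=384 config=25dcfad8064c
```

`out/triage.tsv` records each target's strategy and retained interval
(1-based inclusive), `out/primer_order.tsv` the vendor-ready oligos, e.g.

```
plate	well	primer_name	sequence	length	hyb_tm
oligo_plate_1	A1	t2_000_F	GGGGGGGGATCCATGCTTCCCGACATCAAATC	32	58.0
oligo_plate_1	A2	t2_000_R	CCCCCCGAATTCTTACACCGTGTCAGGAAGAAGG	34	60.0
```

(read: hexa-G tail, `GGATCC`, then a hybridization region with Wallace Tm
58 °C; the reverse oligo carries the hexa-C tail, `GAATTC`, the `TTA` stop
anticodon and the reverse-complemented 3' end of the gene). With the
screen TSV supplied, `out/summary_percent.tsv` holds the integer
percentage rows, denominator = all 192 targets:

```
percentage of soluble proteins	4	6	5	15	10	10	19	30	41
percentage of soluble + insoluble proteins	11	13	7	15	17	26	34	54	69
```

— columns are eukarya/bacteria/archaea × pFO4/pGEX-4T-1, then per-vector
totals and the combined (best-of-two-vectors) column; this simulated
campaign lands at 41% combined soluble.

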