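# Methods

## The cloning model

`isoclone` simulates a two-vector restriction-cloning strategy in which all
expression vectors are digested with BamHI and EcoRI, while each insert is
amplified with primers that add either the same sites or their isocaudomers
(BglII for BamHI, MfeI for EcoRI). The four enzymes are modelled exactly:

| enzyme | site | top-strand cut | 5' overhang |
|--------|--------|---------------|-------------|
| BamHI | GGATCC | after base 1 | GATC |
| BglII | AGATCT | after base 1 | GATC |
| EcoRI | GAATTC | after base 1 | AATT |
| MfeI | CAATTG | after base 1 | AATT |

All four sites are palindromic, so single-strand scanning is complete; this
is asserted at enzyme construction. Fragments are represented by their top
strand with overhang labels; ligation concatenates top strands, and with a
cut offset of 1 every junction 6-mer is `upstream[-1] + downstream[:5]`.
Same-enzyme junctions reconstitute the site; cross-family-compatible
junctions (BamHI×BglII → GGATCT, AGATCC; EcoRI×MfeI → GAATTG, CAATTC) are
cut by none of the four enzymes. Circular plasmids are kept as linear
strings cut at the vector origin; the circularization junction is checked
through a 10-nt wraparound window rather than by introducing a circular
sequence type.

Both bundled vectors place `GGATCC` at phase 0 of the tag ORF, so the
junction reads Gly-Ser whether the insert arrived via BamHI or BglII, and
the insert's own codons follow in frame. The vector cloning-site contexts
are short **synthetic stand-ins** (a His6 tag in a pET-style leader for
pFO4; an abridged GST N-terminus with thrombin site for pGEX-4T-1): the
real vector sequences are not bundled, and the stand-ins carry exactly the
information needed for frame validation and junction simulation. Reports
that include junction data flag this.

Frame validation is by construction *and* by check: the fusion ORF is
translated from the tag ATG and must contain the trimmed target protein as
a contiguous substring, terminated by the single stop introduced with the
reverse primer (native terminal stops are stripped during design).
Expected colony-PCR product size is insert length plus a configurable
150 nt screening-primer flank per side (tolerance 100 nt); these two
constants are bookkeeping defaults, not measured values.

## Triage

Candidates are vetted in this order, with elimination precedence
restriction > membrane > mass (matching the order in which a campaign
discards targets):

1. **Trimming.** Residue-level annotations (signal peptide, transmembrane)
   are used when available; otherwise segments come from a hydropathy
   heuristic that stands in for dedicated predictors (SignalP/TMHMM-class
   tools are deliberately out of scope). A residue is membrane-associated
   iff it lies in at least one 19-residue window whose mean Kyte–Doolittle
   value is ≥ 1.6; maximal runs of ≥ 19 such residues are transmembrane
   segments, reclassified as a signal peptide when fully inside the first
   35 residues. Window 19, threshold 1.6 and the 35-residue zone are
   standard literature defaults and configurable. Detected boundaries are
   guaranteed within ±9 residues (half a window) of an implanted
   hydrophobic stretch only when its surroundings are polar; against a
   random-composition background the boundary can creep slightly further,
   which is why the parameter-recovery fixtures use annotation-driven
   trimming.
2. An N-terminal signal peptide is removed (retention starts at the next
   codon); a protein whose transmembrane residues cover > 30% of its length
   or fall in > 2 segments is eliminated ("membrane zones throughout");
   otherwise the largest segment-free terminal span is retained. Retained
   spans shorter than 30 aa are eliminated. A fully retained C-terminus
   keeps its native stop codon.
3. **Strategy assignment** scans the CDS that will actually be amplified
   (i.e. post-trim) for internal sites. Preference is BamHI > BglII and
   EcoRI > MfeI — vector-native sites first, minimizing scar junctions;
   the choice of preference order is open in principle and this one is a
   package decision.
4. **Mass bounds.** Average-mass molecular weight of the retained
   translation must lie in the inclusive window 7–140 kDa.

Multi-module proteins can additionally be split into child targets (one
per annotated module, full-length parent retained), reflecting the practice
of cloning both full-length proteins and their individual domains.

## Primer design

Hybridization regions are the 5'/3'-terminal L-mers of the (trimmed,
stop-stripped) CDS with L the shortest length in [18, 35] whose Wallace
Tm, 2(A+T) + 4(G+C), lands within the target window (default 60 ± 2 °C;
ties and out-of-window cases minimize |Tm − target|, smaller L first). The
Wallace rule was chosen over nearest-neighbour thermodynamics because it
is deterministic and hand-checkable; the common Tm value itself is not a
claim about any particular study, only a configurable default consistent
with a 50 °C annealing step. The stop anticodon defaults to TTA (a TAA
stop, the strongest in *E. coli*) and accepts CTA/TCA. After assembly the
whole amplicon is rescanned: exactly one site per assigned enzyme may be
present, otherwise the design errors out advising strategy reassignment
(this also catches the rare case of a site formed across the
site/hybridization junction).

## Screen aggregation

Per-target per-vector statuses are `soluble`, `insoluble`,
`no_expression`, `no_clone`, plus `not_screened` for padding. The combined
column takes the per-target best outcome across vectors with precedence
soluble > insoluble > no_expression > no_clone — the rule that makes a
"combined" column a best-of-two summary. Percentages are integers with
denominator equal to the **full** target count (not the per-vector
screened count) and rounding of halves away from zero; this pair of
conventions is what regenerates all 18 published percentage cells of the
192-target campaign the package's defaults emulate, including the
12.5 → 13 half-up cell. Funnel efficiencies are consecutive-stage integer
percentages over whatever ordered stage counts are supplied;
non-monotone stages warn rather than fail, since real campaigns screen
fewer clones than they make.

## Synthetic data

The fixture generator emulates the raw material of a multi-organism
campaign at the structural level the pipeline cares about:

- CDSs start ATG, end TAA, contain no internal in-frame stop, hold GC
  within ±5% of a requested fraction (codon sampling from a GC-weighted
  table plus a bounded adjustment loop — no rejection sampling), and are
  free of all four recognition sites except those implanted in frame at
  requested codon positions (GGATCC = Gly-Ser, AGATCT = Arg-Ser,
  GAATTC = Glu-Phe, CAATTG = Gln-Leu).
- Hydrophobic stretches are alternating CTG/TTA leucine codons (GC-neutral
  and provably unable to form any of the four sites).
- Screens are independent categorical draws per target × vector with
  per-domain probabilities; probability mass not assigned to a status goes
  to `no_clone`.
- Every generator consumes one `numpy` Generator seeded from a single
  integer; no global random state.

The bundled "table2-like" scenario uses domain strata of 74 eukaryal, 32
bacterial and 86 archaeal targets (summing to 192) with per-cell
probabilities equal to published count cells over the domain size. The
published per-domain archaeal columns are mutually inconsistent (their
per-vector sums, 70 and 73, fall short of any domain size compatible with
the 192 total), so the archaeal shortfall is emitted as `not_screened`
padding in marginal fixtures and as extra `no_clone` mass in stochastic
draws; recovery tests therefore assert the soluble/insoluble cells, which
are construction-consistent, within three binomial standard deviations per
cell across 200 replicate seeds.

What the fixtures do **not** emulate: organism-specific codon usage, PCR
failure mechanisms, ligation/transformation efficiency, partial digestion,
or any sequence-dependent cause of insolubility — outcome frequencies are
exogenous probabilities. Passing tests therefore demonstrate that the
bookkeeping, arithmetic and sequence transformations are correct, not that
the pipeline predicts wet-lab solubility.

## Problem sizes and numerical choices

Default test and acceptance problem sizes — 200-target triage and
end-to-end suites, 1000 × 1 kb scanner-oracle comparisons, 200 replicate
screen simulations at n = 192 — were chosen as the smallest sets that
exercise all four strategies, both vectors and every elimination path with
comfortable statistical margins. Percent values are exact integer
arithmetic; the only floating-point tolerances in the package are the mass
check (library-accurate average masses) and hydropathy means.

## Known limitations

- The hydropathy heuristic is a triage aid, not a SignalP/TMHMM
  replacement; on real proteomes it will mislabel marginal or atypical
  signal anchors. Supplying annotations is always preferred.
- Vector contexts are synthetic; colony-PCR sizes and fusion N-termini are
  exact only relative to these stand-ins.
- `no_expression` vs `no_clone` semantics follow the combined-status
  precedence; records carry no per-colony evidence.
- Only uppercase A/C/G/T inputs are accepted (no IUPAC ambiguity codes),
  and UTR trimming of eukaryotic cDNA is assumed done upstream.
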