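"""Core domain types and FASTA/TSV I/O shared by the whole pipeline.

Coordinate conventions
----------------------
Nucleotide coordinates are 0-based half-open internally; every user-facing
report is 1-based inclusive and says so in its header.  Protein (residue)
coordinates in annotations are 1-based inclusive, the way signal-peptide
and transmembrane predictors report them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AnnotatedSegment",
    "TargetGene",
    "Enzyme",
    "VectorSpec",
    "BAMHI",
    "BGLII",
    "ECORI",
    "MFEI",
    "ENZYMES",
    "FORWARD_FAMILY",
    "REVERSE_FAMILY",
    "PFO4",
    "PGEX",
    "VECTORS",
    "DOMAINS_OF_LIFE",
    "translate",
    "reverse_complement",
    "read_targets",
    "write_targets",
]

DOMAINS_OF_LIFE = ("eukarya", "bacteria", "archaea", "virus")
SEGMENT_KINDS = ("signal_peptide", "transmembrane", "module")

_NT = set("ACGT")


def translate(cds: str) -> str:
    """Standard-genetic-code translation of successive codons from position 1.

    A trailing incomplete codon is ignored; stop codons are rendered ``*``.
    """
    if len(cds) < 3:
        raise ValueError("need at least one full codon to translate")
    usable = len(cds) - len(cds) % 3
    return str(Seq(cds[:usable]).translate())


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of an A/C/G/T string."""
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class AnnotatedSegment:
    """A residue interval on the translated protein (1-based inclusive)."""

    kind: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in SEGMENT_KINDS:
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid residue interval {self.start}-{self.end} (1-based inclusive)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class TargetGene:
    """One candidate CDS with organism metadata and optional residue annotations.

    The CDS must be uppercase A/C/G/T and at least 30 nt.  If it is a whole
    ORF (multiple of 3, starts ATG) its translation may not contain an
    internal stop; a terminal stop is permitted.
    """

    id: str
    cds: str
    organism: str = ""
    domain_of_life: str = "bacteria"
    annotations: list[AnnotatedSegment] = field(default_factory=list)
    source_note: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("target id must be non-empty")
        if self.domain_of_life not in DOMAINS_OF_LIFE:
            raise ValueError(
                f"{self.id}: domain_of_life {self.domain_of_life!r} not in {DOMAINS_OF_LIFE}"
            )
        bad = next((i for i, c in enumerate(self.cds) if c not in _NT), None)
        if bad is not None:
            raise ValueError(
                f"{self.id}: non-ACGT character {self.cds[bad]!r} at position {bad + 1}"
            )
        if len(self.cds) < 30:
            raise ValueError(f"{self.id}: CDS shorter than 30 nt ({len(self.cds)})")
        if len(self.cds) % 3 == 0 and self.cds.startswith("ATG"):
            prot = translate(self.cds)
            if "*" in prot[:-1]:
                raise ValueError(f"{self.id}: internal stop codon in ORF")
        plen = len(self.cds) // 3
        for seg in self.annotations:
            if seg.end > plen:
                raise ValueError(
                    f"{self.id}: segment {seg.kind} {seg.start}-{seg.end} exceeds "
                    f"protein length {plen}"
                )

    @property
    def protein(self) -> str:
        """Translation of the CDS, without a terminal stop if present."""
        prot = translate(self.cds)
        return prot[:-1] if prot.endswith("*") else prot


@dataclass(frozen=True)
class Enzyme:
    """A type-II restriction enzyme with a palindromic 6-mer site.

    ``cut_offset`` is the number of nt after the site's first base at which
    the top strand is cut; the staggered bottom-strand cut leaves a 4-nt
    5' extension (``overhang``) on the downstream fragment.
    """

    name: str
    site: str
    cut_offset: int
    overhang: str
    role: str  # forward_family | reverse_family

    def __post_init__(self) -> None:
        if self.site != reverse_complement(self.site):
            raise ValueError(f"{self.name}: recognition site must be palindromic")


BAMHI = Enzyme("BamHI", "GGATCC", 1, "GATC", "forward_family")
BGLII = Enzyme("BglII", "AGATCT", 1, "GATC", "forward_family")
ECORI = Enzyme("EcoRI", "GAATTC", 1, "AATT", "reverse_family")
MFEI = Enzyme("MfeI", "CAATTG", 1, "AATT", "reverse_family")

ENZYMES = {e.name: e for e in (BAMHI, BGLII, ECORI, MFEI)}
#: BamHI/BglII cut to a GATC overhang and sit at the 5' end of the insert.
FORWARD_FAMILY = (BAMHI, BGLII)
#: EcoRI/MfeI cut to an AATT overhang and sit at the 3' end of the insert.
REVERSE_FAMILY = (ECORI, MFEI)


@dataclass(frozen=True)
class VectorSpec:
    """An expression vector opened at a BamHI/EcoRI window downstream of a tag.

    ``cloning_site_context`` is a short SYNTHETIC stand-in sequence spanning
    tag ORF -> GGATCC -> stuffer -> GAATTC -> downstream region: the real
    vector sequences are not bundled, and the stand-in is sufficient for
    frame validation and junction simulation only.  ``upstream_frame_offset``
    gives the reading-frame phase of the first base of GGATCC relative to
    the tag ORF (0 for both bundled vectors: GGA-TCC reads Gly-Ser).
    """

    name: str
    tag: str
    upstream_frame_offset: int
    cloning_site_context: str
    tag_orf_start: int  # index of the tag ATG within cloning_site_context

    def __post_init__(self) -> None:
        if self.upstream_frame_offset not in (0, 1, 2):
            raise ValueError("upstream_frame_offset must be 0, 1 or 2")
        ctx = self.cloning_site_context
        b = ctx.find(BAMHI.site)
        e = ctx.find(ECORI.site)
        if b < 0 or e < 0 or e <= b:
            raise ValueError(f"{self.name}: context must contain GGATCC then GAATTC")
        if (b - self.tag_orf_start) % 3 != self.upstream_frame_offset:
            raise ValueError(f"{self.name}: GGATCC phase does not match frame offset")

    @property
    def bamhi_pos(self) -> int:
        return self.cloning_site_context.find(BAMHI.site)

    @property
    def ecori_pos(self) -> int:
        return self.cloning_site_context.find(ECORI.site)


# Synthetic stand-in contexts (see VectorSpec docstring).  The stuffer between
# the sites and the downstream region are free of all four recognition sites.
_STUFFER = "TCTAGACTGCAGCTCGAG"
_DOWNSTREAM = "TAACTGATAACCCGGGTTT"

PFO4 = VectorSpec(
    name="pFO4",
    tag="His6",
    upstream_frame_offset=0,
    # RBS-like leader, then M G S S H H H H H H (pET15b-style tag), phase-0 BamHI.
    cloning_site_context=(
        "GTTTAACTTTAAGAAGGAGATATACAT"
        + "ATGGGCAGCAGCCATCATCATCATCATCAC"
        + "GGATCC" + _STUFFER + "GAATTC" + _DOWNSTREAM
    ),
    tag_orf_start=27,
)

PGEX = VectorSpec(
    name="pGEX-4T-1",
    tag="GST",
    upstream_frame_offset=0,
    # Abridged GST N-terminus (M S P I L G Y W) + thrombin site L V P R, phase-0 BamHI.
    cloning_site_context=(
        "ATGTCCCCTATACTAGGTTATTGG"
        + "CTGGTTCCGCGT"
        + "GGATCC" + _STUFFER + "GAATTC" + _DOWNSTREAM
    ),
    tag_orf_start=0,
)

VECTORS = {v.name: v for v in (PFO4, PGEX)}


def _format_annotations(segments: list[AnnotatedSegment]) -> str:
    return ";".join(f"{s.kind}:{s.start}-{s.end}" for s in segments)


def _parse_annotations(text: str) -> list[AnnotatedSegment]:
    segments: list[AnnotatedSegment] = []
    for chunk in filter(None, (c.strip() for c in text.split(";"))):
        kind, _, interval = chunk.partition(":")
        start, _, end = interval.partition("-")
        segments.append(AnnotatedSegment(kind.strip(), int(start), int(end)))
    return segments


SIDECAR_COLUMNS = ("id", "organism", "domain_of_life", "annotations")


def read_targets(fasta_path: str | Path, sidecar_path: str | Path | None = None) -> list[TargetGene]:
    """Read candidate CDSs from FASTA, joining an optional TSV sidecar by id.

    The FASTA id is the first whitespace-delimited header token; the rest of
    the header is kept as ``source_note``.  Sidecar rows whose id matches no
    FASTA record raise a warning and are skipped.  Duplicate ids and
    non-ACGT characters are hard errors.
    """
    fasta_path = Path(fasta_path)
    meta: dict[str, dict[str, str]] = {}
    if sidecar_path is not None:
        import csv

        with open(sidecar_path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for row in reader:
                meta[row["id"]] = row

    targets: list[TargetGene] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        if record.id in seen:
            raise ValueError(f"duplicate target id {record.id!r} in {fasta_path}")
        seen.add(record.id)
        row = meta.pop(record.id, None)
        description = record.description.split(None, 1)
        targets.append(
            TargetGene(
                id=record.id,
                cds=str(record.seq).upper(),
                organism=(row or {}).get("organism", ""),
                domain_of_life=(row or {}).get("domain_of_life") or "bacteria",
                annotations=_parse_annotations((row or {}).get("annotations", "")),
                source_note=description[1] if len(description) > 1 else "",
            )
        )
    for orphan in meta:
        warnings.warn(f"sidecar row {orphan!r} has no FASTA record; skipped", stacklevel=2)
    return targets


def write_targets(
    targets: list[TargetGene],
    fasta_path: str | Path,
    sidecar_path: str | Path | None = None,
) -> None:
    """Write targets as FASTA plus an optional TSV sidecar (inverse of read_targets)."""
    records = [
        SeqRecord(Seq(t.cds), id=t.id, description=t.source_note) for t in targets
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    if sidecar_path is not None:
        with open(sidecar_path, "w") as fh:
            fh.write("\t".join(SIDECAR_COLUMNS) + "\n")
            for t in targets:
                fh.write(
                    "\t".join(
                        (t.id, t.organism, t.domain_of_life, _format_annotations(t.annotations))
                    )
                    + "\n"
                )
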