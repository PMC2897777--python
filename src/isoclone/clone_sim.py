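"""In-silico digestion, sticky-end ligation and fusion-frame validation.

The cloning chemistry simulated here is the isocaudomer trick: the two
expression vectors are always opened with BamHI and EcoRI, while the insert
may carry BamHI-or-BglII and EcoRI-or-MfeI ends.  BamHI/BglII both leave a
GATC 5' overhang and EcoRI/MfeI an AATT overhang, so any insert ligates
into the same vector window.  A cross (isocaudomer) junction produces a
hybrid 6-mer ("scar") cut by neither parent enzyme; a same-enzyme junction
reconstitutes the site.  Either way the junction is silent at the protein
level (the first two insert-borne codons still read Gly-Ser downstream of
a phase-0 GGATCC).

Circular plasmids are represented as linear strings cut at the vector
origin; junction scans use a wraparound window so the circularization
junction is checked too.
"""

from __future__ import annotations

from dataclasses import dataclass

from .sequence_model import ENZYMES, Enzyme, TargetGene, VectorSpec, translate
from .primer_design import DesignParams, PrimerPair, amplicon_sequence, strip_stop
from .triage import StrategyAssignment, TrimReport, scan_sites

__all__ = [
    "Fragment",
    "ConstructPlan",
    "CloneParams",
    "digest",
    "ligate",
    "ligation_junctions",
    "open_vector",
    "build_construct",
    "verify_clone",
    "construct_report",
]

BLUNT = "blunt"
#: junction scans look this many nt across each seam (and across the origin)
JUNCTION_WINDOW = 10


@dataclass(frozen=True)
class Fragment:
    """A double-stranded fragment, stored as its top strand 5'->3'.

    5' overhangs are labelled by their 4-mer sequence (GATC, AATT) or
    ``blunt``; the first/last bases of ``top_strand`` at a sticky end are
    the single-stranded extension itself.
    """

    top_strand: str
    left_overhang: str = BLUNT
    right_overhang: str = BLUNT
    origin: str = "insert"  # vector | insert

    def __post_init__(self) -> None:
        for oh in (self.left_overhang, self.right_overhang):
            if oh not in (BLUNT, "GATC", "AATT"):
                raise ValueError(f"unknown overhang label {oh!r}")


@dataclass
class ConstructPlan:
    """One simulated vector-insert fusion and its verification data."""

    target_id: str
    vector: VectorSpec
    assignment: StrategyAssignment
    pair: PrimerPair
    insert_seq: str
    plasmid: str
    fusion_protein: str
    junction_5: str
    junction_3: str
    frame_ok: bool
    expected_colony_pcr_len: int
    diagnostic: str = ""


@dataclass(frozen=True)
class CloneParams:
    """Colony-PCR bookkeeping: screening-primer offset per vector side, and
    the size tolerance for calling a colony-PCR band correct."""

    flank_per_side: int = 150
    size_tol: int = 100


def digest(seq: str, enzymes: set[Enzyme] | frozenset[Enzyme]) -> list[Fragment]:
    """Cut a linear sequence at every recognition site, left to right.

    The top strand is cut ``cut_offset`` nt after the site's first base;
    the 4-nt 5' overhang stays on the downstream fragment's left end.
    Sites are counted on one strand only, which is complete because all
    four sites are palindromic.
    """
    cuts: list[tuple[int, Enzyme]] = []
    for enz in enzymes:
        cuts.extend((pos + enz.cut_offset, enz) for pos in scan_sites(seq, enz))
    cuts.sort()
    fragments: list[Fragment] = []
    prev, left_oh = 0, BLUNT
    for cut_pos, enz in cuts:
        fragments.append(Fragment(seq[prev:cut_pos], left_oh, enz.overhang))
        prev, left_oh = cut_pos, enz.overhang
    fragments.append(Fragment(seq[prev:], left_oh, BLUNT))
    return fragments


def ligate(vector_frag: Fragment, insert_frag: Fragment) -> str:
    """Circularize an opened vector with an insert; returns the plasmid
    linearized at the vector fragment's 5' end.

    Requires complementary sticky ends on both junctions:
    vector.right == insert.left and insert.right == vector.left.
    """
    if vector_frag.right_overhang != insert_frag.left_overhang:
        raise ValueError(
            f"incompatible overhangs at vector->insert junction: "
            f"{vector_frag.right_overhang} vs {insert_frag.left_overhang}"
        )
    if insert_frag.right_overhang != vector_frag.left_overhang:
        raise ValueError(
            f"incompatible overhangs at insert->vector junction: "
            f"{insert_frag.right_overhang} vs {vector_frag.left_overhang}"
        )
    return vector_frag.top_strand + insert_frag.top_strand


def ligation_junctions(vector_frag: Fragment, insert_frag: Fragment) -> tuple[str, str]:
    """The two realized junction 6-mers (seam and wraparound), 5'->3'.

    With cut_offset 1 the upstream fragment retains one base of the 6-mer
    and the downstream fragment five, so each junction is
    ``upstream[-1] + downstream[:5]``.
    """
    seam = vector_frag.top_strand[-1] + insert_frag.top_strand[:5]
    wrap = insert_frag.top_strand[-1] + vector_frag.top_strand[:5]
    return seam, wrap


def junction_recut(junction_region: str) -> list[str]:
    """Names of the enzymes (of the four) whose site occurs in a junction window."""
    return [name for name, enz in ENZYMES.items() if scan_sites(junction_region, enz)]


def open_vector(vector: VectorSpec) -> Fragment:
    """The BamHI+EcoRI-opened backbone, linearized at the vector origin.

    Represented as context-up-to-the-BamHI-cut; the downstream arm (from
    the EcoRI cut) is carried by the wraparound convention and re-attached
    by :func:`assemble_plasmid`.
    """
    ctx = vector.cloning_site_context
    return Fragment(ctx[: vector.bamhi_pos + 1], left_overhang="AATT",
                    right_overhang="GATC", origin="vector")


def assemble_plasmid(vector: VectorSpec, insert_frag: Fragment) -> tuple[str, str, str]:
    """Ligate an insert into the vector's GGATCC/GAATTC window.

    Returns (plasmid linearized at the vector origin, 5' junction 6-mer,
    3' junction 6-mer).
    """
    ctx = vector.cloning_site_context
    upstream = ctx[: vector.bamhi_pos + 1]          # ...G  (GATC overhang)
    downstream = ctx[vector.ecori_pos + 1 :]        # AATTC... (AATT overhang)
    if insert_frag.left_overhang != "GATC" or insert_frag.right_overhang != "AATT":
        raise ValueError(
            f"insert overhangs ({insert_frag.left_overhang}, {insert_frag.right_overhang}) "
            "do not fit a BamHI/EcoRI-opened vector"
        )
    plasmid = upstream + insert_frag.top_strand + downstream
    j5 = upstream[-1] + insert_frag.top_strand[:5]
    j3 = insert_frag.top_strand[-1] + downstream[:5]
    return plasmid, j5, j3


def build_construct(
    target: TargetGene,
    assignment: StrategyAssignment,
    trim: TrimReport,
    pair: PrimerPair,
    vector: VectorSpec,
    design_params: DesignParams | None = None,
    clone_params: CloneParams | None = None,
) -> ConstructPlan:
    """Amplify, digest, ligate and frame-check one target into one vector."""
    design_params = design_params or DesignParams()
    clone_params = clone_params or CloneParams()
    if assignment.status != "assigned":
        raise ValueError(f"{target.id}: cannot clone status {assignment.status}")

    amp = amplicon_sequence(pair, trim.retained_cds, design_params)
    fragments = digest(amp, {assignment.forward_enzyme, assignment.reverse_enzyme})
    if len(fragments) != 3:
        raise ValueError(
            f"{target.id}: amplicon digest produced {len(fragments)} fragments "
            "(expected 3: two tail scraps + insert); internal site slipped past triage"
        )
    insert = Fragment(fragments[1].top_strand, fragments[1].left_overhang,
                      fragments[1].right_overhang, origin="insert")

    plasmid, j5, j3 = assemble_plasmid(vector, insert)

    orf = plasmid[vector.tag_orf_start :]
    fusion = translate(orf[: len(orf) - len(orf) % 3])
    fusion_protein, _, _ = fusion.partition("*")

    payload = strip_stop(trim.retained_cds)
    target_protein = translate(payload) if payload else ""
    frame_ok = bool(target_protein) and target_protein in fusion_protein
    diagnostic = "" if frame_ok else (
        f"{target.id}: trimmed protein not in fusion ORF (frame violation?)"
    )

    expected = len(insert.top_strand) + 2 * clone_params.flank_per_side
    return ConstructPlan(
        target_id=target.id,
        vector=vector,
        assignment=assignment,
        pair=pair,
        insert_seq=insert.top_strand,
        plasmid=plasmid,
        fusion_protein=fusion_protein,
        junction_5=j5,
        junction_3=j3,
        frame_ok=frame_ok,
        expected_colony_pcr_len=expected,
        diagnostic=diagnostic,
    )


def verify_clone(plan: ConstructPlan, observed_len: int, tol: int = 100) -> str:
    """Colony-PCR size check: 'pass' iff the band is within tol nt of expected."""
    return "pass" if abs(observed_len - plan.expected_colony_pcr_len) <= tol else "fail"


def construct_report(plans: list[ConstructPlan]):
    """Per-construct map as a DataFrame.

    Coordinates are 1-based inclusive; vector cloning-site contexts are
    synthetic stand-ins (see VectorSpec).
    """
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "id": p.target_id,
                "vector": p.vector.name,
                "strategy": p.assignment.strategy_label,
                "junction_5": p.junction_5,
                "junction_3": p.junction_3,
                "insert_len": len(p.insert_seq),
                "fusion_len_aa": len(p.fusion_protein),
                "frame_ok": p.frame_ok,
                "expected_colony_pcr_len": p.expected_colony_pcr_len,
            }
            for p in plans
        ]
    )
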