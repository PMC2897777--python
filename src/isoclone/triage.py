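"""Bioinformatic target triage ahead of cloning.

Four steps, mirroring how candidates are vetted before a two-vector
restriction-cloning campaign:

1. hydrophobic-segment detection (a documented Kyte-Doolittle stand-in for
   dedicated signal-peptide/transmembrane predictors) and trimming;
2. restriction-site screening of the CDS that will actually be amplified,
   assigning one of the four compatible enzyme pairs
   (BamHI/EcoRI, BamHI/MfeI, BglII/EcoRI, BglII/MfeI) or eliminating the
   target when no pair is internally clean;
3. predicted-mass bounds (7-140 kDa inclusive);
4. optional splitting of multi-module proteins into individually cloned
   child targets.

Elimination precedence is restriction > membrane > mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from Bio.SeqUtils import molecular_weight
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .sequence_model import (
    BAMHI,
    BGLII,
    ECORI,
    MFEI,
    AnnotatedSegment,
    Enzyme,
    TargetGene,
    translate,
)

__all__ = [
    "StrategyAssignment",
    "TrimReport",
    "TriageParams",
    "TriageResult",
    "scan_sites",
    "classify_strategy",
    "hydropathy_profile",
    "detect_membrane_segments",
    "predicted_mass",
    "trim_target",
    "split_modules",
    "triage_target",
    "triage_targets",
    "triage_table",
]

MASS_MIN_KDA = 7.0
MASS_MAX_KDA = 140.0
MIN_RETAINED_AA = 30

STATUSES = ("assigned", "eliminated_restriction", "eliminated_membrane", "eliminated_mass")


@dataclass(frozen=True)
class StrategyAssignment:
    """Which of the four enzyme pairs (or elimination) applies to a target."""

    target_id: str
    forward_enzyme: Enzyme | None
    reverse_enzyme: Enzyme | None
    status: str
    reason: str = ""

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        both = self.forward_enzyme is not None and self.reverse_enzyme is not None
        if (self.status == "assigned") != both:
            raise ValueError("status 'assigned' iff both enzymes are set")

    @property
    def strategy_label(self) -> str:
        if self.status != "assigned":
            return self.status
        return f"{self.forward_enzyme.name}/{self.reverse_enzyme.name}"


@dataclass
class TrimReport:
    """Outcome of signal-peptide/transmembrane trimming for one target.

    ``retained_interval`` is 1-based inclusive on the original CDS.
    ``eliminated``/``reason`` flag membrane-riddled or too-short proteins.
    """

    target_id: str
    removed_segments: list[AnnotatedSegment]
    retained_cds: str
    retained_interval: tuple[int, int]
    predicted_mass_kda: float
    mass_in_range: bool
    eliminated: bool = False
    reason: str = ""


@dataclass(frozen=True)
class TriageParams:
    """Tunables for the hydropathy stand-in and mass bounds.

    Defaults are standard literature values: Kyte-Doolittle window 19,
    mean-hydropathy threshold 1.6, signal-peptide zone = first 35 residues,
    a membrane protein is eliminated when transmembrane residues cover more
    than 30% of the protein or more than 2 segments are found.
    """

    window: int = 19
    threshold: float = 1.6
    sp_zone: int = 35
    min_tm_len: int = 19
    max_tm_coverage: float = 0.30
    max_tm_segments: int = 2
    mass_min_kda: float = MASS_MIN_KDA
    mass_max_kda: float = MASS_MAX_KDA
    use_annotations: bool = True


def scan_sites(cds: str, enzyme: Enzyme) -> list[int]:
    """All 0-based start positions of the enzyme's site, ascending, overlaps included.

    The four sites are palindromic, so scanning the given strand alone is
    complete (asserted).
    """
    assert enzyme.site == str(enzyme.site), "site must be a plain string"
    site = enzyme.site
    hits: list[int] = []
    start = cds.find(site)
    while start != -1:
        hits.append(start)
        start = cds.find(site, start + 1)
    return hits


def classify_strategy(target: TargetGene, *, cds: str | None = None) -> StrategyAssignment:
    """Pick the enzyme pair whose sites are absent from the CDS to be amplified.

    Preference order is BamHI > BglII and EcoRI > MfeI (vector-native sites
    first, minimising non-native junction scars).  If both enzymes of a
    family cut internally the target is eliminated.
    """
    seq = target.cds if cds is None else cds
    forward = next((e for e in (BAMHI, BGLII) if not scan_sites(seq, e)), None)
    reverse = next((e for e in (ECORI, MFEI) if not scan_sites(seq, e)), None)
    if forward is None or reverse is None:
        blocked = [
            fam
            for fam, enz in (("forward", (BAMHI, BGLII)), ("reverse", (ECORI, MFEI)))
            if all(scan_sites(seq, e) for e in enz)
        ]
        return StrategyAssignment(
            target.id,
            None,
            None,
            "eliminated_restriction",
            reason=f"internal sites block {' and '.join(blocked)} enzyme famil"
            + ("ies" if len(blocked) > 1 else "y"),
        )
    return StrategyAssignment(target.id, forward, reverse, "assigned")


def hydropathy_profile(protein: str, window: int) -> list[float | None]:
    """Centred moving average of Kyte-Doolittle values; window must be odd.

    Returns one entry per residue; positions whose window would overrun a
    terminus carry ``None``.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > len(protein):
        raise ValueError("window larger than protein")
    try:
        values = [KYTE_DOOLITTLE[aa] for aa in protein]
    except KeyError as exc:
        raise ValueError(f"unknown residue letter {exc.args[0]!r}") from None
    half = window // 2
    scores: list[float | None] = [None] * len(protein)
    running = sum(values[:window])
    for center in range(half, len(protein) - half):
        scores[center] = running / window
        if center + half + 1 < len(protein):
            running += values[center + half + 1] - values[center - half]
    return scores


def detect_membrane_segments(
    protein: str,
    window: int = 19,
    threshold: float = 1.6,
    sp_zone: int = 35,
    min_len: int = 19,
) -> list[AnnotatedSegment]:
    """Hydropathy-based stand-in for signal-peptide/transmembrane predictors.

    A residue is membrane-associated iff it lies within at least one
    ``window``-wide stretch whose mean Kyte-Doolittle hydropathy reaches
    ``threshold``.  Maximal runs of membrane-associated residues of length
    >= ``min_len`` are reported as transmembrane segments; a segment fully
    contained in the first ``sp_zone`` residues is reported as a signal
    peptide instead.  Detected boundaries can differ from a true hydrophobic
    stretch by at most (window-1)/2 on each side.
    """
    if len(protein) < window:
        return []
    scores = hydropathy_profile(protein, window)
    half = window // 2
    covered = [False] * len(protein)
    for center, score in enumerate(scores):
        if score is not None and score >= threshold:
            for j in range(center - half, center + half + 1):
                covered[j] = True

    segments: list[AnnotatedSegment] = []
    i = 0
    n = len(protein)
    while i < n:
        if covered[i]:
            j = i
            while j < n and covered[j]:
                j += 1
            if j - i >= min_len:
                kind = "signal_peptide" if j <= sp_zone else "transmembrane"
                segments.append(AnnotatedSegment(kind, i + 1, j))
            i = j
        else:
            i += 1
    return segments


def predicted_mass(protein: str) -> float:
    """Average molecular mass of the protein in kDa (residue masses + one water)."""
    if not protein:
        raise ValueError("empty protein")
    if "*" in protein:
        raise ValueError("stop character in protein")
    return molecular_weight(protein, seq_type="protein") / 1000.0


def trim_target(target: TargetGene, use_annotations: bool = True, params: TriageParams | None = None) -> TrimReport:
    """Remove an N-terminal signal peptide and judge transmembrane content.

    Segments come from the target's annotations when ``use_annotations`` is
    true (module-kind annotations are ignored here), otherwise from
    :func:`detect_membrane_segments`.  Proteins whose transmembrane residues
    cover more than ``max_tm_coverage`` of the sequence, or with more than
    ``max_tm_segments`` segments, are eliminated ("membrane zones
    throughout").  Otherwise the largest segment-free terminal span is
    retained.  Predicted mass is computed on the retained translation and
    checked against the inclusive [mass_min, mass_max] kDa window.
    """
    params = params or TriageParams()
    protein = target.protein
    plen = len(protein)

    if use_annotations:
        segments = [s for s in target.annotations if s.kind in ("signal_peptide", "transmembrane")]
    else:
        segments = detect_membrane_segments(
            protein, params.window, params.threshold, params.sp_zone, params.min_tm_len
        )
    segments = sorted(segments, key=lambda s: s.start)

    def report(retained_start_res: int, retained_end_res: int, removed, eliminated=False, reason=""):
        # residue interval (1-based inclusive) -> nt interval on the original CDS;
        # a native terminal stop codon travels with a fully retained C-terminus
        nt_start = (retained_start_res - 1) * 3 + 1
        nt_end = retained_end_res * 3
        if retained_end_res == plen and len(target.cds) == (plen + 1) * 3:
            nt_end = len(target.cds)
        retained = target.cds[nt_start - 1 : nt_end]
        prot = translate(retained) if retained else ""
        prot = prot[:-1] if prot.endswith("*") else prot
        mass = predicted_mass(prot) if prot else 0.0
        return TrimReport(
            target_id=target.id,
            removed_segments=list(removed),
            retained_cds=retained,
            retained_interval=(nt_start, nt_end),
            predicted_mass_kda=mass,
            mass_in_range=params.mass_min_kda <= mass <= params.mass_max_kda,
            eliminated=eliminated,
            reason=reason,
        )

    sp = [s for s in segments if s.kind == "signal_peptide"]
    tm = [s for s in segments if s.kind == "transmembrane"]

    tm_residues = sum(s.length for s in tm)
    if tm and (tm_residues / plen > params.max_tm_coverage or len(tm) > params.max_tm_segments):
        out = report(1, plen, segments, eliminated=True,
                     reason=f"transmembrane zones throughout: {len(tm)} segments, "
                            f"{tm_residues}/{plen} residues")
        return out

    start_res = 1
    removed: list[AnnotatedSegment] = []
    if sp:
        lead = max(s.end for s in sp)
        start_res = lead + 1
        removed.extend(sp)

    end_res = plen
    if tm:
        # keep the largest TM-free span anchored at a terminus
        first, last = tm[0], tm[-1]
        n_span = (start_res, first.start - 1)
        c_span = (last.end + 1, plen)
        n_len = n_span[1] - n_span[0] + 1
        c_len = c_span[1] - c_span[0] + 1
        removed.extend(tm)
        if n_len >= c_len:
            start_res, end_res = n_span
        else:
            start_res, end_res = c_span

    if end_res - start_res + 1 < MIN_RETAINED_AA:
        out = report(1, plen, segments, eliminated=True,
                     reason=f"retained span shorter than {MIN_RETAINED_AA} aa after trimming")
        return out
    return report(start_res, end_res, removed)


def split_modules(target: TargetGene, boundaries: list[AnnotatedSegment]) -> list[TargetGene]:
    """Full-length parent plus one child target per module (kind=module) interval.

    Children are named ``<parent>_m<k>`` and inherit organism and domain of
    life; their CDS is the codon range of the module.  Overlapping modules
    are an error.
    """
    plen = len(target.protein)
    modules = sorted((s for s in boundaries if s.kind == "module"), key=lambda s: s.start)
    prev_end = 0
    for seg in modules:
        if seg.start <= prev_end:
            raise ValueError(f"{target.id}: overlapping modules at residue {seg.start}")
        if seg.end > plen:
            raise ValueError(f"{target.id}: module {seg.start}-{seg.end} out of bounds")
        prev_end = seg.end
    children = [
        TargetGene(
            id=f"{target.id}_m{k}",
            cds=target.cds[(seg.start - 1) * 3 : seg.end * 3],
            organism=target.organism,
            domain_of_life=target.domain_of_life,
            source_note=f"module {seg.start}-{seg.end} of {target.id}",
        )
        for k, seg in enumerate(modules, start=1)
    ]
    return [target] + children


@dataclass
class TriageResult:
    """Joined triage verdict for one target."""

    target: TargetGene
    trim: TrimReport
    assignment: StrategyAssignment


def triage_target(target: TargetGene, params: TriageParams | None = None) -> TriageResult:
    """Full triage of one target: trim, classify on the trimmed CDS, mass check.

    Elimination precedence: restriction > membrane > mass.
    """
    params = params or TriageParams()
    trim = trim_target(target, use_annotations=params.use_annotations, params=params)
    assignment = classify_strategy(target, cds=trim.retained_cds)
    if assignment.status == "assigned":
        if trim.eliminated:
            assignment = StrategyAssignment(
                target.id, None, None, "eliminated_membrane", reason=trim.reason
            )
        elif not trim.mass_in_range:
            assignment = StrategyAssignment(
                target.id, None, None, "eliminated_mass",
                reason=f"predicted mass {trim.predicted_mass_kda:.1f} kDa outside "
                       f"[{params.mass_min_kda:g}, {params.mass_max_kda:g}]",
            )
    return TriageResult(target, trim, assignment)


def triage_targets(targets: list[TargetGene], params: TriageParams | None = None) -> list[TriageResult]:
    return [triage_target(t, params) for t in targets]


def triage_table(results: list[TriageResult]):
    """Triage report as a DataFrame (all coordinates 1-based inclusive)."""
    import pandas as pd

    rows = []
    for r in results:
        rows.append(
            {
                "id": r.target.id,
                "status": r.assignment.status,
                "forward_enzyme": r.assignment.forward_enzyme.name if r.assignment.forward_enzyme else "",
                "reverse_enzyme": r.assignment.reverse_enzyme.name if r.assignment.reverse_enzyme else "",
                "removed_segments": ";".join(
                    f"{s.kind}:{s.start}-{s.end}" for s in r.trim.removed_segments
                ),
                "retained_interval": f"{r.trim.retained_interval[0]}-{r.trim.retained_interval[1]}",
                "predicted_mass_kda": round(r.trim.predicted_mass_kda, 2),
                "reason": r.assignment.reason,
            }
        )
    return pd.DataFrame(rows)
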