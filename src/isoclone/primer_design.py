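"""Tailed PCR primer construction with Tm-matched hybridization regions.

The primer scheme is fixed by the cloning strategy:

* forward: ``5'-[hexa-G tail][BamHI or BglII site][hybridization site]-3'``
* reverse: ``5'-[hexa-C tail][EcoRI or MfeI site][stop anticodon][hybridization site]-3'``

Hybridization regions are chosen so every target anneals at the same
theoretical Tm (Wallace rule, 2(A+T) + 4(G+C)); the native terminal stop
codon is stripped so exactly one stop — the one introduced by the reverse
primer — terminates the insert ORF.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.SeqUtils import MeltingTemp

from .sequence_model import reverse_complement
from .triage import StrategyAssignment, TrimReport, scan_sites

__all__ = [
    "PrimerPair",
    "DesignParams",
    "wallace_tm",
    "select_hyb_region",
    "strip_stop",
    "design_primer_pair",
    "amplicon_sequence",
    "annealing_check",
    "primer_order_sheet",
]

G_TAIL = "GGGGGG"
C_TAIL = "CCCCCC"
STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class DesignParams:
    """Primer design parameters.

    ``tm_target``/``tm_tol`` bound the Wallace Tm of both hybridization
    regions; ``min_len``/``max_len`` bound their length in nt.  The stop
    anticodon (reverse complement of the stop codon the insert will carry)
    defaults to TTA, i.e. a TAA stop.
    """

    tm_target: float = 60.0
    tm_tol: float = 2.0
    min_len: int = 18
    max_len: int = 35
    stop_anticodon: str = "TTA"

    def __post_init__(self) -> None:
        if reverse_complement(self.stop_anticodon) not in STOP_CODONS:
            raise ValueError(
                f"stop anticodon {self.stop_anticodon!r} is not the reverse "
                "complement of a stop codon"
            )
        if not (0 < self.min_len <= self.max_len):
            raise ValueError("need 0 < min_len <= max_len")


@dataclass(frozen=True)
class PrimerPair:
    """Designed oligos for one target, written 5'->3' as ordered from a vendor."""

    target_id: str
    forward: str
    reverse: str
    fwd_hyb_len: int
    rev_hyb_len: int
    fwd_tm_c: float
    rev_tm_c: float


def wallace_tm(seq: str) -> float:
    """Wallace-rule melting temperature: 2(A+T) + 4(G+C) degrees Celsius."""
    if not seq:
        raise ValueError("empty sequence")
    return float(MeltingTemp.Tm_Wallace(seq))


def strip_stop(cds: str) -> str:
    """Drop a terminal in-frame stop codon, if present."""
    if len(cds) % 3 == 0 and cds[-3:] in STOP_CODONS:
        return cds[:-3]
    return cds


def select_hyb_region(
    cds: str,
    end: str,
    tm_target: float,
    tm_tol: float,
    min_len: int,
    max_len: int,
) -> str:
    """Choose the hybridization region at the 5' or 3' end of the coding strand.

    Returns the shortest length L in [min_len, max_len] whose Wallace Tm
    falls within tm_target +/- tm_tol; if none lands in the window, the L
    minimising |Tm - tm_target| (ties to the smaller L).  For ``end='3prime'``
    a native terminal stop codon is removed first.  The returned string is
    always on the coding strand.
    """
    if end not in ("5prime", "3prime"):
        raise ValueError("end must be '5prime' or '3prime'")
    if end == "3prime":
        cds = strip_stop(cds)
    if len(cds) < min_len:
        raise ValueError(f"CDS shorter than min_len={min_len}")
    max_len = min(max_len, len(cds))

    def region(length: int) -> str:
        return cds[:length] if end == "5prime" else cds[-length:]

    best_len, best_err = min_len, float("inf")
    for length in range(min_len, max_len + 1):
        err = abs(wallace_tm(region(length)) - tm_target)
        if err <= tm_tol:
            return region(length)
        if err < best_err:
            best_len, best_err = length, err
    return region(best_len)


def design_primer_pair(
    target_id: str,
    assignment: StrategyAssignment,
    trim: TrimReport,
    params: DesignParams | None = None,
) -> PrimerPair:
    """Assemble the tailed primer pair for an assigned target.

    Raises if the trimmed CDS is shorter than twice the minimum
    hybridization length, or if a hybridization region (or a tail/junction
    it creates on the amplicon) contains a site of a chosen enzyme — the
    latter advises strategy reassignment.
    """
    params = params or DesignParams()
    if assignment.status != "assigned":
        raise ValueError(f"{target_id}: cannot design primers for status {assignment.status}")
    body = strip_stop(trim.retained_cds)
    if len(body) < 2 * params.min_len:
        raise ValueError(
            f"{target_id}: trimmed CDS ({len(body)} nt) shorter than twice min_len"
        )

    fwd_hyb = select_hyb_region(body, "5prime", params.tm_target, params.tm_tol,
                                params.min_len, params.max_len)
    rev_template = select_hyb_region(body, "3prime", params.tm_target, params.tm_tol,
                                     params.min_len, params.max_len)
    rev_hyb = reverse_complement(rev_template)

    fwd_enz, rev_enz = assignment.forward_enzyme, assignment.reverse_enzyme
    for name, hyb in (("forward", fwd_hyb), ("reverse", rev_hyb)):
        for enz in (fwd_enz, rev_enz):
            if enz.site in hyb:
                raise ValueError(
                    f"{target_id}: {name} hybridization region contains {enz.name} "
                    "site; reassign the cloning strategy"
                )

    pair = PrimerPair(
        target_id=target_id,
        forward=G_TAIL + fwd_enz.site + fwd_hyb,
        reverse=C_TAIL + rev_enz.site + params.stop_anticodon + rev_hyb,
        fwd_hyb_len=len(fwd_hyb),
        rev_hyb_len=len(rev_hyb),
        fwd_tm_c=wallace_tm(fwd_hyb),
        rev_tm_c=wallace_tm(rev_hyb),
    )

    # the full amplicon must carry exactly one site per chosen enzyme
    amp = amplicon_sequence(pair, trim.retained_cds, params)
    for enz in (fwd_enz, rev_enz):
        hits = scan_sites(amp, enz)
        if len(hits) != 1:
            raise ValueError(
                f"{target_id}: amplicon carries {len(hits)} {enz.name} sites "
                "(expected exactly 1); reassign the cloning strategy"
            )
    return pair


def amplicon_sequence(pair: PrimerPair, retained_cds: str, params: DesignParams | None = None) -> str:
    """Top strand of the PCR product: forward primer + template interior + rc(reverse).

    Equals hexa-G tail + forward site + CDS (native stop stripped) +
    introduced stop + reverse site + hexa-G (the reverse tail's complement).
    """
    params = params or DesignParams()
    body = strip_stop(retained_cds)
    if not body.startswith(pair.forward[len(G_TAIL) + 6 :]):
        raise ValueError("forward hybridization region does not match template start")
    amp = pair.forward + body[pair.fwd_hyb_len :] + reverse_complement(pair.reverse)[pair.rev_hyb_len :]
    # sanity: rc(reverse) contributes [stop codon][site][G-tail] after the template
    assert amp == G_TAIL + pair.forward[len(G_TAIL) : len(G_TAIL) + 6] + body \
        + reverse_complement(params.stop_anticodon) \
        + pair.reverse[len(C_TAIL) : len(C_TAIL) + 6] + G_TAIL
    return amp


def annealing_check(pair: PrimerPair, cds: str) -> bool:
    """True iff each hybridization region matches the template exactly once.

    The forward region is counted on the sense strand; the reverse region's
    complement (the 3'-terminal coding-strand stretch) likewise.
    """
    fwd_hyb = pair.forward[len(G_TAIL) + 6 :]
    rev_site_region = reverse_complement(pair.reverse[-pair.rev_hyb_len :])
    return cds.count(fwd_hyb) == 1 and cds.count(rev_site_region) == 1


def primer_order_sheet(pairs: list[PrimerPair], plate_size: int = 96):
    """Vendor-style order sheet: one row per oligo, arrayed into 96-well plates."""
    import pandas as pd

    from .plate_layout import well_labels

    rows = []
    labels = well_labels(96)
    n = 0
    for pair in pairs:
        for suffix, seq, tm in (("F", pair.forward, pair.fwd_tm_c),
                                ("R", pair.reverse, pair.rev_tm_c)):
            plate, idx = divmod(n, plate_size)
            rows.append(
                {
                    "plate": f"oligo_plate_{plate + 1}",
                    "well": labels[idx],
                    "primer_name": f"{pair.target_id}_{suffix}",
                    "sequence": seq,
                    "length": len(seq),
                    "hyb_tm": tm,
                }
            )
            n += 1
    return pd.DataFrame(rows)
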