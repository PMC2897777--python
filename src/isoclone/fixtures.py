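"""Deterministic synthetic target and screen generators.

These emulate the raw material of a multi-organism expression campaign:
coding sequences with controlled GC content, optionally implanted
restriction sites (in frame, so the ORF is preserved), hydrophobic
signal-peptide/transmembrane stretches, and per-domain per-vector
screening outcomes drawn from categorical distributions.  Every generator
is driven by a single integer seed through its own ``numpy`` Generator; no
global random state is touched.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .sequence_model import (
    ENZYMES,
    AnnotatedSegment,
    Enzyme,
    TargetGene,
)
from .screening_report import ScreeningRecord, VECTOR_NAMES
from .triage import scan_sites

__all__ = [
    "FixtureSpec",
    "random_cds",
    "implant_site",
    "synth_screen",
    "TABLE2_COUNTS",
    "TABLE2_DOMAIN_SIZES",
    "scenario_table2",
    "scenario_strategy_mix",
    "scenario_triage_stress",
    "SCENARIOS",
]

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_ALL_CODONS = ["".join(c) for c in itertools.product(_BASES, repeat=3)]
_SENSE_CODONS = [c for c in _ALL_CODONS if c not in _STOPS]
#: alternating Leu codons used for hydrophobic stretches; GC-balanced and
#: incapable of forming any of the four recognition sites
_HYDROPHOBIC_CYCLE = ("CTG", "TTA")
#: how each site reads in frame when implanted at a codon boundary
SITE_DIPEPTIDE = {"BamHI": "GS", "BglII": "RS", "EcoRI": "EF", "MfeI": "QL"}


@dataclass
class FixtureSpec:
    """Recipe for one synthetic coding sequence.

    ``implant_sites`` maps enzyme name to 1-based codon positions (codon 1
    is the ATG); a site occupies two codons.  ``tm_segments`` are 1-based
    inclusive residue intervals rendered as hydrophobic runs; a
    ``signal_peptide`` renders residues 2-22 hydrophobic and annotates
    residues 1-22.
    """

    seed: int
    n_codons: int = 200
    gc_fraction: float = 0.5
    implant_sites: dict[str, list[int]] = field(default_factory=dict)
    signal_peptide: bool = False
    tm_segments: list[tuple[int, int]] = field(default_factory=list)
    domain_of_life: str = "bacteria"
    id: str = ""

    def __post_init__(self) -> None:
        if self.n_codons < 40:
            raise ValueError("n_codons must be >= 40")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must be in [0, 1]")
        taken: set[int] = set()
        for name, positions in self.implant_sites.items():
            if name not in ENZYMES:
                raise ValueError(f"unknown enzyme {name!r}")
            for pos in positions:
                if not (2 <= pos <= self.n_codons - 2):
                    raise ValueError(f"implant position {pos} out of bounds")
                if {pos, pos + 1} & taken:
                    raise ValueError(f"overlapping implants at codon {pos}")
                taken.update((pos, pos + 1))


def _gc_count(codon: str) -> int:
    return sum(c in "GC" for c in codon)


def _codon_weights(gc_fraction: float) -> np.ndarray:
    p_gc = max(gc_fraction, 1e-6) / 2.0
    p_at = max(1.0 - gc_fraction, 1e-6) / 2.0
    w = np.array(
        [np.prod([p_gc if b in "GC" else p_at for b in codon]) for codon in _SENSE_CODONS]
    )
    return w / w.sum()


def _reserved_codons(spec: FixtureSpec) -> set[int]:
    """0-based indices of codons that must not be resampled."""
    reserved = {0, spec.n_codons - 1}
    for positions in spec.implant_sites.values():
        for pos in positions:
            reserved.update((pos - 1, pos))
    if spec.signal_peptide:
        reserved.update(range(0, 22))
    for start, end in spec.tm_segments:
        reserved.update(range(start - 1, end))
    return reserved


def _scrub_sites(codons: list[str], spec: FixtureSpec, rng: np.random.Generator,
                 weights: np.ndarray) -> None:
    """Resample free codons until only the requested sites remain."""
    allowed = {
        (pos - 1) * 3: ENZYMES[name].site
        for name, positions in spec.implant_sites.items()
        for pos in positions
    }
    reserved = _reserved_codons(spec)
    for _ in range(200):
        seq = "".join(codons)
        offender = None
        for enz in ENZYMES.values():
            for hit in scan_sites(seq, enz):
                if allowed.get(hit) != enz.site:
                    offender = hit
                    break
            if offender is not None:
                break
        if offender is None:
            return
        span = [i for i in range(offender // 3, (offender + 5) // 3 + 1)
                if 0 <= i < len(codons) and i not in reserved]
        if not span:
            raise ValueError("cannot remove unintended site overlapping reserved codons")
        idx = int(rng.choice(span))
        codons[idx] = str(rng.choice(_SENSE_CODONS, p=weights))
    raise ValueError("site scrubbing did not converge")


def _adjust_gc(codons: list[str], spec: FixtureSpec, rng: np.random.Generator) -> None:
    reserved = _reserved_codons(spec)
    free = [i for i in range(len(codons)) if i not in reserved]
    hi = [c for c in _SENSE_CODONS if _gc_count(c) == 3]
    lo = [c for c in _SENSE_CODONS if _gc_count(c) == 0]
    for _ in range(3 * len(codons)):
        seq = "".join(codons)
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        if abs(gc - spec.gc_fraction) <= 0.03 or not free:
            return
        idx = int(rng.choice(free))
        codons[idx] = str(rng.choice(hi if gc < spec.gc_fraction else lo))


def random_cds(spec: FixtureSpec) -> TargetGene:
    """Generate one reproducible synthetic CDS satisfying the spec.

    Starts ATG, ends TAA, no internal in-frame stop, GC within 5% of the
    requested fraction, and none of the four recognition sites present
    except the implanted ones (at their exact codon positions).
    """
    if spec.gc_fraction > 0.95 and spec.implant_sites:
        raise ValueError("cannot implant A/T-containing sites at gc_fraction ~ 1")
    rng = np.random.default_rng(spec.seed)
    weights = _codon_weights(spec.gc_fraction)
    codons = ["ATG"] + [str(c) for c in rng.choice(_SENSE_CODONS, size=spec.n_codons - 2,
                                                   p=weights)] + ["TAA"]

    annotations: list[AnnotatedSegment] = []
    hydro = itertools.cycle(_HYDROPHOBIC_CYCLE)
    if spec.signal_peptide:
        for i in range(1, 22):
            codons[i] = next(hydro)
        annotations.append(AnnotatedSegment("signal_peptide", 1, 22))
    for start, end in spec.tm_segments:
        for i in range(start - 1, end):
            codons[i] = next(hydro)
        annotations.append(AnnotatedSegment("transmembrane", start, end))

    for name, positions in spec.implant_sites.items():
        site = ENZYMES[name].site
        for pos in positions:
            codons[pos - 1] = site[:3]
            codons[pos] = site[3:]

    _adjust_gc(codons, spec, rng)
    _scrub_sites(codons, spec, rng, weights)

    cds = "".join(codons)
    gc = (cds.count("G") + cds.count("C")) / len(cds)
    if abs(gc - spec.gc_fraction) > 0.05:
        raise ValueError(
            f"infeasible spec: GC {gc:.3f} not within 0.05 of {spec.gc_fraction}"
        )
    return TargetGene(
        id=spec.id or f"synth_{spec.seed}",
        cds=cds,
        organism="synthetic",
        domain_of_life=spec.domain_of_life,
        annotations=annotations,
        source_note="synthetic fixture",
    )


def implant_site(cds: str, enzyme: Enzyme, codon_pos: int) -> str:
    """Replace two codons with the enzyme's site read in frame.

    ``codon_pos`` is 1-based; the site occupies codons (codon_pos,
    codon_pos+1) so the ORF is preserved (GGATCC=Gly-Ser, AGATCT=Arg-Ser,
    GAATTC=Glu-Phe, CAATTG=Gln-Leu).  If the replacement would create an
    unintended second site of any of the four enzymes, the window is
    shifted by up to two codons; if no shift works, an error is raised.
    """
    n_codons = len(cds) // 3
    if not 2 <= codon_pos <= n_codons - 2:
        raise ValueError(f"codon_pos {codon_pos} out of bounds (2..{n_codons - 2})")
    baseline = {name: set(scan_sites(cds, e)) for name, e in ENZYMES.items()}
    for shift in (0, 1, -1, 2, -2):
        pos = codon_pos + shift
        if not 2 <= pos <= n_codons - 2:
            continue
        start = (pos - 1) * 3
        candidate = cds[:start] + enzyme.site + cds[start + 6 :]
        ok = True
        for name, e in ENZYMES.items():
            expected = baseline[name] - set(range(start - 5, start + 6))
            if name == enzyme.name:
                expected = expected | {start}
            if set(scan_sites(candidate, e)) != expected:
                ok = False
                break
        if ok:
            return candidate
    raise ValueError(f"implanting {enzyme.name} near codon {codon_pos} creates a spurious site")


def synth_screen(
    target_ids: list[str],
    domain_map: dict[str, str],
    probabilities: dict[tuple[str, str], dict[str, float]],
    seed: int,
) -> list[ScreeningRecord]:
    """Independent categorical draws of per-target per-vector outcomes.

    ``probabilities[(domain, vector)]`` maps status to probability; the
    statuses' probabilities must sum to <= 1 and the remainder goes to
    no_clone.  Fully reproducible from the seed.
    """
    rng = np.random.default_rng(seed)
    records: list[ScreeningRecord] = []
    statuses = ("soluble", "insoluble", "no_expression", "no_clone", "not_screened")
    for tid in target_ids:
        domain = domain_map[tid]
        for vector in VECTOR_NAMES:
            cell = probabilities[(domain, vector)]
            p = [float(cell.get(s, 0.0)) for s in statuses]
            spare = 1.0 - sum(p)
            if spare < -1e-9:
                raise ValueError(f"probabilities for {(domain, vector)} sum to > 1")
            p[3] += max(spare, 0.0)  # remainder -> no_clone
            records.append(
                ScreeningRecord(tid, vector, statuses[int(rng.choice(5, p=np.array(p) / sum(p)))])
            )
    return records


# Published per-domain per-vector outcome counts used to parameterize the
# "table2-like" scenario (the empirical frequencies of a 192-target,
# three-domain, two-vector campaign).
TABLE2_COUNTS: dict[tuple[str, str], dict[str, int]] = {
    ("eukarya", "pFO4"): {"soluble": 14, "insoluble": 10, "no_expression": 42, "no_clone": 8},
    ("eukarya", "pGEX-4T-1"): {"soluble": 13, "insoluble": 19, "no_expression": 37, "no_clone": 5},
    ("bacteria", "pFO4"): {"soluble": 13, "insoluble": 4, "no_expression": 11, "no_clone": 4},
    ("bacteria", "pGEX-4T-1"): {"soluble": 25, "insoluble": 5, "no_expression": 2, "no_clone": 0},
    ("archaea", "pFO4"): {"soluble": 18, "insoluble": 12, "no_expression": 31, "no_clone": 9},
    ("archaea", "pGEX-4T-1"): {"soluble": 26, "insoluble": 24, "no_expression": 11, "no_clone": 12},
}
#: domain strata summing to the 192-target campaign size; the published
#: per-domain columns are mutually inconsistent for archaea, so the archaea
#: probability mass not covered by the counts is drawn as extra no_clone.
TABLE2_DOMAIN_SIZES = {"eukarya": 74, "bacteria": 32, "archaea": 86}


def table2_probabilities() -> dict[tuple[str, str], dict[str, float]]:
    return {
        (domain, vector): {s: c / TABLE2_DOMAIN_SIZES[domain] for s, c in cell.items()}
        for (domain, vector), cell in TABLE2_COUNTS.items()
    }


_STRATEGY_IMPLANTS: list[tuple[str, dict[str, list[int]]]] = [
    ("BamHI/EcoRI", {}),
    ("BglII/EcoRI", {"BamHI": [30]}),
    ("BamHI/MfeI", {"EcoRI": [50]}),
    ("BglII/MfeI", {"BamHI": [30], "EcoRI": [50]}),
]


def scenario_strategy_mix(seed: int, n: int = 200) -> tuple[list[TargetGene], dict[str, str]]:
    """Targets cycling through the four cloning strategies, with periodic
    signal peptides to exercise trimming.

    Returns (targets, expected strategy label per id).
    """
    rng = np.random.default_rng(seed)
    targets, expected = [], {}
    domains = itertools.cycle(("eukarya", "bacteria", "archaea"))
    for k in range(n):
        label, implants = _STRATEGY_IMPLANTS[k % 4]
        spec = FixtureSpec(
            seed=int(rng.integers(0, 2**31 - 1)),
            n_codons=int(rng.integers(140, 360)),
            gc_fraction=0.5,
            implant_sites=implants,
            signal_peptide=(k % 5 == 0),
            domain_of_life=next(domains),
            id=f"mix_{k:03d}",
        )
        targets.append(random_cds(spec))
        expected[spec.id] = label
    return targets, expected


def scenario_triage_stress(seed: int, n: int = 200) -> tuple[list[TargetGene], dict[str, str]]:
    """Targets with constructed triage outcomes for parameter-recovery tests.

    Returns (targets, expected label per id), labels being the strategy
    string for assigned targets or the elimination status.
    """
    rng = np.random.default_rng(seed)
    cases = [
        ("BamHI/EcoRI", {}, False, [], 200),
        ("BglII/EcoRI", {"BamHI": [30]}, False, [], 200),
        ("BamHI/MfeI", {"EcoRI": [50]}, False, [], 200),
        ("BglII/MfeI", {"BamHI": [30], "EcoRI": [50]}, False, [], 200),
        ("eliminated_restriction", {"BamHI": [30], "BglII": [40]}, False, [], 200),
        ("BamHI/EcoRI", {}, True, [], 200),  # signal peptide, trimmed then assigned
        ("eliminated_membrane", {}, False, [(40, 64), (80, 104), (120, 144), (160, 184)], 200),
        ("eliminated_mass", {}, False, [], 40),  # ~4 kDa, below the 7 kDa floor
    ]
    targets, expected = [], {}
    domains = itertools.cycle(("eukarya", "bacteria", "archaea"))
    for k in range(n):
        label, implants, sp, tm, n_codons = cases[k % len(cases)]
        spec = FixtureSpec(
            seed=int(rng.integers(0, 2**31 - 1)),
            n_codons=n_codons,
            implant_sites=implants,
            signal_peptide=sp,
            tm_segments=tm,
            domain_of_life=next(domains),
            id=f"stress_{k:03d}",
        )
        targets.append(random_cds(spec))
        expected[spec.id] = label
    return targets, expected


def scenario_table2(seed: int) -> tuple[list[TargetGene], list[ScreeningRecord]]:
    """A 192-target, three-domain campaign with outcome frequencies taken
    from the published screen."""
    rng = np.random.default_rng(seed)
    targets = []
    k = 0
    for domain, size in TABLE2_DOMAIN_SIZES.items():
        for _ in range(size):
            spec = FixtureSpec(
                seed=int(rng.integers(0, 2**31 - 1)),
                n_codons=int(rng.integers(100, 300)),
                domain_of_life=domain,
                id=f"t2_{k:03d}",
            )
            targets.append(random_cds(spec))
            k += 1
    records = synth_screen(
        [t.id for t in targets],
        {t.id: t.domain_of_life for t in targets},
        table2_probabilities(),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return targets, records


SCENARIOS = {
    "table2-like": scenario_table2,
    "triage-stress": scenario_triage_stress,
    "scar-suite": scenario_strategy_mix,
}
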