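"""Candidate-selection funnel for CE4 deacetylases.

Active carbohydrate esterase family 4 (CE4) deacetylases carry five conserved
catalytic motifs, in order along the catalytic domain:

    MT1  T[FY]DD     metal-coordinating / catalytic-base aspartates
    MT2  H[ST]xxH    metal-coordinating histidines
    MT3  RxPY        oxyanion-stabilizing backbone
    MT4  DxxD[WY]    one wall of the substrate groove
    MT5  LxH         catalytic-acid histidine

A secreted, single-domain candidate is selected by a filter cascade: family
tag, all five motifs present (ordered by default), gene completeness, signal
peptide, single domain.  Annotation inputs (family, completeness flag, domain
count, external signal-peptide call) always override the built-in sequence
heuristics.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Kyte-Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2, "X": 0.0,
}

SMALL_CLEAVAGE_RESIDUES = frozenset("AGSCT")


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    sequence: str
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        allowed = set(AA20) | {"X", "*"}
        bad = set(self.sequence.upper()) - allowed
        if bad:
            raise ValueError(f"{self.id}: invalid residues {sorted(bad)}")


class MotifSyntaxError(ValueError):
    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at offset {offset})")
        self.offset = offset


@dataclass(frozen=True)
class MotifDefinition:
    """Restricted motif syntax: literal residue, [XY] alternative set, x wildcard."""

    motif_id: str
    pattern: str


DEFAULT_MOTIFS = (
    MotifDefinition("MT1", "T[FY]DD"),
    MotifDefinition("MT2", "H[ST]xxH"),
    MotifDefinition("MT3", "RxPY"),
    MotifDefinition("MT4", "DxxD[WY]"),
    MotifDefinition("MT5", "LxH"),
)


def compile_motif(definition: MotifDefinition) -> re.Pattern:
    """Compile the restricted motif syntax to a regex over the 20-letter alphabet.

    The effective motif length (residue positions) must be 3-6.
    """
    pat = definition.pattern
    out: list[str] = []
    n_positions = 0
    i = 0
    while i < len(pat):
        c = pat[i]
        if c == "x":
            out.append(f"[{AA20}]")
            n_positions += 1
            i += 1
        elif c == "[":
            j = pat.find("]", i)
            if j < 0:
                raise MotifSyntaxError("unclosed '['", i)
            inner = pat[i + 1:j]
            if not inner or any(r not in AA20 for r in inner):
                raise MotifSyntaxError(f"bad alternative set [{inner}]", i)
            out.append(f"[{inner}]")
            n_positions += 1
            i = j + 1
        elif c in AA20:
            out.append(c)
            n_positions += 1
            i += 1
        else:
            raise MotifSyntaxError(f"unexpected character {c!r}", i)
    if not 3 <= n_positions <= 6:
        raise MotifSyntaxError(
            f"motif must span 3-6 residues, got {n_positions}", 0
        )
    return re.compile("".join(out))


def find_motif(matcher: re.Pattern, sequence: str) -> list[tuple[int, int]]:
    """All (possibly overlapping) occurrences as 0-based [start, end) spans."""
    hits = []
    start = 0
    while True:
        m = matcher.search(sequence, start)
        if m is None:
            return hits
        hits.append((m.start(), m.end()))
        start = m.start() + 1


@dataclass
class MotifScanResult:
    hits: dict  # motif_id -> list of (start, end)
    all_present: bool
    ordered_chain: list | None  # chosen non-overlapping spans, MT1..MT5


def scan_motifs(
    protein: ProteinRecord,
    motifs: tuple[MotifDefinition, ...] = DEFAULT_MOTIFS,
    require_order: bool = True,
) -> MotifScanResult:
    """Scan for all motifs; ``all_present`` additionally requires (by default)
    one non-overlapping occurrence of each motif in MT1->MT5 order.

    The ordered chain is found greedily, always taking the occurrence with the
    smallest end position that starts at or after the previous motif's end;
    this is optimal for chaining interval sequences.
    """
    seq = protein.sequence.upper().rstrip("*")
    hits = {m.motif_id: find_motif(compile_motif(m), seq) for m in motifs}
    every = all(hits[m.motif_id] for m in motifs)
    chain: list | None = None
    if every and require_order:
        chain = []
        cursor = 0
        for m in motifs:
            nxt = min(
                ((s, e) for s, e in hits[m.motif_id] if s >= cursor),
                key=lambda se: se[1],
                default=None,
            )
            if nxt is None:
                chain = None
                break
            chain.append((m.motif_id, nxt[0], nxt[1]))
            cursor = nxt[1]
        all_present = chain is not None
    else:
        all_present = every
        if every:
            chain = [
                (m.motif_id, *hits[m.motif_id][0]) for m in motifs
            ]
    return MotifScanResult(hits=hits, all_present=all_present, ordered_chain=chain)


@dataclass(frozen=True)
class SignalPeptideCall:
    present: bool
    cleavage_pos: int | None = None  # 1-based last residue of the signal
    reason: str = ""


@dataclass(frozen=True)
class ScreenConfig:
    require_order: bool = True
    min_sp_length: int = 25
    h_window: int = 8
    h_window_span: tuple[int, int] = (6, 25)   # 1-based inclusive
    h_threshold: float = 1.5
    n_region_span: tuple[int, int] = (2, 6)    # 1-based inclusive
    cleavage_span: tuple[int, int] = (16, 35)  # 1-based inclusive
    single_domain_max_length: int = 400


def predict_signal_peptide(
    protein: ProteinRecord,
    config: ScreenConfig = ScreenConfig(),
) -> SignalPeptideCall:
    """Secretion-signal heuristic: charged n-region, hydrophobic h-region,
    small-residue cleavage site.

    An external predictor call stored in annotations (``sp_start``/``sp_end``,
    or ``sp_end`` alone) always overrides the heuristic.  The heuristic
    requires all of: at least one K/R within residues 2-6; an 8-residue window
    inside positions 6-25 with mean Kyte-Doolittle hydropathy >= 1.5; and a
    cleavage position c in 16-35 whose -1 (residue c) and -3 (residue c-2)
    residues are both small (A/G/S/C/T).  The first qualifying c is reported;
    cleavage is after residue c.
    """
    ann = protein.annotations or {}
    if "sp_end" in ann and ann["sp_end"] is not None:
        end = int(ann["sp_end"])
        if end > 0:
            return SignalPeptideCall(True, end, "external call")
        return SignalPeptideCall(False, None, "external call")
    seq = protein.sequence.upper().rstrip("*")
    if len(seq) < config.min_sp_length:
        return SignalPeptideCall(False, None, "too short")

    n_lo, n_hi = config.n_region_span
    if not any(r in "KR" for r in seq[n_lo - 1:n_hi]):
        return SignalPeptideCall(False, None, "no positively charged n-region")

    h_lo, h_hi = config.h_window_span
    w = config.h_window
    hydrophobic = False
    for start in range(h_lo - 1, h_hi - w + 1):
        window = seq[start:start + w]
        mean_kd = sum(KYTE_DOOLITTLE.get(r, 0.0) for r in window) / w
        if mean_kd >= config.h_threshold:
            hydrophobic = True
            break
    if not hydrophobic:
        return SignalPeptideCall(False, None, "no hydrophobic h-region")

    c_lo, c_hi = config.cleavage_span
    for c in range(c_lo, min(c_hi, len(seq)) + 1):
        if seq[c - 1] in SMALL_CLEAVAGE_RESIDUES and seq[c - 3] in SMALL_CLEAVAGE_RESIDUES:
            return SignalPeptideCall(True, c, "heuristic")
    return SignalPeptideCall(False, None, "no small-residue cleavage site")


# ---------------------------------------------------------------------------
# Filter cascade


def _is_ce4(protein: ProteinRecord) -> bool:
    fam = (protein.annotations or {}).get("family")
    return True if fam is None else str(fam).upper() == "CE4"


def _is_complete(protein: ProteinRecord) -> bool:
    flag = (protein.annotations or {}).get("complete_gene")
    if flag is not None:
        return bool(int(flag)) if not isinstance(flag, bool) else flag
    seq = protein.sequence.upper()
    body = seq[:-1] if seq.endswith("*") else seq
    return body.startswith("M") and "*" not in body


def _single_domain(protein: ProteinRecord, config: ScreenConfig) -> bool:
    count = (protein.annotations or {}).get("domain_count")
    if count is not None:
        return int(count) == 1
    seq = protein.sequence.upper().rstrip("*")
    sp = predict_signal_peptide(protein, config)
    mature = len(seq) - (sp.cleavage_pos or 0)
    return mature <= config.single_domain_max_length


FILTER_NAMES = ("family_ce4", "all_motifs", "complete_gene",
                "signal_peptide", "single_domain")


@dataclass
class ScreenReport:
    funnel: list  # ordered (stage name, surviving count), first entry = input
    verdicts: dict  # id -> {filter: bool}, plus motif hits and sp call
    survivors: list  # ids passing every filter


def run_cascade(
    collection: list[ProteinRecord],
    config: ScreenConfig = ScreenConfig(),
    motifs: tuple[MotifDefinition, ...] = DEFAULT_MOTIFS,
) -> ScreenReport:
    """Apply the five-filter funnel and report per-stage survivor counts.

    Every predicate is evaluated per protein, so the final surviving set is
    the intersection of the per-filter passing sets and is independent of
    filter order; the funnel counts reflect the canonical order above.
    """
    verdicts: dict = {}
    for rec in collection:
        scan = scan_motifs(rec, motifs, config.require_order)
        sp = predict_signal_peptide(rec, config)
        verdicts[rec.id] = {
            "family_ce4": _is_ce4(rec),
            "all_motifs": scan.all_present,
            "complete_gene": _is_complete(rec),
            "signal_peptide": sp.present,
            "single_domain": _single_domain(rec, config),
            "motif_hits": scan.hits,
            "sp_call": sp,
        }
    funnel = [("input", len(collection))]
    alive = [rec.id for rec in collection]
    for name in FILTER_NAMES:
        alive = [pid for pid in alive if verdicts[pid][name]]
        funnel.append((name, len(alive)))
    return ScreenReport(funnel=funnel, verdicts=verdicts, survivors=alive)
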