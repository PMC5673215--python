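"""Fragment-ladder enumeration, spectrum matching and positional inference.

MS2 spectra of AMAC-labeled CHOS are dominated by glycosidic-bond cleavages.
Y-type fragments retain the reducing end and therefore the AMAC label; their
masses follow the rule "CHOS plus AMAC and hydrogen".  B-type fragments are
unlabeled non-reducing-end oxocarbenium ions.  Because A and D residues differ
by exactly one acetyl group (42.011 Da), the sequence of consecutive Y-ladder
mass differences spells out the acetylation pattern from the reducing end.

Ranking positional isomers of one composition against an observed spectrum
formalizes the manual reading of such ladders: each candidate pattern is
scored by the fraction of total spectral intensity its theoretical ladder
explains, and per-position deacetylation frequencies are obtained by soft
(weight ~ score^gamma) averaging over candidates.  Mixtures of isomers are
therefore reported as fractional positional support with an ambiguity flag
rather than as a single forced call.
"""

from __future__ import annotations

import bisect
import enum
from dataclasses import dataclass, field

import numpy as np

from .chos import (
    ChosPattern,
    Composition,
    Label,
    MassTable,
    MONOISOTOPIC,
    composition_mz,
    enumerate_patterns,
)


class IonType(str, enum.Enum):
    Y = "Y"  # reducing-end fragment, AMAC-bearing
    B = "B"  # non-reducing-end oxocarbenium


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float = 1.0

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("peak m/z must be positive")
        if self.intensity < 0:
            raise ValueError("peak intensity must be non-negative")


@dataclass
class Spectrum:
    """A peak list; MS2 spectra carry the precursor m/z they were isolated at."""

    peaks: list[Peak]
    ms_level: int = 2
    precursor_mz: float | None = None

    def __post_init__(self) -> None:
        if self.ms_level == 2 and self.precursor_mz is None:
            raise ValueError("MS2 spectrum requires precursor_mz")
        self.peaks = sorted(self.peaks, key=lambda p: p.mz)

    @property
    def total_intensity(self) -> float:
        return float(sum(p.intensity for p in self.peaks))


@dataclass(frozen=True)
class FragmentIon:
    ion_type: IonType
    length: int
    sub_pattern: str
    mz: float


class LabelError(ValueError):
    """Y-type ladder requested for an unlabeled pattern."""


class ConsistencyError(ValueError):
    """Precursor m/z is not explained by the stated composition."""


def fragment_ladder(
    pattern: ChosPattern,
    ion_types: frozenset[IonType] | set[IonType] = frozenset({IonType.Y, IonType.B}),
    table: MassTable = MONOISOTOPIC,
) -> list[FragmentIon]:
    """Theoretical singly protonated Y and B ions of one pattern.

    Y_k covers the k reducing-end residues (label retained), k = 1..DP.
    B_k covers the k non-reducing-end residues, k = 1..DP-1 (B_DP would not
    correspond to a glycosidic cleavage).
    """
    ions: list[FragmentIon] = []
    res = pattern.residues
    if IonType.Y in ion_types:
        if pattern.label is not Label.AMAC:
            raise LabelError("Y ions require an AMAC-labeled reducing end")
        for k in range(1, pattern.dp + 1):
            sub = res[pattern.dp - k:]
            mass = sum(table.residue(r) for r in sub) + table.amac + table.h2
            ions.append(FragmentIon(IonType.Y, k, sub, mass + table.proton))
    if IonType.B in ion_types:
        for k in range(1, pattern.dp):
            sub = res[:k]
            mass = sum(table.residue(r) for r in sub)
            ions.append(FragmentIon(IonType.B, k, sub, mass + table.proton))
    return ions


def match_peaks(
    spectrum: Spectrum,
    ions: list[FragmentIon],
    tol: float = 0.5,
) -> list[tuple[FragmentIon, Peak]]:
    """Pair each ion with the nearest peak within ``tol`` (Da on the m/z axis).

    One peak may support several isobaric ions; ions with no peak within
    tolerance are omitted.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    mzs = [p.mz for p in spectrum.peaks]
    out: list[tuple[FragmentIon, Peak]] = []
    for ion in ions:
        i = bisect.bisect_left(mzs, ion.mz)
        best: Peak | None = None
        best_err = tol
        for j in (i - 1, i):
            if 0 <= j < len(mzs):
                err = abs(mzs[j] - ion.mz)
                if err <= best_err:
                    best, best_err = spectrum.peaks[j], err
        if best is not None:
            out.append((ion, best))
    return out


@dataclass
class PatternScore:
    pattern: ChosPattern
    matched_ions: list[tuple[FragmentIon, Peak]]
    explained_fraction: float
    score: float


@dataclass
class PositionalSupport:
    """Per-position deacetylation frequency, non-reducing -> reducing."""

    frequencies: list[float]
    ambiguity_flag: bool

    @property
    def dp(self) -> int:
        return len(self.frequencies)


@dataclass(frozen=True)
class RankParams:
    tol: float = 0.5            # fragment match tolerance, unit-resolution trap
    b_weight: float = 0.25      # B ions corroborate, Y ions carry the call
    gamma: float = 4.0          # sharpening of score -> weight in mixtures
    ambiguity_eps: float = 0.05  # top-2 score gap below which isomers tie
    precursor_tol: float = 1.0


def rank_patterns(
    spectrum: Spectrum,
    composition: Composition,
    table: MassTable = MONOISOTOPIC,
    params: RankParams = RankParams(),
    label: Label = Label.AMAC,
) -> list[PatternScore]:
    """Score every positional isomer of ``composition`` against an MS2 spectrum.

    explained_fraction is the share of total spectral intensity carried by
    peaks matched by any ladder ion of the candidate.  The ranking score
    down-weights peaks matched only by B ions (b_weight), since Y ions carry
    the label and are the diagnostic series.  Ties break lexicographically on
    the pattern string; ordering is descending by score.
    """
    if spectrum.precursor_mz is not None:
        theo = composition_mz(composition, label, table)
        if abs(theo - spectrum.precursor_mz) > params.precursor_tol:
            raise ConsistencyError(
                f"precursor {spectrum.precursor_mz:.2f} vs theoretical "
                f"{theo:.2f} for {composition.label_str()}"
            )
    total = spectrum.total_intensity
    results: list[PatternScore] = []
    for pattern in enumerate_patterns(composition, label):
        ions = fragment_ladder(pattern, {IonType.Y, IonType.B}, table)
        matched = match_peaks(spectrum, ions, params.tol)
        y_peaks = {m[1] for m in matched if m[0].ion_type is IonType.Y}
        b_only = {m[1] for m in matched if m[0].ion_type is IonType.B} - y_peaks
        if total > 0:
            explained = sum(p.intensity for p in y_peaks | b_only) / total
            score = (
                sum(p.intensity for p in y_peaks)
                + params.b_weight * sum(p.intensity for p in b_only)
            ) / total
        else:
            explained = 0.0
            score = 0.0
        results.append(PatternScore(pattern, matched, explained, score))
    results.sort(key=lambda r: (-r.score, r.pattern.residues))
    return results


def positional_support(
    scores: list[PatternScore],
    params: RankParams = RankParams(),
) -> PositionalSupport:
    """Soft per-position deacetylation frequencies from ranked isomer scores.

    Weights are proportional to score^gamma and normalized, so the
    frequencies sum to nD of the composition.  The ambiguity flag is raised
    when the top two scores differ by less than ambiguity_eps (or when no
    candidate scored at all, in which case the frequency profile is the
    uniform average over isomers).
    """
    if not scores:
        raise ValueError("empty score list")
    dp = scores[0].pattern.dp
    raw = np.array([s.score for s in scores], dtype=float)
    if raw.max() <= 0:
        weights = np.full(len(scores), 1.0 / len(scores))
        ambiguous = True
    else:
        w = raw ** params.gamma
        weights = w / w.sum()
        top = np.sort(raw)[::-1]
        ambiguous = bool(len(raw) > 1 and (top[0] - top[1]) < params.ambiguity_eps)
    freqs = np.zeros(dp)
    for weight, s in zip(weights, scores):
        for i, r in enumerate(s.pattern.residues):
            if r == "D":
                freqs[i] += weight
    return PositionalSupport(frequencies=freqs.tolist(), ambiguity_flag=ambiguous)


def end_diagnostics(
    spectrum: Spectrum,
    composition: Composition,
    table: MassTable = MONOISOTOPIC,
    tol: float = 0.5,
) -> dict:
    """Reducing- and non-reducing-end acetylation state from diagnostic ions.

    Reducing end: Y1 is either GlcNAc-AMAC (acetylated) or GlcN-AMAC
    (deacetylated); their relative intensity reports the reducing-end state of
    the precursor pool.  Non-reducing end: a D at the non-reducing terminus
    implies a Y_(DP-1) ion that lost that D, i.e. of composition
    (nA, nD - 1); its absence means the non-reducing end was not deacetylated
    in the pool.
    """
    if composition.dp < 2:
        raise ValueError("end diagnostics require DP >= 2")

    def peak_intensity(mz: float) -> float:
        best = 0.0
        for p in spectrum.peaks:
            if abs(p.mz - mz) <= tol:
                best = max(best, p.intensity)
        return best

    y1_a = table.residue_a + table.amac + table.h2 + table.proton
    y1_d = table.residue_d + table.amac + table.h2 + table.proton
    int_a = peak_intensity(y1_a)
    int_d = peak_intensity(y1_d)
    denom = int_a + int_d
    report: dict = {
        "reducing_end": {
            "y1_acetylated_mz": round(y1_a, 4),
            "y1_deacetylated_mz": round(y1_d, 4),
            "intensity_acetylated": int_a,
            "intensity_deacetylated": int_d,
            "fraction_acetylated": (int_a / denom) if denom > 0 else None,
            "call": (
                "undetermined" if denom == 0
                else "acetylated" if int_a >= int_d
                else "deacetylated"
            ),
        }
    }
    if composition.nD >= 1:
        # Y_(DP-1) that dropped a D from the non-reducing terminus
        sub = Composition(nA=composition.nA, nD=composition.nD - 1) \
            if composition.nA + composition.nD - 1 >= 1 else None
        if sub is not None:
            mz = (
                sub.nA * table.residue_a + sub.nD * table.residue_d
                + table.amac + table.h2 + table.proton
            )
            inten = peak_intensity(mz)
            report["non_reducing_end"] = {
                "diagnostic": f"Y{composition.dp - 1} of {sub.label_str()}",
                "mz": round(mz, 4),
                "intensity": inten,
                "deacetylation_observed": inten > 0,
            }
    else:
        report["non_reducing_end"] = {
            "diagnostic": None,
            "deacetylation_observed": False,
        }
    return report
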