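"""Synthetic-data generators: deacetylation ensembles, MS2 spectra, protein sets.

Three generators emulate the inputs of a CE4 deacetylase characterization:

* a stochastic position-biased sequential-deacetylation simulator producing
  time-resolved pattern ensembles from a fully acetylated oligomer;
* a spectrum synthesizer turning a pattern mixture into an MS2 peak list
  (Y/B ladders, m/z jitter, noise peaks);
* a protein-collection generator planting CE4 motifs, signal peptides,
  incomplete genes and multi-domain decoys with exact truth labels.

The deacetylation model treats each acetylated position as an independent
exponential clock with first-order rate constant k_i; an optional neighbor
penalty multiplies a position's rate by ``penalty`` per already-deacetylated
adjacent residue, capturing the observation that later deacetylations on a
partially deacetylated chain are slower.  With penalty 1 the per-position
occupancy has the closed form P_i(t) = 1 - exp(-k_i t).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chos import ChosPattern, Composition, Label, MassTable, MONOISOTOPIC, \
    composition_mz
from .msannotate import IonType, Peak, Spectrum, fragment_ladder
from .screen import (
    AA20,
    DEFAULT_MOTIFS,
    ProteinRecord,
    compile_motif,
    find_motif,
)

# ---------------------------------------------------------------------------
# Deacetylation kinetics simulator


@dataclass(frozen=True)
class RateModel:
    """Per-position first-order deacetylation rates (1/s),
    non-reducing -> reducing.

    ``from_classes`` builds a profile from three class rates.  The
    neighbor_penalty multiplies a position's instantaneous rate by
    penalty^(number of already-deacetylated neighbors); 1.0 means positions
    are independent.
    """

    rates: tuple[float, ...]
    neighbor_penalty: float = 1.0

    def __post_init__(self) -> None:
        if any(k < 0 for k in self.rates):
            raise ValueError("rate constants must be non-negative")
        if not 0 < self.neighbor_penalty <= 1:
            raise ValueError("neighbor penalty must be in (0, 1]")

    @property
    def dp(self) -> int:
        return len(self.rates)

    @classmethod
    def from_classes(
        cls,
        dp: int,
        internal: float,
        non_reducing_end: float,
        reducing_end: float,
        neighbor_penalty: float = 1.0,
    ) -> "RateModel":
        if dp < 1:
            raise ValueError("dp must be >= 1")
        if dp == 1:
            rates = (reducing_end,)
        else:
            rates = (non_reducing_end,) + (internal,) * (dp - 2) + (reducing_end,)
        return cls(rates, neighbor_penalty)


@dataclass
class EnsembleState:
    """Pattern-frequency trajectories of a simulated reaction."""

    times: list[float]
    distributions: list[dict]        # per time: pattern string -> frequency
    acetate_per_molecule: list[float]  # expected A->D conversions since t=0
    n_molecules: int

    def mixture_at(self, t_index: int, composition: Composition | None = None,
                   label: Label = Label.AMAC) -> dict:
        """Pattern mixture at one time point, optionally restricted to one
        composition (as after MS1 precursor isolation), renormalized, with the
        reducing-end label applied."""
        dist = self.distributions[t_index]
        if composition is not None:
            dist = {
                p: f for p, f in dist.items()
                if p.count("D") == composition.nD
            }
        total = sum(dist.values())
        if total == 0:
            return {}
        return {
            str(ChosPattern(p, label)): f / total for p, f in dist.items()
        }


def simulate_deacetylation(
    dp: int,
    model: RateModel,
    times: list[float],
    n_molecules: int = 10000,
    seed: int = 0,
) -> EnsembleState:
    """Continuous-time Markov simulation of sequential deacetylation.

    Starts every molecule fully acetylated.  With neighbor_penalty = 1 each
    position fires at its own exponential clock (sampled directly); with
    penalty < 1 a per-molecule Gillespie simulation is run because rates
    change as neighbors convert.
    """
    if not 1 <= dp <= 12:
        raise ValueError("dp must be in [1, 12]")
    if model.dp != dp:
        raise ValueError(f"rate model is for DP {model.dp}, not {dp}")
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    rng = np.random.default_rng(seed)
    times = sorted(times)
    rates = np.asarray(model.rates, dtype=float)

    if model.neighbor_penalty == 1.0:
        # conversion time of each position ~ Exp(k_i); k=0 never converts
        with np.errstate(divide="ignore"):
            scale = np.where(rates > 0, 1.0 / np.where(rates > 0, rates, 1.0),
                             np.inf)
        t_conv = rng.exponential(1.0, size=(n_molecules, dp)) * scale
        distributions = []
        acetate = []
        for t in times:
            deac = t_conv <= t
            counter: Counter = Counter()
            for row in deac:
                counter["".join("D" if d else "A" for d in row)] += 1
            distributions.append(
                {p: c / n_molecules for p, c in counter.items()}
            )
            acetate.append(float(deac.sum()) / n_molecules)
        return EnsembleState(list(times), distributions, acetate, n_molecules)

    # Gillespie with neighbor-dependent rates
    penalty = model.neighbor_penalty
    per_time_counts = [Counter() for _ in times]
    acetate_counts = np.zeros(len(times))
    for _ in range(n_molecules):
        state = np.zeros(dp, dtype=bool)  # True = deacetylated
        t_now = 0.0
        snapshots = iter(enumerate(times))
        idx, t_next = next(snapshots)
        done = False
        while not done:
            eff = np.where(state, 0.0, rates)
            for i in range(dp):
                if not state[i]:
                    n_deac_nb = 0
                    if i > 0 and state[i - 1]:
                        n_deac_nb += 1
                    if i < dp - 1 and state[i + 1]:
                        n_deac_nb += 1
                    eff[i] *= penalty ** n_deac_nb
            total = eff.sum()
            t_event = t_now + rng.exponential(1.0 / total) if total > 0 else np.inf
            while t_next < t_event:
                per_time_counts[idx]["".join(
                    "D" if d else "A" for d in state)] += 1
                acetate_counts[idx] += state.sum()
                nxt = next(snapshots, None)
                if nxt is None:
                    done = True
                    break
                idx, t_next = nxt
            if done:
                break
            pos = rng.choice(dp, p=eff / total)
            state[pos] = True
            t_now = t_event
    distributions = [
        {p: c / n_molecules for p, c in counter.items()}
        for counter in per_time_counts
    ]
    acetate = (acetate_counts / n_molecules).tolist()
    return EnsembleState(list(times), distributions, acetate, n_molecules)


def analytic_occupancy(dp: int, model: RateModel, t: float) -> np.ndarray:
    """Closed-form per-position deacetylation probabilities, penalty-free case:
    P_i(t) = 1 - exp(-k_i t)."""
    if model.neighbor_penalty != 1.0:
        raise ValueError("closed form holds only for neighbor_penalty = 1")
    if model.dp != dp:
        raise ValueError(f"rate model is for DP {model.dp}, not {dp}")
    return 1.0 - np.exp(-np.asarray(model.rates) * t)


# ---------------------------------------------------------------------------
# Spectrum synthesis


@dataclass(frozen=True)
class SpectrumNoise:
    mz_jitter_sd: float = 0.0
    n_noise_peaks: int = 0
    noise_intensity_range: tuple[float, float] = (0.0, 0.1)
    noise_mz_range: tuple[float, float] = (150.0, 2000.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mz_jitter_sd < 0 or self.n_noise_peaks < 0:
            raise ValueError("jitter and noise counts must be non-negative")


def synth_spectrum(
    mixture: dict,
    table: MassTable = MONOISOTOPIC,
    noise: SpectrumNoise = SpectrumNoise(),
    b_ion_scale: float = 0.3,
) -> Spectrum:
    """MS2 spectrum of a pattern mixture (pattern string -> abundance).

    All patterns must share one DP and label.  Each pattern contributes its Y
    ladder at its abundance and its B ladder scaled by ``b_ion_scale``;
    coinciding theoretical m/z values accumulate.  Gaussian m/z jitter and
    uniform noise peaks are added deterministically under the noise seed.
    """
    if not mixture:
        raise ValueError("empty mixture")
    patterns = [ChosPattern.parse(p) for p in mixture]
    dps = {p.dp for p in patterns}
    labels = {p.label for p in patterns}
    if len(dps) != 1 or len(labels) != 1:
        raise ValueError("mixture patterns must share one DP and label")
    label = labels.pop()
    rng = np.random.default_rng(noise.seed)

    accum: dict[float, float] = {}
    for pat, abundance in zip(patterns, mixture.values()):
        ion_types = {IonType.Y, IonType.B} if label is Label.AMAC else {IonType.B}
        for ion in fragment_ladder(pat, ion_types, table):
            scale = 1.0 if ion.ion_type is IonType.Y else b_ion_scale
            key = round(ion.mz, 6)
            accum[key] = accum.get(key, 0.0) + abundance * scale

    peaks = [
        Peak(mz + (rng.normal(0.0, noise.mz_jitter_sd) if noise.mz_jitter_sd else 0.0),
             inten)
        for mz, inten in sorted(accum.items())
    ]
    lo, hi = noise.noise_mz_range
    ilo, ihi = noise.noise_intensity_range
    for _ in range(noise.n_noise_peaks):
        peaks.append(Peak(rng.uniform(lo, hi), rng.uniform(ilo, ihi)))

    comp = Composition(patterns[0].n_acetylated, patterns[0].n_deacetylated)
    precursor = composition_mz(comp, label, table)
    return Spectrum(peaks=peaks, ms_level=2, precursor_mz=precursor)


# ---------------------------------------------------------------------------
# Protein-collection generator

#: Canonical planted motif instances, MT1..MT5.
PLANT_MOTIFS = ("TFDD", "HSTAH", "RPPY", "DAADW", "LAH")

#: Signal peptide template: charged n-region (K2 K3 R4), hydrophobic h-region,
#: small-residue cleavage site with first qualifying cleavage after residue 21.
SP_TEMPLATE = "MKKR" + "LVLFIVLLFVLILV" + "ASA"


@dataclass(frozen=True)
class CollectionConfig:
    """Counts per planted screening category.

    Defaults build a 64-protein collection whose funnel is, by construction,
    64 -> 48 (CE4) -> 24 (all motifs) -> 16 (complete) -> 5 (signal peptide)
    -> 1 (single domain).
    """

    n_non_ce4: int = 16
    n_missing_motifs: int = 24
    n_incomplete: int = 8
    n_no_signal_peptide: int = 11
    n_multi_domain: int = 4
    n_positive: int = 1
    mature_length: int = 250
    multi_domain_length: int = 520

    def __post_init__(self) -> None:
        if min(self.n_non_ce4, self.n_missing_motifs, self.n_incomplete,
               self.n_no_signal_peptide, self.n_multi_domain,
               self.n_positive) < 0:
            raise ValueError("category counts must be non-negative")
        if self.multi_domain_length <= 400:
            raise ValueError("multi-domain plants must exceed the 400-aa proxy")

    @property
    def total(self) -> int:
        return (self.n_non_ce4 + self.n_missing_motifs + self.n_incomplete
                + self.n_no_signal_peptide + self.n_multi_domain
                + self.n_positive)


def _random_background(rng: np.random.Generator, length: int) -> list[str]:
    return list(rng.choice(list(AA20), size=length))


_MATCHERS = [compile_motif(m) for m in DEFAULT_MOTIFS]


def _scrub_motifs(seq: list[str], rng: np.random.Generator) -> list[str]:
    """Destroy accidental motif occurrences in a background sequence.

    Replaces the first residue of each hit with E and repeats to a fixed
    point, so truth labels for decoys are certain under any seed.  Every CE4
    motif starts with a literal residue and uses E in no literal or bracket
    position, so the replacement always kills the hit and can never create a
    new one (E can only occupy wildcard slots, which accept anything).
    """
    text = "".join(seq)
    for _ in range(50):
        dirty = False
        for matcher in _MATCHERS:
            for start, _end in find_motif(matcher, text):
                text = text[:start] + "E" + text[start + 1:]
                dirty = True
        if not dirty:
            return list(text)
    raise RuntimeError("motif scrubbing did not converge")


def _plant_motifs(seq: list[str], start: int, rng: np.random.Generator,
                  spacing: int = 20) -> list[tuple[str, int]]:
    """Overwrite ordered canonical motif instances starting at ``start``
    (0-based); returns planted (motif_id, position) pairs."""
    planted = []
    pos = start
    for mdef, instance in zip(DEFAULT_MOTIFS, PLANT_MOTIFS):
        seq[pos:pos + len(instance)] = list(instance)
        planted.append((mdef.motif_id, pos))
        pos += len(instance) + spacing
    if pos > len(seq):
        raise ValueError("sequence too short for ordered motif plant")
    return planted


def _neutral_nterm(seq: list[str], rng: np.random.Generator) -> None:
    """Make the N-terminus signal-peptide-negative: M start, no K/R at 2-6."""
    seq[0] = "M"
    safe = [a for a in AA20 if a not in "KR"]
    for i in range(1, 6):
        if seq[i] in "KR":
            seq[i] = str(rng.choice(safe))


def synth_protein_collection(
    config: CollectionConfig = CollectionConfig(),
    seed: int = 0,
) -> tuple[list[ProteinRecord], "pd.DataFrame"]:
    """Generate a protein collection with planted screening truth.

    Returns the records (family annotation attached; all other filters rely on
    sequence) and a truth table with the planted category and per-filter
    expectations, including planted motif positions for motif-bearing records.
    """
    rng = np.random.default_rng(seed)
    records: list[ProteinRecord] = []
    truth_rows = []
    counter = 0

    def build(category: str, family: str, plant_motif: bool, complete: bool,
              signal: bool, length: int):
        nonlocal counter
        counter += 1
        pid = f"prot{counter:03d}"
        seq = _scrub_motifs(_random_background(rng, length), rng)
        motif_positions = None
        if signal:
            seq[: len(SP_TEMPLATE)] = list(SP_TEMPLATE)
            body_start = len(SP_TEMPLATE) + 5
        else:
            _neutral_nterm(seq, rng)
            body_start = 30
        if not complete:
            # no initiator methionine, plus an internal stop placed beyond
            # the motif region (Q at position 1 cannot seed any motif)
            seq[0] = "Q"
            seq[length - 10] = "*"
        if plant_motif:
            motif_positions = _plant_motifs(seq, body_start, rng)
        record = ProteinRecord(pid, "".join(seq), {"family": family})
        records.append(record)
        truth_rows.append(
            {
                "id": pid,
                "category": category,
                "family": family,
                "expect_family_ce4": family == "CE4",
                "expect_all_motifs": plant_motif,
                "expect_complete": complete,
                "expect_signal_peptide": signal,
                "expect_single_domain": length <= 400 + (21 if signal else 0),
                "motif_positions": (
                    ";".join(f"{m}:{p}" for m, p in motif_positions)
                    if motif_positions else ""
                ),
            }
        )

    L = config.mature_length
    for _ in range(config.n_non_ce4):
        build("non_ce4", "GH18", False, True, False, L)
    for _ in range(config.n_missing_motifs):
        build("ce4_missing_motifs", "CE4", False, True, False, L)
    for _ in range(config.n_incomplete):
        build("incomplete_gene", "CE4", True, False, False, L)
    for _ in range(config.n_no_signal_peptide):
        build("no_signal_peptide", "CE4", True, True, False, L)
    for _ in range(config.n_multi_domain):
        build("multi_domain", "CE4", True, True, True, config.multi_domain_length)
    for _ in range(config.n_positive):
        build("positive", "CE4", True, True, True, L)

    return records, pd.DataFrame(truth_rows)
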