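"""Deacetylase activity metrics from single-point acetate-release assays.

Activity against a substrate is quantified from the acetic acid released
after a fixed incubation.  Derived quantities:

    ASAR     substrate amount expressed as the molar concentration of acetyl
             groups (uM): molar substrates contribute concentration x acetyl
             groups per molecule; mass-specified polymers contribute
             mass conc (g/L) / residue molar mass x 1e6 x fraction acetylated.
    degree   deacetylation degree (%) = 100 x acetate / ASAR.
    rate     acetate release rate (nmol/min) = acetate (uM = nmol/ml)
             x reaction volume (ml) / time (min).
    k_app    apparent rate constant (1/s) = acetate (uM)
             / (time (s) x enzyme concentration (uM)).

Single-point assays give apparent, not Michaelis-Menten, rates; no saturation
model is fitted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd


def round_half_up(x: float, decimals: int) -> float:
    """Decimal rounding with ties away from zero (matches printed tables)."""
    factor = 10 ** decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (half-up)."""
    if x == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(x)))
    return round_half_up(x, sig - 1 - exponent)


@dataclass(frozen=True)
class ActivityAssay:
    """Raw inputs of one acetate-release assay.

    Exactly one substrate amount specification is required:
    (conc_um, acetyls_per_molecule) for defined oligomers,
    (mass_conc_mg_ml, residue_molar_mass, fraction_acetylated) for polymers,
    or a directly supplied asar_um when the conversion assumptions are
    external to the assay table.
    """

    substrate_name: str
    acetate_um: float
    time_min: float = 30.0
    enzyme_um: float = 0.3
    reaction_volume_ml: float = 0.1
    cv_percent: float | None = None
    # molar specification
    conc_um: float | None = None
    acetyls_per_molecule: float | None = None
    # mass specification
    mass_conc_mg_ml: float | None = None
    residue_molar_mass: float | None = None
    fraction_acetylated: float = 1.0
    # direct ASAR
    asar_um: float | None = None

    def __post_init__(self) -> None:
        if self.time_min <= 0 or self.enzyme_um <= 0:
            raise ValueError("time and enzyme concentration must be positive")
        if self.reaction_volume_ml <= 0:
            raise ValueError("reaction volume must be positive")
        if self.acetate_um < 0:
            raise ValueError("acetate released cannot be negative")
        if not 0 < self.fraction_acetylated <= 1:
            raise ValueError("fraction acetylated must be in (0, 1]")


class SpecificationError(ValueError):
    """Substrate amount specification incomplete."""


def compute_asar(assay: ActivityAssay) -> float:
    """Substrate amount as acetyl-group concentration (uM), 3 significant figures."""
    if assay.asar_um is not None:
        return float(assay.asar_um)
    if assay.conc_um is not None:
        if assay.acetyls_per_molecule is None:
            raise SpecificationError(
                f"{assay.substrate_name}: molar spec needs acetyls per molecule"
            )
        return round_sig(assay.conc_um * assay.acetyls_per_molecule, 3)
    if assay.mass_conc_mg_ml is not None:
        if assay.residue_molar_mass is None:
            raise SpecificationError(
                f"{assay.substrate_name}: mass spec needs a residue molar mass"
            )
        # mg/ml == g/L; mol/L -> uM via 1e6
        molar = assay.mass_conc_mg_ml / assay.residue_molar_mass * 1e6
        return round_sig(molar * assay.fraction_acetylated, 3)
    raise SpecificationError(f"{assay.substrate_name}: no substrate specification")


@dataclass(frozen=True)
class KineticsResult:
    asar_um: float
    degree_percent: float
    release_rate_nmol_min: float
    k_app_per_s: float


def derive_metrics(assay: ActivityAssay) -> KineticsResult:
    """All derived activity metrics, unrounded (see format helpers for reports)."""
    asar = compute_asar(assay)
    degree = 100.0 * assay.acetate_um / asar
    rate = assay.acetate_um * assay.reaction_volume_ml / assay.time_min
    k_app = assay.acetate_um / (assay.time_min * 60.0 * assay.enzyme_um)
    return KineticsResult(asar, degree, rate, k_app)


def format_degree(degree: float) -> float:
    """Report precision for deacetylation degree: 3 decimals below 0.01%,
    2 decimals below 10%, 1 decimal above."""
    if abs(degree) < 0.01:
        return round_half_up(degree, 3)
    if abs(degree) < 10:
        return round_half_up(degree, 2)
    return round_half_up(degree, 1)


def reproduce_table(assays: list[ActivityAssay]) -> pd.DataFrame:
    """One row per assay with raw and derived columns at report precision."""
    if not assays:
        raise ValueError("assay list is empty")
    rows = []
    for assay in assays:
        res = derive_metrics(assay)
        rows.append(
            {
                "substrate": assay.substrate_name,
                "asar_um": res.asar_um,
                "acetate_um": assay.acetate_um,
                "cv_percent": assay.cv_percent,
                "degree_percent": format_degree(res.degree_percent),
                "release_rate_nmol_min": round_half_up(
                    res.release_rate_nmol_min, 2
                ),
                "k_app_per_s": round_half_up(res.k_app_per_s, 2),
            }
        )
    return pd.DataFrame(rows)


def read_assay_tsv(path) -> list[ActivityAssay]:
    """Load assays from a TSV whose columns mirror :class:`ActivityAssay`."""
    df = pd.read_csv(path, sep="\t")
    assays = []
    for _, row in df.iterrows():
        kwargs = {}
        for col in (
            "substrate_name", "acetate_um", "time_min", "enzyme_um",
            "reaction_volume_ml", "cv_percent", "conc_um",
            "acetyls_per_molecule", "mass_conc_mg_ml", "residue_molar_mass",
            "fraction_acetylated", "asar_um",
        ):
            if col in df.columns and pd.notna(row[col]):
                kwargs[col] = row[col]
        assays.append(ActivityAssay(**kwargs))
    return assays


def reference_assays(volume_ml: float = 0.1) -> list[ActivityAssay]:
    """The ten-substrate benchmark panel: CHOS DP1-6 at 2 mM, chitosan,
    alpha/beta-chitin and acetyl xylan at 5 mg/ml, 300 nM enzyme, 30 min.

    Chitosan and acetyl xylan ASAR values are direct inputs (their conversion
    assumptions — F_A 0.64, ~50% acetylation by MALDI-TOF — are stated with
    the panel, not recomputed here); chitin assumes one acetyl per 203.19
    g/mol residue.
    """
    def chos(name, dp, acetate, cv):
        return ActivityAssay(
            substrate_name=name, acetate_um=acetate, cv_percent=cv,
            conc_um=2000.0, acetyls_per_molecule=dp,
            reaction_volume_ml=volume_ml,
        )

    def chitin(name, acetate, cv):
        return ActivityAssay(
            substrate_name=name, acetate_um=acetate, cv_percent=cv,
            mass_conc_mg_ml=5.0, residue_molar_mass=203.19,
            fraction_acetylated=1.0, reaction_volume_ml=volume_ml,
        )

    return [
        chos("GlcNAc", 1, 0.0, 0.0),
        chos("(GlcNAc)2", 2, 0.1, 14.5),
        chos("(GlcNAc)3", 3, 11.9, 2.6),
        chos("(GlcNAc)4", 4, 39.8, 2.8),
        chos("(GlcNAc)5", 5, 95.8, 7.7),
        chos("(GlcNAc)6", 6, 39.4, 0.2),
        ActivityAssay(
            substrate_name="chitosan (FA 0.64)", acetate_um=85.4,
            cv_percent=1.4, asar_um=16000.0, reaction_volume_ml=volume_ml,
        ),
        chitin("alpha-chitin", 0.8, 6.4),
        chitin("beta-chitin", 1.4, 1.9),
        ActivityAssay(
            substrate_name="acetyl xylan", acetate_um=1696.7,
            cv_percent=3.1, asar_um=9000.0, reaction_volume_ml=volume_ml,
        ),
    ]
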