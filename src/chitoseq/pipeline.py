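"""Orchestration: screening and MS-annotation runs with on-disk reports.

Every report header records the pattern orientation (non-reducing end ->
reducing end) and the mass convention, so downstream readers never have to
guess the coordinate system.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import chos, msannotate
from .chos import Label, MassTable, MONOISOTOPIC, composition_from_mz
from .io import read_annotations, read_fasta, read_mgf
from .msannotate import RankParams, end_diagnostics, positional_support, \
    rank_patterns
from .screen import ScreenConfig, run_cascade

log = logging.getLogger("chitoseq")

HEADER_COMMENT = (
    "# orientation: non-reducing end -> reducing end; mass convention: {conv}\n"
)


@dataclass
class RunConfig:
    out_dir: Path
    fasta: Path | None = None
    annotations: Path | None = None
    mgf: Path | None = None
    dp: int | None = None
    label: Label = Label.AMAC
    tol: float = 0.5
    mass_table: MassTable = MONOISOTOPIC
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    rank: RankParams = field(default_factory=RankParams)
    seed: int = 0

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.tol <= 0:
            raise ValueError("tolerance must be positive")


def _write_tsv(df: pd.DataFrame, path: Path, conv: str) -> None:
    with open(path, "w") as fh:
        fh.write(HEADER_COMMENT.format(conv=conv))
        df.to_csv(fh, sep="\t", index=False)


def run_screen_report(config: RunConfig) -> dict:
    """Run the candidate funnel; write funnel and per-protein verdict TSVs."""
    if config.fasta is None:
        raise ValueError("screen run requires a FASTA path")
    ann = read_annotations(config.annotations) if config.annotations else None
    collection = read_fasta(config.fasta, ann)
    log.info("screen: %d proteins read", len(collection))
    report = run_cascade(collection, config.screen)
    config.out_dir.mkdir(parents=True, exist_ok=True)

    funnel_df = pd.DataFrame(report.funnel, columns=["stage", "surviving"])
    _write_tsv(funnel_df, config.out_dir / "funnel.tsv",
               config.mass_table.convention)
    for stage, count in report.funnel:
        log.info("screen: stage %-16s -> %d", stage, count)

    verdict_rows = []
    for pid, v in report.verdicts.items():
        row = {"id": pid}
        for name in ("family_ce4", "all_motifs", "complete_gene",
                     "signal_peptide", "single_domain"):
            row[name] = v[name]
        row["sp_cleavage"] = v["sp_call"].cleavage_pos
        row["survivor"] = pid in report.survivors
        verdict_rows.append(row)
    _write_tsv(pd.DataFrame(verdict_rows), config.out_dir / "verdicts.tsv",
               config.mass_table.convention)
    return {"funnel": report.funnel, "survivors": report.survivors}


def run_ms_report(config: RunConfig) -> dict:
    """Annotate MS2 spectra: composition inference, isomer ranking, positional
    support and end diagnostics; writes TSV + JSON reports."""
    if config.mgf is None:
        raise ValueError("annotation run requires an MGF path")
    spectra = read_mgf(config.mgf)
    log.info("annotate: %d MS2 spectra read", len(spectra))
    config.out_dir.mkdir(parents=True, exist_ok=True)
    dp_range = (config.dp, config.dp) if config.dp else (1, chos.MAX_DP)

    score_rows = []
    support_reports = []
    for i, spectrum in enumerate(spectra, start=1):
        comps = composition_from_mz(
            spectrum.precursor_mz, dp_range, config.label,
            config.mass_table, config.tol,
        )
        if not comps:
            log.warning("annotate: spectrum %d precursor %.2f unassigned",
                        i, spectrum.precursor_mz)
            continue
        dp, comp = comps[0]
        scores = rank_patterns(spectrum, comp, config.mass_table,
                               config.rank, config.label)
        support = positional_support(scores, config.rank)
        ends = end_diagnostics(spectrum, comp, config.mass_table, config.tol)
        for rank, s in enumerate(scores, start=1):
            score_rows.append(
                {
                    "spectrum": i,
                    "precursor_mz": round(spectrum.precursor_mz, 4),
                    "composition": comp.label_str(),
                    "rank": rank,
                    "pattern": str(s.pattern),
                    "score": round(s.score, 4),
                    "explained_fraction": round(s.explained_fraction, 4),
                }
            )
        support_reports.append(
            {
                "spectrum": i,
                "composition": comp.label_str(),
                "positional_deacetylation": [
                    round(f, 4) for f in support.frequencies
                ],
                "ambiguous": support.ambiguity_flag,
                "end_diagnostics": ends,
            }
        )
    if score_rows:
        _write_tsv(pd.DataFrame(score_rows),
                   config.out_dir / "pattern_scores.tsv",
                   config.mass_table.convention)
    payload = {
        "orientation": "non-reducing end -> reducing end",
        "mass_convention": config.mass_table.convention,
        "spectra": support_reports,
    }
    with open(config.out_dir / "positional_support.json", "w") as fh:
        json.dump(payload, fh, indent=2)
    if not support_reports:
        log.warning("annotate: no spectrum could be assigned a composition")
    return payload
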