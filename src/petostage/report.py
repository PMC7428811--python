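"""Assemble baselines and hypothesis solutions into the summary table.

One row per (MR exponent, tissue, target species) holds the unmitigated
lifetime risk plus the four hypothesis solutions; baseline records carry
the calibrated (M, u) pairs.  CSV is the canonical output; Markdown is
provided for eyeballing; values are formatted to 3 significant figures
in capital-E scientific notation (ΔM to 1 decimal) with full-precision
companions retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO
from pathlib import Path

import pandas as pd

from .calibration import CalibrationResult, calibrate_baseline
from .config import StudyConfig, default_config
from .solvers import solve_all

__all__ = [
    "Table2Row",
    "build_baselines",
    "build_table2",
    "table_to_frame",
    "baselines_to_frame",
    "format_sci",
    "format_fold",
    "write_table",
    "frame_to_markdown",
]


@dataclass(frozen=True)
class Table2Row:
    """One scenario row of the scaling-results table."""

    beta: float
    tissue: str
    species: str
    baseline_M: int
    baseline_u: float
    unmitigated_risk: float
    mutation_fold: float
    policing_cancer_escape: float
    policing_driver_escape: float
    added_drivers: float
    achieved_risks: tuple[float, float, float, float]


def build_baselines(config: StudyConfig | None = None) -> list[CalibrationResult]:
    """Calibrate every (beta, tissue) mouse baseline in the config."""
    cfg = config or default_config()
    return [
        calibrate_baseline(
            tissue, cfg.baseline_species, beta,
            p_target=cfg.p_target, u_anchor=cfg.u_anchor,
            reference=cfg.reference_species, M_max=cfg.M_max,
        )
        for beta in cfg.betas
        for tissue in cfg.tissues
    ]


def build_table2(config: StudyConfig | None = None) -> list[Table2Row]:
    """All scenario rows: betas x tissues x target species."""
    cfg = config or default_config()
    rows: list[Table2Row] = []
    for beta in cfg.betas:
        for tissue in cfg.tissues:
            base = calibrate_baseline(
                tissue, cfg.baseline_species, beta,
                p_target=cfg.p_target, u_anchor=cfg.u_anchor,
                reference=cfg.reference_species, M_max=cfg.M_max,
            )
            for species in cfg.target_species:
                sol = solve_all(
                    base, tissue, species, cfg.reference_species, beta,
                    cfg.p_target,
                )
                rows.append(
                    Table2Row(
                        beta=beta,
                        tissue=tissue.name,
                        species=species.name,
                        baseline_M=base.M,
                        baseline_u=base.u,
                        unmitigated_risk=sol["mutation_rate"].unmitigated_risk,
                        mutation_fold=sol["mutation_rate"].value,
                        policing_cancer_escape=sol["policing_cancer"].value,
                        policing_driver_escape=sol["policing_driver"].value,
                        added_drivers=sol["added_drivers"].value,
                        achieved_risks=(
                            sol["mutation_rate"].achieved_risk,
                            sol["policing_cancer"].achieved_risk,
                            sol["policing_driver"].achieved_risk,
                            sol["added_drivers"].achieved_risk,
                        ),
                    )
                )
    return rows


def format_sci(x: float, sig: int = 3) -> str:
    """Capital-E scientific notation with ``sig`` significant figures
    (the table's '7.10E-09' style)."""
    return f"{x:.{sig - 1}E}"


def format_fold(x: float, sig: int = 3) -> str:
    """Comma-grouped fold with 3 significant figures ('8,830' style)."""
    return f"{float(f'{x:.{sig}g}'):,.10g}"


def table_to_frame(rows: list[Table2Row]) -> pd.DataFrame:
    """Scenario rows as a DataFrame: formatted columns plus
    full-precision companions."""
    return pd.DataFrame(
        {
            "beta": [r.beta for r in rows],
            "tissue": [r.tissue for r in rows],
            "species": [r.species for r in rows],
            "baseline_M": [r.baseline_M for r in rows],
            "baseline_u": [format_sci(r.baseline_u) for r in rows],
            "unmitigated_risk_pct": [
                f"{100 * r.unmitigated_risk:.0f}%" for r in rows
            ],
            "mutation_fold": [format_fold(r.mutation_fold) for r in rows],
            "policing_cancer_escape": [
                format_sci(r.policing_cancer_escape) for r in rows
            ],
            "policing_driver_escape": [
                format_sci(r.policing_driver_escape) for r in rows
            ],
            "added_drivers": [f"{r.added_drivers:.1f}" for r in rows],
            "baseline_u_full": [repr(r.baseline_u) for r in rows],
            "mutation_fold_full": [repr(r.mutation_fold) for r in rows],
            "policing_cancer_escape_full": [
                repr(r.policing_cancer_escape) for r in rows
            ],
            "policing_driver_escape_full": [
                repr(r.policing_driver_escape) for r in rows
            ],
            "added_drivers_full": [repr(r.added_drivers) for r in rows],
        }
    )


def baselines_to_frame(baselines: list[CalibrationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "beta": [b.beta for b in baselines],
            "tissue": [b.tissue for b in baselines],
            "M": [b.M for b in baselines],
            "u": [format_sci(b.u) for b in baselines],
            "u_full": [repr(b.u) for b in baselines],
            "achieved_risk": [repr(b.achieved_risk) for b in baselines],
        }
    )


def frame_to_markdown(df: pd.DataFrame) -> str:
    """Render a DataFrame as a GitHub-style Markdown table."""
    cols = [str(c) for c in df.columns]
    body = [[str(v) for v in row] for row in df.itertuples(index=False)]
    widths = [
        max(len(cols[j]), *(len(r[j]) for r in body)) if body else len(cols[j])
        for j in range(len(cols))
    ]
    def line(cells):
        return "| " + " | ".join(c.ljust(w) for c, w in zip(cells, widths)) + " |"
    sep = "|-" + "-|-".join("-" * w for w in widths) + "-|"
    return "\n".join([line(cols), sep, *(line(r) for r in body)]) + "\n"


def write_table(df: pd.DataFrame, out: str | Path | None, fmt: str = "csv") -> str:
    """Serialize a table as csv/tsv/md; write to ``out`` or return text."""
    if fmt == "csv":
        text = df.to_csv(index=False)
    elif fmt == "tsv":
        text = df.to_csv(index=False, sep="\t")
    elif fmt == "md":
        text = frame_to_markdown(df)
    else:
        raise ValueError(f"unknown format {fmt!r} (expected csv, tsv or md)")
    if out is not None:
        Path(out).write_text(text)
    return text
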