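"""Readers/writers and run configuration.

Drug tables travel as CSV with a fixed schema (one row per drug):
``Drug, Mwt, logP, ion_class, pk_a, pk_b, Kpuu_ECF, Kpuu_LV, Kpuu_CM,
BCRP, p-gp, OAT3, MRP4, CL_P, CL_T_ef, CL_T_in``.  Transporter columns
use ``X`` (substrate) / ``-``; missing pk values are ``NA``; clearance
values below the detection limit may be written ``<0.01`` and are
coerced to 0.  The dialect is fixed: comma-separated, UTF-8, ``.``
decimal, mandatory header; units are fixed by the schema (g/mol,
mL/min) and never auto-converted.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .physicochem import IonClass, IonizationSpec, ParameterError
from .physiology import read_physiology, write_physiology  # noqa: F401 (re-export)
from .scenarios import GridResult
from .transport import TRANSPORTER_NAMES, DrugParameters

__all__ = [
    "RunConfig",
    "SchemaError",
    "read_drug_table",
    "write_drug_table",
    "write_outputs",
    "read_physiology",
    "write_physiology",
]

logger = logging.getLogger(__name__)

DRUG_TABLE_COLUMNS = (
    "Drug", "Mwt", "logP", "ion_class", "pk_a", "pk_b",
    "Kpuu_ECF", "Kpuu_LV", "Kpuu_CM",
    "BCRP", "p-gp", "OAT3", "MRP4",
    "CL_P", "CL_T_ef", "CL_T_in",
)

_ION_CLASS_ALIASES = {
    "acid": IonClass.ACID,
    "base": IonClass.BASE,
    "neutral": IonClass.NEUTRAL,
    "zwitterion": IonClass.ZWITTERION,
}


class SchemaError(ValueError):
    """Raised when an input table does not match the expected schema."""


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one scenario-grid run."""

    drug_table: Optional[str] = None
    physiology_file: Optional[str] = None
    scenario_set: str = "default"
    output_dir: str = "results"
    horizon: float = 600.0  # min
    dt: float = 0.5  # min
    rtol: float = 1e-8
    atol: float = 1e-10
    terminal_points: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.horizon <= 0:
            raise ParameterError("horizon must be positive")


def _parse_number(value, drug: str, column: str, line: int) -> float:
    """Parse one numeric cell; '<x' censored values coerce to 0."""
    text = str(value).strip()
    if text.startswith("<"):
        logger.info(
            "%s: %s value %r below detection limit, stored as 0", drug, column, text
        )
        return 0.0
    try:
        return float(text)
    except ValueError as exc:
        raise SchemaError(
            f"line {line}: non-numeric value {text!r} in column {column!r}"
        ) from exc


def _parse_optional(value, drug: str, column: str, line: int) -> Optional[float]:
    text = str(value).strip()
    if text in ("", "NA", "NaN", "nan", "None"):
        return None
    return _parse_number(value, drug, column, line)


def read_drug_table(path) -> list[DrugParameters]:
    """Parse a drug-parameter CSV into ``DrugParameters`` records.

    Raises ``SchemaError`` naming the missing column or offending line
    on malformed input; unknown ion classes are rejected."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc
    missing = [c for c in DRUG_TABLE_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")

    drugs = []
    for i, row in frame.iterrows():
        line = i + 2  # header is line 1
        name = str(row["Drug"]).strip()
        if not name:
            raise SchemaError(f"line {line}: empty drug name")
        class_text = str(row["ion_class"]).strip().lower()
        if class_text not in _ION_CLASS_ALIASES:
            raise SchemaError(
                f"line {line}: unknown ion class {row['ion_class']!r}"
            )
        ion_class = _ION_CLASS_ALIASES[class_text]
        flags = frozenset(
            t for t in TRANSPORTER_NAMES if str(row[t]).strip().upper() == "X"
        )
        try:
            drug = DrugParameters(
                name=name,
                mwt=_parse_number(row["Mwt"], name, "Mwt", line),
                logp=_parse_number(row["logP"], name, "logP", line),
                ionization=IonizationSpec(
                    ion_class=ion_class,
                    pka=_parse_optional(row["pk_a"], name, "pk_a", line),
                    pkb=_parse_optional(row["pk_b"], name, "pk_b", line),
                ),
                kpuu_ecf=_parse_number(row["Kpuu_ECF"], name, "Kpuu_ECF", line),
                kpuu_lv=_parse_optional(row["Kpuu_LV"], name, "Kpuu_LV", line),
                kpuu_cm=_parse_optional(row["Kpuu_CM"], name, "Kpuu_CM", line),
                transporters=flags,
                cl_para=_parse_number(row["CL_P"], name, "CL_P", line),
                cl_trans_ef=_parse_number(row["CL_T_ef"], name, "CL_T_ef", line),
                cl_trans_in=_parse_number(row["CL_T_in"], name, "CL_T_in", line),
            )
        except ParameterError as exc:
            raise SchemaError(f"line {line}: {exc}") from exc
        drugs.append(drug)
    return drugs


def write_drug_table(drugs: Sequence[DrugParameters], path) -> None:
    """Write drugs to the schema CSV (round-trips with the reader)."""
    rows = []
    for d in drugs:
        rows.append(
            {
                "Drug": d.name,
                "Mwt": d.mwt,
                "logP": d.logp,
                "ion_class": d.ionization.ion_class.value,
                "pk_a": "NA" if d.ionization.pka is None else d.ionization.pka,
                "pk_b": "NA" if d.ionization.pkb is None else d.ionization.pkb,
                "Kpuu_ECF": d.kpuu_ecf,
                "Kpuu_LV": "NA" if d.kpuu_lv is None else d.kpuu_lv,
                "Kpuu_CM": "NA" if d.kpuu_cm is None else d.kpuu_cm,
                **{
                    t: ("X" if t in d.transporters else "-")
                    for t in TRANSPORTER_NAMES
                },
                "CL_P": d.cl_para,
                "CL_T_ef": d.cl_trans_ef,
                "CL_T_in": d.cl_trans_in,
            }
        )
    pd.DataFrame(rows, columns=list(DRUG_TABLE_COLUMNS)).to_csv(path, index=False)


def write_outputs(
    grid: GridResult,
    config: RunConfig,
    traces: Optional[dict] = None,
    figure: bool = True,
) -> dict:
    """Write the run artifacts under ``config.output_dir``.

    Produces ``pk_summaries.csv`` (one row per drug x scenario x
    compartment), ``heatmap.csv`` (log2 fold changes), optionally
    ``traces.csv`` (tidy time/compartment/concentration) and
    ``heatmap.png``, and a ``manifest.json`` echoing the configuration,
    package version and solver settings so the CSVs can be reproduced
    bit-identically.  Returns the mapping of artifact name to path."""
    from . import __version__

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    summaries_path = out / "pk_summaries.csv"
    grid.summaries.to_csv(summaries_path, index=False)
    paths["pk_summaries"] = summaries_path

    heatmap_path = out / "heatmap.csv"
    grid.heatmap.to_csv(heatmap_path, index=False)
    paths["heatmap"] = heatmap_path

    if traces:
        frames = []
        for (drug, scenario), result in traces.items():
            frame = result.to_frame()
            frame.insert(0, "scenario", scenario)
            frame.insert(0, "drug", drug)
            frames.append(frame)
        traces_path = out / "traces.csv"
        pd.concat(frames, ignore_index=True).to_csv(traces_path, index=False)
        paths["traces"] = traces_path

    if figure and not grid.heatmap.empty:
        paths["figure"] = _heatmap_figure(grid.heatmap, out / "heatmap.png")

    manifest = {
        "package": "cns-whatif",
        "version": __version__,
        "created": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "config": dataclasses.asdict(config),
        "failures": grid.failures,
        "outputs": {k: str(v) for k, v in paths.items()},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    paths["manifest"] = manifest_path
    return paths


def _heatmap_figure(heatmap: pd.DataFrame, path: Path) -> Path:
    """Render the fold-change matrix as a diverging-colour heatmap."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    matrix = heatmap.set_index(["drug", "compartment"])
    data = matrix.to_numpy(dtype=float)
    span = max(abs(data).max(), 1e-6)
    fig, ax = plt.subplots(
        figsize=(max(6.0, 0.28 * matrix.shape[1]), max(4.0, 0.3 * matrix.shape[0]))
    )
    im = ax.imshow(data, cmap="RdBu_r", vmin=-span, vmax=span, aspect="auto")
    ax.set_xticks(range(matrix.shape[1]), matrix.columns, rotation=90, fontsize=6)
    ax.set_yticks(
        range(matrix.shape[0]),
        [f"{d} ({c})" for d, c in matrix.index],
        fontsize=7,
    )
    fig.colorbar(im, ax=ax, label="log2 fold change vs reference")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
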