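"""CSV record ingestion, report rendering, and run manifests.

The record schema (version 1) is one CSV row per measurement occasion:

    record_id, age, sex, ca, p, pth, creatinine            (required columns)
    black, albumin, vitd25, exclusion_flags, truth_phpt     (optional columns)

Values are SI by default (Ca, P in mmol/L; PTH ng/L; creatinine µmol/L;
albumin g/L; 25-OH-D nmol/L); a units declaration may mark ca/p/creatinine as
mg/dL, in which case they are converted to SI on ingest. The absent-value
token is the empty string. Malformed rows are routed to a rejects list with a
reason — never silently dropped. Unknown columns or unit declarations are a
hard error.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .biochem import LabRecord, Sex, UnitSystem, convert_units
from .config import Config
from .flow import FlowReport

SCHEMA_VERSION = "1"

REQUIRED_COLUMNS = ("record_id", "age", "sex", "ca", "p", "pth", "creatinine")
OPTIONAL_COLUMNS = ("black", "albumin", "vitd25", "exclusion_flags", "truth_phpt")
_CONVERTIBLE = ("ca", "p", "creatinine")

_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no"}


class SchemaError(ValueError):
    """The file does not conform to the declared record schema."""


@dataclass(frozen=True)
class ReadResult:
    records: list[LabRecord]
    rejects: list[tuple[int, str]]  # (0-based data-row index, reason)


def _parse_bool(token: str, default: bool | None) -> bool | None:
    if token == "":
        return default
    low = token.strip().lower()
    if low in _TRUE:
        return True
    if low in _FALSE:
        return False
    raise ValueError(f"not a boolean: {token!r}")


def read_records(path, units: dict[str, str] | None = None) -> ReadResult:
    """Read and validate laboratory records from CSV.

    ``units`` optionally declares the unit system per convertible analyte
    (``{"ca": "CU"}`` means calcium arrives in mg/dL and is converted to
    mmol/L on ingest). Returns validated records plus a rejects list of
    (row index, reason) for rows that fail validation.
    """
    units = units or {}
    for analyte, system in units.items():
        if analyte not in _CONVERTIBLE:
            raise SchemaError(f"units declared for non-convertible column {analyte!r}")
        if system not in (UnitSystem.SI.value, UnitSystem.CU.value):
            raise SchemaError(f"unknown unit system {system!r} for {analyte!r}")

    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return ReadResult(records=[], rejects=[])
    unknown = set(df.columns) - set(REQUIRED_COLUMNS) - set(OPTIONAL_COLUMNS)
    if unknown:
        raise SchemaError(f"unknown columns {sorted(unknown)} (schema version {SCHEMA_VERSION})")
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"missing required columns {sorted(missing)}")

    records: list[LabRecord] = []
    rejects: list[tuple[int, str]] = []
    for idx, row in df.iterrows():
        try:
            records.append(_parse_row(row, units))
        except (ValueError, KeyError) as exc:
            rejects.append((int(idx), str(exc)))
    return ReadResult(records=records, rejects=rejects)


def _parse_row(row: pd.Series, units: dict[str, str]) -> LabRecord:
    def number(col: str, required: bool) -> float | None:
        token = str(row[col]).strip() if col in row.index else ""
        if token == "":
            if required:
                raise ValueError(f"missing_required:{col}")
            return None
        value = float(token)
        if col in _CONVERTIBLE and units.get(col, "SI") == "CU":
            value = convert_units(value, col, UnitSystem.CU, UnitSystem.SI)
        return value

    flags_token = str(row.get("exclusion_flags", "")).strip()
    flags = frozenset(f for f in flags_token.split(";") if f)
    return LabRecord(
        record_id=str(row["record_id"]),
        age=number("age", required=True),
        sex=Sex(str(row["sex"]).strip().lower()),
        ca=number("ca", required=True),
        p=number("p", required=True),
        pth=number("pth", required=True),
        creatinine=number("creatinine", required=True),
        black=bool(_parse_bool(str(row.get("black", "")), False)),
        albumin=number("albumin", required=False),
        vitd25=number("vitd25", required=False),
        exclusion_flags=flags,
        truth_phpt=_parse_bool(str(row.get("truth_phpt", "")), None),
    )


def records_to_frame(records: list[LabRecord]) -> pd.DataFrame:
    """Flatten records to a schema-conformant DataFrame (absent values empty)."""
    rows = []
    for r in records:
        rows.append(
            {
                "record_id": r.record_id,
                "age": r.age,
                "sex": r.sex.value,
                "ca": r.ca,
                "p": r.p,
                "pth": r.pth,
                "creatinine": r.creatinine,
                "black": r.black,
                "albumin": "" if r.albumin is None else r.albumin,
                "vitd25": "" if r.vitd25 is None else r.vitd25,
                "exclusion_flags": ";".join(sorted(r.exclusion_flags)),
                "truth_phpt": "" if r.truth_phpt is None else r.truth_phpt,
            }
        )
    return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS) + list(OPTIONAL_COLUMNS))


def write_records(records: list[LabRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def write_roc_csv(roc_result, path) -> None:
    """ROC operating points as a two-column (FPR, TPR) CSV."""
    pd.DataFrame({"fpr": roc_result.fpr, "tpr": roc_result.tpr}).to_csv(path, index=False)


def plot_roc(roc_result, path, title: str = "ROC curve") -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(roc_result.fpr, roc_result.tpr, drawstyle="steps-post", color="tab:blue")
    ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=1)
    lo, hi = roc_result.auc_ci95
    ax.set_title(f"{title}\nAUC {roc_result.auc:.3f} (SE {roc_result.auc_se:.3f}, "
                 f"95% CI {lo:.3f}–{hi:.3f})")
    ax.set_xlabel("1 − specificity")
    ax.set_ylabel("sensitivity")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_manifest(config: Config, seed: int, extra: dict | None = None) -> dict:
    import caphos

    manifest = {
        "package": "caphos",
        "version": caphos.__version__,
        "schema_version": SCHEMA_VERSION,
        "config_digest": config.digest(),
        "seed": seed,
        "python": platform.python_version(),
    }
    if extra:
        manifest.update(extra)
    return manifest


def render_report(
    outdir,
    config: Config,
    seed: int,
    tables: dict[str, pd.DataFrame] | None = None,
    roc_result=None,
    flow: FlowReport | None = None,
    extras: dict | None = None,
) -> Path:
    """Write a report bundle: metric tables, ROC CSV + plot, flow text, manifest.

    Sections whose inputs are absent are simply omitted (the manifest lists
    what was written); partial pipelines therefore still produce a report.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in (tables or {}).items():
        dest = outdir / f"{name}.csv"
        table.to_csv(dest, index=False)
        written.append(dest.name)
    if roc_result is not None:
        write_roc_csv(roc_result, outdir / "roc.csv")
        plot_roc(roc_result, outdir / "roc.png")
        written += ["roc.csv", "roc.png"]
    if flow is not None:
        (outdir / "flow.txt").write_text(flow.to_text() + "\n")
        written.append("flow.txt")
    manifest = run_manifest(config, seed, {"sections": sorted(written), **(extras or {})})
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return outdir
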