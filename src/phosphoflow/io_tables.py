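"""Readers and writers for MaxQuant-dialect tables and pipeline outputs.

Input tables are tab-separated with one reporter-intensity column per
(plex, channel), named ``Reporter intensity corrected <k> <plex>`` (the
pattern is configurable to tolerate MaxQuant version drift).  MaxQuant
site-multiplicity columns (``...___1/___2/___3``) are summed into one
intensity per site.  Decoy ("Reverse") and contaminant rows use "+"
marking and are dropped on read.  Zero intensities are treated as missing
(NaN), not as measured zeros.
"""
from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    Contrast,
    DesignError,
    FormatError,
    PhosphoSiteRecord,
    ProteinGroupRecord,
    ReporterMatrix,
    SampleDesign,
    make_matrix,
)

log = logging.getLogger(__name__)

DEFAULT_REPORTER_PATTERN = r"^Reporter intensity corrected (?P<channel>\S+) (?P<plex>.+?)(?:___(?P<mult>\d+))?$"

#: default class-I localization-probability cutoff
DEFAULT_MIN_LOCALIZATION = 0.75

MISSING_TOKEN = "NA"


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else None
    return pd.read_csv(path, sep=sep, engine="python", dtype=str, keep_default_na=False)


def read_design(path) -> SampleDesign:
    """Read a sample-design table (TSV or CSV) and validate it."""
    return SampleDesign(_read_table(path))


def write_design(design: SampleDesign, path) -> None:
    design.table.to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------------
# reporter-column parsing

def _reporter_columns(
    columns: list[str], design: SampleDesign, pattern: str
) -> dict[tuple[str, str], list[str]]:
    """Map each design (plex, channel) to the table columns feeding it."""
    rx = re.compile(pattern)
    known = set(design.columns)
    mapping: dict[tuple[str, str], list[str]] = {}
    for col in columns:
        m = rx.match(col)
        if not m:
            continue
        key = (m.group("plex"), m.group("channel"))
        if key not in known:
            raise DesignError(
                f"intensity column {col!r} maps to {key} which is not in the design"
            )
        mapping.setdefault(key, []).append(col)
    return mapping


def _intensity_row(
    row: pd.Series,
    mapping: dict[tuple[str, str], list[str]],
    row_no: int,
    zeros_as_missing: bool = True,
) -> dict[tuple[str, str], float]:
    out: dict[tuple[str, str], float] = {}
    for key, cols in mapping.items():
        vals = []
        for c in cols:
            tok = str(row[c]).strip()
            if tok in {"", "NaN", "nan", MISSING_TOKEN}:
                continue
            try:
                v = float(tok)
            except ValueError as exc:
                raise FormatError(
                    f"non-numeric intensity {tok!r} in column {c!r}, data row {row_no}"
                ) from exc
            if v > 0 or not zeros_as_missing:
                vals.append(v)
        # multiplicity columns are summed; unquantified cells -> missing
        out[key] = float(np.sum(vals)) if vals else np.nan
    return out


def _flag(row: pd.Series, col: str) -> bool:
    return col in row.index and str(row[col]).strip() == "+"


# ----------------------------------------------------------------------
# phosphosites

def read_phosphosites(
    path,
    design: SampleDesign,
    min_localization: float = DEFAULT_MIN_LOCALIZATION,
    reporter_pattern: str = DEFAULT_REPORTER_PATTERN,
    zeros_as_missing: bool = True,
) -> list[PhosphoSiteRecord]:
    """Read a "Phospho (STY) Sites"-style table into site records.

    Reverse-decoy and contaminant rows and sites below ``min_localization``
    are removed; the number removed per reason is logged.
    """
    df = _read_table(path)
    for col in ("Protein", "Position", "Amino acid", "Localization prob"):
        if col not in df.columns:
            raise FormatError(f"sites table missing column {col!r}")
    mapping = _reporter_columns(list(df.columns), design, reporter_pattern)
    records: list[PhosphoSiteRecord] = []
    removed = {"reverse": 0, "contaminant": 0, "localization": 0}
    for i, (_, row) in enumerate(df.iterrows(), start=1):
        if _flag(row, "Reverse"):
            removed["reverse"] += 1
            continue
        if _flag(row, "Potential contaminant") or _flag(row, "Contaminant"):
            removed["contaminant"] += 1
            continue
        prob = float(row["Localization prob"])
        if prob < min_localization:
            removed["localization"] += 1
            continue
        locus = str(row["Protein"]).strip()
        residue = str(row["Amino acid"]).strip()
        position = int(float(row["Position"]))
        records.append(
            PhosphoSiteRecord(
                site_id=f"{locus}_{residue}{position}",
                locus=locus,
                residue=residue,
                position=position,
                localization_prob=prob,
                intensities=_intensity_row(row, mapping, i, zeros_as_missing),
            )
        )
    log.info(
        "read %d sites from %s (removed: %s)",
        len(records), path, ", ".join(f"{k}={v}" for k, v in removed.items()),
    )
    return records


def read_protein_groups(
    path,
    design: SampleDesign,
    reporter_pattern: str = DEFAULT_REPORTER_PATTERN,
    zeros_as_missing: bool = True,
) -> list[ProteinGroupRecord]:
    """Read a proteinGroups-style table into protein-group records."""
    df = _read_table(path)
    id_col = next((c for c in ("Majority protein IDs", "Protein IDs", "id") if c in df.columns), None)
    if id_col is None:
        raise FormatError("protein-groups table missing a protein id column")
    mapping = _reporter_columns(list(df.columns), design, reporter_pattern)
    records: list[ProteinGroupRecord] = []
    removed = {"reverse": 0, "contaminant": 0}
    for i, (_, row) in enumerate(df.iterrows(), start=1):
        if _flag(row, "Reverse"):
            removed["reverse"] += 1
            continue
        if _flag(row, "Potential contaminant") or _flag(row, "Contaminant"):
            removed["contaminant"] += 1
            continue
        ids = [s for s in re.split(r"[;,]", str(row[id_col])) if s]
        records.append(
            ProteinGroupRecord(
                group_id=ids[0] if ids else f"group{i}",
                majority_protein_ids=ids,
                intensities=_intensity_row(row, mapping, i, zeros_as_missing),
            )
        )
    if not records:
        log.warning("protein-groups table %s yielded no records", path)
    log.info(
        "read %d protein groups from %s (removed: %s)",
        len(records), path, ", ".join(f"{k}={v}" for k, v in removed.items()),
    )
    return records


def to_matrix(records, design: SampleDesign) -> ReporterMatrix:
    """Stack records into a ReporterMatrix with columns in design order."""
    kind = "phosphosite" if records and isinstance(records[0], PhosphoSiteRecord) else "protein"
    cols = design.columns
    ids = []
    data = np.full((len(records), len(cols)), np.nan)
    for r, rec in enumerate(records):
        ids.append(rec.site_id if isinstance(rec, PhosphoSiteRecord) else rec.group_id)
        for c, key in enumerate(cols):
            if key in rec.intensities:
                data[r, c] = rec.intensities[key]
    if len(set(ids)) != len(ids):
        raise FormatError("duplicate feature ids in records")
    return make_matrix(data, ids, cols, kind)


# ----------------------------------------------------------------------
# matrix / results round-trip

def write_matrix(matrix: ReporterMatrix, path) -> None:
    """Write a ReporterMatrix as TSV (columns named ``plex:channel``)."""
    df = matrix.values.copy()
    df.columns = [f"{p}:{c}" for p, c in df.columns]
    df.insert(0, "feature_kind", matrix.feature_kind)
    df.to_csv(path, sep="\t", na_rep=MISSING_TOKEN, index=True, index_label="feature_id")


def read_matrix(path) -> ReporterMatrix:
    df = pd.read_csv(path, sep="\t", index_col="feature_id", na_values=[MISSING_TOKEN], keep_default_na=False)
    kind = str(df["feature_kind"].iloc[0]) if len(df) else "protein"
    df = df.drop(columns=["feature_kind"])
    cols = [tuple(c.split(":", 1)) for c in df.columns]
    return make_matrix(df.to_numpy(dtype=float), list(df.index.astype(str)), cols, kind)


def write_results(df: pd.DataFrame, path) -> None:
    """Write a results table with a stable header and NA marking."""
    df.to_csv(path, sep="\t", na_rep=MISSING_TOKEN, index=False)


def read_contrasts_yaml(path) -> list[Contrast]:
    import yaml

    with open(path) as fh:
        entries = yaml.safe_load(fh)
    return [Contrast(name=c["name"], group_a=list(c["group_a"]), group_b=list(c["group_b"])) for c in entries]


# ----------------------------------------------------------------------
# MaxQuant-dialect writers (used by the simulator so that generated data
# exercises the same readers as real exports)

def write_sites_table(matrix: ReporterMatrix, path, localization_prob: float = 1.0) -> None:
    """Write a phosphosite ReporterMatrix in the sites-table dialect."""
    rows = []
    rx = re.compile(r"^(?P<locus>.+)_(?P<res>[STY])(?P<pos>\d+)$")
    for fid in matrix.feature_ids:
        m = rx.match(fid)
        if not m:
            raise ValueError(f"feature id {fid!r} is not a <locus>_<residue><position> site id")
        row = {
            "Protein": m.group("locus"),
            "Position": m.group("pos"),
            "Amino acid": m.group("res"),
            "Localization prob": localization_prob,
            "Reverse": "",
            "Potential contaminant": "",
        }
        for (plex, chan), v in matrix.values.loc[fid].items():
            row[f"Reporter intensity corrected {chan} {plex}"] = "" if pd.isna(v) else v
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_protein_groups_table(matrix: ReporterMatrix, path) -> None:
    rows = []
    for fid in matrix.feature_ids:
        row = {
            "Majority protein IDs": fid,
            "Reverse": "",
            "Potential contaminant": "",
        }
        for (plex, chan), v in matrix.values.loc[fid].items():
            row[f"Reporter intensity corrected {chan} {plex}"] = "" if pd.isna(v) else v
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
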