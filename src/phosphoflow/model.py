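"""Core data model for the multi-plex TMT pipeline.

The central objects are :class:`SampleDesign` (which channel of which plex
holds which biological sample) and :class:`ReporterMatrix` (features x
channels reporter intensities).  Missing intensities are ``NaN`` and are
distinct from measured zero throughout the pipeline.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

GENOTYPES = ("WT", "quad")
TREATMENTS = ("mock", "flg22")
TIMES_MIN = (3, 15)
#: label used on pooled-reference channels for fields that do not apply
POOL = "pool"

DESIGN_COLUMNS = [
    "sample_id",
    "genotype",
    "treatment",
    "time_min",
    "replicate",
    "plex_id",
    "channel_id",
    "is_reference",
]


class DesignError(ValueError):
    """Raised when a sample-design table violates its invariants."""


class FormatError(ValueError):
    """Raised when an input file does not match the expected schema."""


@dataclass
class SampleDesign:
    """Validated sample-design table.

    One row per (plex, channel).  Pooled-reference channels carry
    ``is_reference=True`` and use the placeholder ``"pool"`` / 0 for the
    biological factors, which only apply to real samples.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in DESIGN_COLUMNS if c not in t.columns]
        if missing:
            raise FormatError(f"design table missing column(s): {', '.join(missing)}")
        t = t.copy()
        t["time_min"] = t["time_min"].astype(int)
        t["replicate"] = t["replicate"].astype(int)
        t["plex_id"] = t["plex_id"].astype(str)
        t["channel_id"] = t["channel_id"].astype(str)
        t["is_reference"] = t["is_reference"].map(_parse_bool)
        dup = t.duplicated(subset=["plex_id", "channel_id"])
        if dup.any():
            pair = t.loc[dup.idxmax(), ["plex_id", "channel_id"]].tolist()
            raise DesignError(f"duplicated (plex, channel) pair: {tuple(pair)}")
        if t["sample_id"].duplicated().any():
            raise DesignError("duplicated sample_id in design")
        samples = t[~t["is_reference"]]
        bad_g = set(samples["genotype"]) - set(GENOTYPES)
        if bad_g:
            raise DesignError(f"unknown genotype(s): {sorted(bad_g)}")
        bad_t = set(samples["treatment"]) - set(TREATMENTS)
        if bad_t:
            raise DesignError(f"unknown treatment(s): {sorted(bad_t)}")
        bad_time = set(samples["time_min"]) - set(TIMES_MIN)
        if bad_time:
            raise DesignError(f"unknown time_min value(s): {sorted(bad_time)}")
        for plex, grp in t.groupby("plex_id"):
            if not grp["is_reference"].any():
                raise DesignError(f"plex {plex!r} has no reference channel")
        self.table = t.reset_index(drop=True)

    # ------------------------------------------------------------------
    @property
    def columns(self) -> list[tuple[str, str]]:
        """(plex_id, channel_id) pairs in design order."""
        return list(zip(self.table["plex_id"], self.table["channel_id"]))

    @property
    def plexes(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.table["plex_id"]:
            seen.setdefault(p)
        return list(seen)

    @property
    def samples(self) -> pd.DataFrame:
        """Non-reference rows."""
        return self.table[~self.table["is_reference"]]

    def reference_columns(self, plex_id: str) -> list[tuple[str, str]]:
        t = self.table
        sel = t[(t["plex_id"] == plex_id) & t["is_reference"]]
        return list(zip(sel["plex_id"], sel["channel_id"]))

    def column_of(self, sample_id: str) -> tuple[str, str]:
        row = self.table[self.table["sample_id"] == sample_id]
        if row.empty:
            raise DesignError(f"unknown sample_id {sample_id!r}")
        return (row["plex_id"].iloc[0], row["channel_id"].iloc[0])

    def sample_ids(
        self,
        genotype: str | None = None,
        treatment: str | None = None,
        time_min: int | None = None,
    ) -> list[str]:
        s = self.samples
        if genotype is not None:
            s = s[s["genotype"] == genotype]
        if treatment is not None:
            s = s[s["treatment"] == treatment]
        if time_min is not None:
            s = s[s["time_min"] == int(time_min)]
        return list(s["sample_id"])

    def __len__(self) -> int:
        return len(self.table)


def _parse_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    if isinstance(v, (int, np.integer, float)):
        return bool(int(v))
    s = str(v).strip().lower()
    if s in {"true", "t", "yes", "y", "1", "+"}:
        return True
    if s in {"false", "f", "no", "n", "0", "-", ""}:
        return False
    raise FormatError(f"cannot interpret {v!r} as boolean")


@dataclass
class ReporterMatrix:
    """Features x channels intensity matrix.

    ``values`` is a DataFrame indexed by feature id with a two-level
    (plex_id, channel_id) column index ordered like the design.  Values are
    non-negative floats; NaN marks a missing (unquantified) cell.
    """

    values: pd.DataFrame
    feature_kind: str  # "protein" or "phosphosite"

    def __post_init__(self) -> None:
        if self.feature_kind not in ("protein", "phosphosite"):
            raise ValueError(f"bad feature_kind {self.feature_kind!r}")
        v = self.values
        if not isinstance(v.columns, pd.MultiIndex) or v.columns.nlevels != 2:
            raise ValueError("ReporterMatrix columns must be (plex_id, channel_id) pairs")
        with np.errstate(invalid="ignore"):
            if (v.to_numpy(dtype=float) < 0).any():
                raise ValueError("negative reporter intensities")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def columns(self) -> list[tuple[str, str]]:
        return list(self.values.columns)

    def copy(self) -> "ReporterMatrix":
        return ReporterMatrix(self.values.copy(), self.feature_kind)


def make_matrix(
    values: np.ndarray | pd.DataFrame,
    feature_ids: Iterable[str],
    columns: Iterable[tuple[str, str]],
    feature_kind: str,
) -> ReporterMatrix:
    cols = pd.MultiIndex.from_tuples(list(columns), names=["plex_id", "channel_id"])
    df = pd.DataFrame(np.asarray(values, dtype=float), index=list(feature_ids), columns=cols)
    df.index.name = "feature_id"
    return ReporterMatrix(df, feature_kind)


@dataclass
class PhosphoSiteRecord:
    """One phosphosite with per-channel reporter intensities."""

    site_id: str
    locus: str
    residue: str
    position: int
    localization_prob: float
    intensities: dict[tuple[str, str], float]
    reverse_flag: bool = False
    contaminant_flag: bool = False

    def __post_init__(self) -> None:
        if self.residue not in ("S", "T", "Y"):
            raise ValueError(f"residue must be S/T/Y, got {self.residue!r}")
        if not (0.0 <= self.localization_prob <= 1.0):
            raise ValueError("localization_prob outside [0, 1]")
        if self.position < 1:
            raise ValueError("position must be 1-based positive")


@dataclass
class ProteinGroupRecord:
    """One protein group with per-channel reporter intensities."""

    group_id: str
    majority_protein_ids: list[str]
    intensities: dict[tuple[str, str], float]
    reverse_flag: bool = False
    contaminant_flag: bool = False


@dataclass
class NormalizationFactors:
    """Scaling factors produced by the two-stage normalization.

    ``loading_factor`` maps (plex, channel) to the sample-loading scale;
    ``irs_factor`` is a feature x plex table of internal-reference scales
    (NaN for features not cross-plex comparable).
    """

    loading_factor: dict[tuple[str, str], float] = field(default_factory=dict)
    irs_factor: pd.DataFrame | None = None
    not_cross_plex: list[str] = field(default_factory=list)


@dataclass
class Contrast:
    """Two-group comparison (group_a vs group_b, e.g. flg22 vs mock)."""

    name: str
    group_a: list[str]
    group_b: list[str]

    def __post_init__(self) -> None:
        overlap = set(self.group_a) & set(self.group_b)
        if overlap:
            raise ValueError(f"contrast groups overlap: {sorted(overlap)}")
        if len(self.group_a) < 2 or len(self.group_b) < 2:
            raise ValueError("each contrast group needs >= 2 samples")
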