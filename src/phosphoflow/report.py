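"""Post-statistics classification and run reports.

Covers three summaries the differential results feed into:

* per-protein direction calls (all significant sites up, all down, or
  mixed -> "both"),
* G-protein dependence of phosphosite changes: a WT-significant site is
  called dependent unless the same site is significant with the same sign
  in the quad mutant, and the dependent fraction is reported per scope,
* cross-dataset overlap of phosphoproteins (how many loci appear in k or
  more published lists).

``write_report`` emits the QC artifacts of a run: p-/q-value histograms,
volcano-plot tables, per-contrast counts and a machine-readable summary.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class DependenceSummary:
    scope: str
    n_wt_sig_sites: int
    n_also_quad_sig: int
    dependent_fraction: float | None

    def to_dict(self) -> dict:
        return self.__dict__.copy()


@dataclass
class OverlapSummary:
    dataset_names: list[str]
    presence: pd.DataFrame  # loci x datasets, boolean
    n_in_k_or_more: dict[int, int] = field(default_factory=dict)


# ----------------------------------------------------------------------

def _locus_of(site_id: str) -> str:
    return site_id.rsplit("_", 1)[0]


def call_protein_direction(
    site_results: pd.DataFrame, site_to_locus: dict[str, str] | None = None
) -> pd.DataFrame:
    """Collapse per-site calls to per-protein direction calls.

    ``site_results`` needs columns feature_id, significant, direction (and
    optionally contrast; calls are made per contrast).  Sites map to loci
    via ``site_to_locus`` or, by default, by stripping the residue suffix
    from ``<locus>_<residue><position>`` ids.
    """
    df = site_results.copy()
    if site_to_locus is None:
        df["locus"] = df["feature_id"].map(_locus_of)
    else:
        unknown = set(df["feature_id"]) - set(site_to_locus)
        if unknown:
            raise KeyError(f"site(s) with unknown locus: {sorted(unknown)[:5]}")
        df["locus"] = df["feature_id"].map(site_to_locus)
    if "contrast" not in df.columns:
        df["contrast"] = "all"
    rows = []
    for (contrast, locus), grp in df.groupby(["contrast", "locus"], sort=True):
        sig = grp[grp["significant"]]
        up = (sig["direction"] == "up").any()
        down = (sig["direction"] == "down").any()
        call = "both" if (up and down) else "increased" if up else "decreased" if down else "none"
        rows.append({"contrast": contrast, "locus": locus, "call": call,
                     "n_sites": len(grp), "n_significant": len(sig)})
    return pd.DataFrame(rows)


def dependence_fraction(
    wt_results: pd.DataFrame,
    quad_results: pd.DataFrame,
    scope_loci: set[str] | None = None,
    scope: str = "all",
    count_undetected_as_dependent: bool = True,
) -> DependenceSummary:
    """Fraction of WT-significant sites whose change requires G proteins.

    A WT-significant site counts as G-protein dependent unless the same
    site is significant with the same direction in the quad mutant.  With
    ``count_undetected_as_dependent=False``, WT sites never tested in the
    quad experiment are excluded from the denominator instead of counting
    as dependent.
    """
    wt = wt_results[wt_results["significant"]].set_index("feature_id")
    if scope_loci is not None:
        upper = {str(x).upper() for x in scope_loci}
        wt = wt[[(_locus_of(f).upper() in upper) for f in wt.index]]
    if not count_undetected_as_dependent:
        wt = wt[wt.index.isin(quad_results["feature_id"])]
    quad_sig = quad_results[quad_results["significant"]].set_index("feature_id")
    n_wt = len(wt)
    if n_wt == 0:
        return DependenceSummary(scope, 0, 0, None)
    shared = wt.index.intersection(quad_sig.index)
    same_sign = int((wt.loc[shared, "direction"] == quad_sig.loc[shared, "direction"]).sum())
    return DependenceSummary(
        scope=scope,
        n_wt_sig_sites=n_wt,
        n_also_quad_sig=same_sign,
        dependent_fraction=(n_wt - same_sign) / n_wt,
    )


def dataset_overlap(protein_lists: dict[str, set[str]]) -> OverlapSummary:
    """Presence matrix and >=k counts for phosphoprotein lists."""
    names = list(protein_lists)
    if len(names) != len(set(names)):
        raise ValueError("duplicate dataset names")
    if len(names) < 2:
        raise ValueError("need at least two datasets to overlap")
    loci = sorted(set().union(*protein_lists.values()))
    presence = pd.DataFrame(
        {name: [locus in protein_lists[name] for locus in loci] for name in names},
        index=loci,
    )
    counts = presence.sum(axis=1)
    n_in_k = {k: int((counts >= k).sum()) for k in range(1, len(names) + 1)}
    return OverlapSummary(dataset_names=names, presence=presence, n_in_k_or_more=n_in_k)


# ----------------------------------------------------------------------

def write_report(
    out_dir,
    contrast_results: dict[str, pd.DataFrame],
    norm_report=None,
    node_table: pd.DataFrame | None = None,
    enrichments: list | None = None,
    dependence: list[DependenceSummary] | None = None,
    config: dict | None = None,
) -> Path:
    """Write QC figures, result tables and a machine-readable run summary."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    sig_counts = {}
    for name, res in contrast_results.items():
        res.to_csv(out / f"results_{name}.tsv", sep="\t", index=False, na_rep="NA")
        sig_counts[name] = int(res["significant"].sum()) if len(res) else 0
        volcano = pd.DataFrame(
            {
                "feature_id": res.get("feature_id", pd.Series(dtype=str)),
                "log2fc": res.get("log2fc", pd.Series(dtype=float)),
                "neg_log10_q": -np.log10(res["q_value"].clip(lower=np.finfo(float).tiny))
                if len(res) else pd.Series(dtype=float),
                "significant": res.get("significant", pd.Series(dtype=bool)),
            }
        )
        volcano.to_csv(out / f"volcano_{name}.tsv", sep="\t", index=False, na_rep="NA")
        if len(res):
            fig, axes = plt.subplots(1, 2, figsize=(8, 3))
            axes[0].hist(res["p_value"], bins=20, range=(0, 1))
            axes[0].set_xlabel("p-value")
            axes[1].hist(res["q_value"], bins=20, range=(0, 1))
            axes[1].set_xlabel("q-value")
            fig.suptitle(name)
            fig.tight_layout()
            fig.savefig(out / f"pq_hist_{name}.png", dpi=100)
            plt.close(fig)

    if norm_report is not None:
        norm_report.to_frame().to_csv(out / "normalization_report.tsv", sep="\t", index=False, na_rep="NA")
    if node_table is not None:
        node_table.to_csv(out / "network_nodes.tsv", sep="\t", index=False)
    if enrichments:
        pd.DataFrame([e.to_dict() for e in enrichments]).to_csv(
            out / "hub_enrichment.tsv", sep="\t", index=False, na_rep="NA"
        )
    if dependence:
        pd.DataFrame([d.to_dict() for d in dependence]).to_csv(
            out / "dependence_summary.tsv", sep="\t", index=False, na_rep="NA"
        )

    summary = {
        "significant_per_contrast": sig_counts,
        "config": config or {},
    }
    summary_path = out / "run_summary.json"
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary_path


def read_run_summary(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
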