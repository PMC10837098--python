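"""Synthetic multi-plex TMT data and annotated PPI networks with ground truth.

The generator emulates the structure of a two-genotype (WT vs G-protein
quadruple mutant) x two-treatment (mock vs flg22) x two-time (3, 15 min)
phosphoproteomics study quantified on 16-plex TMT with one pooled-reference
channel per plex.  Reporter intensities are simulated as counts
(Poisson or negative binomial) on top of multiplicative per-channel loading
factors and per-(plex, feature) batch effects -- exactly the nuisance
structure the sample-loading + internal-reference normalization stages are
designed to remove.  Networks are scale-free (preferential attachment) with
an optional planted association between the phospho label and node degree.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .model import GENOTYPES, POOL, TIMES_MIN, TREATMENTS, ReporterMatrix, SampleDesign, make_matrix


@dataclass
class SimulationParams:
    """Knobs of the reporter-count simulator.

    Intensity units are log2 of a count-like reporter intensity;
    ``baseline_log2_mean=10`` places the median feature near 2**10 = 1024
    counts.  ``frac_quad_suppressed`` is the fraction of WT-differential
    features whose flg22 effect is absent in the quad mutant, i.e. the
    planted G-protein-dependent fraction.
    """

    n_features: int = 2000
    n_replicates: int = 3
    baseline_log2_mean: float = 10.0
    baseline_log2_sd: float = 1.5
    frac_differential: float = 0.1
    effect_log2fc_mean: float = 1.0
    effect_log2fc_sd: float = 0.25
    frac_down: float = 0.0
    frac_quad_suppressed: float = 0.95
    loading_factor_range: tuple[float, float] = (0.7, 1.3)
    plex_batch_log2_sd: float = 0.5
    noise_model: str = "poisson"  # or "negative_binomial"
    nb_dispersion: float = 0.05
    feature_kind: str = "phosphosite"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_differential", "frac_quad_suppressed", "frac_down"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.loading_factor_range
        if not (0 < lo <= hi):
            raise ValueError("loading_factor_range must be a well-ordered positive pair")
        if self.noise_model not in ("poisson", "negative_binomial"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        if self.noise_model == "negative_binomial" and self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")


@dataclass
class GroundTruth:
    """What was planted: ids, effects and nuisance factors."""

    differential_ids: set[str] = field(default_factory=set)
    true_log2fc: dict[str, float] = field(default_factory=dict)
    quad_suppressed_ids: set[str] = field(default_factory=set)
    loading_factors: dict[tuple[str, str], float] = field(default_factory=dict)
    batch_factors: pd.DataFrame | None = None  # features x plexes
    network_phospho_bias: float | None = None
    phospho_ids: set[str] = field(default_factory=set)


def simulate_design(n_replicates: int = 3, plex_size: int = 16) -> SampleDesign:
    """Lay out the full factorial design across TMT plexes.

    Each plex holds ``plex_size - 1`` samples plus one pooled-reference
    channel on the last channel.  Samples are interleaved across plexes so
    every plex carries a balanced mix of conditions, as a blocked design
    would.  Deterministic given the inputs.
    """
    if plex_size < 3:
        raise ValueError("plex_size must be >= 3")
    samples = [
        (g, t, tm, r)
        for g in GENOTYPES
        for t in TREATMENTS
        for tm in TIMES_MIN
        for r in range(1, n_replicates + 1)
    ]
    per_plex = plex_size - 1
    n_plex = math.ceil(len(samples) / per_plex)
    rows = []
    next_channel = {p: 1 for p in range(n_plex)}
    for i, (g, t, tm, r) in enumerate(samples):
        p = i % n_plex
        chan = next_channel[p]
        next_channel[p] += 1
        rows.append(
            dict(
                sample_id=f"{g}_{t}_{tm}min_r{r}",
                genotype=g,
                treatment=t,
                time_min=tm,
                replicate=r,
                plex_id=f"plex{p + 1}",
                channel_id=str(chan),
                is_reference=False,
            )
        )
    for p in range(n_plex):
        rows.append(
            dict(
                sample_id=f"ref_plex{p + 1}",
                genotype=POOL,
                treatment=POOL,
                time_min=0,
                replicate=0,
                plex_id=f"plex{p + 1}",
                channel_id=str(plex_size),
                is_reference=True,
            )
        )
    return SampleDesign(pd.DataFrame(rows))


def _feature_ids(n: int, kind: str, rng: np.random.Generator) -> list[str]:
    if kind == "protein":
        return [f"AT{1 + i % 5}G{10 + i:05d}" for i in range(n)]
    residues = rng.choice(np.array(["S", "T", "Y"]), size=n, p=[0.75, 0.2, 0.05])
    positions = rng.integers(1, 1200, size=n)
    return [
        f"AT{1 + i % 5}G{10 + i:05d}_{residues[i]}{positions[i]}" for i in range(n)
    ]


def simulate_reporter_data(
    design: SampleDesign, params: SimulationParams
) -> tuple[ReporterMatrix, GroundTruth]:
    """Draw a reporter-count matrix for ``design`` with known ground truth.

    Per feature j the biological expectation of sample i is
    ``2**b_j * 2**(lfc_j * flg22_i * active_ij)`` where ``active_ij`` is 0
    for quad samples of suppressed features.  The pooled-reference channel
    of each plex has expectation equal to the mean of the sample
    expectations in that plex.  Channel loading factors (uniform on
    ``loading_factor_range``) and per-(plex, feature) log-normal batch
    factors multiply all expectations before counts are drawn.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_features
    ids = _feature_ids(n, params.feature_kind, rng)

    baseline = 2.0 ** rng.normal(params.baseline_log2_mean, params.baseline_log2_sd, size=n)
    n_diff = int(round(params.frac_differential * n))
    diff_idx = rng.choice(n, size=n_diff, replace=False)
    lfc = np.zeros(n)
    if n_diff:
        eff = rng.normal(params.effect_log2fc_mean, params.effect_log2fc_sd, size=n_diff)
        down = rng.random(n_diff) < params.frac_down
        eff[down] *= -1.0
        lfc[diff_idx] = eff
    n_sup = int(round(params.frac_quad_suppressed * n_diff))
    sup_idx = rng.choice(diff_idx, size=n_sup, replace=False) if n_sup else np.array([], dtype=int)
    suppressed = np.zeros(n, dtype=bool)
    suppressed[sup_idx] = True

    cols = design.columns
    t = design.table
    mu = np.empty((n, len(cols)))
    # biological expectations for real samples
    for c, row in enumerate(t.itertuples(index=False)):
        if row.is_reference:
            continue
        effect = lfc.copy()
        if row.treatment != "flg22":
            effect[:] = 0.0
        elif row.genotype == "quad":
            effect = np.where(suppressed, 0.0, effect)
        mu[:, c] = baseline * 2.0 ** effect
    # pooled reference = per-plex mean of sample expectations
    for plex in design.plexes:
        sample_cols = [
            c for c, row in enumerate(t.itertuples(index=False))
            if row.plex_id == plex and not row.is_reference
        ]
        ref_cols = [
            c for c, row in enumerate(t.itertuples(index=False))
            if row.plex_id == plex and row.is_reference
        ]
        plex_mean = mu[:, sample_cols].mean(axis=1)
        for c in ref_cols:
            mu[:, c] = plex_mean

    lo, hi = params.loading_factor_range
    loading = rng.uniform(lo, hi, size=len(cols))
    plexes = design.plexes
    batch = 2.0 ** rng.normal(0.0, params.plex_batch_log2_sd, size=(n, len(plexes)))
    plex_of_col = np.array([plexes.index(p) for p, _ in cols])
    lam = mu * loading[None, :] * batch[:, plex_of_col]

    if params.noise_model == "poisson":
        counts = rng.poisson(lam).astype(float)
    else:
        shape = 1.0 / params.nb_dispersion
        lam_g = rng.gamma(shape, lam / shape)
        counts = rng.poisson(lam_g).astype(float)

    matrix = make_matrix(counts, ids, cols, params.feature_kind)
    truth = GroundTruth(
        differential_ids={ids[i] for i in diff_idx},
        true_log2fc={ids[i]: float(lfc[i]) for i in diff_idx},
        quad_suppressed_ids={ids[i] for i in sup_idx},
        loading_factors=dict(zip(cols, loading.astype(float))),
        batch_factors=pd.DataFrame(batch, index=ids, columns=plexes),
    )
    return matrix, truth


# ----------------------------------------------------------------------
# networks

def simulate_network(
    n_nodes: int,
    attachment_m: int = 2,
    frac_phospho: float = 0.3,
    phospho_degree_bias: float = 0.0,
    frac_immune: float = 0.05,
    frac_ginteractome: float = 0.05,
    frac_effector: float = 0.02,
    seed: int = 0,
) -> tuple[nx.Graph, GroundTruth]:
    """Scale-free PPI network with planted phospho-degree association.

    The phospho label of a node with degree d is Bernoulli with probability
    ``expit(alpha + phospho_degree_bias * log(d))`` where ``alpha`` is
    solved so the expected phospho fraction equals ``frac_phospho``.  Other
    categories are independent of topology.
    """
    if attachment_m < 1 or n_nodes <= attachment_m:
        raise ValueError("need n_nodes > attachment_m >= 1")
    for name, v in (("frac_phospho", frac_phospho), ("frac_immune", frac_immune),
                    ("frac_ginteractome", frac_ginteractome), ("frac_effector", frac_effector)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    if phospho_degree_bias != 0.0 and frac_phospho in (0.0, 1.0):
        raise ValueError("frac_phospho of exactly 0 or 1 is infeasible with a nonzero degree bias")

    g = nx.barabasi_albert_graph(n_nodes, attachment_m, seed=seed)
    mapping = {i: f"AT{1 + i % 5}G{10 + i:05d}" for i in g.nodes}
    g = nx.relabel_nodes(g, mapping)
    rng = np.random.default_rng(seed)

    deg = np.array([g.degree(v) for v in g.nodes], dtype=float)
    logd = np.log(np.maximum(deg, 1.0))
    if frac_phospho in (0.0, 1.0):
        probs = np.full(n_nodes, frac_phospho)
    else:
        def mean_prob(alpha: float) -> float:
            return float(expit(alpha + phospho_degree_bias * logd).mean()) - frac_phospho

        alpha = brentq(mean_prob, -60.0, 60.0)
        probs = expit(alpha + phospho_degree_bias * logd)
    phospho = rng.random(n_nodes) < probs
    immune = rng.random(n_nodes) < frac_immune
    gint = rng.random(n_nodes) < frac_ginteractome
    effector = rng.random(n_nodes) < frac_effector

    for i, node in enumerate(g.nodes):
        g.nodes[node]["phospho"] = bool(phospho[i])
        g.nodes[node]["immune"] = bool(immune[i])
        g.nodes[node]["g_interactome"] = bool(gint[i])
        g.nodes[node]["effector"] = bool(effector[i])
    for _, _, attrs in g.edges(data=True):
        attrs["sources"] = frozenset({"synthetic"})

    truth = GroundTruth(
        network_phospho_bias=phospho_degree_bias,
        phospho_ids={node for i, node in enumerate(g.nodes) if phospho[i]},
    )
    return g, truth


def write_network(g: nx.Graph, edges_path, categories_path) -> None:
    """Write the graph as a 2-column edge TSV plus a node-category TSV."""
    edges = pd.DataFrame(
        [(a, b, ";".join(sorted(attrs.get("sources", {"synthetic"}))))
         for a, b, attrs in g.edges(data=True)],
        columns=["node_a", "node_b", "source"],
    )
    edges.to_csv(edges_path, sep="\t", index=False)
    nodes = pd.DataFrame(
        [
            (v, int(d.get("phospho", False)), int(d.get("immune", False)),
             int(d.get("g_interactome", False)), int(d.get("effector", False)))
            for v, d in g.nodes(data=True)
        ],
        columns=["locus", "phospho", "immune", "g_interactome", "effector"],
    )
    nodes.to_csv(categories_path, sep="\t", index=False)
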