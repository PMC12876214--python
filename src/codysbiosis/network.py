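"""Cross-kingdom correlation network inference and topology metrics.

The central procedure: within one group of samples, compute the Spearman
rank correlation between every (bacterial genus, fungal genus) pair of
relative abundances, adjust the p-values with the Benjamini-Hochberg
step-up across all tested cross-kingdom pairs, and keep edges with
``|rho| >= rho_min`` (default 0.6) and ``q < q_alpha`` (default 0.05).
Only bacterium-fungus pairs are tested: within-kingdom correlations are
excluded by construction.

The resulting signed network is summarised by its edge-sign composition.
The *positivity fraction* (positive edges / all edges) operationalises
"co-dysbiosis": a healthy-like community is rich in negative (competitive)
cross-kingdom edges, while a dysbiotic one collapses toward exclusively
positive (cooperative) edges.

Spearman p-values use the t approximation
``t = |rho| sqrt((n - 2) / (1 - rho^2))`` with n - 2 df, doubled; this
reproduces the printed anchors of the modelled study at 4-decimal rounding.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .core_io import (
    AbundanceTable,
    PipelineConfig,
    SampleMetadata,
    prevalence_filter,
)

logger = logging.getLogger(__name__)

POSITIVE, NEGATIVE = "positive", "negative"

#: Gephi-style display conventions written into GraphML exports
NODE_COLOR = {"bacteria": "yellow", "fungi": "green"}
NODE_SHAPE = {"bacteria": "circle", "fungi": "square"}
EDGE_COLOR = {POSITIVE: "red", NEGATIVE: "blue"}


class ConstantInputError(ValueError):
    """Spearman correlation is undefined for a constant vector."""


def spearman_rho(x, y) -> float:
    """Spearman rank correlation with midranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    for name, v in (("x", x), ("y", y)):
        if len(np.unique(v)) < 2:
            raise ConstantInputError(
                f"undefined correlation: {name} is constant"
            )
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    r = np.corrcoef(rx, ry)[0, 1]
    return float(np.clip(r, -1.0, 1.0))


def spearman_pvalue(rho: float, n: int, _clip_warn: bool = True) -> float:
    """Two-sided p-value for a Spearman coefficient at sample size ``n``.

    Uses ``t = |rho| sqrt((n-2)/(1-rho^2))`` referred to the t distribution
    with ``n - 2`` df, doubled.  ``|rho| = 1`` (where the t statistic
    diverges) returns the exact-permutation floor ``2/n!``.
    """
    if n < 4:
        raise ValueError("need n >= 4 for a Spearman p-value")
    if abs(rho) > 1:
        raise ValueError("|rho| must be <= 1")
    if abs(rho) == 1.0:
        if _clip_warn:
            logger.info("|rho| = 1: returning exact-permutation floor 2/n!")
        return 2.0 / math.factorial(n)
    t = abs(rho) * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * stats.t.sf(t, df=n - 2)
    return float(max(min(p, 1.0), 2.0 / math.factorial(n)))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values),
    ``q_(i) = min_{j>=i} p_(j) m / j`` mapped back to input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# network data model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationEdge:
    bacterial_taxon: str
    fungal_taxon: str
    rho: float
    p_raw: float
    q_bh: float

    @property
    def sign(self) -> str:
        return POSITIVE if self.rho > 0 else NEGATIVE


@dataclass
class CrossKingdomNetwork:
    """Signed, FDR-filtered bacterium-fungus correlation network."""

    group: str
    nodes: pd.DataFrame  # index taxon; columns kingdom, mean_abundance, degree
    edges: list
    rho_min: float
    q_alpha: float
    prevalence_min: float
    n_pairs_tested: int
    n_samples: int
    skipped_constant: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for e in self.edges:
            if abs(e.rho) < self.rho_min or e.q_bh >= self.q_alpha:
                raise ValueError("edge violates the network thresholds")
        deg = {}
        for e in self.edges:
            deg[e.bacterial_taxon] = deg.get(e.bacterial_taxon, 0) + 1
            deg[e.fungal_taxon] = deg.get(e.fungal_taxon, 0) + 1
        for t, row in self.nodes.iterrows():
            if int(row["degree"]) != deg.get(t, 0):
                raise ValueError(f"degree mismatch for node {t!r}")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_frame(self) -> pd.DataFrame:
        cols = ["bacterial_taxon", "fungal_taxon", "rho", "p_raw", "q_bh",
                "sign"]
        return pd.DataFrame(
            [{
                "bacterial_taxon": e.bacterial_taxon,
                "fungal_taxon": e.fungal_taxon,
                "rho": e.rho, "p_raw": e.p_raw, "q_bh": e.q_bh,
                "sign": e.sign,
            } for e in self.edges],
            columns=cols,
        )

    def edge_pairs(self) -> set:
        return {(e.bacterial_taxon, e.fungal_taxon) for e in self.edges}


@dataclass
class NetworkSummary:
    """Edge-sign composition and hub ranking of one network.

    ``positivity_fraction`` — positive edges over all edges — is the
    co-dysbiosis index; it is undefined (``None`` with ``undefined=True``)
    for an empty network.
    """

    group: str
    n_edges: int
    n_positive: int
    n_negative: int
    positivity_fraction: float | None
    undefined: bool
    hubs: list
    degree_by_sign: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "n_edges": self.n_edges,
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
            "positivity_fraction": self.positivity_fraction,
            "undefined": self.undefined,
            "hubs": [list(h) for h in self.hubs],
        }


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

class CrossKingdomNetworkInference(BaseEstimator):
    """Estimator building one group's cross-kingdom correlation network.

    Parameters mirror :class:`~codysbiosis.core_io.PipelineConfig`:
    ``rho_min`` (minimum |Spearman|), ``q_alpha`` (BH q cutoff, the FDR
    family being all cross-kingdom pairs tested within the group) and
    ``prevalence_min`` (taxa must be detected in at least this fraction of
    the group's samples; 0 disables).

    Fitted attributes: ``network_`` (:class:`CrossKingdomNetwork`) and
    ``summary_`` (:class:`NetworkSummary`).
    """

    def __init__(self, rho_min: float = 0.6, q_alpha: float = 0.05,
                 prevalence_min: float = 0.25, n_hubs: int = 5):
        self.rho_min = rho_min
        self.q_alpha = q_alpha
        self.prevalence_min = prevalence_min
        self.n_hubs = n_hubs

    def fit(self, table: AbundanceTable, metadata: SampleMetadata | None = None,
            group: str | None = None) -> "CrossKingdomNetworkInference":
        if not table.normalized:
            raise ValueError("network inference expects a normalized table")
        if metadata is not None and group is not None:
            samples = [s for s in metadata.samples_in(group)
                       if s in table.data.index]
            sub = table.subset(samples=samples)
        else:
            group = group or "all"
            sub = table
        if sub.n_samples < 4:
            raise ValueError("need at least 4 samples for network inference")
        sub = prevalence_filter(sub, self.prevalence_min)

        bact = sub.taxa_of("bacteria")
        fung = sub.taxa_of("fungi")
        n = sub.n_samples

        # midranks once per taxon; drop constant taxa with a log entry
        skipped = []
        ranks = {}
        for t in bact + fung:
            col = sub.data[t].values
            if len(np.unique(col)) < 2:
                skipped.append(t)
                continue
            ranks[t] = stats.rankdata(col)
        bact = [t for t in bact if t in ranks]
        fung = [t for t in fung if t in ranks]
        if skipped:
            logger.info("skipped %d constant taxa: %s", len(skipped), skipped)

        records = []
        if bact and fung:
            rb = np.column_stack([ranks[t] for t in bact])
            rf = np.column_stack([ranks[t] for t in fung])
            rb = (rb - rb.mean(axis=0)) / rb.std(axis=0)
            rf = (rf - rf.mean(axis=0)) / rf.std(axis=0)
            rho = np.clip(rb.T @ rf / n, -1.0, 1.0)
            for i, b in enumerate(bact):
                for j, f in enumerate(fung):
                    records.append((b, f, rho[i, j],
                                    spearman_pvalue(rho[i, j], n,
                                                    _clip_warn=False)))
        n_pairs = len(records)
        if n_pairs == 0:
            logger.info("group %s: zero eligible cross-kingdom pairs", group)
            edges = []
        else:
            qvals = bh_adjust([r[3] for r in records])
            edges = [
                CorrelationEdge(b, f, float(r), float(p), float(q))
                for (b, f, r, p), q in zip(records, qvals)
                if abs(r) >= self.rho_min and q < self.q_alpha
            ]

        deg = {}
        for e in edges:
            deg[e.bacterial_taxon] = deg.get(e.bacterial_taxon, 0) + 1
            deg[e.fungal_taxon] = deg.get(e.fungal_taxon, 0) + 1
        node_ids = sorted(deg)
        nodes = pd.DataFrame(
            {
                "kingdom": [sub.kingdom[t] for t in node_ids],
                "mean_abundance": [float(sub.data[t].mean()) for t in node_ids],
                "degree": [deg[t] for t in node_ids],
            },
            index=pd.Index(node_ids, name="taxon"),
        )
        self.network_ = CrossKingdomNetwork(
            group=group, nodes=nodes, edges=edges,
            rho_min=self.rho_min, q_alpha=self.q_alpha,
            prevalence_min=self.prevalence_min,
            n_pairs_tested=n_pairs, n_samples=n,
            skipped_constant=skipped,
        )
        self.summary_ = summarize_network(self.network_, n_hubs=self.n_hubs)
        return self


def build_cross_kingdom_network(table: AbundanceTable,
                                metadata: SampleMetadata | None = None,
                                group: str | None = None,
                                config: PipelineConfig | None = None,
                                ) -> CrossKingdomNetwork:
    """Functional wrapper around :class:`CrossKingdomNetworkInference`."""
    config = config or PipelineConfig()
    est = CrossKingdomNetworkInference(
        rho_min=config.rho_min, q_alpha=config.q_alpha,
        prevalence_min=config.prevalence_min,
    )
    return est.fit(table, metadata, group).network_


def summarize_network(net: CrossKingdomNetwork, n_hubs: int = 5) -> NetworkSummary:
    """Edge-sign counts, co-dysbiosis index and hub ranking.

    Hubs are the top-``n_hubs`` nodes by degree; ties break by mean
    abundance, then lexicographically, so reports are deterministic.
    """
    n_pos = sum(1 for e in net.edges if e.sign == POSITIVE)
    n_neg = net.n_edges - n_pos
    if net.n_edges:
        frac, undefined = n_pos / net.n_edges, False
    else:
        frac, undefined = None, True
    ranked = sorted(
        net.nodes.itertuples(),
        key=lambda r: (-r.degree, -r.mean_abundance, r.Index),
    )
    hubs = [(r.Index, int(r.degree)) for r in ranked[:n_hubs]]
    by_sign = {t: {"positive": 0, "negative": 0} for t in net.nodes.index}
    for e in net.edges:
        for t in (e.bacterial_taxon, e.fungal_taxon):
            by_sign[t][e.sign] += 1
    degree_by_sign = pd.DataFrame(by_sign).T if by_sign else pd.DataFrame(
        columns=["positive", "negative"]
    )
    return NetworkSummary(
        group=net.group, n_edges=net.n_edges, n_positive=n_pos,
        n_negative=n_neg, positivity_fraction=frac, undefined=undefined,
        hubs=hubs, degree_by_sign=degree_by_sign,
    )


def compare_networks(net_a: CrossKingdomNetwork, net_b: CrossKingdomNetwork,
                     n_hubs: int = 5) -> dict:
    """Compare two networks built under identical thresholds.

    Reports edge-set overlap, sign flips among shared pairs, per-group sign
    counts, the difference in positivity fraction and hub turnover.
    """
    for attr in ("rho_min", "q_alpha", "prevalence_min"):
        if getattr(net_a, attr) != getattr(net_b, attr):
            raise ValueError(
                f"threshold mismatch on {attr}: "
                f"{getattr(net_a, attr)} vs {getattr(net_b, attr)}"
            )
    ea = {(e.bacterial_taxon, e.fungal_taxon): e for e in net_a.edges}
    eb = {(e.bacterial_taxon, e.fungal_taxon): e for e in net_b.edges}
    shared = sorted(set(ea) & set(eb))
    flips = [p for p in shared if ea[p].sign != eb[p].sign]
    sum_a = summarize_network(net_a, n_hubs)
    sum_b = summarize_network(net_b, n_hubs)
    if sum_a.undefined or sum_b.undefined:
        pos_diff = None
    else:
        pos_diff = sum_b.positivity_fraction - sum_a.positivity_fraction
    hubs_a = {h[0] for h in sum_a.hubs}
    hubs_b = {h[0] for h in sum_b.hubs}
    union = hubs_a | hubs_b
    turnover = (len(hubs_a ^ hubs_b) / len(union)) if union else 0.0
    return {
        "groups": (net_a.group, net_b.group),
        "n_edges": (net_a.n_edges, net_b.n_edges),
        "n_shared_pairs": len(shared),
        "shared_pairs": shared,
        "sign_flips": flips,
        "sign_counts": {
            net_a.group: (sum_a.n_positive, sum_a.n_negative),
            net_b.group: (sum_b.n_positive, sum_b.n_negative),
        },
        "positivity_fraction": {
            net_a.group: sum_a.positivity_fraction,
            net_b.group: sum_b.positivity_fraction,
        },
        "positivity_difference": pos_diff,
        "hub_turnover": turnover,
        "hubs": {net_a.group: sum_a.hubs, net_b.group: sum_b.hubs},
    }


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def to_graphml(net: CrossKingdomNetwork, path) -> None:
    """Write the network as GraphML with attribute-complete nodes/edges.

    Node attributes: kingdom, mean_abundance, degree plus the display
    conventions (yellow circles for bacteria, green squares for fungi);
    edge attributes: rho, p, q, sign plus color (red positive, blue
    negative) — ready for Gephi.
    """
    import networkx as nx

    g = nx.Graph(group=net.group, rho_min=net.rho_min, q_alpha=net.q_alpha)
    for t, row in net.nodes.iterrows():
        g.add_node(t, kingdom=row["kingdom"],
                   mean_abundance=float(row["mean_abundance"]),
                   degree=int(row["degree"]),
                   color=NODE_COLOR[row["kingdom"]],
                   shape=NODE_SHAPE[row["kingdom"]])
    for e in net.edges:
        g.add_edge(e.bacterial_taxon, e.fungal_taxon, rho=e.rho,
                   p_raw=e.p_raw, q_bh=e.q_bh, sign=e.sign,
                   color=EDGE_COLOR[e.sign])
    nx.write_graphml(g, path)


def write_edge_list(net: CrossKingdomNetwork, path) -> None:
    net.edge_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")
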