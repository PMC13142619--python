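"""Cross-omics pathway integration and gene-metabolite networks.

Selected features are mapped through user-supplied annotations
(feature -> entity, entity -> pathway) and tested for pathway
over-representation with a one-sided hypergeometric test; layer-level
pathway p-values are pooled with Fisher's method (-2 * sum(ln p) ~ chi^2 with
2k df), and a bipartite entity-pathway network is exported as an edge list.

The enrichment engine is deliberately annotation-driven and generic: it takes
plain TSV annotation maps instead of querying curated databases, so the whole
stage runs on synthetic or user data without downloads.  Raw p-values are
reported (with a Benjamini-Hochberg column alongside for convenience).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import chi2, hypergeom

__all__ = ["AnnotationMap", "enrich", "fisher_combine", "integrate_layers",
           "build_network"]


@dataclass
class AnnotationMap:
    """Feature -> entity and entity -> pathway links.

    ``feature_entity``: columns (feature_id, entity_id);
    ``entity_pathway``: columns (entity_id, pathway_id, pathway_name).
    """

    feature_entity: pd.DataFrame
    entity_pathway: pd.DataFrame
    _names: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        fe, ep = self.feature_entity, self.entity_pathway
        for df, cols in ((fe, ["feature_id", "entity_id"]),
                         (ep, ["entity_id", "pathway_id", "pathway_name"])):
            lack = [c for c in cols if c not in df.columns]
            if lack:
                raise ValueError(f"annotation table lacks columns {lack}")
        if fe.duplicated(["feature_id", "entity_id"]).any():
            raise ValueError("duplicate feature-entity links")
        if ep.duplicated(["entity_id", "pathway_id"]).any():
            raise ValueError("duplicate entity-pathway links")
        names = ep.drop_duplicates("pathway_id").set_index("pathway_id")["pathway_name"]
        if ep.groupby("pathway_id")["pathway_name"].nunique().gt(1).any():
            raise ValueError("conflicting pathway names for one pathway id")
        self._names = names.to_dict()

    def pathway_name(self, pid) -> str:
        return self._names.get(pid, str(pid))

    def feature_pathways(self) -> pd.DataFrame:
        """Feature -> pathway links via entities (deduplicated)."""
        merged = self.feature_entity.merge(self.entity_pathway, on="entity_id")
        return merged[["feature_id", "pathway_id"]].drop_duplicates()

    def entities_of(self, features) -> pd.DataFrame:
        fe = self.feature_entity
        return fe[fe["feature_id"].isin(set(features))]


def enrich(selected, ann: AnnotationMap, universe) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per pathway.

    ``selected`` is the list of selected feature ids (e.g. a stability list),
    ``universe`` the full tested feature list.  Features mapping to no
    pathway remain in the universe denominator.  Returns a table with one
    row per pathway (those with at least one annotated feature in the
    universe): overlap, set size, p-value and BH-adjusted p-value.
    """
    universe = list(dict.fromkeys(universe))
    if not universe:
        raise ValueError("empty universe")
    uni = set(universe)
    sel = [f for f in dict.fromkeys(selected)]
    if not set(sel) <= uni:
        raise ValueError("selected features must be a subset of the universe")
    fp = ann.feature_pathways()
    fp = fp[fp["feature_id"].isin(uni)]
    M, N = len(uni), len(sel)
    rows = []
    for pid, grp in fp.groupby("pathway_id", sort=True):
        members = set(grp["feature_id"])
        n_set = len(members)
        overlap = len(members & set(sel))
        # P(X >= overlap), X ~ Hypergeom(M, n_set, N); overlap 0 -> p = 1
        p = float(hypergeom.sf(overlap - 1, M, n_set, N)) if N else 1.0
        rows.append({"pathway_id": pid, "pathway_name": ann.pathway_name(pid),
                     "overlap": overlap, "set_size": n_set,
                     "universe_size": M, "selected_size": N,
                     "p_value": min(max(p, np.nextafter(0, 1)), 1.0)})
    out = pd.DataFrame(rows, columns=["pathway_id", "pathway_name", "overlap",
                                      "set_size", "universe_size",
                                      "selected_size", "p_value"])
    if len(out):
        out["p_bh"] = _benjamini_hochberg(out["p_value"].to_numpy())
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    adj[order] = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    return np.clip(adj, 0.0, 1.0)


def fisher_combine(p_values) -> float:
    """Fisher's method: X^2 = -2 sum(ln p_i) referred to chi^2 with 2k df."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    stat = -2.0 * np.log(p).sum()
    return float(chi2.sf(stat, 2 * p.size))


def integrate_layers(dnam: pd.DataFrame, metab: pd.DataFrame) -> pd.DataFrame:
    """Outer-join two per-layer pathway tables and Fisher-combine shared rows.

    Adds -log10 p columns per layer (for the enrichment scatter) and a
    ``shared`` flag (shared / dnam-only / metab-only); the combined p-value
    is present only where both layers supply one.
    """
    for name, t in (("dnam", dnam), ("metabolome", metab)):
        if t["pathway_id"].duplicated().any():
            raise ValueError(f"duplicate pathway ids in {name} table")
    d = dnam.set_index("pathway_id").add_suffix("_dnam")
    m = metab.set_index("pathway_id").add_suffix("_metab")
    out = d.join(m, how="outer")
    name = out.get("pathway_name_dnam")
    out["pathway_name"] = (name.combine_first(out["pathway_name_metab"])
                           if name is not None else out["pathway_name_metab"])
    both = out["p_value_dnam"].notna() & out["p_value_metab"].notna()
    out["shared"] = np.where(both, "shared",
                             np.where(out["p_value_dnam"].notna(),
                                      "dnam-only", "metab-only"))
    comb = np.full(len(out), np.nan)
    for i, (pd_, pm) in enumerate(zip(out["p_value_dnam"], out["p_value_metab"])):
        if not (np.isnan(pd_) or np.isnan(pm)):
            comb[i] = fisher_combine([pd_, pm])
    out["p_combined"] = comb
    with np.errstate(divide="ignore"):
        out["neglog10_p_dnam"] = -np.log10(out["p_value_dnam"])
        out["neglog10_p_metab"] = -np.log10(out["p_value_metab"])
    return out.reset_index().sort_values("pathway_id", ignore_index=True)


def build_network(selected_by_layer: dict, ann: AnnotationMap,
                  significant_pathways) -> tuple[pd.DataFrame, nx.Graph]:
    """Bipartite entity-pathway network over the significant pathways.

    ``selected_by_layer`` maps a layer tag to its selected feature ids; the
    features are mapped to entities (genes for CpGs, compounds for
    metabolites), and an edge (entity, pathway) is drawn whenever the entity
    is annotated to one of the supplied significant pathways.  Returns the
    edge list (with node types and a degree-based pathway hub ranking) and
    the networkx graph.  No entity-entity edges are created.
    """
    sig = list(dict.fromkeys(significant_pathways))
    g = nx.Graph()
    edges = []
    if sig:
        ep = ann.entity_pathway
        ep = ep[ep["pathway_id"].isin(set(sig))]
        for layer, feats in sorted(selected_by_layer.items()):
            ents = ann.entities_of(feats)["entity_id"].drop_duplicates()
            sub = ep[ep["entity_id"].isin(set(ents))]
            for _, r in sub.iterrows():
                g.add_node(r["entity_id"], bipartite="entity", layer=layer)
                g.add_node(r["pathway_id"], bipartite="pathway",
                           name=ann.pathway_name(r["pathway_id"]))
                g.add_edge(r["entity_id"], r["pathway_id"])
                edges.append({"source": r["entity_id"], "target": r["pathway_id"],
                              "source_type": "entity", "target_type": "pathway",
                              "layer": layer})
    edge_df = pd.DataFrame(edges, columns=["source", "target", "source_type",
                                           "target_type", "layer"])
    edge_df = edge_df.drop_duplicates(["source", "target"], ignore_index=True)
    hub = pd.Series({n: d for n, d in g.degree()
                     if g.nodes[n].get("bipartite") == "pathway"}, dtype=int)
    edge_df.attrs["pathway_hubs"] = hub.sort_values(ascending=False)
    return edge_df, g
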