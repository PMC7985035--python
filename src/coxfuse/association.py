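"""Image-feature / gene-feature association analysis.

Links the top image features to the top gene-expression features by
simple linear regression (image feature on gene feature): each pair gets
a Pearson correlation, R-squared, and the two-sided p-value of the slope.
Pairs passing |r| > 0.1 with p < 0.05 become edges of a bipartite graph;
gene-gene edges require correlation > 0.5. Nodes are annotated with the
sign of a univariate Cox proportional-hazards coefficient (positive =
worse prognosis) and with importance scores for sizing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats

from .survival import SurvivalDataset

__all__ = ["AssociationEdge", "HazardSign", "pairwise_association",
           "build_bipartite_graph", "univariate_hazard_sign", "export_graph"]


@dataclass(frozen=True)
class AssociationEdge:
    image_feature: str
    gene_feature: str
    pearson_r: float
    r_squared: float
    p_value: float


@dataclass(frozen=True)
class HazardSign:
    """Univariate Cox-PH coefficient sign for one feature.

    ``stable`` is False when |z| < 1 (the sign is within one standard
    error of zero) or the fit did not converge.
    """

    feature: str
    sign: int          # +1 worse prognosis, -1 protective, 0 indeterminate
    coefficient: float
    z: float
    stable: bool


def pairwise_association(top_image: pd.DataFrame,
                         top_gene: pd.DataFrame) -> pd.DataFrame:
    """All image x gene simple regressions (image feature ~ gene feature).

    Inputs are sample-aligned DataFrames (rows = samples). Returns a
    table with columns image_feature, gene_feature, pearson_r, r_squared,
    p_value, q_value; q_value is a Benjamini-Hochberg adjusted p-value
    supplied as an extension for the user's judgment (the filtering
    convention itself uses raw p). Zero-variance pairs are skipped with a
    warning.
    """
    if len(top_image) != len(top_gene):
        raise ValueError("image and gene tables must be sample-aligned")
    if len(top_image) < 3:
        raise ValueError("need at least 3 samples for regression")
    rows = []
    for img_col in top_image.columns:
        y = top_image[img_col].to_numpy(dtype=float)
        for gene_col in top_gene.columns:
            x = top_gene[gene_col].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                warnings.warn(
                    f"zero-variance pair skipped: {img_col} ~ {gene_col}"
                )
                continue
            res = stats.linregress(x, y)
            rows.append({
                "image_feature": img_col,
                "gene_feature": gene_col,
                "pearson_r": float(res.rvalue),
                "r_squared": float(res.rvalue ** 2),
                "p_value": float(res.pvalue),
            })
    table = pd.DataFrame(rows)
    if len(table):
        table["q_value"] = stats.false_discovery_control(table["p_value"])
    return table


def build_bipartite_graph(edges: pd.DataFrame, gene_corr: pd.DataFrame = None,
                          image_gene_threshold: float = 0.1,
                          gene_gene_threshold: float = 0.5,
                          alpha: float = 0.05,
                          importance: dict = None,
                          signs: dict = None) -> nx.Graph:
    """Thresholded association graph.

    Image-gene edges are kept iff |r| > ``image_gene_threshold`` and
    p < ``alpha`` ("correlation > 0.1" is read as absolute correlation:
    both protective and harmful features appear in practice). Gene-gene
    edges require ``gene_corr`` (a genes x genes Pearson matrix)
    exceeding ``gene_gene_threshold``. Isolated nodes are dropped.
    Optional ``importance`` (feature -> score) and ``signs``
    (feature -> HazardSign) become node attributes.
    """
    g = nx.Graph()
    kept = edges[(edges["pearson_r"].abs() > image_gene_threshold)
                 & (edges["p_value"] < alpha)]
    for _, e in kept.iterrows():
        g.add_node(e["image_feature"], kind="image")
        g.add_node(e["gene_feature"], kind="gene")
        g.add_edge(e["image_feature"], e["gene_feature"], kind="image-gene",
                   r=float(e["pearson_r"]), r_squared=float(e["r_squared"]),
                   p=float(e["p_value"]))
    if gene_corr is not None:
        genes = [n for n, a in g.nodes(data=True) if a["kind"] == "gene"]
        for i, gi in enumerate(genes):
            for gj in genes[i + 1:]:
                if gi in gene_corr.index and gj in gene_corr.columns:
                    r = float(gene_corr.loc[gi, gj])
                    if r > gene_gene_threshold:
                        g.add_edge(gi, gj, kind="gene-gene", r=r)
    g.remove_nodes_from([n for n in g if g.degree(n) == 0])
    for n in g.nodes:
        if importance and n in importance:
            g.nodes[n]["importance"] = float(importance[n])
        if signs and n in signs:
            s = signs[n]
            g.nodes[n]["hazard_sign"] = int(s.sign)
            g.nodes[n]["sign_stable"] = bool(s.stable)
    return g


def univariate_hazard_sign(data: SurvivalDataset, feature: str) -> HazardSign:
    """Sign of a single-covariate Cox-PH coefficient for one feature.

    Positive means higher feature values carry a higher hazard (worse
    prognosis). Non-convergent fits are reported as sign 0 with
    ``stable=False`` rather than raising.
    """
    j = data.feature_names.index(feature)
    x = data.X[:, j]
    if np.std(x) == 0:
        raise ValueError(f"feature {feature!r} is constant")
    if data.n_events < 1:
        raise ValueError("need at least one observed event")
    df = pd.DataFrame({"x": (x - x.mean()) / x.std(),
                       "T": data.T, "E": data.d})
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="T", event_col="E")
        coef = float(cph.params_["x"])
        z = float(cph.summary.loc["x", "z"])
    except Exception:
        return HazardSign(feature=feature, sign=0, coefficient=np.nan,
                          z=np.nan, stable=False)
    sign = int(np.sign(coef))
    return HazardSign(feature=feature, sign=sign, coefficient=coef, z=z,
                      stable=bool(abs(z) >= 1.0))


def export_graph(g: nx.Graph, graphml_path=None, edge_list_path=None):
    """Write GraphML and/or a plain TSV edge list (source, target, attrs)."""
    if graphml_path is not None:
        nx.write_graphml(g, graphml_path)
    if edge_list_path is not None:
        rows = []
        for u, v, a in g.edges(data=True):
            rows.append({
                "source": u, "target": v, "type": a.get("kind", ""),
                "r": a.get("r", np.nan),
                "r_squared": a.get("r_squared", np.nan),
                "p": a.get("p", np.nan),
            })
        pd.DataFrame(rows).to_csv(edge_list_path, sep="\t", index=False)
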