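"""Thresholded association networks from Z/P matrices.

Feature pairs whose P-value falls below a threshold (or whose |Z| exceeds
one, in Z mode) become edges of an undirected graph; nodes are the
features incident to at least one edge, coloured by prefix-derived
category.  The graph is written as GraphML for viewers such as Cytoscape.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import MatrixShapeError, ParameterError


@dataclass(frozen=True)
class FeatureCategoryMap:
    """Ordered prefix -> (category, colour) rules; first match wins."""

    rules: tuple[tuple[str, str, str], ...] = ()
    default_category: str = "other"
    default_color: str = "#bbbbbb"

    def categorize(self, name: str) -> tuple[str, str]:
        for prefix, category, color in self.rules:
            if name.startswith(prefix):
                return category, color
        return self.default_category, self.default_color

    @classmethod
    def from_specs(cls, specs: Sequence[str]) -> "FeatureCategoryMap":
        """Parse ``prefix=category=color`` triples."""
        rules = []
        for spec in specs:
            parts = spec.split("=")
            if len(parts) != 3:
                raise ParameterError(
                    f"category rule {spec!r} is not prefix=category=color"
                )
            rules.append(tuple(parts))
        return cls(tuple(rules))


def build_graph(
    p_matrix: pd.DataFrame,
    z_matrix: pd.DataFrame | None = None,
    threshold: float = 0.005,
    categories: FeatureCategoryMap | None = None,
    mode: str = "p",
) -> nx.Graph:
    """Association graph of feature pairs passing the threshold.

    Parameters
    ----------
    p_matrix, z_matrix
        Symmetric matrices over a shared feature ordering, NA for untested
        cells (as written by :func:`phyloccm.io.write_matrices`).
    threshold
        Strict cutoff: in ``"p"`` mode an edge requires P < threshold; in
        ``"z"`` mode it requires |Z| > threshold.
    categories
        Prefix rules assigning a category and display colour to each node.
    """
    if mode not in ("p", "z"):
        raise ParameterError("mode must be 'p' or 'z'")
    if mode == "p" and not 0 < threshold <= 1:
        raise ParameterError("a P-value threshold must lie in (0, 1]")
    primary = p_matrix if mode == "p" else z_matrix
    if primary is None:
        raise ParameterError(f"mode {mode!r} requires the matching matrix")
    other = z_matrix if mode == "p" else p_matrix
    if other is not None and (
        list(other.index) != list(primary.index)
        or list(other.columns) != list(primary.columns)
    ):
        raise MatrixShapeError("Z and P matrices must share feature ordering")
    if list(primary.index) != list(primary.columns):
        raise MatrixShapeError("matrix rows and columns must match")

    categories = categories or FeatureCategoryMap()
    features = list(primary.index)
    graph = nx.Graph()
    for i, a in enumerate(features):
        for b in features[i + 1 :]:
            value = primary.loc[a, b]
            if pd.isna(value):
                continue
            passes = (
                value < threshold if mode == "p" else abs(value) > threshold
            )
            if not passes:
                continue
            attrs = {}
            if p_matrix is not None and not pd.isna(p_matrix.loc[a, b]):
                attrs["p"] = float(p_matrix.loc[a, b])
            if z_matrix is not None and not pd.isna(z_matrix.loc[a, b]):
                attrs["z"] = float(z_matrix.loc[a, b])
            for node in (a, b):
                if node not in graph:
                    category, color = categories.categorize(node)
                    graph.add_node(node, category=category, color=color)
            graph.add_edge(a, b, **attrs)
    return graph


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(graph, str(path))


def read_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(str(path))
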