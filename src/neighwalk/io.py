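"""Reading and writing the pipeline's plain-text interchange formats.

Cohort tables travel as CSV (header documented in
:func:`neighwalk.simulate.generate_cohort`), adjacency graphs as
2-column whitespace edge lists plus optional GeoJSON polygons, and
pipeline/generator configuration as YAML or JSON.
"""

from __future__ import annotations

import json
import os

import pandas as pd
import yaml

from .exceptions import InvalidArgumentError
from .graphs import AdjacencyGraph

__all__ = ["save_cohort", "load_cohort", "save_graph", "load_graph", "load_config_file"]


def save_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def load_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["recruitment_date"])
    if "neighborhood_id" not in df.columns:
        raise InvalidArgumentError("cohort CSV lacks a neighborhood_id column")
    return df


def save_graph(graph: AdjacencyGraph, path) -> None:
    graph.to_edgelist(path)


def load_graph(path) -> AdjacencyGraph:
    return AdjacencyGraph.from_edgelist(path)


def load_config_file(path) -> dict:
    """Load a YAML or JSON config mapping."""
    ext = os.path.splitext(str(path))[1].lower()
    with open(path) as fh:
        if ext == ".json":
            return json.load(fh)
        return yaml.safe_load(fh)
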