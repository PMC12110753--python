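"""Readers and writers for the package's on-disk formats.

Graphs travel as edge-list TSV (header ``parent<TAB>child``; isolated nodes
in an optional ``#nodes:`` comment), datasets as integer-coded CSV, and
everything structured (functors, certificates, categories, monoids) as JSON.
All round trips are identities on canonical form.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Union

import numpy as np
import pandas as pd

from .dag import Dag
from .finstoch import BayesNetFunctor, FinSpace, StochMorphism
from .ges import DiscreteDataset
from .transform import Edit, TransformCertificate

__all__ = [
    "read_dag",
    "write_dag",
    "dag_to_dot",
    "read_dataset",
    "write_dataset",
    "read_functor",
    "write_functor",
    "certificate_to_json",
    "certificate_from_json",
]

PathLike = Union[str, Path]


def read_dag(path: PathLike) -> Dag:
    """Parse an edge-list TSV; malformed lines are reported with their line
    number, and cycles are detected on load."""
    nodes: set = set()
    edges = []
    header_seen = False
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#nodes:"):
                nodes.update(
                    n.strip() for n in line[len("#nodes:"):].split(",") if n.strip()
                )
                continue
            if line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two tab-separated fields")
            a, b = (s.strip() for s in parts)
            if not header_seen and (a, b) == ("parent", "child"):
                header_seen = True
                continue
            if (a, b) in edges:
                raise ValueError(f"{path}:{lineno}: duplicate edge {a}->{b}")
            edges.append((a, b))
            nodes.update((a, b))
    if not nodes:
        raise ValueError(f"{path}: no nodes declared")
    try:
        return Dag(nodes, edges)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_dag(g: Dag, path: PathLike) -> None:
    isolated = [n for n in g.nodes if not any(n in e for e in g.edges)]
    with open(path, "w", encoding="utf-8") as fh:
        if isolated:
            fh.write("#nodes: " + ",".join(isolated) + "\n")
        fh.write("parent\tchild\n")
        for a, b in g.sorted_edges():
            fh.write(f"{a}\t{b}\n")


def dag_to_dot(g: Dag) -> str:
    lines = ["digraph G {"]
    for n in g.nodes:
        lines.append(f'  "{n}";')
    for a, b in g.sorted_edges():
        lines.append(f'  "{a}" -> "{b}";')
    lines.append("}")
    return "\n".join(lines)


def read_dataset(path: PathLike, arities=None) -> DiscreteDataset:
    """CSV with a header row of variable labels and integer category codes."""
    df = pd.read_csv(path)
    if df.empty and df.shape[1] == 0:
        raise ValueError(f"{path}: empty dataset")
    try:
        data = df.to_numpy(dtype=np.int64)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-integer cell ({exc})") from exc
    return DiscreteDataset(list(df.columns), data, arities=arities)


def write_dataset(data: DiscreteDataset, path: PathLike) -> None:
    pd.DataFrame(data.data, columns=list(data.variables)).to_csv(
        path, index=False
    )


def write_functor(bn: BayesNetFunctor, path: PathLike) -> None:
    doc = {
        "nodes": [
            {"label": v, "size": bn.spaces[v].size} for v in bn.dag.nodes
        ],
        "edges": [list(e) for e in bn.dag.sorted_edges()],
        "cpts": {
            v: {
                "parents": sorted(bn.dag.parents(v)),
                "matrix": bn.cpts[v].matrix.tolist(),
            }
            for v in bn.dag.nodes
        },
    }
    Path(path).write_text(json.dumps(doc, indent=2), encoding="utf-8")


def read_functor(path: PathLike) -> BayesNetFunctor:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    spaces: Dict[str, FinSpace] = {
        n["label"]: FinSpace(n["label"], int(n["size"])) for n in doc["nodes"]
    }
    dag = Dag(list(spaces), [tuple(e) for e in doc["edges"]])
    cpts = {}
    for v, entry in doc["cpts"].items():
        parents = sorted(entry["parents"])
        cpts[v] = StochMorphism(
            tuple(spaces[p] for p in parents), (spaces[v],),
            np.asarray(entry["matrix"], dtype=float),
        )
    return BayesNetFunctor(dag=dag, spaces=spaces, cpts=cpts)


def certificate_to_json(cert: TransformCertificate) -> dict:
    return {
        "edits": [
            {"kind": e.kind, "parent": e.edge[0], "child": e.edge[1]}
            for e in cert.edits
        ],
        "r": cert.r,
        "m": cert.m,
        "length": cert.length,
        "intermediate_ok": cert.intermediate_ok,
    }


def certificate_from_json(doc: dict) -> TransformCertificate:
    return TransformCertificate(
        edits=tuple(
            Edit(e["kind"], (e["parent"], e["child"])) for e in doc["edits"]
        ),
        r=int(doc["r"]),
        m=int(doc["m"]),
        intermediate_ok=bool(doc.get("intermediate_ok", True)),
    )
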