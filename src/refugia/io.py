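"""File-format plumbing: FASTA, popmap TSV, result JSON/TSV, networks.

All readers are strict (duplicate ids, unmapped samples and malformed rows
raise with the offending id / line number); writers round-trip exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import networkx as nx
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alignment import Alignment, PopulationMap


def read_fasta(path: str | Path) -> Alignment:
    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq))
    if not ids:
        raise ValueError(f"no sequences in {path}")
    return Alignment(ids, seqs)


def write_fasta(aln: Alignment, path: str | Path, wrap: int | None = 70) -> None:
    records = [
        SeqRecord(Seq(s), id=i, description="")
        for i, s in zip(aln.sequence_ids, aln.sequences)
    ]
    with open(path, "w") as fh:
        if wrap is None:
            for r in records:
                fh.write(f">{r.id}\n{r.seq}\n")
        else:
            SeqIO.write(records, fh, "fasta")


def read_popmap(path: str | Path) -> PopulationMap:
    """Read a ``sample_id<TAB>population`` table."""
    assignments: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise ValueError(f"{path}:{lineno}: malformed popmap row {line!r}")
            sid, pop = parts
            if sid in assignments:
                raise ValueError(f"{path}:{lineno}: duplicate sample id {sid!r}")
            assignments[sid] = pop
    return PopulationMap(assignments)


def write_popmap(pm: PopulationMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, pop in pm.assignments.items():
            fh.write(f"{sid}\t{pop}\n")


def write_json(obj: Any, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")


def _jsonable(x: Any) -> Any:
    import numpy as np

    if isinstance(x, np.bool_):
        return bool(x)
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


def write_reference_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_reference_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_network_edgelist(graph: nx.Graph, path: str | Path) -> None:
    """Edge list as ``node1<TAB>node2<TAB>steps`` (every edge is one step)."""
    with open(path, "w") as fh:
        fh.write("node1\tnode2\tsteps\n")
        for u, v, d in graph.edges(data=True):
            fh.write(f"{u}\t{v}\t{d.get('steps', 1)}\n")


def write_network_graphml(graph: nx.Graph, path: str | Path) -> None:
    g = graph.copy()
    for _, data in g.nodes(data=True):
        for k, v in list(data.items()):
            if isinstance(v, (list, tuple, dict)):
                data[k] = json.dumps(v)
    nx.write_graphml(g, str(path))


def read_network_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(str(path))
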