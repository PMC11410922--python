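"""File formats: graph TSV, observational data CSV, report JSON.

Graph TSV dialect::

    #latent: U1 U2
    source<TAB>target<TAB>type
    fur<TAB>dpiA<TAB>directed
    oxyR<TAB>soxS<TAB>bidirected

``type`` is ``directed`` or ``bidirected``; latent nodes are declared
either by ``#latent:`` comment lines before the header or by a sidecar
text file (one node per line).  Reading then writing reproduces the
canonical form losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .graphs import GraphError, MixedGraph

__all__ = ["read_graph", "write_graph", "read_data", "write_data", "ParseError"]


class ParseError(ValueError):
    """Malformed input file; message carries the offending line number."""


def read_graph(path: str | Path, latent_sidecar: str | Path | None = None) -> MixedGraph:
    path = Path(path)
    latent: set[str] = set()
    directed: list[tuple[str, str]] = []
    bidirected: list[tuple[str, str]] = []
    isolated: set[str] = set()
    seen: set[tuple[str, str, str]] = set()
    header_seen = False
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#latent:"):
                latent.update(line[len("#latent:") :].split())
                continue
            if line.startswith("#node:"):
                isolated.update(line[len("#node:") :].split())
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if not header_seen:
                if [f.strip() for f in fields] != ["source", "target", "type"]:
                    raise ParseError(
                        f"{path.name}:{lineno}: expected header 'source\\ttarget\\ttype', got {line!r}"
                    )
                header_seen = True
                continue
            if len(fields) != 3:
                raise ParseError(f"{path.name}:{lineno}: expected 3 tab-separated fields")
            u, v, kind = (f.strip() for f in fields)
            if kind not in ("directed", "bidirected"):
                raise ParseError(
                    f"{path.name}:{lineno}: unknown edge type {kind!r} (expected directed|bidirected)"
                )
            key = (u, v, kind) if kind == "directed" else (min(u, v), max(u, v), kind)
            if key in seen:
                raise ParseError(f"{path.name}:{lineno}: duplicate edge {u} {kind} {v}")
            seen.add(key)
            (directed if kind == "directed" else bidirected).append((u, v))
    if not header_seen:
        raise ParseError(f"{path.name}: missing header line")
    if latent_sidecar is not None:
        with open(latent_sidecar, encoding="utf-8") as fh:
            latent.update(tok for line in fh for tok in line.split())
    try:
        return MixedGraph.from_edges(
            directed=directed, bidirected=bidirected, latent=latent, nodes=isolated
        )
    except GraphError as exc:
        raise ParseError(f"{path.name}: {exc}") from exc


def write_graph(g: MixedGraph, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if g.latent:
            fh.write("#latent: " + " ".join(sorted(g.latent)) + "\n")
        connected = {n for e in g.directed | g.bidirected for n in e}
        isolated = sorted(g.nodes - connected)
        if isolated:
            fh.write("#node: " + " ".join(isolated) + "\n")
        fh.write("source\ttarget\ttype\n")
        for u, v in sorted(g.directed):
            fh.write(f"{u}\t{v}\tdirected\n")
        for u, v in sorted(g.bidirected):
            fh.write(f"{u}\t{v}\tbidirected\n")


def read_data(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"{path.name}: {exc}") from exc
    if df.shape[0] < 1:
        raise ParseError(f"{path.name}: data table has no rows")
    if df.columns.duplicated().any():
        dupes = sorted(set(df.columns[df.columns.duplicated()]))
        raise ParseError(f"{path.name}: duplicate column names {dupes}")
    return df


def write_data(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")
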