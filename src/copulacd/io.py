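"""Readers and writers for graph artefacts and run provenance."""

from __future__ import annotations

import json
import platform
import re
import time
from pathlib import Path
from typing import Mapping

from .graphs import Mark, PAG

__all__ = ["write_pag", "read_pag", "write_provenance"]

_EDGE_RE = re.compile(
    r"^\s*(\S+)\s+([<o-])-([>o-])\s+(\S+)(?:\s+([0-9.]+)\s*%)?\s*$")


def write_pag(pag: PAG, path,
              reliabilities: Mapping[frozenset[str], float] | None = None,
              ) -> None:
    """Write a PAG as an edge list, e.g. ``A o-> B 73.0%``.

    Nodes without edges are preserved as ``node X`` lines so the round trip
    is lossless.
    """
    lines = [f"node {v}" for v in pag.nodes]
    lines += pag.to_edge_lines(reliabilities)
    Path(path).write_text("\n".join(lines) + "\n")


def read_pag(path) -> tuple[PAG, dict[frozenset[str], float]]:
    """Parse an edge-list file back into a PAG plus edge reliabilities."""
    nodes: list[str] = []
    edges: list[tuple[str, Mark, Mark, str, float | None]] = []
    for ln, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("node "):
            nodes.append(line.split(None, 1)[1])
            continue
        m = _EDGE_RE.match(line)
        if not m:
            raise ValueError(f"line {ln}: malformed edge line {raw!r}")
        x, left, right, y, rel = m.groups()
        edges.append((x, PAG._LEFT_INV[left], PAG._RIGHT_INV[right], y,
                      float(rel) / 100 if rel else None))
    for x, _, _, y, _ in edges:
        for v in (x, y):
            if v not in nodes:
                nodes.append(v)
    pag = PAG(nodes)
    rels: dict[frozenset[str], float] = {}
    for x, mark_x, mark_y, y, rel in edges:
        pag.add_edge(x, y, mark_x, mark_y)
        if rel is not None:
            rels[frozenset((x, y))] = rel
    return pag, rels


def write_provenance(path, config: dict, seed=None) -> None:
    """Machine-readable record of a run: config, seed, versions, wall time."""
    from importlib.metadata import version

    import networkx
    import numpy
    import pandas
    import scipy

    from . import __version__

    record = {
        "config": config,
        "seed": seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        "python": platform.python_version(),
        "versions": {
            "copulacd": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
            "networkx": networkx.__version__,
            "click": version("click"),
        },
    }
    Path(path).write_text(json.dumps(record, indent=1, default=str) + "\n")
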