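"""Readers/writers, evaluation metrics, and report serialization.

Structures travel as plain edge lists ("parent child" per line, ``#``
comments) or as structure-only parses of BIF files (conditional
probability tables are ignored).  Evaluation compares a learned DAG to a
reference: AD/DD/RD count skeleton edges wrongly added / deleted /
oriented, while precision, recall, and F1 are computed on exactly
oriented directed edges.
"""

from __future__ import annotations

import json
import re
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from causalhh.model_core import DataMatrix, StructuralError, is_acyclic
from causalhh.scoring import ScoreContext


@dataclass
class MetricsReport:
    AD: int
    DD: int
    RD: int
    precision: float
    recall: float
    f1: float
    learned_score: float | None = None
    sbs: float | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(self)])


def read_data(path: str | Path) -> DataMatrix:
    """Load a samples-by-variables CSV/TSV with a header of names."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    return DataMatrix(values=df.to_numpy(dtype=float), names=list(df.columns))


def write_data(data: DataMatrix, path: str | Path) -> None:
    pd.DataFrame(data.values, columns=list(data.names)).to_csv(path, index=False)


def _finalize(edges: list[tuple[str, str]], names: list[str]) -> tuple[np.ndarray, list[str]]:
    n = len(names)
    pos = {name: i for i, name in enumerate(names)}
    adj = np.zeros((n, n), dtype=bool)
    for p, c in edges:
        adj[pos[p], pos[c]] = True
    if not is_acyclic(adj):
        raise StructuralError(f"structure file encodes a cyclic graph (e.g. around {edges[0]})")
    return adj, names


def read_edge_list(path: str | Path, names: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
    """Edge list format: one "parent child" pair per whitespace-separated
    line; '#' starts a comment.  Returns (adjacency, names)."""
    edges: list[tuple[str, str]] = []
    seen: list[str] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise StructuralError(f"bad edge-list line: {raw!r}")
        for name in parts:
            if name not in seen:
                seen.append(name)
        edges.append((parts[0], parts[1]))
    if names is None:
        names = sorted(seen)
    else:
        unknown = set(seen) - set(names)
        if unknown:
            raise StructuralError(f"unknown variable name(s): {sorted(unknown)}")
    return _finalize(edges, list(names))


_BIF_VARIABLE = re.compile(r"variable\s+(\S+)\s*\{")
_BIF_PROBABILITY = re.compile(r"probability\s*\(\s*([^)|]+?)(?:\|([^)]+))?\)")


def read_bif_structure(path: str | Path, names: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
    """Structure-only BIF parse: variable declarations plus the parent
    lists in probability headers; CPDs are ignored."""
    text = Path(path).read_text()
    declared = _BIF_VARIABLE.findall(text)
    edges: list[tuple[str, str]] = []
    for match in _BIF_PROBABILITY.finditer(text):
        child = match.group(1).strip()
        if match.group(2):
            for parent in match.group(2).split(","):
                edges.append((parent.strip(), child))
    if names is None:
        names = declared or sorted({v for e in edges for v in e})
    return _finalize(edges, list(names))


def read_structure(path: str | Path, names: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
    """Dispatch on extension: .bif -> BIF, anything else -> edge list."""
    if str(path).endswith(".bif"):
        return read_bif_structure(path, names)
    return read_edge_list(path, names)


def write_structure(adjacency: np.ndarray, names: list[str], path: str | Path) -> None:
    """Write an edge list in lexicographic order."""
    lines = sorted(
        f"{names[i]} {names[j]}" for i, j in np.argwhere(np.asarray(adjacency, bool)).tolist()
    )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# -- metrics ---------------------------------------------------------------


def structural_errors(learned: np.ndarray, truth: np.ndarray) -> tuple[int, int, int]:
    """(AD, DD, RD) on the skeleton decomposition.

    AD: learned skeleton edges absent from the true skeleton; DD: true
    skeleton edges absent from the learned one; RD: shared skeleton
    edges oriented oppositely.
    """
    lg = np.asarray(learned, bool)
    tg = np.asarray(truth, bool)
    if lg.shape != tg.shape:
        raise StructuralError("graph dimension mismatch")
    lsk = lg | lg.T
    tsk = tg | tg.T
    ad = int(np.triu(lsk & ~tsk).sum())
    dd = int(np.triu(tsk & ~lsk).sum())
    rd = int((lg & tg.T & ~tg).sum())
    return ad, dd, rd


def f1_score(learned: np.ndarray, truth: np.ndarray) -> tuple[float, float, float]:
    """(precision, recall, F1) on exactly oriented directed edges."""
    lg = np.asarray(learned, bool)
    tg = np.asarray(truth, bool)
    tp = int((lg & tg).sum())
    n_learned = int(lg.sum())
    n_true = int(tg.sum())
    p = tp / n_learned if n_learned else 0.0
    r = tp / n_true if n_true else 0.0
    f1 = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
    return p, r, f1


def evaluate(
    learned: np.ndarray,
    truth: np.ndarray,
    data: DataMatrix | None = None,
    score: ScoreContext | None = None,
) -> MetricsReport:
    """Full comparison; BIC of both graphs is included when data (or a
    score context) is supplied.  The true structure's score is the SBS
    reference value."""
    ad, dd, rd = structural_errors(learned, truth)
    p, r, f1 = f1_score(learned, truth)
    learned_score = sbs = None
    if score is None and data is not None:
        score = ScoreContext(data)
    if score is not None:
        learned_score = score.graph_score(np.asarray(learned, bool))
        sbs = score.graph_score(np.asarray(truth, bool))
    return MetricsReport(
        AD=ad, DD=dd, RD=rd, precision=p, recall=r, f1=f1,
        learned_score=learned_score, sbs=sbs,
    )
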