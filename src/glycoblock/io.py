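"""Delimited-text I/O for peak matrices, metadata, trait tables and networks.

All matrix files are plain CSV (comma by default, tab via ``delimiter``)
with a leading sample-id column.  Trait definitions use a three-column
dialect ``trait_id,family,formula``.  Networks are written as edge lists
(source, target, weight, source_block, target_block) or GraphML.
"""

from __future__ import annotations

from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from glycoblock.datamodel import (
    DEFAULT_PEAK_PANEL,
    GlycanPeakMatrix,
    SampleMetadata,
    TraitDefinitionTable,
    parse_formula,
)
from glycoblock.errors import IntegrityError, SchemaError, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from glycoblock.network import RelevanceNetwork

FLOAT_FORMAT = "%.12g"


def read_peak_table(path: str | Path, delimiter: str = ",",
                    panel: Sequence[str] | None = None,
                    compositional: bool = True,
                    row_sum_rtol: float = 1e-6) -> GlycanPeakMatrix:
    """Read a samples x peaks table, validating schema and row sums.

    The first column is the sample id.  When ``panel`` is given, all its
    peaks must be present (extra columns are an error too); otherwise every
    non-id column is taken as a peak.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].tolist()
        raise IntegrityError(f"duplicate sample ids in {path.name}: {dups}")
    if panel is not None:
        missing = [p for p in panel if p not in df.columns]
        if missing:
            raise SchemaError(f"{path.name} is missing peak columns: {missing}")
        extra = [c for c in df.columns if c not in set(panel)]
        if extra:
            raise SchemaError(f"{path.name} has unexpected columns: {extra}")
        df = df[list(panel)]
    non_numeric = df.columns[~df.apply(lambda c: pd.to_numeric(c, errors="coerce").notna().all())]
    if len(non_numeric):
        raise SchemaError(f"{path.name}: non-numeric values in columns {list(non_numeric)}")
    return GlycanPeakMatrix.from_frame(df.astype(float), compositional=compositional,
                                       row_sum_rtol=row_sum_rtol)


def write_peak_table(X: GlycanPeakMatrix, path: str | Path, delimiter: str = ",") -> None:
    X.to_frame().to_csv(Path(path), sep=delimiter, index_label="sample_id",
                        float_format=FLOAT_FORMAT)


def read_metadata(path: str | Path, delimiter: str = ",", group_col: str = "group",
                  batch_col: str = "batch") -> SampleMetadata:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    return SampleMetadata(df, group_col=group_col, batch_col=batch_col)


def write_metadata(meta: SampleMetadata, path: str | Path, delimiter: str = ",") -> None:
    meta.table.to_csv(Path(path), sep=delimiter, index_label="sample_id")


def read_trait_definitions(path: str | Path, delimiter: str = ",",
                           panel: Sequence[str] = DEFAULT_PEAK_PANEL) -> TraitDefinitionTable:
    """Parse a ``trait_id,family,formula`` file into expression trees.

    Formulas may quote the whole expression; lines starting with ``#`` are
    comments.  Parse failures report the offending line number.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    formulas = []
    with open(path) as fh:
        header_seen = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if not header_seen:
                header_seen = True
                first = line.split(delimiter)[0].strip().lower()
                if first == "trait_id":
                    continue  # header row
            parts = line.split(delimiter, 2)
            if len(parts) != 3:
                raise SchemaError(f"{path.name}:{lineno}: expected trait_id,family,formula")
            trait_id, family, formula = (p.strip().strip('"') for p in parts)
            try:
                formulas.append(parse_formula(trait_id, family, formula, panel))
            except ValidationError as exc:
                raise type(exc)(f"{path.name}:{lineno}: {exc}") from exc
    return TraitDefinitionTable(tuple(formulas), panel=tuple(panel))


def write_trait_definitions(defs: TraitDefinitionTable, path: str | Path,
                            delimiter: str = ",") -> None:
    with open(Path(path), "w") as fh:
        fh.write(delimiter.join(["trait_id", "family", "formula"]) + "\n")
        for f in defs:
            fh.write(delimiter.join([f.trait_id, f.family, f'"{f.source}"']) + "\n")


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

EDGE_COLUMNS = ("source", "target", "weight", "source_block", "target_block")


def write_network(net: "RelevanceNetwork", path: str | Path,
                  format: str = "edge-list") -> None:
    """Write a relevance network as a 3+2-column edge list or GraphML."""
    path = Path(path)
    if format == "edge-list":
        rows = [
            {"source": u, "target": v, "weight": f"{w:.6f}",
             "source_block": bu, "target_block": bv}
            for u, v, w, bu, bv in net.edge_records()
        ]
        pd.DataFrame(rows, columns=list(EDGE_COLUMNS)).to_csv(path, index=False)
    elif format == "graphml":
        nx.write_graphml(net.to_graph(), path)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path: str | Path, format: str = "edge-list") -> "RelevanceNetwork":
    from glycoblock.network import RelevanceNetwork

    path = Path(path)
    if format == "edge-list":
        df = pd.read_csv(path)
        missing = [c for c in EDGE_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"{path.name} is missing edge columns: {missing}")
        g = nx.Graph()
        for _, row in df.iterrows():
            g.add_node(row["source"], block=row["source_block"])
            g.add_node(row["target"], block=row["target_block"])
            g.add_edge(row["source"], row["target"], weight=float(row["weight"]))
        return RelevanceNetwork.from_graph(g)
    if format == "graphml":
        g = nx.read_graphml(path)
        for _, _, d in g.edges(data=True):
            d["weight"] = float(d["weight"])
        return RelevanceNetwork.from_graph(g)
    raise ValueError(f"unknown network format {format!r}")


def write_matrix(values: np.ndarray, index: Sequence[str], columns: Sequence[str],
                 path: str | Path, index_label: str = "id") -> None:
    pd.DataFrame(values, index=list(index), columns=list(columns)).to_csv(
        Path(path), index_label=index_label, float_format=FLOAT_FORMAT)
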