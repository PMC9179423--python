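"""Readers and writers for the pipeline's file formats.

Formats:

* TF interactions — TRRUST-dialect TSV: ``tf <TAB> target <TAB> mode
  <TAB> evidence`` (the last two columns optional).
* Pathways — GMT: ``id <TAB> description <TAB> member1 <TAB> ...``.
* Co-expression — TSV edge list: ``gene_a <TAB> gene_b [<TAB> weight]``.
* Ct measurements — CSV with header ``gene,patient,tissue,replicate,ct``.
* Seed / gene lists — plain text, one symbol per line, ``#`` comments.

All readers normalize symbols (uppercase, optional alias resolution) so a
mixed-case file parses to the same object as its uppercase twin.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from markermine.model import (
    TISSUES,
    VALID_MODES,
    CoexpressionEdge,
    ParseError,
    PathwayDB,
    PathwayRecord,
    RegulatoryNetwork,
    TFInteraction,
    dedupe_edges,
    normalize_symbol,
)

CT_COLUMNS = ["gene", "patient", "tissue", "replicate", "ct"]


def _data_lines(path: str | Path):
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def read_gene_list(
    path: str | Path, aliases: Mapping[str, str] | None = None
) -> frozenset[str]:
    """Read a plain-text gene list (one symbol per line), deduplicated."""
    genes = set()
    for _, line in _data_lines(path):
        genes.add(normalize_symbol(line, aliases))
    return frozenset(genes)


def read_alias_table(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping alias -> official symbol."""
    table: dict[str, str] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: alias line needs 2 columns")
        table[fields[0].strip().upper()] = fields[1].strip().upper()
    return table


def read_tf_interactions(
    path: str | Path, aliases: Mapping[str, str] | None = None
) -> RegulatoryNetwork:
    """Read a TRRUST-dialect TSV of TF -> target interactions.

    Duplicate (tf, target) pairs collapse to one interaction.  A header
    line is detected by a first token of ``TF`` (case-insensitive).
    """
    network = RegulatoryNetwork()
    n_lines = 0
    for lineno, line in _data_lines(path):
        fields = [f.strip() for f in line.split("\t")]
        if len(fields) < 2 or not fields[0] or not fields[1]:
            raise ParseError(
                f"{path}:{lineno}: expected at least 2 tab-separated columns"
            )
        if n_lines == 0 and fields[0].upper() == "TF":
            continue
        n_lines += 1
        mode = fields[2].strip().lower() if len(fields) > 2 and fields[2] else "unknown"
        if mode not in VALID_MODES:
            mode = "unknown"
        evidence = fields[3] if len(fields) > 3 else ""
        network.add(
            TFInteraction(
                tf=normalize_symbol(fields[0], aliases),
                target=normalize_symbol(fields[1], aliases),
                mode=mode,
                evidence=evidence,
            )
        )
    if len(network) == 0:
        warnings.warn(f"{path}: no TF interactions parsed", stacklevel=2)
    return network


def write_tf_interactions(network: RegulatoryNetwork, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("TF\ttarget\tmode\tevidence\n")
        for ia in network:
            fh.write(f"{ia.tf}\t{ia.target}\t{ia.mode}\t{ia.evidence}\n")


def read_gmt(
    path: str | Path, aliases: Mapping[str, str] | None = None
) -> PathwayDB:
    """Read a Broad-dialect GMT file into a PathwayDB.

    Lines with fewer than three fields are a parse error; a line whose
    member list deduplicates to nothing is rejected with a warning.
    Duplicate pathway ids keep the last occurrence (with a warning).
    """
    records: list[PathwayRecord] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(
                f"{path}:{lineno}: GMT line needs id, description and >=1 member"
            )
        pathway_id = fields[0].strip()
        name = fields[1].strip()
        members = frozenset(
            normalize_symbol(f, aliases) for f in fields[2:] if f.strip()
        )
        if not members:
            warnings.warn(
                f"{path}:{lineno}: pathway {pathway_id!r} has an empty member "
                "list; record rejected",
                stacklevel=2,
            )
            continue
        records.append(PathwayRecord(pathway_id, name, members))
    return PathwayDB(records)


def write_gmt(db: PathwayDB, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in db:
            members = "\t".join(sorted(rec.members))
            fh.write(f"{rec.pathway_id}\t{rec.name}\t{members}\n")


def read_coexpression(
    path: str | Path, aliases: Mapping[str, str] | None = None
) -> list[CoexpressionEdge]:
    """Read a TSV edge list (gene_a, gene_b[, weight]); undirected."""
    edges: list[CoexpressionEdge] = []
    for lineno, line in _data_lines(path):
        fields = [f.strip() for f in line.split("\t")]
        if len(fields) < 2 or not fields[0] or not fields[1]:
            raise ParseError(
                f"{path}:{lineno}: edge line needs at least 2 columns"
            )
        if lineno == 1 and fields[0].lower() in ("gene_a", "source", "gene1"):
            continue
        weight = 1.0
        if len(fields) > 2 and fields[2]:
            try:
                weight = float(fields[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: weight {fields[2]!r} is not a number"
                ) from exc
        edges.append(
            CoexpressionEdge(
                normalize_symbol(fields[0], aliases),
                normalize_symbol(fields[1], aliases),
                weight,
            )
        )
    return dedupe_edges(edges)


def write_coexpression(edges: Iterable[CoexpressionEdge], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_a\tgene_b\tweight\n")
        for e in dedupe_edges(edges):
            fh.write(f"{e.gene_a}\t{e.gene_b}\t{e.weight:g}\n")


def validate_ct_frame(df: pd.DataFrame, source: str = "<frame>") -> pd.DataFrame:
    """Validate and canonicalize a Ct measurement table.

    Enforces the column contract, the tissue vocabulary, finite numeric
    Ct values and uniqueness of (gene, patient, tissue, replicate).
    """
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{source}: missing column(s) {missing}")
    out = df.loc[:, CT_COLUMNS].copy()
    out["gene"] = out["gene"].map(normalize_symbol)
    out["patient"] = out["patient"].astype(str).str.strip()
    out["tissue"] = out["tissue"].astype(str).str.strip().str.lower()
    bad_tissue = sorted(set(out["tissue"]) - set(TISSUES))
    if bad_tissue:
        raise ParseError(
            f"{source}: unknown tissue label(s) {bad_tissue}; expected "
            f"one of {list(TISSUES)}"
        )
    try:
        out["replicate"] = out["replicate"].astype(int)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{source}: replicate must be an integer") from exc
    if (out["replicate"] < 1).any():
        raise ParseError(f"{source}: replicate indices must be >= 1")
    ct = pd.to_numeric(out["ct"], errors="coerce")
    if ct.isna().any() or (~ct.map(lambda x: abs(x) < float("inf"))).any():
        bad = out.loc[ct.isna(), "ct"].head(3).tolist()
        raise ParseError(f"{source}: non-numeric or non-finite ct value(s): {bad}")
    out["ct"] = ct.astype(float)
    key = ["gene", "patient", "tissue", "replicate"]
    dup = out.duplicated(subset=key)
    if dup.any():
        first = out.loc[dup, key].iloc[0].tolist()
        raise ParseError(f"{source}: duplicate measurement key {first}")
    return out.sort_values(key).reset_index(drop=True)


def read_ct_csv(path: str | Path) -> pd.DataFrame:
    """Read a Ct measurement CSV (gene,patient,tissue,replicate,ct)."""
    df = pd.read_csv(path, dtype={"patient": str})
    return validate_ct_frame(df, source=str(path))


def write_ct_csv(df: pd.DataFrame, path: str | Path) -> None:
    validate_ct_frame(df).to_csv(path, index=False)
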