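"""Readers and writers for the formats the pipeline touches.

FASTA (wrapped at 70 columns on write), GFF3-style feature tables (1-based
inclusive on disk, 0-based half-open in memory), Newick trees (via dendropy)
and TSV reports.  Every reader/writer pair round-trips exactly up to line
wrapping.
"""

from __future__ import annotations

import io as _stdio
from pathlib import Path
from typing import IO, Iterable, Sequence

import dendropy

from .core import (
    Alignment,
    AnnotatedMitogenome,
    FeatureRecord,
    FormatError,
    SequenceRecord,
    normalize_sequence,
)

_FASTA_WRAP = 70


def _as_text_handle(source: str | Path | IO[str], mode: str = "r"):
    """Accept a path or an open text handle; returns (handle, should_close)."""
    if isinstance(source, (str, Path)):
        return open(source, mode), True
    return source, False


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(source: str | Path | IO[str], *, aligned: bool = False) -> list[SequenceRecord]:
    """Parse FASTA into :class:`SequenceRecord` objects, order preserved.

    Sequences are upper-cased and U is mapped to T.  A character outside the
    alphabet raises :class:`FormatError` naming the record and offset.
    """
    handle, close = _as_text_handle(source)
    try:
        records: list[SequenceRecord] = []
        name: str | None = None
        chunks: list[str] = []
        for line in handle:
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    records.append(
                        SequenceRecord(name, "".join(chunks), aligned=aligned)
                    )
                name = line[1:].split()[0] if line[1:].strip() else ""
                if not name:
                    raise FormatError("FASTA header with empty id")
                chunks = []
            else:
                if name is None:
                    raise FormatError("sequence data before first FASTA header")
                chunks.append(line)
        if name is not None:
            records.append(SequenceRecord(name, "".join(chunks), aligned=aligned))
        if not records:
            raise FormatError("empty FASTA stream")
        return records
    finally:
        if close:
            handle.close()


def write_fasta(
    records: Iterable[SequenceRecord], dest: str | Path | IO[str]
) -> None:
    handle, close = _as_text_handle(dest, "w")
    try:
        for rec in records:
            handle.write(f">{rec.id}\n")
            seq = rec.sequence
            for i in range(0, len(seq), _FASTA_WRAP):
                handle.write(seq[i : i + _FASTA_WRAP] + "\n")
    finally:
        if close:
            handle.close()


def read_alignment(source: str | Path | IO[str]) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`."""
    return Alignment(read_fasta(source, aligned=True))


# ---------------------------------------------------------------------------
# GFF3-style feature tables
# ---------------------------------------------------------------------------

_GFF_SOURCE = "mitokit"
_GFF_TYPE_BY_KIND = {"PCG": "gene", "tRNA": "tRNA", "rRNA": "rRNA", "control": "region"}


def read_features(source: str | Path | IO[str]) -> list[FeatureRecord]:
    """Read a GFF3 feature table (tab-separated, 1-based inclusive).

    Gene name and kind are carried in the attributes column as
    ``gene=<name>;kind=<PCG|tRNA|rRNA|control>``.  Coordinates are converted
    to internal 0-based half-open (start-1, end).
    """
    handle, close = _as_text_handle(source)
    try:
        feats: list[FeatureRecord] = []
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(
                    f"line {lineno}: expected 9 tab-separated columns, got {len(cols)}"
                )
            _seqid, _src, _type, start_s, end_s, _score, strand, _phase, attrs = cols
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"line {lineno}: non-integer coordinates") from exc
            if end1 < start1:
                raise FormatError(
                    f"line {lineno}: end {end1} < start {start1}"
                )
            attr_map = {}
            for item in attrs.split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attr_map[k.strip()] = v.strip()
            gene = attr_map.get("gene") or attr_map.get("Name") or attr_map.get("ID")
            if not gene:
                raise FormatError(f"line {lineno}: missing gene attribute")
            kind = attr_map.get("kind")
            if kind is None:
                raise FormatError(f"line {lineno}: missing kind attribute")
            feats.append(
                FeatureRecord(
                    gene_name=gene,
                    kind=kind,
                    strand=strand,
                    start=start1 - 1,
                    end=end1,
                )
            )
        if not feats:
            raise FormatError("empty feature table")
        return feats
    finally:
        if close:
            handle.close()


def write_features(
    features: Iterable[FeatureRecord],
    dest: str | Path | IO[str],
    *,
    seqid: str = "mitogenome",
) -> None:
    """Write features as GFF3 (1-based inclusive coordinates)."""
    handle, close = _as_text_handle(dest, "w")
    try:
        handle.write("##gff-version 3\n")
        for f in features:
            handle.write(
                "\t".join(
                    [
                        seqid,
                        _GFF_SOURCE,
                        _GFF_TYPE_BY_KIND[f.kind],
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        f"gene={f.gene_name};kind={f.kind}",
                    ]
                )
                + "\n"
            )
    finally:
        if close:
            handle.close()


def read_annotated_genome(
    fasta: str | Path | IO[str], gff: str | Path | IO[str]
) -> AnnotatedMitogenome:
    records = read_fasta(fasta)
    if len(records) != 1:
        raise FormatError(
            f"expected a single genome record, found {len(records)}"
        )
    return AnnotatedMitogenome(records[0], read_features(gff))


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def read_newick(source: str | Path | IO[str]) -> dendropy.Tree:
    """Parse a rooted Newick tree; tip labels must be unique."""
    handle, close = _as_text_handle(source)
    try:
        text = handle.read()
    finally:
        if close:
            handle.close()
    if not text.strip():
        raise FormatError("empty Newick stream")
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"Newick parse error: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise FormatError("duplicate tip labels in Newick tree")
    tree.is_rooted = True
    return tree


def write_newick(tree: dendropy.Tree, dest: str | Path | IO[str]) -> None:
    handle, close = _as_text_handle(dest, "w")
    try:
        handle.write(
            tree.as_string(
                schema="newick",
                suppress_rooting=True,
                unquoted_underscores=True,
                real_value_format_specifier=".10g",
            )
        )
    finally:
        if close:
            handle.close()


def newick_string(tree: dendropy.Tree) -> str:
    buf = _stdio.StringIO()
    write_newick(tree, buf)
    return buf.getvalue().strip()


# ---------------------------------------------------------------------------
# TSV reports
# ---------------------------------------------------------------------------

def write_tsv(
    rows: Iterable[Sequence], header: Sequence[str], dest: str | Path | IO[str]
) -> None:
    """Write a TSV report with a header row."""
    handle, close = _as_text_handle(dest, "w")
    try:
        handle.write("\t".join(header) + "\n")
        for row in rows:
            handle.write("\t".join(str(x) for x in row) + "\n")
    finally:
        if close:
            handle.close()
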