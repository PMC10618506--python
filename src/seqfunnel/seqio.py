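"""Sequence, tree and matrix file I/O.

Reads and validates the formats the pipeline touches: FASTA (unaligned, or
aligned with ``-`` gap characters), Newick trees, and labeled CSV distance
matrices (the matrix readers live in :mod:`seqfunnel.distances` and are
re-exported here).

Normalization on input: sequences are uppercased, RNA ``U`` is mapped to
``T``, and IUPAC ambiguity codes other than ``N`` are mapped to ``N`` (a
warning is logged with the count). Gaps are stripped from unaligned input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import dendropy
from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

#: residues allowed after normalization
ALPHABET = frozenset("ACGTN-")

_IUPAC_AMBIGUOUS = set("RYSWKMBDHV")


class SeqIOError(ValueError):
    """Malformed or inconsistent sequence/tree/matrix input."""


@dataclass(frozen=True)
class SequenceRecord:
    """One labeled DNA sequence.

    ``seq`` is normalized: uppercase, over the alphabet ``{A,C,G,T,N,-}``.
    """

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise SeqIOError(f"sequence id must be a non-empty token, got {self.id!r}")
        bad = set(self.seq) - ALPHABET
        if bad:
            raise SeqIOError(
                f"record {self.id!r}: residues {sorted(bad)} outside alphabet ACGTN-"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class SequenceSet:
    """Ordered collection of records; order is preserved end-to-end.

    If ``aligned`` is true all sequences must have equal length (gap
    characters included).
    """

    records: list[SequenceRecord]
    aligned: bool = False
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SeqIOError(f"duplicate sequence ids: {dupes}")
        if self.aligned:
            lengths = {len(r) for r in self.records}
            if len(lengths) > 1:
                raise SeqIOError(
                    f"aligned set has ragged lengths: {sorted(lengths)}"
                )
        self._index = {r.id: i for i, r in enumerate(self.records)}

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __getitem__(self, key: str | int) -> SequenceRecord:
        if isinstance(key, str):
            return self.records[self._index[key]]
        return self.records[key]


def normalize_sequence(raw: str, *, strip_gaps: bool, record_id: str = "?") -> str:
    """Uppercase, map U->T, map non-N ambiguity codes to N, optionally drop gaps."""
    s = raw.upper().replace("U", "T")
    n_ambig = sum(s.count(c) for c in _IUPAC_AMBIGUOUS)
    if n_ambig:
        logger.warning(
            "record %s: %d ambiguity code(s) mapped to N", record_id, n_ambig
        )
        table = str.maketrans({c: "N" for c in _IUPAC_AMBIGUOUS})
        s = s.translate(table)
    if strip_gaps:
        s = s.replace("-", "").replace(".", "")
    bad = set(s) - ALPHABET
    if bad:
        raise SeqIOError(
            f"record {record_id!r}: unrecognized residues {sorted(bad)}"
        )
    return s


def read_fasta(path: str | Path, aligned: bool = False) -> SequenceSet:
    """Read a FASTA file into a :class:`SequenceSet`.

    Records come back in file order. Unaligned input has gaps stripped and
    must be non-empty afterwards; aligned input keeps gaps and is checked
    for equal lengths.
    """
    records = []
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        seq = normalize_sequence(str(rec.seq), strip_gaps=not aligned, record_id=rec.id)
        if not seq.replace("-", ""):
            raise SeqIOError(f"record {rec.id!r} is empty after gap stripping")
        records.append(SequenceRecord(id=rec.id, seq=seq))
    if not records:
        raise SeqIOError(f"no FASTA records found in {path}")
    return SequenceSet(records=records, aligned=aligned)


def write_fasta(seqs: SequenceSet | Iterable[SequenceRecord], path: str | Path) -> None:
    recs = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in seqs
    ]
    _BioSeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Newick trees (dendropy-backed)
# ---------------------------------------------------------------------------

def parse_newick(text: str, rooted: bool | None = None) -> dendropy.Tree:
    """Parse a Newick string, validating leaf-label uniqueness."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        if "Duplicate taxon" in str(exc):
            raise SeqIOError(f"duplicate leaf labels in Newick: {exc}") from exc
        raise SeqIOError(f"malformed Newick: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise SeqIOError(f"duplicate leaf labels in Newick: {dupes}")
    if rooted is not None:
        tree.is_rooted = rooted
    return tree


def read_newick(path: str | Path, rooted: bool | None = None) -> dendropy.Tree:
    return parse_newick(Path(path).read_text(), rooted=rooted)


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(tree_to_newick(tree))


def tree_to_newick(tree: dendropy.Tree) -> str:
    return (
        tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        ).strip()
        + "\n"
    )


# Matrix CSV/PHYLIP I/O is implemented next to the DistanceMatrix type; the
# names are re-exported here so all file-format entry points share a module.
def read_matrix_csv(path):  # noqa: D103 - thin re-export
    from .distances import read_matrix_csv as _f

    return _f(path)


def write_matrix_csv(matrix, path) -> None:  # noqa: D103 - thin re-export
    from .distances import write_matrix_csv as _f

    _f(matrix, path)


def write_matrix_phylip(matrix, path) -> None:  # noqa: D103 - thin re-export
    from .distances import write_matrix_phylip as _f

    _f(matrix, path)
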