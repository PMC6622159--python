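"""Multiple-sequence alignments: FASTA/A2M reading and reference-column
filtering.

The coupling analysis operates on an alignment whose columns correspond
one-to-one to the residues of a reference structure.  Alignments built
against a reference sequence are therefore filtered to the columns where
the reference is ungapped; all sequences and all other columns are kept
regardless of their gap content.

Sequences are stored internally as an (n_seqs, n_cols) integer matrix
over a 21-state alphabet (20 amino acids plus gap), the container the
frequency-based scoring in :mod:`coevocontacts.coupling_scores` works
on.  A2M conventions (lowercase insert states, '.' gaps) are normalised
on input; ambiguity codes (B, Z, X) are mapped to gap by default so they
never contribute invented amino-acid counts.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["ALPHABET", "GAP", "Alignment", "read_alignment", "write_alignment", "filter_to_reference"]

ALPHABET = "ACDEFGHIKLMNPQRSTVWY-"
GAP = 20
_CODE = {ch: k for k, ch in enumerate(ALPHABET)}


@dataclass(frozen=True)
class Alignment:
    """Gapped amino-acid sequences with a designated reference row."""

    ids: tuple[str, ...]
    matrix: np.ndarray  # (n_seqs, n_cols) uint8 codes into ALPHABET
    ref_row: int = 0

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=np.uint8)
        if m.ndim != 2 or m.shape[0] == 0 or m.shape[1] == 0:
            raise ValueError("alignment must be a non-empty 2-D matrix")
        if m.shape[0] != len(self.ids):
            raise ValueError("ids/matrix row mismatch")
        if not (0 <= self.ref_row < m.shape[0]):
            raise ValueError(f"ref_row {self.ref_row} out of range")
        if m.max(initial=0) > GAP:
            raise ValueError("matrix codes exceed the 21-state alphabet")
        object.__setattr__(self, "matrix", m)

    @property
    def n_seqs(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cols(self) -> int:
        return self.matrix.shape[1]

    def sequence(self, row: int) -> str:
        return "".join(ALPHABET[c] for c in self.matrix[row])

    @property
    def reference(self) -> str:
        return self.sequence(self.ref_row)


def _encode(seq: str, id_: str) -> np.ndarray:
    # A2M: '.' is a gap in insert columns, lowercase marks insert states
    s = seq.replace(".", "-").upper()
    out = np.empty(len(s), dtype=np.uint8)
    for k, ch in enumerate(s):
        if ch in _CODE:
            out[k] = _CODE[ch]
        elif ch in "BZXJUO*":
            out[k] = GAP  # ambiguity/rare codes carry no usable frequency
        else:
            raise ValueError(f"sequence {id_!r}: unexpected character {ch!r}")
    return out


def read_alignment(source: str | Path, ref_id: str | None = None) -> Alignment:
    """Read a FASTA/A2M alignment.

    ``source`` may be a path or the alignment text itself.  The reference
    row is the first record, or the record whose id equals ``ref_id``.
    """
    if isinstance(source, str) and not source.strip():
        raise ValueError("no sequences in alignment input")
    text_mode = isinstance(source, str) and (source.lstrip().startswith(">"))
    handle = io.StringIO(source) if text_mode else open(source)
    try:
        records = list(SeqIO.parse(handle, "fasta"))
    finally:
        handle.close()
    if not records:
        raise ValueError("no sequences in alignment input")
    rows = [_encode(str(r.seq), r.id) for r in records]
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
    ref_row = 0
    if ref_id is not None:
        ids = [r.id for r in records]
        if ref_id not in ids:
            raise ValueError(f"reference id {ref_id!r} not in alignment")
        ref_row = ids.index(ref_id)
    return Alignment(ids=tuple(r.id for r in records), matrix=np.vstack(rows), ref_row=ref_row)


def write_alignment(aln: Alignment, path: str | Path | None = None) -> str:
    """Write the alignment as FASTA; returns the text."""
    records = [
        SeqRecord(Seq(aln.sequence(k)), id=aln.ids[k], description="")
        for k in range(aln.n_seqs)
    ]
    buf = io.StringIO()
    SeqIO.write(records, buf, "fasta")
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text


def filter_to_reference(aln: Alignment) -> Alignment:
    """Keep exactly the columns where the reference row is ungapped.

    All sequences are retained regardless of their own gap coverage.
    Idempotent: filtering a filtered alignment is the identity.
    """
    keep = aln.matrix[aln.ref_row] != GAP
    if not keep.any():
        raise ValueError("reference sequence is entirely gapped")
    return Alignment(ids=aln.ids, matrix=aln.matrix[:, keep], ref_row=aln.ref_row)
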