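"""DNA alignment container with IUPAC ambiguity support and pattern compression."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import AlignIO, SeqIO

__all__ = ["AlignmentData", "read_alignment", "AlignmentError", "IUPAC_MASKS"]


class AlignmentError(ValueError):
    pass


# 4-bit masks over (A, C, G, T); gaps and '?' are full ambiguity
IUPAC_MASKS = {
    "A": 0b0001, "C": 0b0010, "G": 0b0100, "T": 0b1000, "U": 0b1000,
    "R": 0b0101, "Y": 0b1010, "S": 0b0110, "W": 0b1001,
    "K": 0b1100, "M": 0b0011,
    "B": 0b1110, "D": 0b1101, "H": 0b1011, "V": 0b0111,
    "N": 0b1111, "-": 0b1111, "?": 0b1111, "X": 0b1111, ".": 0b1111,
    "O": 0b1111,
}

_MASK_TABLE = np.zeros(256, dtype=np.uint8)
for _ch, _m in IUPAC_MASKS.items():
    _MASK_TABLE[ord(_ch)] = _m
    _MASK_TABLE[ord(_ch.lower())] = _m


@dataclass
class AlignmentData:
    """Taxa-by-sites character matrix plus compressed site patterns.

    ``patterns`` has shape (n_taxa, n_patterns) holding IUPAC bit masks over
    (A, C, G, T); ``pattern_weights`` are the column multiplicities.
    """

    taxa: list[str]
    matrix: np.ndarray          # (n_taxa, n_sites) uint8 bit masks
    patterns: np.ndarray        # (n_taxa, n_patterns) uint8 bit masks
    pattern_weights: np.ndarray  # (n_patterns,) int

    @classmethod
    def from_sequences(cls, taxa: list[str], seqs: list[str]) -> "AlignmentData":
        if len(taxa) != len(seqs) or not taxa:
            raise AlignmentError("need equal, nonzero numbers of labels and sequences")
        if len(set(taxa)) != len(taxa):
            dupes = sorted({t for t in taxa if taxa.count(t) > 1})
            raise AlignmentError(f"duplicate taxa labels: {dupes}")
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise AlignmentError(f"ragged alignment: row lengths {sorted(lengths)}")
        (n_sites,) = lengths
        if n_sites == 0:
            raise AlignmentError("alignment has zero sites")
        raw = np.frombuffer(
            "".join(seqs).encode("ascii"), dtype=np.uint8
        ).reshape(len(taxa), n_sites)
        matrix = _MASK_TABLE[raw]
        if np.any(matrix == 0):
            t, s = np.argwhere(matrix == 0)[0]
            raise AlignmentError(
                f"invalid character {chr(raw[t, s])!r} for taxon {taxa[t]!r} "
                f"at site {s + 1}"
            )
        patterns, inverse, weights = np.unique(
            matrix, axis=1, return_inverse=True, return_counts=True
        )
        del inverse
        return cls(
            taxa=list(taxa),
            matrix=matrix,
            patterns=patterns,
            pattern_weights=weights.astype(np.int64),
        )

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[1]

    def sequence(self, taxon: str) -> str:
        """Decode one row back to IUPAC text (canonical uppercase codes)."""
        inv = {m: c for c, m in IUPAC_MASKS.items() if c not in "U?X.O-"}
        inv[0b1111] = "N"
        row = self.matrix[self.taxa.index(taxon)]
        return "".join(inv[int(m)] for m in row)

    def empirical_freqs(self) -> np.ndarray:
        """Base frequencies from unambiguous characters, floored away from 0."""
        counts = np.zeros(4)
        for b in range(4):
            counts[b] = np.count_nonzero(self.matrix == (1 << b))
        counts += 0.25  # pseudo-weight: keeps all freqs strictly positive
        return counts / counts.sum()

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for t in self.taxa:
                fh.write(f">{t}\n{self.sequence(t)}\n")

    def write_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f" {self.n_taxa} {self.n_sites}\n")
            for t in self.taxa:
                fh.write(f"{t}  {self.sequence(t)}\n")


def read_alignment(path, fmt: str = None) -> AlignmentData:
    """Read a FASTA or PHYLIP (sequential or interleaved) alignment.

    ``fmt`` is 'fasta' or 'phylip'; if omitted it is sniffed from the first
    non-blank character ('>' means FASTA).
    """
    path = str(path)
    if fmt is None:
        with open(path) as fh:
            head = fh.read(1024).lstrip()
        fmt = "fasta" if head.startswith(">") else "phylip"
    fmt = fmt.lower()
    if fmt == "fasta":
        records = list(SeqIO.parse(path, "fasta"))
        if not records:
            raise AlignmentError(f"no sequences found in {path}")
        return AlignmentData.from_sequences(
            [r.id for r in records], [str(r.seq) for r in records]
        )
    if fmt == "phylip":
        last_err = None
        for schema in ("phylip-relaxed", "phylip", "phylip-sequential"):
            try:
                aln = AlignIO.read(path, schema)
                return AlignmentData.from_sequences(
                    [r.id for r in aln], [str(r.seq) for r in aln]
                )
            except AlignmentError:
                raise
            except Exception as exc:
                last_err = exc
        raise AlignmentError(f"could not parse PHYLIP file {path}: {last_err}")
    raise AlignmentError(f"unknown alignment format {fmt!r}")
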