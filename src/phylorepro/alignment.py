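"""Nucleotide alignments with site-pattern compression.

Thin wrapper over a taxa x sites character matrix.  File I/O (FASTA,
relaxed PHYLIP) goes through Biopython.  Likelihood code consumes the
compressed site patterns: the distinct alignment columns and their
multiplicities, which leave the total log-likelihood unchanged while
collapsing repeated columns.
"""

from __future__ import annotations

import io
from typing import Iterable, Sequence

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.Align import MultipleSeqAlignment

__all__ = ["Alignment", "AlignmentError", "CHAR_PARTIALS"]

# IUPAC codes -> conditional likelihood vector over (A, C, G, T).
# Ambiguity and gap characters marginalize over their compatible states.
CHAR_PARTIALS: dict[str, tuple[float, float, float, float]] = {
    "A": (1, 0, 0, 0), "C": (0, 1, 0, 0), "G": (0, 0, 1, 0), "T": (0, 0, 0, 1),
    "U": (0, 0, 0, 1),
    "R": (1, 0, 1, 0), "Y": (0, 1, 0, 1), "S": (0, 1, 1, 0), "W": (1, 0, 0, 1),
    "K": (0, 0, 1, 1), "M": (1, 1, 0, 0),
    "B": (0, 1, 1, 1), "D": (1, 0, 1, 1), "H": (1, 1, 0, 1), "V": (1, 1, 1, 0),
    "N": (1, 1, 1, 1), "-": (1, 1, 1, 1), "?": (1, 1, 1, 1), ".": (1, 1, 1, 1),
}
_CODE_OF = {c: i for i, c in enumerate(CHAR_PARTIALS)}
_PARTIAL_TABLE = np.array(list(CHAR_PARTIALS.values()), dtype=float)


class AlignmentError(ValueError):
    """Invalid alignment."""


class Alignment:
    """A gapped-or-not nucleotide alignment over uniquely named taxa.

    Parameters
    ----------
    records : iterable of (name, sequence) pairs, order preserved.
    """

    def __init__(self, records: Iterable[tuple[str, str]]):
        pairs = [(str(n), str(s).upper()) for n, s in records]
        if not pairs:
            raise AlignmentError("empty alignment")
        names = [n for n, _ in pairs]
        if len(set(names)) != len(names):
            raise AlignmentError("duplicate sequence names")
        lengths = {len(s) for _, s in pairs}
        if len(lengths) != 1:
            raise AlignmentError(f"unequal sequence lengths: {sorted(lengths)}")
        bad = {ch for _, s in pairs for ch in s if ch not in CHAR_PARTIALS}
        if bad:
            raise AlignmentError(f"unrecognized characters: {sorted(bad)}")
        self.taxa: tuple[str, ...] = tuple(names)
        self.length: int = lengths.pop()
        if self.length < 1:
            raise AlignmentError("alignment must have at least one site")
        self._seqs: dict[str, str] = dict(pairs)
        self._pattern_cache: tuple | None = None

    # ------------------------------------------------------------------ #

    def sequence(self, name: str) -> str:
        return self._seqs[name]

    def __len__(self) -> int:
        return self.length

    def n_taxa(self) -> int:
        return len(self.taxa)

    def matrix(self, taxon_order: Sequence[str] | None = None) -> np.ndarray:
        """Integer code matrix (m, length) in the requested taxon order."""
        order = tuple(taxon_order) if taxon_order is not None else self.taxa
        out = np.empty((len(order), self.length), dtype=np.uint8)
        for i, name in enumerate(order):
            try:
                seq = self._seqs[name]
            except KeyError:
                raise AlignmentError(f"taxon {name!r} not in alignment") from None
            out[i] = [_CODE_OF[ch] for ch in seq]
        return out

    def patterns(self, taxon_order: Sequence[str] | None = None
                 ) -> tuple[np.ndarray, np.ndarray]:
        """Compressed site patterns.

        Returns ``(codes, weights)`` where ``codes`` is (m, n_patterns) of
        integer character codes and ``weights`` the column multiplicities
        (summing to the alignment length).
        """
        order = tuple(taxon_order) if taxon_order is not None else self.taxa
        if self._pattern_cache is not None and self._pattern_cache[0] == order:
            return self._pattern_cache[1], self._pattern_cache[2]
        mat = self.matrix(order)
        cols, counts = np.unique(mat.T, axis=0, return_counts=True)
        codes, weights = cols.T.copy(), counts.astype(float)
        self._pattern_cache = (order, codes, weights)
        return codes, weights

    def leaf_partials(self, taxon_order: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        """(partials, weights): partials is (m, n_patterns, 4) conditional
        likelihood vectors for the compressed patterns."""
        codes, weights = self.patterns(taxon_order)
        return _PARTIAL_TABLE[codes], weights

    def base_frequencies(self) -> np.ndarray:
        """Empirical frequencies of unambiguous A, C, G, T characters."""
        counts = np.zeros(4)
        for s in self._seqs.values():
            for i, ch in enumerate("ACGT"):
                counts[i] += s.count(ch)
        counts[3] += sum(s.count("U") for s in self._seqs.values())
        if counts.sum() == 0:
            raise AlignmentError("no unambiguous nucleotides in alignment")
        return counts / counts.sum()

    def bootstrap(self, rng: np.random.Generator) -> "Alignment":
        """Resample columns with replacement (same length)."""
        idx = rng.integers(0, self.length, size=self.length)
        return self.subset_sites(idx)

    def subset_sites(self, indices) -> "Alignment":
        idx = np.asarray(indices)
        return Alignment(
            (name, "".join(self._seqs[name][i] for i in idx)) for name in self.taxa
        )

    # ------------------------------------------------------------------ #
    # I/O via Biopython

    @classmethod
    def from_fasta(cls, source) -> "Alignment":
        records = [(r.id, str(r.seq)) for r in SeqIO.parse(source, "fasta")]
        return cls(records)

    @classmethod
    def from_phylip(cls, source) -> "Alignment":
        aln = AlignIO.read(source, "phylip-relaxed")
        return cls((r.id, str(r.seq)) for r in aln)

    def to_fasta(self, dest) -> None:
        recs = [SeqRecord(Seq(self._seqs[n]), id=n, description="")
                for n in self.taxa]
        SeqIO.write(recs, dest, "fasta")

    def to_phylip(self, dest) -> None:
        msa = MultipleSeqAlignment(
            [SeqRecord(Seq(self._seqs[n]), id=n, description="")
             for n in self.taxa]
        )
        AlignIO.write(msa, dest, "phylip-relaxed")

    def fasta_str(self) -> str:
        buf = io.StringIO()
        self.to_fasta(buf)
        return buf.getvalue()

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Alignment m={self.n_taxa()} sites={self.length}>"
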