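"""Concatenated multiple sequence alignments and column statistics.

A *concatenated* MSA covers a two-protein (or two-domain) complex: each row
is one homologous sequence, columns ``0..N1-1`` belong to the first protein
and columns ``N1..N-1`` to the second.  The module reads aligned FASTA,
validates the alignment, and computes the single-column and pairwise column
frequency distributions (optionally smoothed with a per-cell pseudocount)
that every downstream coevolution statistic consumes.

All indices exposed by this module are 0-based; ``boundary`` is the *count*
of first-protein columns (N1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

#: 20 standard amino acids followed by the gap symbol.  Gap is a first-class
#: state (q = 21): gappy columns are modelled rather than dropped.
PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY-"

GAP = "-"


class AlignmentShapeError(ValueError):
    """Rows of the alignment do not all have the same length."""


class AlignmentFormatError(ValueError):
    """The input is not a usable alignment file (e.g. empty FASTA)."""


@dataclass(frozen=True)
class Alignment:
    """An aligned set of concatenated sequences over a fixed alphabet.

    Parameters
    ----------
    matrix
        Integer-encoded alignment of shape ``(M, N)``; entry ``(s, i)`` is
        the index into ``alphabet`` of the symbol in row ``s``, column ``i``.
    alphabet
        The symbol set; its length is the state count ``q``.
    boundary
        Number of columns belonging to the first protein (``N1``), so
        ``N2 = N - N1``.  Must satisfy ``1 <= N1 < N``.
    """

    matrix: np.ndarray
    alphabet: str
    boundary: int
    ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.ndim != 2 or m.shape[0] < 1 or m.shape[1] < 2:
            raise AlignmentShapeError(
                f"alignment matrix must be (M>=1, N>=2), got {m.shape}"
            )
        if not (1 <= self.boundary < m.shape[1]):
            raise ValueError(
                f"boundary must be in [1, N-1]={m.shape[1] - 1}, got {self.boundary}"
            )
        if m.min() < 0 or m.max() >= len(self.alphabet):
            raise ValueError("alignment contains symbols outside the alphabet")
        object.__setattr__(self, "matrix", m)

    # -- dimensions -------------------------------------------------------
    @property
    def n_sequences(self) -> int:
        """M, the number of rows."""
        return int(self.matrix.shape[0])

    @property
    def length(self) -> int:
        """N, the number of columns."""
        return int(self.matrix.shape[1])

    @property
    def n1(self) -> int:
        return self.boundary

    @property
    def n2(self) -> int:
        return self.length - self.boundary

    @property
    def n_states(self) -> int:
        """q, the alphabet size."""
        return len(self.alphabet)

    # -- construction -----------------------------------------------------
    @classmethod
    def from_sequences(
        cls,
        sequences: list[str],
        boundary: int,
        alphabet: str = PROTEIN_ALPHABET,
        ids: tuple[str, ...] | None = None,
        canonicalise: bool | None = None,
    ) -> "Alignment":
        """Build an alignment from symbol strings.

        With ``canonicalise`` (defaulting to on whenever the alphabet has a
        gap state) symbols are upper-cased and anything outside the alphabet
        — unknown residues, ``.``, ``X`` — is mapped to the gap state.
        """
        if canonicalise is None:
            canonicalise = GAP in alphabet
        if not sequences:
            raise AlignmentFormatError("no sequences given")
        lengths = {len(s) for s in sequences}
        if len(lengths) != 1:
            raise AlignmentShapeError(
                f"sequences have unequal lengths: {sorted(lengths)}"
            )
        lut = np.full(256, -1, dtype=np.int16)
        for k, sym in enumerate(alphabet):
            lut[ord(sym)] = k
            lut[ord(sym.lower())] = k
        if canonicalise:
            if GAP not in alphabet:
                raise ValueError("canonicalisation requires a gap state in the alphabet")
            gap_code = alphabet.index(GAP)
            missing = lut < 0
            lut[missing] = gap_code
        raw = np.frombuffer(
            "".join(sequences).encode("ascii"), dtype=np.uint8
        ).reshape(len(sequences), -1)
        enc = lut[raw]
        if (enc < 0).any():
            bad = sorted({chr(c) for c in raw[enc < 0]})
            raise ValueError(f"symbols outside alphabet: {bad}")
        return cls(
            matrix=enc.astype(np.int32),
            alphabet=alphabet,
            boundary=boundary,
            ids=tuple(ids) if ids is not None else tuple(f"seq{i}" for i in range(len(sequences))),
        )

    def sequences(self) -> list[str]:
        """Decode rows back to symbol strings."""
        alpha = np.array(list(self.alphabet))
        return ["".join(row) for row in alpha[self.matrix]]


def read_msa(
    path, boundary: int, alphabet: str = PROTEIN_ALPHABET
) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`.

    Rows are kept in file order; symbols are upper-cased and any symbol
    outside the 20 amino acids is mapped to the gap state.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentFormatError(f"no FASTA records in {path}")
    seqs = [str(r.seq) for r in records]
    if not (1 <= boundary < len(seqs[0])):
        raise ValueError(
            f"boundary {boundary} out of range for alignment of length {len(seqs[0])}"
        )
    return Alignment.from_sequences(
        seqs, boundary, alphabet=alphabet, ids=tuple(r.id for r in records)
    )


@dataclass(frozen=True)
class FrequencyModel:
    """Single and pairwise column frequency distributions of an alignment.

    ``single[i, a]`` is the (smoothed) frequency of state ``a`` in column
    ``i``; the pair table is stored flat as an ``(N*q, N*q)`` symmetric
    matrix whose ``(i, j)`` block is ``f_ij(a, b)``.  Smoothing adds the
    pseudocount ``lam`` to every cell, i.e.::

        f_i(a)     = (count_i(a) + lam)  / (M + q   * lam)
        f_ij(a, b) = (count_ij(a,b)+lam) / (M + q^2 * lam)

    so that marginalising the pair table over ``b`` reproduces the single
    frequencies computed with pseudocount ``q * lam`` (exactly equal when
    ``lam = 0``).  Diagonal blocks hold ``f_ii(a, a) = f_i(a)`` on their
    diagonal by convention.
    """

    single: np.ndarray
    pair_flat: np.ndarray
    pseudocount: float
    n_states: int

    @property
    def length(self) -> int:
        return int(self.single.shape[0])

    def pair(self, i: int, j: int) -> np.ndarray:
        """The q x q joint distribution of columns ``i`` and ``j``."""
        q = self.n_states
        return self.pair_flat[i * q : (i + 1) * q, j * q : (j + 1) * q]


def frequencies(aln: Alignment, pseudocount: float = 0.0) -> FrequencyModel:
    """Empirical (optionally pseudocount-smoothed) column frequencies.

    With ``pseudocount = 0`` these are the raw relative frequencies of the
    alignment.  Deterministic: identical input gives bit-identical output.
    """
    if pseudocount < 0:
        raise ValueError(f"pseudocount must be non-negative, got {pseudocount}")
    m, n = aln.matrix.shape
    q = aln.n_states
    one_hot_cols = aln.matrix + q * np.arange(n)[None, :]
    from scipy import sparse

    rows = np.repeat(np.arange(m), n)
    x = sparse.csr_matrix(
        (np.ones(m * n), (rows, one_hot_cols.ravel())), shape=(m, n * q)
    )
    counts2 = np.asarray((x.T @ x).todense())
    counts1 = counts2.diagonal().reshape(n, q).copy()
    lam = float(pseudocount)
    single = (counts1 + lam) / (m + q * lam)
    pair_flat = (counts2 + lam) / (m + q * q * lam)
    # i = j blocks are not a pair distribution; store diag(f_i) there.
    for i in range(n):
        blk = np.zeros((q, q))
        np.fill_diagonal(blk, single[i])
        pair_flat[i * q : (i + 1) * q, i * q : (i + 1) * q] = blk
    return FrequencyModel(
        single=single, pair_flat=pair_flat, pseudocount=lam, n_states=q
    )


def column_entropy(freq: FrequencyModel, i: int) -> float:
    """Shannon entropy of column ``i`` in nats, with 0 ln 0 = 0."""
    if not (0 <= i < freq.length):
        raise IndexError(f"column {i} out of range 0..{freq.length - 1}")
    p = freq.single[i]
    nz = p > 0
    return float(-(p[nz] * np.log(p[nz])).sum())


def write_frequency_table(freq: FrequencyModel, path) -> None:
    """Write the single-column frequencies as TSV (column, state, freq)."""
    with open(path, "w") as fh:
        fh.write("column\tstate\tfrequency\n")
        for i in range(freq.length):
            for a in range(freq.n_states):
                fh.write(f"{i}\t{a}\t{freq.single[i, a]:.10g}\n")
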