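"""Per-decoy score components for docking-decoy rescoring.

Five components are computed for each decoy pose from its interface set I
(cross-chain surface residue pairs in heavy-atom contact):

* ``S_N`` — interface size: the number of distinct interface residues;
* ``S_RP`` — residue-pair potential: the sum of a pluggable 20x20
  knowledge-based potential over the interface pairs;
* ``S_ent`` — interaction-weighted mean MSA column entropy of the
  interface residues (low = conserved interface);
* ``S_CT`` — complementarity-trace score: the proportion of interface
  pairs whose polarity-group complementarity (both hydrophobic, both
  polar, or opposite charges — with first/second structural-neighbour
  rescue) is preserved in at least 95% of the MSA rows;
* ``S_CMM`` — the interface-level correlated-mutation score: residue-level
  CMM values D(i, j) are smoothed over surface neighbourhoods
  (chi(i, j) = mean of D(i, k) over k in N_j), standardised per residue
  against all interface pairs on its own protein, symmetrised into
  Z(i, j), and averaged over I.  ``S_CMM_raw`` is the unsmoothed mean of
  D over I.

All components depend on the pose only through inter-atomic distances, so
they are invariant under global rigid motion of the decoy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .alignment import Alignment, FrequencyModel, column_entropy
from .maxent import CouplingMatrix
from .structure import ComplexStructure, InterfaceSet, UndefinedScoreError

logger = logging.getLogger(__name__)

PRESERVATION_THRESHOLD = 0.95

#: Default polarity-group assignment (editable; group membership is a
#: package choice, only the four groups themselves are canonical).
DEFAULT_POLARITY = {
    "hydrophobic": set("AVLIMFPG"),
    "polar": set("STNQCYW"),
    "positive": set("KRH"),
    "negative": set("DE"),
}


@dataclass(frozen=True)
class PolarityScheme:
    """Maps each amino acid to one of four polarity groups.

    Groups: 0 hydrophobic, 1 polar, 2 positively charged, 3 negatively
    charged; gap and unknown symbols map to -1 (no group).
    """

    groups: dict[str, int]

    @classmethod
    def default(cls) -> "PolarityScheme":
        g: dict[str, int] = {}
        for code, name in enumerate(("hydrophobic", "polar", "positive", "negative")):
            for aa in DEFAULT_POLARITY[name]:
                g[aa] = code
        return cls(groups=g)

    @classmethod
    def from_tsv(cls, path) -> "PolarityScheme":
        """Read an (amino acid, group name) TSV."""
        codes = {"hydrophobic": 0, "polar": 1, "positive": 2, "negative": 3}
        g = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                aa, name = line.split("\t")
                g[aa.upper()] = codes[name.lower()]
        return cls(groups=g)

    def code(self, aa: str) -> int:
        return self.groups.get(aa.upper(), -1)

    def codes_for_alphabet(self, alphabet: str) -> np.ndarray:
        return np.array([self.code(sym) for sym in alphabet])


def complementary(a: str, b: str, scheme: PolarityScheme | None = None) -> bool:
    """True iff both hydrophobic, both polar, or oppositely charged.

    Gaps and unknown symbols are never complementary.
    """
    scheme = scheme or PolarityScheme.default()
    ga, gb = scheme.code(a), scheme.code(b)
    if ga < 0 or gb < 0:
        return False
    return (ga == gb and ga in (0, 1)) or {ga, gb} == {2, 3}


@dataclass(frozen=True)
class RPMatrix:
    """Symmetric 20x20 residue-pair potential, keyed by one-letter codes."""

    values: dict[tuple[str, str], float]
    source: str = ""

    @classmethod
    def from_tsv(cls, path) -> "RPMatrix":
        """Read a square TSV with one-letter row/column headers."""
        with open(path) as fh:
            lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
        header = lines[0].split("\t")[1:]
        vals: dict[tuple[str, str], float] = {}
        for ln in lines[1:]:
            parts = ln.split("\t")
            row = parts[0].upper()
            for colname, cell in zip(header, parts[1:]):
                vals[(row, colname.upper())] = float(cell)
        for (a, b), v in list(vals.items()):
            if abs(vals.get((b, a), v) - v) > 1e-9:
                raise ValueError(f"RP matrix not symmetric at ({a},{b})")
        return cls(values=vals, source=str(path))

    @classmethod
    def from_array(cls, letters: str, matrix: np.ndarray, source: str = "") -> "RPMatrix":
        matrix = np.asarray(matrix, float)
        if not np.allclose(matrix, matrix.T):
            raise ValueError("RP matrix must be symmetric")
        vals = {
            (a, b): float(matrix[i, j])
            for i, a in enumerate(letters)
            for j, b in enumerate(letters)
        }
        return cls(values=vals, source=source)

    def get(self, a: str, b: str) -> float:
        try:
            return self.values[(a.upper(), b.upper())]
        except KeyError:
            raise KeyError(f"RP matrix has no entry for pair ({a}, {b})") from None


@dataclass
class ScoreComponents:
    """All per-decoy score components, with audit intermediates."""

    S_N: int
    S_RP: float | None
    S_ent: float
    S_CT: float
    S_CMM: float
    S_CMM_raw: float
    chi: dict[tuple[int, int], float] = field(default_factory=dict)
    mu: dict[int, float] = field(default_factory=dict)
    sigma: dict[int, float] = field(default_factory=dict)
    z: dict[tuple[int, int], float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# CMM components
# ---------------------------------------------------------------------------

def _column_of(struct: ComplexStructure, k: int) -> int:
    col = struct.residues[k].column
    if col is None:
        raise UndefinedScoreError(f"residue index {k} has no MSA column")
    return col


def raw_cmm_score(d: CouplingMatrix, struct: ComplexStructure, iface: InterfaceSet) -> float:
    """Mean residue-level CMM over the interface pairs (nats)."""
    if not iface.pairs:
        raise UndefinedScoreError("interface set is empty")
    vals = [
        d.D[_column_of(struct, i), _column_of(struct, j)] for i, j in iface.pairs
    ]
    return float(np.mean(vals))


def neighbour_averaged_cmm(
    d: CouplingMatrix, struct: ComplexStructure, i: int, j: int
) -> float:
    """chi(i, j): D(i, .) averaged over the surface neighbourhood of j.

    ``i`` and ``j`` are residue indices on different chains; smoothing runs
    over N_j on j's own protein.
    """
    if struct.residues[i].chain == struct.residues[j].chain:
        raise ValueError("neighbour-averaged CMM requires a cross-chain pair")
    nbh = struct.surface_neighbourhood(j)
    if not nbh:
        raise UndefinedScoreError(f"residue {j} has an empty surface neighbourhood")
    ci = _column_of(struct, i)
    vals = [d.D[ci, _column_of(struct, k)] for k in nbh]
    return float(np.mean(vals))


def standardised_cmm(
    d: CouplingMatrix,
    struct: ComplexStructure,
    iface: InterfaceSet,
    standardise_over: str = "all_pairs",
) -> ScoreComponents:
    """Neighbour-averaged, per-residue standardised, symmetrised Z table.

    For each interface pair (i, j) the directed scores chi(i, j) and
    chi(j, i) are computed; residue i's standardisation set is
    { chi(l, k) : l in S_i, (l, k) in I }, i.e. all directed interface
    scores originating on i's own protein, summarised by the sample mean
    mu_i and sd sigma_i (n-1 denominator).  Z(i, j) symmetrises the two
    standardised terms.  A degenerate set (size < 2 or sigma = 0)
    contributes 0, logged.

    ``standardise_over`` picks the standardisation population.  The default
    ``"all_pairs"`` uses every directed cross-chain surface pair of the
    complex — a pose-invariant population, so Z measures how a pair's
    smoothed coupling compares with all candidate interactions.  The
    alternative ``"interface"`` restricts it to the decoy's own interface
    pairs; note that averaging Z back over that same interface then cancels
    exactly (S_CMM = 0 for every decoy), which is why it is not the
    default — it is retained for inspecting the Z table itself.

    Returns a partially-filled :class:`ScoreComponents` carrying the chi,
    mu, sigma and Z tables plus S_CMM and S_CMM_raw; the remaining fields
    are filled by :func:`score_decoy`.
    """
    if not iface.pairs:
        raise UndefinedScoreError("interface set is empty")
    if standardise_over not in ("interface", "all_pairs"):
        raise ValueError(f"unknown standardisation mode {standardise_over!r}")
    chi: dict[tuple[int, int], float] = {}
    for i, j in iface.pairs:
        chi[(i, j)] = neighbour_averaged_cmm(d, struct, i, j)
        chi[(j, i)] = neighbour_averaged_cmm(d, struct, j, i)

    # the standardisation set of residue i is the same for every residue on
    # its chain: all directed chi values whose origin l lies on that chain
    by_chain: dict[int, list[float]] = {1: [], 2: []}
    if standardise_over == "interface":
        for (l, k), v in chi.items():
            by_chain[struct.residues[l].chain].append(v)
    else:
        flags = struct.surface_flags()
        surf1 = [k for k in struct.chain_indices(1) if flags[k]]
        surf2 = [k for k in struct.chain_indices(2) if flags[k]]
        for l in surf1:
            for k in surf2:
                if struct.residues[l].column is None or struct.residues[k].column is None:
                    continue
                by_chain[1].append(neighbour_averaged_cmm(d, struct, l, k))
                by_chain[2].append(neighbour_averaged_cmm(d, struct, k, l))

    stats: dict[int, tuple[float, float]] = {}
    for chain in (1, 2):
        vals = np.array(by_chain[chain])
        if len(vals) < 2:
            logger.debug(
                "standardisation set on protein %d has %d values; "
                "its standardised terms contribute 0",
                chain,
                len(vals),
            )
            stats[chain] = (float(vals.mean()) if len(vals) else 0.0, 0.0)
            continue
        mu = float(vals.mean())
        sigma = float(vals.std(ddof=1))
        if sigma == 0.0:
            logger.debug(
                "zero spread in the standardisation set on protein %d; "
                "its standardised terms contribute 0",
                chain,
            )
        stats[chain] = (mu, sigma)

    def std_term(l: int, k: int) -> float:
        mu, sigma = stats[struct.residues[l].chain]
        if sigma == 0.0:
            return 0.0
        return (chi[(l, k)] - mu) / sigma

    z: dict[tuple[int, int], float] = {}
    for i, j in iface.pairs:
        val = 0.5 * (std_term(i, j) + std_term(j, i))
        z[(i, j)] = z[(j, i)] = val

    mu_map = {r: stats[struct.residues[r].chain][0] for r in iface.residues}
    sd_map = {r: stats[struct.residues[r].chain][1] for r in iface.residues}
    s_cmm = float(np.mean([z[p] for p in iface.pairs]))
    return ScoreComponents(
        S_N=interface_size_score(iface),
        S_RP=None,
        S_ent=float("nan"),
        S_CT=float("nan"),
        S_CMM=s_cmm,
        S_CMM_raw=raw_cmm_score(d, struct, iface),
        chi=chi,
        mu=mu_map,
        sigma=sd_map,
        z=z,
    )


def interface_cmm_score(
    z: dict[tuple[int, int], float], iface: InterfaceSet
) -> float:
    """S_CMM: mean symmetrised standardised score over the interface."""
    if not iface.pairs:
        raise UndefinedScoreError("interface set is empty")
    return float(np.mean([z[p] for p in iface.pairs]))


# ---------------------------------------------------------------------------
# Size, potential and entropy components
# ---------------------------------------------------------------------------

def interface_size_score(iface: InterfaceSet) -> int:
    """S_N: distinct residues (both chains) in any interface pair."""
    return len(iface.residues)


def rp_score(
    struct: ComplexStructure, iface: InterfaceSet, matrix: RPMatrix
) -> float:
    """S_RP: summed residue-pair potential over the interface pairs."""
    total = 0.0
    for i, j in iface.pairs:
        a = struct.residues[i].one_letter
        b = struct.residues[j].one_letter
        if a is None or b is None:
            raise KeyError(
                f"non-standard residue in interface pair "
                f"({struct.residues[i].name}, {struct.residues[j].name})"
            )
        total += matrix.get(a, b)
    return total


def entropy_score(
    freq: FrequencyModel, struct: ComplexStructure, iface: InterfaceSet
) -> float:
    """S_ent: interaction-count-weighted mean interface column entropy (nats).

    Equals sum over pairs of (H_i + H_j) / (2 |I|).
    """
    if not iface.pairs:
        raise UndefinedScoreError("interface set is empty")
    counts = iface.interaction_counts()
    num = 0.0
    den = 0
    for r, n_r in counts.items():
        num += n_r * column_entropy(freq, _column_of(struct, r))
        den += n_r
    return num / den


# ---------------------------------------------------------------------------
# Complementarity trace
# ---------------------------------------------------------------------------

def ct_score(
    aln: Alignment,
    struct: ComplexStructure,
    iface: InterfaceSet,
    scheme: PolarityScheme | None = None,
    preservation: float = PRESERVATION_THRESHOLD,
    neighbour_order: int = 2,
) -> float:
    """S_CT: fraction of interface pairs with preserved complementarity.

    For each interface pair (i, j) and each MSA row, the pair counts as
    complementary in that row if the symbol at i's column is complementary
    to the symbol at the column of j *or of any of j's structural
    neighbours up to* ``neighbour_order`` *(on the decoy geometry)*, or
    symmetrically with i's neighbours against j.  The pair is preserved
    when this holds in at least ``preservation`` of the rows; gapped
    symbols are never complementary, so gapped rows count against
    preservation.
    """
    if not iface.pairs:
        raise UndefinedScoreError("interface set is empty")
    scheme = scheme or PolarityScheme.default()
    codes = scheme.codes_for_alphabet(aln.alphabet)
    g = codes[aln.matrix]  # (M, N) polarity-group codes per row/column

    def comp_rows(col_a: np.ndarray, col_b: np.ndarray) -> np.ndarray:
        both_hp = (col_a == col_b) & ((col_a == 0) | (col_a == 1))
        opposite = ((col_a == 2) & (col_b == 3)) | ((col_a == 3) & (col_b == 2))
        return both_hp | opposite

    def candidates(k: int) -> list[int]:
        cand = {k}
        if neighbour_order >= 1:
            cand |= set(struct.structural_neighbours(k, order=1))
        if neighbour_order >= 2:
            cand |= set(struct.structural_neighbours(k, order=2))
        return [c for c in cand if struct.residues[c].column is not None]

    preserved = 0
    for i, j in iface.pairs:
        ci = _column_of(struct, i)
        cj = _column_of(struct, j)
        ok = np.zeros(aln.n_sequences, dtype=bool)
        for k in candidates(j):
            ok |= comp_rows(g[:, ci], g[:, _column_of(struct, k)])
        for l in candidates(i):
            ok |= comp_rows(g[:, _column_of(struct, l)], g[:, cj])
        if ok.mean() >= preservation:
            preserved += 1
    return preserved / len(iface.pairs)


# ---------------------------------------------------------------------------
# One-call component assembly
# ---------------------------------------------------------------------------

def score_decoy(
    decoy: ComplexStructure,
    d: CouplingMatrix,
    aln: Alignment,
    freq: FrequencyModel,
    rp_matrix: RPMatrix | None = None,
    scheme: PolarityScheme | None = None,
    cutoff: float = 4.5,
    threshold: float = 0.08,
    standardise_over: str = "all_pairs",
) -> ScoreComponents:
    """Compute every score component for one decoy pose.

    ``freq`` should be the unsmoothed (pseudocount 0) frequency model: the
    entropy component is defined on raw frequencies.  Raises
    :class:`UndefinedScoreError` when the decoy has an empty interface.
    """
    iface = decoy.interface_set(cutoff=cutoff, threshold=threshold)
    if not iface.pairs:
        raise UndefinedScoreError("decoy has an empty interface")
    comp = standardised_cmm(d, decoy, iface, standardise_over=standardise_over)
    comp.S_ent = entropy_score(freq, decoy, iface)
    comp.S_CT = ct_score(aln, decoy, iface, scheme=scheme)
    comp.S_RP = rp_score(decoy, iface, rp_matrix) if rp_matrix is not None else None
    return comp
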