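"""Two-chain complex geometry: surface sets, interface contacts, and
interface backbone RMSD.

A :class:`ComplexStructure` holds the heavy-atom coordinates of the two
partners of a (docked or native) complex, with each residue mapped to a
column of the concatenated MSA.  From it the module derives every geometric
predicate the scoring functions need:

* per-residue *relative accessibility* (Shrake-Rupley SASA on the undocked
  single chains, normalised by a per-residue-type maximum-ASA reference);
* the surface sets ``S_i`` (same-protein surface residues) and ``S̄_i``
  (other-protein surface residues), with a residue counting as surface when
  its relative accessibility is at least 0.08;
* the interface interaction set ``I``: cross-chain surface pairs whose
  closest heavy atoms are strictly within 4.5 Å;
* surface neighbourhoods ``N_i`` and first/second structural neighbours
  (same-chain, 4.5 Å heavy-atom cutoff);
* the interface backbone RMSD against the native pose, used to label
  near-native decoys (iRMSD < 3 Å).

Intra-chain distances are invariant under rigid-body docking moves, so
accessibility, surface flags, neighbourhoods and structural neighbours are
computed once per complex on the undocked chains, while the interface set
is recomputed per decoy pose.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
from Bio.SVDSuperimposer import SVDSuperimposer
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

SURFACE_THRESHOLD = 0.08
CONTACT_CUTOFF = 4.5
BACKBONE_ATOMS = ("N", "CA", "C", "O")

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


class ChainMappingError(ValueError):
    """A chain in the file has no protein assignment."""


class StructureFormatError(ValueError):
    """The coordinate file does not yield a usable two-chain complex."""


class UndefinedScoreError(ValueError):
    """A score is undefined for this input (e.g. empty interface)."""


def load_max_asa(path=None) -> dict[str, float]:
    """Load the per-residue maximum-ASA reference table (Å²).

    Defaults to the theoretical Gly-X-Gly values of Tien et al. shipped
    with the package; any 20-row TSV (residue name, Å²) may be supplied.
    """
    if path is None:
        path = resources.files("coevodock.data") / "max_asa.tsv"
    table = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, val = line.split("\t")
            table[name.upper()] = float(val)
    return table


@dataclass(frozen=True)
class Residue:
    """One residue: chain assignment, MSA column, and heavy-atom geometry."""

    chain: int  # 1 or 2
    res_id: int  # author numbering (with insertion code folded in the key)
    name: str  # three-letter residue name
    column: int | None  # 0-based concatenated MSA column, None = unmapped
    atom_names: tuple[str, ...]
    coords: np.ndarray  # (n_atoms, 3) heavy-atom coordinates, Å
    icode: str = ""

    @property
    def one_letter(self) -> str | None:
        return _THREE_TO_ONE.get(self.name.upper())

    def backbone(self) -> dict[str, np.ndarray]:
        return {
            n: self.coords[k]
            for k, n in enumerate(self.atom_names)
            if n in BACKBONE_ATOMS
        }


@dataclass(frozen=True)
class InterfaceSet:
    """Cross-chain surface residue pairs in heavy-atom contact.

    Pairs are stored as ``(i, j)`` residue indices with ``i`` on chain 1 and
    ``j`` on chain 2 (indices into ``ComplexStructure.residues``).
    """

    pairs: frozenset[tuple[int, int]]

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def residues(self) -> frozenset[int]:
        return frozenset(r for pair in self.pairs for r in pair)

    def interaction_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for i, j in self.pairs:
            counts[i] = counts.get(i, 0) + 1
            counts[j] = counts.get(j, 0) + 1
        return counts

    def write_tsv(self, struct: "ComplexStructure", path) -> None:
        dmat = struct.residue_distance_matrix()
        with open(path, "w") as fh:
            fh.write("i\tj\td_ij\n")
            for i, j in sorted(self.pairs):
                fh.write(f"{i}\t{j}\t{dmat[i, j]:.4f}\n")


class ComplexStructure:
    """Heavy-atom model of a two-chain complex.

    Residues are held in file order; chain ids are the protein labels 1
    and 2.  Distance matrices and accessibility values are cached, with
    pose-dependent caches (cross-chain distances, interface sets)
    recomputed on transformed copies.
    """

    def __init__(self, residues: list[Residue], max_asa: dict[str, float] | None = None):
        if not residues:
            raise StructureFormatError("no residues")
        chains = {r.chain for r in residues}
        if chains != {1, 2}:
            raise StructureFormatError(
                f"expected residues on both proteins 1 and 2, got chains {sorted(chains)}"
            )
        for r in residues:
            if len(r.coords) < 1:
                raise StructureFormatError(
                    f"residue {r.chain}/{r.res_id} has no heavy atoms"
                )
        cols = [r.column for r in residues if r.column is not None]
        if len(cols) != len(set(cols)):
            raise StructureFormatError("residue-to-column mapping is not injective")
        self.residues = list(residues)
        self.max_asa = dict(max_asa) if max_asa else load_max_asa()
        self._dmat: np.ndarray | None = None
        self._rel_acc: np.ndarray | None = None

    # -- basic views ------------------------------------------------------
    def __len__(self) -> int:
        return len(self.residues)

    def chain_indices(self, chain: int) -> np.ndarray:
        return np.array([k for k, r in enumerate(self.residues) if r.chain == chain])

    def residue_distance_matrix(self) -> np.ndarray:
        """Minimum heavy-atom distance between every residue pair (Å)."""
        if self._dmat is None:
            coords = np.concatenate([r.coords for r in self.residues])
            owner = np.repeat(
                np.arange(len(self.residues)),
                [len(r.coords) for r in self.residues],
            )
            atom_d = cdist(coords, coords)
            n = len(self.residues)
            dmat = np.full((n, n), np.inf)
            np.minimum.at(dmat, (owner[:, None], owner[None, :]), atom_d)
            self._dmat = dmat
        return self._dmat

    # -- accessibility and surface ---------------------------------------
    def relative_accessibility(
        self, point_number: int = 1000, missing: str = "surface"
    ) -> np.ndarray:
        """Per-residue relative SASA on the *undocked* chains.

        Shrake-Rupley SASA (probe 1.4 Å, ``point_number`` sphere points per
        atom) is computed for each chain in isolation and divided by the
        maximum-ASA reference of the residue type.  A residue type missing
        from the reference table is treated per ``missing``: ``"surface"``
        assigns relative accessibility 1.0, ``"error"`` raises.
        """
        if self._rel_acc is not None:
            return self._rel_acc
        import biotite.structure as struc

        values = np.empty(len(self.residues))
        for chain in (1, 2):
            idx = self.chain_indices(chain)
            arr = _to_atom_array([self.residues[k] for k in idx])
            per_atom = struc.sasa(
                arr, probe_radius=1.4, point_number=point_number, vdw_radii="Single"
            )
            per_atom = np.nan_to_num(per_atom)
            offsets = np.cumsum([0] + [len(self.residues[k].coords) for k in idx])
            for pos, k in enumerate(idx):
                res = self.residues[k]
                asa = per_atom[offsets[pos] : offsets[pos + 1]].sum()
                ref = self.max_asa.get(res.name.upper())
                if ref is None:
                    if missing == "error":
                        raise KeyError(
                            f"no max-ASA reference for residue type {res.name}"
                        )
                    logger.warning(
                        "residue type %s not in max-ASA table; treated as surface",
                        res.name,
                    )
                    values[k] = 1.0
                else:
                    values[k] = asa / ref
        self._rel_acc = values
        return values

    def surface_flags(self, threshold: float = SURFACE_THRESHOLD) -> np.ndarray:
        """Surface residue iff relative accessibility >= threshold (inclusive)."""
        return self.relative_accessibility() >= threshold

    def surface_set(self, i: int, threshold: float = SURFACE_THRESHOLD) -> frozenset[int]:
        """S_i: surface residues of residue i's own protein."""
        flags = self.surface_flags(threshold)
        chain = self.residues[i].chain
        return frozenset(
            k for k, r in enumerate(self.residues) if r.chain == chain and flags[k]
        )

    def other_surface_set(
        self, i: int, threshold: float = SURFACE_THRESHOLD
    ) -> frozenset[int]:
        """S̄_i: surface residues of the other protein."""
        flags = self.surface_flags(threshold)
        chain = self.residues[i].chain
        return frozenset(
            k for k, r in enumerate(self.residues) if r.chain != chain and flags[k]
        )

    # -- interface and neighbourhoods -------------------------------------
    def interface_set(
        self,
        cutoff: float = CONTACT_CUTOFF,
        threshold: float = SURFACE_THRESHOLD,
    ) -> InterfaceSet:
        """I: cross-chain surface pairs with min heavy-atom distance < cutoff."""
        flags = self.surface_flags(threshold)
        dmat = self.residue_distance_matrix()
        c1 = [k for k in self.chain_indices(1) if flags[k]]
        c2 = [k for k in self.chain_indices(2) if flags[k]]
        pairs = frozenset(
            (i, j) for i in c1 for j in c2 if dmat[i, j] < cutoff
        )
        return InterfaceSet(pairs=pairs)

    def surface_neighbourhood(
        self,
        i: int,
        cutoff: float = CONTACT_CUTOFF,
        threshold: float = SURFACE_THRESHOLD,
    ) -> frozenset[int]:
        """N_i: same-chain surface residues within the cutoff (including i
        itself, since d_ii = 0); for a buried residue, the whole surface set."""
        s_i = self.surface_set(i, threshold)
        if i not in s_i:  # buried
            return s_i
        dmat = self.residue_distance_matrix()
        return frozenset(k for k in s_i if dmat[i, k] < cutoff)

    def structural_neighbours(
        self, i: int, order: int = 1, cutoff: float = CONTACT_CUTOFF
    ) -> frozenset[int]:
        """Same-chain residues within the heavy-atom cutoff of i (order 1),
        or neighbours-of-neighbours (order 2), excluding i itself."""
        if order not in (1, 2):
            raise ValueError("order must be 1 or 2")
        dmat = self.residue_distance_matrix()
        chain = self.residues[i].chain
        same = [k for k, r in enumerate(self.residues) if r.chain == chain]
        first = frozenset(k for k in same if k != i and dmat[i, k] < cutoff)
        if order == 1:
            return first
        second = set()
        for k in first:
            second.update(n for n in same if n != k and dmat[k, n] < cutoff)
        second.discard(i)
        return frozenset(second)

    # -- pose manipulation -------------------------------------------------
    def transformed(
        self, rotation: np.ndarray, translation: np.ndarray, chain: int | None = 2
    ) -> "ComplexStructure":
        """A copy with ``chain`` (or the whole complex if None) rigidly moved.

        Coordinates are mapped as ``x -> R x + t``.  Pose-invariant caches
        (accessibility) are carried over; distance caches are dropped.
        """
        rotation = np.asarray(rotation, float)
        translation = np.asarray(translation, float)
        new_residues = []
        for r in self.residues:
            if chain is None or r.chain == chain:
                new_residues.append(
                    replace(r, coords=r.coords @ rotation.T + translation)
                )
            else:
                new_residues.append(r)
        out = ComplexStructure(new_residues, max_asa=self.max_asa)
        out._rel_acc = self._rel_acc  # SASA on undocked chains is pose-invariant
        return out


def _to_atom_array(residues: list[Residue]):
    """Build a biotite AtomArray from our residue records (for SASA)."""
    import biotite.structure as struc

    n_atoms = sum(len(r.coords) for r in residues)
    arr = struc.AtomArray(n_atoms)
    pos = 0
    for r in residues:
        k = len(r.coords)
        sl = slice(pos, pos + k)
        arr.coord[sl] = r.coords
        arr.chain_id[sl] = "A" if r.chain == 1 else "B"
        arr.res_id[sl] = r.res_id
        arr.res_name[sl] = r.name
        arr.atom_name[sl] = r.atom_names
        arr.element[sl] = [_element_of(a) for a in r.atom_names]
        arr.hetero[sl] = False
        pos += k
    return arr


def _element_of(atom_name: str) -> str:
    stripped = atom_name.strip().lstrip("0123456789")
    return stripped[0].upper() if stripped else "C"


def read_complex(
    path,
    chain_map: dict[str, int],
    msa_map: dict | None = None,
    max_asa: dict[str, float] | None = None,
) -> ComplexStructure:
    """Read a PDB file into a :class:`ComplexStructure`.

    ``chain_map`` assigns each PDB chain id to protein 1 or 2.  ``msa_map``
    maps ``(chain_id, res_id)`` or ``(chain_id, res_id, icode)`` to the
    0-based concatenated MSA column; with ``None``, residues are numbered
    consecutively in file order (chain-1 residues first).  Only ATOM
    records are used; hydrogens are discarded; for disordered atoms the
    highest-occupancy conformer is kept; models beyond the first are
    ignored with a warning.
    """
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    if pdb.get_model_count() > 1:
        logger.warning("%s has %d models; using the first", path, pdb.get_model_count())
    arr = pdb.get_structure(model=1, altloc="occupancy")
    arr = arr[~arr.hetero]
    arr = arr[~np.isin(arr.element, ("H", "D"))]
    if arr.array_length() == 0:
        raise StructureFormatError(f"no heavy ATOM records in {path}")
    for cid in np.unique(arr.chain_id):
        if cid not in chain_map:
            raise ChainMappingError(f"chain {cid!r} has no protein assignment")

    residues: list[Residue] = []
    import biotite.structure as struc

    starts = struc.get_residue_starts(arr, add_exclusive_stop=True)
    records = []
    for s, e in zip(starts[:-1], starts[1:]):
        sub = arr[s:e]
        records.append(sub)
    # chain-1 residues first to make default column numbering contiguous
    records.sort(key=lambda sub: (chain_map[str(sub.chain_id[0])],))
    next_col = 0
    for sub in records:
        cid = str(sub.chain_id[0])
        res_id = int(sub.res_id[0])
        icode = str(sub.ins_code[0]) if hasattr(sub, "ins_code") else ""
        if msa_map is None:
            col: int | None = next_col
            next_col += 1
        else:
            col = msa_map.get((cid, res_id, icode), msa_map.get((cid, res_id)))
        residues.append(
            Residue(
                chain=chain_map[cid],
                res_id=res_id,
                name=str(sub.res_name[0]),
                column=col,
                atom_names=tuple(str(a) for a in sub.atom_name),
                coords=np.array(sub.coord, float),
                icode=icode,
            )
        )
    counts = {1: 0, 2: 0}
    for r in residues:
        counts[r.chain] += 1
    if min(counts.values()) == 0:
        raise StructureFormatError("one protein has zero residues after parsing")
    return ComplexStructure(residues, max_asa=max_asa)


def write_pdb(struct: ComplexStructure, path) -> None:
    """Write the complex as a minimal two-chain PDB file."""
    from biotite.structure.io.pdb import PDBFile

    arr = _to_atom_array(struct.residues)
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def interface_backbone_rmsd(
    decoy: ComplexStructure,
    native: ComplexStructure,
    native_interface: InterfaceSet,
    fit: bool = True,
) -> float:
    """Backbone RMSD over the native interface residues (Å).

    Backbone atoms (N, CA, C, O) of the native interface residue set are
    collected from both structures, matched by (chain, residue id,
    insertion code, atom name); with ``fit=True`` (the common interface-RMSD
    convention) the decoy set is least-squares superposed on the native set
    first, with ``fit=False`` the RMSD is taken in the docking frame.
    """
    if not native_interface.pairs:
        raise UndefinedScoreError("native interface is empty")
    decoy_lookup = {
        (r.chain, r.res_id, r.icode): r for r in decoy.residues
    }
    nat_pts, dec_pts = [], []
    for k in sorted(native_interface.residues):
        nres = native.residues[k]
        dres = decoy_lookup.get((nres.chain, nres.res_id, nres.icode))
        if dres is None:
            continue
        nbb, dbb = nres.backbone(), dres.backbone()
        for atom in BACKBONE_ATOMS:
            if atom in nbb and atom in dbb:
                nat_pts.append(nbb[atom])
                dec_pts.append(dbb[atom])
    if not nat_pts:
        raise ValueError("no shared backbone atoms over the native interface")
    nat = np.array(nat_pts)
    dec = np.array(dec_pts)
    if not fit:
        return float(np.sqrt(((nat - dec) ** 2).sum(axis=1).mean()))
    sup = SVDSuperimposer()
    sup.set(nat, dec)
    sup.run()
    return float(sup.get_rms())
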