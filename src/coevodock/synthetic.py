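"""Synthetic fixtures: planted-coupling MSAs, toy complexes and decoy sets.

Every stage of the pipeline is testable offline with data generated here:

* :func:`make_coupled_model` builds a maximum-entropy sequence model with
  couplings *planted* at chosen cross-boundary column pairs (a diagonal
  symbol-matching pattern at a chosen strength) and optional conserved
  columns — the statistical structure that coevolution scoring assumes;
* :func:`sample_potts_msa` draws an alignment from such a model by Gibbs
  sampling;
* :func:`make_toy_complex` builds a two-chain pseudo-protein whose native
  interface is a designated residue block, with every residue solvent
  exposed by construction;
* :func:`generate_decoys` produces rigid-body decoy poses of chain 2 at a
  small (near-native candidate) and a large perturbation scale;
* :func:`make_benchmark_fixture` wires these into a multi-complex dataset
  with per-decoy score components, mirroring what the paper-scale pipeline
  computes from real MSAs and FTDock decoys.

All generators are pure functions of their spec and seed.

Default fixture dimensions emulate the regime the method targets — small
alignments (a few hundred rows) over short concatenated domains with a
handful of genuinely coupled interface pairs — at desk scale: a reduced
q=8 alphabet, 10+10 residue chains and dozens (not 10,000) of decoys.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from .alignment import Alignment, frequencies
from .maxent import (
    CDConfig,
    CouplingMatrix,
    PottsModel,
    cmm_matrix,
    fit_potts_cd,
    gibbs_sweeps,
)
from .ranking import NEAR_NATIVE_RMSD
from .scoring import RPMatrix, UndefinedScoreError, score_decoy
from .structure import ComplexStructure, Residue, interface_backbone_rmsd

AA20 = "ACDEFGHIKLMNPQRSTVWY"


class FixtureSpecError(ValueError):
    """The fixture specification is internally inconsistent."""


@dataclass(frozen=True)
class FixtureSpec:
    """Dimensions and knobs of one synthetic complex fixture.

    ``planted_pairs`` are (i, j, strength) with 0-based columns, i on
    protein 1 (i < N1) and j on protein 2 (j >= N1); ``conserved_columns``
    are (column, field strength) pairs.  Chain geometry: one pseudo-residue
    per MSA column, ``spacing`` Å apart along the chain; ``contact_block``
    designates which aligned residue positions of the two chains face each
    other in the native pose.  Decoy knobs give the count, the requested
    near-native fraction and the two rigid perturbation scales.
    """

    seed: int
    n1: int = 10
    n2: int = 10
    q: int = 8
    m: int = 350
    planted_pairs: tuple[tuple[int, int, float], ...] = ()
    conserved_columns: tuple[tuple[int, float], ...] = ()
    spacing: float = 3.8
    zigzag: float = 3.0
    contact_gap: float = 4.0
    standoff: float = 10.0
    contact_block: tuple[int, ...] | None = None
    n_decoys: int = 60
    near_native_fraction: float = 0.25
    small_translation: float = 0.35
    small_rotation_deg: float = 6.0
    large_translation: float = 8.0
    large_rotation_deg: float = 90.0
    large_min_rotation_deg: float = 25.0

    def __post_init__(self) -> None:
        if min(self.n1, self.n2, self.q, self.m, self.seed + 1) <= 0:
            raise FixtureSpecError("all counts must be positive and seed >= 0")
        n = self.n1 + self.n2
        for i, j, s in self.planted_pairs:
            if not (0 <= i < self.n1 <= j < n):
                raise FixtureSpecError(
                    f"planted pair ({i}, {j}) does not cross the boundary {self.n1}"
                )

    @property
    def length(self) -> int:
        return self.n1 + self.n2

    @property
    def alphabet(self) -> str:
        if self.q == 21:
            return AA20 + "-"
        if self.q <= 20:
            return AA20[: self.q]
        raise FixtureSpecError(f"unsupported alphabet size {self.q}")


# ---------------------------------------------------------------------------
# Sequence model and sampler
# ---------------------------------------------------------------------------

def make_coupled_model(spec: FixtureSpec) -> PottsModel:
    """Maximum-entropy model with couplings planted at the given pairs.

    Each planted pair gets the diagonal compatibility pattern
    e_ij(a, b) = -strength if b == a else 0 (matching symbols favoured);
    conserved columns get a field bonus on one symbol (symbol index
    ``column mod q``); everything else is zero.
    """
    n, q = spec.length, spec.q
    h = np.zeros((n, q))
    for col, level in spec.conserved_columns:
        h[col, col % q] = level
    e = np.zeros((n * q, n * q))
    for i, j, strength in spec.planted_pairs:
        blk = -strength * np.eye(q)
        e[i * q : (i + 1) * q, j * q : (j + 1) * q] += blk
        e[j * q : (j + 1) * q, i * q : (i + 1) * q] += blk.T
    return PottsModel(
        fields=h,
        coupling_flat=e,
        boundary=spec.n1,
        gauge_note=f"synthetic planted model, seed={spec.seed}",
    )


def sample_potts_msa(
    model: PottsModel,
    m: int,
    burn_in: int = 100,
    thin: int = 5,
    seed: int = 0,
    max_chains: int = 256,
) -> Alignment:
    """Sample an alignment of ``m`` rows from the model by Gibbs sampling.

    Up to ``max_chains`` parallel chains are started from uniform random
    states and run for ``burn_in`` sweeps; rows are then collected from
    all chains every ``thin`` sweeps until ``m`` rows exist.  Deterministic
    given the seed.
    """
    if m < 1 or burn_in < 1 or thin < 1:
        raise ValueError("m, burn_in and thin must be positive")
    n, q = model.length, model.n_states
    rng = np.random.default_rng(seed)
    n_chains = min(m, max_chains)
    states = rng.integers(0, q, size=(n_chains, n))
    j_flat = -model.coupling_flat
    h_flat = model.fields.ravel()
    gibbs_sweeps(states, j_flat, h_flat, q, burn_in, rng)
    rows = [states.copy()]
    collected = n_chains
    while collected < m:
        gibbs_sweeps(states, j_flat, h_flat, q, thin, rng)
        rows.append(states.copy())
        collected += n_chains
    matrix = np.concatenate(rows)[:m]
    alphabet = AA20 + "-" if q == 21 else AA20[:q]
    return Alignment(
        matrix=matrix.astype(np.int32),
        alphabet=alphabet,
        boundary=model.boundary,
        ids=tuple(f"synth{i}" for i in range(m)),
    )


# ---------------------------------------------------------------------------
# Toy complexes and decoys
# ---------------------------------------------------------------------------

#: compact 4-atom pseudo-residue (alanine-labelled backbone-like cluster);
#: the small 0.4 Å radius keeps native contacts to the designated facing
#: pairs (diagonal neighbours stay outside the 4.5 Å cutoff).
_ATOM_TEMPLATE = (
    ("N", np.array([-0.4, 0.0, 0.0])),
    ("CA", np.array([0.0, 0.0, 0.0])),
    ("C", np.array([0.4, 0.0, 0.0])),
    ("O", np.array([0.0, 0.0, 0.4])),
)


def make_toy_complex(spec: FixtureSpec) -> ComplexStructure:
    """Native pose of a two-chain pseudo-protein.

    Chain 1 residues sit along x at ``spacing`` Å, alternating by
    ``zigzag`` Å in z so the backbone is not collinear (a straight chain
    would make rolls about the chain axis invisible to fitted RMSD);
    chain 2 residues face them at ``contact_gap`` Å for positions in the
    contact block (default: the central half of the shorter chain) and are
    bent away to ``standoff`` Å elsewhere.  Residue k of chain c maps to
    MSA column k (chain 1) or N1 + k (chain 2); every residue is
    solvent-exposed.
    """
    block = spec.contact_block
    if block is None:
        short = min(spec.n1, spec.n2)
        lo = short // 4
        hi = lo + max(1, short // 2)
        block = tuple(range(lo, hi))
    if any(not (0 <= b < min(spec.n1, spec.n2)) for b in block):
        raise FixtureSpecError("contact block outside both chains")

    residues: list[Residue] = []
    for r in range(spec.n1):
        center = np.array([spec.spacing * r, 0.0, spec.zigzag * (r % 2)])
        names, coords = zip(*[(n, center + d) for n, d in _ATOM_TEMPLATE])
        residues.append(
            Residue(
                chain=1, res_id=r + 1, name="ALA", column=r,
                atom_names=tuple(names), coords=np.array(coords),
            )
        )
    for r in range(spec.n2):
        y = spec.contact_gap if r in block else spec.standoff
        center = np.array([spec.spacing * r, y, spec.zigzag * (r % 2)])
        names, coords = zip(*[(n, center + d) for n, d in _ATOM_TEMPLATE])
        residues.append(
            Residue(
                chain=2, res_id=r + 1, name="ALA", column=spec.n1 + r,
                atom_names=tuple(names), coords=np.array(coords),
            )
        )
    return ComplexStructure(residues)


def _random_rotation(
    rng: np.random.Generator, max_angle_deg: float, min_angle_deg: float = 0.0
) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(math.radians(min_angle_deg), math.radians(max_angle_deg))
    return Rotation.from_rotvec(angle * axis).as_matrix()


def _min_cross_distance(decoy: ComplexStructure) -> float:
    from scipy.spatial.distance import cdist

    c1 = np.concatenate([decoy.residues[k].coords for k in decoy.chain_indices(1)])
    c2 = np.concatenate([decoy.residues[k].coords for k in decoy.chain_indices(2)])
    return float(cdist(c1, c2).min())


def _restore_contact(
    decoy: ComplexStructure, target: float, tol: float = 0.05
) -> ComplexStructure:
    """Translate chain 2 along the centroid axis until the chains touch.

    Docking searches only emit surface-contacting poses; a perturbed toy
    decoy that drifted out of contact is slid rigidly back until its
    minimum cross-chain heavy-atom distance is ``target`` (bisection).
    """
    c1 = np.concatenate(
        [decoy.residues[k].coords for k in decoy.chain_indices(1)]
    ).mean(axis=0)
    c2 = np.concatenate(
        [decoy.residues[k].coords for k in decoy.chain_indices(2)]
    ).mean(axis=0)
    axis = c1 - c2
    norm = np.linalg.norm(axis)
    if norm == 0:
        return decoy
    axis /= norm

    def dmin_at(s: float) -> float:
        return _min_cross_distance(
            decoy.transformed(np.eye(3), s * axis, chain=2)
        )

    lo, hi = 0.0, norm  # sliding all the way to coincident centroids
    if dmin_at(lo) <= target:
        return decoy
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if dmin_at(mid) > target:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return decoy.transformed(np.eye(3), hi * axis, chain=2)


def generate_decoys(
    native: ComplexStructure, spec: FixtureSpec
) -> tuple[list[ComplexStructure], np.ndarray]:
    """Rigid-body decoy poses of chain 2 plus their true interface RMSDs.

    The first ``round(near_native_fraction * n_decoys)`` decoys use the
    small perturbation scale (near-native candidates), the rest the large
    scale.  Chain 1 stays fixed; chain 2 is rotated about its centroid
    (uniform axis, bounded angle) and translated (isotropic Gaussian); a
    pose that loses heavy-atom contact is slid rigidly back into contact,
    as a docking search would only output touching poses.
    """
    rng = np.random.default_rng(spec.seed + 7)
    native_iface = native.interface_set()
    idx2 = native.chain_indices(2)
    centroid = np.concatenate(
        [native.residues[k].coords for k in idx2]
    ).mean(axis=0)
    n_small = int(round(spec.near_native_fraction * spec.n_decoys))
    decoys, rmsds = [], []
    for d in range(spec.n_decoys):
        if d < n_small:
            rot = _random_rotation(rng, spec.small_rotation_deg)
            trans = rng.normal(scale=spec.small_translation, size=3)
        else:
            # wrong poses mimic the failure modes of a grid docking search:
            # register shifts along the chain (wrong patch, realistic
            # interface size), face flips, and free misorientations — the
            # latter carrying at least a coarse rotation step, since a
            # near-identity rotation plus contact restoration would just
            # re-create the native pose
            kind = rng.choice(("shift", "flip", "free"), p=(0.4, 0.2, 0.4))
            if kind == "shift":
                rot = _random_rotation(rng, spec.small_rotation_deg)
                k = rng.choice((-4, -3, -2, 2, 3, 4))
                trans = rng.normal(scale=spec.small_translation, size=3)
                trans[0] += k * spec.spacing
            elif kind == "flip":
                from scipy.spatial.transform import Rotation

                rot = Rotation.from_rotvec(
                    np.array([math.pi, 0.0, 0.0])
                ).as_matrix() @ _random_rotation(rng, spec.small_rotation_deg)
                trans = rng.normal(scale=spec.small_translation, size=3)
                trans[0] += rng.choice((-1, 0, 1)) * spec.spacing
            else:
                rot = _random_rotation(
                    rng, spec.large_rotation_deg, spec.large_min_rotation_deg
                )
                trans = rng.normal(scale=spec.large_translation, size=3)
        # rotate about the chain-2 centroid, then translate
        shift = centroid - rot @ centroid + trans
        decoy = native.transformed(rot, shift, chain=2)
        if _min_cross_distance(decoy) > 4.4:
            decoy = _restore_contact(decoy, target=rng.uniform(3.2, 4.2))
        decoys.append(decoy)
        rmsds.append(interface_backbone_rmsd(decoy, native, native_iface))
    return decoys, np.array(rmsds)


def random_rp_matrix(seed: int, scale: float = 0.5) -> RPMatrix:
    """A synthetic symmetric residue-pair potential (test stand-in for the
    FTDock RP table, whose values are an external input)."""
    rng = np.random.default_rng(seed)
    raw = rng.normal(scale=scale, size=(20, 20))
    return RPMatrix.from_array(AA20, (raw + raw.T) / 2.0, source=f"synthetic(seed={seed})")


# ---------------------------------------------------------------------------
# End-to-end benchmark fixture
# ---------------------------------------------------------------------------

@dataclass
class ComplexFixture:
    """Everything generated for one synthetic complex."""

    name: str
    spec: FixtureSpec
    alignment: Alignment
    model: PottsModel
    native: ComplexStructure
    decoys: list[ComplexStructure]
    irmsd: np.ndarray
    coupling: CouplingMatrix
    components: pd.DataFrame


def plant_at_native_contacts(
    spec: FixtureSpec, native: ComplexStructure, strength: float, max_pairs: int = 5
) -> FixtureSpec:
    """Return a spec whose planted pairs are (a subset of) the native
    interface contacts, mapped to MSA columns."""
    iface = native.interface_set()
    pairs = sorted(
        (native.residues[i].column, native.residues[j].column)
        for i, j in iface.pairs
    )
    chosen = pairs[:: max(1, len(pairs) // max_pairs)][:max_pairs]
    return dc_replace(
        spec, planted_pairs=tuple((i, j, strength) for i, j in chosen)
    )


def make_benchmark_fixture(
    n_complexes: int = 9,
    seed: int = 0,
    base_spec: FixtureSpec | None = None,
    coupling_strength: float = 2.0,
    cd_updates: int = 500,
    rp_seed: int | None = None,
) -> tuple[pd.DataFrame, list[ComplexFixture]]:
    """Generate a multi-complex dataset with per-decoy score components.

    For each complex: a toy native, couplings planted at its native contact
    columns, an MSA sampled from that model, a CD-fitted CMM, a decoy set
    with near-native labels, and all five score components per decoy.
    Decoys whose interface is empty are dropped from the table (logged via
    the count difference).  Deterministic given ``seed``.
    """
    rows = []
    fixtures = []
    rp = random_rp_matrix(rp_seed if rp_seed is not None else seed + 10_001)
    for c in range(n_complexes):
        cseed = seed * 10_007 + c + 1
        spec = base_spec or FixtureSpec(seed=cseed)
        spec = dc_replace(spec, seed=cseed)
        native = make_toy_complex(spec)
        spec = plant_at_native_contacts(spec, native, coupling_strength)
        model = make_coupled_model(spec)
        aln = sample_potts_msa(model, spec.m, seed=cseed + 1)
        freq_fit = frequencies(aln, pseudocount=0.01)
        freq_raw = frequencies(aln, pseudocount=0.0)
        cfg = CDConfig(seed=cseed + 2, n_updates=cd_updates, batch_size=128)
        potts = fit_potts_cd(aln, freq_fit, cfg)
        coupling = cmm_matrix(potts, freq_fit)
        decoys, irmsd = generate_decoys(native, spec)
        name = f"complex{c:02d}"
        for k, (decoy, r) in enumerate(zip(decoys, irmsd)):
            try:
                comp = score_decoy(decoy, coupling, aln, freq_raw, rp_matrix=rp)
            except UndefinedScoreError:
                continue
            rows.append(
                {
                    "complex": name,
                    "decoy": k,
                    "S_N": comp.S_N,
                    "S_RP": comp.S_RP,
                    "S_ent": comp.S_ent,
                    "S_CT": comp.S_CT,
                    "S_CMM": comp.S_CMM,
                    "S_CMM_raw": comp.S_CMM_raw,
                    "irmsd": float(r),
                    "near_native": bool(r < NEAR_NATIVE_RMSD),
                }
            )
        fixtures.append(
            ComplexFixture(
                name=name,
                spec=spec,
                alignment=aln,
                model=model,
                native=native,
                decoys=decoys,
                irmsd=irmsd,
                coupling=coupling,
                components=pd.DataFrame([r for r in rows if r["complex"] == name]),
            )
        )
    return pd.DataFrame(rows), fixtures


def write_fixture_dataset(fixtures: list[ComplexFixture], out_dir) -> None:
    """Write a fixture as FASTA MSAs, PDB poses and a manifest TSV,
    mirroring the on-disk layout the CLI consumes."""
    import os

    from .structure import write_pdb

    os.makedirs(out_dir, exist_ok=True)
    manifest = []
    for fx in fixtures:
        cdir = os.path.join(out_dir, fx.name)
        os.makedirs(cdir, exist_ok=True)
        msa_path = os.path.join(cdir, "msa.fasta")
        with open(msa_path, "w") as fh:
            for rid, seq in zip(fx.alignment.ids, fx.alignment.sequences()):
                fh.write(f">{rid}\n{seq}\n")
        write_pdb(fx.native, os.path.join(cdir, "native.pdb"))
        for k, decoy in enumerate(fx.decoys):
            write_pdb(decoy, os.path.join(cdir, f"decoy{k:04d}.pdb"))
        fx.components.to_csv(os.path.join(cdir, "components.tsv"), sep="\t", index=False)
        manifest.append(
            {
                "complex": fx.name,
                "boundary": fx.alignment.boundary,
                "n_decoys": len(fx.decoys),
                "msa": os.path.relpath(msa_path, out_dir),
            }
        )
    pd.DataFrame(manifest).to_csv(
        os.path.join(out_dir, "manifest.tsv"), sep="\t", index=False
    )
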