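"""Score components: CMM interface scores, size, potential, entropy, CT."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from coevodock.alignment import Alignment, FrequencyModel, frequencies
from coevodock.maxent import CouplingMatrix
from coevodock.scoring import (
    PolarityScheme,
    RPMatrix,
    UndefinedScoreError,
    complementary,
    ct_score,
    entropy_score,
    interface_cmm_score,
    interface_size_score,
    neighbour_averaged_cmm,
    raw_cmm_score,
    rp_score,
    score_decoy,
    standardised_cmm,
)
from coevodock.structure import InterfaceSet

from test_structure import bead, force_surface, two_chain


def coupling(d_matrix):
    d = np.asarray(d_matrix, float)
    return CouplingMatrix(D=d, boundary=d.shape[0] // 2)


def line_complex(n1=4, n2=4, gap=4.0, spacing=6.0):
    """Two facing rows of single-point residues; columns = indices.

    Wide spacing keeps surface neighbourhoods to singletons unless stated.
    """
    atom = [("CA", (0.0, 0.0, 0.0))]
    residues = [
        bead(1, i, (spacing * i, 0, 0), column=i, atoms=atom) for i in range(n1)
    ]
    residues += [
        bead(2, i, (spacing * i, gap, 0), column=n1 + i, atoms=atom)
        for i in range(n2)
    ]
    from coevodock.structure import ComplexStructure

    return force_surface(ComplexStructure(residues))


class TestRawCmmScore:
    def test_constant_d_returns_constant(self):
        struct = line_complex()
        iface = struct.interface_set()
        d = coupling(np.full((8, 8), 0.7))
        assert raw_cmm_score(d, struct, iface) == pytest.approx(0.7)

    def test_two_pair_arithmetic(self):
        struct = line_complex(n1=2, n2=2)
        iface = InterfaceSet(pairs=frozenset({(0, 2), (1, 3)}))
        d = np.zeros((4, 4))
        d[0, 2] = d[2, 0] = 0.2
        d[1, 3] = d[3, 1] = 0.4
        assert raw_cmm_score(coupling(d), struct, iface) == pytest.approx(0.3)

    def test_matches_brute_force_mean(self):
        rng = np.random.default_rng(3)
        struct = line_complex(n1=5, n2=5)
        iface = struct.interface_set()
        d = rng.random((10, 10))
        d = (d + d.T) / 2
        got = raw_cmm_score(coupling(d), struct, iface)
        expect = sum(d[i, j] for i, j in iface.pairs) / len(iface)
        assert got == pytest.approx(expect, abs=1e-12)

    def test_empty_interface_is_undefined(self):
        struct = line_complex()
        with pytest.raises(UndefinedScoreError):
            raw_cmm_score(coupling(np.zeros((8, 8))), struct, InterfaceSet(frozenset()))


class TestNeighbourAveragedCmm:
    def test_singleton_neighbourhood_returns_d(self):
        struct = line_complex()  # spacing 6 > 4.5: every N_j = {j}
        d = np.zeros((8, 8))
        d[0, 4] = d[4, 0] = 0.9
        assert neighbour_averaged_cmm(coupling(d), struct, 0, 4) == pytest.approx(0.9)

    def test_constant_row_returns_constant(self):
        struct = line_complex(spacing=3.8)  # chains connected: N_j = {j-1, j, j+1}
        d = np.full((8, 8), 0.42)
        assert neighbour_averaged_cmm(coupling(d), struct, 0, 5) == pytest.approx(0.42)

    def test_two_member_neighbourhood_mean(self):
        struct = two_chain([(0, 0, 0)], [(0, 4, 0), (4, 4, 0)])
        force_surface(struct)
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = 0.1
        d[0, 2] = d[2, 0] = 0.3
        got = neighbour_averaged_cmm(
            CouplingMatrix(D=d, boundary=1), struct, 0, 1
        )
        assert got == pytest.approx(0.2)

    def test_same_chain_pair_rejected(self):
        struct = line_complex()
        with pytest.raises(ValueError):
            neighbour_averaged_cmm(coupling(np.zeros((8, 8))), struct, 0, 1)


class TestStandardisedCmm:
    def test_z_table_symmetric_and_score_matches_mean(self):
        rng = np.random.default_rng(1)
        struct = line_complex(n1=5, n2=5, spacing=3.8)
        iface = struct.interface_set()
        d = rng.random((10, 10)) * 0.2
        d = (d + d.T) / 2
        comp = standardised_cmm(coupling(d), struct, iface)
        for i, j in iface.pairs:
            assert comp.z[(i, j)] == comp.z[(j, i)]
        assert interface_cmm_score(comp.z, iface) == pytest.approx(comp.S_CMM)

    def test_interface_mode_standardisation_recentres_exactly(self):
        rng = np.random.default_rng(2)
        struct = line_complex(n1=5, n2=5, spacing=3.8)
        iface = struct.interface_set()
        d = rng.random((10, 10)) * 0.2
        d = (d + d.T) / 2
        comp = standardised_cmm(
            coupling(d), struct, iface, standardise_over="interface"
        )
        # standardised values of the population average to 0, so averaging Z
        # over the same interface cancels exactly
        for r in iface.residues:
            if comp.sigma[r] > 0:
                vals = [
                    (comp.chi[(l, k)] - comp.mu[l]) / comp.sigma[l]
                    for (l, k) in comp.chi
                    if struct.residues[l].chain == struct.residues[r].chain
                ]
                assert np.mean(vals) == pytest.approx(0.0, abs=1e-10)
        assert comp.S_CMM == pytest.approx(0.0, abs=1e-10)

    def test_degenerate_spread_contributes_zero(self):
        struct = line_complex(n1=3, n2=3)
        iface = struct.interface_set()
        comp = standardised_cmm(coupling(np.zeros((6, 6))), struct, iface)
        assert all(v == 0.0 for v in comp.z.values())

    def test_all_pairs_mode_rewards_coupled_interface(self):
        # couplings sit exactly on the facing pairs: Z over the interface
        # should be clearly positive when standardised against all pairs
        struct = line_complex(n1=4, n2=4, spacing=3.8)
        iface = struct.interface_set()
        d = np.zeros((8, 8))
        for i in range(4):
            d[i, 4 + i] = d[4 + i, i] = 1.0
        comp = standardised_cmm(coupling(d), struct, iface)
        assert comp.S_CMM > 0.5


class TestSizeAndPotential:
    def test_interface_size_counts_distinct_residues(self):
        assert interface_size_score(InterfaceSet(frozenset({(0, 5), (1, 5)}))) == 3
        assert interface_size_score(InterfaceSet(frozenset())) == 0
        five = InterfaceSet(frozenset({(i, 10 + i) for i in range(5)}))
        assert interface_size_score(five) == 10

    def test_rp_score_arithmetic(self):
        struct = line_complex(n1=2, n2=2)
        iface = InterfaceSet(frozenset({(0, 2), (1, 3)}))
        zero = RPMatrix.from_array("A", np.zeros((1, 1)))
        assert rp_score(struct, iface, zero) == 0.0
        vals = {("A", "A"): 1.5}
        m = RPMatrix(values={("A", "A"): 1.5})
        assert rp_score(struct, InterfaceSet(frozenset({(0, 2)})), m) == 1.5

    def test_rp_score_brute_force(self):
        rng = np.random.default_rng(7)
        struct = line_complex(n1=5, n2=5)
        iface = struct.interface_set()
        raw = rng.normal(size=(20, 20))
        m = RPMatrix.from_array("ACDEFGHIKLMNPQRSTVWY", (raw + raw.T) / 2)
        got = rp_score(struct, iface, m)
        expect = sum(m.get("A", "A") for _ in iface.pairs)
        assert got == pytest.approx(expect, abs=1e-12)

    def test_missing_entry_is_an_error(self):
        struct = line_complex(n1=1, n2=1, gap=4.0)
        iface = InterfaceSet(frozenset({(0, 1)}))
        with pytest.raises(KeyError):
            rp_score(struct, iface, RPMatrix(values={}))


def entropy_two_state(p):
    return -(p * math.log(p) + (1 - p) * math.log(1 - p))


class TestEntropyScore:
    def test_conserved_interface_has_zero_entropy(self):
        aln = Alignment.from_sequences(["AAAA"] * 4, boundary=2)
        freq = frequencies(aln, pseudocount=0.0)
        struct = line_complex(n1=2, n2=2)
        iface = InterfaceSet(frozenset({(0, 2), (1, 3)}))
        assert entropy_score(freq, struct, iface) == 0.0

    def test_weighted_mean_with_hand_computed_value(self):
        # residue a interacts twice (columns: a=0, x=1 on chain 1; cross
        # partners at columns 2, 3); H_a = 0.6, H_x = H_y = 0.3 in nats
        p_a = brentq(lambda p: entropy_two_state(p) - 0.6, 1e-6, 0.5)
        p_x = brentq(lambda p: entropy_two_state(p) - 0.3, 1e-6, 0.5)
        q = 21
        single = np.zeros((4, q))
        for col, p in [(0, p_a), (1, 0.5), (2, p_x), (3, p_x)]:
            single[col, 0] = p
            single[col, 1] = 1 - p
        freq = FrequencyModel(
            single=single, pair_flat=np.zeros((4 * q, 4 * q)), pseudocount=0.0,
            n_states=q,
        )
        struct = line_complex(n1=2, n2=2)
        iface = InterfaceSet(frozenset({(0, 2), (0, 3)}))
        got = entropy_score(freq, struct, iface)
        assert got == pytest.approx((2 * 0.6 + 0.3 + 0.3) / 4, abs=1e-9)

    def test_equal_entropies_give_plain_value(self):
        aln = Alignment.from_sequences(["AAAA", "VVVV"], boundary=2)
        freq = frequencies(aln, pseudocount=0.0)
        struct = line_complex(n1=2, n2=2)
        iface = InterfaceSet(frozenset({(0, 2), (1, 3)}))
        assert entropy_score(freq, struct, iface) == pytest.approx(math.log(2))

    def test_bounded_by_max_interface_entropy(self):
        aln = Alignment.from_sequences(["AAVA", "AVAC", "AADG", "AVLT"], boundary=2)
        freq = frequencies(aln, pseudocount=0.0)
        struct = line_complex(n1=2, n2=2)
        iface = struct.interface_set()
        from coevodock.alignment import column_entropy

        h_max = max(column_entropy(freq, c) for c in range(4))
        assert entropy_score(freq, struct, iface) <= h_max + 1e-12


class TestComplementarity:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ("D", "K", True),   # opposite charges
            ("K", "D", True),
            ("L", "V", True),   # both hydrophobic
            ("S", "T", True),   # both polar
            ("D", "E", False),  # same charge
            ("K", "R", False),
            ("L", "S", False),  # different groups
            ("-", "K", False),  # gap never complementary
            ("X", "K", False),  # unknown symbol
        ],
    )
    def test_pairwise_rules(self, a, b, expected):
        assert complementary(a, b) is expected

    def test_scheme_covers_all_standard_amino_acids(self):
        scheme = PolarityScheme.default()
        for aa in "ACDEFGHIKLMNPQRSTVWY":
            assert scheme.code(aa) in (0, 1, 2, 3)


class TestCtScore:
    def make_struct(self):
        return line_complex(n1=2, n2=2)

    def aln_from_cols(self, cols):
        """Build an alignment from per-column symbol strings (rows zipped)."""
        rows = ["".join(t) for t in zip(*cols)]
        return Alignment.from_sequences(rows, boundary=2)

    def test_fully_complementary_gives_one(self):
        m = 40
        aln = self.aln_from_cols(["D" * m, "A" * m, "K" * m, "A" * m])
        struct = self.make_struct()
        iface = InterfaceSet(frozenset({(0, 2)}))  # columns 0 (D) vs 2 (K)
        assert ct_score(aln, struct, iface) == 1.0

    def test_never_complementary_gives_zero(self):
        m = 40
        aln = self.aln_from_cols(["D" * m, "A" * m, "E" * m, "A" * m])
        struct = self.make_struct()
        iface = InterfaceSet(frozenset({(0, 2)}))
        assert ct_score(aln, struct, iface) == 0.0

    @pytest.mark.parametrize("n_good, expected", [(94, 0.0), (95, 1.0)])
    def test_preservation_threshold_at_95_percent(self, n_good, expected):
        col0 = "D" * n_good + "A" * (100 - n_good)  # A-K is not complementary
        aln = self.aln_from_cols([col0, "A" * 100, "K" * 100, "A" * 100])
        struct = self.make_struct()
        iface = InterfaceSet(frozenset({(0, 2)}))
        # wide spacing: no structural neighbours, so no rescue
        assert ct_score(aln, struct, iface) == expected

    def test_neighbour_rescue_is_monotone_in_order(self):
        # direct pair never complementary, but j's chain neighbour is
        m = 40
        cols = ["D" * m, "A" * m, "E" * m, "K" * m]
        aln = self.aln_from_cols(cols)
        struct = line_complex(n1=2, n2=2, spacing=3.8)  # chains connected
        iface = InterfaceSet(frozenset({(0, 2)}))
        scores = [
            ct_score(aln, struct, iface, neighbour_order=k) for k in (0, 1, 2)
        ]
        assert scores[0] == 0.0
        assert scores[0] <= scores[1] <= scores[2]
        assert scores[1] == 1.0  # rescued by neighbour column 3 (K vs D)


class TestScoreDecoyInvariance:
    def test_components_invariant_under_global_rigid_motion(self, toy_native):
        from scipy.spatial.transform import Rotation

        from coevodock.synthetic import (
            FixtureSpec,
            make_coupled_model,
            random_rp_matrix,
            sample_potts_msa,
        )

        spec = FixtureSpec(seed=3, n1=10, n2=10, q=8, m=150)
        aln = sample_potts_msa(make_coupled_model(spec), spec.m, seed=3)
        freq = frequencies(aln, pseudocount=0.0)
        rng = np.random.default_rng(0)
        d = rng.random((20, 20)) * 0.3
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        dmat = CouplingMatrix(D=d, boundary=10)
        rp = random_rp_matrix(1)
        comp0 = score_decoy(toy_native, dmat, aln, freq, rp_matrix=rp)
        rot = Rotation.from_euler("xyz", [0.4, 1.2, -0.8]).as_matrix()
        moved = toy_native.transformed(rot, np.array([7.0, -2.0, 3.0]), chain=None)
        comp1 = score_decoy(moved, dmat, aln, freq, rp_matrix=rp)
        for attr in ("S_N", "S_RP", "S_ent", "S_CT", "S_CMM", "S_CMM_raw"):
            assert getattr(comp1, attr) == pytest.approx(
                getattr(comp0, attr), abs=1e-9
            )
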