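"""Structure loading, chain assignment, distance mapping and superposition."""

import numpy as np
import pytest

from xlorg import structure_map, synthetic
from xlorg.structure_map import (
    Chain,
    Residue,
    StructureModel,
    build_chain_assignment,
    ca_distance,
    distance_distribution,
    kabsch_superpose,
    map_crosslink,
    satisfaction_report,
)
from xlorg.xl_io import CrossLinkRecord


MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.000   0.000   0.000  1.00  0.00           C
ATOM      3  CA  LYS A   2       4.000   4.000   0.000  1.00  0.00           C
TER
END
"""


class TestLoadStructure:
    def test_minimal_pdb_fixture(self, tmp_path):
        path = tmp_path / "mini.pdb"
        path.write_text(MINIMAL_PDB)
        model = structure_map.load_structure(path)
        assert list(model.chains) == ["A"]
        assert len(model.chains["A"].residues) == 2
        assert model.ca("A", 2).tolist() == [4.0, 4.0, 0.0]

    def test_pdb_and_mmcif_give_identical_model(self, tmp_path, small_complex):
        pdb = tmp_path / "cx.pdb"
        cif = tmp_path / "cx.cif"
        synthetic.structure_to_pdb(small_complex.structure, pdb)
        synthetic.structure_to_cif(small_complex.structure, cif)
        from_pdb = structure_map.load_structure(pdb)
        from_cif = structure_map.load_structure(cif)
        assert sorted(from_pdb.chains) == sorted(from_cif.chains)
        for chain_id in from_pdb.chains:
            for res_p, res_c in zip(
                from_pdb.chains[chain_id].residues,
                from_cif.chains[chain_id].residues,
            ):
                assert res_p.number == res_c.number and res_p.name == res_c.name
                assert np.allclose(res_p.ca, res_c.ca, atol=1e-3)

    def test_residue_without_ca_flagged_absent(self, tmp_path):
        pdb = (
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  N   GLY A   2       2.000   0.000   0.000  1.00  0.00           N\n"
            "END\n"
        )
        path = tmp_path / "gap.pdb"
        path.write_text(pdb)
        model = structure_map.load_structure(path)
        residues = model.chains["A"].residues
        assert residues[0].present and not residues[1].present

    def test_unparseable_file_raises(self, tmp_path):
        path = tmp_path / "junk.cif"
        path.write_text("this is not a structure\n")
        with pytest.raises(ValueError):
            structure_map.load_structure(path)


def _linear_chain(numbers, names=None, spacing=3.8, chain_id="A"):
    names = names or ["ALA"] * len(numbers)
    residues = [
        Residue(n, names[i], (i * spacing, 0.0, 0.0))
        for i, n in enumerate(numbers)
    ]
    return StructureModel(id="fixture", chains={chain_id: Chain(chain_id, residues)})


class TestChainAssignment:
    def test_identical_chain_identity_one(self, small_complex):
        assignment = build_chain_assignment(
            small_complex.structure, small_complex.sequences
        )
        assert not assignment.unassigned_chains
        for chain_id, identity in assignment.identities.items():
            assert identity == 1.0
        chains = assignment.chains_for("SYN001")
        assert len(chains) == 1
        _, residue_map = chains[0]
        n = len(small_complex.sequences["SYN001"])
        assert residue_map == {i: i for i in range(1, n + 1)}

    def test_renumbered_chain_offset_recovered(self, small_complex):
        seq = small_complex.sequences["SYN001"]
        from xlorg.structure_map import AA1_TO_3

        model = _linear_chain(
            [i + 6 for i in range(1, len(seq) + 1)],
            names=[AA1_TO_3[c] for c in seq],
        )
        assignment = build_chain_assignment(model, {"SYN001": seq})
        _, residue_map = assignment.chains_for("SYN001")[0]
        assert residue_map == {i: i + 6 for i in range(1, len(seq) + 1)}

    def test_internal_deletion_skips_gap(self, small_complex):
        seq = small_complex.sequences["SYN001"]
        from xlorg.structure_map import AA1_TO_3

        kept = [i for i in range(1, len(seq) + 1) if i not in (60, 61, 62)]
        model = _linear_chain(kept, names=[AA1_TO_3[seq[i - 1]] for i in kept])
        assignment = build_chain_assignment(
            model, {"SYN001": seq}, min_identity=0.8
        )
        chain_id, residue_map = assignment.chains_for("SYN001")[0]
        assert assignment.identities[chain_id] == pytest.approx(
            (len(seq) - 3) / len(seq)
        )
        assert set(residue_map) == set(kept)

    def test_low_identity_chain_left_unassigned(self, small_complex):
        assignment = build_chain_assignment(
            small_complex.structure,
            {"OTHER": "M" * 100},
            min_identity=0.9,
        )
        assert not assignment.assignments
        assert sorted(assignment.unassigned_chains) == sorted(
            small_complex.structure.chains
        )


class TestCaDistance:
    def test_identical_endpoints_zero(self):
        model = _linear_chain([1, 2])
        assert ca_distance(model, ("A", 1), ("A", 1)) == 0.0

    def test_pythagorean(self):
        model = StructureModel(
            id="p",
            chains={
                "A": Chain(
                    "A",
                    [
                        Residue(1, "ALA", (0.0, 0.0, 0.0)),
                        Residue(2, "ALA", (3.0, 4.0, 0.0)),
                    ],
                )
            },
        )
        assert ca_distance(model, ("A", 1), ("A", 2)) == pytest.approx(5.0)

    def test_absent_residue_raises_with_location(self):
        model = StructureModel(
            id="m", chains={"A": Chain("A", [Residue(1, "ALA", None)])}
        )
        with pytest.raises(KeyError, match="chain 'A'"):
            ca_distance(model, ("A", 1), ("A", 1))

    def test_symmetry_and_componentwise_formula(self, small_complex, rng):
        model = small_complex.structure
        chain_ids = sorted(model.chains)
        for _ in range(200):
            ca_id, cb_id = rng.choice(chain_ids, size=2)
            ra = int(rng.integers(1, 150)), int(rng.integers(1, 150))
            p = model.ca(ca_id, ra[0])
            q = model.ca(cb_id, ra[1])
            expected = (
                (p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 + (p[2] - q[2]) ** 2
            ) ** 0.5
            d_fwd = ca_distance(model, (ca_id, ra[0]), (cb_id, ra[1]))
            d_rev = ca_distance(model, (cb_id, ra[1]), (ca_id, ra[0]))
            assert d_fwd == pytest.approx(expected, abs=1e-9)
            assert d_fwd == d_rev


class TestMapCrosslink:
    def test_single_copy_unique_pair(self, small_complex, small_assignment):
        record = CrossLinkRecord("SYN001", 10, "SYN002", 20)
        mapped = map_crosslink(record, small_complex.structure, small_assignment)
        assert mapped.status == "mapped"
        expected = ca_distance(
            small_complex.structure,
            (small_assignment.chains_for("SYN001")[0][0], 10),
            (small_assignment.chains_for("SYN002")[0][0], 20),
        )
        assert mapped.distance == pytest.approx(expected)

    def test_homodimer_min_rule(self, dimer_complex, dimer_assignment):
        """The chosen distance is the minimum over every copy-pair combination."""
        record = CrossLinkRecord("SYN001", 5, "SYN002", 40)
        mapped = map_crosslink(record, dimer_complex.structure, dimer_assignment)
        copies_a = [c for c, _ in dimer_assignment.chains_for("SYN001")]
        copy_b = dimer_assignment.chains_for("SYN002")[0][0]
        enumerated = [
            ca_distance(dimer_complex.structure, (ca, 5), (copy_b, 40))
            for ca in copies_a
        ]
        assert len(copies_a) == 2
        assert mapped.distance == pytest.approx(min(enumerated))
        assert all(mapped.distance <= d + 1e-12 for d in enumerated)

    def test_intra_link_may_cross_copies(self, dimer_complex, dimer_assignment):
        record = CrossLinkRecord("SYN001", 5, "SYN001", 100)
        mapped = map_crosslink(record, dimer_complex.structure, dimer_assignment)
        copies = [c for c, _ in dimer_assignment.chains_for("SYN001")]
        enumerated = [
            ca_distance(dimer_complex.structure, (ca, 5), (cb, 100))
            for ca in copies
            for cb in copies
        ]
        assert mapped.distance == pytest.approx(min(enumerated))

    def test_endpoint_beyond_chain_is_missing(self, small_complex, small_assignment):
        record = CrossLinkRecord("SYN001", 9999, "SYN002", 20)
        mapped = map_crosslink(record, small_complex.structure, small_assignment)
        assert mapped.status == "endpoint_missing"
        assert mapped.distance is None

    def test_absent_protein(self, small_complex, small_assignment):
        record = CrossLinkRecord("NOPE", 1, "SYN002", 20)
        mapped = map_crosslink(record, small_complex.structure, small_assignment)
        assert mapped.status == "protein_absent"


class TestSatisfactionReport:
    def test_fourteen_of_sixteen(self, small_complex, small_assignment):
        """16 mapped links with 14 within the restraint give 87.5% agreement."""
        links, truth = synthetic.sample_crosslinks(
            small_complex, n_satisfying=14, n_violating=2, seed=7
        )
        mapped = [
            map_crosslink(r, small_complex.structure, small_assignment)
            for r in links.records
        ]
        report = satisfaction_report(mapped, max_distance=35.0)
        assert (report.n_mapped, report.n_satisfied) == (16, 14)
        assert report.agreement == pytest.approx(14 / 16)

    def test_empty_input(self):
        report = satisfaction_report([])
        assert report.n_input == 0 and report.agreement is None

    def test_monotone_in_max_distance(self, small_complex, small_assignment, planted_links):
        links, _ = planted_links
        mapped = [
            map_crosslink(r, small_complex.structure, small_assignment)
            for r in links.records
        ]
        satisfied = [
            satisfaction_report(mapped, max_distance=d).n_satisfied
            for d in (10, 20, 35, 50, 80)
        ]
        assert satisfied == sorted(satisfied)


class TestDistanceDistribution:
    @staticmethod
    def _mapped(distances):
        return [
            structure_map.MappedCrossLink(
                CrossLinkRecord("A", 1, "B", i + 1),
                status="mapped",
                distance=float(d),
                satisfied=d <= 35,
            )
            for i, d in enumerate(distances)
        ]

    def test_simple_binning(self):
        edges, counts = distance_distribution(self._mapped([5, 5, 12]), 10)
        assert counts.tolist() == [2, 1]
        assert edges.tolist() == [0.0, 10.0, 20.0]

    def test_boundary_value_falls_right(self):
        edges, counts = distance_distribution(self._mapped([10]), 10)
        assert counts.tolist() == [0, 1]

    def test_counts_match_loop_oracle(self, rng):
        distances = rng.uniform(0, 80, size=500)
        width = 5.0
        edges, counts = distance_distribution(self._mapped(distances), width)
        oracle = [0] * (len(edges) - 1)
        for d in distances:
            for i in range(len(edges) - 1):
                if edges[i] <= d < edges[i + 1]:
                    oracle[i] += 1
                    break
        assert counts.tolist() == oracle
        assert counts.sum() == 500


class TestKabsch:
    def test_identity_on_equal_sets(self, rng):
        coords = rng.normal(size=(30, 3))
        rotation, translation, rmsd = kabsch_superpose(coords, coords)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(rotation, np.eye(3), atol=1e-8)

    def test_recovers_planted_transform(self, rng):
        coords = rng.normal(size=(100, 3)) * 10
        true_rotation = synthetic._random_rotation(rng)
        true_translation = rng.normal(size=3) * 5
        moved = coords @ true_rotation.T + true_translation
        rotation, translation, rmsd = kabsch_superpose(coords, moved)
        assert rmsd < 1e-8
        assert np.allclose(rotation, true_rotation, atol=1e-8)
        assert np.allclose(translation, true_translation, atol=1e-8)

    def test_noise_rmsd_matches_monte_carlo_scale(self, rng):
        """With isotropic per-coordinate noise σ the fitted RMSD sits just
        below σ√3 (six rigid degrees of freedom absorbed)."""
        sigma = 0.5
        coords = rng.normal(size=(100, 3)) * 10
        rotation = synthetic._random_rotation(rng)
        noise = rng.normal(0, sigma, size=coords.shape)
        moved = coords @ rotation.T + 3.0 + noise
        _, _, rmsd = kabsch_superpose(coords, moved)
        true_residual = np.sqrt((noise**2).sum(axis=1).mean())
        assert rmsd <= true_residual + 1e-12
        assert rmsd == pytest.approx(sigma * np.sqrt(3), rel=0.15)

    def test_invariant_under_common_rigid_motion(self, rng):
        coords_a = rng.normal(size=(50, 3))
        coords_b = coords_a + rng.normal(0, 0.3, size=coords_a.shape)
        _, _, rmsd0 = kabsch_superpose(coords_a, coords_b)
        common_rotation = synthetic._random_rotation(rng)
        shift = rng.normal(size=3) * 7
        _, _, rmsd1 = kabsch_superpose(
            coords_a @ common_rotation.T + shift,
            coords_b @ common_rotation.T + shift,
        )
        assert rmsd1 == pytest.approx(rmsd0, abs=1e-8)

    def test_rejects_degenerate_input(self):
        line = np.array([[float(i), 0.0, 0.0] for i in range(10)])
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line, line)
        with pytest.raises(ValueError, match="3 paired points"):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
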