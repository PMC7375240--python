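"""Frame extraction, superposed RMSD, k-medoids clustering, conservation."""

import numpy as np
import pytest
from importlib import resources
from scipy.spatial.transform import Rotation

from cyslock import fixtures, pocketmap
from cyslock.pocketmap import (
    ca_rmsd,
    cluster_frames,
    conservation_screen,
    extract_even,
)

from conftest import atom_line


def multi_model_pdb(n_models, n_res=4):
    """Each model translated by its index along z (distinct frames)."""
    lines = []
    for m in range(1, n_models + 1):
        lines.append(f"MODEL     {m:>4d}")
        for i in range(1, n_res + 1):
            lines.append(
                atom_line(i, "CA", "ALA", "A", i, 3.8 * i, 0.0, float(m), "C")
            )
        lines.append("ENDMDL")
    return "\n".join(lines) + "\nEND\n"


class TestExtractEven:
    def test_keep_all_is_identity(self):
        fs = extract_even(multi_model_pdb(10), 10)
        assert fs.n_frames == 10

    def test_even_indices_formula(self):
        fs = extract_even(multi_model_pdb(9), 3)
        # models 0, 4, 8 -> z = 1, 5, 9
        assert [f[0][2] for f in fs.frames] == [1.0, 5.0, 9.0]

    def test_single_frame_keeps_first(self):
        fs = extract_even(multi_model_pdb(5), 1)
        assert fs.n_frames == 1
        assert fs.frames[0][0][2] == 1.0

    def test_first_and_last_always_kept(self):
        fs = extract_even(multi_model_pdb(17), 5)
        zs = [f[0][2] for f in fs.frames]
        assert zs[0] == 1.0 and zs[-1] == 17.0

    def test_overdraw_rejected(self):
        with pytest.raises(ValueError):
            extract_even(multi_model_pdb(5), 6)

    def test_only_ca_atoms_used(self):
        pdb, _ = fixtures.make_trajectory(1, n_frames=5, n_residues=10)
        fs = extract_even(pdb, 5)
        assert fs.frames.shape == (5, 10, 3)
        assert fs.residue_numbers == list(range(1, 11))


class TestCaRmsd:
    def test_identity_and_symmetry(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=(2, 12, 3))
        assert ca_rmsd(a, a) == pytest.approx(0.0, abs=1e-9)
        assert ca_rmsd(a, b) == pytest.approx(ca_rmsd(b, a), abs=1e-9)

    def test_rigid_motion_removed_by_superposition(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(20, 3))
        R = Rotation.random(random_state=5).as_matrix()
        moved = a @ R.T + np.array([4.0, -2.0, 9.0])
        assert ca_rmsd(a, moved, superpose=True) == pytest.approx(0.0, abs=1e-9)
        assert ca_rmsd(a, moved, superpose=False) > 1.0

    def test_two_point_stretch(self):
        a = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        b = np.array([[0.0, 0, 0], [4.0, 0, 0]])
        assert ca_rmsd(a, b, superpose=True) == pytest.approx(1.0, abs=1e-9)

    def test_superposed_never_exceeds_raw(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            a, b = rng.normal(size=(2, 15, 3))
            assert ca_rmsd(a, b, True) <= ca_rmsd(a, b, False) + 1e-12

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            ca_rmsd(np.zeros((3, 3)), np.zeros((4, 3)))


class TestClusterFrames:
    def test_singletons_when_k_equals_n(self):
        pdb, _ = fixtures.make_trajectory(
            2, n_frames=6, state_fractions=(0.5, 0.5), n_residues=15
        )
        fs = extract_even(pdb, 6)
        rep = cluster_frames(fs, k=6)
        assert np.allclose(rep.occupancies, 1 / 6)
        assert sorted(rep.labels) == list(range(6))

    def test_two_state_recovery(self):
        pdb, labels = fixtures.make_trajectory(3)
        fs = extract_even(pdb, 100)
        rep = cluster_frames(fs, k=2)
        assert np.allclose(rep.occupancies, [0.6, 0.4])
        # zero label mixing: each generated state maps to one cluster
        lab = np.array(labels)
        for s in (0, 1):
            assert len(set(rep.labels[lab == s])) == 1
        assert rep.occupancies.sum() == pytest.approx(1.0, abs=1e-9)

    def test_medoid_belongs_to_its_cluster(self):
        pdb, _ = fixtures.make_trajectory(4, n_frames=40)
        fs = extract_even(pdb, 40)
        rep = cluster_frames(fs, k=3)
        for c in range(rep.k):
            assert rep.labels[rep.medoid_frame[c]] == c

    def test_occupancy_invariant_under_frame_permutation(self):
        pdb, _ = fixtures.make_trajectory(5, n_frames=30)
        fs = extract_even(pdb, 30)
        rep = cluster_frames(fs, k=2)
        rng = np.random.default_rng(9)
        perm = rng.permutation(30)
        fs2 = pocketmap.FrameSet(
            frames=fs.frames[perm], residue_numbers=fs.residue_numbers
        )
        rep2 = cluster_frames(fs2, k=2)
        assert np.allclose(rep2.occupancies, rep.occupancies)
        # same partition up to relabeling
        for c in range(2):
            members = set(perm[np.flatnonzero(rep2.labels == c)])
            orig = [set(np.flatnonzero(rep.labels == d)) for d in range(2)]
            assert members in orig

    def test_k_out_of_range(self):
        pdb, _ = fixtures.make_trajectory(6, n_frames=10)
        fs = extract_even(pdb, 10)
        with pytest.raises(ValueError):
            cluster_frames(fs, k=11)

    def test_medoid_frame_exports_as_single_model_pdb(self):
        pdb, _ = fixtures.make_trajectory(8, n_frames=12, n_residues=20)
        fs = extract_even(pdb, 12)
        rep = cluster_frames(fs, k=2)
        from cyslock import structures

        out = structures.read_structure(
            pocketmap.write_frame_pdb(fs, int(rep.medoid_frame[0]))
        )
        assert out.n_models == 1
        assert np.allclose(
            out.coords(), fs.frames[rep.medoid_frame[0]], atol=1e-3
        )

    def test_report_tsv_shape(self):
        pdb, _ = fixtures.make_trajectory(7, n_frames=20)
        rep = cluster_frames(extract_even(pdb, 20), k=2)
        lines = rep.to_tsv().strip().splitlines()
        assert lines[0] == "cluster\toccupancy\tmedoid_model"
        assert len(lines) == 3


TOY_ALN = """\
>ref
MK-CDE
>other1
MKQ-DE
>other2
MKWADE
"""


class TestConservationScreen:
    def test_reference_column_mapping_skips_gaps(self):
        rep = conservation_screen(TOY_ALN, "ref", 3)  # M,K,C -> column 3
        assert rep.column_index == 3
        assert rep.matching_ids == ["ref"]

    def test_packaged_family_snippet_cys_unique_to_rhoa(self):
        aln = (
            resources.files("cyslock.data")
            .joinpath("ras_superfamily_cys_column_synthetic.afa")
            .read_text()
        )
        # residue 9 of the packaged fragment corresponds to the anchor Cys107
        rep = conservation_screen(aln, "RhoA", 9)
        assert rep.matching_ids == ["RhoA"]
        assert dict(rep.symbols)["RhoA"] == "C"

    @pytest.mark.parametrize("resnum", [0, -3, 99])
    def test_bad_residue_number(self, resnum):
        with pytest.raises(ValueError):
            conservation_screen(TOY_ALN, "ref", resnum)

    def test_missing_reference(self):
        with pytest.raises(ValueError, match="nope"):
            conservation_screen(TOY_ALN, "nope", 1)

    def test_unaligned_input_rejected(self):
        with pytest.raises(ValueError, match="aligned"):
            conservation_screen(">a\nMKC\n>b\nMK\n", "a", 1)
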