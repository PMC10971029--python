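import subprocess
import textwrap

import numpy as np
import pytest

from varidyn import (
    AtomRecord,
    Structure,
    TrajectoryEnsemble,
    convert_rdata,
    drop_equilibration,
    read_ensemble,
    resolve_selection,
    write_ensemble,
)
from varidyn import synthetic as syn

TOY_PDB = textwrap.dedent(
    """\
    MODEL        1
    ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
    ATOM      2  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C
    ATOM      3  CA  ALA A   3       7.600   0.000   0.000  1.00  0.00           C
    ATOM      4  CA  GLY B  10       0.000   5.000   0.000  1.00  0.00           C
    ATOM      5  CA  GLY B  11       3.800   5.000   0.000  1.00  0.00           C
    ENDMDL
    MODEL        2
    ATOM      1  CA  ALA A   1       0.100   0.000   0.000  1.00  0.00           C
    ATOM      2  CA  ALA A   2       3.900   0.000   0.000  1.00  0.00           C
    ATOM      3  CA  ALA A   3       7.700   0.000   0.000  1.00  0.00           C
    ATOM      4  CA  GLY B  10       0.100   5.000   0.000  1.00  0.00           C
    ATOM      5  CA  GLY B  11       3.900   5.000   0.000  1.00  0.00           C
    ENDMDL
    MODEL        3
    ATOM      1  CA  ALA A   1       0.200   0.000   0.000  1.00  0.00           C
    ATOM      2  CA  ALA A   2       4.000   0.000   0.000  1.00  0.00           C
    ATOM      3  CA  ALA A   3       7.800   0.000   0.000  1.00  0.00           C
    ATOM      4  CA  GLY B  10       0.200   5.000   0.000  1.00  0.00           C
    ATOM      5  CA  GLY B  11       4.000   5.000   0.000  1.00  0.00           C
    ENDMDL
    END
    """
)


def _toy_structure(residues, chain="B", start=1):
    atoms = [
        AtomRecord(atom_index=i, atom_name="CA", residue_number=start + i,
                   residue_name="ALA", chain_id=chain)
        for i in range(residues)
    ]
    coords = np.column_stack([np.arange(residues) * 3.8, np.zeros(residues), np.zeros(residues)])
    return Structure(atoms=atoms, coordinates=coords)


class TestReadEnsemble:
    def test_multi_model_toy_counts(self, tmp_path):
        p = tmp_path / "toy.pdb"
        p.write_text(TOY_PDB)
        ens = read_ensemble(p)
        assert ens.n_frames == 3
        assert ens.n_atoms == 5
        assert ens.atoms[3].chain_id == "B" and ens.atoms[3].residue_number == 10
        assert ens.frames[2, 0, 0] == pytest.approx(0.2)

    def test_mismatched_model_errors_name_the_model(self, tmp_path):
        bad = TOY_PDB.replace(
            "ATOM      5  CA  GLY B  11       4.000   5.000   0.000  1.00  0.00           C\n"
            "ENDMDL\nEND\n",
            "ENDMDL\nEND\n",
        )
        p = tmp_path / "bad.pdb"
        p.write_text(bad)
        with pytest.raises(ValueError, match="model 3"):
            read_ensemble(p)

    def test_zero_models_is_an_error(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("END\n")
        with pytest.raises(ValueError, match="no models"):
            read_ensemble(p)

    def test_insertion_codes_rejected(self, tmp_path):
        line = "ATOM      1  CA  ALA A   1A      0.000   0.000   0.000  1.00  0.00           C\n"
        p = tmp_path / "icode.pdb"
        p.write_text("MODEL        1\n" + line + "ENDMDL\nEND\n")
        with pytest.raises(ValueError, match="insertion code"):
            read_ensemble(p)

    def test_pdb_round_trip(self, tmp_path, template, planted_modes):
        sc = syn.VariantScenario(name="rt", seed=7, n_frames=5)
        ens = syn.sample_ensemble(template, planted_modes, sc)
        p = tmp_path / "rt.pdb"
        write_ensemble(ens, p)
        back = read_ensemble(p)
        assert back.atoms == ens.atoms
        assert np.abs(back.frames - ens.frames).max() <= 1e-3

    def test_xyz_round_trip(self, tmp_path):
        ens = TrajectoryEnsemble(
            atoms=_toy_structure(4, chain="A").atoms,
            frames=np.random.default_rng(0).normal(size=(3, 4, 3)),
        )
        p = tmp_path / "rt.xyz"
        write_ensemble(ens, p, format="xyz")
        back = read_ensemble(p, format="xyz")
        assert back.n_frames == 3 and back.n_atoms == 4
        assert np.abs(back.frames - ens.frames).max() <= 1e-5

    def test_synthetic_fixture_contract(self, template, planted_modes):
        sc = syn.VariantScenario(name="fix", seed=1, n_frames=50)
        ens = syn.sample_ensemble(template, planted_modes, sc)
        assert ens.n_frames == 50
        assert all(a.atom_name == "CA" for a in ens.atoms)


class TestSelections:
    def test_inclusive_residue_range_count(self):
        s = _toy_structure(191, chain="B", start=420)  # residues 420..610
        sel = resolve_selection(s, "chain B and resid 440-600 and name CA")
        assert len(sel) == 161  # 600 - 440 + 1

    def test_absent_chain_is_hard_error(self, template):
        with pytest.raises(ValueError, match="chain 'Z'"):
            resolve_selection(template, "chain Z and name CA")

    def test_generator_chain_counts(self, template):
        assert len(resolve_selection(template, "chain A and name CA")) == 80
        assert len(resolve_selection(template, "chain B and name CA")) == 120

    def test_clause_order_stable_and_idempotent(self, template):
        a = resolve_selection(template, "chain B and resid 61-120 and name CA")
        b = resolve_selection(template, "name CA and resid 61-120 and chain B")
        assert np.array_equal(a.resolved_indices, b.resolved_indices)
        assert np.all(np.diff(a.resolved_indices) > 0)

    def test_empty_match_warns(self, template):
        with pytest.warns(UserWarning, match="matched no atoms"):
            sel = resolve_selection(template, "chain A and resid 500")
        assert len(sel) == 0


class TestDropEquilibration:
    @pytest.mark.parametrize(
        "total, fraction, expected",
        [(15, 1.0 / 3.0, 10), (7, 0.0, 7), (100, 0.5, 50), (10, 0.25, 8)],
    )
    def test_retained_frame_count(self, total, fraction, expected):
        s = _toy_structure(2)
        ens = TrajectoryEnsemble(atoms=s.atoms, frames=np.random.default_rng(1).normal(size=(total, 2, 3)))
        out = drop_equilibration(ens, fraction)
        assert out.n_frames == expected

    def test_keeps_the_tail(self):
        s = _toy_structure(2)
        ens = TrajectoryEnsemble(atoms=s.atoms, frames=np.random.default_rng(2).normal(size=(100, 2, 3)))
        out = drop_equilibration(ens, 0.5)
        assert np.array_equal(out.frames, ens.frames[50:])

    def test_original_untouched_and_composition(self):
        s = _toy_structure(2)
        frames = np.random.default_rng(3).normal(size=(30, 2, 3))
        ens = TrajectoryEnsemble(atoms=s.atoms, frames=frames.copy())
        once = drop_equilibration(ens, 1.0 / 3.0)
        again = drop_equilibration(once, 0.0)
        assert np.array_equal(ens.frames, frames)
        assert np.array_equal(once.frames, again.frames)

    @pytest.mark.parametrize("fraction", [-0.1, 1.0, 1.5])
    def test_invalid_fraction(self, fraction):
        s = _toy_structure(2)
        ens = TrajectoryEnsemble(atoms=s.atoms, frames=np.zeros((5, 2, 3)))
        with pytest.raises(ValueError):
            drop_equilibration(ens, fraction)


class TestRdataConverter:
    """Validated against a synthetic RData cache written by Rscript."""

    def test_matrix_cache_converts(self, tmp_path):
        rdata = tmp_path / "synthetic_cache.RData"
        subprocess.run(
            ["Rscript", "--vanilla", "-e",
             f"m <- matrix(as.numeric(1:45), nrow=5); traj <- m; save(traj, file='{rdata}')"],
            check=True, capture_output=True,
        )
        out = convert_rdata(rdata, tmp_path / "conv")
        assert len(out) == 1
        ens = read_ensemble(out[0])
        assert ens.n_frames == 5 and ens.n_atoms == 3
        # R fills matrices column-major: frame 1 is row 1 = (1, 6, 11, ...)
        assert ens.frames[0, 0, 0] == pytest.approx(1.0)

    def test_layout_mismatch_fails_loudly(self, tmp_path):
        rdata = tmp_path / "bad.RData"
        subprocess.run(
            ["Rscript", "--vanilla", "-e", f"x <- 'not a trajectory'; save(x, file='{rdata}')"],
            check=True, capture_output=True,
        )
        with pytest.raises(RuntimeError, match="no numeric matrix"):
            convert_rdata(rdata, tmp_path / "conv2")
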