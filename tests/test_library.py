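"""Tiling libraries, deep positional scans, and PTM variant panels."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import abepitope as ab
from abepitope.library import ROLE_PTM, ROLE_SUBSTITUTION, ROLE_WILDTYPE


class TestTiling:
    def test_full_region_yields_sixty_15mers(self):
        lib = ab.tile_sequence(ab.ABETA_REGION, window=15, step=1, abeta_start=-23)
        assert len(lib) == 60
        assert all(len(p.peptide) == 15 for p in lib)

    def test_window_equal_length_is_identity(self):
        lib = ab.tile_sequence("DAEFRHDSGY", window=10)
        assert len(lib) == 1
        assert lib.probes[0].peptide.residues == "DAEFRHDSGY"

    def test_twenty_mer_gives_six_probes_overlapping_by_14(self):
        seq = ab.ABETA_REGION[:20]
        lib = ab.tile_sequence(seq, window=15, step=1)
        assert len(lib) == 6
        for a, b in zip(lib.probes, lib.probes[1:]):
            assert a.peptide.residues[1:] == b.peptide.residues[:-1]

    def test_window_larger_than_sequence_rejected(self):
        with pytest.raises(ValueError):
            ab.tile_sequence("DAEFR", window=6)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.text(alphabet=ab.AMINO_ACIDS, min_size=1, max_size=40),
        st.integers(min_value=1, max_value=40),
        st.integers(min_value=1, max_value=5),
    )
    def test_count_formula_and_reconstruction(self, seq, window, step):
        if window > len(seq):
            return
        lib = ab.tile_sequence(seq, window=window, step=step)
        assert len(lib) == (len(seq) - window) // step + 1
        if step == 1:
            # overlaying the tiles reproduces the input exactly
            rebuilt = lib.probes[0].peptide.residues + "".join(
                p.peptide.residues[-1] for p in lib.probes[1:]
            )
            assert rebuilt == seq

    def test_tiles_carry_abeta_coordinates(self):
        lib = ab.tile_sequence(ab.ABETA_REGION, window=15, step=1, abeta_start=-23)
        starts = [p.peptide.abeta_start for p in lib]
        assert starts[0] == -23
        assert starts[-1] == 37  # the last 15-mer covers Abeta 37..51


class TestPositionalScan:
    def test_18mer_yields_342_substitutions(self):
        lib = ab.positional_scan("DAEFRHDSGYEVHHQKLV")
        subs = [p for p in lib if p.role == ROLE_SUBSTITUTION]
        assert len(subs) == 342
        assert len(lib) == 343  # plus the wildtype reference

    def test_15mer_yields_285_substitutions(self):
        lib = ab.positional_scan("DAEFRHDSGYEVHHQ")
        assert sum(p.role == ROLE_SUBSTITUTION for p in lib) == 15 * 19

    def test_every_substitution_at_hamming_distance_one(self):
        wt = "DAEFRHDSGY"
        lib = ab.positional_scan(wt)
        for p in lib:
            if p.role != ROLE_SUBSTITUTION:
                continue
            diffs = [i for i, (a, b) in enumerate(zip(p.peptide.residues, wt)) if a != b]
            assert diffs == [p.wt_position - 1]
            assert p.peptide.residues[p.wt_position - 1] == p.substitution

    def test_scan_completeness_no_duplicates(self):
        wt = "DAEFR"
        lib = ab.positional_scan(wt)
        pairs = {
            (p.wt_position, p.substitution) for p in lib if p.role == ROLE_SUBSTITUTION
        }
        expected = {
            (pos, letter)
            for pos in range(1, 6)
            for letter in ab.AMINO_ACIDS
            if letter != wt[pos - 1]
        }
        assert pairs == expected

    def test_modified_wildtype_rejected(self):
        with pytest.raises(ab.PeptideError):
            ab.positional_scan(ab.parse_peptide("DAEFRHDS[p]GY"))

    def test_empty_alphabet_rejected(self):
        with pytest.raises(ValueError):
            ab.positional_scan("DAEFR", alphabet="")


class TestPtmPanel:
    def test_pe3_panel_pairs_with_unmodified_control(self):
        lib = ab.ptm_panel(3, 17, ["pE3"])
        control = lib.wildtype
        variants = [p for p in lib if p.role == ROLE_PTM]
        assert control is not None and len(variants) == 1
        assert variants[0].partner_id == control.probe_id
        assert variants[0].peptide.residues == control.peptide.residues
        assert variants[0].peptide.mods[0] == "pyroglutamate"

    def test_pser8_panel_exports_digit_2(self):
        lib = ab.ptm_panel(1, 15, ["pSer8"])
        variant = next(p for p in lib if p.role == ROLE_PTM)
        assert ab.to_array_digit(variant.peptide) == "DAEFRHD2GYEVHHQ"

    def test_asp1_isomer_and_stereoisomer_panel(self):
        lib = ab.ptm_panel(-1, 14, ["D-Asp1", "iso-Asp1"])
        tags = sorted(p.peptide.mods[1] for p in lib if p.role == ROLE_PTM)
        assert tags == ["d-stereo", "iso-aspartate"]
        # every variant shares the control's residue string
        control = lib.wildtype.peptide.residues
        assert all(p.peptide.residues == control for p in lib)

    def test_pe3_requires_span_starting_at_3(self):
        with pytest.raises(ab.PeptideError):
            ab.ptm_panel(1, 17, ["pE3"])

    def test_modification_outside_region_rejected(self):
        with pytest.raises(ab.PeptideError):
            ab.ptm_panel(1, 15, ["pSer26"])


class TestLibraryIO:
    def test_csv_round_trip(self, tmp_path, default_scan):
        path = tmp_path / "lib.csv"
        default_scan.to_csv(path)
        loaded = ab.ProbeLibrary.from_csv(path)
        assert len(loaded) == len(default_scan)
        for a, b in zip(loaded, default_scan):
            assert a.probe_id == b.probe_id
            assert a.peptide == b.peptide
            assert (a.role, a.wt_position, a.substitution) == (
                b.role,
                b.wt_position,
                b.substitution,
            )

    def test_duplicate_ids_rejected(self):
        p = ab.Probe("x", ab.ModifiedPeptide("DAEFR"), "tile")
        with pytest.raises(ValueError):
            ab.ProbeLibrary([p, p])
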