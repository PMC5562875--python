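import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from earlyfold.structmetrics import (
    Atom,
    ContactS2Params,
    DsspFormatError,
    StructureModel,
    benjamini_hochberg,
    bias_correct,
    compare_groups,
    contact_s2,
    parse_dssp,
    rsa,
    significance_stars,
    wilcoxon_ranksum,
)
from earlyfold.synthetic import generate_structure_fixture

DSSP_HEADER = """==== Secondary Structure Definition by the program DSSP ==== DATE=2024-01-01 .
REFERENCE W. KABSCH AND C.SANDER, BIOPOLYMERS 22 (1983) 2577-2637 .
HEADER    SYNTHETIC FIXTURE .
  3  1  0  0  0 TOTAL NUMBER OF RESIDUES .
  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N    N-H-->O    O-->H-N    TCO  KAPPA ALPHA  PHI   PSI    X-CA   Y-CA   Z-CA
"""


def _dssp_line(idx, resnum, chain, aa, acc):
    return (
        f"{idx:5d}{resnum:5d} {chain} {aa}  "
        f"            0   0{acc:5d}      0, 0.0     0, 0.0     0, 0.0     "
        f"0, 0.0   0.000 360.0 360.0 360.0 360.0    0.0    0.0    0.0"
    )


def _dssp_break_line(idx):
    # chain breaks leave the residue-number and chain fields blank
    return f"{idx:5d}        !              0   0    0"


class TestParseDssp:
    def test_residue_lines_parsed(self, tmp_path):
        f = tmp_path / "x.dssp"
        f.write_text(
            DSSP_HEADER
            + _dssp_line(1, 1, "A", "A", 106)
            + "\n"
            + _dssp_line(2, 2, "A", "G", 40)
            + "\n"
        )
        recs = parse_dssp(f)
        assert [(r.chain, r.residue_number, r.amino_acid, r.acc) for r in recs] == [
            ("A", 1, "A", 106.0),
            ("A", 2, "G", 40.0),
        ]

    def test_chain_break_skipped(self, tmp_path):
        f = tmp_path / "x.dssp"
        f.write_text(
            DSSP_HEADER
            + _dssp_line(1, 1, "A", "A", 10)
            + "\n"
            + _dssp_break_line(2)
            + "\n"
            + _dssp_line(3, 3, "A", "V", 20)
            + "\n"
        )
        recs = parse_dssp(f)
        assert [r.amino_acid for r in recs] == ["A", "V"]

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            parse_dssp(tmp_path / "nope.dssp")

    def test_malformed_header(self, tmp_path):
        f = tmp_path / "bad.dssp"
        f.write_text("this is not dssp output\n")
        with pytest.raises(DsspFormatError, match="header"):
            parse_dssp(f)


class TestRsa:
    def test_buried_residue(self):
        assert rsa(0.0, "ALA") == 0.0

    def test_fully_exposed_equals_one(self):
        assert rsa(106.0, "A", scale="Sander") == 1.0

    def test_sander_alanine_half_exposed(self):
        assert rsa(53.0, "ALA", scale="Sander") == 0.5

    def test_above_one_flagged_not_clipped(self):
        with pytest.warns(UserWarning, match="not clipped"):
            v = rsa(120.0, "ALA")
        assert v > 1.0

    def test_unknown_residue_named(self):
        with pytest.raises(KeyError, match="XYZ"):
            rsa(10.0, "XYZ")


def _bare_structure(extra_atoms=()):
    """Two residues giving the probe H and O, plus optional external atoms.

    Residue 2's amide proton sits at the origin; residue 1's carbonyl
    oxygen at (1, 0, 0).
    """
    atoms = [
        Atom("A", 1, "ALA", "N", "N", -3.0, 2.0, 0.0),
        Atom("A", 1, "ALA", "CA", "C", -2.0, 2.0, 0.0),
        Atom("A", 1, "ALA", "C", "C", -1.0, 2.0, 0.0),
        Atom("A", 1, "ALA", "O", "O", 1.0, 0.0, 0.0),
        Atom("A", 2, "ALA", "N", "N", 0.0, -1.0, 0.0),
        Atom("A", 2, "ALA", "CA", "C", 1.0, -2.0, 0.0),
        Atom("A", 2, "ALA", "C", "C", 2.0, -2.0, 0.0),
        Atom("A", 2, "ALA", "H", "H", 0.0, 0.0, 0.0),
    ]
    return StructureModel(tuple(atoms) + tuple(extra_atoms))


class TestContactS2:
    def test_empty_neighbourhood_equals_minus_c(self):
        params = ContactS2Params()
        assert contact_s2(_bare_structure(), "A", 2, params) == pytest.approx(
            -params.c
        )

    def test_single_atom_at_r0_matches_hand_evaluation(self):
        params = ContactS2Params()
        # equidistant (r0 = 1 A) from the H probe at origin and O at (1,0,0)
        ext = Atom("A", 3, "ALA", "CA", "C", 0.5, math.sqrt(0.75), 0.0)
        got = contact_s2(_bare_structure((ext,)), "A", 2, params)
        want = math.tanh(params.b * (params.w + 1.0) * math.exp(-1.0)) - params.c
        assert got == pytest.approx(want, abs=1e-12)

    def test_moving_an_atom_farther_never_increases_s2(self):
        params = ContactS2Params()
        vals = []
        for dist in (1.0, 2.0, 4.0, 8.0):
            ext = Atom("A", 3, "ALA", "CA", "C", 0.0, dist, 0.0)
            vals.append(contact_s2(_bare_structure((ext,)), "A", 2, params))
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_first_residue_is_undefined(self):
        assert math.isnan(contact_s2(_bare_structure(), "A", 1))

    def test_hydrogens_do_not_count_as_contacts(self):
        ext_h = Atom("A", 3, "ALA", "H", "H", 0.5, math.sqrt(0.75), 0.0)
        params = ContactS2Params()
        assert contact_s2(
            _bare_structure((ext_h,)), "A", 2, params
        ) == pytest.approx(-params.c)

    def test_bounded_above_by_one_minus_c(self):
        params = ContactS2Params()
        helix = generate_structure_fixture(12, "ideal_helix")
        for _, resnum in helix.residues("A")[1:]:
            assert contact_s2(helix, "A", resnum, params) <= 1.0 - params.c


class TestBiasCorrect:
    def test_hand_computed_example(self):
        out = bias_correct([1, 3, 2, 4], ["A", "A", "C", "C"])
        np.testing.assert_allclose(out, [1.5, 3.5, 1.5, 3.5])

    def test_single_type_is_identity(self, rng):
        v = rng.normal(size=11)
        np.testing.assert_allclose(bias_correct(v, ["G"] * 11), v)

    def test_per_type_medians_equalized(self, rng):
        v = rng.normal(size=200) + np.repeat([0, 1, 5, -2], 50)
        aa = np.repeat(list("AVLG"), 50)
        out = bias_correct(v, aa)
        global_median = np.median(v)
        for t in "AVLG":
            assert np.median(out[aa == t]) == pytest.approx(global_median)

    def test_idempotent(self, rng):
        v = rng.normal(size=60)
        aa = rng.choice(list("AVLG"), 60)
        once = bias_correct(v, aa)
        np.testing.assert_allclose(bias_correct(once, aa), once)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            bias_correct([], [])


class TestWilcoxon:
    def test_exact_small_sample(self):
        assert wilcoxon_ranksum([1, 2], [3, 4]) == pytest.approx(1 / 3)

    def test_identical_samples(self):
        assert wilcoxon_ranksum([1, 2, 3], [1, 2, 3]) == 1.0

    def test_symmetric_in_arguments(self, rng):
        x, y = rng.normal(size=15), rng.normal(1, 1, size=12)
        assert wilcoxon_ranksum(x, y) == pytest.approx(wilcoxon_ranksum(y, x))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            wilcoxon_ranksum([], [1.0])


class TestBenjaminiHochberg:
    def test_hand_computed_stepup(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.04, 0.03]), [0.03, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(benjamini_hochberg([0.2]), [0.2])

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.05] * 4), [0.05] * 4
        )

    def test_adjusted_at_least_raw(self, rng):
        p = rng.random(30)
        assert (benjamini_hochberg(p) >= p - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.2])

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40)
    )
    @settings(derandomize=True, deadline=None)
    def test_stepup_properties(self, pvals):
        adj = benjamini_hochberg(pvals)
        assert (adj <= 1.0).all()
        assert (adj >= np.asarray(pvals) - 1e-12).all()
        # step-up adjustment preserves the ordering of the raw p-values
        order = np.argsort(pvals, kind="stable")
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestCompareGroups:
    def test_identical_groups_not_significant(self, rng):
        v = rng.normal(size=50)
        rep = compare_groups({"a": v, "b": v.copy()})
        assert rep.pairs[0].pvalue_adjusted == 1.0
        assert rep.pairs[0].stars == ""

    def test_well_separated_groups_highly_significant(self, rng):
        rep = compare_groups(
            {"lo": rng.normal(0, 1, 50), "hi": rng.normal(3, 1, 50)}
        )
        assert rep.pairs[0].stars == "***"

    def test_star_thresholds(self):
        assert significance_stars(0.0009) == "***"
        assert significance_stars(0.001) == "**"
        assert significance_stars(0.01) == "*"
        assert significance_stars(0.05) == ""

    def test_bias_correction_removes_composition_shift(self, rng):
        # group difference driven purely by amino-acid composition
        vals_a = np.concatenate([rng.normal(0, 0.1, 40), rng.normal(5, 0.1, 10)])
        aa_a = ["G"] * 40 + ["V"] * 10
        vals_b = np.concatenate([rng.normal(0, 0.1, 10), rng.normal(5, 0.1, 40)])
        aa_b = ["G"] * 10 + ["V"] * 40
        raw = compare_groups({"a": vals_a, "b": vals_b})
        corrected = compare_groups(
            {"a": vals_a, "b": vals_b},
            amino_acids_by_group={"a": aa_a, "b": aa_b},
            bias_correct_flag=True,
        )
        assert raw.pairs[0].pvalue < 0.001
        assert corrected.pairs[0].pvalue > raw.pairs[0].pvalue

    def test_summaries_expose_notch(self, rng):
        rep = compare_groups({"a": rng.normal(size=30), "b": rng.normal(size=30)})
        s = rep.summaries[0]
        assert s.n == 30
        assert s.notch == pytest.approx(1.57 * (s.q3 - s.q1) / math.sqrt(30))

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            compare_groups({"a": [1.0, 2.0]})
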