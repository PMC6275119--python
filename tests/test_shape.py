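"""Pentamer shape model: profiles, the 88-feature vector, and invariants.

The brute-force oracle below enumerates pentamer placements independently
of the implementation: each pentamer centered at c contributes its MGW/ProT
to position c and its left/right step values to steps c-1 and c; step
contributions are averaged, and base-pair-level Roll/HelT at position i is
the mean of the defined steps i-1 and i.
"""

import math

import numpy as np
import pytest

from promshape import shape_feature_vector, shape_profiles
from promshape.errors import CompletenessError, ContractError, ParseError
from promshape.shape import (
    PentamerTable,
    all_pentamers,
    load_pentamer_table,
    shape_feature_names,
    write_pentamer_table,
)
from promshape._seq import revcomp
from promshape.synth import make_pentamer_table

from conftest import random_table


def brute_force_profiles(seq: str, table: PentamerTable):
    """Independent enumeration of pentamer contributions."""
    L = len(seq)
    mgw = [math.nan] * L
    prot = [math.nan] * L
    step_roll: list[list[float]] = [[] for _ in range(L - 1)]
    step_helt: list[list[float]] = [[] for _ in range(L - 1)]
    for c in range(3, L - 1):  # 1-based pentamer centers 3..L-2
        e = table[seq[c - 3 : c + 2]]
        mgw[c - 1] = e.mgw
        prot[c - 1] = e.prot
        step_roll[c - 2].append(e.roll_left)  # step c-1
        step_roll[c - 1].append(e.roll_right)  # step c
        step_helt[c - 2].append(e.helt_left)
        step_helt[c - 1].append(e.helt_right)
    roll_steps = [sum(v) / len(v) if v else math.nan for v in step_roll]
    helt_steps = [sum(v) / len(v) if v else math.nan for v in step_helt]
    roll = [math.nan] * L
    helt = [math.nan] * L
    for i in range(2, L):  # 1-based positions 2..L-1
        rs = [roll_steps[k - 1] for k in (i - 1, i) if not math.isnan(roll_steps[k - 1])]
        hs = [helt_steps[k - 1] for k in (i - 1, i) if not math.isnan(helt_steps[k - 1])]
        if rs:
            roll[i - 1] = sum(rs) / len(rs)
            helt[i - 1] = sum(hs) / len(hs)
    return mgw, prot, roll, helt, roll_steps, helt_steps


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestTableIO:
    def test_load_complete_table(self, tmp_path):
        table = make_pentamer_table(seed=3)
        path = tmp_path / "p.tsv"
        write_pentamer_table(table, path)
        loaded = load_pentamer_table(path, symmetric=True)
        np.testing.assert_allclose(loaded.values, table.values, rtol=0, atol=0)

    def test_missing_pentamer_errors(self, tmp_path):
        table = make_pentamer_table(seed=3)
        path = tmp_path / "p.tsv"
        write_pentamer_table(table, path)
        lines = path.read_text().splitlines()
        path.write_text("\n".join(lines[:-1]) + "\n")  # drop one pentamer
        with pytest.raises(CompletenessError, match="1"):
            load_pentamer_table(path)

    def test_non_numeric_errors(self, tmp_path):
        table = make_pentamer_table(seed=3)
        path = tmp_path / "p.tsv"
        write_pentamer_table(table, path)
        # corrupt the first data value of the first data line
        lines = path.read_text().splitlines()
        parts = lines[1].split("\t")
        parts[1] = "oops"
        lines[1] = "\t".join(parts)
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ParseError, match="line 2"):
            load_pentamer_table(path)

    def test_duplicate_last_wins(self, tmp_path):
        table = make_pentamer_table(seed=3)
        path = tmp_path / "p.tsv"
        write_pentamer_table(table, path)
        with open(path, "a") as fh:
            fh.write("AAAAA\t1\t2\t3\t4\t5\t6\n")
        loaded = load_pentamer_table(path)
        assert loaded["AAAAA"].mgw == 1.0

    def test_constant_table_lookup(self, const_table):
        assert const_table["ACGTA"].roll_left == 5.0


class TestProfiles:
    def test_constant_table_propagates(self, const_table):
        prof = shape_profiles("ACGTACGTAC", const_table)
        for param in ("MGW", "ProT", "Roll", "HelT"):
            vals = prof.values(param)
            defined = vals[~np.isnan(vals)]
            assert len(defined) > 0
            np.testing.assert_allclose(defined, 5.0)

    def test_length5_single_contributions(self):
        rng = np.random.default_rng(11)
        table = random_table(rng)
        seq = "ACGTT"
        prof = shape_profiles(seq, table)
        e = table[seq]
        # exactly one MGW value, at position 3
        assert np.isnan(prof.mgw).sum() == 4
        assert prof.mgw[2] == e.mgw
        # steps 2 and 3 each come from the single centered pentamer
        assert prof.roll_steps[1] == e.roll_left
        assert prof.roll_steps[2] == e.roll_right
        assert prof.helt_steps[1] == e.helt_left
        assert prof.helt_steps[2] == e.helt_right

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            table = random_table(rng)
            seq = _random_seq(rng, int(rng.integers(5, 30)))
            prof = shape_profiles(seq, table)
            mgw, prot, roll, helt, rsteps, hsteps = brute_force_profiles(seq, table)
            np.testing.assert_allclose(prof.mgw, mgw, atol=1e-12)
            np.testing.assert_allclose(prof.prot, prot, atol=1e-12)
            np.testing.assert_allclose(prof.roll, roll, atol=1e-12)
            np.testing.assert_allclose(prof.helt, helt, atol=1e-12)
            np.testing.assert_allclose(prof.roll_steps, rsteps, atol=1e-12)
            np.testing.assert_allclose(prof.helt_steps, hsteps, atol=1e-12)

    def test_revcomp_symmetry(self):
        """Symmetric table: profiles of the reverse complement are reversed."""
        table = make_pentamer_table(seed=5, symmetric=True)
        rng = np.random.default_rng(6)
        for _ in range(10):
            seq = _random_seq(rng, 15)
            fwd = shape_profiles(seq, table)
            rev = shape_profiles(revcomp(seq), table)
            np.testing.assert_allclose(rev.mgw, fwd.mgw[::-1], atol=1e-12)
            np.testing.assert_allclose(rev.prot, fwd.prot[::-1], atol=1e-12)
            np.testing.assert_allclose(rev.roll, fwd.roll[::-1], atol=1e-12)
            np.testing.assert_allclose(rev.helt, fwd.helt[::-1], atol=1e-12)
            np.testing.assert_allclose(rev.roll_steps, fwd.roll_steps[::-1], atol=1e-12)

    def test_rejects_n_and_short(self, const_table):
        with pytest.raises(ContractError):
            shape_profiles("ACGN A".replace(" ", ""), const_table)
        with pytest.raises(ContractError):
            shape_profiles("ACGT", const_table)


class TestFeatureVector:
    def test_names_and_length(self):
        names = shape_feature_names()
        assert len(names) == 88
        assert len(set(names)) == 88
        assert names[0] == "shape_MGW_mut_-5"
        assert names[11] == "shape_MGW_diff_-5"

    def test_constant_table_vector(self, const_table):
        ref = "AAAAAAACAAAAAAA"
        mut = ref[:7] + "G" + ref[8:]
        vec = shape_feature_vector(ref, mut, const_table)
        assert vec.shape == (88,)
        for p in range(4):
            np.testing.assert_allclose(vec[22 * p : 22 * p + 11], 5.0)
            np.testing.assert_allclose(vec[22 * p + 11 : 22 * p + 22], 0.0)

    def test_diff_support_is_local(self):
        """Substituting the center only perturbs positions whose pentamers
        cover it: MGW/ProT diffs vanish outside offsets -2..+2, base-pair
        Roll/HelT diffs outside -3..+3."""
        rng = np.random.default_rng(77)
        names = shape_feature_names()
        for _ in range(20):
            table = random_table(rng)
            ref = _random_seq(rng, 15)
            alt = rng.choice([b for b in "ACGT" if b != ref[7]])
            mut = ref[:7] + alt + ref[8:]
            vec = shape_feature_vector(ref, mut, table)
            for name, value in zip(names, vec):
                if "_diff_" not in name:
                    continue
                param, off = name.split("_")[1], int(name.rsplit("_", 1)[1])
                reach = 2 if param in ("MGW", "ProT") else 3
                if abs(off) > reach:
                    assert value == 0.0, name

    def test_center_blind_table_zeroes_offset0_diffs(self):
        """A table whose values ignore the pentamer's central base leaves the
        MGW/ProT diff at offset 0 exactly 0 (that pentamer is blind to the
        substitution), while off-center pentamers may still move."""
        values = np.zeros((1024, 6))
        for i, pent in enumerate(all_pentamers()):
            code = sum("ACGT".index(c) * 4**k for k, c in enumerate(pent[:2] + pent[3:]))
            values[i] = code / 10.0
        table = PentamerTable(values)
        rng = np.random.default_rng(13)
        names = shape_feature_names()
        for _ in range(10):
            ref = _random_seq(rng, 15)
            alt = rng.choice([b for b in "ACGT" if b != ref[7]])
            mut = ref[:7] + alt + ref[8:]
            vec = dict(zip(names, shape_feature_vector(ref, mut, table)))
            assert vec["shape_MGW_diff_+0"] == 0.0
            assert vec["shape_ProT_diff_+0"] == 0.0

    def test_contract_errors(self, const_table):
        with pytest.raises(ContractError):
            shape_feature_vector("ACGTACG", "ACGTACG", const_table)
        ref = "AAAAAAACAAAAAAA"
        with pytest.raises(ContractError):
            shape_feature_vector(ref, ref, const_table)
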