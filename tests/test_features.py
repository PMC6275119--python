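"""Feature groups: exact dimensionalities, arithmetic, and oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from promshape import (
    AnnotationLayout,
    AnnotationTrack,
    ExtractionConfig,
    FeatureSchema,
    Pwm,
    VariantRecord,
    ZScoreModel,
    annotation_features,
    build_matrix,
    conservation_features,
    dinucleotide_features,
    encode_sequence,
    gc_features,
    tf_motif_features,
)
from promshape.errors import ConfigurationError, ContractError
from promshape.features import GROUP_ORDER, GROUP_SIZES, best_logodds, group_feature_names
from promshape.variants import SequenceWindow, fetch_window, substitute_center
from promshape._seq import revcomp

NINE_MERS = st.text(alphabet="ACGT", min_size=9, max_size=9)


class TestSchema:
    # every size printed in the performance table, as group unions
    TABLE_UNIONS = [
        (GROUP_ORDER, 227),
        (("sequence",), 52),
        (("gc",), 8),
        (("shape",), 88),
        (("conservation",), 10),
        (("tfbs",), 12),
        (("histone",), 38),
        (("dnase",), 1),
        (("dinucleotide",), 16),
        (("tf_maxscore", "tf_disruption"), 2),
        (("sequence", "gc"), 60),
        (("shape", "gc"), 96),
        (("sequence", "gc", "shape"), 148),
        (("sequence", "gc", "shape", "tf_disruption"), 149),
        (("sequence", "gc", "shape", "tf_disruption", "tf_maxscore"), 150),
        (("sequence", "gc", "tfbs"), 72),
        (("sequence", "gc", "histone"), 98),
    ]

    @pytest.mark.parametrize("groups,expected", TABLE_UNIONS)
    def test_union_sizes(self, groups, expected):
        assert len(FeatureSchema.canonical(groups)) == expected

    def test_group_sizes_constant(self):
        assert sum(GROUP_SIZES.values()) == 227
        for g in GROUP_ORDER:
            assert len(group_feature_names(g)) == GROUP_SIZES[g]

    def test_unknown_or_empty_groups(self):
        with pytest.raises(ConfigurationError):
            FeatureSchema.canonical(("nonsense",))
        with pytest.raises(ConfigurationError):
            FeatureSchema.canonical(())

    def test_roundtrip_tsv(self, tmp_path):
        schema = FeatureSchema.canonical(("gc", "shape"))
        schema.to_tsv(tmp_path / "s.tsv")
        assert FeatureSchema.from_tsv(tmp_path / "s.tsv") == schema


class TestEncodeSequence:
    def test_counts_and_indicators(self):
        vec = encode_sequence("AAAACAAAA", "G")
        assert vec.shape == (52,)
        assert vec[:36].sum() == 9  # one bit per position
        assert vec[36:40].sum() == 1  # alt one-hot
        assert vec[40:].sum() == 1  # exactly one mutation-type bit
        names = group_feature_names("sequence")
        assert names[40 + 4] == "seq_mut_CtoG"
        assert vec[40 + 4] == 1.0  # C->G is the 5th ordered pair
        assert vec[40:].tolist().count(1.0) == 1

    @settings(max_examples=100, deadline=None)
    @given(NINE_MERS, st.sampled_from("ACGT"), NINE_MERS, st.sampled_from("ACGT"))
    def test_injective(self, r1, a1, r2, a2):
        if a1 == r1[4] or a2 == r2[4]:
            return
        v1, v2 = encode_sequence(r1, a1), encode_sequence(r2, a2)
        if (r1, a1) != (r2, a2):
            assert not np.array_equal(v1, v2)
        else:
            assert np.array_equal(v1, v2)

    def test_contract(self):
        with pytest.raises(ContractError):
            encode_sequence("AAAA", "G")
        with pytest.raises(ContractError):
            encode_sequence("AAAACAAAA", "C")


class TestGcFeatures:
    def test_at_only_reference(self):
        ref = "ATATATATA"
        mut = "ATATGTATA"  # center A->G
        vec = gc_features(ref, mut)
        assert vec[0] == 0.0  # gc_ref7
        assert vec[4] == 0.0  # gc_ref9

    def test_single_substitution_arithmetic(self):
        ref = "ATATATATA"
        mut = ref[:4] + "G" + ref[5:]
        vec = gc_features(ref, mut)
        assert vec[2] == pytest.approx(1 / 7)  # diff7
        assert vec[6] == pytest.approx(1 / 9)  # diff9
        assert len(vec) == 8

    @settings(max_examples=50, deadline=None)
    @given(NINE_MERS, st.sampled_from("ACGT"))
    def test_antisymmetry(self, ref, alt):
        if alt == ref[4]:
            return
        mut = ref[:4] + alt + ref[5:]
        fwd = gc_features(ref, mut)
        rev = gc_features(mut, ref)
        for k in (2, 6):  # diff features flip sign
            assert fwd[k] == pytest.approx(-rev[k])
        for k in (3, 7):  # absdiff invariant
            assert fwd[k] == pytest.approx(rev[k])


class TestDinucleotide:
    def test_homopolymer(self):
        vec = dinucleotide_features("AAAAAAAAA")
        np.testing.assert_allclose(vec, 0.0, atol=1e-12)

    def test_alternating_ac(self):
        vec = dinucleotide_features("ACACACACA")
        names = group_feature_names("dinucleotide")
        v = dict(zip(names, vec))
        assert v["dinuc_AC"] == pytest.approx(0.5 - 20 / 81)
        assert v["dinuc_CA"] == pytest.approx(0.5 - 20 / 81)

    @settings(max_examples=50, deadline=None)
    @given(NINE_MERS)
    def test_sums_to_zero(self, nine):
        assert dinucleotide_features(nine).sum() == pytest.approx(0.0, abs=1e-12)


def _tracks_with(layout, overlapping_ids, chrom="chr1", lo=0, hi=1000):
    tracks = {}
    for tid in layout.binary_track_ids():
        ivs = [(chrom, lo, hi, 1.0)] if tid in overlapping_ids else []
        tracks[tid] = AnnotationTrack(tid, ivs)
    return tracks


class TestAnnotationFeatures:
    layout = AnnotationLayout()
    v = VariantRecord("chr1", 500, "A", "G")

    def test_no_overlap_all_zero(self):
        feats = annotation_features(self.v, _tracks_with(self.layout, set()), self.layout)
        assert feats.shape == (51,)
        np.testing.assert_allclose(feats, 0.0)

    def test_saturation(self):
        tracks = _tracks_with(self.layout, set(self.layout.binary_track_ids()))
        feats = annotation_features(self.v, tracks, self.layout)
        np.testing.assert_allclose(feats, 1.0)

    def test_partial_counts(self):
        # H3K9ac in 4 of 16 cell lines, nothing else
        ids = {
            self.layout.histone_track_id("H3K9ac", c)
            for c in self.layout.cell_lines[:4]
        }
        feats = annotation_features(self.v, _tracks_with(self.layout, ids), self.layout)
        names = group_feature_names("histone") + group_feature_names("tfbs") + ["dnase"]
        v = dict(zip(names, feats))
        assert v["hist_mean_H3K9ac"] == pytest.approx(0.25)
        assert v["hist_any_H3K9ac"] == 1.0
        assert v["hist_mean_H3K4me3"] == 0.0
        assert v["hist_mean_either"] == pytest.approx(0.25)
        assert v["tfbs_mean"] == 0.0

    def test_missing_track_listed(self):
        tracks = _tracks_with(self.layout, set())
        del tracks["DNase"]
        with pytest.raises(ConfigurationError, match="DNase"):
            annotation_features(self.v, tracks, self.layout)


class TestConservation:
    def test_z_matches_enumeration_oracle(self):
        """Analytic mean/variance of the per-base log-likelihood agree with
        exhaustive enumeration over all sequences at w=7."""
        q = (0.4, 0.1, 0.1, 0.4)
        model = ZScoreModel(q)
        logq = np.log(q)
        # enumeration over all 4^7 windows of the total log-likelihood
        totals, probs = [], []
        for tup in itertools.product(range(4), repeat=7):
            totals.append(sum(logq[i] for i in tup))
            probs.append(math.prod(q[i] for i in tup))
        totals, probs = np.array(totals), np.array(probs)
        mean = float((totals * probs).sum())
        var = float((totals**2 * probs).sum() - mean**2)
        assert mean == pytest.approx(7 * model.mu1, rel=1e-12)
        assert var == pytest.approx(7 * model.sigma1_sq, rel=1e-12)
        # and the z of an all-A window is the closed form
        z = model.z("AAAAAAA")
        expected = (7 * math.log(0.4) - 7 * model.mu1) / math.sqrt(7 * model.sigma1_sq)
        assert z == pytest.approx(expected, rel=1e-12)

    def test_uniform_background_degenerate(self):
        model = ZScoreModel((0.25, 0.25, 0.25, 0.25))
        with pytest.raises(ConfigurationError):
            model.z("AAAAAAA")

    def test_vector_layout(self):
        genome = {"chr1": "ATGCATGCATGCATGCATGCATGC"}
        ref = fetch_window(genome, "chr1", 12, 7)
        mut = substitute_center(ref, "A" if ref.center != "A" else "C")
        gerp = AnnotationTrack("GERP", [("chr1", 0, 24, 2.0)], kind="scored")
        pc = AnnotationTrack("PhastCons", [("chr1", 0, 24, 0.5)], kind="scored")
        model = ZScoreModel((0.4, 0.1, 0.1, 0.4))
        v = VariantRecord("chr1", 12, ref.center, mut.center)
        feats = conservation_features(v, gerp, pc, model, ref, mut)
        assert feats.shape == (10,)
        assert feats[0] == 2.0 and feats[1] == pytest.approx(2.0)
        assert feats[2] == 0.5
        # diffs are mut - ref
        assert feats[6] == pytest.approx(feats[5] - feats[4])
        assert feats[9] == pytest.approx(feats[8] - feats[7])


class TestTfMotifFeatures:
    background = (0.25, 0.25, 0.25, 0.25)

    def test_null_motif(self):
        pwm = Pwm("flat", tuple((0.25, 0.25, 0.25, 0.25) for _ in range(4)))
        ref = "AACGTACGTACGTAA"
        mut = ref[:7] + ("A" if ref[7] != "A" else "C") + ref[8:]
        pval, maxscore = tf_motif_features(ref, mut, [pwm], self.background, n_null=19, seed=0)
        assert maxscore == pytest.approx(0.0, abs=1e-12)
        assert pval == pytest.approx(1.0)

    def test_disruptive_mutation(self):
        # PWM matching the ref center 5-mer; the observed alt is the single
        # most disruptive alternative, so few null substitutions reach
        # delta_obs and the p-value is small
        ref = "AAAAACGTACAAAAA"
        center5 = ref[5:10]
        rows = []
        for i, c in enumerate(center5):
            p = [0.1, 0.1, 0.1, 0.1]
            p["ACGT".index(c)] = 0.7
            if i == 2:  # motif position of the SNV (window center, ref T)
                p = [0.005, 0.1475, 0.1475, 0.7]  # alt A is the worst outcome
            rows.append(tuple(p))
        pwm = Pwm("match", tuple(rows))
        mut = ref[:7] + "A" + ref[8:]  # T -> A at the motif's core
        pval, maxscore = tf_motif_features(ref, mut, [pwm], self.background, n_null=50, seed=1)
        assert maxscore > 0
        assert pval <= 0.5

    def test_strand_symmetry(self):
        rng = np.random.default_rng(3)
        rows = tuple(tuple(p) for p in rng.dirichlet(np.ones(4), size=6))
        pwm = Pwm("x", rows)
        rc_pwm = Pwm("xrc", tuple(tuple(r[::-1]) for r in rows[::-1]))
        win = "ACGTACGTACGTACG"
        assert best_logodds(win, pwm, self.background) == pytest.approx(
            best_logodds(revcomp(win), pwm, self.background)
        )
        assert best_logodds(win, pwm, self.background) == pytest.approx(
            best_logodds(win, rc_pwm, self.background)
        )

    def test_empty_pwms(self):
        with pytest.raises(ConfigurationError):
            tf_motif_features("A" * 15, "C" + "A" * 14, [], self.background)


class TestBuildMatrix:
    def test_column_counts_on_bundle(self, small_bundle):
        for groups, expected in [
            (("sequence", "gc", "shape"), 148),
            (("shape", "gc"), 96),
        ]:
            m = build_matrix(
                small_bundle.variants,
                small_bundle.genome,
                small_bundle.pentamers,
                small_bundle.tracks,
                ExtractionConfig(groups=groups),
            )
            assert m.data.shape == (len(small_bundle.variants), expected)
            assert np.isfinite(m.values()).all()

    def test_all_groups_finite(self, small_bundle):
        config = ExtractionConfig(
            groups=GROUP_ORDER,
            layout=small_bundle.layout,
            zmodel=small_bundle.zmodel,
            pwms=small_bundle.pwms,
            background=small_bundle.background,
            n_null=10,
        )
        m = build_matrix(
            small_bundle.variants[:30],
            small_bundle.genome,
            small_bundle.pentamers,
            small_bundle.tracks,
            config,
        )
        assert m.data.shape == (30, 227)
        assert np.isfinite(m.values()).all()

    def test_mismatched_ref_excluded(self, small_bundle):
        v = small_bundle.variants[0]
        wrong_ref = next(b for b in "ACGT" if b not in (v.ref, v.alt))
        bad = VariantRecord(v.chrom, v.pos, wrong_ref, v.alt)
        m = build_matrix(
            [v, bad],
            small_bundle.genome,
            small_bundle.pentamers,
            small_bundle.tracks,
            ExtractionConfig(groups=("gc",)),
        )
        assert list(m.data.index) == [v.key]

    def test_no_groups_configuration_error(self):
        with pytest.raises(ConfigurationError):
            ExtractionConfig(groups=())
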