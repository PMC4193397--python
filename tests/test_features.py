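import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aggprop import features
from aggprop.core_io import AMINO_ACIDS, ProteinRecord
from aggprop.features import (
    CTD_GROUPINGS,
    FeatureSpec,
    aa_composition,
    autocorrelation,
    charge_distribution,
    ctd_composition,
    ctd_distribution,
    ctd_transition,
    default_spec,
    extract,
    foldindex_features,
    foldindex_profile,
    gapped_pair_composition,
    pseaac,
    quasi_sequence_order,
)
from aggprop.scales import (
    AA_INDEX,
    get_scale,
    load_scales,
    physicochemical_distance_matrix,
)

peptides = st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=120)


# --------------------------------------------------------------------------
# independent naive oracles
# --------------------------------------------------------------------------


def naive_gapped_pair(seq, a, b, gap):
    hits = 0
    windows = 0
    for i in range(len(seq)):
        j = i + gap + 1
        if j < len(seq):
            windows += 1
            if seq[i] == a and seq[j] == b:
                hits += 1
    return hits / windows if windows else 0.0


def naive_autocorrelation(seq, kind, scale_name, lag):
    table = get_scale(scale_name).standardized
    vals = [table[AA_INDEX[c]] for c in seq]
    L = len(vals)
    if L <= lag:
        return 0.0
    if kind == "MoreauBroto":
        return sum(vals[i] * vals[i + lag] for i in range(L - lag)) / (L - lag)
    mean = sum(vals) / L
    if kind == "Moran":
        den = sum((v - mean) ** 2 for v in vals) / L
        if den == 0:
            return 0.0
        num = sum(
            (vals[i] - mean) * (vals[i + lag] - mean) for i in range(L - lag)
        ) / (L - lag)
        return num / den
    den = sum((v - mean) ** 2 for v in vals) / (L - 1)
    if den == 0:
        return 0.0
    num = sum((vals[i] - vals[i + lag]) ** 2 for i in range(L - lag)) / (2 * (L - lag))
    return num / den


def naive_pseaac(seq, lam, w):
    props = [get_scale(n).standardized for n in features.PSEAAC_PROPERTIES]
    thetas = []
    for d in range(1, lam + 1):
        acc = 0.0
        for i in range(len(seq) - d):
            a, b = AA_INDEX[seq[i]], AA_INDEX[seq[i + d]]
            acc += sum((p[a] - p[b]) ** 2 for p in props) / len(props)
        thetas.append(acc / (len(seq) - d))
    freqs = [seq.count(aa) / len(seq) for aa in AMINO_ACIDS]
    denom = 1.0 + w * sum(thetas)
    return [f / denom for f in freqs] + [w * t / denom for t in thetas]


def naive_qso(seq, maxlag, w):
    dmat = physicochemical_distance_matrix()
    taus = []
    for d in range(1, maxlag + 1):
        taus.append(
            sum(
                dmat[AA_INDEX[seq[i]], AA_INDEX[seq[i + d]]] ** 2
                for i in range(len(seq) - d)
            )
        )
    freqs = [seq.count(aa) / len(seq) for aa in AMINO_ACIDS]
    denom = 1.0 + w * sum(taus)
    return [f / denom for f in freqs] + [w * t / denom for t in taus]


def naive_ctd_distribution(seq, grouping, group, point):
    members = CTD_GROUPINGS[grouping][group - 1]
    positions = [i + 1 for i, c in enumerate(seq) if c in members]
    if not positions:
        return 0.0
    if point == "first":
        k = 1
    else:
        q = int(point.rstrip("%")) / 100
        k = max(1, math.ceil(q * len(positions)))
    return positions[k - 1] / len(seq) * 100


def naive_fold_segments(flags):
    """Run-length-encoding oracle for folded-segment statistics."""
    runs = []
    i = 0
    while i < len(flags):
        if flags[i]:
            j = i
            while j < len(flags) and flags[j]:
                j += 1
            runs.append(j - i)
            i = j
        else:
            i += 1
    return runs


# --------------------------------------------------------------------------
# scale data
# --------------------------------------------------------------------------


class TestScales:
    def test_all_scales_cover_20_residues(self):
        scales = load_scales()
        assert set(scales) == {
            "hydrophobicity",
            "hydrophilicity",
            "mutability",
            "volume",
            "polarizability",
            "steric",
            "free_energy",
            "asa_tripeptide",
        }
        for s in scales.values():
            assert len(s.raw) == 20
            assert abs(s.standardized.mean()) < 1e-12
            assert abs(s.standardized.std() - 1.0) < 1e-12

    def test_distance_matrix_symmetric_zero_diag(self):
        d = physicochemical_distance_matrix()
        assert d.shape == (20, 20)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert (d[~np.eye(20, dtype=bool)] > 0).all()


# --------------------------------------------------------------------------
# per-family contracts
# --------------------------------------------------------------------------


class TestComposition:
    def test_homopolymer(self):
        comp = aa_composition("TTT")
        assert comp[AA_INDEX["T"]] == 1.0
        assert comp.sum() == 1.0

    def test_ac(self):
        comp = aa_composition("AC")
        assert comp[AA_INDEX["A"]] == 0.5
        assert comp[AA_INDEX["C"]] == 0.5

    def test_random_sums_to_one(self, make_peptide):
        assert abs(aa_composition(make_peptide(200)).sum() - 1.0) < 1e-12

    def test_empty_error(self):
        with pytest.raises(ValueError):
            aa_composition("")

    @given(peptides)
    @settings(max_examples=50, deadline=None)
    def test_property_sums_to_one(self, seq):
        assert abs(aa_composition(seq).sum() - 1.0) < 1e-12


class TestGappedPair:
    def test_single_window_hit(self):
        assert gapped_pair_composition("HAAAAAAAAM", "H", "M", 8) == 1.0

    def test_short_sequence_convention(self):
        assert gapped_pair_composition("MMMM", "H", "M", 8) == 0.0

    def test_against_oracle(self, make_peptide):
        for _ in range(20):
            seq = make_peptide(50)
            for gap in (0, 3, 8):
                got = gapped_pair_composition(seq, "A", "L", gap)
                assert got == pytest.approx(naive_gapped_pair(seq, "A", "L", gap), abs=1e-12)


class TestPseaac:
    def test_homopolymer_lam0(self):
        vec = pseaac("DDDDDD", lam=0)
        assert vec[AA_INDEX["D"]] == 1.0

    def test_homopolymer_thetas_zero(self):
        vec = pseaac("DDDDD", lam=3)
        assert np.allclose(vec[20:], 0.0)
        assert np.allclose(vec[:20], aa_composition("DDDDD"))

    def test_hand_computed(self):
        seq, lam, w = "ACDEFG", 2, 0.05
        got = pseaac(seq, lam=lam, w=w)
        expected = naive_pseaac(seq, lam, w)
        assert np.allclose(got, expected, atol=1e-12)

    def test_sums_to_one_nonnegative(self, make_peptide):
        vec = pseaac(make_peptide(100), lam=30)
        assert vec.sum() == pytest.approx(1.0, abs=1e-12)
        assert (vec >= 0).all()

    def test_lam_too_large_error(self):
        with pytest.raises(ValueError):
            pseaac("ACDE", lam=4)


class TestAutocorrelation:
    def test_homopolymer_moreau_broto_is_z_squared(self):
        z = get_scale("hydrophobicity").standardized[AA_INDEX["W"]]
        got = autocorrelation("W" * 40, "MoreauBroto", "hydrophobicity", 1)
        assert got == pytest.approx(z * z, abs=1e-12)

    def test_homopolymer_moran_zero(self):
        assert autocorrelation("W" * 40, "Moran", "volume", 5) == 0.0

    def test_homopolymer_geary_zero(self):
        assert autocorrelation("W" * 40, "Geary", "volume", 5) == 0.0

    def test_short_sequence_zero(self):
        assert autocorrelation("ACD", "MoreauBroto", "volume", 5) == 0.0

    @pytest.mark.parametrize("kind", ["MoreauBroto", "Moran", "Geary"])
    @pytest.mark.parametrize("lag", [1, 6, 27])
    def test_against_oracle(self, make_peptide, kind, lag):
        for _ in range(5):
            seq = make_peptide(30 + lag)
            got = autocorrelation(seq, kind, "hydrophobicity", lag)
            assert got == pytest.approx(
                naive_autocorrelation(seq, kind, "hydrophobicity", lag), abs=1e-9
            )

    def test_moreau_broto_reversal_invariance(self, make_peptide):
        seq = make_peptide(80)
        for lag in (1, 12, 30):
            a = autocorrelation(seq, "MoreauBroto", "volume", lag)
            b = autocorrelation(seq[::-1], "MoreauBroto", "volume", lag)
            assert a == pytest.approx(b, abs=1e-12)


class TestCtd:
    def test_all_group2_composition_and_distribution(self):
        seq = "CPNV" * 5  # all polarizability group 2
        assert ctd_composition(seq, "polarizability", 2) == 1.0
        assert ctd_distribution(seq, "polarizability", 2, "100%") == 100.0

    def test_alternating_transition(self):
        # G (group 1) and C (group 2) alternate: every adjacent pair crosses
        seq = "GC" * 5
        assert ctd_transition(seq, "polarizability", 1, 2) == pytest.approx(9 / 9)

    def test_distribution_50pct_quantile_position(self):
        # group-1 residues at positions 1..5 of a 10-mer: 50% point = 3rd of 5
        seq = "GGGGG" + "CCCCC"
        assert ctd_distribution(seq, "polarizability", 1, "50%") == pytest.approx(30.0)

    def test_absent_group_zero(self):
        assert ctd_distribution("GGGG", "polarizability", 3, "50%") == 0.0

    def test_against_oracle(self, make_peptide):
        for _ in range(10):
            seq = make_peptide(60)
            for grouping in CTD_GROUPINGS:
                for group in (1, 2, 3):
                    for point in features.DISTRIBUTION_POINTS:
                        got = ctd_distribution(seq, grouping, group, point)
                        want = naive_ctd_distribution(seq, grouping, group, point)
                        assert got == pytest.approx(want, abs=1e-12)

    def test_groupings_partition_alphabet(self):
        for grouping, groups in CTD_GROUPINGS.items():
            assert sorted("".join(groups)) == sorted(AMINO_ACIDS), grouping


class TestQso:
    def test_homopolymer_reduces_to_composition(self):
        vec = quasi_sequence_order("AAAAAA", maxlag=3)
        assert np.allclose(vec[20:], 0.0)
        assert vec[AA_INDEX["A"]] == pytest.approx(1.0)

    def test_dipeptide_tau1(self):
        dmat = physicochemical_distance_matrix()
        vec = quasi_sequence_order("AC", maxlag=1)
        tau1 = dmat[AA_INDEX["A"], AA_INDEX["C"]] ** 2
        w = 0.1
        assert vec[20] == pytest.approx(w * tau1 / (1 + w * tau1), abs=1e-12)

    def test_against_oracle(self, make_peptide):
        for _ in range(10):
            seq = make_peptide(40)
            got = quasi_sequence_order(seq, maxlag=10)
            want = naive_qso(seq, 10, 0.1)
            assert np.allclose(got, want, atol=1e-9)

    def test_normalized(self, make_peptide):
        vec = quasi_sequence_order(make_peptide(100), maxlag=30)
        assert vec.sum() == pytest.approx(1.0, abs=1e-12)


class TestFoldIndex:
    def test_poly_isoleucine_all_folded(self):
        stats = foldindex_features("I" * 60, window=16)
        assert stats["avg_folded_segment_length"] == 60 - 16 + 1
        assert stats["n_folded_segments"] == 1.0

    def test_poly_lysine_never_folded(self):
        stats = foldindex_features("K" * 60, window=16)
        assert stats["avg_folded_segment_length"] == 0.0
        assert stats["folded_fraction"] == 0.0

    def test_block_construction_matches_rle_oracle(self):
        seq = ("I" * 30 + "K" * 30) * 2
        profile = foldindex_profile(seq, window=16)
        runs = naive_fold_segments(list(profile > 0))
        stats = foldindex_features(seq, window=16)
        assert stats["n_folded_segments"] == len(runs)
        assert stats["avg_folded_segment_length"] == pytest.approx(np.mean(runs))
        assert stats["longest_folded_segment"] == max(runs)

    def test_short_sequence_whole_window(self):
        stats = foldindex_features("I" * 10, window=16)
        assert stats["avg_folded_segment_length"] == 1.0


class TestChargeDistribution:
    def test_all_positive(self):
        assert charge_distribution("KKKKK")["100%"] == 100.0

    def test_single_terminal_lysine(self):
        dist = charge_distribution("AAAAAAAAAK")
        assert dist["first"] == 100.0

    def test_no_positive_residues(self):
        dist = charge_distribution("AAAA")
        assert all(v == 0.0 for v in dist.values())


# --------------------------------------------------------------------------
# extract / spec
# --------------------------------------------------------------------------


class TestExtract:
    def test_default_spec_has_24_unique_features(self):
        spec = default_spec()
        assert len(spec) == 24
        assert len(set(spec.feature_ids)) == 24

    def test_24_finite_values(self, make_peptide):
        vec = extract(ProteinRecord("p", make_peptide(100)))
        assert len(vec.values) == 24
        assert all(math.isfinite(v) for v in vec.values)

    def test_determinism(self, make_peptide):
        seq = make_peptide(80)
        a = extract(ProteinRecord("a", seq))
        b = extract(ProteinRecord("b", seq))
        assert a.values == b.values

    def test_id_invariance(self, make_peptide):
        seq = make_peptide(60)
        assert extract(ProteinRecord("x", seq)).values == extract(
            ProteinRecord("someotherid", seq)
        ).values

    def test_total_on_short_sequences(self):
        # shorter than every lag: must still produce finite values
        vec = extract(ProteinRecord("p", "ACDEF"))
        assert all(math.isfinite(v) for v in vec.values)

    def test_spec_round_trip_and_digest(self):
        spec = default_spec()
        again = FeatureSpec.from_json(spec.to_json())
        assert again == spec
        assert again.digest() == spec.digest()

    @given(st.text(alphabet=AMINO_ACIDS, min_size=31, max_size=80))
    @settings(max_examples=25, deadline=None)
    def test_property_no_nan_inf(self, seq):
        vec = extract(ProteinRecord("p", seq))
        assert all(math.isfinite(v) for v in vec.values)
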