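"""Data model, text round trips, beta/detection/QC rules, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from enmix import (
    IntensitySet,
    ProbeManifest,
    compute_beta,
    detection_pvalue,
    frequency_polygon,
    nmode,
    qc_filter,
    read_intensity_tables,
    split_six_parts,
    write_intensity_tables,
)


@pytest.fixture
def toy_manifest():
    return ProbeManifest(pd.DataFrame({
        "probe_id": ["p1", "p2", "p3", "p4"],
        "design_type": ["I", "I", "II", "II"],
        "channel": ["red", "green", "", ""],
    }))


@pytest.fixture
def toy_set(toy_manifest):
    probes = toy_manifest.probe_ids
    samples = ["s1", "s2"]
    M = pd.DataFrame([[1000.0, 1100.0], [5000.0, 5100.0],
                      [200.0, 210.0], [8000.0, 7900.0]], index=probes, columns=samples)
    U = pd.DataFrame([[4000.0, 4100.0], [300.0, 310.0],
                      [9000.0, 9100.0], [150.0, 140.0]], index=probes, columns=samples)
    oob = pd.DataFrame([[400.0, 410.0], [500.0, 490.0]],
                       index=["p1", "p2"], columns=samples)
    rng = np.random.default_rng(0)
    controls = pd.concat([
        pd.DataFrame({"sample_id": s, "control_type": "negative",
                      "red": rng.uniform(300, 700, 30),
                      "green": rng.uniform(400, 800, 30)})
        for s in samples
    ], ignore_index=True)
    return IntensitySet(M=M, U=U, oob_M=oob, oob_U=oob.copy(), controls=controls)


class TestManifest:
    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ProbeManifest(pd.DataFrame({
                "probe_id": ["p1", "p1"], "design_type": ["I", "II"],
                "channel": ["red", ""]}))

    def test_type_one_needs_channel(self):
        with pytest.raises(ValueError, match="channel"):
            ProbeManifest(pd.DataFrame({
                "probe_id": ["p1"], "design_type": ["I"], "channel": [""]}))


class TestIO:
    def test_round_trip_identity(self, toy_set, toy_manifest, tmp_path):
        paths = write_intensity_tables(toy_set, tmp_path)
        back = read_intensity_tables(paths, toy_manifest)
        pd.testing.assert_frame_equal(back.M, toy_set.M)
        pd.testing.assert_frame_equal(back.U, toy_set.U)
        pd.testing.assert_frame_equal(back.oob_M, toy_set.oob_M)

    def test_round_trip_full_float_precision(self, toy_manifest, tmp_path):
        probes = toy_manifest.probe_ids
        rng = np.random.default_rng(1)
        M = pd.DataFrame(rng.uniform(0, 2 ** 16, (4, 3)), index=probes,
                         columns=["a", "b", "c"])
        x = IntensitySet(M=M, U=M * np.pi)
        back = read_intensity_tables(write_intensity_tables(x, tmp_path), toy_manifest)
        assert (back.M.to_numpy() == x.M.to_numpy()).all()
        assert (back.U.to_numpy() == x.U.to_numpy()).all()

    def test_negative_entry_reported_with_location(self, toy_manifest, tmp_path):
        p = tmp_path / "M.tsv"
        pd.DataFrame({"s1": [1.0, -5.0, 1.0, 1.0]},
                     index=pd.Index(["p1", "p2", "p3", "p4"], name="probe_id")
                     ).to_csv(p, sep="\t")
        u = tmp_path / "U.tsv"
        pd.DataFrame({"s1": [1.0, 1.0, 1.0, 1.0]},
                     index=pd.Index(["p1", "p2", "p3", "p4"], name="probe_id")
                     ).to_csv(u, sep="\t")
        with pytest.raises(ValueError, match="p2"):
            read_intensity_tables({"M": p, "U": u}, toy_manifest)

    def test_probe_mismatch_lists_offenders(self, toy_set, toy_manifest, tmp_path):
        paths = write_intensity_tables(toy_set, tmp_path)
        bad = ProbeManifest(pd.DataFrame({
            "probe_id": ["p1", "p2", "p3", "zz"],
            "design_type": ["I", "I", "II", "II"],
            "channel": ["red", "green", "", ""]}))
        with pytest.raises(ValueError, match="zz"):
            read_intensity_tables(paths, bad)


class TestSixPartSplit:
    def test_toy_part_sizes(self, toy_set, toy_manifest):
        parts = split_six_parts(toy_set, toy_manifest).parts
        sizes = {k: len(v) for k, v in parts.items()}
        assert sizes == {"I-red-M": 1, "I-red-U": 1, "I-green-M": 1,
                         "I-green-U": 1, "II-green-M": 2, "II-red-U": 2}

    def test_no_type_one_probes(self):
        mf = ProbeManifest(pd.DataFrame({
            "probe_id": ["a", "b"], "design_type": ["II", "II"], "channel": ["", ""]}))
        M = pd.DataFrame({"s": [1.0, 2.0]}, index=["a", "b"])
        split = split_six_parts(IntensitySet(M=M, U=M + 1), mf)
        assert len(split.parts["I-red-M"]) == 0
        assert len(split.parts["II-green-M"]) == 2

    def test_partition_conserves_all_elements(self, small_array):
        x, manifest, _ = small_array
        split = split_six_parts(x, manifest)
        assert split.n_elements() == 2 * len(x.probe_ids) * len(x.samples)
        # no probe appears in two M-parts or two U-parts
        m_ids = np.concatenate([split.parts[n].index for n in
                                ("I-red-M", "I-green-M", "II-green-M")])
        assert len(m_ids) == len(set(m_ids)) == len(x.probe_ids)


class TestBeta:
    @pytest.mark.parametrize("M,U,expected", [
        (100.0, 0.0, 0.5),
        (0.0, 0.0, 0.0),
        (900.0, 0.0, 0.9),
    ])
    def test_offset_formula_cases(self, M, U, expected):
        assert compute_beta(M, U) == expected

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            compute_beta(-1.0, 5.0)

    @given(M=st.floats(1e-3, 1e5), U=st.floats(0, 1e5), dM=st.floats(1e-3, 1e4))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_strictly_monotone_in_each_argument(self, M, U, dM):
        assert compute_beta(M + dM, U) > compute_beta(M, U)
        # decreasing in U needs M > 0 (beta is identically 0 at M = 0)
        assert compute_beta(M, U + dM) < compute_beta(M, U)


class TestDetectionPvalue:
    def test_extremes_and_monotonicity(self, toy_set, toy_manifest):
        p = detection_pvalue(toy_set, toy_manifest)
        assert ((p.to_numpy() > 0) & (p.to_numpy() <= 1)).all()
        # a dark probe must not be called detected
        dark = toy_set.copy()
        dark.M.loc["p3"] = 0.0
        dark.U.loc["p3"] = 0.0
        p_dark = detection_pvalue(dark, toy_manifest)
        assert p_dark.loc["p3", "s1"] == 1.0
        # brighter total signal -> smaller or equal p
        bright = toy_set.copy()
        bright.M.loc["p3"] += 1e5
        assert (detection_pvalue(bright, toy_manifest).loc["p3", "s1"]
                <= p.loc["p3", "s1"])

    def test_median_signal_gives_half(self, toy_manifest):
        probes = toy_manifest.probe_ids
        controls = pd.DataFrame({
            "sample_id": "s1", "control_type": "negative",
            "red": np.arange(1.0, 102.0), "green": np.arange(1.0, 102.0)})
        # type II probe p3 sums green+red control pairs: sums are 2..202
        M = pd.DataFrame({"s1": [1.0, 1.0, 102.0, 1.0]}, index=probes)
        U = pd.DataFrame({"s1": [1.0, 1.0, 0.0, 1.0]}, index=probes)
        x = IntensitySet(M=M, U=U, controls=controls)
        p = detection_pvalue(x, toy_manifest)
        # brute-force ecdf oracle
        sums = np.arange(1.0, 102.0) * 2
        expected = ((sums >= 102.0).sum() + 1) / (len(sums) + 1)
        assert p.loc["p3", "s1"] == pytest.approx(expected)
        assert abs(p.loc["p3", "s1"] - 0.5) < 0.01

    def test_missing_controls_is_error(self, toy_set, toy_manifest):
        x = toy_set.copy()
        x.controls = None
        with pytest.raises(ValueError):
            detection_pvalue(x, toy_manifest)


class TestQcFilter:
    def make(self, toy_set, beads_m, beads_u, pval):
        x = toy_set.copy()
        shape = x.M.shape
        x.bead_count_M = pd.DataFrame(np.full(shape, beads_m), index=x.M.index,
                                      columns=x.M.columns)
        x.bead_count_U = pd.DataFrame(np.full(shape, beads_u), index=x.M.index,
                                      columns=x.M.columns)
        p = pd.DataFrame(np.full(shape, pval), index=x.M.index, columns=x.M.columns)
        return x, p

    def test_low_bead_count_excluded(self, toy_set):
        x, p = self.make(toy_set, 2, 5, 0.01)
        assert qc_filter(x, p).to_numpy().all()

    def test_high_detection_p_excluded(self, toy_set):
        x, p = self.make(toy_set, 5, 5, 0.06)
        assert qc_filter(x, p).to_numpy().all()

    def test_boundary_values_retained(self, toy_set):
        # thresholds are strict: exactly 3 beads and p = 0.05 survive
        x, p = self.make(toy_set, 3, 3, 0.05)
        assert not qc_filter(x, p).to_numpy().any()

    def test_absent_bead_counts_skip_bead_rule(self, toy_set):
        p = pd.DataFrame(np.full(toy_set.M.shape, 0.01), index=toy_set.M.index,
                         columns=toy_set.M.columns)
        assert not qc_filter(toy_set, p).to_numpy().any()


class TestNmode:
    def test_unimodal_beta_distribution(self):
        rng = np.random.default_rng(0)
        assert nmode(rng.beta(50, 50, 500)) == 1

    def test_bimodal_mixture(self):
        rng = np.random.default_rng(1)
        v = np.concatenate([rng.beta(80, 8, 250), rng.beta(8, 80, 250)])
        assert nmode(v) == 2

    def test_constant_values_single_mode(self):
        assert nmode(np.full(100, 0.42)) == 1

    def test_too_few_samples_refused(self):
        with pytest.raises(ValueError):
            nmode(np.linspace(0, 1, 19))


class TestFrequencyPolygon:
    def test_two_bins(self):
        mids, counts = frequency_polygon([0.1, 0.9], 2, (0.0, 1.0))
        assert list(counts) == [1, 1]
        assert mids == pytest.approx([0.25, 0.75])

    def test_counts_conserved_and_deterministic(self):
        rng = np.random.default_rng(2)
        v = rng.uniform(0, 1, 1000)
        m1, c1 = frequency_polygon(v, 17)
        m2, c2 = frequency_polygon(v, 17)
        assert c1.sum() == 1000
        assert (c1 == c2).all() and (m1 == m2).all()
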