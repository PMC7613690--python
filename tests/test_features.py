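"""Footprint cutouts, waveform features, and delta/sham dataset assembly."""

import numpy as np
import pytest

from aistrack.features import (
    FEATURE_NAMES,
    Footprint,
    NoSpikeError,
    build_delta_dataset,
    compute_features,
    dataset_arrays,
    extract_footprint,
    select_and_order_electrodes,
)
from aistrack.forward_sim import SimResult
from aistrack.pipeline import biphasic_pulse, make_fixture

FS = 32000.0


def _sim_from_traces(traces):
    return SimResult(
        extracellular=np.asarray(traces, dtype=float),
        electrode_indices=np.arange(len(traces)),
        fs=FS,
        metadata={},
    )


class TestExtractFootprint:
    @pytest.mark.parametrize("profile,n", [("bas", 96), ("detailed", 177)])
    def test_cutout_length(self, profile, n):
        traces = np.zeros((30, 600))
        traces[4] = biphasic_pulse(600, 300, amplitude=60)
        fp = extract_footprint(_sim_from_traces(traces), profile)
        assert fp.n_samples == n

    def test_window_brackets_trough(self):
        traces = np.zeros((30, 600))
        traces[7] = biphasic_pulse(600, 250, amplitude=80)
        fp = extract_footprint(_sim_from_traces(traces), "bas")
        start, end = fp.cutout_indices
        assert start < 250 < end
        # one third of the window precedes the trough
        assert start == 250 - 32

    def test_no_spike_raises(self):
        traces = np.zeros((30, 600))
        traces[3] = biphasic_pulse(600, 300, amplitude=5)  # below the floor
        with pytest.raises(NoSpikeError):
            extract_footprint(_sim_from_traces(traces), "bas")

    def test_aligns_to_first_spike_of_a_train(self):
        """With repeated spikes, the window locks to the earliest one even if
        a later spike is deeper."""
        traces = np.zeros((30, 1200))
        traces[0] = biphasic_pulse(1200, 300, 50) + biphasic_pulse(1200, 700, 90)
        fp = extract_footprint(_sim_from_traces(traces), "bas")
        start, end = fp.cutout_indices
        assert start < 300 < end and not (start < 700 < end)


class TestSelection:
    def test_deepest_earliest_is_first(self):
        traces = np.zeros((30, 300))
        for i in range(30):
            traces[i] = biphasic_pulse(300, 100 + i, 20 + i)
        traces[5] = biphasic_pulse(300, 90, 200.0)  # deepest and earliest
        fp = extract_footprint(_sim_from_traces(traces), "bas")
        order = select_and_order_electrodes(fp)
        assert order[0] == 5

    def test_matches_brute_force_ranking(self):
        rng = np.random.default_rng(0)
        traces = np.stack(
            [biphasic_pulse(300, int(rng.integers(80, 160)), float(rng.uniform(15, 90)))
             for _ in range(40)]
        )
        fp = extract_footprint(_sim_from_traces(traces), "bas")
        order = select_and_order_electrodes(fp)
        base = fp.waveforms[:, :10].mean(axis=1, keepdims=True)
        rel = fp.waveforms - base
        troughs = rel.min(axis=1)
        top = sorted(range(len(rel)), key=lambda i: troughs[i])[:26]
        expected = sorted(top, key=lambda i: (rel[i].argmin(), troughs[i], i))
        assert list(order) == expected

    def test_latency_tie_broken_by_depth_then_id(self):
        traces = np.zeros((30, 300))
        for i in range(30):
            traces[i] = biphasic_pulse(300, 150, 20)
        traces[9] = biphasic_pulse(300, 150, 70)
        fp = extract_footprint(_sim_from_traces(traces), "bas")
        order = select_and_order_electrodes(fp)
        assert order[0] == 9
        assert list(order[1:5]) == [0, 1, 2, 3]

    def test_too_few_electrodes(self):
        traces = np.zeros((10, 300))
        traces[0] = biphasic_pulse(300, 150, 50)
        fp = extract_footprint(_sim_from_traces(traces), "bas")
        with pytest.raises(ValueError):
            select_and_order_electrodes(fp)


class TestWaveformFeatures:
    def test_gaussian_half_width(self):
        """FWHM of a pure negative Gaussian is 2 sigma sqrt(2 ln 2)."""
        sigma = 6.0
        n = 96
        t = np.arange(n)
        w = -50.0 * np.exp(-0.5 * ((t - 48) / sigma) ** 2)
        fp = Footprint(np.tile(w, (1, 1)), np.array([0]), FS, (0, n))
        feats = compute_features(fp)
        expected_ms = 2 * sigma * np.sqrt(2 * np.log(2)) / FS * 1000.0
        assert feats.loc[0, "half_width"] == pytest.approx(expected_ms, rel=0.05)

    def test_scaling_linearity(self):
        w = biphasic_pulse(96, 32, 40.0)
        fp = Footprint(np.stack([w, 2 * w]), np.arange(2), FS, (0, 96))
        feats = compute_features(fp)
        assert feats.loc[1, "trough_amplitude"] == pytest.approx(2 * feats.loc[0, "trough_amplitude"])
        assert feats.loc[1, "peak_to_peak"] == pytest.approx(2 * feats.loc[0, "peak_to_peak"])
        assert feats.loc[1, "half_width"] == pytest.approx(feats.loc[0, "half_width"])
        assert feats.loc[1, "latency"] == feats.loc[0, "latency"]

    def test_latency_relative_to_earliest(self):
        w0 = biphasic_pulse(96, 30, 50.0)
        w1 = biphasic_pulse(96, 40, 50.0)
        fp = Footprint(np.stack([w0, w1]), np.arange(2), FS, (0, 96))
        feats = compute_features(fp)
        assert feats.loc[0, "latency"] == 0.0
        assert feats.loc[1, "latency"] == pytest.approx(10 / FS * 1000.0)

    def test_never_recrossing_flagged(self):
        w = np.linspace(0, -50, 96)  # monotone fall, never recovers
        fp = Footprint(w[None, :], np.array([0]), FS, (0, 96))
        feats = compute_features(fp)
        assert bool(feats.loc[0, "flagged"])


class TestDeltaDataset:
    def _family(self, seed=0, n_el=30, d_list=(5.0, 20.0)):
        """Synthetic footprint family: sink moves along +x with d_ais."""
        rng = np.random.default_rng(seed)
        base_amp = rng.uniform(20, 80, n_el)
        out = []
        for d in d_list:
            wf = np.stack(
                [biphasic_pulse(96, 30 + (i % 7) + int(d / 10), base_amp[i] * (1 + 0.01 * d * ((i % 5) - 2)))
                 for i in range(n_el)]
            )
            out.append(
                Footprint(wf, np.arange(n_el), FS, (0, 96),
                          meta={"offset": (0.0, 0.0), "theta_deg": 0.0, "d_ais": d})
            )
        return out

    def test_self_pair_is_zero_valid(self):
        fps = self._family(d_list=(5.0, 5.0))
        vectors = build_delta_dataset([fps[0]], [fps[1]], sham_ratio=0)
        (v,) = vectors
        assert v.label_valid and v.relocation_um == 0.0
        np.testing.assert_allclose(v.values, 0.0, atol=1e-9)

    def test_magnitude_label(self):
        fps = self._family(d_list=(5.0, 40.0))
        vectors = build_delta_dataset([fps[0]], [fps[1]], sham_ratio=0)
        assert vectors[0].relocation_um == pytest.approx(35.0)

    def test_sham_of_zero_delta_is_nonzero_invalid(self):
        fps = self._family(d_list=(5.0, 5.0))
        vectors = build_delta_dataset([fps[0]], [fps[1]], sham_ratio=1, seed=3)
        sham = [v for v in vectors if not v.label_valid][0]
        assert sham.relocation_um is None
        assert np.abs(sham.values).max() > 0

    def test_balance_exact(self):
        fps = self._family(d_list=(5.0, 10.0, 20.0, 30.0))
        vectors = build_delta_dataset([fps[0]], fps[1:], sham_ratio=2, seed=0)
        y = np.array([v.label_valid for v in vectors])
        assert (~y).sum() == 2 * y.sum()

    def test_missing_baseline_rejected(self):
        fps = self._family(d_list=(5.0, 20.0))
        fps[1].meta["theta_deg"] = 90.0
        with pytest.raises(ValueError):
            build_delta_dataset([fps[0]], [fps[1]])

    def test_amplitude_column_subset(self):
        fps = self._family(d_list=(5.0, 20.0))
        vectors = build_delta_dataset([fps[0]], [fps[1]], sham_ratio=1, seed=0)
        X_full, y, mag = dataset_arrays(vectors)
        X_amp, _, _ = dataset_arrays(vectors, feature_set=("trough_amplitude",))
        assert X_full.shape[1] == 26 * len(FEATURE_NAMES)
        assert X_amp.shape[1] == 26
        j = FEATURE_NAMES.index("trough_amplitude")
        np.testing.assert_allclose(X_amp[:, 0], X_full[:, j])

    def test_simulated_self_deltas_are_zero(self, bas_reduced_footprints):
        """Pairing a simulated baseline with itself yields a null vector."""
        base = [fp for fp in bas_reduced_footprints
                if fp.meta["d_ais"] == 5.0][:3]
        vectors = build_delta_dataset(base, base, sham_ratio=0)
        for v in vectors:
            np.testing.assert_allclose(v.values, 0.0, atol=1e-9)


def test_fixture_kinds():
    x, y, h = make_fixture("waveform_pair", 0)
    np.testing.assert_allclose(np.convolve(x, h)[: len(x)], y)
    fp, probe = make_fixture("footprint", 1)
    assert fp.waveforms.shape[0] == probe.n_electrodes
    X, yb = make_fixture("dataset", 2)
    assert X.shape[0] == len(yb) and yb.sum() * 2 == len(yb)
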