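"""Spike-footprint cutouts, waveform features, and labeled delta-datasets.

A *footprint* is the spatial pattern of spike-triggered extracellular
voltages across the probe's analysis electrodes.  Cutouts are aligned on the
electrode with the earliest signal trough; the same window indices apply to
every electrode.  Per-electrode waveform features (trough amplitude, latency,
half-width, peak-to-peak, slopes at the half-amplitude crossings) are
differenced between a baseline footprint (AIS at 5 um) and a comparison
footprint to form delta-feature vectors; sham vectors — permuted comparisons
— provide the negative class for relocation detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forward_sim import SimResult

CUTOUT_SAMPLES = {"bas": 96, "detailed": 177}
N_SELECTED_ELECTRODES = 26
DETECTION_FLOOR_UV = -10.0
PRE_FRACTION = 1.0 / 3.0  # fraction of the window before the earliest trough
BASELINE_SAMPLES = 10  # pre-spike samples defining the per-electrode baseline
FEATURE_NAMES = (
    "trough_amplitude",
    "latency",
    "half_width",
    "peak_to_peak",
    "slope_rising",
    "slope_falling",
)


class NoSpikeError(RuntimeError):
    """No electrode shows a trough below the detection floor."""


@dataclass
class Footprint:
    waveforms: np.ndarray  # (n_electrodes, N) uV
    electrode_ids: np.ndarray
    fs: float  # Hz
    cutout_indices: tuple  # (start, end) samples in the source trace
    meta: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.waveforms.shape[1]


def extract_footprint(
    sim: SimResult,
    profile: str = "bas",
    detection_floor_uv: float = DETECTION_FLOOR_UV,
) -> Footprint:
    """Cut a spike-aligned footprint out of a simulation.

    The electrode with the earliest trough (global minimum below the
    detection floor) defines the window indices: one third of the samples
    before the trough, two thirds after; identical indices are applied to all
    electrodes.  Raises :class:`NoSpikeError` if nothing crosses the floor.
    """
    if profile not in CUTOUT_SAMPLES:
        raise ValueError(f"unknown profile {profile!r}")
    n_cut = CUTOUT_SAMPLES[profile]
    x = sim.extracellular
    below = x < detection_floor_uv
    candidates = np.flatnonzero(below.any(axis=1))
    if len(candidates) == 0:
        raise NoSpikeError(
            f"no trough below {detection_floor_uv} uV (deepest: {x.min():.2f} uV)"
        )
    # earliest trough = local minimum right after the earliest floor crossing
    # (stimulus trains fire repeatedly; alignment must lock to the first spike,
    # not to whichever spike in the train happens to be deepest)
    first_cross = below[candidates].argmax(axis=1)
    order = np.lexsort((candidates, x[candidates].min(axis=1), first_cross))
    earliest = candidates[order[0]]
    cross = int(first_cross[order[0]])
    trough_search = int(round(sim.fs / 1000.0))  # 1 ms past the crossing
    t0 = cross + int(x[earliest, cross : cross + trough_search].argmin())

    pre = int(round(n_cut * PRE_FRACTION))
    start = t0 - pre
    start = max(0, min(start, x.shape[1] - n_cut))
    end = start + n_cut
    return Footprint(
        waveforms=x[:, start:end].copy(),
        electrode_ids=np.asarray(sim.electrode_indices),
        fs=sim.fs,
        cutout_indices=(start, end),
        meta=dict(sim.metadata),
    )


# ---------------------------------------------------------------------------
# waveform features

def _waveform_features(w: np.ndarray, fs: float) -> dict:
    """Features of one cutout waveform; latency here is the absolute trough
    time (s relative alignment happens at footprint level)."""
    base = float(np.mean(w[:BASELINE_SAMPLES]))
    rel = w - base
    i_min = int(np.argmin(rel))
    trough = float(rel[i_min])  # <= 0
    dt_ms = 1000.0 / fs
    half = trough / 2.0

    below = rel <= half
    flagged = False
    if trough >= 0 or not below.any():
        # degenerate flat/positive waveform
        return {
            "trough_amplitude": min(trough, 0.0),
            "trough_sample": i_min,
            "half_width": len(w) * dt_ms,
            "peak_to_peak": float(rel.max() - rel.min()),
            "slope_rising": 0.0,
            "slope_falling": 0.0,
            "flagged": True,
        }
    # crossing indices around the trough, linearly interpolated
    i_on = i_min
    while i_on > 0 and rel[i_on - 1] <= half:
        i_on -= 1
    i_off = i_min
    while i_off < len(rel) - 1 and rel[i_off + 1] <= half:
        i_off += 1

    if i_on == 0:
        t_on, flagged = 0.0, True
        slope_fall = (rel[1] - rel[0]) / dt_ms
    else:
        frac = (half - rel[i_on - 1]) / (rel[i_on] - rel[i_on - 1])
        t_on = (i_on - 1 + frac) * dt_ms
        slope_fall = (rel[i_on] - rel[i_on - 1]) / dt_ms  # downstroke into the trough
    if i_off == len(rel) - 1:
        t_off, flagged = (len(rel) - 1) * dt_ms, True
        slope_rise = (rel[-1] - rel[-2]) / dt_ms
    else:
        frac = (half - rel[i_off]) / (rel[i_off + 1] - rel[i_off])
        t_off = (i_off + frac) * dt_ms
        slope_rise = (rel[i_off + 1] - rel[i_off]) / dt_ms  # recovery upstroke

    return {
        "trough_amplitude": trough,
        "trough_sample": i_min,
        "half_width": max(t_off - t_on, dt_ms),
        "peak_to_peak": float(rel.max() - rel.min()),
        "slope_rising": slope_rise,
        "slope_falling": slope_fall,
        "flagged": flagged,
    }


def compute_features(fp: Footprint, order=None) -> "pd.DataFrame":
    """Per-electrode waveform features.

    Latency is reported in ms relative to the earliest trough in the
    footprint (hence >= 0 with a zero at the initiation site).  If ``order``
    is given, rows follow it; otherwise all electrodes in id order.
    """
    import pandas as pd

    rows = []
    ids = np.arange(len(fp.waveforms)) if order is None else np.asarray(order)
    for i in ids:
        f = _waveform_features(fp.waveforms[i], fp.fs)
        rows.append(f)
    df = pd.DataFrame(rows, index=ids)
    dt_ms = 1000.0 / fp.fs
    earliest = df["trough_sample"].min()
    df["latency"] = (df["trough_sample"] - earliest) * dt_ms
    return df[list(FEATURE_NAMES) + ["flagged"]]


def select_and_order_electrodes(fp: Footprint, n: int = N_SELECTED_ELECTRODES) -> np.ndarray:
    """Row indices of the top-``n`` electrodes by |trough amplitude|, sorted by
    latency ascending.

    Ties in latency are broken by deeper trough first, then lower electrode
    id, so the ordering is fully deterministic.
    """
    if len(fp.waveforms) < n:
        raise ValueError(f"footprint has {len(fp.waveforms)} electrodes; need >= {n}")
    base = fp.waveforms[:, :BASELINE_SAMPLES].mean(axis=1, keepdims=True)
    rel = fp.waveforms - base
    troughs = rel.min(axis=1)  # negative
    top = np.argsort(troughs, kind="stable")[:n]  # deepest first
    trough_samples = rel[top].argmin(axis=1)
    # sort by (latency, amplitude depth, id)
    order = sorted(
        range(n), key=lambda j: (trough_samples[j], troughs[top[j]], top[j])
    )
    return top[np.asarray(order)]


# ---------------------------------------------------------------------------
# delta-feature datasets

@dataclass
class DeltaFeatureVector:
    values: np.ndarray  # (n_electrodes * n_features,)
    label_valid: bool
    relocation_um: float | None  # present iff valid
    electrode_order: np.ndarray  # baseline ordering (row indices)
    feature_names: tuple = FEATURE_NAMES
    meta: dict = field(default_factory=dict)


def _feature_matrix(fp: Footprint, order: np.ndarray, feature_set) -> np.ndarray:
    df = compute_features(fp, order)
    return df[list(feature_set)].to_numpy()  # (M, n_features)


def build_delta_dataset(
    baselines,
    comparisons,
    feature_set=FEATURE_NAMES,
    sham_ratio: int = 1,
    seed: int = 0,
    n_electrodes: int = N_SELECTED_ELECTRODES,
    baseline_d_ais: float = 5.0,
):
    """Assemble labeled delta-feature vectors from footprint pairs.

    ``baselines`` and ``comparisons`` are iterables of :class:`Footprint`
    whose ``meta`` carries ``offset``, ``theta_deg`` and ``d_ais``.  Each
    comparison is paired with the baseline sharing its (offset, theta); the
    difference of per-electrode features (comparison minus baseline, over the
    baseline's 26-electrode ordering) forms a valid vector labeled with the
    relocation magnitude ``d_ais - 5``.  For each valid vector, ``sham_ratio``
    sham vectors are built by permuting the comparison's per-electrode feature
    rows (seeded; identity permutations are redrawn) before subtraction.
    """
    rng = np.random.default_rng(seed)
    base_by_key = {}
    for fp in baselines:
        if fp.meta.get("d_ais") != baseline_d_ais:
            raise ValueError(
                f"baseline footprint has d_ais={fp.meta.get('d_ais')}, expected {baseline_d_ais}"
            )
        base_by_key[(fp.meta["offset"], fp.meta["theta_deg"])] = fp

    base_cache = {}
    out = []
    for fp in comparisons:
        key = (fp.meta["offset"], fp.meta["theta_deg"])
        if key not in base_by_key:
            raise ValueError(f"no baseline for (offset, theta) = {key}")
        base = base_by_key[key]
        if key not in base_cache:
            order = select_and_order_electrodes(base, n_electrodes)
            base_cache[key] = (order, _feature_matrix(base, order, feature_set))
        order, base_feat = base_cache[key]
        comp_feat = _feature_matrix(fp, order, feature_set)
        delta = comp_feat - base_feat
        magnitude = float(fp.meta["d_ais"] - baseline_d_ais)
        out.append(
            DeltaFeatureVector(
                delta.ravel(), True, magnitude, order, tuple(feature_set),
                meta={"offset": key[0], "theta_deg": key[1], "d_ais": fp.meta["d_ais"]},
            )
        )
        m = comp_feat.shape[0]
        for _ in range(sham_ratio):
            perm = rng.permutation(m)
            while np.array_equal(perm, np.arange(m)):
                perm = rng.permutation(m)
            sham = comp_feat[perm] - base_feat
            out.append(
                DeltaFeatureVector(
                    sham.ravel(), False, None, order, tuple(feature_set),
                    meta={"offset": key[0], "theta_deg": key[1], "sham_of": fp.meta["d_ais"]},
                )
            )
    return out


def dataset_arrays(vectors, feature_set=None):
    """Stack delta vectors into (X, y_valid, magnitudes) numpy arrays.

    ``feature_set`` optionally restricts columns to a subset of the features
    used when the vectors were built (e.g. only amplitude changes for the
    magnitude regressor).  Magnitude is NaN for sham rows.
    """
    X = np.vstack([v.values for v in vectors])
    y = np.array([v.label_valid for v in vectors], dtype=bool)
    mag = np.array(
        [v.relocation_um if v.label_valid else np.nan for v in vectors]
    )
    if feature_set is not None:
        names = vectors[0].feature_names
        m = len(vectors[0].electrode_order)
        cols = []
        for f in feature_set:
            j = names.index(f)
            cols.extend(e * len(names) + j for e in range(m))
        X = X[:, np.asarray(cols)]
    return X, y, mag


def feature_column_names(vectors):
    """Column labels like 'e03.trough_amplitude' matching dataset_arrays."""
    names = vectors[0].feature_names
    m = len(vectors[0].electrode_order)
    return [f"e{e:02d}.{f}" for e in range(m) for f in names]
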