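"""End-to-end pipeline: simulate -> featurize -> train -> kernel library.

The reduced grid (15 degree rotations, 5 um AIS steps, 2 soma offsets) is the
first-class desk-scale configuration used by tests, worked examples and the
reproduction script; the paper-scale full grids are reached purely through
configuration.  Also hosts deterministic synthetic fixtures (biphasic pulses,
moving-sink footprints, planted-feature datasets) that exercise the feature
and kernel machinery without the simulator.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .features import (
    FEATURE_NAMES,
    Footprint,
    build_delta_dataset,
    dataset_arrays,
    extract_footprint,
)
from .forward_sim import SimulationConfig, simulate_family
from .kernels import DEFAULT_L, KernelLibrary, build_kernel_library
from .ml import NCAConfig, train_detector, train_magnitude_regressor
from .morphology import AISSpec, assign_biophysics, build_ball_and_stick, build_synthetic_detailed, load_swc
from .probe import Probe, build_probe


@dataclass
class PipelineConfig:
    profile: str = "bas"  # 'bas', 'detailed', or 'swc:PATH'
    grid: str = "reduced"  # 'reduced' or 'full'
    seed: int = 0
    out_dir: str | None = None
    sham_ratio: int = 1
    kernel_length: int = DEFAULT_L
    feature_set: tuple = FEATURE_NAMES
    detailed_seed: int = 1
    hillock_angle_deg: float = -115.6

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "feature_set" in data:
            data["feature_set"] = tuple(data["feature_set"])
        return cls(**data)


def make_builder(profile: str, detailed_seed: int = 1, hillock_angle_deg: float = -115.6):
    """``builder(d_ais) -> Morphology`` factory for a model profile."""
    if profile == "bas":
        return lambda d: assign_biophysics(build_ball_and_stick(AISSpec(d)))
    if profile == "detailed":
        return lambda d: assign_biophysics(
            build_synthetic_detailed(detailed_seed, hillock_angle_deg, AISSpec(d))
        )
    if profile.startswith("swc:"):
        path = profile[4:]
        return lambda d: assign_biophysics(load_swc(path, ais=AISSpec(d)))
    raise ValueError(f"unknown profile {profile!r}")


def grid_config(profile: str, grid: str) -> SimulationConfig:
    if grid == "full":
        return (
            SimulationConfig.ball_and_stick_default()
            if profile == "bas"
            else SimulationConfig.detailed_default()
        )
    if grid == "reduced":
        return SimulationConfig.reduced()
    raise ValueError(f"unknown grid {grid!r}")


def run_family_footprints(
    cfg: SimulationConfig,
    profile: str = "bas",
    probe: Probe | None = None,
    detailed_seed: int = 1,
    hillock_angle_deg: float = -115.6,
):
    """Simulate a model family on the analysis block and return footprints."""
    if probe is None:
        probe = build_probe()
    builder = make_builder(profile, detailed_seed, hillock_angle_deg)
    cut_profile = "bas" if profile == "bas" else "detailed"
    fps = []
    for sim in simulate_family(builder, probe, cfg, electrode_indices=probe.analysis_block):
        fps.append(extract_footprint(sim, cut_profile))
    return fps


def split_baselines(footprints, baseline_d_ais: float = 5.0):
    baselines = [fp for fp in footprints if fp.meta["d_ais"] == baseline_d_ais]
    comparisons = [fp for fp in footprints if fp.meta["d_ais"] > baseline_d_ais]
    return baselines, comparisons


def save_footprints_npz(footprints, path) -> None:
    wf = np.stack([fp.waveforms for fp in footprints]).astype(np.float32)
    meta = [fp.meta for fp in footprints]
    np.savez_compressed(
        path,
        waveforms=wf,
        electrode_ids=footprints[0].electrode_ids,
        fs=footprints[0].fs,
        cutouts=np.array([fp.cutout_indices for fp in footprints]),
        meta_json=json.dumps(meta),
    )


def load_footprints_npz(path):
    z = np.load(path, allow_pickle=False)
    meta = json.loads(str(z["meta_json"]))
    fps = []
    for i, m in enumerate(meta):
        m["offset"] = tuple(m["offset"])
        fps.append(
            Footprint(
                waveforms=z["waveforms"][i].astype(float),
                electrode_ids=z["electrode_ids"],
                fs=float(z["fs"]),
                cutout_indices=tuple(z["cutouts"][i]),
                meta=m,
            )
        )
    return fps


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig, dry_run: bool = False) -> dict:
    """Simulate, featurize, train the detector and regressor, and fit the
    kernel library; returns (and optionally writes) a manifest of artifacts
    and metrics.  With ``dry_run`` only the grid bookkeeping is computed —
    the manifest then declares the scheduled simulations without running
    them."""
    t_start = time.time()
    make_builder(cfg.profile, cfg.detailed_seed, cfg.hillock_angle_deg)  # validate profile
    sim_cfg = grid_config(cfg.profile, cfg.grid)
    grid = None
    manifest: dict = {
        "config": asdict(cfg),
        "sim_config": asdict(sim_cfg),
        "stages": {},
        "artifacts": {},
    }
    from .forward_sim import enumerate_grid

    grid = enumerate_grid(sim_cfg)
    manifest["stages"]["grid"] = {
        "n_simulations": len(grid),
        "per_ais_position": len(sim_cfg.soma_offsets) * len(sim_cfg.angles),
        "n_ais_positions": len(sim_cfg.ais_positions),
    }

    out = Path(cfg.out_dir) if cfg.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.json").write_text(json.dumps(manifest["config"], indent=2))
    if dry_run:
        return manifest

    stage = "simulate"
    try:
        t0 = time.time()
        footprints = run_family_footprints(
            sim_cfg, cfg.profile, detailed_seed=cfg.detailed_seed,
            hillock_angle_deg=cfg.hillock_angle_deg,
        )
        manifest["stages"][stage] = {
            "n_footprints": len(footprints), "seconds": round(time.time() - t0, 2),
        }
        if out:
            save_footprints_npz(footprints, out / "footprints.npz")
            manifest["artifacts"]["footprints"] = _sha256(out / "footprints.npz")

        stage = "featurize"
        t0 = time.time()
        baselines, comparisons = split_baselines(footprints)
        vectors = build_delta_dataset(
            baselines, comparisons, cfg.feature_set, cfg.sham_ratio, cfg.seed
        )
        X, y, mag = dataset_arrays(vectors)
        X_amp, _, _ = dataset_arrays(vectors, feature_set=("trough_amplitude",))
        manifest["stages"][stage] = {
            "n_vectors": len(vectors), "n_valid": int(y.sum()),
            "n_sham": int((~y).sum()), "n_features": X.shape[1],
            "seconds": round(time.time() - t0, 2),
        }

        stage = "train"
        t0 = time.time()
        detector = train_detector(X, y, split_seed=cfg.seed, nca_cfg=NCAConfig(seed=cfg.seed))
        valid = y
        regressor = train_magnitude_regressor(X_amp[valid], mag[valid], split_seed=cfg.seed)
        manifest["stages"][stage] = {
            "detector": detector.metrics,
            "regressor": regressor.metrics,
            "seconds": round(time.time() - t0, 2),
        }

        stage = "kernel"
        t0 = time.time()
        lib = build_kernel_library(footprints, L=cfg.kernel_length)
        manifest["stages"][stage] = {
            "n_kernels": lib.n_kernels(), "d_grid": lib.d_grid.tolist(),
            "seconds": round(time.time() - t0, 2),
        }
        if out:
            lib.save_npz(out / "kernel_library.npz")
            manifest["artifacts"]["kernel_library"] = _sha256(out / "kernel_library.npz")
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        if out:
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest["seconds_total"] = round(time.time() - t_start, 2)
    if out:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


# ---------------------------------------------------------------------------
# synthetic fixtures (no simulator required)

def biphasic_pulse(n: int, trough_sample: int, amplitude: float = 50.0,
                   sigma_samples: float = 6.0, fs: float = 32000.0) -> np.ndarray:
    """Negative biphasic spike-like pulse: sharp trough, slower rebound."""
    t = np.arange(n)
    w = -amplitude * np.exp(-0.5 * ((t - trough_sample) / sigma_samples) ** 2)
    w += 0.35 * amplitude * np.exp(-0.5 * ((t - trough_sample - 3 * sigma_samples) / (2 * sigma_samples)) ** 2)
    return w


def make_fixture(kind: str, seed: int = 0):
    """Deterministic unit-test inputs.

    - ``waveform_pair``: (x, y, h) where y = x * h with a known short kernel.
    - ``footprint``: a 900-electrode footprint with a sink moving along a
      synthetic axon path (returns the Footprint and the probe).
    - ``dataset``: balanced valid/sham delta vectors with a planted
      separating feature (returns X, y).
    """
    rng = np.random.default_rng(seed)
    if kind == "waveform_pair":
        n = 96
        x = biphasic_pulse(n, 32, amplitude=40 + 10 * rng.random())
        h = np.zeros(9)
        h[0], h[2], h[5] = 0.8, 0.35, -0.15
        y = np.convolve(x, h)[:n]
        return x, y, h
    if kind == "footprint":
        probe = build_probe()
        n = 96
        fs = 32000.0
        soma = np.array([0.0, 0.0, 10.0])
        axon_dir = np.array([1.0, 0.0, 0.0])
        sink = soma + (20.0 + 20.0 * rng.random()) * axon_dir
        d = np.linalg.norm(probe.centers - sink, axis=1)
        amp = 120.0 / np.maximum(d / 10.0, 1.0) ** 1.5
        lat = (d / 300.0) * fs / 1000.0  # samples of propagation delay
        wf = np.stack(
            [biphasic_pulse(n, int(24 + li), ai) for ai, li in zip(amp, lat)]
        )
        fp = Footprint(wf, np.arange(probe.n_electrodes), fs, (0, n),
                       meta={"offset": (0.0, 0.0), "theta_deg": 0.0, "d_ais": 5.0})
        return fp, probe
    if kind == "dataset":
        n_per, p = 120, 24
        X = rng.normal(size=(2 * n_per, p))
        y = np.zeros(2 * n_per, dtype=bool)
        y[:n_per] = True
        X[y, 3] += 3.0  # planted separating feature
        perm = rng.permutation(2 * n_per)
        return X[perm], y[perm]
    raise ValueError(f"unknown fixture kind {kind!r}")
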