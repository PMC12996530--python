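"""Desk-scale benchmark experiments.

Self-contained, seeded experiments that exercise the full pipeline at
sizes a single CPU handles in minutes: printed-value arithmetic checks,
simulator increment statistics, Cramer-Rao bound attainment by reference
estimators, and a scaled-down training run of the vision transformer on
a three-point molecular-weight grid.  Both the test suite and the
reproduction script drive these functions.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy import stats

from . import hvit
from .properties import (
    crlb_amplitude,
    crlb_diffusivity,
    increment_diffusivity_estimator,
    matched_filter_amplitude,
    precision_vs_n,
)
from .simulate import (
    ChannelGeometry,
    Kymograph,
    NoiseParams,
    OpticalParams,
    TrajectoryParams,
    render_molecule_response,
    sample_trajectory,
)

__all__ = [
    "printed_reference_values",
    "increment_statistics",
    "contrast_conservation",
    "diffusivity_crlb_benchmark",
    "amplitude_crlb_benchmark",
    "desk_training_benchmark",
]


def printed_reference_values() -> dict[str, float]:
    """Closed-form quantities of the experimental design, computed from
    the package's calculators (dsDNA ladder, channel geometry, coarse-grid
    size at 7 downsamplings, effective frame rate)."""
    from .properties import dsdna_length, dsdna_mw

    small_channel = ChannelGeometry(width_nm=63.0, depth_nm=30.0)
    return {
        "dsdna_mw_200bp_kda": dsdna_mw(200),
        "dsdna_mw_100bp_kda": dsdna_mw(100),
        "dsdna_mw_50bp_kda": dsdna_mw(50),
        "dsdna_length_200bp_nm": dsdna_length(200),
        "dsdna_length_100bp_nm": dsdna_length(100),
        "dsdna_length_50bp_nm": dsdna_length(50),
        "channel_area_nm2": small_channel.area_nm2,
        "probability_map_space_bins": 512 / 2**7,
        "frame_rate_hz": 1.0 / TrajectoryParams(D=1.0).dt,
    }


def increment_statistics(seed: int, d_um2_s: float = 40.0, v_um_s: float = 2.0,
                         dt: float = 0.005, k: int = 100_000) -> dict[str, float]:
    """Empirical increment mean/variance of a long trajectory against the
    drift-diffusion theory values, with their standard errors."""
    geometry = ChannelGeometry(width_nm=63.0, depth_nm=30.0)
    rng = np.random.default_rng(seed)
    traj = sample_trajectory(
        TrajectoryParams(D=d_um2_s, v=v_um_s, dt=dt, x0=0.0, k=k),
        geometry, rng=rng)
    inc = np.diff(traj.positions)
    var_true = 2.0 * d_um2_s * 1e6 * dt
    mean_true = v_um_s * 1e3 * dt
    return {
        "mean_nm": float(inc.mean()),
        "mean_true_nm": mean_true,
        "mean_se_nm": float(np.sqrt(var_true / inc.size)),
        "var_nm2": float(inc.var(ddof=1)),
        "var_true_nm2": var_true,
        "var_se_nm2": float(var_true * np.sqrt(2.0 / (inc.size - 1))),
    }


def contrast_conservation(seed: int, ioc: float = 10.0, s: float = 300.0,
                          n_frames: int = 200) -> dict[str, float]:
    """Worst-case relative error of the per-frame integrated contrast
    deficit against iOC, for a molecule kept safely in view."""
    geometry = ChannelGeometry(width_nm=63.0, depth_nm=30.0, n_pixels=512)
    rng = np.random.default_rng(seed)
    traj = sample_trajectory(
        TrajectoryParams(D=1.0, x0=geometry.view_length_nm / 2, k=n_frames),
        geometry, rng=rng)
    resp = render_molecule_response(traj, OpticalParams(ioc=ioc, s=s), geometry)
    margin = 6 * s
    inside = ((traj.positions > margin)
              & (traj.positions < geometry.view_length_nm - margin))
    integrals = geometry.pixel_size_nm * (1.0 - resp[inside]).sum(axis=1)
    rel_err = np.abs(integrals - ioc) / ioc
    return {"max_rel_err": float(rel_err.max()), "n_frames_checked":
            int(inside.sum()), "ioc": ioc}


def diffusivity_crlb_benchmark(seed: int, n_grid=(100, 1000, 10_000),
                               replicates: int = 500, d_um2_s: float = 40.0,
                               dt: float = 0.005) -> dict:
    """Empirical relative sigma of the increment-ML diffusivity estimator
    vs. the sqrt(2/N) bound."""
    rng = np.random.default_rng(seed)
    sd = np.sqrt(2.0 * d_um2_s * 1e6 * dt)

    def simulate(n, r):
        return np.concatenate([[0.0], np.cumsum(r.standard_normal(n) * sd)])

    emp, curve = precision_vs_n(
        lambda pos: increment_diffusivity_estimator(pos, dt),
        simulate, list(n_grid), replicates, rng, bound=crlb_diffusivity)
    return {
        "n_grid": list(n_grid),
        "empirical": [float(x) for x in emp],
        "bound": list(curve.sigma_rel_rs),
        "ratio": [float(e / b) for e, b in zip(emp, curve.sigma_rel_rs)],
    }


def amplitude_crlb_benchmark(seed: int, n: int = 10_000, replicates: int = 500,
                             snr_eff: float = 0.1) -> dict:
    """Matched-filter amplitude estimation in white noise at per-frame
    effective SNR ``snr_eff`` against the 1/(snr sqrt(N)) bound."""
    rng = np.random.default_rng(seed)
    template = np.exp(-0.5 * ((np.arange(64) - 32.0) / 4.0) ** 2)
    template /= np.linalg.norm(template)   # unit energy: amp 1/sigma = snr_eff
    estimates = np.empty(replicates)
    for i in range(replicates):
        frames = snr_eff * template[None, :] + rng.standard_normal((n, 64))
        estimates[i] = matched_filter_amplitude(frames, template)
    emp = float(estimates.std(ddof=1) / estimates.mean())
    bound = crlb_amplitude(n, snr_eff)
    return {"n": n, "empirical": emp, "bound": bound, "ratio": emp / bound}


# ---------------------------------------------------------------------------
# scaled-down learning benchmark
# ---------------------------------------------------------------------------

DESK_MW_GRID = (5.0, 15.0, 30.0)
DESK_SHAPE = (64, 128)


def desk_sim_config() -> hvit.SimConfig:
    """High-SNR desk-scale generator: 50 x 50 nm^2 channel, fixed noise
    level, slow diffusion so the molecule stays in view of a 64-frame
    kymograph."""
    geometry = ChannelGeometry(width_nm=50.0, depth_nm=50.0,
                               n_pixels=DESK_SHAPE[1])
    noise = NoiseParams(sampling_ranges={
        **NoiseParams().sampling_ranges,
        "x0_bg": (geometry.view_length_nm / 2, geometry.view_length_nm / 8),
        "lambda_bg": (2000.0, 4000.0),
        "n_theta": (1.0e-4, 1.0e-4),
        "d_x": (0.0, 0.2),
        "amp_A": (0.0, 0.0),
    })
    return hvit.SimConfig(geometry=geometry, noise=noise,
                          gaussian_width_nm=150.0,
                          d_range_um2_s=(2.0, 10.0),
                          mw_values=DESK_MW_GRID, p_empty=0.25)


def desk_arch_config() -> hvit.ArchConfig:
    return hvit.ArchConfig(n_scales=3, filters_per_scale=(8, 16, 32),
                           embed_dim=32, n_heads=4, mlp_dim=64,
                           n_transformer_blocks=2,
                           prop_scales=(30.0, 3.0, float(DESK_SHAPE[0])))


def desk_training_benchmark(seed: int, steps: int = 200, batch_size: int = 8,
                            n_eval: int = 12, n_controls: int = 24) -> dict:
    """Train the tiny network ``steps`` steps on the three-point MW grid
    and evaluate: loss trend, MW rank order across the grid (Spearman),
    and probability-total separation of signal vs. pure-noise kymographs
    (paired sign test).
    """
    sim = desk_sim_config()
    tcfg = hvit.TrainConfig(kymo_shape=DESK_SHAPE, steps=steps,
                            batch_size=batch_size, validation_every=50,
                            n_validation=16, learning_rate=2e-3,
                            mw_range=(DESK_MW_GRID[0], DESK_MW_GRID[-1]),
                            rs_range=(1.0, 2.7), seed=seed)
    model = hvit.build_model(desk_arch_config(), DESK_SHAPE, seed=seed)
    history = hvit.train(model, sim, tcfg)

    rng = np.random.default_rng(seed + 10_000)
    geometry = sim.geometry
    class_means, class_sds, signal_totals = [], [], []
    for mw in DESK_MW_GRID:
        fixed = replace(sim, mw_values=(mw,))
        preds, totals = [], []
        for _ in range(n_eval):
            values, _, _ = hvit._simulate_training_kymograph(
                fixed, DESK_SHAPE, (mw, mw), tcfg.rs_range, rng,
                force_empty=False)
            kymo = Kymograph(values=values, geometry=geometry, dt=0.005)
            _, _, est = hvit.predict(model, kymo)
            preds.append(est.mw_kDa)
            totals.append(est.p_total)
        class_means.append(float(np.mean(preds)))
        class_sds.append(float(np.std(preds)))
        signal_totals.extend(totals)
    noise_totals = []
    for _ in range(n_controls):
        values, _, _ = hvit._simulate_training_kymograph(
            sim, DESK_SHAPE, tcfg.mw_range, tcfg.rs_range, rng,
            force_empty=True)
        kymo = Kymograph(values=values, geometry=geometry, dt=0.005)
        _, _, est = hvit.predict(model, kymo)
        noise_totals.append(est.p_total)

    spearman = float(stats.spearmanr(class_means, DESK_MW_GRID).statistic)
    paired = min(len(signal_totals), len(noise_totals))
    wins = int(sum(s > n for s, n
                   in zip(signal_totals[:paired], noise_totals[:paired])))
    sign_p = float(stats.binomtest(wins, paired, 0.5,
                                   alternative="greater").pvalue)
    first = history["train_loss"][0]
    last = float(np.mean(history["train_loss"][-10:]))
    return {
        "train_loss_first": first,
        "train_loss_last10": last,
        "loss_decreased": bool(last < first),
        "mw_grid": list(DESK_MW_GRID),
        "mw_pred_means": class_means,
        "mw_pred_sds": class_sds,
        "spearman_mw": spearman,
        "signal_p_total_mean": float(np.mean(signal_totals)),
        "noise_p_total_mean": float(np.mean(noise_totals)),
        "sign_test_wins": wins,
        "sign_test_n": paired,
        "sign_test_p": sign_p,
        "history": {"train_loss": history["train_loss"],
                    "val_loss": history["val_loss"]},
    }
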