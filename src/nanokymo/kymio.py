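"""Kymograph file I/O and deterministic packaged fixtures.

HDF5 is the canonical format (values + geometry/time metadata + ground
truth); TIFF is supported for interoperability with microscopy tooling
and carries values only (missing metadata falls back to documented
defaults with a logged warning).
"""

from __future__ import annotations

import logging
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .properties import ConversionConstants, mw_to_ioc, rs_to_d
from .simulate import (
    ChannelGeometry,
    Kymograph,
    NoiseParams,
    OpticalParams,
    Trajectory,
    TrajectoryParams,
    render_molecule_response,
    sample_background,
    sample_trajectory,
    synthesize_kymograph,
)

__all__ = ["read_kymograph", "write_kymograph", "fixtures"]

logger = logging.getLogger(__name__)

DEFAULT_PIXEL_SIZE_NM = 27.4
DEFAULT_DT_S = 0.005


def write_kymograph(kymo: Kymograph, path: str | Path) -> None:
    """Write to HDF5 (.h5/.hdf5, lossless incl. metadata) or TIFF (.tif)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=kymo.values)
            f.attrs["dt"] = kymo.dt
            f.attrs["pixel_size_nm"] = kymo.geometry.pixel_size_nm
            f.attrs["width_nm"] = kymo.geometry.width_nm
            f.attrs["depth_nm"] = kymo.geometry.depth_nm
            f.attrs["area_nm2"] = kymo.geometry.area_nm2
            f.attrs["n_pixels"] = kymo.geometry.n_pixels
            f.attrs["provenance"] = kymo.provenance
            if kymo.ground_truth:
                grp = f.create_group("ground_truth")
                for i, (traj, opt) in enumerate(kymo.ground_truth):
                    m = grp.create_group(f"molecule_{i:03d}")
                    m.create_dataset("positions_nm", data=traj.positions)
                    m.attrs["D_um2_s"] = traj.params.D
                    m.attrs["v_um_s"] = traj.params.v
                    m.attrs["dt"] = traj.params.dt
                    m.attrs["k"] = traj.params.k
                    m.attrs["seed"] = traj.params.seed
                    m.attrs["n_in_view"] = traj.n_in_view
                    m.attrs["ioc"] = opt.ioc
                    m.attrs["s_nm"] = opt.s
    elif suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, kymo.values.astype(np.float32))
    else:
        raise ValueError(f"unsupported format: {suffix}")


def read_kymograph(path: str | Path) -> Kymograph:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            values = f["values"][()]
            geom = ChannelGeometry(
                width_nm=float(f.attrs.get("width_nm", 63.0)),
                depth_nm=float(f.attrs.get("depth_nm", 30.0)),
                pixel_size_nm=float(f.attrs.get("pixel_size_nm",
                                                DEFAULT_PIXEL_SIZE_NM)),
                n_pixels=int(f.attrs.get("n_pixels", values.shape[1])),
                area_nm2=float(f.attrs["area_nm2"])
                if "area_nm2" in f.attrs else None,
            )
            dt = float(f.attrs.get("dt", DEFAULT_DT_S))
            provenance = str(f.attrs.get("provenance", "measured"))
            truths = None
            if "ground_truth" in f:
                truths = []
                for name in sorted(f["ground_truth"]):
                    m = f["ground_truth"][name]
                    positions = m["positions_nm"][()]
                    params = TrajectoryParams(
                        D=float(m.attrs["D_um2_s"]), v=float(m.attrs["v_um_s"]),
                        dt=float(m.attrs["dt"]), x0=float(positions[0]),
                        k=int(m.attrs["k"]), seed=int(m.attrs["seed"]),
                    )
                    traj = Trajectory(positions=positions, params=params,
                                      n_in_view=int(m.attrs["n_in_view"]))
                    truths.append(
                        (traj, OpticalParams(ioc=float(m.attrs["ioc"]),
                                             s=float(m.attrs["s_nm"])))
                    )
        return Kymograph(values=values, geometry=geom, dt=dt,
                         provenance=provenance, ground_truth=truths)
    if suffix in (".tif", ".tiff"):
        values = np.asarray(tifffile.imread(path), dtype=np.float64)
        logger.warning(
            "TIFF carries no geometry metadata; applying defaults "
            "(pixel size %.1f nm, dt %.3f s)", DEFAULT_PIXEL_SIZE_NM, DEFAULT_DT_S,
        )
        geom = ChannelGeometry(width_nm=63.0, depth_nm=30.0,
                               pixel_size_nm=DEFAULT_PIXEL_SIZE_NM,
                               n_pixels=values.shape[1])
        return Kymograph(values=values, geometry=geom, dt=DEFAULT_DT_S,
                         provenance="measured")
    raise ValueError(f"unsupported format: {suffix}")


#: fixture study design: three molecular-weight classes bracketing a
#: dsDNA-ladder-style experiment plus a buffer-only control.
FIXTURE_CLASSES: dict[str, tuple[float, float] | None] = {
    "class_132kDa": (132.0, 5.7),
    "class_66kDa": (66.0, 4.9),
    "class_33kDa": (33.0, 4.0),
    "control": None,
}


def fixtures(seed: int, out_dir: str | Path, n_per_class: int = 24,
             shape: tuple[int, int] = (128, 256),
             n_debug: int = 6) -> pd.DataFrame:
    """Deterministic synthetic test dataset emulating a ladder experiment.

    Writes ``n_per_class`` kymographs for each of three MW classes and a
    molecule-free control, plus a high-SNR debugging set with clearly
    visible trajectories, and returns the ground-truth manifest (also
    written as ``manifest.csv``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    const = ConversionConstants()
    geom = ChannelGeometry(width_nm=122.0, depth_nm=97.0, n_pixels=shape[1])
    noise = NoiseParams(sampling_ranges={
        **NoiseParams().sampling_ranges,
        "x0_bg": (geom.view_length_nm / 2, geom.view_length_nm / 8),
        "lambda_bg": (geom.view_length_nm / 2, geom.view_length_nm),
    })
    rows = []

    def one(name: str, mw_rs: tuple[float, float] | None,
            ioc_override: float | None = None) -> None:
        truths, responses = [], []
        mw = rs = ioc = d = np.nan
        n_points = 0
        if mw_rs is not None:
            mw, rs = mw_rs
            ioc = ioc_override if ioc_override is not None \
                else mw_to_ioc(mw, geom.area_nm2, const)
            d = rs_to_d(rs, const)
            params = TrajectoryParams(D=d, v=0.0, dt=DEFAULT_DT_S, x0="uniform",
                                      k=shape[0], seed=int(rng.integers(2**31)))
            traj = sample_trajectory(params, geom, rng=rng)
            opt = OpticalParams(ioc=ioc, s=300.0)
            responses.append(render_molecule_response(traj, opt, geom))
            truths.append((traj, opt))
            n_points = traj.n_in_view
        bg = sample_background(noise.draw(rng), shape, geom, rng=rng)
        kymo = synthesize_kymograph(responses, bg, geom, DEFAULT_DT_S,
                                    ground_truth=truths or None)
        write_kymograph(kymo, out_dir / f"{name}.h5")
        rows.append({"file": f"{name}.h5", "mw_kDa": mw, "rs_nm": rs,
                     "ioc": ioc, "D_um2_s": d, "N": n_points})

    for cls, mw_rs in FIXTURE_CLASSES.items():
        for i in range(n_per_class):
            one(f"{cls}_{i:02d}", mw_rs)
    for i in range(n_debug):  # high-SNR set: contrast far above the noise
        one(f"debug_highsnr_{i:02d}", (132.0, 5.7),
            ioc_override=50.0 * mw_to_ioc(132.0, geom.area_nm2, const))

    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
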