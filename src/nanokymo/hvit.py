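"""Hierarchical vision transformer for kymograph property regression.

The network ingests a standardized kymograph (time x channel position)
plus the nanochannel cross-section area and emits, on a coarse grid
downsampled by 2^n_scales in both axes:

* a probability map — per-bin likelihood that a molecule trajectory
  crosses that space-time cell (sigmoid head, binary cross-entropy
  against a ground-truth occupancy raster), and
* a property map — per-bin molecular weight (kDa), hydrodynamic radius
  (nm) and trajectory-point count predictions (softplus heads, L1 loss),

together with per-scale scalar property predictions from globally pooled
convolutional features.  The final scalar estimate for each property is
the probability-weighted mean of its property map, so bins the model is
confident about dominate the readout.

Training data is simulated on the fly: every batch draws fresh
trajectories, optical parameters and background noise, with molecular
weight and radius ranges widened over curriculum stages as the loss
plateaus.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from typing import Sequence

import numpy as np

from . import nn
from .preprocess import lowpass_subtract
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
)

__all__ = [
    "ArchConfig",
    "TrainConfig",
    "SimConfig",
    "ProbabilityMap",
    "PropertyMap",
    "MoleculeEstimate",
    "HViT",
    "build_model",
    "standardize_kymograph",
    "rasterize_ground_truth",
    "loss",
    "train",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArchConfig:
    """Architecture hyperparameters.

    The full-scale configuration uses 7 scales on 512-pixel-long
    kymographs (hence 512/2^7 = 4 probability-map columns); the desk
    default of 4 scales keeps CPU training tractable while preserving
    the architecture.
    """

    n_scales: int = 4
    initial_kernel: int = 7
    filters_per_scale: tuple[int, ...] | None = None
    patch_size: int = 1
    embed_dim: int = 64
    n_heads: int = 4
    mlp_dim: int = 128
    n_transformer_blocks: int = 2
    leaky_slope: float = 0.1
    # output scaling of the (MW kDa, Rs nm, N points) heads so each target
    # is O(1) for the optimizer; set N to the kymograph frame budget
    prop_scales: tuple[float, float, float] = (30.0, 3.0, 10000.0)

    def __post_init__(self):
        if self.n_scales < 1:
            raise ValueError("n_scales must be >= 1")
        if self.filters_per_scale is None:
            object.__setattr__(
                self, "filters_per_scale",
                tuple(8 * 2 ** min(i, 2) for i in range(self.n_scales)),
            )
        elif len(self.filters_per_scale) != self.n_scales:
            raise ValueError("filters_per_scale must have n_scales entries")
        if any(b < a for a, b in zip(self.filters_per_scale,
                                     self.filters_per_scale[1:])):
            raise ValueError("filters_per_scale must be non-decreasing")


@dataclass(frozen=True)
class SimConfig:
    """On-the-fly training-data generator settings.

    ``p_empty`` is the fraction of generated kymographs containing no
    molecule (buffer-only), which teaches the probability head to stay
    low on pure noise.  ``gaussian_width_nm`` is the optical response
    width s; ``highpass_window`` the preprocessing window applied to the
    raw product stack before standardization.
    """

    geometry: ChannelGeometry = field(
        default_factory=lambda: ChannelGeometry(width_nm=63.0, depth_nm=30.0)
    )
    noise: NoiseParams = field(default_factory=NoiseParams)
    constants: ConversionConstants = field(default_factory=ConversionConstants)
    gaussian_width_nm: float = 300.0
    d_range_um2_s: tuple[float, float] | None = None  # derived from rs if None
    mw_values: tuple[float, ...] | None = None        # discrete MW grid if set
    p_empty: float = 0.25
    highpass_window: int = 200


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings; defaults follow the full-scale recipe
    (ADAM, learning rate 1e-4, MW 0-30 kDa, Rs 0.7-3 nm) with desk-scale
    kymograph shape and step counts."""

    optimizer: str = "adam"
    learning_rate: float = 1e-4
    kymo_shape: tuple[int, int] = (512, 512)
    mw_range: tuple[float, float] = (0.0, 30.0)
    rs_range: tuple[float, float] = (0.7, 3.0)
    curriculum: tuple[dict, ...] = ()
    steps: int = 200
    batch_size: int = 4
    validation_every: int = 50
    n_validation: int = 150
    lam: float = 1.0
    plateau_patience: int = 20
    plateau_tol: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        for lo, hi in (self.mw_range, self.rs_range):
            if lo > hi:
                raise ValueError("ranges must be proper intervals")


# ---------------------------------------------------------------------------
# output containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbabilityMap:
    """Per-bin molecule-presence likelihood on the coarse space-time grid."""

    values: np.ndarray          # (time_bins, space_bins) in [0, 1]
    frames_per_bin: int
    nm_per_bin: float

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.min() < 0.0 or v.max() > 1.0:
            raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class PropertyMap:
    """Per-bin (MW kDa, Rs nm, N points) predictions and per-scale scalars."""

    mw_kDa: np.ndarray
    rs_nm: np.ndarray
    n_points: np.ndarray
    per_scale: np.ndarray       # (n_scales, 3)

    def __post_init__(self):
        for arr in (self.mw_kDa, self.rs_nm, self.n_points, self.per_scale):
            if not np.all(np.isfinite(arr)):
                raise ValueError("property predictions must be finite")
            if np.any(np.asarray(arr) < 0):
                raise ValueError("property predictions must be non-negative")


@dataclass(frozen=True)
class MoleculeEstimate:
    """Probability-weighted per-kymograph estimate."""

    mw_kDa: float
    rs_nm: float
    n_points: float
    p_total: float
    accepted: bool = False
    defined: bool = True

    def __post_init__(self):
        if self.p_total < 0:
            raise ValueError("p_total must be non-negative")
        if self.defined and self.n_points < 0:
            raise ValueError("n_points must be non-negative")


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

def standardize_kymograph(values: np.ndarray) -> np.ndarray:
    """Standardize by the temporal standard deviation.

    The per-pixel temporal mean is subtracted first (documented default),
    then the frame is divided by the mean temporal standard deviation of
    the kymograph; an all-constant input passes through as zeros.
    """
    v = np.asarray(values, dtype=np.float64)
    centred = v - v.mean(axis=0, keepdims=True)
    scale = v.std(axis=0).mean()
    if scale == 0.0:
        return centred
    return centred / scale


class HViT(nn.Module):
    """Multi-scale convolution + patch-encoded transformer network."""

    def __init__(self, arch: ArchConfig, input_shape: tuple[int, int],
                 seed: int = 0):
        t, x = input_shape
        div = 2 ** arch.n_scales
        if t % div or x % div:
            raise ValueError(
                f"input shape {input_shape} not divisible by 2^{arch.n_scales}"
            )
        self.arch = arch
        self.input_shape = (t, x)
        self.grid_shape = (t // div, x // div)
        p = arch.patch_size
        if self.grid_shape[0] % p or self.grid_shape[1] % p:
            raise ValueError("coarse grid not divisible by patch_size")
        rng = np.random.default_rng(seed)
        filters = arch.filters_per_scale
        self.stem = nn.Conv2d(1, filters[0], arch.initial_kernel, rng)
        self.blocks = [
            nn.Conv2d(filters[max(i - 1, 0)], filters[i], 3, rng)
            for i in range(arch.n_scales)
        ]
        self.pool = nn.MaxPool2d()
        self.scale_prob = [nn.Conv2d(filters[i], 1, 1, rng)
                           for i in range(arch.n_scales)]
        self.scale_props = [nn.Dense(filters[i], 3, rng)
                            for i in range(arch.n_scales)]
        n_patches = (self.grid_shape[0] // p) * (self.grid_shape[1] // p)
        self.encoder = nn.PatchEncoder(n_patches, filters[-1] * p * p,
                                       arch.embed_dim, rng)
        self.area_embed = nn.Dense(1, arch.embed_dim, rng)
        self.transformers = [
            nn.TransformerBlock(arch.embed_dim, arch.n_heads, arch.mlp_dim,
                                rng, arch.leaky_slope)
            for _ in range(arch.n_transformer_blocks)
        ]
        self.head_prob = nn.Dense(arch.embed_dim, p * p, rng)
        self.head_props = nn.Dense(arch.embed_dim, 3 * p * p, rng)
        self.fuse = nn.Conv2d(arch.n_scales + 1, 1, 3, rng)

    # -- helpers -------------------------------------------------------
    @staticmethod
    def _avg_pool(x: nn.Tensor, factor: int) -> nn.Tensor:
        if factor == 1:
            return x
        b, c, h, w = x.shape
        y = x.reshape(b, c, h // factor, factor, w // factor, factor)
        return y.mean(axis=(3, 5))

    def _tokens_to_grid(self, x: nn.Tensor, channels: int) -> nn.Tensor:
        """(B, n_patches, p*p*channels) -> (B, channels, Tg, Xg)."""
        p = self.arch.patch_size
        tg, xg = self.grid_shape
        b = x.shape[0]
        y = x.reshape(b, tg // p, xg // p, p, p, channels)
        y = y.transpose((0, 5, 1, 3, 2, 4))
        return y.reshape(b, channels, tg, xg)

    def forward(self, kymos: np.ndarray, area_nm2: np.ndarray) -> dict:
        """Run the network on a standardized batch (B, T, X).

        Returns tensors: ``prob_logits``/``prob`` (B, Tg, Xg), ``props``
        (B, Tg, Xg, 3, non-negative) and ``scale_props`` (list over
        scales of (B, 3)).
        """
        kymos = np.asarray(kymos, dtype=np.float64)
        if kymos.ndim == 2:
            kymos = kymos[None]
        if kymos.shape[1:] != self.input_shape:
            raise ValueError(
                f"input shape {kymos.shape[1:]} != model shape {self.input_shape}"
            )
        area = np.atleast_1d(np.asarray(area_nm2, dtype=np.float64))
        slope = self.arch.leaky_slope
        x = nn.Tensor(kymos[:, None])                       # (B, 1, T, X)
        x = self.stem(x).leaky_relu(slope)

        scale_logits: list[nn.Tensor] = []
        scale_props: list[nn.Tensor] = []
        prop_scale = nn.Tensor(np.array(self.arch.prop_scales))
        for i, conv in enumerate(self.blocks):
            x = self.pool(conv(x).leaky_relu(slope))
            factor = 2 ** (self.arch.n_scales - 1 - i)
            scale_logits.append(self._avg_pool(self.scale_prob[i](x), factor))
            pooled = x.mean(axis=(2, 3))                    # (B, C)
            scale_props.append(
                self.scale_props[i](pooled).softplus() * prop_scale
            )

        # patch-encode the coarsest feature map and apply the transformer
        b = x.shape[0]
        p = self.arch.patch_size
        tg, xg = self.grid_shape
        c = x.shape[1]
        patches = x.reshape(b, c, tg // p, p, xg // p, p)
        patches = patches.transpose((0, 2, 4, 3, 5, 1))
        patches = patches.reshape(b, (tg // p) * (xg // p), p * p * c)
        tokens = self.encoder(patches)
        area_feat = nn.Tensor(np.log10(area)[:, None, None] / 4.0)  # (B, 1, 1)
        tokens = tokens + self.area_embed(area_feat)
        for block in self.transformers:
            tokens = block(tokens)

        token_logits = self._tokens_to_grid(self.head_prob(tokens), 1)
        fused = nn.cat(scale_logits + [token_logits], axis=1)
        prob_logits = self.fuse(fused).reshape(b, tg, xg)
        props = self._tokens_to_grid(self.head_props(tokens), 3)
        props = props.transpose((0, 2, 3, 1)).softplus() * prop_scale  # (B,Tg,Xg,3)
        return {
            "prob_logits": prob_logits,
            "prob": prob_logits.sigmoid(),
            "props": props,
            "scale_props": scale_props,
        }

    __call__ = forward


def build_model(arch: ArchConfig, input_shape: tuple[int, int] = (512, 512),
                seed: int = 0) -> HViT:
    return HViT(arch, input_shape, seed=seed)


# ---------------------------------------------------------------------------
# targets and loss
# ---------------------------------------------------------------------------

def rasterize_ground_truth(truths: Sequence[tuple[Trajectory, OpticalParams]],
                           map_shape: tuple[int, int],
                           geometry: ChannelGeometry,
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Occupancy raster and per-bin point counts for the coarse grid.

    A bin is occupied (1) if any molecule position falls inside its
    space-time cell; positions outside the imaged segment never occupy.
    Returns ``(occupancy, counts)``, both of ``map_shape``.
    """
    tb, xb = map_shape
    counts = np.zeros((tb, xb))
    for traj, _ in truths:
        k = traj.params.k
        frames_per_bin = k / tb
        nm_per_bin = geometry.view_length_nm / xb
        in_view = (traj.positions >= 0) & (traj.positions < geometry.view_length_nm)
        f_idx = np.minimum((np.arange(k) / frames_per_bin).astype(int), tb - 1)
        x_idx = np.minimum((traj.positions / nm_per_bin).astype(int), xb - 1)
        np.add.at(counts, (f_idx[in_view], x_idx[in_view]), 1.0)
    occupancy = (counts > 0).astype(np.float64)
    return occupancy, counts


def binary_cross_entropy(logits: nn.Tensor, targets: np.ndarray) -> nn.Tensor:
    """Mean BCE with logits: softplus(z) - z*y, numerically stable."""
    y = nn.Tensor(np.asarray(targets, dtype=np.float64))
    return (logits.softplus() - logits * y).mean()


def loss(outputs: dict, occupancy: np.ndarray, truth_props: np.ndarray,
         lam: float = 1.0) -> tuple[nn.Tensor, dict]:
    """Total loss: BCE(probability map) + lam * sum-over-scales L1(props).

    ``truth_props`` is (B, 3): per-kymograph (MW kDa, Rs nm, N points).
    The final property map is additionally supervised with L1 on occupied
    bins (each occupied bin targets the kymograph-level truth).
    """
    prob_logits = outputs["prob_logits"]
    if prob_logits.shape != np.asarray(occupancy).shape:
        raise ValueError(
            f"occupancy shape {np.shape(occupancy)} != map {prob_logits.shape}"
        )
    truth = np.atleast_2d(np.asarray(truth_props, dtype=np.float64))
    bce = binary_cross_entropy(prob_logits, occupancy)

    l1_scales = nn.Tensor(0.0)
    for preds in outputs["scale_props"]:
        err = preds - nn.Tensor(truth)
        # per scale: mean over batch of the summed absolute property errors
        l1_scales = l1_scales + ((err * err + 1e-12) ** 0.5).sum(axis=1).mean()

    occ = np.asarray(occupancy, dtype=np.float64)
    map_l1 = nn.Tensor(0.0)
    n_occ = occ.sum()
    if n_occ > 0:
        props = outputs["props"]                      # (B, Tg, Xg, 3)
        target = np.broadcast_to(
            truth[:, None, None, :], props.shape
        )
        err = props - nn.Tensor(np.ascontiguousarray(target))
        w = nn.Tensor(occ[..., None] / n_occ)
        map_l1 = (((err * err + 1e-12) ** 0.5) * w).sum()

    total = bce + lam * (l1_scales + map_l1)
    parts = {
        "bce": bce.item(),
        "l1_scales": l1_scales.item(),
        "l1_map": map_l1.item(),
        "total": total.item(),
    }
    return total, parts


# ---------------------------------------------------------------------------
# data generation
# ---------------------------------------------------------------------------

def _simulate_training_kymograph(sim: SimConfig, shape: tuple[int, int],
                                 mw_range: tuple[float, float],
                                 rs_range: tuple[float, float],
                                 rng: np.random.Generator,
                                 force_empty: bool | None = None,
                                 ) -> tuple[np.ndarray, list, np.ndarray]:
    """One preprocessed kymograph, its ground truth and (MW, Rs, N) target."""
    frames, pixels = shape
    geom = replace(sim.geometry, n_pixels=pixels,
                   area_nm2=sim.geometry.area_nm2)
    empty = (rng.uniform() < sim.p_empty) if force_empty is None else force_empty
    truths: list[tuple[Trajectory, OpticalParams]] = []
    responses = []
    target = np.zeros(3)
    if not empty:
        if sim.mw_values is not None:
            mw = float(sim.mw_values[rng.integers(len(sim.mw_values))])
        else:
            mw = rng.uniform(max(mw_range[0], 1e-3), mw_range[1])
        rs = rng.uniform(*rs_range)
        ioc = mw_to_ioc(mw, geom.area_nm2, sim.constants)
        if sim.d_range_um2_s is not None:
            d = rng.uniform(*sim.d_range_um2_s)
        else:
            d = rs_to_d(rs, sim.constants)
        params = TrajectoryParams(D=d, v=0.0, dt=0.005, x0="uniform",
                                  k=frames, seed=int(rng.integers(2**31)))
        traj = sample_trajectory(params, geom, rng=rng)
        optical = OpticalParams(ioc=ioc, s=sim.gaussian_width_nm)
        responses.append(render_molecule_response(traj, optical, geom))
        truths.append((traj, optical))
        target = np.array([mw, rs, float(traj.n_in_view)])
    noise = sim.noise.draw(rng)
    background = sample_background(noise, shape, geom, rng=rng)
    raw = background.copy()
    for resp in responses:
        raw *= resp
    # raw product -> relative contrast -> high-pass, as in preprocessing
    mean = raw.mean(axis=0, keepdims=True)
    mean[mean <= 0] = 1.0
    norm = (raw - mean) / mean
    w = sim.highpass_window
    values = lowpass_subtract(norm, w, w)
    return values, truths, target


def make_batch(sim: SimConfig, shape: tuple[int, int], map_shape: tuple[int, int],
               mw_range: tuple[float, float], rs_range: tuple[float, float],
               batch_size: int, rng: np.random.Generator) -> dict:
    """Generate one training batch of standardized kymographs + targets."""
    geom = replace(sim.geometry, n_pixels=shape[1],
                   area_nm2=sim.geometry.area_nm2)
    kymos = np.empty((batch_size,) + shape)
    occupancy = np.empty((batch_size,) + map_shape)
    targets = np.empty((batch_size, 3))
    for i in range(batch_size):
        values, truths, target = _simulate_training_kymograph(
            sim, shape, mw_range, rs_range, rng
        )
        kymos[i] = standardize_kymograph(values)
        occupancy[i], _ = rasterize_ground_truth(truths, map_shape, geom)
        targets[i] = target
    areas = np.full(batch_size, geom.area_nm2)
    return {"kymos": kymos, "occupancy": occupancy, "targets": targets,
            "areas": areas}


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _plateaued(losses: list[float], patience: int, tol: float) -> bool:
    if len(losses) < 2 * patience:
        return False
    prev = float(np.mean(losses[-2 * patience : -patience]))
    last = float(np.mean(losses[-patience:]))
    if prev == 0:
        return True
    return (prev - last) / abs(prev) < tol


def train(model: HViT, sim: SimConfig, tcfg: TrainConfig) -> dict:
    """Train with ADAM on freshly simulated kymographs each step.

    Curriculum stages (if any) override the (MW, Rs) sampling ranges and
    advance when the training loss plateaus.  Returns a history dict with
    per-step losses, validation losses and the best-validation state dict.
    """
    rng = np.random.default_rng(tcfg.seed)
    val_rng = np.random.default_rng(tcfg.seed + 1)
    if tcfg.optimizer.lower() != "adam":
        raise ValueError("only the ADAM optimizer is supported")
    opt = nn.Adam(model.parameters(), lr=tcfg.learning_rate)
    shape = tuple(tcfg.kymo_shape)
    map_shape = model.grid_shape

    stages = list(tcfg.curriculum) or [
        {"mw_range": tcfg.mw_range, "rs_range": tcfg.rs_range}
    ]
    stage = 0

    def make_validation() -> dict:
        n = max(2, tcfg.n_validation)
        return make_batch(sim, shape, map_shape,
                          tuple(stages[stage]["mw_range"]),
                          tuple(stages[stage]["rs_range"]),
                          n, val_rng)

    val_batch = make_validation()
    history: dict = {"train_loss": [], "val_loss": [], "val_steps": [],
                     "stage": [], "parts": []}
    best_val = np.inf
    best_state: dict | None = None

    for step in range(tcfg.steps):
        batch = make_batch(sim, shape, map_shape,
                           tuple(stages[stage]["mw_range"]),
                           tuple(stages[stage]["rs_range"]),
                           tcfg.batch_size, rng)
        outputs = model(batch["kymos"], batch["areas"])
        total, parts = loss(outputs, batch["occupancy"], batch["targets"],
                            lam=tcfg.lam)
        if not np.isfinite(total.item()):
            raise RuntimeError(
                f"training diverged at step {step}: loss={total.item()!r}, "
                f"parts={parts!r}"
            )
        opt.zero_grad()
        total.backward()
        opt.step()
        history["train_loss"].append(total.item())
        history["stage"].append(stage)
        history["parts"].append(parts)

        if (step + 1) % tcfg.validation_every == 0 or step == tcfg.steps - 1:
            v_out = model(val_batch["kymos"], val_batch["areas"])
            v_loss, _ = loss(v_out, val_batch["occupancy"],
                             val_batch["targets"], lam=tcfg.lam)
            history["val_loss"].append(v_loss.item())
            history["val_steps"].append(step)
            if v_loss.item() < best_val:
                best_val = v_loss.item()
                best_state = model.state_dict()

        if stage + 1 < len(stages) and _plateaued(
            history["train_loss"], tcfg.plateau_patience, tcfg.plateau_tol
        ):
            stage += 1
            history.setdefault("stage_advances", []).append(step)
            val_batch = make_validation()

    history["best_val_loss"] = best_val
    history["best_state"] = best_state
    return history


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def predict(model: HViT, kymo: Kymograph, area_nm2: float | None = None,
            ) -> tuple[ProbabilityMap, PropertyMap, MoleculeEstimate]:
    """Probability-weighted property estimate for one kymograph.

    The kymograph is standardized internally; the estimate for each
    property theta is sum(P * theta) / sum(P) over bins.  When the map
    carries no probability mass the estimate is flagged undefined
    (fields zero) rather than NaN.
    """
    if area_nm2 is None:
        area_nm2 = kymo.geometry.area_nm2
    values = standardize_kymograph(kymo.values)
    out = model(values[None], np.array([area_nm2]))
    prob = out["prob"].data[0]
    props = out["props"].data[0]
    per_scale = np.stack([p.data[0] for p in out["scale_props"]])
    tg, xg = prob.shape
    pmap = ProbabilityMap(
        values=prob,
        frames_per_bin=kymo.n_frames // tg,
        nm_per_bin=kymo.geometry.view_length_nm / xg,
    )
    prop_map = PropertyMap(mw_kDa=props[..., 0], rs_nm=props[..., 1],
                           n_points=props[..., 2], per_scale=per_scale)
    p_total = float(prob.sum())
    if p_total == 0.0:
        est = MoleculeEstimate(0.0, 0.0, 0.0, 0.0, defined=False)
    else:
        w = prob / p_total
        est = MoleculeEstimate(
            mw_kDa=float((w * props[..., 0]).sum()),
            rs_nm=float((w * props[..., 1]).sum()),
            n_points=float((w * props[..., 2]).sum()),
            p_total=p_total,
        )
    return pmap, prop_map, est


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(model: HViT, path) -> None:
    """Single-file archive: parameters plus the embedded ArchConfig."""
    meta = {
        "arch": asdict(model.arch),
        "input_shape": list(model.input_shape),
    }
    state = model.state_dict()
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8
    ), **state)


def load_checkpoint(path) -> HViT:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    arch_dict = meta["arch"]
    arch_dict["filters_per_scale"] = tuple(arch_dict["filters_per_scale"])
    arch = ArchConfig(**arch_dict)
    model = HViT(arch, tuple(meta["input_shape"]))
    model.load_state_dict(state)
    return model
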