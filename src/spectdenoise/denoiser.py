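"""Conditional GAN that maps low-dose projection views to standard-dose views.

The generator is a six-level U-Net operating on single 64 x 64 projection
views: 4 x 4 stride-2 convolutions with encoder filter counts
(64, 128, 256, 512, 512, 512) down to a 1 x 1 bottleneck, batch
normalization in encoder blocks 2-4, LeakyReLU(0.2) in encoder blocks 1-5
and ReLU in block 6; six decoder blocks of stride-2 transposed convolutions
(512, 512, 256, 128, 64, 1) with skip concatenations into decoders 1-5,
dropout in decoder 1, ReLU after each concatenation and a sigmoid output.
No pooling layers are used anywhere.

The discriminator is conditional: it sees the low-dose view concatenated
channel-wise with a candidate standard-dose view and applies four 4 x 4
convolutional blocks (filters 48, 96, 192, 384; strides 2, 2, 2, 1; each
conv -> batch-norm -> LeakyReLU(0.2)) followed by a 1 x 1 single-filter
convolution, batch normalization and a sigmoid, yielding an 8 x 8 patch
probability map.

Both networks train concurrently with Adam (lr 0.001): the discriminator
minimizes binary cross-entropy on real/fake pairs, and the generator
minimizes adversarial BCE plus an L2 (mean-squared-error) term weighted
100:1 in favor of the L2 loss.  Views are normalized into [0, 1] by a single
global constant recorded with the model (required by the sigmoid output) and
predictions are inverse-scaled back to counts.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from . import nn
from .phantom import ProjectionSet

__all__ = [
    "GanSpec",
    "TrainConfig",
    "PairedViews",
    "Generator",
    "Discriminator",
    "GanModel",
    "build_generator",
    "build_discriminator",
    "make_paired_views",
    "train",
    "denoise",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class GanSpec:
    """Architecture hyperparameters of the generator and discriminator."""

    encoder_filters: tuple[int, ...] = (64, 128, 256, 512, 512, 512)
    decoder_filters: tuple[int, ...] = (512, 512, 256, 128, 64, 1)
    kernel: int = 4
    stride: int = 2
    encoder_bn_blocks: tuple[int, ...] = (2, 3, 4)  # 1-based block indices
    leaky_slope: float = 0.2
    n_skip_blocks: int = 5  # skip concatenations into decoders 1..5
    dropout_block: int = 1
    dropout_rate: float = 0.5
    disc_filters: tuple[int, ...] = (48, 96, 192, 384)
    disc_strides: tuple[int, ...] = (2, 2, 2, 1)
    disc_bn_first_block: bool = True
    init_std: float = 0.02

    def __post_init__(self) -> None:
        if len(self.encoder_filters) != 6 or len(self.decoder_filters) != 6:
            raise ValueError("generator must have six encoder and six decoder blocks")
        if self.decoder_filters[-1] != 1:
            raise ValueError("final decoder must produce a single channel")

    def scaled(self, factor: float) -> "GanSpec":
        """Width-reduced copy (same depth/topology) for CPU-scale experiments."""
        def s(v):
            return tuple(max(1, int(round(f * factor))) for f in v)
        return replace(
            self,
            encoder_filters=s(self.encoder_filters),
            decoder_filters=s(self.decoder_filters[:-1]) + (1,),
            disc_filters=s(self.disc_filters),
        )


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters (defaults follow the reference protocol)."""

    loss_weight_l2: float = 100.0
    loss_weight_adv: float = 1.0
    learning_rate: float = 0.001
    epochs: int = 50
    batch_size: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.loss_weight_l2 <= 0 or self.loss_weight_adv < 0:
            raise ValueError("loss weights must be positive (adv may be zero)")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be > 0")


@dataclass
class PairedViews:
    """Matched (low-dose input, standard-dose target) 2D views, normalized.

    Both arms are scaled by the same ``scale`` constant (counts per unit) so
    that targets lie in [0, 1]; inputs, having fewer counts, then lie in
    [0, ~dose_fraction].
    """

    inputs: np.ndarray  # (N, 64, 64) float32 in [0, 1]
    targets: np.ndarray
    scale: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.inputs.shape != self.targets.shape:
            raise ValueError("inputs and targets must have matching shapes")
        if self.inputs.ndim != 3:
            raise ValueError("views must be a (N, rows, cols) stack")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def __len__(self) -> int:
        return self.inputs.shape[0]


def make_paired_views(
    lowdose_sets: list[ProjectionSet],
    reference_sets: list[ProjectionSet],
    scale: float | None = None,
) -> PairedViews:
    """Stack per-view training pairs from matched projection sets.

    Each of the 32 views of a study is one training sample.  The
    normalization constant defaults to the maximum reference-view count over
    the whole set and is recorded for inverse scaling at inference.
    """
    if len(lowdose_sets) != len(reference_sets) or not lowdose_sets:
        raise ValueError("need equal, nonzero numbers of low-dose and reference sets")
    lo = np.concatenate([p.counts for p in lowdose_sets]).astype(np.float32)
    hi = np.concatenate([p.counts for p in reference_sets]).astype(np.float32)
    if scale is None:
        scale = float(hi.max())
        if scale <= 0:
            raise ValueError("reference views are empty; cannot derive a scale")
    return PairedViews(inputs=lo / scale, targets=hi / scale, scale=float(scale),
                       provenance={"n_sets": len(lowdose_sets),
                                   "dose_fraction": lowdose_sets[0].dose_fraction})


class Generator:
    """Six-level U-Net built from the primitive layers in :mod:`spectdenoise.nn`."""

    def __init__(self, spec: GanSpec, rng: np.random.Generator):
        self.spec = spec
        k, s = spec.kernel, spec.stride
        self.enc_convs: list[nn.Conv2d] = []
        self.enc_bns: list[nn.BatchNorm2d | None] = []
        self.enc_acts: list[nn.Layer] = []
        c_in = 1
        for i, f in enumerate(spec.encoder_filters, start=1):
            self.enc_convs.append(nn.Conv2d(c_in, f, k, s, rng, spec.init_std, f"enc{i}"))
            self.enc_bns.append(nn.BatchNorm2d(f, name=f"enc{i}.bn")
                                if i in spec.encoder_bn_blocks else None)
            self.enc_acts.append(nn.ReLU() if i == 6 else nn.LeakyReLU(spec.leaky_slope))
            c_in = f
        self.dec_convs: list[nn.ConvTranspose2d] = []
        self.dec_bns: list[nn.BatchNorm2d | None] = []
        self.dec_drops: list[nn.Dropout | None] = []
        self.dec_acts: list[nn.Layer] = []
        enc_f = spec.encoder_filters
        for i, f in enumerate(spec.decoder_filters, start=1):
            self.dec_convs.append(nn.ConvTranspose2d(c_in, f, k, s, rng, spec.init_std, f"dec{i}"))
            last = i == 6
            self.dec_bns.append(None if last else nn.BatchNorm2d(f, name=f"dec{i}.bn"))
            self.dec_drops.append(nn.Dropout(spec.dropout_rate, rng)
                                  if i == spec.dropout_block else None)
            self.dec_acts.append(nn.Sigmoid() if last else nn.ReLU())
            # decoder i concatenates the output of encoder block (6 - i)
            c_in = f if last else f + enc_f[5 - i]

    def layers(self) -> list[nn.Layer]:
        out: list[nn.Layer] = []
        for conv, bn, act in zip(self.enc_convs, self.enc_bns, self.enc_acts):
            out += [conv] + ([bn] if bn else []) + [act]
        for conv, bn, drop, act in zip(self.dec_convs, self.dec_bns, self.dec_drops, self.dec_acts):
            out += [conv] + ([bn] if bn else []) + ([drop] if drop else []) + [act]
        return out

    def params(self) -> list[nn.Param]:
        return [p for layer in self.layers() for p in layer.params()]

    def forward(self, x: np.ndarray, training: bool = True,
                collect_shapes: list | None = None) -> np.ndarray:
        if x.ndim == 3:
            x = x[:, None]
        if x.shape[2] % 64 or x.shape[3] % 64:
            raise ValueError(f"input spatial size {x.shape[2:]} must be divisible by 64 (2^6)")
        h = x.astype(np.float32)
        skips = []
        for conv, bn, act in zip(self.enc_convs, self.enc_bns, self.enc_acts):
            h = conv.forward(h, training)
            if bn is not None:
                h = bn.forward(h, training)
            h = act.forward(h, training)
            skips.append(h)
            if collect_shapes is not None:
                collect_shapes.append(h.shape)
        self._split_sizes = []
        for i, (conv, bn, drop, act) in enumerate(
            zip(self.dec_convs, self.dec_bns, self.dec_drops, self.dec_acts), start=1
        ):
            h = conv.forward(h, training)
            if bn is not None:
                h = bn.forward(h, training)
            if drop is not None:
                h = drop.forward(h, training)
            if i <= self.spec.n_skip_blocks:
                skip = skips[5 - i]
                self._split_sizes.append(h.shape[1])
                h = np.concatenate([h, skip], axis=1)
            h = act.forward(h, training)
            if collect_shapes is not None:
                collect_shapes.append(h.shape)
        return h

    def backward(self, dy: np.ndarray) -> np.ndarray:
        skip_grads: list[np.ndarray | None] = [None] * 6
        h = dy
        for i in range(6, 0, -1):
            conv = self.dec_convs[i - 1]
            bn = self.dec_bns[i - 1]
            drop = self.dec_drops[i - 1]
            act = self.dec_acts[i - 1]
            h = act.backward(h)
            if i <= self.spec.n_skip_blocks:
                split = self._split_sizes[i - 1]
                h, dskip = h[:, :split], h[:, split:]
                skip_grads[5 - i] = dskip
            if drop is not None:
                h = drop.backward(h)
            if bn is not None:
                h = bn.backward(h)
            h = conv.backward(h)
        for i in range(6, 0, -1):
            conv = self.enc_convs[i - 1]
            bn = self.enc_bns[i - 1]
            act = self.enc_acts[i - 1]
            if skip_grads[i - 1] is not None:
                h = h + skip_grads[i - 1]
            h = act.backward(h)
            if bn is not None:
                h = bn.backward(h)
            h = conv.backward(h)
        return h


class Discriminator:
    """Conditional patch discriminator over (low-dose, candidate) view pairs."""

    def __init__(self, spec: GanSpec, rng: np.random.Generator):
        self.spec = spec
        k = spec.kernel
        self.blocks: list[list[nn.Layer]] = []
        c_in = 2
        for i, (f, s) in enumerate(zip(spec.disc_filters, spec.disc_strides), start=1):
            block: list[nn.Layer] = [nn.Conv2d(c_in, f, k, s, rng, spec.init_std, f"disc{i}")]
            if i > 1 or spec.disc_bn_first_block:
                block.append(nn.BatchNorm2d(f, name=f"disc{i}.bn"))
            block.append(nn.LeakyReLU(spec.leaky_slope))
            self.blocks.append(block)
            c_in = f
        self.blocks.append([
            nn.Conv2d(c_in, 1, 1, 1, rng, spec.init_std, "disc.out"),
            nn.BatchNorm2d(1, name="disc.out.bn"),
            nn.Sigmoid(),
        ])

    def layers(self) -> list[nn.Layer]:
        return [l for block in self.blocks for l in block]

    def params(self) -> list[nn.Param]:
        return [p for layer in self.layers() for p in layer.params()]

    def forward(self, x_cond: np.ndarray, y_cand: np.ndarray, training: bool = True) -> np.ndarray:
        if x_cond.ndim == 3:
            x_cond = x_cond[:, None]
        if y_cand.ndim == 3:
            y_cand = y_cand[:, None]
        if x_cond.shape != y_cand.shape:
            raise ValueError("conditioning and candidate views must share a shape")
        h = np.concatenate([x_cond, y_cand], axis=1).astype(np.float32)
        for layer in self.layers():
            h = layer.forward(h, training)
        return h

    def backward(self, dy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Returns gradients w.r.t. (conditioning, candidate) inputs."""
        h = dy
        for layer in reversed(self.layers()):
            h = layer.backward(h)
        return h[:, :1], h[:, 1:]


@dataclass
class GanModel:
    """Trained generator (plus discriminator) with its normalization constant."""

    generator: Generator
    discriminator: Discriminator | None
    spec: GanSpec
    config: TrainConfig
    scale: float
    history: dict = field(default_factory=dict)


def build_generator(spec: GanSpec | None = None, seed: int = 0) -> Generator:
    spec = spec or GanSpec()
    return Generator(spec, np.random.default_rng(seed))


def build_discriminator(spec: GanSpec | None = None, seed: int = 0) -> Discriminator:
    spec = spec or GanSpec()
    return Discriminator(spec, np.random.default_rng(seed))


def train(pairs: PairedViews, config: TrainConfig | None = None,
          spec: GanSpec | None = None, verbose: bool = False) -> GanModel:
    """Adversarial training of the generator against the patch discriminator.

    Alternates a discriminator step (BCE on real pairs labelled 1 and
    generated pairs labelled 0) with a generator step minimizing
    ``loss_weight_adv * BCE(D(x, G(x)), 1) + loss_weight_l2 * MSE(G(x), y)``.
    With ``loss_weight_adv == 0`` the discriminator is skipped entirely and
    training reduces to a supervised L2 regression.  Fully seeded: the same
    (pairs, config, spec) reproduce the same loss history.
    """
    if len(pairs) < 1:
        raise ValueError("need at least one training pair")
    config = config or TrainConfig()
    spec = spec or GanSpec()
    rng = np.random.default_rng(config.seed)
    gen = Generator(spec, np.random.default_rng(rng.integers(2**31 - 1)))
    use_adv = config.loss_weight_adv > 0
    disc = Discriminator(spec, np.random.default_rng(rng.integers(2**31 - 1))) if use_adv else None
    opt_g = nn.Adam(gen.params(), lr=config.learning_rate)
    opt_d = nn.Adam(disc.params(), lr=config.learning_rate) if use_adv else None

    n = len(pairs)
    bs = min(config.batch_size, n)
    hist = {"l2": [], "adv": [], "disc": []}
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        ep_l2, ep_adv, ep_disc, nb = 0.0, 0.0, 0.0, 0
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            x = pairs.inputs[idx][:, None]
            y = pairs.targets[idx][:, None]

            if use_adv:
                fake = gen.forward(x, training=True)
                # discriminator step
                opt_d.zero_grad()
                p_real = disc.forward(x, y, training=True)
                l_real, g_real = nn.bce_loss(p_real, 1.0)
                disc.backward(g_real)
                p_fake = disc.forward(x, fake, training=True)
                l_fake, g_fake = nn.bce_loss(p_fake, 0.0)
                disc.backward(g_fake)
                opt_d.step()
                ep_disc += 0.5 * (l_real + l_fake)
                # generator step (through the updated discriminator)
                opt_g.zero_grad()
                fake = gen.forward(x, training=True)
                p_gen = disc.forward(x, fake, training=True)
                l_adv, g_adv = nn.bce_loss(p_gen, 1.0)
                _, d_fake = disc.backward(g_adv)
                for p in disc.params():  # D params are frozen in the G step
                    p.zero_grad()
                l_l2, g_l2 = nn.mse_loss(fake, y)
                gen.backward(config.loss_weight_adv * d_fake + config.loss_weight_l2 * g_l2)
                opt_g.step()
                ep_adv += l_adv
            else:
                opt_g.zero_grad()
                fake = gen.forward(x, training=True)
                l_l2, g_l2 = nn.mse_loss(fake, y)
                gen.backward(config.loss_weight_l2 * g_l2)
                opt_g.step()
            if not np.isfinite(l_l2):
                raise FloatingPointError(
                    f"generator L2 loss became non-finite at epoch {_epoch}; "
                    "lower the learning rate or check input normalization"
                )
            ep_l2 += l_l2
            nb += 1
        hist["l2"].append(ep_l2 / nb)
        hist["adv"].append(ep_adv / nb if use_adv else 0.0)
        hist["disc"].append(ep_disc / nb if use_adv else 0.0)
        if verbose:
            print(f"epoch {_epoch + 1}/{config.epochs}  L2={hist['l2'][-1]:.3e}"
                  f"  adv={hist['adv'][-1]:.3f}")
    return GanModel(generator=gen, discriminator=disc, spec=spec, config=config,
                    scale=pairs.scale, history=hist)


def denoise(model: GanModel, proj: ProjectionSet) -> ProjectionSet:
    """Predict a standard-dose projection set from a low-dose one.

    Each view is normalized by the model's recorded constant, passed through
    the generator in inference mode, and inverse-scaled back to (real-valued,
    nonnegative) counts.  The result's ``dose_fraction`` is 1 with provenance
    marking it as a prediction; predictions live in ``expected``.
    """
    if proj.counts is None:
        raise ValueError("projection set has no counts to denoise")
    r, c = proj.geometry.detector_rows, proj.geometry.detector_cols
    if r % 64 or c % 64:
        raise ValueError(f"geometry {r}x{c} incompatible with the 64x64 network input")
    x = proj.counts.astype(np.float32) / model.scale
    pred = model.generator.forward(x[:, None], training=False)[:, 0]
    pred_counts = np.clip(pred.astype(float) * model.scale, 0.0, None)
    return ProjectionSet(
        geometry=proj.geometry,
        counts=None,
        expected=pred_counts,
        dose_fraction=1.0,
        gate=proj.gate,
        n_gates=proj.n_gates,
        provenance={**proj.provenance, "stage": "denoise", "predicted": True,
                    "input_dose_fraction": proj.dose_fraction},
    )


def _collect_state(model: GanModel) -> dict[str, np.ndarray]:
    state: dict[str, np.ndarray] = {}
    nets = [("gen", model.generator)] + (
        [("disc", model.discriminator)] if model.discriminator else [])
    for prefix, net in nets:
        for i, layer in enumerate(net.layers()):
            for j, p in enumerate(layer.params()):
                state[f"{prefix}.{i}.{j}"] = p.value
            if isinstance(layer, nn.BatchNorm2d):
                state[f"{prefix}.{i}.rm"] = layer.running_mean
                state[f"{prefix}.{i}.rv"] = layer.running_var
    return state


def save_model(model: GanModel, path: str) -> None:
    """Serialize architecture, training config, scale and weights to ``.npz``."""
    meta = {
        "spec": asdict(model.spec),
        "config": asdict(model.config),
        "scale": model.scale,
        "history": model.history,
        "has_disc": model.discriminator is not None,
    }
    np.savez_compressed(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **_collect_state(model))


def load_model(path: str) -> GanModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        spec_d = meta["spec"]
        for key in ("encoder_filters", "decoder_filters", "encoder_bn_blocks",
                    "disc_filters", "disc_strides"):
            spec_d[key] = tuple(spec_d[key])
        spec = GanSpec(**spec_d)
        config = TrainConfig(**meta["config"])
        gen = Generator(spec, np.random.default_rng(0))
        disc = Discriminator(spec, np.random.default_rng(0)) if meta["has_disc"] else None
        model = GanModel(generator=gen, discriminator=disc, spec=spec, config=config,
                         scale=meta["scale"], history=meta["history"])
        for prefix, net in [("gen", gen)] + ([("disc", disc)] if disc else []):
            for i, layer in enumerate(net.layers()):
                for j, p in enumerate(layer.params()):
                    p.value = data[f"{prefix}.{i}.{j}"].copy()
                if isinstance(layer, nn.BatchNorm2d):
                    layer.running_mean = data[f"{prefix}.{i}.rm"].copy()
                    layer.running_var = data[f"{prefix}.{i}.rv"].copy()
    return model
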