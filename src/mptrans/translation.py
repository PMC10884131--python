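"""Cycle-consistent translation between attenuated and reference domains.

Two generators (S->P and P->S) and one least-squares patch discriminator
per domain are trained on unpaired image pools.  The objective is the
summation of the two adversarial losses with the cycle-consistency loss:

    total = adv_S + adv_P + cycle_weight * cyc

where ``cyc`` is the mean absolute reconstruction error over both round
trips S->P->S and P->S->P, and each adversarial term is the least-squares
generator loss for translating into that domain.  Optimization is
stochastic gradient descent with momentum.

Images are handled internally on a [0, 1] scale (uptake / 100).  The
``paper`` profile preserves the full-scale clinical-workflow
hyperparameters (256 x 256 matrix, 50 epochs, batch 8, learning rate
0.002, momentum optimizer); the ``desk`` profile is a small configuration
that trains in minutes on one CPU.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from .nn import PatchDiscriminator, ResUNetGenerator, make_optimizer
from .preprocess import downsize_after_network, resize_for_network
from .stacks import UPTAKE_MAX, ImageStack

CHECKPOINT_FORMAT_VERSION = 1


@dataclass
class TrainConfig:
    epochs: int = 50
    batch_size: int = 8
    learning_rate: float = 0.002
    optimizer_momentum: float = 0.9
    cycle_weight: float = 10.0
    image_size: int = 256
    generator_width: int = 32
    discriminator_width: int = 32
    discriminator_lr_scale: float = 1.0
    optimizer: str = "momentum"  # "momentum" (plain SGD+momentum) or "adam"
    lr_decay: str = "none"  # "none" or "linear-half" (linear to 0 over the 2nd half)
    generator_ema: float = 0.0  # EMA decay of generator weights (0 disables)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.cycle_weight < 0:
            raise ValueError("cycle_weight must be nonnegative")
        if self.image_size % 4:
            raise ValueError("image_size must be divisible by 4")
        if self.optimizer not in ("momentum", "adam"):
            raise ValueError('optimizer must be "momentum" or "adam"')
        if self.lr_decay not in ("none", "linear-half"):
            raise ValueError('lr_decay must be "none" or "linear-half"')
        if not 0 <= self.generator_ema < 1:
            raise ValueError("generator_ema must lie in [0, 1)")


def paper_profile(**overrides) -> TrainConfig:
    """The full-scale reference training configuration."""
    return replace(TrainConfig(), **overrides)


def desk_profile(**overrides) -> TrainConfig:
    """Small-scale profile that trains in minutes on one CPU."""
    cfg = TrainConfig(
        epochs=12,
        batch_size=4,
        learning_rate=0.002,
        cycle_weight=10.0,
        image_size=64,
        generator_width=6,
        discriminator_width=6,
        discriminator_lr_scale=1.0,
        optimizer="adam",
        lr_decay="linear-half",
        generator_ema=0.99,
    )
    return replace(cfg, **overrides)


@dataclass
class TranslationModel:
    """Generator/discriminator parameter sets plus training provenance."""

    gen_sp: ResUNetGenerator          # attenuated -> reference
    gen_ps: ResUNetGenerator          # reference -> attenuated
    disc_s: PatchDiscriminator
    disc_p: PatchDiscriminator
    train_config: TrainConfig
    loss_trace: list[dict] = field(default_factory=list)
    trained: bool = False

    @classmethod
    def initialize(cls, config: TrainConfig) -> "TranslationModel":
        rng = np.random.default_rng(config.seed)
        return cls(
            gen_sp=ResUNetGenerator(config.generator_width, rng),
            gen_ps=ResUNetGenerator(config.generator_width, rng),
            disc_s=PatchDiscriminator(config.discriminator_width, rng),
            disc_p=PatchDiscriminator(config.discriminator_width, rng),
            train_config=config,
        )

    def _named_modules(self):
        return {
            "gen_sp": self.gen_sp,
            "gen_ps": self.gen_ps,
            "disc_s": self.disc_s,
            "disc_p": self.disc_p,
        }

    def save(self, path: str | Path) -> None:
        """Versioned binary checkpoint with the TrainConfig embedded."""
        arrays: dict[str, np.ndarray] = {}
        for net_name, net in self._named_modules().items():
            for i, m in enumerate(net.modules()):
                for k, v in m.params.items():
                    arrays[f"{net_name}/{i}/{k}"] = v
        import json

        arrays["__meta__"] = np.frombuffer(
            json.dumps(
                {
                    "format_version": CHECKPOINT_FORMAT_VERSION,
                    "train_config": asdict(self.train_config),
                    "trained": self.trained,
                    "loss_trace": self.loss_trace,
                }
            ).encode(),
            dtype=np.uint8,
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "TranslationModel":
        import json

        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            if meta["format_version"] != CHECKPOINT_FORMAT_VERSION:
                raise ValueError("unsupported checkpoint format version")
            config = TrainConfig(**meta["train_config"])
            model = cls.initialize(config)
            for net_name, net in model._named_modules().items():
                for i, m in enumerate(net.modules()):
                    for k in m.params:
                        m.params[k][...] = data[f"{net_name}/{i}/{k}"]
            model.trained = meta["trained"]
            model.loss_trace = meta["loss_trace"]
        return model


def _as_batch(images: np.ndarray) -> np.ndarray:
    images = np.asarray(images, dtype=float)
    if images.ndim == 3:
        images = images[:, None, :, :]
    if images.ndim != 4:
        raise ValueError("expected (N, H, W) or (N, 1, H, W) image batch")
    if images.shape[2] != images.shape[3]:
        raise ValueError("images must be square")
    return images


def cycle_cost(
    batch_s: np.ndarray, batch_p: np.ndarray, model: TranslationModel
) -> tuple[float, float, float]:
    """Loss components (adv_S, adv_P, cyc) for one unpaired batch pair.

    adv_P is the least-squares generator loss for translating into the
    reference domain (fooling its discriminator) and adv_S the mirrored
    term; cyc is the mean absolute error over both round trips.  The total
    objective is adv_S + adv_P + cycle_weight * cyc.
    """
    s = _as_batch(batch_s)
    p = _as_batch(batch_p)
    if s.shape[2:] != p.shape[2:]:
        raise ValueError("domain batches must share the image size")
    fake_p, _ = model.gen_sp.forward(s)
    fake_s, _ = model.gen_ps.forward(p)
    rec_s, _ = model.gen_ps.forward(fake_p)
    rec_p, _ = model.gen_sp.forward(fake_s)
    d_fake_p, _ = model.disc_p.forward(fake_p)
    d_fake_s, _ = model.disc_s.forward(fake_s)
    adv_p = float(np.mean((d_fake_p - 1.0) ** 2))
    adv_s = float(np.mean((d_fake_s - 1.0) ** 2))
    cyc = float(0.5 * (np.mean(np.abs(rec_s - s)) + np.mean(np.abs(rec_p - p))))
    return adv_s, adv_p, cyc


def _disc_update(disc, opt, real: np.ndarray, fake: np.ndarray) -> float:
    disc.zero_grad()
    out_r, cache_r = disc.forward(real)
    out_f, cache_f = disc.forward(fake)
    loss = 0.5 * float(np.mean((out_r - 1.0) ** 2) + np.mean(out_f**2))
    disc.backward((out_r - 1.0) / out_r.size, cache_r)
    disc.backward(out_f / out_f.size, cache_f)
    opt.step()
    return loss


def train(
    dataset_s: np.ndarray,
    dataset_p: np.ndarray,
    config: TrainConfig,
    *,
    progress: bool = False,
) -> TranslationModel:
    """Train the cycle-consistent model on unpaired image pools.

    ``dataset_s`` / ``dataset_p`` are (N, H, W) arrays on the [0, 1] scale
    (uptake / 100).  Returns the model with a per-epoch loss trace of
    length ``config.epochs``; fully deterministic for a fixed seed.
    """
    s_pool = _as_batch(dataset_s)
    p_pool = _as_batch(dataset_p)
    if s_pool.shape[0] == 0 or p_pool.shape[0] == 0:
        raise ValueError("both domain pools must be nonempty")
    size = config.image_size
    if s_pool.shape[2] != size or p_pool.shape[2] != size:
        raise ValueError(
            f"training images must match image_size={size}; resize beforehand"
        )

    model = TranslationModel.initialize(config)
    rng = np.random.default_rng(config.seed + 1)
    lam = config.cycle_weight
    opt_g = make_optimizer(
        config.optimizer,
        model.gen_sp.modules() + model.gen_ps.modules(),
        lr=config.learning_rate,
        momentum=config.optimizer_momentum,
    )
    d_lr = config.learning_rate * config.discriminator_lr_scale
    opt_ds = make_optimizer(config.optimizer, model.disc_s.modules(), lr=d_lr, momentum=config.optimizer_momentum)
    opt_dp = make_optimizer(config.optimizer, model.disc_p.modules(), lr=d_lr, momentum=config.optimizer_momentum)

    gen_modules = model.gen_sp.modules() + model.gen_ps.modules()
    ema = None
    if config.generator_ema > 0:
        ema = [{k: v.copy() for k, v in m.params.items()} for m in gen_modules]

    n_batches = max(1, min(s_pool.shape[0], p_pool.shape[0]) // config.batch_size)
    for epoch in range(config.epochs):
        if config.lr_decay == "linear-half":
            frac = (epoch + 1) / config.epochs
            scale = 1.0 if frac <= 0.5 else max(2.0 * (1.0 - frac), 1.0 / config.epochs)
            opt_g.lr = config.learning_rate * scale
            opt_ds.lr = d_lr * scale
            opt_dp.lr = d_lr * scale
        s_idx = rng.permutation(s_pool.shape[0])
        p_idx = rng.permutation(p_pool.shape[0])
        ep = {"adv_s": 0.0, "adv_p": 0.0, "cyc": 0.0, "disc": 0.0}
        for b in range(n_batches):
            sl = slice(b * config.batch_size, (b + 1) * config.batch_size)
            s = s_pool[s_idx[sl]]
            p = p_pool[p_idx[sl]]

            fake_p, c_sp1 = model.gen_sp.forward(s)
            fake_s, c_ps1 = model.gen_ps.forward(p)

            ep["disc"] += _disc_update(model.disc_p, opt_dp, p, fake_p)
            ep["disc"] += _disc_update(model.disc_s, opt_ds, s, fake_s)

            # --- generator update ---------------------------------------
            model.gen_sp.zero_grad()
            model.gen_ps.zero_grad()
            rec_s, c_ps2 = model.gen_ps.forward(fake_p)
            rec_p, c_sp2 = model.gen_sp.forward(fake_s)

            d_fp, c_dp = model.disc_p.forward(fake_p)
            d_fs, c_ds = model.disc_s.forward(fake_s)
            adv_p = float(np.mean((d_fp - 1.0) ** 2))
            adv_s = float(np.mean((d_fs - 1.0) ** 2))
            cyc_s = np.mean(np.abs(rec_s - s))
            cyc_p = np.mean(np.abs(rec_p - p))

            g_fake_p = model.disc_p.backward(2.0 * (d_fp - 1.0) / d_fp.size, c_dp)
            g_fake_s = model.disc_s.backward(2.0 * (d_fs - 1.0) / d_fs.size, c_ds)
            # cycle terms: d(lam * 0.5 * mean|rec - x|)
            g_rec_s = lam * 0.5 * np.sign(rec_s - s) / rec_s.size
            g_rec_p = lam * 0.5 * np.sign(rec_p - p) / rec_p.size
            g_fake_p = g_fake_p + model.gen_ps.backward(g_rec_s, c_ps2)
            g_fake_s = g_fake_s + model.gen_sp.backward(g_rec_p, c_sp2)
            model.gen_sp.backward(g_fake_p, c_sp1)
            model.gen_ps.backward(g_fake_s, c_ps1)
            opt_g.step()
            if ema is not None:
                d = config.generator_ema
                for m, e in zip(gen_modules, ema):
                    for k, v in m.params.items():
                        e[k] *= d
                        e[k] += (1 - d) * v

            ep["adv_s"] += adv_s
            ep["adv_p"] += adv_p
            ep["cyc"] += 0.5 * float(cyc_s + cyc_p)
        for k in ep:
            ep[k] /= n_batches
        ep["total"] = ep["adv_s"] + ep["adv_p"] + lam * ep["cyc"]
        ep["epoch"] = epoch + 1
        model.loss_trace.append(ep)
        if progress:
            print(
                f"epoch {epoch + 1}/{config.epochs}: total={ep['total']:.4f} "
                f"adv_s={ep['adv_s']:.4f} adv_p={ep['adv_p']:.4f} cyc={ep['cyc']:.4f}"
            )
    if ema is not None:
        for m, e in zip(gen_modules, ema):
            for k in m.params:
                m.params[k][...] = e[k]
    model.trained = True
    return model


def translate_stack(model: TranslationModel, spect: ImageStack) -> ImageStack:
    """Apply the S->P generator slice by slice to an uptake-scale stack.

    Slices are bilinearly resized to the model's matrix size, translated,
    resized back and clipped into [0, 100]; the result is flagged with
    modality ``spect_spt``.
    """
    if not model.trained:
        raise ValueError("model has not been trained")
    if not spect.is_uptake:
        raise ValueError("stack must be on the uptake scale")
    size = model.train_config.image_size
    out = np.empty_like(spect.voxels, dtype=float)
    orig = spect.size
    for i in range(spect.n_slices):
        x = spect.voxels[i] / UPTAKE_MAX
        x = resize_for_network(x, size)
        y, _ = model.gen_sp.forward(x[None, None])
        y = np.clip(y[0, 0], 0.0, 1.0)
        y = downsize_after_network(y, orig)
        out[i] = np.clip(y, 0.0, 1.0) * UPTAKE_MAX
    return spect.copy_with(voxels=out, modality="spect_spt")


def loss_trace_csv(model: TranslationModel, path: str | Path) -> None:
    """Write the per-epoch loss trace as CSV."""
    cols = ["epoch", "adv_s", "adv_p", "cyc", "disc", "total"]
    lines = [",".join(cols)]
    for row in model.loss_trace:
        lines.append(",".join(f"{row[c]:.8g}" if c != "epoch" else str(row[c]) for c in cols))
    Path(path).write_text("\n".join(lines) + "\n")
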