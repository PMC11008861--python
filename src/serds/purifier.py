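"""1-D encoder-decoder ("U-Net") purifier for SERDS difference spectra.

The network maps a z-score difference spectrum, resampled to a uniform
1024-point Raman-shift grid over 550-1800 cm^-1, to the background-free
Raman spectrum on the same grid.  The encoder halves the resolution and
doubles the channel count at each of four levels (16/32/64/128, bottleneck
capped at 128); the decoder mirrors the encoder and concatenates the
matching encoder features (skip connections) before each convolution.  All
convolutions use kernel width 9 and ReLU activations except the final
linear 1x1 projection.  Training minimises mean squared error against
clean spectra scaled to unit maximum, with Adam, on synthetic pairs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import axes, core, synthetic
from .nn import (DTYPE, Adam, Conv1D, maxpool2_backward, maxpool2_forward,
                 upsample2_backward, upsample2_forward)


@dataclass(frozen=True)
class PurifierConfig:
    input_len: int = axes.PURIFIER_POINTS
    depth: int = 4
    base_channels: int = 16
    max_channels: int = 128
    kernel: int = 9
    epochs: int = 10
    batch_size: int = 32
    learning_rate: float = 1e-3
    loss: str = "mse"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.input_len, self.depth, self.base_channels,
               self.kernel, self.epochs, self.batch_size) < 1:
            raise ValueError("all counts must be positive")
        if self.input_len % (2 ** self.depth) != 0:
            raise ValueError(
                f"input length {self.input_len} not divisible by 2^{self.depth}")
        if self.loss != "mse":
            raise ValueError(f"unsupported loss {self.loss!r}")

    def channel_schedule(self) -> list[int]:
        """Encoder output channels per level, plus the bottleneck."""
        return [min(self.base_channels * 2 ** i, self.max_channels)
                for i in range(self.depth + 1)]


class UNet1D:
    """Encoder-decoder network over (batch, length, 1) spectra."""

    def __init__(self, config: PurifierConfig) -> None:
        self.config = config
        rng = np.random.default_rng(config.seed)
        chans = config.channel_schedule()
        enc_ch, bott_ch = chans[:-1], chans[-1]
        k = config.kernel
        self.enc = []
        c_prev = 1
        for c in enc_ch:
            self.enc.append(Conv1D(c_prev, c, k, rng))
            c_prev = c
        self.bottleneck = Conv1D(c_prev, bott_ch, k, rng)
        self.dec = []
        c_up = bott_ch
        for c_skip in reversed(enc_ch):
            self.dec.append(Conv1D(c_up + c_skip, c_skip, k, rng))
            c_up = c_skip
        self.out = Conv1D(c_up, 1, 1, rng, relu=False)
        self._pools: list[np.ndarray] = []

    @property
    def layers(self) -> list[Conv1D]:
        return [*self.enc, self.bottleneck, *self.dec, self.out]

    @property
    def n_params(self) -> int:
        return sum(layer.n_params for layer in self.layers)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if x.ndim == 2:
            x = x[:, :, None]
        if x.shape[1] != self.config.input_len:
            raise ValueError(f"expected length {self.config.input_len}, got {x.shape[1]}")
        h = np.ascontiguousarray(x, dtype=DTYPE)
        skips, pools = [], []
        for conv in self.enc:
            h = conv.forward(h, train)
            skips.append(h)
            h, idx = maxpool2_forward(h)
            pools.append(idx)
        h = self.bottleneck.forward(h, train)
        for conv, skip in zip(self.dec, reversed(skips)):
            h = upsample2_forward(h)
            h = np.concatenate([h, skip], axis=2)
            h = conv.forward(h, train)
        y = self.out.forward(h, train)
        if train:
            self._pools = pools
        return y[:, :, 0]

    def backward(self, dy: np.ndarray) -> None:
        depth = self.config.depth
        dh = self.out.backward(dy[:, :, None].astype(DTYPE))
        dskips: list[np.ndarray | None] = [None] * depth
        for i in reversed(range(depth)):
            d = self.dec[i].backward(dh)
            c_skip = self.dec[i].c_out
            c_up = self.dec[i].c_in - c_skip
            dskips[depth - 1 - i] = d[:, :, c_up:]
            dh = upsample2_backward(d[:, :, :c_up])
        dh = self.bottleneck.backward(dh)
        for j in reversed(range(depth)):
            dh = maxpool2_backward(dh, self._pools[j])
            dh = dh + dskips[j]
            dh = self.enc[j].backward(dh)

    def get_weights(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers:
            out.extend([layer.w.copy(), layer.b.copy()])
        return out

    def set_weights(self, weights: list[np.ndarray]) -> None:
        it = iter(weights)
        for layer in self.layers:
            layer.w = np.asarray(next(it), dtype=DTYPE)
            layer.b = np.asarray(next(it), dtype=DTYPE)


@dataclass
class TrainedPurifier:
    config: PurifierConfig
    model: UNet1D
    history: list[float] = field(default_factory=list)   # per-epoch mean loss
    train_fingerprint: str = ""

    def __post_init__(self) -> None:
        if not self.train_fingerprint:
            raise ValueError("trained purifier requires a training-set fingerprint")


def build_purifier(config: PurifierConfig | None = None) -> UNet1D:
    """Seeded, untrained network for the given architecture config."""
    return UNet1D(config or PurifierConfig())


def expected_parameter_count(config: PurifierConfig) -> int:
    """Layer-by-layer parameter audit of the stated architecture.

    Each convolution contributes (kernel * c_in + 1) * c_out parameters.
    """
    chans = config.channel_schedule()
    enc_ch, bott = chans[:-1], chans[-1]
    k = config.kernel
    total, c_prev = 0, 1
    for c in enc_ch:
        total += (k * c_prev + 1) * c
        c_prev = c
    total += (k * c_prev + 1) * bott
    c_up = bott
    for c_skip in reversed(enc_ch):
        total += (k * (c_up + c_skip) + 1) * c_skip
        c_up = c_skip
    total += (1 * c_up + 1) * 1
    return total


def _fingerprint(x: np.ndarray, t: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(x).tobytes())
    h.update(np.ascontiguousarray(t).tobytes())
    return h.hexdigest()[:16]


def train_purifier(pairs, config: PurifierConfig | None = None,
                   model: UNet1D | None = None) -> TrainedPurifier:
    """Train on (difference, clean-truth) pairs with Adam on MSE.

    ``pairs`` is a sequence of 1-D array pairs already resampled to the
    config input length, truths scaled to unit maximum (see
    :func:`prepare_pairs`).  Deterministic for a fixed config seed.
    """
    config = config or PurifierConfig()
    if len(pairs) < 1:
        raise ValueError("need at least one training pair")
    x = np.stack([np.asarray(p[0], dtype=DTYPE) for p in pairs])
    t = np.stack([np.asarray(p[1], dtype=DTYPE) for p in pairs])
    if x.shape[1] != config.input_len or t.shape != x.shape:
        raise ValueError("pair length does not match the config input length")
    model = model or build_purifier(config)
    opt = Adam(model.layers, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    n = x.shape[0]
    history: list[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            sel = order[start:start + config.batch_size]
            xb, tb = x[sel], t[sel]
            y = model.forward(xb)
            resid = y - tb
            losses.append(float(np.mean(resid ** 2)))
            model.backward((2.0 / resid.size) * resid)
            opt.step()
        history.append(float(np.mean(losses)))
    return TrainedPurifier(config=config, model=model, history=history,
                           train_fingerprint=_fingerprint(x, t))


def prepare_pair(diff: core.DifferenceSpectrum,
                 shift_axis: np.ndarray, clean_axis: np.ndarray,
                 clean: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Resample one (difference, truth) pair onto the purifier grid.

    The input is scaled to unit maximum absolute value and the truth to
    unit maximum, making the regression target scale-free.
    """
    x = core.resample_difference(diff, shift_axis)
    xmax = np.max(np.abs(x))
    if xmax > 0:
        x = x / xmax
    t = np.interp(shift_axis, clean_axis, clean, left=0.0, right=0.0)
    tmax = t.max()
    if tmax > 0:
        t = t / tmax
    return x, t


def make_training_pairs(n_pairs: int,
                        library=None,
                        cohort_config: synthetic.CohortConfig | None = None,
                        purifier_config: PurifierConfig | None = None,
                        seed: int = 0,
                        empty_fraction: float = 0.05):
    """Generate synthetic (difference, truth) training pairs in bulk.

    Draws a random tissue class per pair and renders the repeat-averaged
    dual-excitation spectra directly (see
    :func:`serds.synthetic.render_mean_spectrum`).  A small fraction of
    pairs carries no Raman signal at all (background and noise only, zero
    target) so the network learns not to hallucinate peaks.
    """
    library = library or synthetic.build_class_library()
    cohort_config = cohort_config or synthetic.CohortConfig()
    purifier_config = purifier_config or PurifierConfig()
    shift_axis = axes.purifier_shift_axis(purifier_config.input_len)
    truth_axis = synthetic.truth_shift_axis()
    grid = cohort_config.detector_grid()
    ex_lo, ex_hi = sorted(cohort_config.excitations_nm)
    rng = np.random.default_rng(seed)
    names = list(library)
    pairs = []
    for i in range(n_pairs):
        template = library[names[rng.integers(len(names))]]
        if rng.random() < empty_fraction:
            clean = np.zeros_like(truth_axis)
            clean_max = template.max_mean_amplitude
        else:
            clean = synthetic.sample_clean_spectrum(template, truth_axis, rng)
            clean_max = float(clean.max())
        amp = synthetic.locus_background_amplitude(template, clean_max, rng)
        bg = amp * template.background.profile(grid)
        m_lo = synthetic.render_mean_spectrum(truth_axis, clean, ex_lo,
                                              template, cohort_config, rng,
                                              background=bg)
        m_hi = synthetic.render_mean_spectrum(truth_axis, clean, ex_hi,
                                              template, cohort_config, rng,
                                              background=bg)
        diff = core.serds_difference(m_lo, m_hi)
        pairs.append(prepare_pair(diff, shift_axis, truth_axis, clean))
    return pairs


def purify(trained: TrainedPurifier, diff: core.DifferenceSpectrum,
           shift_axis: np.ndarray | None = None) -> core.PurifiedSpectrum:
    """Single forward pass of a trained purifier on one difference spectrum."""
    if not isinstance(trained, TrainedPurifier):
        raise TypeError("purify requires a TrainedPurifier; train the model first")
    config = trained.config
    if shift_axis is None:
        shift_axis = axes.purifier_shift_axis(config.input_len)
    shift_axis = np.asarray(shift_axis, dtype=float)
    if shift_axis.size != config.input_len:
        raise ValueError("shift axis length does not match the model input length")
    x = core.resample_difference(diff, shift_axis)
    xmax = np.max(np.abs(x))
    if xmax > 0:
        x = x / xmax
    y = trained.model.forward(x[None, :], train=False)[0]
    return core.PurifiedSpectrum(shift_cm1=shift_axis, values=y.astype(float),
                                 locus_id=diff.locus_id, label=diff.label,
                                 purifier_id=f"unet-{trained.train_fingerprint}")


def save_purifier(trained: TrainedPurifier, path) -> None:
    """Persist architecture, weights, history and fingerprint to .npz."""
    weights = trained.model.get_weights()
    np.savez(path,
             config=json.dumps(asdict(trained.config)),
             history=np.asarray(trained.history, dtype=float),
             fingerprint=trained.train_fingerprint,
             n_weights=len(weights),
             **{f"w{i}": w for i, w in enumerate(weights)})


def load_purifier(path) -> TrainedPurifier:
    with np.load(path, allow_pickle=False) as data:
        config = PurifierConfig(**json.loads(str(data["config"])))
        model = build_purifier(config)
        model.set_weights([data[f"w{i}"] for i in range(int(data["n_weights"]))])
        return TrainedPurifier(config=config, model=model,
                               history=list(map(float, data["history"])),
                               train_fingerprint=str(data["fingerprint"]))
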