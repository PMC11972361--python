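"""Conditional-GAN reference imputer.

The generator maps rows of the observed view (v1) directly to the target
view (v2) through a stack of residual blocks; the discriminator scores v2
rows real/fake and carries an auxiliary classifier that scores whether a
concatenated <v1, v2> pair is genuinely paired.  All three loss terms take
the least-squares (MSE) form:

    L = w_rec * L_rec + w_adv * L_adv + w_aux * L_aux

The defining contrast with the disentanglement model: the cGAN only learns
from samples where both views are present (paired rows), so with no
revealed rows at the target timepoint it can only learn the v1->v2 mapping
at the other timepoint and cannot account for temporal distribution shift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import DataBlock, LongitudinalDataset, SplitAssignment
from .errors import ConfigError, DataError
from .nn import Adam, BatchNorm, Dense, Module, PReLU, Sequential, Sigmoid, Tensor, as_tensor, concatenate
from .objectives import d_step_loss, g_step_loss

__all__ = ["CganConfig", "CganGenerator", "CganDiscriminator", "cgan_losses",
           "cgan_fit_and_impute", "CganModel"]


@dataclass
class CganConfig:
    generator_blocks: int = 5
    generator_width: int = 64
    discriminator_layers: int = 3
    discriminator_width: int = 128
    batchnorm_blocks: int = 4      # batch normalization in the first blocks of G
    batchnorm_disc_layers: int = 2  # ... and the last layers of D
    w_rec: float = 0.5
    w_adv: float = 0.25
    w_aux: float = 0.25
    batch_size: int = 32
    learning_rate: float = 1e-3
    max_epochs: int = 600
    early_stop_patience: int = 30

    def __post_init__(self):
        if self.batchnorm_blocks > self.generator_blocks:
            raise ConfigError("batchnorm_blocks cannot exceed generator_blocks")


class _ResidualBlock(Module):
    """Dense -> [BatchNorm] -> PReLU with an identity skip on the hidden state."""

    def __init__(self, width: int, rng, batchnorm: bool):
        super().__init__()
        self.dense = Dense(width, width, rng)
        self.bn = BatchNorm(width) if batchnorm else None
        self.act = PReLU()

    def forward(self, x: Tensor) -> Tensor:
        h = self.dense(x)
        if self.bn is not None:
            h = self.bn(h)
        return x + self.act(h)


class CganGenerator(Module):
    def __init__(self, in_width: int, out_width: int, config: CganConfig, rng):
        super().__init__()
        w = config.generator_width
        self.entry = Sequential(Dense(in_width, w, rng), PReLU())
        self.blocks = [
            _ResidualBlock(w, rng, batchnorm=(i < config.batchnorm_blocks))
            for i in range(config.generator_blocks)
        ]
        self.exit = Dense(w, out_width, rng)
        self.in_width = in_width
        self.out_width = out_width

    def forward(self, rows) -> Tensor:
        x = as_tensor(rows)
        if x.shape[-1] != self.in_width:
            raise ConfigError(
                f"input width {x.shape[-1]} does not match generator input "
                f"({self.in_width})")
        h = self.entry(x)
        for block in self.blocks:
            h = block(h)
        return self.exit(h)


class CganDiscriminator(Module):
    """Real/fake branch on v2 rows plus auxiliary pairing branch on <v1, v2>."""

    def __init__(self, v1_width: int, v2_width: int, config: CganConfig, rng):
        super().__init__()
        self.adv = self._branch(v2_width, config, rng)
        self.aux = self._branch(v1_width + v2_width, config, rng)

    @staticmethod
    def _branch(in_width: int, config: CganConfig, rng) -> Sequential:
        w = config.discriminator_width
        layers: list[Module] = [Dense(in_width, w, rng), Sigmoid()]
        n_bn_from = config.discriminator_layers - config.batchnorm_disc_layers
        for i in range(1, config.discriminator_layers):
            layers.append(Dense(w, w, rng))
            if i >= n_bn_from:
                layers.append(BatchNorm(w))
            layers.append(Sigmoid())
        layers.append(Dense(w, 1, rng))
        layers.append(Sigmoid())
        return Sequential(*layers)

    def score_real_fake(self, v2_rows) -> Tensor:
        return self.adv(as_tensor(v2_rows)).reshape((-1,))

    def score_pair(self, v1_rows, v2_rows) -> Tensor:
        pair = concatenate([as_tensor(v1_rows), as_tensor(v2_rows)], axis=1)
        return self.aux(pair).reshape((-1,))


def cgan_losses(v1_rows, v2_rows, v2_generated, discriminator: CganDiscriminator,
                config: CganConfig) -> dict[str, float]:
    """Generator-side loss components on aligned rows (diagnostic form).

    L_rec = MSE(v2, v_hat2); L_adv and L_aux are least-squares real/fake terms
    evaluated at the generator step (target 1 on generated data).
    """
    v1 = np.asarray(v1_rows, float)
    v2 = np.asarray(v2_rows, float)
    vh = v2_generated.data if isinstance(v2_generated, Tensor) else np.asarray(v2_generated, float)
    if v1.shape[0] != v2.shape[0] or v2.shape != vh.shape:
        raise ConfigError("rows are misaligned across views")
    l_rec = float(np.mean((v2 - vh) ** 2))
    l_adv = float(g_step_loss(discriminator.score_real_fake(vh).data))
    l_aux = float(g_step_loss(discriminator.score_pair(v1, vh).data))
    l_total = config.w_rec * l_rec + config.w_adv * l_adv + config.w_aux * l_aux
    return {"rec": l_rec, "adv": l_adv, "aux": l_aux, "total": l_total}


@dataclass
class CganModel:
    generator: CganGenerator
    discriminator: CganDiscriminator
    config: CganConfig
    v1_mean: np.ndarray
    v1_sd: np.ndarray
    v2_mean: np.ndarray
    v2_sd: np.ndarray

    def impute(self, v1_rows: np.ndarray) -> np.ndarray:
        self.generator.eval()
        x = (np.asarray(v1_rows, float) - self.v1_mean) / self.v1_sd
        out = self.generator(x).data
        return out * self.v2_sd + self.v2_mean


def _paired_rows(dataset: LongitudinalDataset, v1: str, v2: str, t: str,
                 sample_ids, row_filter=None) -> tuple[np.ndarray, np.ndarray]:
    """Rows of (v1, v2) at timepoint t where both views are fully present."""
    b1 = dataset.blocks[(v1, t)]
    b2 = dataset.blocks[(v2, t)]
    idx1 = b1.row_indices(sample_ids)
    idx2 = b2.row_indices(sample_ids)
    ok = b1.observed_mask[idx1].all(axis=1) & b2.observed_mask[idx2].all(axis=1)
    if row_filter is not None:
        ok &= row_filter
    return b1.values[idx1][ok], b2.values[idx2][ok]


def cgan_fit_and_impute(
    dataset: LongitudinalDataset,
    split: SplitAssignment,
    target: tuple[str, str],
    obs_num: int = 0,
    config: CganConfig | None = None,
    seed: int = 0,
    return_model: bool = False,
):
    """Train the cGAN on paired <v1, v2> rows and impute the target test block.

    Training pairs: all paired rows at the non-target timepoint(s), plus
    ``obs_num`` revealed paired rows at the target timepoint.  The trained
    generator is applied to the test v1 rows at the target timepoint.
    """
    config = config or CganConfig()
    v2, t2 = target
    views = [v for v in dataset.view_ids if v != v2]
    if not views:
        raise ConfigError("cGAN needs a second observed view")
    v1 = views[0]
    other_tps = [t for t in dataset.timepoint_ids
                 if t != t2 and (v1, t) in dataset.blocks and (v2, t) in dataset.blocks]
    if not other_tps:
        raise DataError("no paired timepoint to learn the v1->v2 mapping from")

    rng = np.random.default_rng(seed)
    train_pairs = [
        _paired_rows(dataset, v1, v2, t, split.train_ids) for t in other_tps
    ]
    if obs_num > 0:
        if (v2, t2) not in dataset.blocks:
            raise DataError("obs_num > 0 but the target block has no data to reveal")
        from .data import select_training_observations

        revealed = select_training_observations(
            dataset.blocks[(v2, t2)], split.train_ids, obs_num, seed)
        idx = revealed.row_indices(split.train_ids)
        keep = revealed.observed_mask[idx].all(axis=1)
        b1 = dataset.blocks[(v1, t2)]
        x1 = b1.values[b1.row_indices(split.train_ids)][keep]
        x2 = revealed.values[idx][keep]
        train_pairs.append((x1, x2))
    x1_train = np.concatenate([p[0] for p in train_pairs], axis=0)
    x2_train = np.concatenate([p[1] for p in train_pairs], axis=0)
    if x1_train.shape[0] == 0:
        raise DataError("zero paired training rows")
    val_pairs = [_paired_rows(dataset, v1, v2, t, split.validation_ids)
                 for t in other_tps]
    x1_val = np.concatenate([p[0] for p in val_pairs], axis=0)
    x2_val = np.concatenate([p[1] for p in val_pairs], axis=0)

    m1, s1 = x1_train.mean(axis=0), x1_train.std(axis=0, ddof=1)
    m2, s2 = x2_train.mean(axis=0), x2_train.std(axis=0, ddof=1)
    s1 = np.where(s1 > 0, s1, 1.0)
    s2 = np.where(s2 > 0, s2, 1.0)
    z1, z2 = (x1_train - m1) / s1, (x2_train - m2) / s2
    z1v, z2v = (x1_val - m1) / s1, (x2_val - m2) / s2

    gen = CganGenerator(z1.shape[1], z2.shape[1], config, rng)
    disc = CganDiscriminator(z1.shape[1], z2.shape[1], config, rng)
    opt_g = Adam(gen.parameters(), lr=config.learning_rate)
    opt_d = Adam(disc.parameters(), lr=config.learning_rate)

    n = z1.shape[0]
    best_val = np.inf
    best_state = gen.get_state()
    best_epoch = -1
    history = []
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            sel = order[start:start + config.batch_size]
            if sel.size < 2:
                continue
            xb1, xb2 = z1[sel], z2[sel]
            gen.train()
            disc.train()
            fake = gen(xb1)
            # discriminator update on constant fakes
            d_loss = (d_step_loss(disc.score_real_fake(xb2),
                                  disc.score_real_fake(fake.data))
                      + d_step_loss(disc.score_pair(xb1, xb2),
                                    disc.score_pair(xb1, fake.data))) * 0.5
            opt_d.zero_grad()
            d_loss.backward()
            opt_d.step()
            # generator update
            diff = fake - Tensor(xb2)
            l_rec = (diff * diff).mean()
            l_adv = g_step_loss(disc.score_real_fake(fake))
            l_aux = g_step_loss(disc.score_pair(xb1, fake))
            total = l_rec * config.w_rec + l_adv * config.w_adv + l_aux * config.w_aux
            opt_g.zero_grad()
            opt_d.zero_grad()
            total.backward()
            opt_g.step()
            opt_d.zero_grad()
        gen.eval()
        val_mse = float(np.mean((gen(z1v).data - z2v) ** 2))
        history.append({"epoch": epoch, "val_mse": val_mse})
        if val_mse < best_val:
            best_val = val_mse
            best_state = gen.get_state()
            best_epoch = epoch
        elif epoch - best_epoch >= config.early_stop_patience:
            break
    gen.set_state(best_state)
    model = CganModel(gen, disc, config, m1, s1, m2, s2)

    test_b1 = dataset.blocks[(v1, t2)]
    idx = test_b1.row_indices(split.test_ids)
    test_rows = test_b1.values[idx]
    test_mask = test_b1.observed_mask[idx]
    if not test_mask.all():
        # missing points in the observed input view: mean-encode with the
        # training means of the input view
        test_rows = np.where(test_mask, test_rows, m1[None, :])
    imputed = model.impute(test_rows)
    n_vars = imputed.shape[1]
    var_ids = (dataset.blocks[(v2, t2)].variable_ids
               if (v2, t2) in dataset.blocks
               else dataset.blocks[(v2, other_tps[0])].variable_ids[:n_vars])
    block = DataBlock(v2, t2, list(split.test_ids), list(var_ids), imputed,
                      np.ones_like(imputed, dtype=bool))
    if return_model:
        return block, model, history
    return block
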