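"""LEOPARD training: minibatch assembly, in-loop missing-view generation,
alternating discriminator/generator updates, and early stopping.

Training composition follows the method's defining property: every observed
block contributes, including samples present in only one view, plus the
``obs_num`` revealed rows of the to-be-completed block.  In each iteration
the missing view is generated first (content from the same view at the
nearest observed timepoint, temporal knowledge from the other view at the
target timepoint) so its re-encoded representations can participate in the
contrastive and reconstruction terms.  The reconstruction loss is computed
only for outputs whose content and temporal sources come from *different*
source classes - the cross-class constraint that forces genuine
disentanglement rather than per-class auto-encoding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import DataBlock, LongitudinalDataset, SplitAssignment
from .errors import ConfigError, DataError, NumericError
from .networks import LeopardModel, NetworkConfig
from .nn import Adam, Tensor, concatenate
from .objectives import (
    LossWeights,
    g_step_loss,
    masked_reconstruction_loss,
    ntxent,
)

__all__ = ["TrainingConfig", "Trainer", "fit"]


@dataclass
class TrainingConfig:
    batch_size: int = 64
    max_epochs: int = 600
    early_stop_patience: int = 30
    seed: int = 0
    obs_num: int = 0
    included_timepoints: list[str] | None = None
    update_discriminator: bool = True

    def __post_init__(self):
        if self.batch_size < 2:
            raise ConfigError("batch_size must be >= 2")
        if self.max_epochs < 1:
            raise ConfigError("max_epochs must be >= 1")


@dataclass
class _ClassData:
    """Per source class: standardized, mean-encoded matrices aligned to a split."""

    key: tuple[str, str]
    x: np.ndarray               # rows x variables, standardized + mean-encoded
    imputation_mask: np.ndarray  # cells that were mean-encoded (excluded from L_rec)
    row_observed: np.ndarray     # rows with at least one measured cell


@dataclass
class Minibatch:
    indices: np.ndarray
    classes: dict[tuple[str, str], _ClassData]
    content_pair_families: list[tuple[tuple[str, str], tuple[str, str]]]
    temporal_pair_families: list[tuple[tuple[str, str], tuple[str, str]]]


def _nearest_timepoint(timepoints: list[str], available: list[str], target: str) -> str:
    ti = timepoints.index(target)
    return min(available, key=lambda t: (abs(timepoints.index(t) - ti),
                                         timepoints.index(t)))


class Trainer:
    """Owns the prepared arrays, the model, and both optimizers."""

    def __init__(
        self,
        dataset: LongitudinalDataset,
        split: SplitAssignment,
        target: tuple[str, str],
        training: TrainingConfig,
        network: NetworkConfig,
        weights: LossWeights,
    ):
        if not split.train_ids:
            raise ConfigError("empty training split")
        self.dataset = dataset
        self.split = split
        self.target = target
        self.training = training
        self.weights = weights
        self.timepoints = list(dataset.timepoint_ids)
        if training.included_timepoints is not None:
            self.timepoints = [t for t in self.timepoints
                               if t in training.included_timepoints]
            if target[1] not in self.timepoints:
                raise ConfigError("target timepoint excluded by included_timepoints")

        keys = [k for k in dataset.iter_keys() if k[1] in self.timepoints]
        self.observed_classes = [k for k in keys
                                 if k in dataset.blocks and k != target]
        self.all_classes = list(keys)
        if target not in self.all_classes:
            raise ConfigError(f"target block {target} not declared in dataset")

        view_widths: dict[str, int] = {}
        for (v, _t), block in dataset.blocks.items():
            view_widths.setdefault(v, block.n_variables)
        if not network.view_widths:
            network.view_widths = view_widths
        self.network = network
        self.model = LeopardModel(network, self.all_classes, seed=training.seed)
        self._fit_standardization()
        self.train_data = self._prepare_split(split.train_ids, is_train=True)
        self.val_data = self._prepare_split(split.validation_ids, is_train=False)
        self._plan_sources()
        self.opt_g = Adam(self.model.generator_parameters(), lr=network.learning_rate,
                          betas=network.adam_betas)
        self.opt_d = Adam(self.model.discriminator_parameters(),
                          lr=network.learning_rate, betas=network.adam_betas)
        self.rng = np.random.default_rng(training.seed)

    # ------------------------------------------------------------ preparation
    def _train_block(self, key: tuple[str, str]) -> DataBlock | None:
        """The block for ``key`` with obs_num retention applied to the target."""
        if key == self.target:
            if key not in self.dataset.blocks:
                return None
            from .data import select_training_observations

            block = select_training_observations(
                self.dataset.blocks[key], self.split.train_ids,
                self.training.obs_num, self.training.seed)
            # rows outside the training split are never read during training
            return block
        return self.dataset.blocks.get(key)

    def _fit_standardization(self) -> None:
        """Per-view z-scoring statistics pooled over training observed cells
        across timepoints, so temporal shifts survive standardization."""
        per_view: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
        for key in self.all_classes:
            block = self._train_block(key)
            if block is None:
                continue
            rows = block.row_indices(self.split.train_ids)
            per_view.setdefault(key[0], []).append(
                (block.values[rows], block.observed_mask[rows]))
        for view, parts in per_view.items():
            vals = np.concatenate([p[0] for p in parts], axis=0)
            mask = np.concatenate([p[1] for p in parts], axis=0)
            counts = mask.sum(axis=0)
            if np.any(counts == 0):
                raise DataError(f"view {view!r} has variables with no observed "
                                f"training cells")
            mean = np.where(mask, vals, 0.0).sum(axis=0) / counts
            sq = np.where(mask, (vals - mean) ** 2, 0.0).sum(axis=0)
            sd = np.sqrt(sq / np.maximum(counts - 1, 1))
            sd = np.where(sd > 0, sd, 1.0)
            self.model.set_standardization(view, mean, sd)

    def _prepare_split(self, sample_ids, is_train: bool) -> dict:
        out: dict[tuple[str, str], _ClassData] = {}
        sample_ids = list(sample_ids)
        for key in self.all_classes:
            if key == self.target:
                if not is_train:
                    continue  # the target block is never read outside training
                block = self._train_block(key)
            else:
                block = self.dataset.blocks.get(key)
            if block is None:
                continue
            rows = block.row_indices(sample_ids)
            vals = block.values[rows]
            mask = block.observed_mask[rows]
            row_obs = mask.any(axis=1)
            means = self.model.standardize_mean[key[0]]
            filled = np.where(mask, vals, means[None, :])
            x = self.model.standardize(filled, key[0])
            x[~row_obs] = 0.0
            out[key] = _ClassData(key, x, ~mask, row_obs)
        return out

    def _plan_sources(self) -> None:
        """Resolve, per class, the cross-class content/temporal sources.

        The target block is always generated in-loop (its re-encoded
        representations stand in for the missing source class); obs_num
        retained rows additionally supervise it as real data.
        """
        self.generated_classes = [k for k in self.all_classes
                                  if k == self.target or k not in self.dataset.blocks]
        available = set(self.all_classes)
        self.gen_sources: dict[tuple[str, str], tuple[tuple[str, str], tuple[str, str]]] = {}
        for key in self.generated_classes:
            v, t = key
            content_tps = [tp for (vv, tp) in self.observed_classes if vv == v]
            temporal_views = [vv for (vv, tp) in self.observed_classes if tp == t]
            if not content_tps or not temporal_views:
                raise DataError(f"cannot generate block {key}: no observed content "
                                f"or temporal source")
            c_tp = _nearest_timepoint(self.timepoints, content_tps, t)
            self.gen_sources[key] = ((v, c_tp), (temporal_views[0], t))
        # Reconstructions of block (v, t): content from view v at another
        # timepoint, temporal from any class at timepoint t other than the
        # content source.  Both the cross-view pair (paper's canonical
        # example) and the within-view pair (direct temporal transfer
        # supervision) are admissible - only content and temporal drawn from
        # the *same* source class are excluded from optimization.
        self.recon_sources: dict[tuple[str, str],
                                 list[tuple[tuple[str, str], tuple[str, str]]]] = {}
        for key in self.all_classes:
            v, t = key
            content_tps = [tp for (vv, tp) in available
                           if vv == v and tp != t]
            if not content_tps:
                continue
            observed_tps = [tp for tp in content_tps
                            if (v, tp) not in self.generated_classes]
            c_tp = _nearest_timepoint(self.timepoints, observed_tps or content_tps, t)
            c_src = (v, c_tp)
            pairs = []
            for t_src in [(vv, tp) for (vv, tp) in available if tp == t]:
                if t_src == c_src:
                    continue
                if t_src == key and key in self.generated_classes:
                    continue  # temporal of its own generated data: circular
                pairs.append((c_src, t_src))
            if pairs:
                self.recon_sources[key] = pairs
        self.content_pair_families = []
        for v in self.model.views:
            tps = [t for t in self.timepoints if (v, t) in self.all_classes]
            for i in range(len(tps)):
                for j in range(i + 1, len(tps)):
                    self.content_pair_families.append(((v, tps[i]), (v, tps[j])))
        self.temporal_pair_families = []
        for t in self.timepoints:
            views = [v for v in self.model.views if (v, t) in self.all_classes]
            for i in range(len(views)):
                for j in range(i + 1, len(views)):
                    self.temporal_pair_families.append(((views[i], t), (views[j], t)))

    # ------------------------------------------------------------- minibatches
    def assemble_minibatch(self, batch_indices) -> Minibatch:
        """Aligned per-class rows for a batch plus the positive-pair structure.

        Every sample must have at least one observed block.
        """
        idx = np.asarray(batch_indices, dtype=int)
        classes = {}
        any_obs = np.zeros(len(idx), dtype=bool)
        for key, cd in self.train_data.items():
            classes[key] = _ClassData(key, cd.x[idx], cd.imputation_mask[idx],
                                      cd.row_observed[idx])
            any_obs |= classes[key].row_observed
        if not np.all(any_obs):
            raise DataError("batch contains samples with zero observed blocks")
        return Minibatch(idx, classes, list(self.content_pair_families),
                         list(self.temporal_pair_families))

    # ------------------------------------------------------------ forward pass
    def _forward(self, classes: dict) -> dict:
        """Build the full generator-side graph for one batch of class rows."""
        model = self.model
        reps: dict[tuple[str, str], tuple[Tensor, Tensor]] = {}
        avail: dict[tuple[str, str], np.ndarray] = {}
        for key, cd in classes.items():
            z_pre = model.pre_embed(cd.x, key[0])
            reps[key] = (model.encode_content(z_pre), model.encode_temporal(z_pre))
            avail[key] = cd.row_observed
        generated: dict[tuple[str, str], Tensor] = {}
        for key in self.generated_classes:
            (c_src, t_src) = self.gen_sources[key]
            z_c = reps[c_src][0]
            z_t = reps[t_src][1]
            x_hat = model.generate_std(z_c, z_t, key[0])
            z_pre_hat = model.pre_embed(x_hat, key[0])
            reps[key] = (model.encode_content(z_pre_hat),
                         model.encode_temporal(z_pre_hat))
            generated[key] = x_hat
            avail[key] = avail[c_src] & avail[t_src]
        recons: list[tuple[tuple[str, str], Tensor, np.ndarray]] = []
        for key, pairs in self.recon_sources.items():
            if key not in classes or not classes[key].row_observed.any():
                continue  # nothing real to reconstruct against
            for c_src, t_src in pairs:
                rows = classes[key].row_observed & avail[c_src] & avail[t_src]
                if not rows.any():
                    continue
                if key in generated and (c_src, t_src) == self.gen_sources.get(key):
                    x_hat = generated[key]
                else:
                    x_hat = model.generate_std(reps[c_src][0], reps[t_src][1], key[0])
                recons.append((key, x_hat, rows))
        return {"reps": reps, "avail": avail, "generated": generated,
                "recons": recons}

    def _contrastive(self, fw: dict) -> Tensor | float:
        losses = []
        for kind, families in (("content", self.content_pair_families),
                               ("temporal", self.temporal_pair_families)):
            chunks, pairs, offset = [], [], 0
            for a, b in families:
                if a not in fw["reps"] or b not in fw["reps"]:
                    continue
                rows = fw["avail"][a] & fw["avail"][b]
                n = int(rows.sum())
                if n == 0:
                    continue
                sel = np.flatnonzero(rows)
                za = fw["reps"][a][0 if kind == "content" else 1][sel]
                zb = fw["reps"][b][0 if kind == "content" else 1][sel]
                chunks.extend([za, zb])
                pairs.extend([(offset + i, offset + n + i) for i in range(n)])
                offset += 2 * n
            if not chunks:
                losses.append(Tensor(0.0))
                continue
            z = concatenate(chunks, axis=0)
            losses.append(ntxent(z, np.asarray(pairs), self.network.temperature))
        return (losses[0] + losses[1]) * 0.5

    def _reconstruction(self, fw: dict, classes: dict) -> Tensor:
        terms = []
        for key, x_hat, rows in fw["recons"]:
            cd = classes[key]
            sel = np.flatnonzero(rows)
            terms.append(masked_reconstruction_loss(
                cd.x[sel], x_hat[sel], cd.imputation_mask[sel]))
        if not terms:
            raise DataError("no cross-class reconstruction targets in batch")
        total = terms[0]
        for t in terms[1:]:
            total = total + t
        return total * (1.0 / len(terms))

    def _representation(self, fw: dict) -> Tensor:
        model = self.model
        c_terms, t_terms = [], []
        for key, x_hat, rows in fw["recons"]:
            sel = np.flatnonzero(rows)
            z_pre_hat = model.pre_embed(x_hat[sel], key[0])
            zc_hat = model.encode_content(z_pre_hat)
            zt_hat = model.encode_temporal(z_pre_hat)
            zc, zt = fw["reps"][key]
            dc = zc_hat - zc[sel]
            dt = zt_hat - zt[sel]
            c_terms.append((dc * dc).mean())
            t_terms.append((dt * dt).mean())
        if not c_terms:
            return Tensor(0.0)
        c_sum = c_terms[0]
        t_sum = t_terms[0]
        for c in c_terms[1:]:
            c_sum = c_sum + c
        for t in t_terms[1:]:
            t_sum = t_sum + t
        return (c_sum * (1.0 / len(c_terms)) + t_sum * (1.0 / len(t_terms))) * 0.5

    # ------------------------------------------------------------- train loop
    def train_step(self, batch: Minibatch) -> dict[str, float]:
        model = self.model
        model.train()
        fw = self._forward(batch.classes)

        # --- discriminator update (fakes treated as constants)
        if self.training.update_discriminator:
            d_terms = []
            recon_keys = {key for key, _x, _r in fw["recons"]}
            for key in recon_keys:
                cd = batch.classes[key]
                real_rows = np.flatnonzero(cd.row_observed)
                real = model.head_score(cd.x[real_rows], key)
                fakes = [(model.head_score(x_hat.data[np.flatnonzero(rows)], key))
                         for k2, x_hat, rows in fw["recons"] if k2 == key]
                fake_term = fakes[0] ** 2
                fake_loss = fake_term.mean()
                for f in fakes[1:]:
                    fake_loss = fake_loss + (f**2).mean()
                fake_loss = fake_loss * (1.0 / len(fakes))
                d_terms.append(((real - 1.0) ** 2).mean() + fake_loss)
            # classes with no real data contribute no adversarial term: their
            # head has nothing genuine to contrast against
            if d_terms:
                d_loss = d_terms[0]
                for t in d_terms[1:]:
                    d_loss = d_loss + t
                d_loss = d_loss * (1.0 / len(d_terms))
                self.opt_d.zero_grad()
                d_loss.backward()
                self.opt_d.step()
                d_loss_val = float(d_loss.data)
            else:
                d_loss_val = np.nan
        else:
            d_loss_val = np.nan

        # --- generator-side update (Eq.-7-style total with G-step adversarial)
        l_rec = self._reconstruction(fw, batch.classes)
        l_con = self._contrastive(fw)
        l_rep = self._representation(fw)
        g_terms = []
        for key, x_hat, rows in fw["recons"]:
            sel = np.flatnonzero(rows)
            g_terms.append(g_step_loss(model.head_score(x_hat[sel], key)))
        if g_terms:
            l_adv = g_terms[0]
            for t in g_terms[1:]:
                l_adv = l_adv + t
            l_adv = l_adv * (1.0 / len(g_terms))
        else:
            l_adv = Tensor(0.0)
        w = self.weights
        total = (l_con * w.w_con + l_rep * w.w_rep + l_rec * w.w_rec
                 + l_adv * w.w_adv)
        if not np.isfinite(total.data):
            raise NumericError("non-finite training loss; components: "
                               f"rec={float(l_rec.data):.4g} con={float(l_con.data):.4g} "
                               f"rep={float(l_rep.data):.4g} adv={float(l_adv.data):.4g}")
        self.opt_g.zero_grad()
        self.opt_d.zero_grad()
        total.backward()
        self.opt_g.step()
        self.opt_d.zero_grad()
        return {
            "rec": float(l_rec.data),
            "con": float(l_con.data),
            "rep": float(l_rep.data),
            "adv": float(l_adv.data),
            "d": d_loss_val,
            "total": float(total.data),
        }

    def validation_reconstruction_mse(self) -> float:
        """Cross-class reconstruction MSE over observed validation blocks."""
        model = self.model
        model.eval()
        fw = self._forward(self.val_data)
        terms = []
        for key, x_hat, rows in fw["recons"]:
            cd = self.val_data[key]
            sel = np.flatnonzero(rows)
            terms.append(float(masked_reconstruction_loss(
                cd.x[sel], x_hat.data[sel], cd.imputation_mask[sel])))
        model.train()
        if not terms:
            raise DataError("no observed validation blocks to score")
        return float(np.mean(terms))

    def fit(self) -> tuple[LeopardModel, list[dict]]:
        n = len(self.split.train_ids)
        history: list[dict] = []
        best_val = np.inf
        best_state = self.model.get_state()
        best_epoch = -1
        patience = self.training.early_stop_patience
        for epoch in range(self.training.max_epochs):
            order = self.rng.permutation(n)
            sums: dict[str, float] = {}
            steps = 0
            for start in range(0, n, self.training.batch_size):
                idx = order[start:start + self.training.batch_size]
                if idx.size < 2:
                    continue
                comps = self.train_step(self.assemble_minibatch(idx))
                for k, v in comps.items():
                    sums[k] = sums.get(k, 0.0) + v
                steps += 1
            record = {k: v / max(steps, 1) for k, v in sums.items()}
            record["epoch"] = epoch
            record["val_mse"] = self.validation_reconstruction_mse()
            history.append(record)
            if record["val_mse"] < best_val:
                best_val = record["val_mse"]
                best_state = self.model.get_state()
                best_epoch = epoch
            elif epoch - best_epoch >= patience:
                break
        self.model.set_state(best_state)
        self.model.eval()
        return self.model, history


def fit(
    dataset: LongitudinalDataset,
    split: SplitAssignment,
    target: tuple[str, str],
    training: TrainingConfig | None = None,
    network: NetworkConfig | None = None,
    weights: LossWeights | None = None,
) -> tuple[LeopardModel, list[dict]]:
    """Train LEOPARD to complete ``target``; returns the best-validation model
    (early stopping on observed-block reconstruction MSE) and the history."""
    trainer = Trainer(dataset, split, target,
                      training or TrainingConfig(),
                      network or NetworkConfig(),
                      weights or LossWeights())
    return trainer.fit()
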