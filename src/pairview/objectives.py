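"""Training objective: supervised loss on the aggregated and sampled per-view
predictions, plus two consistency terms (embedding-space InfoNCE between two
sampled views, and output-space MSE toward the aggregated soft label), with
the Adam + warmup/polynomial-decay training loop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from . import nn, views
from .data import RunConfig, TripletRecord
from .model import DrugCombinationModel, ForwardResult

logger = logging.getLogger("pairview")


@dataclass
class LossBreakdown:
    total: float
    supervised_main: float
    supervised_aux: float
    infonce: float
    mse: float
    lambda_aux: float
    lambda_infonce: float
    lambda_mse: float

    def recompose(self) -> float:
        return (self.supervised_main + self.lambda_aux * self.supervised_aux
                + self.lambda_infonce * self.infonce + self.lambda_mse * self.mse)


def sample_modality_pairs(available_keys, r: int, rng: np.random.Generator):
    """Draw min(r, #keys) distinct view keys uniformly without replacement."""
    keys = sorted(available_keys, key=lambda k: views.VIEW_KEY_INDEX[k])
    if not keys:
        raise ValueError("no available view keys to sample from")
    n = min(r, len(keys))
    chosen = rng.choice(len(keys), size=n, replace=False)
    return [keys[i] for i in sorted(chosen)]


def _bce(pred: nn.Tensor, labels: np.ndarray) -> nn.Tensor:
    y = nn.constant(labels)
    p = pred.clamp(views.EPS_CLAMP, 1.0 - views.EPS_CLAMP)
    return -(y * p.log() + (1.0 - y) * (1.0 - p).log()).mean()


def _mse(pred: nn.Tensor, labels: np.ndarray) -> nn.Tensor:
    return ((pred - nn.constant(labels)) ** 2.0).mean()


def supervised_loss(labels: np.ndarray, y_star: nn.Tensor,
                    sampled_views, lambda_aux: float,
                    regression: bool = False) -> tuple[nn.Tensor, float, float]:
    """Main loss on the aggregated prediction plus lambda_aux times the same
    loss on each sampled per-view prediction (binary cross-entropy, or squared
    error for the regression task).

    `sampled_views` is a list of (row_indices, prediction_tensor) pairs — a
    view contributes only the triplets for which it exists.
    Returns (loss tensor, main value, aux value).
    """
    labels = np.asarray(labels, dtype=float)
    fn = _mse if regression else _bce
    main = fn(y_star, labels)
    aux_terms = [fn(pred, labels[rows]) for rows, pred in sampled_views
                 if len(rows) > 0]
    if aux_terms and lambda_aux > 0:
        aux = aux_terms[0]
        for t in aux_terms[1:]:
            aux = aux + t
        total = main + lambda_aux * aux
        return total, float(main.data), float(aux.data)
    aux_val = float(sum(float(t.data) for t in aux_terms))
    return main, float(main.data), aux_val


def consistency_infonce(z1: nn.Tensor, z2: nn.Tensor) -> nn.Tensor:
    """InfoNCE over cosine similarities matching each triplet's first sampled
    view embedding to its own second sampled view against the whole batch."""
    if z1.shape[0] < 2:
        raise ValueError("consistency InfoNCE needs a batch of >= 2")
    for z in (z1, z2):
        if np.any(np.linalg.norm(z.data, axis=-1) == 0):
            raise ValueError("zero-norm view embedding in consistency loss")
    n1 = z1 * ((z1 * z1).sum(axis=1, keepdims=True) ** -0.5)
    n2 = z2 * ((z2 * z2).sum(axis=1, keepdims=True) ** -0.5)
    from .encoders import infonce

    return infonce(n1 @ n2.T)


def consistency_mse(y_star: nn.Tensor, sampled_views) -> nn.Tensor:
    """Squared deviation of each sampled per-view prediction from the
    aggregated prediction treated as a fixed soft label (no gradient flows
    into y*); mean over the batch, summed over the sampled views."""
    soft = y_star.data  # detached
    terms = []
    for rows, pred in sampled_views:
        if len(rows) == 0:
            continue
        terms.append(((pred - nn.constant(soft[rows])) ** 2.0).mean())
    if not terms:
        return nn.constant(0.0)
    out = terms[0]
    for t in terms[1:]:
        out = out + t
    return out


def compute_losses(model: DrugCombinationModel, batch: list[TripletRecord],
                   config: RunConfig, rng: np.random.Generator,
                   train: bool = True) -> tuple[nn.Tensor, LossBreakdown, ForwardResult]:
    res = model.forward_batch(batch, train=train, rng=rng)
    labels = np.array([t.label for t in batch], dtype=float)
    regression = model.task == "xenograft"

    available = [k for k, (rows, _) in res.per_key.items() if len(rows)]
    sampled = sample_modality_pairs(available, config.r_sampled_pairs, rng)
    sampled_views = [res.view_predictions(k) for k in sampled]

    total, main_val, aux_val = supervised_loss(
        labels, res.y_star, sampled_views, config.lambda_aux, regression=regression)

    nce_val = 0.0
    if config.lambda_infonce > 0 and len(sampled) >= 2:
        rows1, z1 = res.view_embeddings(sampled[0])
        rows2, z2 = res.view_embeddings(sampled[1])
        common, i1, i2 = np.intersect1d(rows1, rows2, return_indices=True)
        # drop rows where ReLU/dropout zeroed a whole embedding (cosine undefined)
        ok = ((np.linalg.norm(z1.data[i1], axis=1) > 0)
              & (np.linalg.norm(z2.data[i2], axis=1) > 0))
        i1, i2 = i1[ok], i2[ok]
        if ok.sum() >= 2:
            nce = consistency_infonce(z1.take_rows(i1), z2.take_rows(i2))
            total = total + config.lambda_infonce * nce
            nce_val = float(nce.data)

    mse_val = 0.0
    if config.lambda_mse > 0:
        mse = consistency_mse(res.y_star, sampled_views)
        total = total + config.lambda_mse * mse
        mse_val = float(mse.data)

    breakdown = LossBreakdown(
        total=float(total.data), supervised_main=main_val,
        supervised_aux=aux_val, infonce=nce_val, mse=mse_val,
        lambda_aux=config.lambda_aux, lambda_infonce=config.lambda_infonce,
        lambda_mse=config.lambda_mse)
    return total, breakdown, res


def train(model: DrugCombinationModel, triplets: list[TripletRecord],
          config: Optional[RunConfig] = None, steps: Optional[int] = None,
          callback: Optional[Callable[[int, LossBreakdown], None]] = None,
          valid_set: Optional[list[TripletRecord]] = None,
          eval_every: int = 100,
          ) -> list[LossBreakdown]:
    """Adam optimization with linear warmup and polynomial decay.

    Batches are drawn from `triplets` using the config seed, so two runs with
    identical config bytes produce identical loss histories.  Aborts with a
    diagnostic dump if the loss turns non-finite.  When `valid_set` is given,
    the validation score (balanced accuracy for classification, negative
    squared error for regression) is evaluated every `eval_every` steps and
    the best-scoring parameters are restored at the end (best-validation
    checkpointing).
    """
    config = config or model.config
    steps = steps if steps is not None else config.steps
    if not triplets:
        raise ValueError("empty training set")
    rng = config.rng(stream=2)
    params = model.parameters()
    opt = nn.Adam(params, lr=config.learning_rate,
                  weight_decay=config.weight_decay)
    history = []
    avg_start = steps - int(round(config.polyak_frac * steps))
    avg = None
    n_avg = 0

    best_score, best_params = -np.inf, None

    def _valid_score():
        scores = model.predict(valid_set)
        labels = np.array([t.label for t in valid_set])
        if model.task == "xenograft":
            return -float(np.mean((scores - labels) ** 2))
        calls = (scores >= 0.5).astype(int)
        pos, neg = labels == 1, labels == 0
        if not pos.any() or not neg.any():
            return -float(np.mean((scores - labels) ** 2))
        return 0.5 * (calls[pos].mean() + (1 - calls[neg]).mean())
    for step in range(steps):
        idx = rng.choice(len(triplets), size=min(config.batch_size, len(triplets)),
                         replace=False)
        batch = [triplets[i] for i in idx]
        total, breakdown, _ = compute_losses(model, batch, config, rng, train=True)
        if not np.isfinite(breakdown.total):
            logger.error("non-finite loss at step %d; offending batch: %s",
                         step, [(t.drug_a, t.drug_b, t.context_id, t.label)
                                for t in batch])
            raise FloatingPointError(f"non-finite loss at step {step}")
        opt.zero_grad()
        total.backward()
        lr = nn.warmup_poly_lr(step, config.learning_rate, config.warmup_steps,
                               steps, power=config.poly_decay_power)
        opt.step(lr=lr)
        if config.polyak_frac > 0 and step >= avg_start:
            if avg is None:
                avg = [p.data.copy() for p in params]
            else:
                for a, p in zip(avg, params):
                    a += p.data
            n_avg += 1
        history.append(breakdown)
        if valid_set is not None and (step + 1) % eval_every == 0:
            score = _valid_score()
            if score > best_score:
                best_score = score
                best_params = [p.data.copy() for p in params]
        if callback is not None:
            callback(step, breakdown)
    if valid_set is not None and best_params is not None:
        final = _valid_score()
        if final > best_score:
            best_params = None  # final parameters already best
        else:
            for p, b in zip(params, best_params):
                p.data = b
    if avg is not None:
        # Polyak tail averaging: evaluate with the mean of late-step parameters
        for a, p in zip(avg, params):
            p.data = a / n_avg
    return history


def grid_search_learning_rate(make_model: Callable[[], DrugCombinationModel],
                              train_set, valid_set, config: RunConfig,
                              score_fn, steps: int) -> tuple[float, dict]:
    """Fit one model per learning rate in the config grid and return the rate
    with the best validation score."""
    results = {}
    for lr in config.learning_rate_grid:
        cfg = RunConfig(**{**config.__dict__, "learning_rate": lr})
        m = make_model()
        m.config = cfg
        train(m, train_set, cfg, steps=steps)
        results[lr] = score_fn(m, valid_set)
    best = max(results, key=results.get)
    return best, results
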