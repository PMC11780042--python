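"""Seeded minibatch training loop with optional early stopping."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor
from .optim import Adam


def train_model(model, X: np.ndarray, Y: np.ndarray, loss_fn, *, epochs: int = 50,
                batch_size: int = 8, lr: float = 1e-3, seed: int = 0,
                val_fraction: float = 0.0, patience: int = 0, verbose: bool = False,
                augment=None):
    """Train `model` on arrays X (N,C,H,W) and Y (targets, leading axis N).

    Returns a history dict with per-epoch train (and validation) losses.
    With `val_fraction > 0` and `patience > 0`, stops when the validation
    loss has not improved for `patience` epochs and restores the best
    weights.  `augment`, if given, is called as ``augment(Xb, Yb, rng)``
    on every training batch and must return transformed copies;
    validation batches are never augmented.
    """
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    idx = rng.permutation(n)
    n_val = int(round(n * val_fraction)) if val_fraction > 0 else 0
    val_idx, tr_idx = idx[:n_val], idx[n_val:]
    opt = Adam(model.parameters(), lr=lr)
    history = {"train_loss": [], "val_loss": []}
    best_val, best_state, bad = np.inf, None, 0

    for epoch in range(epochs):
        model.train(True)
        order = rng.permutation(tr_idx)
        losses = []
        for start in range(0, len(order), batch_size):
            batch = order[start:start + batch_size]
            xb, yb = X[batch], Y[batch]
            if augment is not None:
                xb, yb = augment(xb, yb, rng)
            pred = model(Tensor(xb))
            loss = loss_fn(pred, yb)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history["train_loss"].append(float(np.mean(losses)))

        if n_val > 0:
            vl = evaluate_loss(model, X[val_idx], Y[val_idx], loss_fn, batch_size=batch_size)
            history["val_loss"].append(vl)
            if vl < best_val - 1e-6:
                best_val, bad = vl, 0
                best_state = {k: v.copy() for k, v in model.state_dict().items()}
            else:
                bad += 1
                if patience and bad >= patience:
                    break
        if verbose:
            msg = f"epoch {epoch + 1}: train {history['train_loss'][-1]:.5f}"
            if history["val_loss"]:
                msg += f" val {history['val_loss'][-1]:.5f}"
            print(msg)

    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return history


def evaluate_loss(model, X, Y, loss_fn, batch_size: int = 8) -> float:
    model.eval()
    losses, weights = [], []
    for start in range(0, X.shape[0], batch_size):
        sl = slice(start, start + batch_size)
        loss = loss_fn(model(Tensor(X[sl])), Y[sl])
        losses.append(float(loss.data))
        weights.append(X[sl].shape[0])
    return float(np.average(losses, weights=weights))


def predict_batched(model, X: np.ndarray, batch_size: int = 8) -> np.ndarray:
    model.eval()
    outs = [model(Tensor(X[s:s + batch_size])).data for s in range(0, X.shape[0], batch_size)]
    return np.concatenate(outs, axis=0)
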