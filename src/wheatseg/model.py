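"""Scikit-learn style estimator around the numpy U-Net.

`UNetSegmenter` exposes the familiar fit/predict surface: `fit(X, y)` trains
with SGD on the compound Dice+BCE loss, tracking per-epoch train/validation
loss and keeping the weights of the epoch with the smallest validation loss
(the model-selection rule used throughout the pipeline). `predict` returns
binary masks, `predict_proba` per-pixel head probabilities. Images of
arbitrary size are zero-padded to the model stride and predictions cropped
back.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .errors import DivergenceError, InputError
from .losses import LossConfig, combined_loss, combined_loss_grad
from .metrics import dice as dice_score
from .nn import SGD, ModelSpec, UNet

Images = "list[np.ndarray] | np.ndarray"


def pad_to_divisor(image: np.ndarray, divisor: int) -> tuple[np.ndarray, tuple[int, int]]:
    """Zero-pad (H, W, ...) to the next multiple of ``divisor``; return pad sizes."""
    h, w = image.shape[:2]
    ph = (-h) % divisor
    pw = (-w) % divisor
    if ph == 0 and pw == 0:
        return image, (0, 0)
    pad = [(0, ph), (0, pw)] + [(0, 0)] * (image.ndim - 2)
    return np.pad(image, pad), (ph, pw)


def _as_list(X) -> list[np.ndarray]:
    if isinstance(X, np.ndarray) and X.ndim == 4:
        return [X[i] for i in range(X.shape[0])]
    if isinstance(X, np.ndarray) and X.ndim == 3:
        return [X]
    return list(X)


class UNetSegmenter(BaseEstimator):
    """Binary head/background segmenter trained with Dice+BCE and SGD.

    Parameters
    ----------
    encoder : preset name, "tiny" (~27k parameters) or "base" (~440k).
    epochs, learning_rate, momentum, batch_size : SGD schedule; the study
        protocol uses SGD with learning rate 0.01.
    epsilon : Dice smoothing constant of the loss.
    threshold : probability cut for `predict`.
    online_augment : re-augment each training image on every access
        (flips/right-angle rotations with the matching mask transform, plus
        photometric jitter on the image only).
    seed : seeds weight init, batch shuffling and online augmentation.

    Fitted attributes: ``net_`` (the network, at the selected epoch),
    ``history_`` (list of per-epoch dicts with train/val loss),
    ``selected_epoch_`` (1-based argmin of validation loss) and
    ``best_val_loss_``.
    """

    def __init__(
        self,
        encoder: str = "tiny",
        epochs: int = 10,
        learning_rate: float = 0.01,
        momentum: float = 0.9,
        batch_size: int = 8,
        epsilon: float = 1e-5,
        threshold: float = 0.5,
        online_augment: bool = False,
        seed: int = 0,
    ):
        self.encoder = encoder
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.batch_size = batch_size
        self.epsilon = epsilon
        self.threshold = threshold
        self.online_augment = online_augment
        self.seed = seed

    # ------------------------------------------------------------------ fit

    def fit(self, X, y, X_val=None, y_val=None, init_state: dict | None = None):
        X = _as_list(X)
        y = [np.asarray(m, dtype=np.uint8) for m in _as_list(y)]
        if len(X) == 0:
            raise InputError("training set is empty")
        if len(X) != len(y):
            raise InputError(f"{len(X)} images but {len(y)} masks")
        has_val = X_val is not None and y_val is not None and len(_as_list(X_val)) > 0
        if has_val:
            X_val = _as_list(X_val)
            y_val = [np.asarray(m, dtype=np.uint8) for m in _as_list(y_val)]

        net = UNet(ModelSpec(encoder_name=self.encoder), seed=self.seed)
        if init_state is not None:
            net.load_state_dict(init_state)
        # pad every image (train and val) to one divisor-aligned canvas so
        # rotation-expanded sets with angle-dependent sizes batch uniformly
        all_imgs = X + (X_val if has_val else [])
        max_h = max(im.shape[0] for im in all_imgs)
        max_w = max(im.shape[1] for im in all_imgs)
        d = net.divisor
        self._pad_target = (max_h + (-max_h) % d, max_w + (-max_w) % d)
        opt = SGD(net, lr=self.learning_rate, momentum=self.momentum)
        cfg = LossConfig(epsilon=self.epsilon)
        rng = np.random.default_rng(self.seed)

        self.history_ = []
        best = (np.inf, None, -1)
        for epoch in range(1, self.epochs + 1):
            order = rng.permutation(len(X))
            train_losses = []
            for batch in self._batches(order, X):
                imgs, masks = self._load_batch(X, y, batch, rng if self.online_augment else None)
                logits = net.forward(imgs, train=True)
                loss, grad = combined_loss_grad(logits, masks, cfg)
                if not np.isfinite(loss):
                    raise DivergenceError(f"non-finite loss at epoch {epoch}")
                net.zero_grad()
                net.backward(grad)
                opt.step()
                train_losses.append(loss)
            train_loss = float(np.mean(train_losses))
            if has_val:
                val_loss = self._eval_loss(net, X_val, y_val, cfg)
            else:
                val_loss = train_loss
            self.history_.append(
                {"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss}
            )
            if val_loss < best[0]:
                best = (val_loss, net.state_dict(), epoch)
        net.load_state_dict(best[1])
        self.net_ = net
        self.selected_epoch_ = best[2]
        self.best_val_loss_ = best[0]
        return self

    def _batches(self, order, X):
        for k in range(0, len(order), self.batch_size):
            yield [int(i) for i in order[k : k + self.batch_size]]

    def _pad_one(self, img: np.ndarray) -> np.ndarray:
        th, tw = self._pad_target
        h, w = img.shape[:2]
        pad = [(0, th - h), (0, tw - w)] + [(0, 0)] * (img.ndim - 2)
        return np.pad(img, pad) if (h, w) != (th, tw) else img

    def _load_batch(self, X, y, batch, aug_rng):
        imgs, masks = [], []
        for i in batch:
            img, msk = X[i], y[i]
            if aug_rng is not None:
                img, msk = _strong_augment(img, msk, aug_rng)
            imgs.append(self._pad_one(img))
            masks.append(self._pad_one(msk))
        return np.stack(imgs), np.stack(masks)

    def _eval_loss(self, net, X_val, y_val, cfg) -> float:
        losses = []
        for k in range(0, len(X_val), self.batch_size):
            grp = list(range(k, min(k + self.batch_size, len(X_val))))
            imgs, masks = self._load_batch(X_val, y_val, grp, None)
            logits = net.forward(imgs)
            losses.extend(
                combined_loss(logits[j : j + 1], masks[j : j + 1], cfg) for j in range(len(grp))
            )
        return float(np.mean(losses))

    # -------------------------------------------------------------- predict

    def predict_proba(self, X) -> list[np.ndarray]:
        """Per-pixel head probabilities for each image, original sizes."""
        self._check_fitted()
        from scipy.special import expit

        out = []
        for img in _as_list(X):
            h, w = img.shape[:2]
            padded, _ = pad_to_divisor(np.asarray(img, dtype=np.float32), self.net_.divisor)
            logits = self.net_.forward(padded[None])[0]
            out.append(expit(logits[:h, :w]))
        return out

    def predict(self, X) -> list[np.ndarray]:
        """Binary masks ({0,1} uint8) at the configured threshold."""
        return [(p >= self.threshold).astype(np.uint8) for p in self.predict_proba(X)]

    def score(self, X, y) -> float:
        """Mean Dice over the set (sklearn convention: higher is better)."""
        preds = self.predict(X)
        return float(np.mean([dice_score(p, np.asarray(m)) for p, m in zip(preds, _as_list(y))]))

    def _check_fitted(self) -> None:
        if not hasattr(self, "net_"):
            raise InputError("estimator is not fitted; call fit() first")


def _strong_augment(img: np.ndarray, mask: np.ndarray, rng: np.random.Generator):
    """Label-preserving augmentation applied on access during training.

    Geometric part (flips / right-angle rotations) transforms image and mask
    together — the labeling stays computationally inferable; photometric
    jitter touches the image only.
    """
    # right-angle rotations swap H/W; restrict to half-turns off-square so
    # same-shape batch grouping still holds
    k = int(rng.integers(4)) if img.shape[0] == img.shape[1] else 2 * int(rng.integers(2))
    img = np.rot90(img, k, axes=(0, 1))
    mask = np.rot90(mask, k, axes=(0, 1))
    if rng.random() < 0.5:
        img, mask = img[:, ::-1], mask[:, ::-1]
    if rng.random() < 0.5:
        img, mask = img[::-1], mask[::-1]
    img = img * rng.uniform(0.85, 1.15) + rng.uniform(-0.05, 0.05)
    if rng.random() < 0.3:
        img = img + rng.normal(0.0, 0.02, img.shape)
    return np.clip(img, 0, 1).astype(np.float32), np.ascontiguousarray(mask)
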