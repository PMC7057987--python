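"""Model/Results interface for the frame classifier.

``FrameClassifier`` is built from labelled frames (stomach/duodenal bulb = 0,
descending duodenum = 1) and a network/training configuration; ``fit()``
runs the focal-loss/Adam training loop with online augmentation and returns
a ``FrameClassifierResults`` carrying the trained weights, the per-epoch
loss history, hold-out ROC diagnostics and the Youden operating cutoff.

Example
-------
>>> stream = synth.generate_stream(spec)
>>> model = FrameClassifier(stream.frames, stream.labels)
>>> res = model.fit(holdout_fraction=0.2)
>>> print(res.summary())
>>> scores = res.predict_score(new_frames)
"""

from __future__ import annotations

import json
from dataclasses import asdict

import numpy as np

from . import metrics as _metrics
from .nnet import Network, NetworkSpec, TrainConfig, build_network
from .preprocess import AugmentationConfig, augment, normalize

__all__ = ["FrameClassifier", "FrameClassifierResults"]


class FrameClassifier:
    """Binary DSD-vs-stomach frame classifier (untrained model object).

    Parameters
    ----------
    images : (n, H, W) array
        Raw 8-bit frames (0–255) or already-normalized [0, 1] floats.
    labels : (n,) array of {0, 1}
        1 = descending duodenum.
    network : NetworkSpec
    train_config : TrainConfig
    augmentation : AugmentationConfig or None
        ``None`` disables training-time augmentation.
    """

    def __init__(
        self,
        images,
        labels,
        network: NetworkSpec = NetworkSpec(),
        train_config: TrainConfig = TrainConfig(),
        augmentation: AugmentationConfig | None = AugmentationConfig(),
    ):
        images = np.asarray(images)
        labels = np.asarray(labels).astype(np.int64).ravel()
        if images.ndim != 3:
            raise ValueError("images must be (n, H, W)")
        if len(images) != len(labels):
            raise ValueError("images and labels must have equal length")
        if not np.isin(labels, (0, 1)).all():
            raise ValueError("labels must be 0 or 1")
        if len(np.unique(labels)) < 2:
            raise ValueError("training data must contain both classes")
        if images.dtype == np.uint8 or images.max() > 1.0:
            images = normalize(images)
        self.images = images.astype(np.float32)
        self.labels = labels
        self.network_spec = network
        self.train_config = train_config
        self.augmentation = augmentation
        self.input_shape = images.shape[1:3]

    @classmethod
    def from_directory(cls, path, **kwargs) -> "FrameClassifier":
        """Build from an on-disk dataset (manifest or three-part naming)."""
        from .datasets import read_dataset

        ds = read_dataset(path)
        return cls(ds.frames, ds.labels, **kwargs)

    # ------------------------------------------------------------------

    def fit(
        self,
        holdout_fraction: float = 0.2,
        verbose: bool = False,
    ) -> "FrameClassifierResults":
        """Train the network and return a results object.

        A stratified hold-out split (``holdout_fraction`` of each class) is
        set aside for the ROC/AUC diagnostics and the Youden cutoff; pass
        ``0`` to train on everything (diagnostics then unavailable).
        """
        cfg = self.train_config
        rng = np.random.default_rng(cfg.seed)
        n = len(self.images)

        # stratified split
        holdout_idx = []
        if holdout_fraction > 0:
            for c in (0, 1):
                idx_c = np.where(self.labels == c)[0]
                k = max(int(round(holdout_fraction * len(idx_c))), 1)
                holdout_idx.append(rng.permutation(idx_c)[:k])
            holdout_idx = np.sort(np.concatenate(holdout_idx))
        else:
            holdout_idx = np.array([], dtype=int)
        train_mask = np.ones(n, dtype=bool)
        train_mask[holdout_idx] = False
        x_train, y_train = self.images[train_mask], self.labels[train_mask]
        x_hold, y_hold = self.images[holdout_idx], self.labels[holdout_idx]
        if len(np.unique(y_train)) < 2:
            raise ValueError("training split lost a class; lower holdout_fraction")

        net = build_network(self.network_spec, self.input_shape, seed=cfg.seed)
        opt = net.make_optimizer(cfg)

        loss_history: list[float] = []
        for epoch in range(cfg.epochs):
            order = rng.permutation(len(x_train))
            epoch_losses = []
            for lo in range(0, len(order), cfg.batch_size):
                sel = order[lo : lo + cfg.batch_size]
                batch = x_train[sel]
                if self.augmentation is not None:
                    batch = np.stack(
                        [augment(f, self.augmentation, rng) for f in batch]
                    )
                loss = net.loss_and_backward(batch, y_train[sel], cfg.gamma, cfg.alpha)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}, batch {lo // cfg.batch_size}"
                    )
                opt.step(net.grads())
                epoch_losses.append(loss)
            loss_history.append(float(np.mean(epoch_losses)))
            if verbose:
                print(f"epoch {epoch + 1}/{cfg.epochs}  mean focal loss {loss_history[-1]:.5f}")

        return FrameClassifierResults(
            model=self,
            network=net,
            loss_history=loss_history,
            holdout_images=x_hold,
            holdout_labels=y_hold,
        )


class FrameClassifierResults:
    """Fitted classifier: weights, training diagnostics, operating cutoff."""

    def __init__(self, model, network: Network, loss_history, holdout_images, holdout_labels):
        self.model = model
        self.network = network
        self.loss_history = list(loss_history)
        self.holdout_labels = np.asarray(holdout_labels)
        self.nobs = len(model.images) if model is not None else None

        self.holdout_scores = None
        self.holdout_auc = None
        self.cutoff_result = None
        if holdout_images is not None and len(holdout_images) and len(np.unique(self.holdout_labels)) == 2:
            self.holdout_scores = self.predict_score(holdout_images)
            curve = _metrics.roc_curve(self.holdout_scores, self.holdout_labels)
            self.holdout_auc = curve.auc
            self.roc = curve
            self.cutoff_result = _metrics.youden_cutoff(self.holdout_scores, self.holdout_labels)

    # ------------------------------------------------------------------

    @property
    def cutoff(self) -> float | None:
        """Youden operating cutoff from the hold-out split."""
        return None if self.cutoff_result is None else self.cutoff_result.cutoff

    def predict_score(self, frames, batch_size: int = 256) -> np.ndarray:
        """Per-frame DSD probability score in [0, 1].

        Accepts raw 8-bit or normalized frames, single or batched.
        """
        x = np.asarray(frames)
        single = x.ndim == 2
        if single:
            x = x[None]
        if x.dtype == np.uint8 or (x.size and x.max() > 1.0):
            x = normalize(x)
        out = np.empty(len(x), dtype=float)
        for lo in range(0, len(x), batch_size):
            out[lo : lo + batch_size] = self.network.predict_score(x[lo : lo + batch_size])
        return out[0] if single else out

    def summary(self) -> str:
        spec = self.network.spec
        lines = [
            "Frame classifier (DSD vs stomach/duodenal bulb)",
            "=" * 56,
            f"architecture        {len(spec.conv_filters)}-conv-{len(spec.fc_widths)}-fully "
            f"{spec.conv_filters} / {spec.fc_widths}",
            f"input resolution    {self.network.input_shape[0]} x {self.network.input_shape[1]}",
            f"parameters          {self.network.n_params:,}",
            f"observations        {self.nobs}",
            f"epochs              {len(self.loss_history)}",
        ]
        if self.loss_history:
            lines.append(f"focal loss          {self.loss_history[0]:.5f} -> {self.loss_history[-1]:.5f}")
        if self.holdout_auc is not None:
            c = self.cutoff_result
            lines += [
                f"hold-out AUC        {self.holdout_auc:.4f}  (n={len(self.holdout_labels)})",
                f"Youden cutoff       {c.cutoff:.4f}  (J={c.youden_j:.4f}, "
                f"sens={c.sensitivity:.3f}, spec={c.specificity:.3f})",
            ]
        return "\n".join(lines)

    def plot_roc(self, ax=None):
        """Hold-out ROC curve (requires a fitted hold-out split)."""
        if self.holdout_auc is None:
            raise ValueError("no hold-out diagnostics available")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.roc.fpr, self.roc.tpr, label=f"AUC = {self.holdout_auc:.3f}")
        ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend()
        return ax

    # -- persistence -----------------------------------------------------

    def save(self, checkpoint_path, sidecar_path=None) -> None:
        """Write weights (.npz) plus a JSON sidecar with the full recipe."""
        model = self.model
        np.savez(
            checkpoint_path,
            **{f"w{i}": w for i, w in enumerate(self.network.get_weights())},
        )
        if sidecar_path is None:
            sidecar_path = str(checkpoint_path) + ".json"
        sidecar = {
            "network_spec": asdict(self.network.spec),
            "train_config": asdict(model.train_config) if model else asdict(TrainConfig()),
            "input_shape": list(self.network.input_shape),
            "seed": self.network.seed,
            "loss_history": self.loss_history,
            "holdout_auc": self.holdout_auc,
            "cutoff": self.cutoff,
        }
        with open(sidecar_path, "w") as fh:
            json.dump(sidecar, fh, indent=2)

    @classmethod
    def load(cls, checkpoint_path, sidecar_path=None) -> "FrameClassifierResults":
        if sidecar_path is None:
            sidecar_path = str(checkpoint_path) + ".json"
        with open(sidecar_path) as fh:
            sc = json.load(fh)
        spec_d = dict(sc["network_spec"])
        spec_d["conv_filters"] = tuple(spec_d["conv_filters"])
        spec_d["fc_widths"] = tuple(spec_d["fc_widths"])
        spec = NetworkSpec(**spec_d)
        net = build_network(spec, tuple(sc["input_shape"]), seed=sc.get("seed", 0))
        data = np.load(checkpoint_path)
        net.set_weights([data[f"w{i}"] for i in range(len(data.files))])
        res = cls(
            model=None,
            network=net,
            loss_history=sc.get("loss_history", []),
            holdout_images=None,
            holdout_labels=np.array([]),
        )
        res.holdout_auc = sc.get("holdout_auc")
        cut = sc.get("cutoff")
        if cut is not None:
            res.cutoff_result = _metrics.CutoffResult(cut, np.nan, np.nan, np.nan)
        return res
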