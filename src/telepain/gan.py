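"""Conditional GAN over encoded patient tables.

A generator G maps a Gaussian noise vector z plus a one-hot outcome label c
to an encoded patient record; a discriminator D scores (record, label) pairs
as real vs generated.  Both are trained in the standard minimax game

    min_G max_D  E_x[log D(x|c)] + E_z[log(1 - D(G(z|c)|c))]

with binary cross-entropy losses; G uses the non-saturating form
-E[log D(G(z))], which shares the same fixed point.  Categorical blocks of
the encoding are produced through a per-block softmax and decoded by
arg-max; numeric columns are linear outputs on the standardized scale.

Both networks are two-hidden-layer perceptrons (leaky-ReLU) implemented
directly on numpy with Adam updates, which is plenty for tables of a few
hundred rows and a few dozen columns.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import EncodingMap, decode

log = logging.getLogger(__name__)

LABELS = ("one", "more")
_EPS = 1e-7


# --------------------------------------------------------------------------
# losses (empirical value function)
# --------------------------------------------------------------------------

def d_loss(d_real, d_fake) -> float:
    """Discriminator loss −[mean log D(x) + mean log(1 − D(G(z)))].

    This is the negated empirical value function; its minimum over D for
    matched real/fake distributions is ln 4.
    """
    d_real = np.asarray(d_real, float)
    d_fake = np.asarray(d_fake, float)
    if ((d_real <= 0) | (d_real >= 1)).any() or ((d_fake <= 0) | (d_fake >= 1)).any():
        raise ValueError("discriminator probabilities must lie strictly in (0, 1)")
    return float(-(np.mean(np.log(d_real)) + np.mean(np.log(1.0 - d_fake))))


def g_loss(d_fake) -> float:
    """Non-saturating generator loss −mean log D(G(z))."""
    d_fake = np.asarray(d_fake, float)
    if ((d_fake <= 0) | (d_fake >= 1)).any():
        raise ValueError("discriminator probabilities must lie strictly in (0, 1)")
    return float(-np.mean(np.log(d_fake)))


# --------------------------------------------------------------------------
# minimal MLP with Adam
# --------------------------------------------------------------------------

class MLP:
    """Fully connected net with leaky-ReLU hidden layers and linear output."""

    def __init__(self, sizes, rng: np.random.Generator, leak: float = 0.2):
        self.leak = leak
        self.W, self.b = [], []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            scale = np.sqrt(2.0 / fan_in)
            self.W.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))
        self._adam_m = [np.zeros_like(p) for p in self.W + self.b]
        self._adam_v = [np.zeros_like(p) for p in self.W + self.b]
        self._adam_t = 0

    def forward(self, x):
        acts = [x]
        h = x
        last = len(self.W) - 1
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            h = h @ W + b
            if i < last:
                h = np.where(h > 0, h, self.leak * h)
            acts.append(h)
        return h, acts

    def backward(self, acts, grad_out):
        """Gradient of a scalar loss wrt params and input; ``grad_out`` is
        dL/d(output)."""
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        g = grad_out
        last = len(self.W) - 1
        for i in range(last, -1, -1):
            if i < last:
                pre = acts[i] @ self.W[i] + self.b[i]
                g = g * np.where(pre > 0, 1.0, self.leak)
            gW[i] = acts[i].T @ g
            gb[i] = g.sum(axis=0)
            g = g @ self.W[i].T
        return gW, gb, g

    def adam_step(self, gW, gb, lr, beta1=0.5, beta2=0.999, eps=1e-8):
        self._adam_t += 1
        params = self.W + self.b
        grads = gW + gb
        t = self._adam_t
        for p, g, m, v in zip(params, grads, self._adam_m, self._adam_v):
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)

    def state(self):
        return {"W": [w.copy() for w in self.W], "b": [b.copy() for b in self.b]}

    def load_state(self, st):
        self.W = [np.asarray(w, float) for w in st["W"]]
        self.b = [np.asarray(b, float) for b in st["b"]]


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _softmax(x):
    z = x - x.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# --------------------------------------------------------------------------
# config / bundle
# --------------------------------------------------------------------------

@dataclass
class GanConfig:
    noise_dim: int = 32
    hidden: tuple = (128, 64)
    lr: float = 2e-4
    batch_size: int = 32
    epochs: int = 300
    seed: int = 0
    #: weight of the feature-matching term added to the generator loss
    #: (squared distance between generated batch means and the
    #: class-conditional training means); stabilizes the marginals of small
    #: tabular problems without changing the adversarial fixed point
    fm_weight: float = 5.0
    #: fraction of final epochs over which generator weights are averaged
    #: (Polyak averaging; damps the minimax oscillation of the endpoint)
    avg_tail: float = 0.5


@dataclass
class GanBundle:
    """Trained generator/discriminator pair plus everything needed to sample."""

    config: GanConfig
    emap: EncodingMap
    g_state: dict
    d_state: dict
    training_log: pd.DataFrame
    trained: bool = False

    # -- persistence ------------------------------------------------------
    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.savez(
            d / "weights.npz",
            **{f"g_W{i}": w for i, w in enumerate(self.g_state["W"])},
            **{f"g_b{i}": b for i, b in enumerate(self.g_state["b"])},
            **{f"d_W{i}": w for i, w in enumerate(self.d_state["W"])},
            **{f"d_b{i}": b for i, b in enumerate(self.d_state["b"])},
        )
        with open(d / "config.json", "w") as fh:
            json.dump({**asdict(self.config), "hidden": list(self.config.hidden)}, fh)
        self.emap.to_json(d / "encoding.json")
        self.training_log.to_csv(d / "training_log.csv", index=False)

    @classmethod
    def load(cls, directory) -> "GanBundle":
        d = Path(directory)
        with open(d / "config.json") as fh:
            cfg = json.load(fh)
        cfg["hidden"] = tuple(cfg["hidden"])
        config = GanConfig(**cfg)
        z = np.load(d / "weights.npz")
        n_layers = len(config.hidden) + 1
        g_state = {
            "W": [z[f"g_W{i}"] for i in range(n_layers)],
            "b": [z[f"g_b{i}"] for i in range(n_layers)],
        }
        d_state = {
            "W": [z[f"d_W{i}"] for i in range(n_layers)],
            "b": [z[f"d_b{i}"] for i in range(n_layers)],
        }
        return cls(
            config=config,
            emap=EncodingMap.from_json(d / "encoding.json"),
            g_state=g_state,
            d_state=d_state,
            training_log=pd.read_csv(d / "training_log.csv"),
            trained=True,
        )


def _g_output_transform(u, emap: EncodingMap):
    """Linear numerics + per-block softmax; returns output and cache."""
    out = u.copy()
    slices = emap.block_slices()
    for var in emap.categorical:
        s = slices[var]
        out[:, s] = _softmax(u[:, s])
    return out


def _g_output_backward(u, out, grad_out, emap: EncodingMap):
    """dL/du given dL/d(out) through the per-block softmax."""
    g = grad_out.copy()
    slices = emap.block_slices()
    for var in emap.categorical:
        s = slices[var]
        p = out[:, s]
        gp = grad_out[:, s]
        g[:, s] = p * (gp - (gp * p).sum(axis=1, keepdims=True))
    return g


def _labels_onehot(labels) -> np.ndarray:
    labels = np.asarray(labels)
    idx = np.full(len(labels), -1, int)
    for j, lab in enumerate(LABELS):
        idx[labels == lab] = j
    if (idx < 0).any():
        raise ValueError(f"labels must be in {LABELS}")
    return np.eye(len(LABELS))[idx]


def _forward_g(gnet: MLP, z, c, emap):
    u, acts = gnet.forward(np.hstack([z, c]))
    return _g_output_transform(u, emap), u, acts


def train(
    encoded_train: np.ndarray,
    labels,
    config: GanConfig,
    emap: EncodingMap,
    holdout: np.ndarray | None = None,
    holdout_labels=None,
) -> GanBundle:
    """Adversarial training; deterministic for a given config seed.

    ``encoded_train`` must be produced by :func:`telepain.preprocess.encode`
    with the map ``emap`` (full indicator set).  The per-epoch log records
    both losses and the discriminator's accuracy on held-out real rows vs
    freshly generated rows.
    """
    x = np.asarray(encoded_train, float)
    c = _labels_onehot(labels)
    if len(np.unique(np.asarray(labels))) < 2:
        raise ValueError("training labels contain a single class; need both")
    if x.shape[1] != emap.width:
        raise ValueError("encoded matrix width does not match encoding map")
    rng = np.random.default_rng(config.seed)
    n, width = x.shape
    gnet = MLP([config.noise_dim + len(LABELS), *config.hidden, width], rng)
    dnet = MLP([width + len(LABELS), *config.hidden, 1], rng)

    if holdout is None:
        holdout, holdout_labels = x, np.asarray(labels)
        log.info("no held-out set supplied; discriminator accuracy logged on train rows")
    c_hold = _labels_onehot(holdout_labels)

    # class-conditional feature means of the training data (moment-matching
    # targets for the generator)
    class_means = np.stack([x[c[:, j] == 1].mean(axis=0) for j in range(len(LABELS))])

    records = []
    g_avg, n_avg = None, 0
    n_batches = max(1, n // config.batch_size)
    for epoch in range(config.epochs):
        perm = rng.permutation(n)
        d_losses, g_losses = [], []
        for bi in range(n_batches):
            idx = perm[bi * config.batch_size : (bi + 1) * config.batch_size]
            if len(idx) == 0:
                continue
            xb, cb = x[idx], c[idx]
            m = len(idx)

            # ---- D step
            z = rng.standard_normal((m, config.noise_dim))
            x_fake, _, _ = _forward_g(gnet, z, cb, emap)
            logits_r, acts_r = dnet.forward(np.hstack([xb, cb]))
            logits_f, acts_f = dnet.forward(np.hstack([x_fake, cb]))
            p_r = np.clip(_sigmoid(logits_r), _EPS, 1 - _EPS)
            p_f = np.clip(_sigmoid(logits_f), _EPS, 1 - _EPS)
            dl = d_loss(p_r, p_f)
            # dL/dlogit for BCE with targets 1 (real) and 0 (fake)
            gW_r, gb_r, _ = dnet.backward(acts_r, (p_r - 1.0) / m)
            gW_f, gb_f, _ = dnet.backward(acts_f, p_f / m)
            dnet.adam_step(
                [a + b for a, b in zip(gW_r, gW_f)],
                [a + b for a, b in zip(gb_r, gb_f)],
                config.lr,
            )

            # ---- G step (non-saturating)
            z = rng.standard_normal((m, config.noise_dim))
            x_fake, u, acts_g = _forward_g(gnet, z, cb, emap)
            logits_f, acts_f = dnet.forward(np.hstack([x_fake, cb]))
            p_f = np.clip(_sigmoid(logits_f), _EPS, 1 - _EPS)
            gl = g_loss(p_f)
            _, _, grad_din = dnet.backward(acts_f, (p_f - 1.0) / m)
            grad_x = grad_din[:, :width]  # label part of D input is constant
            if config.fm_weight > 0:
                # moment matching against the class-conditional training
                # means: d/dx_fake ||mean(x_fake) - E[x | batch labels]||^2
                target = class_means[cb.argmax(axis=1)].mean(axis=0)
                gap = x_fake.mean(axis=0) - target
                grad_x = grad_x + config.fm_weight * 2.0 * gap / m
            grad_u = _g_output_backward(u, x_fake, grad_x, emap)
            gW_g, gb_g, _ = gnet.backward(acts_g, grad_u)
            gnet.adam_step(gW_g, gb_g, config.lr)

            if not (np.isfinite(dl) and np.isfinite(gl)):
                raise FloatingPointError(f"GAN training diverged at epoch {epoch}")
            d_losses.append(dl)
            g_losses.append(gl)

        # held-out discriminator accuracy: real rows vs equally many fakes
        z = rng.standard_normal((len(holdout), config.noise_dim))
        x_fake, _, _ = _forward_g(gnet, z, c_hold, emap)
        p_r = _sigmoid(dnet.forward(np.hstack([holdout, c_hold]))[0]).ravel()
        p_f = _sigmoid(dnet.forward(np.hstack([x_fake, c_hold]))[0]).ravel()
        acc = 0.5 * ((p_r > 0.5).mean() + (p_f <= 0.5).mean())

        # mode-collapse monitor: distinct tumour sites among decoded fakes
        if "site" in emap.categorical:
            n_sites = decode(x_fake, emap)["site"].nunique()
            if n_sites < 6:
                log.warning(
                    "epoch %d: generator emits only %d distinct tumour sites "
                    "(possible mode collapse)",
                    epoch,
                    n_sites,
                )
        records.append(
            {
                "epoch": epoch,
                "d_loss": float(np.mean(d_losses)),
                "g_loss": float(np.mean(g_losses)),
                "d_heldout_acc": float(acc),
            }
        )

        # Polyak-average the generator over the tail of training
        if epoch >= config.epochs * (1.0 - config.avg_tail):
            st = gnet.state()
            if g_avg is None:
                g_avg, n_avg = st, 1
            else:
                n_avg += 1
                for key in ("W", "b"):
                    for p_avg, p in zip(g_avg[key], st[key]):
                        p_avg += (p - p_avg) / n_avg

    return GanBundle(
        config=config,
        emap=emap,
        g_state=g_avg if g_avg is not None else gnet.state(),
        d_state=dnet.state(),
        training_log=pd.DataFrame(records),
        trained=True,
    )


def _repair_invariants(df: pd.DataFrame, labels) -> pd.DataFrame:
    """Enforce patient-record invariants on a decoded table (columns that a
    reduced/toy table lacks are simply skipped)."""
    df = df.copy()
    labels = np.asarray(labels)
    if {"site", "gender"} <= set(df.columns):
        df.loc[df["site"] == "prostate", "gender"] = "male"
        df.loc[df["site"].isin(["gynecological", "breast"]), "gender"] = "female"
    if {"bone_mets", "metastatic"} <= set(df.columns):
        df.loc[df["bone_mets"] == 1, "metastatic"] = 1
    if "n_televisits" in df.columns:
        df["n_televisits"] = np.where(
            labels == "one", 1, np.maximum(df["n_televisits"].to_numpy(), 2)
        )
    df["outcome"] = labels
    return df


def generate(
    bundle: GanBundle,
    n: int,
    label_mix: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample ``n`` decoded synthetic patients from a trained bundle.

    ``label_mix`` gives the exact fraction of each conditioning class
    (default 50/50); labels are inputs to the generator, so the generated
    class frequencies match the mix exactly.
    """
    if not bundle.trained:
        raise ValueError("bundle has not been trained")
    if n < 0:
        raise ValueError("n must be non-negative")
    mix = dict(label_mix or {"one": 0.5, "more": 0.5})
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("label mix must sum to 1")
    n_one = int(round(n * mix.get("one", 0.0)))
    labels = np.array(["one"] * n_one + ["more"] * (n - n_one), dtype=object)
    if n == 0:
        from .cohort import COHORT_COLUMNS

        return pd.DataFrame(columns=list(COHORT_COLUMNS))

    rng = np.random.default_rng(seed)
    gnet = MLP([bundle.config.noise_dim + len(LABELS), *bundle.config.hidden, bundle.emap.width], rng)
    gnet.load_state(bundle.g_state)
    z = rng.standard_normal((n, bundle.config.noise_dim))
    c = _labels_onehot(labels)
    x_fake, _, _ = _forward_g(gnet, z, c, bundle.emap)
    # categorical blocks are realized by sampling from the per-block softmax
    # (not arg-max): the generated level frequencies then equal the softmax
    # means that training matched against the data
    slices = bundle.emap.block_slices()
    for var in bundle.emap.categorical:
        s = slices[var]
        p = x_fake[:, s]
        p = p / p.sum(axis=1, keepdims=True)
        pick = (rng.random((n, 1)) > p.cumsum(axis=1)).sum(axis=1)
        x_fake[:, s] = np.eye(p.shape[1])[pick]
    df = _repair_invariants(decode(x_fake, bundle.emap), labels)
    df.insert(0, "patient_id", np.arange(n))
    from .cohort import COHORT_COLUMNS

    if set(COHORT_COLUMNS) <= set(df.columns):
        df = df[list(COHORT_COLUMNS)]
    return df


def discriminate(bundle: GanBundle, encoded: np.ndarray, labels) -> np.ndarray:
    """D's probability that each (record, label) pair is real."""
    rng = np.random.default_rng(0)
    dnet = MLP(
        [bundle.emap.width + len(LABELS), *bundle.config.hidden, 1], rng
    )
    dnet.load_state(bundle.d_state)
    c = _labels_onehot(labels)
    return _sigmoid(dnet.forward(np.hstack([np.asarray(encoded, float), c]))[0]).ravel()
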