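"""Semi-supervised clustering GAN over CN-referenced ROI volumes.

The model learns a one-to-many mapping from the cognitively-normal (CN)
domain X to the patient domain Y. A latent subtype code z — a one-hot
vector of dimension M, each position drawn with probability 1/M,
independent of x — selects which of M transformations the mapping
f : X × Z → Y applies. Three terms shape f:

* an adversarial loss: a discriminator D is trained to tell real patient
  vectors from synthesized ones f(x, z), forcing the transformed CN
  distribution onto the patient distribution;
* a change loss, the L1 norm of the displacement ``f(x,z) − x``, which
  keeps transformations sparse and disease-like rather than arbitrary;
* a cluster loss, the cross-entropy between z and g(f(x, z)) for a
  clustering network g : Y → simplex(M), which makes the M transformations
  mutually distinguishable and, crucially, makes g an inverse that can
  read the subtype back off real patient data.

The full objective is L_GAN + mu·L_change + lam·L_cluster, minimized over
(f, g) and maximized over D in alternating steps. Lipschitz continuity of D
is enforced by clipping its weights to [−c, c] after every update. All
networks are small fully-connected nets (leaky-ReLU hidden layers) with
hand-written backprop on NumPy arrays and Adam updates, which keeps seeded
runs bitwise reproducible.

After training, ``predict_probabilities`` evaluates g on patient rows and
returns the n×M matrix of pattern pseudo-probabilities — the method's
primary output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace as _dc_replace

import numpy as np

from .io import ROITable

logger = logging.getLogger(__name__)

EPS_PROB = 1e-12
SIMPLEX_TOL = 1e-6


class ModelCollapseError(RuntimeError):
    """All restarts ended with one or more empty/near-empty clusters."""


# ---------------------------------------------------------------------------
# hyperparameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HyperParams:
    """Training configuration.

    mu and lam weigh the change (L1 displacement) and cluster
    (cross-entropy) losses against the adversarial term. ``clip_c`` is the
    weight-clip radius enforcing a Lipschitz bound on D (optionally also on
    f and g via ``clip_fg``). ``gan_form`` selects the discriminator
    objective: "standard" uses log(1 − D(y')) for fakes, "printed" uses the
    1 − log D(y') variant. Training stops when the moving averages of the
    change and cluster losses over ``plateau_window`` iterations each move
    less than ``plateau_tol``, or at ``max_iters``. A run whose smallest
    cluster holds less than ``collapse_threshold`` of patient rows is
    restarted with seed+1, at most ``max_restarts`` times.
    """

    M: int = 4
    mu: float = 0.1
    lam: float = 1.0
    lr_g: float = 5e-4
    lr_d: float = 1e-3
    batch_size: int = 25
    max_iters: int = 6000
    d_steps: int = 1
    leaky_slope: float = 0.2
    clip_c: float = 0.1
    clip_fg: bool = False
    plateau_window: int = 1000
    plateau_tol: float = 1e-3
    collapse_threshold: float = 0.05
    max_restarts: int = 3
    gan_form: str = "standard"
    seed: int = 0
    f_hidden: tuple[int, ...] | None = None  # default: (R//2, R//4, R//2)
    g_hidden: tuple[int, ...] | None = None  # default: (R//2, R//4)
    d_hidden: tuple[int, ...] | None = None  # default: (R//4, R//16)

    def __post_init__(self) -> None:
        if self.M < 2:
            raise ValueError("M must be >= 2")
        if self.mu < 0 or self.lam < 0:
            raise ValueError("mu and lam must be non-negative")
        if self.clip_c <= 0:
            raise ValueError("clip_c must be positive")
        if self.gan_form not in ("standard", "printed"):
            raise ValueError("gan_form must be 'standard' or 'printed'")


def replace_hp(hp: HyperParams, **kw) -> HyperParams:
    """Functional update of a HyperParams instance."""
    return _dc_replace(hp, **kw)


# ---------------------------------------------------------------------------
# networks: minimal fully-connected nets with explicit backprop
# ---------------------------------------------------------------------------

class MLP:
    """Fully-connected net; leaky-ReLU hidden layers, linear final layer.

    ``forward`` caches activations; ``backward`` takes dL/d(output) and
    accumulates parameter gradients (call :meth:`zero_grad` between
    unrelated passes), returning dL/d(input). Softmax / sigmoid heads are
    applied by the callers so losses can be computed on logits.
    """

    def __init__(self, dims: list[int], rng: np.random.Generator, leaky_slope: float = 0.2):
        self.dims = list(dims)
        self.slope = leaky_slope
        self.Ws = [
            rng.normal(0.0, np.sqrt(2.0 / dims[i]), size=(dims[i], dims[i + 1]))
            for i in range(len(dims) - 1)
        ]
        self.bs = [np.zeros(dims[i + 1]) for i in range(len(dims) - 1)]
        self.zero_grad()

    # -- parameter plumbing -------------------------------------------------
    @property
    def params(self) -> list[np.ndarray]:
        return self.Ws + self.bs

    @property
    def grads(self) -> list[np.ndarray]:
        return self.gWs + self.gbs

    def zero_grad(self) -> None:
        if not hasattr(self, "gWs"):
            self.gWs = [np.zeros_like(W) for W in self.Ws]
            self.gbs = [np.zeros_like(b) for b in self.bs]
        else:
            for g in self.gWs:
                g.fill(0.0)
            for g in self.gbs:
                g.fill(0.0)

    def clip_weights(self, c: float) -> None:
        for p in self.params:
            np.clip(p, -c, c, out=p)

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 2 or x.shape[1] != self.dims[0]:
            raise ValueError(f"expected input with {self.dims[0]} columns, got {x.shape}")
        self._inputs = [x]
        self._pre = []
        a = x
        last = len(self.Ws) - 1
        for i, (W, b) in enumerate(zip(self.Ws, self.bs)):
            z = a @ W + b
            self._pre.append(z)
            a = z if i == last else np.where(z > 0, z, self.slope * z)
            if i < last:
                self._inputs.append(a)
        return a

    def backward(self, gout: np.ndarray) -> np.ndarray:
        g = gout
        for i in range(len(self.Ws) - 1, -1, -1):
            self.gWs[i] += self._inputs[i].T @ g
            self.gbs[i] += g.sum(axis=0)
            g = g @ self.Ws[i].T
            if i > 0:
                g = g * np.where(self._pre[i - 1] > 0, 1.0, self.slope)
        return g


class Adam:
    """Adam on a fixed list of parameter arrays (betas 0.5/0.999, GAN style)."""

    def __init__(self, params: list[np.ndarray], lr: float, betas=(0.5, 0.999), eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self._buf = [np.empty_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        alpha = self.lr / b1t
        root = 1.0 / np.sqrt(b2t)
        for p, g, m, v, buf in zip(self.params, grads, self.m, self.v, self._buf):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            np.multiply(g, g, out=buf)
            buf *= 1 - self.b2
            v += buf
            np.sqrt(v, out=buf)
            buf *= root
            buf += self.eps
            np.divide(m, buf, out=buf)
            buf *= alpha
            p -= buf


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# subtype sampling and losses
# ---------------------------------------------------------------------------

def sample_subtypes(M: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """n one-hot rows of dimension M, position uniform with probability 1/M."""
    if M < 2:
        raise ValueError("M must be >= 2")
    if n < 1:
        raise ValueError("n must be >= 1")
    idx = rng.integers(0, M, size=n)
    return np.eye(M)[idx]


def synthesize(f: MLP, x: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Deterministic forward pass y' = f([x, z])."""
    if x.shape[0] != z.shape[0]:
        raise ValueError("x and z batch sizes differ")
    if x.shape[1] + z.shape[1] != f.dims[0]:
        raise ValueError("f expects input of size R + M")
    return f.forward(np.concatenate([x, z], axis=1))


def change_loss(x: np.ndarray, y_prime: np.ndarray) -> float:
    """Mean over the batch of the L1 displacement ||y' − x||_1."""
    if x.shape != y_prime.shape:
        raise ValueError("shape mismatch between x and y'")
    return float(np.abs(y_prime - x).sum(axis=1).mean())


def cluster_loss(z: np.ndarray, q: np.ndarray) -> float:
    """Mean cross-entropy −Σ z_i log q_i, with q clipped to [1e-12, 1]."""
    if z.shape != q.shape:
        raise ValueError("shape mismatch between z and q")
    if np.any(q < -SIMPLEX_TOL) or np.any(np.abs(q.sum(axis=1) - 1.0) > SIMPLEX_TOL):
        raise ValueError("q rows are not on the probability simplex")
    qc = np.clip(q, EPS_PROB, 1.0)
    return float(-(z * np.log(qc)).sum(axis=1).mean())


def discriminator_probability(D: MLP, v: np.ndarray) -> np.ndarray:
    """D's probability that each row is real patient data, in (0, 1)."""
    return _sigmoid(D.forward(v)[:, 0])


def adversarial_losses(
    D: MLP, y_real: np.ndarray, y_fake: np.ndarray, form: str = "standard"
) -> tuple[float, float]:
    """(discriminator objective, generator objective) at the current D.

    The discriminator ascends its objective. With ``form="standard"`` it is
    E[log D(y)] + E[log(1 − D(y'))] and the generator descends the
    non-saturating −E[log D(y')]; with ``form="printed"`` the fake term is
    E[1 − log D(y')] for both players.
    """
    if len(y_real) == 0 or len(y_fake) == 0:
        raise ValueError("empty batch")
    p_real = np.clip(discriminator_probability(D, y_real), EPS_PROB, 1 - EPS_PROB)
    p_fake = np.clip(discriminator_probability(D, y_fake), EPS_PROB, 1 - EPS_PROB)
    if form == "standard":
        d_obj = float(np.log(p_real).mean() + np.log1p(-p_fake).mean())
        g_obj = float(-np.log(p_fake).mean())
    elif form == "printed":
        d_obj = float(np.log(p_real).mean() + (1.0 - np.log(p_fake)).mean())
        g_obj = float((1.0 - np.log(p_fake)).mean())
    else:
        raise ValueError("form must be 'standard' or 'printed'")
    return d_obj, g_obj


def total_objective(hp: HyperParams, adversarial: float, change: float, cluster: float) -> float:
    """L = L_GAN + mu·L_change + lam·L_cluster."""
    return adversarial + hp.mu * change + hp.lam * cluster


# ---------------------------------------------------------------------------
# trained model and prediction
# ---------------------------------------------------------------------------

@dataclass
class ProbabilityMatrix:
    """n×M pattern pseudo-probabilities; rows follow the input row order."""

    probs: np.ndarray
    provenance: str = "single"

    def __post_init__(self) -> None:
        if np.any(self.probs < -SIMPLEX_TOL) or np.any(
            np.abs(self.probs.sum(axis=1) - 1.0) > SIMPLEX_TOL
        ):
            raise ValueError("probability rows are not on the simplex")

    @property
    def n(self) -> int:
        return self.probs.shape[0]

    @property
    def M(self) -> int:
        return self.probs.shape[1]

    def argmax_labels(self) -> np.ndarray:
        """Hard labels; exact ties resolve to the lowest pattern index."""
        return np.argmax(self.probs, axis=1)


@dataclass
class TrainedModel:
    """One draw of the stochastic training procedure.

    ``center``/``scale`` hold the per-ROI affine standardization (CN mean
    and SD of the training data) applied before every network; on properly
    preprocessed inputs these are ~1 and ~0.1. Losses are always reported
    on the data scale.
    """

    f: MLP
    g: MLP
    D: MLP
    hp: HyperParams
    seed: int
    roi_names: list[str]
    history: dict[str, np.ndarray]
    converged: bool
    restarts: int
    center: np.ndarray | None = None
    scale: np.ndarray | None = None

    @property
    def M(self) -> int:
        return self.hp.M

    # -- persistence (versioned JSON archive) -------------------------------
    def save(self, path) -> None:
        def net(m: MLP):
            return {
                "dims": m.dims,
                "slope": m.slope,
                "Ws": [W.tolist() for W in m.Ws],
                "bs": [b.tolist() for b in m.bs],
            }

        doc = {
            "schema": "subtypegan.trained_model",
            "version": 1,
            "seed": self.seed,
            "roi_names": self.roi_names,
            "converged": self.converged,
            "restarts": self.restarts,
            "hp": {k: v for k, v in vars(self.hp).items()},
            "center": None if self.center is None else self.center.tolist(),
            "scale": None if self.scale is None else self.scale.tolist(),
            "nets": {"f": net(self.f), "g": net(self.g), "D": net(self.D)},
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        if doc.get("schema") != "subtypegan.trained_model":
            raise ValueError("not a trained-model archive")

        def net(d):
            m = MLP(d["dims"], np.random.default_rng(0), d["slope"])
            m.Ws = [np.array(W) for W in d["Ws"]]
            m.bs = [np.array(b) for b in d["bs"]]
            return m

        hp_doc = dict(doc["hp"])
        for key in ("f_hidden", "g_hidden", "d_hidden"):
            if hp_doc.get(key) is not None:
                hp_doc[key] = tuple(hp_doc[key])
        hp = HyperParams(**hp_doc)
        return cls(
            f=net(doc["nets"]["f"]),
            g=net(doc["nets"]["g"]),
            D=net(doc["nets"]["D"]),
            hp=hp,
            seed=doc["seed"],
            roi_names=list(doc["roi_names"]),
            history={},
            converged=doc["converged"],
            restarts=doc["restarts"],
            center=None if doc["center"] is None else np.array(doc["center"]),
            scale=None if doc["scale"] is None else np.array(doc["scale"]),
        )


def _as_array(rows) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(rows, ROITable):
        return rows.values, list(rows.roi_names)
    arr = np.asarray(rows, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D feature array or an ROITable")
    return arr, None


def predict_probabilities(model: TrainedModel, rows) -> ProbabilityMatrix:
    """Evaluate the clustering network g on each row; deterministic."""
    Y, names = _as_array(rows)
    if names is not None and model.roi_names and names != model.roi_names:
        raise ValueError("ROI names do not match the trained model")
    if Y.shape[1] != model.g.dims[0]:
        raise ValueError("feature count does not match the trained model")
    if model.center is not None:
        Y = (Y - model.center) / model.scale
    return ProbabilityMatrix(_softmax(model.g.forward(Y)), provenance="single")


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _default_widths(R: int, hp: HyperParams) -> tuple[list[int], list[int], list[int]]:
    f_h = list(hp.f_hidden) if hp.f_hidden else [max(R // 2, 4), max(R // 4, 4), max(R // 2, 4)]
    g_h = list(hp.g_hidden) if hp.g_hidden else [max(R // 2, 4), max(R // 4, 4)]
    d_h = list(hp.d_hidden) if hp.d_hidden else [max(R // 4, 4), max(R // 16, 4)]
    return (
        [R + hp.M] + f_h + [R],
        [R] + g_h + [hp.M],
        [R] + d_h + [1],
    )


def _train_once(X: np.ndarray, Y: np.ndarray, hp: HyperParams, seed: int):
    rng = np.random.default_rng(seed)
    R = X.shape[1]
    # standardize on the CN reference so the nets see ~N(0, 1) features;
    # losses stay on the data scale
    center = X.mean(axis=0)
    scale = np.maximum(X.std(axis=0), 1e-8)
    X = (X - center) / scale
    Y = (Y - center) / scale
    f_dims, g_dims, d_dims = _default_widths(R, hp)
    f = MLP(f_dims, rng, hp.leaky_slope)
    g = MLP(g_dims, rng, hp.leaky_slope)
    D = MLP(d_dims, rng, hp.leaky_slope)
    opt_fg = Adam(f.params + g.params, hp.lr_g)
    opt_d = Adam(D.params, hp.lr_d)

    B = hp.batch_size
    hist = {"adversarial": [], "change": [], "cluster": []}
    converged = False
    w = hp.plateau_window

    for it in range(hp.max_iters):
        # ---- discriminator step(s): ascend the adversarial objective ----
        for _ in range(hp.d_steps):
            xb = X[rng.integers(0, len(X), B)]
            zb = sample_subtypes(hp.M, B, rng)
            yb = Y[rng.integers(0, len(Y), B)]
            y_fake = synthesize(f, xb, zb)

            D.zero_grad()
            lr_real = D.forward(yb)
            s_real = _sigmoid(lr_real)
            D.backward(-(1.0 - s_real) / B)  # descend −E[log D(real)]
            lr_fake = D.forward(y_fake)
            s_fake = _sigmoid(lr_fake)
            if hp.gan_form == "standard":
                D.backward(s_fake / B)  # descend −E[log(1 − D(fake))]
            else:
                D.backward((1.0 - s_fake) / B)  # descend +E[log D(fake)]
            opt_d.step(D.grads)
            D.clip_weights(hp.clip_c)

        # ---- generator step: descend L_GAN + mu·L_change + lam·L_cluster ----
        xb = X[rng.integers(0, len(X), B)]
        zb = sample_subtypes(hp.M, B, rng)
        y_fake = synthesize(f, xb, zb)

        D.zero_grad()
        s_fake = _sigmoid(D.forward(y_fake))
        # non-saturating generator gradient (identical under both forms)
        dy = D.backward(-(1.0 - s_fake) / B)

        # change loss lives on the data scale: |(y'_std − x_std) · scale|
        diff = y_fake - xb
        dy = dy + hp.mu * np.sign(diff) * scale[None, :] / B

        g.zero_grad()
        q = _softmax(g.forward(y_fake))
        dy = dy + g.backward(hp.lam * (q - zb) / B)

        f.zero_grad()
        f.backward(dy)
        opt_fg.step(f.grads + g.grads)
        if hp.clip_fg:
            f.clip_weights(hp.clip_c)
            g.clip_weights(hp.clip_c)

        # ---- bookkeeping and stopping ----
        yb_eval = Y[rng.integers(0, len(Y), B)]
        adv, _ = adversarial_losses(D, yb_eval, y_fake, hp.gan_form)
        chg = change_loss(xb * scale, y_fake * scale)
        clu = cluster_loss(zb, q)
        if not (np.isfinite(adv) and np.isfinite(chg) and np.isfinite(clu)):
            raise RuntimeError(
                f"non-finite loss at iteration {it}: adv={adv} change={chg} cluster={clu}"
            )
        hist["adversarial"].append(adv)
        hist["change"].append(chg)
        hist["cluster"].append(clu)

        if it + 1 >= 2 * w and (it + 1) % w == 0:
            stable = True
            for key in ("change", "cluster"):
                a = np.mean(hist[key][-w:])
                b = np.mean(hist[key][-2 * w : -w])
                if abs(a - b) >= hp.plateau_tol:
                    stable = False
            if stable:
                converged = True
                break

    history = {k: np.asarray(v) for k, v in hist.items()}
    return f, g, D, history, converged, center, scale


def train(cn, pt, hp: HyperParams | None = None) -> TrainedModel:
    """Train the adversarial mapping on preprocessed CN and patient rows.

    Inputs must already be on the CN-referenced scale (mean 1, SD 0.1).
    Alternating updates: per iteration one (or ``d_steps``) weight-clipped
    discriminator ascent step, then one joint (f, g) descent step on the
    full objective. A run ending with a near-empty cluster (smallest
    dominant-assignment fraction below ``collapse_threshold``) is restarted
    with an incremented seed; if every restart collapses the best attempt
    is still rejected loudly.
    """
    hp = hp or HyperParams()
    X, names_x = _as_array(cn)
    Y, names_y = _as_array(pt)
    if names_x is not None and names_y is not None and names_x != names_y:
        raise ValueError("CN and PT tables have different ROI names")
    if X.shape[1] != Y.shape[1]:
        raise ValueError("CN and PT feature counts differ")
    if len(Y) < 5 * hp.M:
        raise ValueError(f"need at least {5 * hp.M} patient rows for M={hp.M}")

    best = None
    for attempt in range(hp.max_restarts + 1):
        seed = hp.seed + attempt
        f, g, D, history, converged, center, scale = _train_once(X, Y, hp, seed)
        model = TrainedModel(
            f=f,
            g=g,
            D=D,
            hp=hp,
            seed=seed,
            roi_names=names_y or names_x or [],
            history=history,
            converged=converged,
            restarts=attempt,
            center=center,
            scale=scale,
        )
        labels = predict_probabilities(model, Y).argmax_labels()
        frac = np.bincount(labels, minlength=hp.M) / len(Y)
        if frac.min() >= hp.collapse_threshold:
            return model
        logger.warning(
            "cluster collapse at seed %d (smallest fraction %.3f); restarting", seed, frac.min()
        )
        if best is None or frac.min() > best[0]:
            best = (frac.min(), model)
    raise ModelCollapseError(
        f"all {hp.max_restarts + 1} runs collapsed; "
        f"best smallest-cluster fraction {best[0]:.3f} < {hp.collapse_threshold}"
    )
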