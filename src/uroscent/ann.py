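"""MLP emulation of canine diagnoses, skeletonization, and anomaly filtering.

A fully connected multilayer perceptron with sigmoid units is trained by
online (per-exemplar) backpropagation with momentum to emulate the dog's
positive/negative indication from the 10–14 minute window of a total-ion
chromatogram (205 input points, 32 hidden nodes, 2 outputs).  Two rule
extraction techniques then interrogate what the net learned:

* **Network skeletonization** — working backward from an output node,
  only the largest-magnitude weights into each retained node are kept,
  exposing the dominant connective paths and thereby the input retention
  times the prediction depends on most.

* **Auto-associative filtering** — a bottleneck net trained to
  reconstruct only canine-negative spectra acts as a nearest-exemplar
  lookup; the difference spectrum (input minus reconstruction) of a
  canine-positive sample shows excess peaks and depletion troughs at the
  anomalous retention times.

Targets are encoded with a scale margin (0.1 / 0.9 rather than 0 / 1) so
the sigmoids are never driven into saturation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .config import ValidationError
from .containers import Chromatogram


@dataclass
class TrainSpec:
    """Backpropagation settings (defaults follow the emulated protocol)."""

    lr: float = 0.1
    momentum: float = 0.03
    rms_target: float = 0.15
    scale_margin: float = 0.1
    max_epochs: int = 2000
    shuffle_each_epoch: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValidationError("lr must be positive")
        if not 0.0 <= self.scale_margin < 0.5:
            raise ValidationError("scale_margin must lie in [0, 0.5)")


@dataclass
class MlpModel:
    """Layered sigmoid network with its stored normalization and train log."""

    layer_sizes: tuple[int, ...]
    weights: list[np.ndarray]  # weights[l] has shape (n_out, n_in)
    biases: list[np.ndarray]
    norm_min: float
    norm_max: float
    retention_times: np.ndarray | None = None
    training_log: dict = field(default_factory=dict)

    def forward(self, x: np.ndarray) -> list[np.ndarray]:
        """Activations per layer, input first."""
        acts = [np.asarray(x, dtype=float)]
        for W, b in zip(self.weights, self.biases):
            acts.append(_sigmoid(W @ acts[-1] + b))
        return acts

    def predict(self, X: np.ndarray) -> np.ndarray:
        A = np.atleast_2d(np.asarray(X, dtype=float))
        for W, b in zip(self.weights, self.biases):
            A = _sigmoid(A @ W.T + b)
        return A

    def normalize(self, raw: np.ndarray) -> np.ndarray:
        span = self.norm_max - self.norm_min
        if span == 0:
            return np.zeros_like(np.asarray(raw, dtype=float))
        return (np.asarray(raw, dtype=float) - self.norm_min) / span


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60.0, 60.0)))


# ------------------------------------------------------------- preprocessing


def window_and_normalize(
    chromatograms: list[Chromatogram],
    rt_window: tuple[float, float] = (10.0, 14.0),
    n_points: int = 205,
) -> tuple[np.ndarray, np.ndarray, tuple[float, float]]:
    """Cut the retention-time window and scale the matrix to [0, 1].

    The window is half-open ``[lo, hi)``.  If the grid inside the window
    does not hold exactly ``n_points`` samples the traces are linearly
    resampled onto a uniform ``n_points`` grid with a warning.
    Normalization uses one global min/max over the whole matrix (not
    per-feature), returned for storage in the model.
    """
    lo, hi = rt_window
    rows, grids = [], []
    for c in chromatograms:
        if lo < c.retention_times[0] or hi > c.retention_times[-1] + c.spacing:
            raise ValidationError(
                f"window {rt_window} outside data span for {c.sample_id}"
            )
        m = (c.retention_times >= lo) & (c.retention_times < hi)
        rows.append(c.abundances[m])
        grids.append(c.retention_times[m])
    lengths = {r.size for r in rows}
    if lengths == {n_points}:
        rts = grids[0]
        X = np.stack(rows)
    else:
        warnings.warn(
            f"window holds {sorted(lengths)} points; resampling to {n_points}"
        )
        rts = np.linspace(lo, hi, n_points, endpoint=False)
        X = np.stack(
            [np.interp(rts, g, r) for g, r in zip(grids, rows)]
        )
    vmin, vmax = float(X.min()), float(X.max())
    if vmin == vmax:
        warnings.warn("constant data; normalized matrix is all zeros")
        return np.zeros_like(X), rts, (vmin, vmax)
    return (X - vmin) / (vmax - vmin), rts, (vmin, vmax)


# ------------------------------------------------------------- training core


def _init_net(
    sizes: tuple[int, ...], rng: np.random.Generator
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    weights = [
        rng.uniform(-0.5, 0.5, size=(sizes[i + 1], sizes[i]))
        for i in range(len(sizes) - 1)
    ]
    biases = [rng.uniform(-0.5, 0.5, size=sizes[i + 1]) for i in range(len(sizes) - 1)]
    return weights, biases


def _grads(
    weights: list[np.ndarray],
    biases: list[np.ndarray],
    x: np.ndarray,
    t: np.ndarray,
) -> tuple[list[np.ndarray], list[np.ndarray], np.ndarray]:
    """Per-exemplar gradients of 0.5*||output - target||^2."""
    acts = [x]
    for W, b in zip(weights, biases):
        acts.append(_sigmoid(W @ acts[-1] + b))
    out = acts[-1]
    delta = (out - t) * out * (1 - out)
    gw, gb = [], []
    for l in range(len(weights) - 1, -1, -1):
        gw.insert(0, np.outer(delta, acts[l]))
        gb.insert(0, delta.copy())
        if l > 0:
            a = acts[l]
            delta = (weights[l].T @ delta) * a * (1 - a)
    return gw, gb, out


def _rms(model_w, model_b, X: np.ndarray, T: np.ndarray) -> float:
    A = X
    for W, b in zip(model_w, model_b):
        A = _sigmoid(A @ W.T + b)
    return float(np.sqrt(((A - T) ** 2).mean()))


@njit(cache=True)
def _epoch_1h(W1, b1, W2, b2, vW1, vb1, vW2, vb2, X, T, order, lr, mom):
    """One online-backprop epoch for a single-hidden-layer net (in place)."""
    for k in range(order.size):
        i = order[k]
        x = X[i]
        t = T[i]
        h = 1.0 / (1.0 + np.exp(-np.minimum(np.maximum(W1 @ x + b1, -60.0), 60.0)))
        o = 1.0 / (1.0 + np.exp(-np.minimum(np.maximum(W2 @ h + b2, -60.0), 60.0)))
        do = (o - t) * o * (1.0 - o)
        dh = (W2.T @ do) * h * (1.0 - h)
        for a in range(W2.shape[0]):
            for b in range(W2.shape[1]):
                vW2[a, b] = mom * vW2[a, b] - lr * do[a] * h[b]
                W2[a, b] += vW2[a, b]
        for a in range(b2.size):
            vb2[a] = mom * vb2[a] - lr * do[a]
            b2[a] += vb2[a]
        for a in range(W1.shape[0]):
            for b in range(W1.shape[1]):
                vW1[a, b] = mom * vW1[a, b] - lr * dh[a] * x[b]
                W1[a, b] += vW1[a, b]
        for a in range(b1.size):
            vb1[a] = mom * vb1[a] - lr * dh[a]
            b1[a] += vb1[a]


def train_mlp(
    X: np.ndarray,
    T: np.ndarray,
    hidden: tuple[int, ...] = (32,),
    spec: TrainSpec | None = None,
    norm: tuple[float, float] = (0.0, 1.0),
    retention_times: np.ndarray | None = None,
) -> MlpModel:
    """Online backpropagation with momentum on (X, T).

    Exemplars are visited in a fresh Fisher-Yates shuffle every epoch.
    Training stops when the epoch RMS error (root mean square over all
    exemplars and output nodes) reaches ``spec.rms_target``, at
    ``max_epochs`` (flagged), or on divergence (RMS rising for 10
    consecutive epochs).
    """
    spec = spec or TrainSpec()
    X = np.ascontiguousarray(X, dtype=np.float64)
    T = np.ascontiguousarray(np.atleast_2d(np.asarray(T, dtype=float)))
    sizes = (X.shape[1], *hidden, T.shape[1])
    rng = np.random.default_rng(spec.seed)
    weights, biases = _init_net(sizes, rng)
    vel_w = [np.zeros_like(W) for W in weights]
    vel_b = [np.zeros_like(b) for b in biases]

    trajectory = []
    n = X.shape[0]
    rising = 0
    reached = False
    fast = len(weights) == 2
    for epoch in range(spec.max_epochs):
        order = rng.permutation(n) if spec.shuffle_each_epoch else np.arange(n)
        if fast:
            _epoch_1h(
                weights[0], biases[0], weights[1], biases[1],
                vel_w[0], vel_b[0], vel_w[1], vel_b[1],
                X, T, order, spec.lr, spec.momentum,
            )
        else:
            for i in order:
                gw, gb, _ = _grads(weights, biases, X[i], T[i])
                for l in range(len(weights)):
                    vel_w[l] = spec.momentum * vel_w[l] - spec.lr * gw[l]
                    vel_b[l] = spec.momentum * vel_b[l] - spec.lr * gb[l]
                    weights[l] += vel_w[l]
                    biases[l] += vel_b[l]
        rms = _rms(weights, biases, X, T)
        trajectory.append(rms)
        if rms <= spec.rms_target:
            reached = True
            break
        if len(trajectory) > 1 and rms > trajectory[-2]:
            rising += 1
            if rising >= 10:
                warnings.warn("training diverging; halted")
                break
        else:
            rising = 0

    return MlpModel(
        layer_sizes=sizes,
        weights=weights,
        biases=biases,
        norm_min=norm[0],
        norm_max=norm[1],
        retention_times=retention_times,
        training_log={
            "epochs": len(trajectory),
            "rms_trajectory": trajectory,
            "final_rms": trajectory[-1] if trajectory else float("nan"),
            "reached_target": reached,
            "seed": spec.seed,
        },
    )


def encode_targets(calls: np.ndarray, scale_margin: float = 0.1) -> np.ndarray:
    """One-hot (positive, negative) targets with saturation margin."""
    lo, hi = scale_margin, 1.0 - scale_margin
    calls = np.asarray(calls, dtype=object)
    T = np.full((calls.size, 2), lo)
    T[calls == "positive", 0] = hi
    T[calls == "negative", 1] = hi
    return T


def train_classifier(
    X: np.ndarray,
    canine_calls: np.ndarray,
    spec: TrainSpec | None = None,
    hidden: int = 32,
    norm: tuple[float, float] = (0.0, 1.0),
    retention_times: np.ndarray | None = None,
) -> MlpModel:
    """Train the diagnosis emulator on the DOG's calls (not biopsy truth).

    The two output nodes represent canine-indicated positive and
    canine-indicated negative.
    """
    spec = spec or TrainSpec()
    T = encode_targets(canine_calls, spec.scale_margin)
    model = train_mlp(X, T, (hidden,), spec, norm, retention_times)
    model.training_log["output_nodes"] = ["positive", "negative"]
    return model


def classify(model: MlpModel, X: np.ndarray) -> np.ndarray:
    """Predicted calls: whichever output node activates more strongly."""
    out = model.predict(X)
    return np.where(out[:, 0] >= out[:, 1], "positive", "negative")


def train_autoassociator(
    X_negative: np.ndarray,
    spec: TrainSpec | None = None,
    hidden: int = 32,
    norm: tuple[float, float] = (0.0, 1.0),
    retention_times: np.ndarray | None = None,
) -> MlpModel:
    """Train the bottleneck reconstruction net on canine-negative spectra.

    Identity targets, same backpropagation regime.  The default RMS target
    is tighter than the classifier's (0.05): reconstruction has to be
    sample-specific for the net to act as a nearest-exemplar lookup, not
    just reproduce the class mean.  The median absolute training residual
    is stored for the default anomaly threshold.
    """
    spec = spec or TrainSpec(rms_target=0.01, max_epochs=5000)
    X_negative = np.asarray(X_negative, dtype=float)
    model = train_mlp(
        X_negative, X_negative, (hidden,), spec, norm, retention_times
    )
    recon = model.predict(X_negative)
    resid = X_negative - recon
    model.training_log["residual_mad"] = float(np.median(np.abs(resid)))
    model.training_log["residual_max"] = float(np.max(np.abs(resid)))
    model.training_log["residual_q995"] = float(
        np.quantile(np.abs(resid), 0.995)
    )
    if not model.training_log["reached_target"]:
        model.training_log.setdefault("flags", []).append("rms_target_not_reached")
    return model


# ------------------------------------------------------------- rule extraction


@dataclass
class SaliencyTrace:
    """Retained connective paths from inputs to one output node."""

    output_node: int
    retained_weights: list[tuple[int, int, int, float]]  # (layer, from, to, w)
    input_saliency: np.ndarray
    input_signs: np.ndarray
    dominant_inputs: np.ndarray  # input indices ranked by saliency
    retention_times: np.ndarray | None = None

    def dominant_rts(self, n: int = 5) -> np.ndarray:
        if self.retention_times is None:
            raise ValidationError("model carries no retention-time grid")
        return self.retention_times[self.dominant_inputs[:n]]


def skeletonize(
    model: MlpModel, output_node: int, keep_per_layer: int
) -> SaliencyTrace:
    """Greedy backward pruning exposing the dominant input connections.

    At the output layer the ``keep_per_layer`` largest-|w| weights into
    the chosen output are retained; for each retained hidden node, its
    ``keep_per_layer`` largest-|w| incoming weights are retained in turn,
    down to the inputs.  An input's saliency is the maximum over retained
    paths of the product of |w| along the path; its sign of influence is
    the product of the weight signs along that maximizing path.  With
    ``keep_per_layer`` at or above the fan-in no pruning occurs and the
    saliency equals the exhaustive all-paths computation.
    """
    n_layers = len(model.weights)
    if not 0 <= output_node < model.layer_sizes[-1]:
        raise ValidationError("output_node out of range")

    retained: list[tuple[int, int, int, float]] = []
    # DP over retained edges: best |path product| and its sign per node
    sal = {(n_layers, output_node): 1.0}
    sign = {(n_layers, output_node): 1.0}
    active = {output_node}
    for layer in range(n_layers - 1, -1, -1):
        W = model.weights[layer]
        next_active: set[int] = set()
        new_sal: dict[tuple[int, int], float] = {}
        new_sign: dict[tuple[int, int], float] = {}
        for node in active:
            w_in = W[node]
            k = min(keep_per_layer, w_in.size)
            top = np.argsort(-np.abs(w_in), kind="stable")[:k]
            for j in top:
                w = float(w_in[j])
                retained.append((layer, int(j), int(node), w))
                cand = sal[(layer + 1, node)] * abs(w)
                key = (layer, int(j))
                if cand > new_sal.get(key, 0.0):
                    new_sal[key] = cand
                    new_sign[key] = sign[(layer + 1, node)] * np.sign(w)
                next_active.add(int(j))
        sal.update(new_sal)
        sign.update(new_sign)
        active = next_active

    n_in = model.layer_sizes[0]
    saliency = np.zeros(n_in)
    signs = np.zeros(n_in)
    for (layer, j), v in sal.items():
        if layer == 0:
            saliency[j] = v
            signs[j] = sign[(0, j)]
    order = np.argsort(-saliency, kind="stable")
    order = order[saliency[order] > 0]
    return SaliencyTrace(
        output_node=output_node,
        retained_weights=retained,
        input_saliency=saliency,
        input_signs=signs,
        dominant_inputs=order,
        retention_times=model.retention_times,
    )


@dataclass
class DifferenceSpectrum:
    """Input-minus-reconstruction residual with flagged regions."""

    sample_id: str
    retention_times: np.ndarray
    residual: np.ndarray
    threshold: float
    excesses: list[tuple[float, float]]  # (apex rt, magnitude), |mag| desc
    depletions: list[tuple[float, float]]


def _regions(rts, residual, mask, sign, min_width=2):
    out = []
    i = 0
    n = mask.size
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            if j - i + 1 >= min_width:
                seg = residual[i : j + 1]
                apex = i + int(np.argmax(sign * seg))
                out.append((float(rts[apex]), float(residual[apex])))
            i = j + 1
        else:
            i += 1
    out.sort(key=lambda t: -abs(t[1]))
    return out


def difference_spectrum(
    model: MlpModel,
    x: np.ndarray,
    sample_id: str = "",
    threshold: float | None = None,
) -> DifferenceSpectrum:
    """Residual of one (normalized) spectrum against its reconstruction.

    Excess regions are maximal contiguous runs of at least two points with
    residual above the threshold, depletions below its negative (real
    elutes span several grid points; isolated one-point excursions are
    noise).  The default threshold is calibrated on the auto-associator's
    training set as the 99.5th percentile of absolute residuals, so
    in-distribution spectra essentially never produce a flagged region
    while anomalies beyond what the trained class explains do.
    """
    x = np.asarray(x, dtype=float)
    recon = model.forward(x)[-1]
    residual = x - recon
    if threshold is None:
        cal = model.training_log.get("residual_q995")
        if cal is None:
            raise ValidationError(
                "model has no stored training residuals; pass a threshold"
            )
        threshold = cal
    rts = (
        model.retention_times
        if model.retention_times is not None
        else np.arange(x.size, dtype=float)
    )
    return DifferenceSpectrum(
        sample_id=sample_id,
        retention_times=rts,
        residual=residual,
        threshold=threshold,
        excesses=_regions(rts, residual, residual > threshold, +1.0),
        depletions=_regions(rts, residual, residual < -threshold, -1.0),
    )


# ------------------------------------------------------------- concordance


def concordance_report(
    skeleton: SaliencyTrace,
    diffs: list[DifferenceSpectrum],
    n_top_inputs: int = 5,
    rt_tol: float = 0.1,
) -> list[dict]:
    """Cross-reference the two rule-extraction methods by retention time.

    Retention times flagged by skeletonization (top saliency inputs) and
    by the difference spectra (excess/depletion apexes) are merged into
    regions; each region reports which methods flagged it.
    """
    skel_rts = list(skeleton.dominant_rts(n_top_inputs)) if (
        skeleton.dominant_inputs.size and skeleton.retention_times is not None
    ) else []
    diff_rts = []
    for d in diffs:
        diff_rts += [rt for rt, _ in d.excesses] + [rt for rt, _ in d.depletions]

    tagged = sorted(
        [(float(rt), "skeleton") for rt in skel_rts]
        + [(float(rt), "autoassoc") for rt in diff_rts]
    )
    report: list[dict] = []
    for rt, method in tagged:
        if report and rt - report[-1]["rt_max"] <= rt_tol:
            region = report[-1]
            region["rt_max"] = max(region["rt_max"], rt)
        else:
            region = {"rt_min": rt, "rt_max": rt, "methods": set()}
            report.append(region)
        region["methods"].add(method)
    for region in report:
        region["methods"] = sorted(region["methods"])
        region["flagged_by_both"] = len(region["methods"]) == 2
    return report
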