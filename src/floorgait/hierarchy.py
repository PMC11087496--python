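"""Hierarchical step -> trace -> person model for functional-stage prediction.

A person's gait evidence is hierarchical: individual footsteps carry
noisy but rich features, a trace (one walking pass recorded by one
sensor) summarizes a consecutive series of footsteps, and the person
level adds biometrics. One small rectifier network per level learns an
embedding; each level's 6-way class-probability output (a normalized-
exponential head) is mean-aggregated over the group and concatenated
with the next level's own features:

    trace input  = concat(trace features,          mean over steps of step probs)
    person input = concat(mean of trace probs,     age, gender, BMI)

Each level is first pretrained directly against the stage labels
broadcast to its samples ("teacher enforcing"), then the whole stack is
fine-tuned jointly with gradients flowing end-to-end through the
softmax and mean-aggregation links. Dropout (20%) is active only in
training; standardization statistics are fitted on the training split
only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import MLP, Adam, cross_entropy_grad, softmax, softmax_backward
from .records import Biometrics

__all__ = [
    "ModelConfig",
    "FeatureDataset",
    "StagePrediction",
    "Standardizer",
    "HierarchicalModel",
    "assemble_step_features",
    "aggregate_mean",
    "build_trace_input",
    "pretrain_level",
    "train_hierarchical",
    "predict_stage",
    "encode_biometrics",
]

STEP_FEATURE_NAMES = (
    "step_time", "toe_contact_probability", "sensor_number",
    "mean", "sd", "skewness", "kurtosis",
    "dominant_freq_strike", "dominant_freq_off",
    "psd_band_1", "psd_band_2", "psd_band_3",
)
TRACE_FEATURE_NAMES = (
    "symmetry_score", "step_time_variability", "cadence", "energy_variability",
) + tuple(f"rep_psd_{k}" for k in range(1, 11))


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training hyperparameters (defaults per level:
    step 12->256->64, trace 20->128->32, person 9->64)."""

    step_widths: tuple[int, ...] = (12, 256, 64)
    trace_widths: tuple[int, ...] = (20, 128, 32)
    person_widths: tuple[int, ...] = (9, 64)
    n_classes: int = 6
    dropout: float = 0.2
    lr: float = 1e-3
    pretrain_epochs: int = 200
    joint_epochs: int = 100
    val_frac: float = 0.1
    patience: int = 20
    train_frac: float = 0.8
    split_by_subject: bool = False


@dataclass
class FeatureDataset:
    """Assembled multi-level feature tables for a cohort.

    ``step_trace`` maps each step row to its trace row; ``trace_person``
    maps each trace row to its person row. Labels are the person stage
    broadcast down the hierarchy.
    """

    step_X: np.ndarray  # (n_steps, 12)
    step_trace: np.ndarray  # (n_steps,) int
    trace_X: np.ndarray  # (n_traces, 14)
    trace_person: np.ndarray  # (n_traces,) int
    person_bio: np.ndarray  # (n_persons, 3): age, gender{0,1}, BMI
    person_label: np.ndarray  # (n_persons,) int stage

    @property
    def step_label(self) -> np.ndarray:
        return self.person_label[self.trace_person[self.step_trace]]

    @property
    def trace_label(self) -> np.ndarray:
        return self.person_label[self.trace_person]


@dataclass(frozen=True)
class StagePrediction:
    """Probability vector over stages 0-5 and its argmax stage."""

    probabilities: np.ndarray
    stage: int


class Standardizer:
    """Per-feature zero-mean/unit-sd scaling, fitted on training data only."""

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.sd_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.sd_ = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise ValueError("standardizer is not fitted")
        return (np.asarray(X, dtype=float) - self.mean_) / self.sd_


def assemble_step_features(
    step_time: float,
    toe_probability: float,
    sensor_id: int,
    basic: tuple[float, float, float, float],
    dominant_freq_strike: float,
    dominant_freq_off: float,
    psd_bands: np.ndarray,
) -> np.ndarray:
    """Fixed-order 12-dimensional step feature vector (see STEP_FEATURE_NAMES)."""
    psd_bands = np.asarray(psd_bands, dtype=float)
    if psd_bands.size != 3:
        raise ValueError("step-level PSD summary must have 3 bands")
    vec = np.array(
        [step_time, toe_probability, float(sensor_id), *basic,
         dominant_freq_strike, dominant_freq_off, *psd_bands]
    )
    if not np.all(np.isfinite(vec)):
        raise ValueError("step feature vector contains non-finite entries")
    return vec


def aggregate_mean(embeddings: np.ndarray) -> np.ndarray:
    """Element-wise mean over a group's embeddings (permutation invariant)."""
    embeddings = np.atleast_2d(np.asarray(embeddings, dtype=float))
    if embeddings.shape[0] == 0:
        raise ValueError("cannot aggregate an empty group")
    return embeddings.mean(axis=0)


def build_trace_input(step_probs: np.ndarray, trace_features: np.ndarray) -> np.ndarray:
    """Concatenate trace features with the mean step class-probability vector."""
    agg = aggregate_mean(step_probs)
    return np.concatenate([np.asarray(trace_features, dtype=float), agg])


def encode_biometrics(bio: Biometrics) -> np.ndarray:
    """(age, gender in {0,1}, BMI) encoding of the person-level covariates."""
    return np.array([bio.age, 1.0 if bio.gender == "male" else 0.0, bio.bmi])


def pretrain_level(
    X: np.ndarray,
    y: np.ndarray,
    widths: tuple[int, ...],
    config: ModelConfig,
    seed: int,
) -> MLP:
    """Train one level's network against broadcast stage labels.

    Cross-entropy on a softmax head, Adam, up to ``pretrain_epochs``
    full-batch epochs with early stopping on a held-out validation
    fraction of the training portion. Raises on single-class labels.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("pretraining requires at least 2 classes in the labels")
    rng = np.random.default_rng(seed)
    net = MLP(widths, config.n_classes, dropout=config.dropout, seed=seed)
    opt = Adam(net.parameters(), lr=config.lr)

    n = X.shape[0]
    perm = rng.permutation(n)
    n_val = max(int(round(config.val_frac * n)), 1) if n > 10 else 0
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    best_val, best_params, stall = np.inf, None, 0
    for _ in range(config.pretrain_epochs):
        logits, cache = net.forward(X[tr_idx], train=True, rng=rng)
        _, dlogits = cross_entropy_grad(logits, y[tr_idx])
        dW, db, _ = net.backward(cache, dlogits)
        opt.step(dW + db)
        if n_val:
            val_logits, _ = net.forward(X[val_idx], train=False)
            val_loss, _ = cross_entropy_grad(val_logits, y[val_idx])
            if val_loss < best_val - 1e-6:
                best_val, stall = val_loss, 0
                best_params = [p.copy() for p in net.parameters()]
            else:
                stall += 1
                if stall >= config.patience:
                    break
    if best_params is not None:
        for p, bp in zip(net.parameters(), best_params):
            p[...] = bp
    return net


def _group_mean_probs(
    probs: np.ndarray, group_of: np.ndarray, n_groups: int
) -> tuple[np.ndarray, np.ndarray]:
    """Mean probability vector per group; returns (means, member counts)."""
    k = probs.shape[1]
    sums = np.zeros((n_groups, k))
    np.add.at(sums, group_of, probs)
    counts = np.bincount(group_of, minlength=n_groups).astype(float)
    means = np.divide(sums, counts[:, None], out=np.zeros_like(sums), where=counts[:, None] > 0)
    return means, counts


@dataclass
class HierarchicalModel:
    """Trained three-level stack with its standardization statistics."""

    config: ModelConfig
    step_net: MLP
    trace_net: MLP
    person_net: MLP
    step_scaler: Standardizer
    trace_scaler: Standardizer
    bio_scaler: Standardizer
    metrics: dict = field(default_factory=dict)

    # -- inference -----------------------------------------------------
    def _forward_eval(
        self, data: FeatureDataset
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Step, trace and person probabilities in evaluation mode."""
        n_traces = data.trace_X.shape[0]
        n_persons = data.person_bio.shape[0]
        step_p = self.step_net.predict_proba(self.step_scaler.transform(data.step_X))
        step_agg, _ = _group_mean_probs(step_p, data.step_trace, n_traces)
        trace_in = np.hstack([self.trace_scaler.transform(data.trace_X), step_agg])
        trace_p = self.trace_net.predict_proba(trace_in)
        trace_agg, _ = _group_mean_probs(trace_p, data.trace_person, n_persons)
        person_in = np.hstack([trace_agg, self.bio_scaler.transform(data.person_bio)])
        person_p = self.person_net.predict_proba(person_in)
        return step_p, trace_p, person_p

    def predict_stage(self, data: FeatureDataset) -> list[StagePrediction]:
        """Per-person stage prediction; argmax ties break toward the lower stage."""
        _, _, person_p = self._forward_eval(data)
        return [
            StagePrediction(probabilities=p, stage=int(np.argmax(p))) for p in person_p
        ]

    def save(self, path) -> None:
        import joblib

        joblib.dump({"version": "1", "model": self}, path)

    @classmethod
    def load(cls, path) -> "HierarchicalModel":
        import joblib

        return joblib.load(path)["model"]


def predict_stage(model: HierarchicalModel, data: FeatureDataset) -> list[StagePrediction]:
    """Module-level convenience wrapper around :meth:`HierarchicalModel.predict_stage`."""
    return model.predict_stage(data)


def train_hierarchical(
    data: FeatureDataset,
    config: ModelConfig | None = None,
    seed: int = 0,
) -> HierarchicalModel:
    """Pretrain each level bottom-up, then fine-tune the stack jointly.

    The train/test split is at footstep granularity by default (a
    subject-level split is available via ``config.split_by_subject``).
    Trace- and person-level training inputs aggregate only training
    footsteps; test metrics aggregate only test footsteps. The returned
    model carries step/trace/person test accuracies in ``metrics``.
    """
    config = config or ModelConfig()
    rng = np.random.default_rng(seed)
    n_steps = data.step_X.shape[0]
    n_traces = data.trace_X.shape[0]
    n_persons = data.person_bio.shape[0]
    y_step, y_trace, y_person = data.step_label, data.trace_label, data.person_label
    if np.unique(y_person).size < 2:
        raise ValueError("training requires at least 2 stages in the cohort")

    if config.split_by_subject:
        perm = rng.permutation(n_persons)
        n_tr = max(int(round(config.train_frac * n_persons)), 1)
        train_persons = np.zeros(n_persons, dtype=bool)
        train_persons[perm[:n_tr]] = True
        step_is_train = train_persons[data.trace_person[data.step_trace]]
    else:
        perm = rng.permutation(n_steps)
        n_tr = int(round(config.train_frac * n_steps))
        step_is_train = np.zeros(n_steps, dtype=bool)
        step_is_train[perm[:n_tr]] = True

    # ---- level scalers (training footsteps only: no leakage) ----------
    step_scaler = Standardizer().fit(data.step_X[step_is_train])
    Xs = step_scaler.transform(data.step_X)
    trace_has_train = np.bincount(data.step_trace[step_is_train], minlength=n_traces) > 0
    trace_scaler = Standardizer().fit(data.trace_X[trace_has_train])
    Xt_feat = trace_scaler.transform(data.trace_X)
    person_has_train = np.bincount(
        data.trace_person[trace_has_train], minlength=n_persons
    ) > 0
    bio_scaler = Standardizer().fit(data.person_bio[person_has_train])
    Xp_bio = bio_scaler.transform(data.person_bio)

    # ---- teacher-enforced pretraining, bottom-up ----------------------
    step_net = pretrain_level(
        Xs[step_is_train], y_step[step_is_train], config.step_widths, config,
        seed=int(rng.integers(2**31)),
    )
    step_p = step_net.predict_proba(Xs)
    agg_tr, _ = _group_mean_probs(
        step_p[step_is_train], data.step_trace[step_is_train], n_traces
    )
    trace_in_tr = np.hstack([Xt_feat, agg_tr])[trace_has_train]
    trace_net = pretrain_level(
        trace_in_tr, y_trace[trace_has_train], config.trace_widths, config,
        seed=int(rng.integers(2**31)),
    )
    trace_p_tr = trace_net.predict_proba(np.hstack([Xt_feat, agg_tr]))
    pagg_tr, _ = _group_mean_probs(
        trace_p_tr[trace_has_train], data.trace_person[trace_has_train], n_persons
    )
    person_in_tr = np.hstack([pagg_tr, Xp_bio])[person_has_train]
    person_net = pretrain_level(
        person_in_tr, y_person[person_has_train], config.person_widths, config,
        seed=int(rng.integers(2**31)),
    )

    # ---- joint fine-tuning (gradients flow through softmax + mean) ----
    opt = Adam(
        step_net.parameters() + trace_net.parameters() + person_net.parameters(),
        lr=config.lr,
    )
    st_idx = np.flatnonzero(step_is_train)
    tr_idx = np.flatnonzero(trace_has_train)
    pe_idx = np.flatnonzero(person_has_train)
    step_trace_tr = data.step_trace[st_idx]
    trace_person_all = data.trace_person
    step_counts = np.bincount(step_trace_tr, minlength=n_traces).astype(float)
    trace_counts = np.bincount(
        trace_person_all[tr_idx], minlength=n_persons
    ).astype(float)

    for _ in range(config.joint_epochs):
        s_logits, s_cache = step_net.forward(Xs[st_idx], train=True, rng=rng)
        s_probs = softmax(s_logits)
        s_agg, _ = _group_mean_probs(s_probs, step_trace_tr, n_traces)
        t_in = np.hstack([Xt_feat, s_agg])
        t_logits, t_cache = trace_net.forward(t_in[tr_idx], train=True, rng=rng)
        t_probs = softmax(t_logits)
        t_agg, _ = _group_mean_probs(t_probs, trace_person_all[tr_idx], n_persons)
        p_in = np.hstack([t_agg, Xp_bio])
        p_logits, p_cache = person_net.forward(p_in[pe_idx], train=True, rng=rng)

        _, d_p_logits = cross_entropy_grad(p_logits, y_person[pe_idx])
        pW, pb, d_p_in = person_net.backward(p_cache, d_p_logits)
        d_t_agg = np.zeros((n_persons, config.n_classes))
        d_t_agg[pe_idx] = d_p_in[:, : config.n_classes]
        d_t_probs = d_t_agg[trace_person_all[tr_idx]] / np.maximum(
            trace_counts[trace_person_all[tr_idx], None], 1.0
        )
        _, d_t_logits = cross_entropy_grad(t_logits, y_trace[tr_idx])
        d_t_logits = d_t_logits + softmax_backward(t_probs, d_t_probs)
        tW, tb, d_t_in = trace_net.backward(t_cache, d_t_logits)
        n_trace_feat = data.trace_X.shape[1]
        d_s_agg = np.zeros((n_traces, config.n_classes))
        d_s_agg[tr_idx] = d_t_in[:, n_trace_feat:]
        d_s_probs = d_s_agg[step_trace_tr] / np.maximum(
            step_counts[step_trace_tr, None], 1.0
        )
        _, d_s_logits = cross_entropy_grad(s_logits, y_step[st_idx])
        d_s_logits = d_s_logits + softmax_backward(s_probs, d_s_probs)
        sW, sb, _ = step_net.backward(s_cache, d_s_logits)
        opt.step(sW + sb + tW + tb + pW + pb)

    model = HierarchicalModel(
        config=config,
        step_net=step_net,
        trace_net=trace_net,
        person_net=person_net,
        step_scaler=step_scaler,
        trace_scaler=trace_scaler,
        bio_scaler=bio_scaler,
    )

    # ---- held-out accuracies at each level ----------------------------
    test_idx = np.flatnonzero(~step_is_train)
    step_p_eval = step_net.predict_proba(Xs)
    step_acc = float(
        np.mean(np.argmax(step_p_eval[test_idx], axis=1) == y_step[test_idx])
    ) if test_idx.size else float("nan")
    agg_te, cnt_te = _group_mean_probs(
        step_p_eval[test_idx], data.step_trace[test_idx], n_traces
    )
    trace_has_test = cnt_te > 0
    trace_in_te = np.hstack([Xt_feat, agg_te])
    trace_p_te = trace_net.predict_proba(trace_in_te)
    trace_acc = float(
        np.mean(
            np.argmax(trace_p_te[trace_has_test], axis=1) == y_trace[trace_has_test]
        )
    )
    pagg_te, pcnt_te = _group_mean_probs(
        trace_p_te[trace_has_test], trace_person_all[trace_has_test], n_persons
    )
    person_has_test = pcnt_te > 0
    person_p_te = person_net.predict_proba(np.hstack([pagg_te, Xp_bio]))
    person_acc = float(
        np.mean(
            np.argmax(person_p_te[person_has_test], axis=1)
            == y_person[person_has_test]
        )
    )
    model.metrics = {
        "step_accuracy": step_acc,
        "trace_accuracy": trace_acc,
        "person_accuracy": person_acc,
        "n_test_steps": int(test_idx.size),
        "n_test_traces": int(np.sum(trace_has_test)),
        "n_test_persons": int(np.sum(person_has_test)),
    }
    return model
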