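"""Two-stage training: per-modality GRU encoders, then l1-logistic fusion.

Stage 1 trains one GRU classifier per modality by full-batch gradient
descent on the cross-entropy of its final-step prediction.  Training is
warm-started on the auxiliary diagnostic classes — cognitively normal
subjects labelled as the non-converter class and AD patients as the
converter class — because the CN-vs-AD boundary is an easier proxy for the
NC-vs-C boundary; the main phase then continues on the auxiliaries plus the
horizon-labelled MCI subjects.  Each encoder uses every subject that has its
modality, so subjects missing other modalities still contribute
(non-overlapping samples are not discarded).

Stage 2 freezes the encoders, concatenates the four fixed-size hidden
representations in registry order (absent modalities filled per the missing
policy, zero vector by default), and fits an l1-regularized logistic
classifier for converter vs non-converter on labelled MCI subjects only.
Stage 2 never touches encoder parameters.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.special import expit

from .datamodel import Cohort, ModalitySpec, Subject
from .rnn_core import (
    GRUParams,
    encode_sequence,
    load_params,
    loss_and_gradients,
    save_params,
)

__all__ = [
    "TrainConfig",
    "Standardization",
    "ModalityEncoder",
    "FusionModel",
    "train_modality_gru",
    "extract_representation",
    "assemble_features",
    "fit_l1_logistic",
    "predict_conversion",
    "select_l1_strength",
    "fit_two_stage",
    "save_model",
    "load_model",
]

CONVERTER, NON_CONVERTER = 1, 0


@dataclass
class TrainConfig:
    """Optimizer and regularization settings for both training stages.

    ``l1_strength=None`` triggers an inner 3-fold grid search over
    ``l1_grid`` on the stage-2 training features.  Training is full-batch,
    constant-learning-rate gradient descent, deterministic under ``seed``.
    """

    learning_rate: float = 0.2
    epochs_pretrain: int = 30
    epochs_main: int = 60
    batch_size: int = 0  # 0 = full batch
    l1_strength: float | None = 0.01
    l1_grid: tuple[float, ...] = (1e-3, 1e-2, 1e-1, 1.0, 10.0)
    seed: int = 0
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs_pretrain < 0 or self.epochs_main < 0:
            raise ValueError("epoch counts must be >= 0")
        if self.batch_size < 0:
            raise ValueError("batch_size must be >= 0")
        if self.l1_strength is not None and self.l1_strength < 0:
            raise ValueError("l1_strength must be >= 0")

    @classmethod
    def from_file(cls, path: str | Path) -> "TrainConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "l1_grid" in data:
            data["l1_grid"] = tuple(float(x) for x in data["l1_grid"])
        return cls(**data)


@dataclass
class Standardization:
    """Per-feature z-scoring statistics fitted on training subjects only."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, rows: np.ndarray) -> "Standardization":
        mean = rows.mean(axis=0)
        sd = rows.std(axis=0, ddof=0)
        sd = np.where(sd < 1e-8, 1.0, sd)  # constant features pass through
        return cls(mean, sd)

    @classmethod
    def identity(cls, n_features: int) -> "Standardization":
        return cls(np.zeros(n_features), np.ones(n_features))

    def apply(self, obs: np.ndarray) -> np.ndarray:
        return (obs - self.mean) / self.sd


@dataclass
class ModalityEncoder:
    """A trained GRU feature extractor for one modality."""

    spec: ModalitySpec
    params: GRUParams
    standardization: Standardization
    loss_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.params.hidden_dim != self.spec.hidden_dim:
            raise ValueError(
                f"{self.spec.name}: encoder hidden dim {self.params.hidden_dim} "
                f"!= registry hidden dim {self.spec.hidden_dim}"
            )


@dataclass
class FusionModel:
    """l1-regularized logistic classifier over concatenated representations."""

    weights: np.ndarray
    intercept: float
    l1_strength: float
    missing_policy: str = "zero"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 1:
            raise ValueError("weights must be a vector")

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.weights))


def _modality_seed(base_seed: int, modality: str) -> int:
    """Stable per-modality child seed (< 2^31)."""
    return int(np.random.SeedSequence([base_seed, zlib.crc32(modality.encode())])
               .generate_state(1)[0] % (2 ** 31))


def _standardized_sequences(
    subjects: list[Subject], modality: str, standardization: Standardization
) -> list[np.ndarray]:
    return [standardization.apply(s.sequences[modality].observations) for s in subjects]


def train_modality_gru(
    cohort: Cohort,
    modality: str,
    dt: float,
    config: TrainConfig,
) -> ModalityEncoder:
    """Stage-1 training of one modality's GRU classifier.

    Pre-training phase: ``epochs_pretrain`` epochs of gradient descent on
    CN (non-converter label) and AD (converter label) subjects possessing the
    modality.  Main phase: ``epochs_main`` further epochs on the auxiliaries
    plus MCI subjects whose conversion label at horizon ``dt`` is defined
    (ineligible MCI subjects are dropped).  Subjects lacking the modality are
    simply excluded.  Raises if the MCI training set does not contain both
    classes.
    """
    from .evaluation import derive_label  # local import: evaluation builds on training

    specs = cohort.registry_by_name
    if modality not in specs:
        raise ValueError(f"unknown modality {modality!r}")
    spec = specs[modality]

    aux_subjects, aux_labels = [], []
    for group, label in (("CN", NON_CONVERTER), ("AD", CONVERTER)):
        for s in cohort.subjects_in_group(group):
            if s.has_modality(modality):
                aux_subjects.append(s)
                aux_labels.append(label)

    mci_subjects, mci_labels = [], []
    for s in cohort.subjects_in_group("MCI"):
        if not s.has_modality(modality):
            continue
        status = derive_label(s, dt)
        if status == "ineligible":
            continue
        mci_subjects.append(s)
        mci_labels.append(CONVERTER if status == "converter" else NON_CONVERTER)

    if not aux_subjects and not mci_subjects:
        raise ValueError(f"no subject has modality {modality!r}")
    if mci_subjects and len(set(mci_labels)) < 2:
        raise ValueError(
            f"{modality}: MCI training set contains a single class at dt={dt}"
        )

    train_subjects = aux_subjects + mci_subjects
    if config.standardize:
        rows = np.vstack([s.sequences[modality].observations for s in train_subjects])
        standardization = Standardization.fit(rows)
    else:
        standardization = Standardization.identity(spec.n_features)

    params = GRUParams.init(
        spec.n_features, spec.hidden_dim, n_classes=2,
        seed=_modality_seed(config.seed, modality),
    )

    trace: list[float] = []

    def run_phase(subjects, labels, epochs):
        if not subjects or epochs == 0:
            return
        seqs = _standardized_sequences(subjects, modality, standardization)
        y = np.asarray(labels, dtype=int)
        if config.batch_size and config.batch_size < len(seqs):
            batches = [
                (seqs[i:i + config.batch_size], y[i:i + config.batch_size])
                for i in range(0, len(seqs), config.batch_size)
            ]
        else:
            batches = [(seqs, y)]
        for _ in range(epochs):
            epoch_loss = 0.0
            for bseqs, by in batches:
                loss, grads = loss_and_gradients(params, bseqs, by)
                for name, g in grads.arrays().items():
                    getattr(params, name)[...] -= config.learning_rate * g
                epoch_loss += loss * len(bseqs)
            trace.append(epoch_loss / len(seqs))

    run_phase(aux_subjects, aux_labels, config.epochs_pretrain)
    run_phase(
        aux_subjects + mci_subjects,
        aux_labels + mci_labels,
        config.epochs_main,
    )
    return ModalityEncoder(spec, params, standardization, trace)


def extract_representation(encoder: ModalityEncoder, subject: Subject) -> np.ndarray | None:
    """Final GRU hidden state of the subject's standardized sequence, or None.

    ``None`` marks a subject who never contributed this modality; the fusion
    step decides how to fill the gap.
    """
    name = encoder.spec.name
    if not subject.has_modality(name):
        return None
    obs = encoder.standardization.apply(subject.sequences[name].observations)
    return encode_sequence(encoder.params, obs)


def assemble_features(
    encoders: dict[str, ModalityEncoder],
    subject: Subject,
    order: list[str] | None = None,
    missing_policy: str = "zero",
    fill_vectors: dict[str, np.ndarray] | None = None,
) -> np.ndarray:
    """Concatenate per-modality representations in fixed registry order.

    Absent modalities are filled with zeros (``missing_policy='zero'``, the
    neutral point of the standardized representation space) or with supplied
    per-modality ``fill_vectors`` (``missing_policy='mean'``).  The result
    always has length sum of hidden dims.
    """
    if missing_policy not in ("zero", "mean"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    names = list(order) if order is not None else list(encoders)
    parts = []
    for name in names:
        enc = encoders[name]
        rep = extract_representation(enc, subject)
        if rep is None:
            if missing_policy == "mean" and fill_vectors and name in fill_vectors:
                rep = np.asarray(fill_vectors[name], dtype=float)
            else:
                rep = np.zeros(enc.spec.hidden_dim)
        parts.append(rep)
    return np.concatenate(parts)


# ---------------------------------------------------------------------------
# Stage 2: l1-regularized logistic regression via proximal gradient (FISTA).

def _logistic_loss(X: np.ndarray, y: np.ndarray, w: np.ndarray, b: float) -> float:
    m = X @ w + b
    # log(1 + exp(-s*m)) with s = +-1, stable form
    s = 2.0 * y - 1.0
    return float(np.mean(np.logaddexp(0.0, -s * m)))


def fit_l1_logistic(
    features: np.ndarray,
    labels: np.ndarray,
    l1_strength: float,
    seed: int = 0,
    max_iter: int = 5000,
    tol: float = 1e-10,
    missing_policy: str = "zero",
) -> FusionModel:
    """Minimize mean logistic loss + l1 * ||w||_1 (intercept unpenalized).

    Solved by FISTA (accelerated proximal gradient with soft-thresholding)
    with a fixed step from the spectral norm of the design matrix, which is a
    Lipschitz bound for the logistic gradient.  Deterministic given inputs;
    ``seed`` is accepted for interface symmetry but unused.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("features must be (n_samples, n_features) matching labels")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if l1_strength < 0:
        raise ValueError("l1_strength must be >= 0")
    n, d = X.shape

    X1 = np.column_stack([X, np.ones(n)])
    lip = (np.linalg.norm(X1, 2) ** 2) / (4.0 * n)
    step = 1.0 / max(lip, 1e-12)

    w = np.zeros(d)
    b = 0.0
    vw, vb = w.copy(), b  # momentum iterate
    t_k = 1.0
    for _ in range(max_iter):
        m = X @ vw + vb
        g = expit(m) - y
        grad_w = X.T @ g / n
        grad_b = float(g.mean())
        w_new = vw - step * grad_w
        w_new = np.sign(w_new) * np.maximum(np.abs(w_new) - step * l1_strength, 0.0)
        b_new = vb - step * grad_b
        t_next = (1.0 + np.sqrt(1.0 + 4.0 * t_k ** 2)) / 2.0
        beta = (t_k - 1.0) / t_next
        vw = w_new + beta * (w_new - w)
        vb = b_new + beta * (b_new - b)
        delta = max(np.max(np.abs(w_new - w)), abs(b_new - b))
        w, b, t_k = w_new, b_new, t_next
        if delta < tol:
            break
    return FusionModel(w, float(b), l1_strength, missing_policy)


def predict_conversion(model: FusionModel, features: np.ndarray) -> float | np.ndarray:
    """Conversion probability logistic(intercept + w . features)."""
    X = np.asarray(features, dtype=float)
    if X.shape[-1] != model.weights.size:
        raise ValueError(
            f"feature length {X.shape[-1]} != model weight length {model.weights.size}"
        )
    p = expit(X @ model.weights + model.intercept)
    return float(p) if p.ndim == 0 else p


def select_l1_strength(
    features: np.ndarray,
    labels: np.ndarray,
    grid: tuple[float, ...],
    k: int = 3,
    seed: int = 0,
) -> float:
    """Pick lambda from ``grid`` by inner stratified k-fold mean log-loss."""
    from sklearn.model_selection import StratifiedKFold

    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2 ** 31))
    scores = []
    for lam in grid:
        losses = []
        for train_idx, val_idx in skf.split(X, y):
            model = fit_l1_logistic(X[train_idx], y[train_idx], lam)
            losses.append(
                _logistic_loss(X[val_idx], y[val_idx], model.weights, model.intercept)
            )
        scores.append(np.mean(losses))
    return float(grid[int(np.argmin(scores))])


def fit_two_stage(
    cohort: Cohort,
    modalities: list[str],
    dt: float,
    config: TrainConfig,
    mci_ids: list[str] | None = None,
) -> tuple[dict[str, ModalityEncoder], FusionModel]:
    """Train encoders on the full cohort, then the fusion head on labelled MCI.

    ``mci_ids`` restricts stage 2 (and the MCI portion of stage 1) to a
    subset of MCI subjects — the cross-validation driver passes the training
    fold here while auxiliaries always stay in.
    """
    from .evaluation import derive_label

    if mci_ids is not None:
        keep = set(mci_ids) | {
            s.id for s in cohort.subjects if s.baseline_group != "MCI"
        }
        train_cohort = cohort.restrict(keep)
    else:
        train_cohort = cohort

    encoders = {
        m: train_modality_gru(train_cohort, m, dt, config) for m in modalities
    }

    rows, ys = [], []
    for s in train_cohort.subjects_in_group("MCI"):
        status = derive_label(s, dt)
        if status == "ineligible":
            continue
        rows.append(assemble_features(encoders, s, order=modalities))
        ys.append(CONVERTER if status == "converter" else NON_CONVERTER)
    X, y = np.asarray(rows), np.asarray(ys)
    lam = config.l1_strength
    if lam is None:
        lam = select_l1_strength(X, y, config.l1_grid, seed=config.seed)
    fusion = fit_l1_logistic(X, y, lam, seed=config.seed)
    return encoders, fusion


# ---------------------------------------------------------------------------
# Model persistence: per-modality parameter files + a JSON header.

def save_model(
    encoders: dict[str, ModalityEncoder], fusion: FusionModel, path: str | Path
) -> None:
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    header = {
        "order": list(encoders),
        "missing_policy": fusion.missing_policy,
        "l1_strength": fusion.l1_strength,
        "intercept": fusion.intercept,
        "weights": fusion.weights.tolist(),
        "encoders": {},
    }
    for name, enc in encoders.items():
        save_params(enc.params, out / f"encoder_{name}.json")
        header["encoders"][name] = {
            "spec": dataclasses.asdict(enc.spec),
            "mean": enc.standardization.mean.tolist(),
            "sd": enc.standardization.sd.tolist(),
        }
    (out / "model.json").write_text(json.dumps(header, indent=2))


def load_model(path: str | Path) -> tuple[dict[str, ModalityEncoder], FusionModel]:
    p = Path(path)
    header = json.loads((p / "model.json").read_text())
    encoders = {}
    for name in header["order"]:
        meta = header["encoders"][name]
        encoders[name] = ModalityEncoder(
            spec=ModalitySpec(**meta["spec"]),
            params=load_params(p / f"encoder_{name}.json"),
            standardization=Standardization(
                np.asarray(meta["mean"]), np.asarray(meta["sd"])
            ),
        )
    fusion = FusionModel(
        np.asarray(header["weights"]),
        header["intercept"],
        header["l1_strength"],
        header["missing_policy"],
    )
    return encoders, fusion
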