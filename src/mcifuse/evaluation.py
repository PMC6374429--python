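"""Horizon labelling, experimental schemes, repeated stratified CV, metrics.

Prediction is framed per horizon ``dt`` (months from baseline, default grid
6/12/18/24): an MCI subject is a *converter* at ``dt`` if conversion occurred
by that month, a *non-converter* if unconverted with follow-up reaching
``dt``, and *ineligible* if unconverted but followed for less than ``dt``
(the window cannot rule conversion out).  Eligible MCI subjects are split
into stratified folds; CN/AD auxiliaries join every training split and never
any test fold.

Three scheme families are compared: ``baseline`` (all modalities, every
sequence truncated to its first visit), ``single_modal(m)`` (one modality,
full sequences) and ``proposed`` (all modalities, full sequences).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import Cohort, Subject
from .training import (
    TrainConfig,
    assemble_features,
    fit_two_stage,
    predict_conversion,
)

__all__ = [
    "Scheme",
    "EvalResult",
    "derive_label",
    "truncate_to_baseline",
    "make_folds",
    "run_scheme",
    "compute_metrics",
    "balanced_accuracy",
    "paired_t_test",
    "report",
]

DEFAULT_HORIZONS = (6.0, 12.0, 18.0, 24.0)


def derive_label(subject: Subject, dt: float) -> str:
    """Conversion status of an MCI subject at horizon ``dt`` months.

    ``converter`` if conversion occurred by ``dt``; ``non_converter`` if no
    conversion by ``dt`` and follow-up reaches ``dt`` (conversion after the
    window counts as non-conversion at this horizon); ``ineligible`` if
    unconverted with follow-up shorter than ``dt``.
    """
    if subject.baseline_group != "MCI":
        raise ValueError(f"{subject.id}: horizon labels are defined for MCI subjects only")
    if subject.conversion_month is not None and subject.conversion_month <= dt:
        return "converter"
    if subject.followup_month >= dt:
        return "non_converter"
    return "ineligible"


@dataclass(frozen=True)
class Scheme:
    """One experimental condition: which modalities, and whether longitudinal."""

    name: str
    modalities: tuple[str, ...]
    uses_longitudinal: bool

    def __post_init__(self) -> None:
        if not self.modalities:
            raise ValueError("scheme needs at least one modality")

    @classmethod
    def proposed(cls, cohort: Cohort) -> "Scheme":
        return cls("proposed", tuple(s.name for s in cohort.registry), True)

    @classmethod
    def baseline(cls, cohort: Cohort) -> "Scheme":
        return cls("baseline", tuple(s.name for s in cohort.registry), False)

    @classmethod
    def single(cls, modality: str) -> "Scheme":
        return cls(f"single:{modality}", (modality,), True)


def truncate_to_baseline(cohort: Cohort) -> Cohort:
    """Copy of the cohort with every sequence cut to its first visit."""
    subjects = [
        Subject(
            id=s.id,
            baseline_group=s.baseline_group,
            conversion_month=s.conversion_month,
            followup_month=s.followup_month,
            sequences={
                name: seq.truncated_to_first_visit() for name, seq in s.sequences.items()
            },
        )
        for s in cohort.subjects
    ]
    return Cohort(subjects, cohort.registry)


def make_folds(
    ids: list[str],
    labels: np.ndarray,
    k: int = 5,
    repeats: int = 10,
    seed: int = 0,
) -> list[list[list[str]]]:
    """Repeated stratified k-fold partitions of the labelled ids.

    Returns ``repeats`` partitions, each a list of ``k`` id lists (the test
    folds); every fold's converter fraction is within one subject of the
    global fraction.  Child seeds are spawned from ``seed`` so repeats are
    distinct but the whole structure is reproducible.
    """
    from sklearn.model_selection import StratifiedKFold

    ids = list(ids)
    y = np.asarray(labels, dtype=int)
    if len(ids) != y.size:
        raise ValueError("ids and labels must align")
    if len(ids) < k:
        raise ValueError(f"need at least k={k} subjects, got {len(ids)}")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present for stratification")

    child_seeds = np.random.SeedSequence(seed).generate_state(repeats) % (2 ** 31)
    all_repeats = []
    id_arr = np.asarray(ids, dtype=object)
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(child_seeds[r]))
        folds = [list(id_arr[test_idx]) for _, test_idx in skf.split(id_arr, y)]
        all_repeats.append(folds)
    return all_repeats


def compute_metrics(
    labels: np.ndarray, probabilities: np.ndarray, threshold: float = 0.5
) -> dict[str, float]:
    """Accuracy, sensitivity, specificity at ``threshold``; rank-statistic AUC.

    Converters are the positive class.  AUC is the Mann-Whitney probability
    that a random converter outranks a random non-converter, with tied
    probabilities contributing half — hence invariant under strictly
    monotone transforms of the scores.
    """
    y = np.asarray(labels, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    if y.size != p.size or y.size == 0:
        raise ValueError("labels and probabilities must align and be non-empty")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required for sensitivity/specificity/AUC")

    pred = (p >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    ranks = stats.rankdata(p)  # average ranks on ties
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return {
        "accuracy": (tp + tn) / y.size,
        "sensitivity": tp / n_pos,
        "specificity": tn / n_neg,
        "auc": float(auc),
    }


def balanced_accuracy(sensitivity: float, specificity: float) -> float:
    """Mean of sensitivity and specificity — accuracy robust to class imbalance."""
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    return (sensitivity + specificity) / 2.0


def paired_t_test(metric_a: np.ndarray, metric_b: np.ndarray) -> dict[str, float]:
    """Classical paired t-test on per-fold metric differences.

    Degenerate zero-variance branch (documented convention): identical
    vectors give ``t = 0, p = 1``; a constant nonzero shift gives
    ``t = +-inf, p = 0``.
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length vectors with at least 2 pairs")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return {"t": 0.0, "p": 1.0}
        return {"t": float(np.sign(d.mean()) * np.inf), "p": 0.0}
    t, p = stats.ttest_rel(a, b)
    return {"t": float(t), "p": float(p)}


@dataclass
class EvalResult:
    """Per-(repeat, fold) metric records for one scheme at one horizon."""

    dt: float
    scheme: Scheme
    records: pd.DataFrame  # columns: repeat, fold, accuracy, sensitivity, specificity, auc

    def aggregate(self) -> pd.DataFrame:
        """Mean and sd of each metric over all repeat x fold records."""
        metrics = ["accuracy", "sensitivity", "specificity", "auc"]
        return pd.DataFrame(
            {"mean": self.records[metrics].mean(), "sd": self.records[metrics].std(ddof=1)}
        )

    def metric_vector(self, metric: str) -> np.ndarray:
        """Metric values ordered by (repeat, fold) for paired comparisons."""
        return (
            self.records.sort_values(["repeat", "fold"])[metric].to_numpy(dtype=float)
        )


def run_scheme(
    cohort: Cohort,
    scheme: Scheme,
    dt: float,
    train_config: TrainConfig,
    cv: tuple[int, int, int] = (5, 10, 0),
) -> EvalResult:
    """Repeated stratified CV of one scheme at one horizon.

    Per repeat and fold: stage 1 trains on all CN/AD plus the MCI training
    fold (scheme's modalities; sequences truncated to baseline for
    non-longitudinal schemes), stage 2 on the MCI training fold, and the
    held-out MCI fold alone is scored.  Leakage and the accuracy identity
    ``ACC = prev*SEN + (1-prev)*SPE`` are asserted on every fold.
    """
    k, repeats, fold_seed = cv
    working = cohort if scheme.uses_longitudinal else truncate_to_baseline(cohort)

    eligible_ids, eligible_labels = [], []
    for s in working.subjects_in_group("MCI"):
        status = derive_label(s, dt)
        if status == "ineligible":
            continue
        eligible_ids.append(s.id)
        eligible_labels.append(1 if status == "converter" else 0)
    labels_by_id = dict(zip(eligible_ids, eligible_labels))
    folds = make_folds(eligible_ids, np.asarray(eligible_labels), k, repeats, fold_seed)

    aux_ids = {s.id for s in working.subjects if s.baseline_group != "MCI"}
    records = []
    for r, partition in enumerate(folds):
        for f, test_ids in enumerate(partition):
            if not test_ids:
                raise ValueError("empty test fold")
            test_set = set(test_ids)
            train_mci = [i for i in eligible_ids if i not in test_set]
            assert not (test_set & aux_ids), "CN/AD subject leaked into a test fold"
            assert not (test_set & set(train_mci)), "train/test folds overlap"

            fold_config = _fold_config(train_config, r, f)
            encoders, fusion = fit_two_stage(
                working, list(scheme.modalities), dt, fold_config, mci_ids=train_mci
            )
            X_test = np.asarray(
                [
                    assemble_features(
                        encoders, working.subject(i), order=list(scheme.modalities)
                    )
                    for i in test_ids
                ]
            )
            y_test = np.asarray([labels_by_id[i] for i in test_ids])
            probs = predict_conversion(fusion, X_test)
            m = compute_metrics(y_test, np.atleast_1d(probs))

            prev = y_test.mean()
            identity = prev * m["sensitivity"] + (1 - prev) * m["specificity"]
            assert abs(m["accuracy"] - identity) < 1e-9, "accuracy identity violated"

            records.append({"repeat": r, "fold": f, "n_test": y_test.size,
                            "prevalence": prev, **m})
    return EvalResult(dt, scheme, pd.DataFrame(records))


def _fold_config(config: TrainConfig, repeat: int, fold: int) -> TrainConfig:
    """Per-fold training seed derived from the base seed (separate stream)."""
    import dataclasses as dc

    child = int(
        np.random.SeedSequence([config.seed, repeat, fold]).generate_state(1)[0]
        % (2 ** 31)
    )
    return dc.replace(config, seed=child)


def report(results: list[EvalResult]) -> tuple[pd.DataFrame, dict]:
    """Mean +- sd table per (horizon, scheme) plus paired p-values vs 'proposed'.

    Returns the tidy table and a JSON-serializable dict with the same
    content plus raw per-fold records.
    """
    if not results:
        raise ValueError("need at least one result")
    rows = []
    for res in results:
        agg = res.aggregate()
        row: dict[str, object] = {"dt": res.dt, "scheme": res.scheme.name}
        for metric in ("accuracy", "sensitivity", "specificity", "auc"):
            row[f"{metric}_mean"] = float(agg.loc[metric, "mean"])
            row[f"{metric}_sd"] = float(agg.loc[metric, "sd"])
        rows.append(row)
    table = pd.DataFrame(rows)

    proposed = {res.dt: res for res in results if res.scheme.name == "proposed"}
    pvalues = []
    for res in results:
        if res.scheme.name == "proposed" or res.dt not in proposed:
            continue
        ref = proposed[res.dt]
        entry = {"dt": res.dt, "scheme": res.scheme.name}
        for metric in ("accuracy", "sensitivity", "specificity", "auc"):
            test = paired_t_test(ref.metric_vector(metric), res.metric_vector(metric))
            entry[f"{metric}_p"] = test["p"]
        pvalues.append(entry)

    payload = {
        "table": table.to_dict(orient="records"),
        "pvalues_vs_proposed": pvalues,
        "records": [
            {
                "dt": res.dt,
                "scheme": res.scheme.name,
                "records": res.records.to_dict(orient="records"),
            }
            for res in results
        ],
    }
    return table, payload


def write_report(results: list[EvalResult], out_dir: str | Path) -> dict[str, Path]:
    """Render :func:`report` to ``report.csv`` + ``report.json`` under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table, payload = report(results)
    paths = {"csv": out / "report.csv", "json": out / "report.json"}
    table.to_csv(paths["csv"], index=False)
    paths["json"].write_text(json.dumps(payload, indent=2))
    return paths
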