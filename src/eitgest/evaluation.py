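"""Train/test split regimes, task orchestration, and the drift experiment.

Four regimes probe increasingly hard generalization:

* ``stratified_random`` — 75/25 shuffle split per class inside a session;
  the easy, placement-constant setting.
* ``leave_one_iteration_out`` — hold out one iteration of a session; probes
  robustness to within-session drift.
* ``leave_one_session_out`` — hold out a whole session of a subject; probes
  robustness to device re-placement.
* ``leave_one_subject_out`` — hold out a whole subject; probes transfer to
  unseen physiology.

The drift experiment trains on a single iteration and tests on the next:
with converging drift the 1 -> 2 transition is the hardest and accuracy rises
for later transitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .frames import GestureDataset, N_GESTURES
from .models import ModelSpec, TrainConfig, build_model, prepare_inputs, train
from .results import EvalResult
from .stats import mean_ci
from .transforms import calibrate, fit_normalizer, pair_with_reference

STRATEGIES = (
    "stratified_random",
    "leave_one_iteration_out",
    "leave_one_session_out",
    "leave_one_subject_out",
)

TASKS = ("within_random", "within_iteration", "cross_session", "cross_subject")


@dataclass(frozen=True)
class SplitSpec:
    strategy: str
    holdout: object = None  # iteration number, (subject, session), or subject id
    train_fraction: float = 0.75
    seed: int = 0

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}; one of {STRATEGIES}")


@dataclass
class Split:
    train: GestureDataset
    test: GestureDataset
    description: str
    warnings: list[str] = field(default_factory=list)


def make_split(dataset: GestureDataset, spec: SplitSpec) -> Split:
    """Partition ``dataset`` according to ``spec``; train/test are disjoint."""
    if spec.strategy == "stratified_random":
        rng = np.random.default_rng(spec.seed)
        test_idx: list[int] = []
        for g in sorted(dataset.meta["gesture"].unique()):
            idx = np.flatnonzero(dataset.mask(gesture=int(g)))
            rng.shuffle(idx)
            n_test = int(round(len(idx) * (1.0 - spec.train_fraction)))
            n_test = min(max(n_test, 1), len(idx) - 1)
            test_idx.extend(idx[:n_test])
        test_mask = np.zeros(len(dataset), dtype=bool)
        test_mask[test_idx] = True
        desc = f"stratified_random(seed={spec.seed})"
        sp = Split(dataset.take(np.flatnonzero(~test_mask)),
                   dataset.take(np.flatnonzero(test_mask)), desc)
    elif spec.strategy == "leave_one_iteration_out":
        it = int(spec.holdout)
        its = dataset.meta["iteration"].unique()
        if len(its) < 2:
            raise ValueError("leave-one-iteration-out needs a session with >= 2 iterations")
        if it not in its:
            raise ValueError(f"iteration {it} not present (have {sorted(its)})")
        test_mask = dataset.mask(iteration=it)
        sp = Split(dataset.take(np.flatnonzero(~test_mask)),
                   dataset.take(np.flatnonzero(test_mask)), f"leave_iteration_{it}")
    elif spec.strategy == "leave_one_session_out":
        subj, sess = spec.holdout
        if (subj, sess) not in dataset.session_keys():
            raise ValueError(f"session {subj}/{sess} not present")
        test_mask = dataset.mask(subject=subj, session=sess)
        sp = Split(dataset.take(np.flatnonzero(~test_mask)),
                   dataset.take(np.flatnonzero(test_mask)), f"leave_session_{subj}/{sess}")
    elif spec.strategy == "leave_one_subject_out":
        subj = spec.holdout
        if subj not in dataset.subjects():
            raise ValueError(f"subject {subj!r} not present")
        test_mask = dataset.mask(subject=subj)
        sp = Split(dataset.take(np.flatnonzero(~test_mask)),
                   dataset.take(np.flatnonzero(test_mask)), f"leave_subject_{subj}")
    else:  # pragma: no cover - guarded by SplitSpec
        raise ValueError(spec.strategy)

    if sp.train.n_frames == 0 or sp.test.n_frames == 0:
        raise ValueError(f"{sp.description}: empty train or test side")
    missing = sorted(set(range(N_GESTURES)) - set(sp.train.meta["gesture"].unique()))
    if missing:
        sp.warnings.append(f"classes absent from training: {missing}")
    return sp


# ---------------------------------------------------------------------------
# pipeline glue
# ---------------------------------------------------------------------------

def prepare_run(split: Split, spec: ModelSpec, calibration: str):
    """Normalize (fit on train), calibrate, and arrange model inputs.

    Calibration modes: ``none``, ``global``, ``local`` (subtractive, single
    input) and ``learned`` (dual input: frames paired with their
    iteration-local neutral reference). References for the test side come
    from the test side's own neutral frames — that is the method's protocol,
    not leakage: the reference posture is always available at use time.
    """
    if calibration == "learned" and not spec.dual_input:
        raise ValueError(f"{spec.name} is single-input; learned calibration needs a dual model")
    if calibration != "learned" and spec.dual_input:
        raise ValueError(f"{spec.name} is dual-input; use calibration='learned'")
    norm = fit_normalizer(split.train)
    tr, te = norm.transform(split.train), norm.transform(split.test)
    if calibration == "learned":
        ptr, pte = pair_with_reference(tr), pair_with_reference(te)
        xtr = prepare_inputs(spec, ptr.dataset, ptr.references)
        xte = prepare_inputs(spec, pte.dataset, pte.references)
    else:
        tr, te = calibrate(tr, calibration), calibrate(te, calibration)
        xtr, xte = prepare_inputs(spec, tr), prepare_inputs(spec, te)
    return xtr, split.train.labels, xte, split.test.labels


def run_split(dataset: GestureDataset, split_spec: SplitSpec, model_spec: ModelSpec,
              calibration: str, config: TrainConfig) -> EvalResult:
    """One full run: split, preprocess, build, train."""
    split = make_split(dataset, split_spec)
    xtr, ytr, xte, yte = prepare_run(split, model_spec, calibration)
    model = build_model(model_spec, dataset.schedule, seed=config.seed)
    result = train(model, xtr, ytr, xte, yte, config,
                   model_name=model_spec.name, split=split.description,
                   calibration=calibration)
    result.warnings.extend(split.warnings)
    return result


def run_task(
    dataset: GestureDataset,
    task: str,
    models: list[ModelSpec],
    n_seeds: int = 5,
    calibration: str = "none",
    config: TrainConfig = TrainConfig(),
    base_seed: int = 0,
) -> list[EvalResult]:
    """Full cross-product of holdout units x models x seeds for one task.

    Within-session tasks run once per session; cross-session runs one
    leave-one-session-out fold per session of each multi-session subject
    (training pools all remaining sessions of that subject); cross-subject
    runs one leave-one-subject-out fold per subject.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; one of {TASKS}")
    runs: list[tuple[GestureDataset, SplitSpec, str]] = []

    if task in ("within_random", "within_iteration"):
        for subj, sess in dataset.session_keys():
            session_ds = dataset.select(subject=subj, session=sess)
            its = sorted(session_ds.meta["iteration"].unique())
            if task == "within_iteration" and len(its) < 2:
                raise ValueError(
                    f"within_iteration needs >= 2 iterations; session {subj}/{sess} has {len(its)}"
                )
            for s in range(n_seeds):
                seed = base_seed + s
                if task == "within_random":
                    spec = SplitSpec("stratified_random", seed=seed)
                else:
                    it = int(np.random.default_rng(seed).choice(its))
                    spec = SplitSpec("leave_one_iteration_out", holdout=it, seed=seed)
                runs.append((session_ds, spec, f"{subj}/{sess}"))
    elif task == "cross_session":
        multi = [s for s in dataset.subjects()
                 if len({k for k in dataset.session_keys() if k[0] == s}) >= 2]
        if not multi:
            raise ValueError("cross_session needs a subject with >= 2 sessions")
        for subj in multi:
            subj_ds = dataset.select(subject=subj)
            for key in subj_ds.session_keys():
                for s in range(n_seeds):
                    spec = SplitSpec("leave_one_session_out", holdout=key, seed=base_seed + s)
                    runs.append((subj_ds, spec, f"{key[0]}/{key[1]}"))
    else:  # cross_subject
        subjects = dataset.subjects()
        if len(subjects) < 2:
            raise ValueError("cross_subject needs >= 2 subjects")
        for subj in subjects:
            for s in range(n_seeds):
                spec = SplitSpec("leave_one_subject_out", holdout=subj, seed=base_seed + s)
                runs.append((dataset, spec, subj))

    results = []
    for ds, split_spec, unit in runs:
        for mspec in models:
            cfg = TrainConfig(epochs=config.epochs, batch_size=config.batch_size,
                              learning_rate=config.learning_rate, seed=split_spec.seed)
            res = run_split(ds, split_spec, mspec, calibration, cfg)
            res.split = f"{task}:{res.split}"
            results.append(res)
    return results


def results_table(results: list[EvalResult]) -> pd.DataFrame:
    """Tidy per-run table consumed by the stats module and the CLI."""
    return pd.DataFrame(
        {
            "model": r.model,
            "split": r.split,
            "calibration": r.calibration,
            "seed": r.seed,
            "best_test_accuracy": r.best_test_accuracy,
            "best_epoch": r.best_epoch,
            "final_test_accuracy": r.test_accuracy[-1],
            "warnings": "; ".join(r.warnings),
        }
        for r in results
    )


# ---------------------------------------------------------------------------
# drift experiment
# ---------------------------------------------------------------------------

@dataclass
class DriftResult:
    """Cross-iteration generalization: train on iteration t, test on t + 1."""

    per_run: pd.DataFrame  # subject, session, transition (t -> t+1 labelled t+1), seed, accuracy
    per_transition: pd.DataFrame  # transition, mean, ci_lower, ci_upper, n_runs


def drift_experiment(
    dataset: GestureDataset,
    model_spec: ModelSpec,
    n_seeds: int = 5,
    config: TrainConfig = TrainConfig(),
    base_seed: int = 0,
) -> DriftResult:
    """Quantify within-session drift via next-iteration generalization.

    For every session with at least two iterations and every transition
    ``t -> t + 1`` the session contains, a fresh classifier is trained on
    iteration ``t`` alone and evaluated on iteration ``t + 1``; ``n_seeds``
    random initializations are averaged. Transitions are labelled by the
    evaluated iteration ``t + 1`` and aggregated across sessions with a 95%
    t-interval.
    """
    rows = []
    any_multi = False
    for subj, sess in dataset.session_keys():
        session_ds = dataset.select(subject=subj, session=sess)
        its = sorted(session_ds.meta["iteration"].unique())
        if len(its) < 2:
            continue
        any_multi = True
        for t in its[:-1]:
            if t + 1 not in its:
                continue
            tr = session_ds.select(iteration=int(t))
            te = session_ds.select(iteration=int(t + 1))
            split = Split(tr, te, f"drift_{subj}/{sess}_{t}->{t + 1}")
            for s in range(n_seeds):
                cfg = TrainConfig(epochs=config.epochs, batch_size=config.batch_size,
                                  learning_rate=config.learning_rate, seed=base_seed + s)
                xtr, ytr, xte, yte = prepare_run(split, model_spec, "none")
                model = build_model(model_spec, dataset.schedule, seed=cfg.seed)
                res = train(model, xtr, ytr, xte, yte, cfg, model_name=model_spec.name,
                            split=split.description)
                rows.append((subj, sess, int(t + 1), cfg.seed, res.best_test_accuracy))
    if not any_multi:
        raise ValueError("drift experiment needs at least one session with >= 2 iterations")

    per_run = pd.DataFrame(rows, columns=["subject", "session", "transition", "seed", "accuracy"])
    agg_rows = []
    for t, grp in per_run.groupby("transition"):
        acc = grp["accuracy"].to_numpy()
        if len(acc) >= 2:
            m, lo, hi = mean_ci(acc)
        else:
            m, lo, hi = float(acc.mean()), float(acc.mean()), float(acc.mean())
        agg_rows.append((int(t), m, lo, hi, len(acc)))
    per_transition = pd.DataFrame(
        agg_rows, columns=["transition", "mean_accuracy", "ci_lower", "ci_upper", "n_runs"]
    ).sort_values("transition").reset_index(drop=True)
    return DriftResult(per_run=per_run, per_transition=per_transition)
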