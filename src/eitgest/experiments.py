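"""Canned end-to-end experiments on the synthetic study configuration.

These functions bundle the package's headline analyses at a fixed, documented
problem size so they can be reproduced with one call: the calibration
comparison (raw vs global vs local reference subtraction under
leave-one-session-out evaluation, plus the within-session baseline) and the
cross-iteration drift profile. Problem sizes (sessions used, training seeds,
epochs) are chosen so a full reproduction completes in minutes on one CPU
core; they are parameters, not constants, so larger replications are one
argument away.
"""

from __future__ import annotations

import numpy as np

from .evaluation import drift_experiment, results_table, run_task
from .models import TrainConfig, preset
from .synth import default_paper_like_config, simulate_dataset

DEFAULT_MODEL = "MLP 1 Unreg"


def calibration_ordering(
    seed: int = 0,
    n_seeds: int = 5,
    epochs: int = 15,
    batch_size: int = 64,
    model: str = DEFAULT_MODEL,
    within_sessions: int = 2,
    within_epochs: int = 150,
) -> dict:
    """Cross-session accuracy under each calibration mode, plus within-session.

    Simulates the study-scale dataset for ``seed``, then:

    * leave-one-session-out over all 8 sessions x ``n_seeds`` network
      initializations for calibration in {none, global, local};
    * stratified 75/25 within-session classification on the first
      ``within_sessions`` sessions x ``n_seeds`` initializations.

    Returns a dict with mean best test accuracies under keys
    ``raw``, ``global``, ``local``, ``within``, the per-mode run tables
    under ``tables``, and ``n_frames``.
    """
    ds, _ = simulate_dataset(default_paper_like_config(seed))
    spec = preset(model)
    cfg = TrainConfig(epochs=epochs, batch_size=batch_size)
    out: dict = {"n_frames": ds.n_frames, "tables": {}}
    for mode, key in (("none", "raw"), ("global", "global"), ("local", "local")):
        res = run_task(ds, "cross_session", [spec], n_seeds=n_seeds,
                       calibration=mode, config=cfg, base_seed=seed)
        table = results_table(res)
        out["tables"][key] = table
        out[key] = float(table["best_test_accuracy"].mean())
    # single-session training sets are small (540 frames) and need many more
    # passes to fit at the standard learning rate
    within_cfg = TrainConfig(epochs=within_epochs, batch_size=batch_size)
    within_ds = ds.select(session=[str(i + 1) for i in range(within_sessions)])
    res = run_task(within_ds, "within_random", [spec], n_seeds=n_seeds,
                   calibration="none", config=within_cfg, base_seed=seed)
    table = results_table(res)
    out["tables"]["within"] = table
    out["within"] = float(table["best_test_accuracy"].mean())
    return out


def drift_profile(
    seed: int = 0,
    n_sessions: int = 3,
    n_seeds: int = 2,
    epochs: int = 400,
    model: str = DEFAULT_MODEL,
):
    """Cross-iteration drift profile on the synthetic study configuration.

    Trains on single iterations and tests on the subsequent one for the first
    ``n_sessions`` sessions. Single-iteration training sets hold only 120
    frames, so training runs full-batch for ``epochs`` epochs (the small
    problem is slow to fit at the standard learning rate).

    Returns the per-transition aggregate table (see
    :func:`eitgest.evaluation.drift_experiment`).
    """
    ds, _ = simulate_dataset(default_paper_like_config(seed))
    sub = ds.select(session=[str(i + 1) for i in range(n_sessions)])
    dr = drift_experiment(sub, preset(model), n_seeds=n_seeds,
                          config=TrainConfig(epochs=epochs, batch_size=120),
                          base_seed=seed)
    return dr.per_transition
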