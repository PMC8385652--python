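"""Unsupervised structure analysis: t-SNE embeddings, PCA, calibration effect.

These diagnostics operationalize the visual findings about wrist-EIT data —
sessions forming distinct clusters, a within-session drift gradient across
iterations, and calibration shrinking the dominant variance directions — as
computable quantities (silhouette scores, centroid trajectories, explained
variance) rather than figures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .errors import IntegrityError
from .frames import GestureDataset

#: Conventional embedding settings: perplexity 90 for class/session structure,
#: 100 for the iteration (drift) view; seed 42, 5,000 optimization steps.
SESSION_PERPLEXITY = 90.0
ITERATION_PERPLEXITY = 100.0
DEFAULT_TSNE_SEED = 42
DEFAULT_TSNE_ITER = 5000


@dataclass
class EmbeddingResult:
    """2-D coordinates per frame with metadata and logged parameters."""

    coordinates: np.ndarray  # (n_frames, 2)
    meta: pd.DataFrame  # subject, session, iteration, gesture, frame_index
    method: str
    params: dict

    def frame(self) -> pd.DataFrame:
        out = self.meta.copy()
        out["x"] = self.coordinates[:, 0]
        out["y"] = self.coordinates[:, 1]
        return out


def tsne_embed(
    dataset: GestureDataset,
    perplexity: float = SESSION_PERPLEXITY,
    seed: int = DEFAULT_TSNE_SEED,
    n_iter: int = DEFAULT_TSNE_ITER,
) -> EmbeddingResult:
    """t-SNE embedding of all frames into 2-D.

    Deterministic under a fixed seed within one library version. Requires at
    least ``3 * perplexity`` frames (the usual applicability bound).
    """
    n = dataset.n_frames
    if n < 3 * perplexity:
        raise ValueError(
            f"t-SNE with perplexity {perplexity} needs >= {int(3 * perplexity)} frames, got {n}"
        )
    params = {"perplexity": perplexity, "seed": seed, "n_iter": n_iter}
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed,
                max_iter=n_iter, init="pca")
    coords = tsne.fit_transform(dataset.values)
    return EmbeddingResult(np.asarray(coords, dtype=float), dataset.meta.copy(),
                           "tsne", params)


@dataclass
class PcaReport:
    """Projection onto leading components plus their variances."""

    projection: np.ndarray  # (n_frames, n_components)
    explained_variance: np.ndarray  # absolute variance per component
    explained_variance_ratio: np.ndarray
    meta: pd.DataFrame


def pca_report(dataset: GestureDataset, n_components: int = 2) -> PcaReport:
    """PCA of the frame values; components ordered by decreasing variance."""
    if dataset.n_frames < 2:
        raise ValueError("PCA needs >= 2 frames")
    pca = PCA(n_components=n_components)
    proj = pca.fit_transform(dataset.values)
    return PcaReport(
        projection=proj,
        explained_variance=pca.explained_variance_.copy(),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        meta=dataset.meta.copy(),
    )


def variance_reduction(
    raw: GestureDataset, calibrated: GestureDataset, n_components: int = 2
) -> np.ndarray:
    """Per-component PCA variance reduction of calibration, in percent.

    Both datasets are PCA'd independently (each in its own leading-component
    basis) and the reduction ``100 * (1 - var_cal_k / var_raw_k)`` is
    reported per component rank ``k``. Requires identical frame keys.
    """
    if not raw.meta.astype(str).equals(calibrated.meta.astype(str)):
        raise IntegrityError("raw and calibrated datasets must hold the same frame keys")
    v_raw = pca_report(raw, n_components).explained_variance
    v_cal = pca_report(calibrated, n_components).explained_variance
    return 100.0 * (1.0 - v_cal / v_raw)


# ---------------------------------------------------------------------------
# cluster-structure statistics
# ---------------------------------------------------------------------------

def session_silhouette(emb: EmbeddingResult) -> float:
    """Mean silhouette of the embedding under session labels.

    Near 1 means sessions form well-separated clusters — the signature of
    placement-dominated variance.
    """
    from sklearn.metrics import silhouette_score

    labels = (emb.meta["subject"] + "/" + emb.meta["session"]).to_numpy()
    return float(silhouette_score(emb.coordinates, labels))


def iteration_trajectory_correlation(emb: EmbeddingResult, subject: str, session: str) -> float:
    """Monotone drift statistic for one session in an embedding.

    Computes per-iteration centroids, projects them onto the first-to-last
    centroid direction, and returns the Spearman correlation between
    iteration number and position along that direction. Positive values mean
    iterations progress consistently through the embedding — drift.
    """
    from scipy.stats import spearmanr

    sel = ((emb.meta["subject"] == subject) & (emb.meta["session"] == session)).to_numpy()
    if not sel.any():
        raise ValueError(f"session {subject}/{session} not in embedding")
    coords = emb.coordinates[sel]
    its = emb.meta.loc[sel, "iteration"].to_numpy()
    uniq = np.sort(np.unique(its))
    if len(uniq) < 3:
        raise ValueError("trajectory statistic needs >= 3 iterations")
    centroids = np.stack([coords[its == t].mean(axis=0) for t in uniq])
    direction = centroids[-1] - centroids[0]
    norm = np.linalg.norm(direction)
    if norm == 0:
        return 0.0
    pos = centroids @ (direction / norm)
    rho, _ = spearmanr(uniq, pos)
    return float(rho)


def within_group_dispersion(ds: GestureDataset) -> float:
    """Mean squared distance to the (session, class) group centroid.

    Computed in the original feature space; calibration should shrink it.
    """
    total = 0.0
    n = 0
    for _, idx in ds.meta.groupby(["subject", "session", "gesture"], sort=False).indices.items():
        v = ds.values[idx]
        total += ((v - v.mean(axis=0)) ** 2).sum()
        n += len(idx)
    return total / n
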