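"""Embedding conveniences around external t-SNE / UMAP routines.

These are presentation artifacts: 2-D embeddings of sessions (t-SNE on a
precomputed MMD distance matrix) or of window latents (UMAP, optionally on
a "strand-preserving" modified distance matrix in which the distance
between successive windows of the same motif is shrunk by 1e-3 so motifs
embed as continuous strands).  No quantitative claims should rest on the
embedded geometry beyond relative-distance sanity checks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist


def _check_square(M):
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(M, M.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    return M


def mmd_tsne(mmd_matrix, seed: int = 0, perplexity: float | None = None) -> np.ndarray:
    """2-D t-SNE of sessions with MMD as the precomputed distance.

    Returns an (n_sessions, 2) coordinate array in the input row order.
    Perplexity defaults to min(30, (n-1)/3) so small session sets work.
    """
    from sklearn.manifold import TSNE

    ids = None
    if isinstance(mmd_matrix, pd.DataFrame):
        ids = mmd_matrix.index
        mmd_matrix = mmd_matrix.to_numpy()
    M = _check_square(mmd_matrix)
    M = np.maximum(M, 0.0)
    n = len(M)
    if perplexity is None:
        perplexity = min(30.0, max(1.0, (n - 1) / 3.0))
    coords = TSNE(
        n_components=2,
        metric="precomputed",
        init="random",
        random_state=seed,
        perplexity=perplexity,
    ).fit_transform(M)
    if ids is not None:
        return pd.DataFrame(coords, index=ids, columns=["x", "y"])
    return coords


def strand_distance(latents, motif_ids, window_order, shrink: float = 1e-3):
    """Euclidean distances with successive same-motif windows pulled together.

    The full pairwise Euclidean matrix over rows of *latents* is computed;
    entries for windows (i, i+1) that are consecutive (by *window_order*)
    within the same motif are multiplied by *shrink*, symmetrically.
    Raises on duplicate order indices within a motif.
    """
    X = latents.to_numpy(dtype=float) if isinstance(latents, pd.DataFrame) else np.asarray(latents, dtype=float)
    motif_ids = np.asarray(motif_ids)
    window_order = np.asarray(window_order)
    if not (len(X) == len(motif_ids) == len(window_order)):
        raise ValueError("latents, motif_ids and window_order must align")
    D = squareform(pdist(X))
    for motif in np.unique(motif_ids):
        idx = np.where(motif_ids == motif)[0]
        order = window_order[idx]
        if len(np.unique(order)) != len(order):
            raise ValueError(f"duplicate window order index in motif {motif!r}")
        idx = idx[np.argsort(order)]
        consecutive = np.diff(window_order[idx]) == 1
        a, b = idx[:-1][consecutive], idx[1:][consecutive]
        D[a, b] *= shrink
        D[b, a] = D[a, b]
    return D


def umap_embed(X, seed: int = 0, precomputed: bool = False, **kwargs) -> np.ndarray:
    """Seeded 2-D UMAP of features or of a precomputed distance matrix."""
    import umap  # deferred: numba compilation is slow at import

    if precomputed:
        X = _check_square(X)
        kwargs.setdefault("metric", "precomputed")
    reducer = umap.UMAP(n_components=2, random_state=seed, **kwargs)
    return reducer.fit_transform(np.asarray(X, dtype=float))


def save_embedding_plot(coords, path, labels=None, title=""):
    """Scatter an embedding to PNG/SVG (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    coords = np.asarray(coords)
    fig, ax = plt.subplots(figsize=(5, 5))
    if labels is not None:
        labels = np.asarray(labels)
        for lab in np.unique(labels):
            m = labels == lab
            ax.scatter(coords[m, 0], coords[m, 1], s=8, label=str(lab))
        ax.legend(fontsize=7)
    else:
        ax.scatter(coords[:, 0], coords[:, 1], s=8)
    ax.set_title(title)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
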