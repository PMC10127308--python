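"""Dictionary-based texture segmentation of unfolded slices.

One unfolded slice inside the crystalline-cone layer is sparsely annotated
with two classes (background / cone).  All M×M patches of that slice are
intensity-normalized (patch mean subtracted) and clustered with k-means into
a patch dictionary.  Annotated pixel labels are propagated into per-(cluster,
within-patch-position) class weights in two accumulate/project steps; the
trained dictionary then densely segments every slice of every unfolded
sub-volume by projecting the weights back to pixels through each pixel's
patch assignments.

The training loop is non-interactive: the annotation is supplied as an image
(0 = unlabelled, 1 = background, 2 = cone), so the whole pipeline runs
headless and reproducibly.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import sparse
from sklearn.cluster import MiniBatchKMeans
from sklearn.metrics import pairwise_distances_argmin

__all__ = ["PatchDictionary", "build_dictionary", "train_propagation",
           "segment_stack", "annotation_from_mask"]


def _extract_patches(image: np.ndarray, M: int) -> np.ndarray:
    """All M×M patches (patch mean subtracted), shape (n_windows, M*M)."""
    from numpy.lib.stride_tricks import sliding_window_view

    win = sliding_window_view(np.asarray(image, float), (M, M))
    flat = win.reshape(-1, M * M)
    return flat - flat.mean(axis=1, keepdims=True)


class PatchDictionary:
    """Clustered bank of normalized M×M intensity patches with class weights.

    Parameters
    ----------
    patch_size : odd int
        Side length M of the square patches.
    n_clusters : int
        Requested number of k-means clusters K (capped at the number of
        extractable patches of the training slice).
    seed : int
        Seed for the k-means initialisation; fixes the dictionary exactly.
    """

    def __init__(self, patch_size: int = 9, n_clusters: int = 1000, seed: int = 0):
        if patch_size % 2 == 0 or patch_size < 3:
            raise ValueError("patch_size must be odd and >= 3")
        if n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        self.patch_size = int(patch_size)
        self.n_clusters = int(n_clusters)
        self.seed = int(seed)
        self.centres_: np.ndarray | None = None   # (K, M*M)
        self.weights_: np.ndarray | None = None   # (K * M*M, 2), rows sum to 1

    # -- construction ------------------------------------------------------

    def build(self, image: np.ndarray) -> "PatchDictionary":
        """Cluster all patches of ``image`` into the dictionary (untrained)."""
        image = np.asarray(image, float)
        M = self.patch_size
        if min(image.shape) <= M:
            raise ValueError(f"slice must be larger than {M}x{M}")
        patches = _extract_patches(image, M)
        if np.allclose(patches, 0):
            warnings.warn("constant training slice: no texture to cluster")
        k = min(self.n_clusters, len(patches))
        if k == len(patches):  # degenerate: every patch is its own cluster
            self.centres_ = patches.copy()
            return self
        km = MiniBatchKMeans(n_clusters=k, random_state=self.seed, n_init=3,
                             batch_size=1024, max_iter=100)
        km.fit(patches)
        self.centres_ = km.cluster_centers_
        return self

    def _assignments(self, image: np.ndarray) -> np.ndarray:
        patches = _extract_patches(image, self.patch_size)
        return pairwise_distances_argmin(patches, self.centres_)

    def _biadjacency(self, image: np.ndarray) -> sparse.csr_matrix:
        """Sparse pixel × (cluster, position) incidence matrix of ``image``.

        Window (r, c) assigned to cluster k links pixel (r + qr, c + qc) to
        dictionary entry (k, q) for every within-patch position q.
        """
        M = self.patch_size
        H, W = image.shape
        assign = self._assignments(image)
        nwr, nwc = H - M + 1, W - M + 1
        rr, cc = np.meshgrid(np.arange(nwr), np.arange(nwc), indexing="ij")
        rr, cc = rr.ravel(), cc.ravel()
        n_entries = len(self.centres_) * M * M
        rows, cols = [], []
        for q in range(M * M):
            qr, qc = divmod(q, M)
            rows.append((rr + qr) * W + (cc + qc))
            cols.append(assign * (M * M) + q)
        B = sparse.coo_matrix(
            (np.ones(len(rr) * M * M), (np.concatenate(rows), np.concatenate(cols))),
            shape=(H * W, n_entries))
        return B.tocsr()

    @staticmethod
    def _row_normalize(A):
        if sparse.issparse(A):
            s = np.asarray(A.sum(axis=1)).ravel()
            s[s == 0] = 1.0
            return sparse.diags(1.0 / s) @ A
        s = A.sum(axis=1, keepdims=True)
        return np.divide(A, np.where(s == 0, 1.0, s))

    # -- training ----------------------------------------------------------

    def train(self, image: np.ndarray, annotation: np.ndarray) -> "PatchDictionary":
        """Propagate a sparse two-class annotation into dictionary class weights.

        ``annotation`` codes: 0 unlabelled, 1 background, 2 cone.  Two
        accumulate/project rounds: labels → dictionary weights → dense pixel
        probabilities → dictionary weights, normalized per (cluster, position).
        """
        if self.centres_ is None:
            self.build(image)
        ann = np.asarray(annotation)
        if ann.shape != np.asarray(image).shape:
            raise ValueError("annotation shape must match the slice")
        if not ((ann == 1).any() and (ann == 2).any()):
            raise ValueError("annotation needs at least one pixel of each class")
        L = np.zeros((ann.size, 2))
        L[ann.ravel() == 1, 0] = 1.0
        L[ann.ravel() == 2, 1] = 1.0

        B = self._biadjacency(image)
        T_pix = self._row_normalize(B)        # pixel <- dictionary averaging
        T_dict = self._row_normalize(B.T.tocsr())  # dictionary <- pixel averaging

        W1 = T_dict @ L
        P1 = T_pix @ W1
        W2 = T_dict @ self._row_normalize(P1)
        W2 = self._row_normalize(W2)
        W2[W2.sum(axis=1) == 0] = 0.5  # positions never seen: uninformative
        self.weights_ = W2
        return self

    # -- inference ---------------------------------------------------------

    def probability(self, image: np.ndarray) -> np.ndarray:
        """Per-pixel cone-class probability map of one slice."""
        if self.weights_ is None:
            raise ValueError("dictionary is untrained; call train() first")
        image = np.asarray(image, float)
        B = self._biadjacency(image)
        P = self._row_normalize(B) @ self.weights_
        # rows are convex combinations of weight rows, so they sum to 1;
        # clip float round-off so thresholds at 0 and 1 behave exactly
        return np.clip(P[:, 1].reshape(image.shape), 0.0, 1.0)

    def segment_slice(self, image: np.ndarray, p_threshold: float = 0.5) -> np.ndarray:
        return self.probability(image) > p_threshold

    def segment_stack(self, unfolded, p_threshold: float = 0.5) -> np.ndarray:
        """Binary cone mask for every (u, v) slice of an unfolded volume."""
        data = unfolded.data if hasattr(unfolded, "depth_range") else np.asarray(unfolded)
        out = np.zeros(data.shape, dtype=np.uint8)
        for iw in range(data.shape[2]):
            out[:, :, iw] = self.segment_slice(data[:, :, iw], p_threshold)
        return out

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        np.savez_compressed(path, patch_size=self.patch_size, n_clusters=self.n_clusters,
                            seed=self.seed, centres=self.centres_, weights=self.weights_)

    @classmethod
    def load(cls, path) -> "PatchDictionary":
        d = np.load(path, allow_pickle=False)
        obj = cls(int(d["patch_size"]), int(d["n_clusters"]), int(d["seed"]))
        obj.centres_ = d["centres"]
        obj.weights_ = d["weights"] if d["weights"].ndim else None
        return obj


# -- functional wrappers ----------------------------------------------------

def build_dictionary(image: np.ndarray, patch_size: int = 9, n_clusters: int = 1000,
                     seed: int = 0) -> PatchDictionary:
    return PatchDictionary(patch_size, n_clusters, seed).build(image)


def train_propagation(dictionary: PatchDictionary, image: np.ndarray,
                      annotation: np.ndarray) -> PatchDictionary:
    return dictionary.train(image, annotation)


def segment_stack(dictionary: PatchDictionary, unfolded, p_threshold: float = 0.5) -> np.ndarray:
    return dictionary.segment_stack(unfolded, p_threshold)


def annotation_from_mask(mask: np.ndarray, fraction: float = 1.0,
                         seed: int = 0) -> np.ndarray:
    """Turn a binary cone mask into an annotation image (1 = background, 2 = cone).

    With ``fraction < 1`` only a random subset of pixels is labelled,
    emulating a sparse manual annotation.
    """
    mask = np.asarray(mask).astype(bool)
    ann = np.where(mask, 2, 1).astype(np.uint8)
    if fraction < 1.0:
        rng = np.random.default_rng(seed)
        ann[rng.random(mask.shape) > fraction] = 0
    return ann
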