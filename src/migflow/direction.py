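"""Disorderedness statistics of flow fields.

The migration axis is x (posterior = +x). Each flow vector is binarized to
'left' (vx < 0, anterior) or 'right' (vx > 0, posterior); exact zeros carry
no direction and are excluded. The pooled left fraction p̂ = n_left /
(n_left + n_right) is the MLE of a Bernoulli parameter, and the binary
entropy H(p̂) = −p̂·log2 p̂ − (1−p̂)·log2(1−p̂) measures disorderedness: 1 bit
at p̂ = 0.5 (fully bidirectional), 0 when every vector agrees.

κ is a frame-specific scale — the 0.9-quantile of vector norms — used to
normalize magnitudes before cross-frame pooling. The 1D variance share
Varx/(Varx+Vary) of the vectors whose norm exceeds the 0.2-quantile
measures how much of the motion variance lies along the migration axis.
"""

from __future__ import annotations

import numpy as np

from .datatypes import DirectionSummary, ParameterError, VectorField

__all__ = [
    "kappa",
    "variance_share",
    "component_variance_share",
    "magnitude_filter_vectors",
    "binarize_directions",
    "estimate_p",
    "binary_entropy",
    "summarize_directionality",
]

#: quantile level of the frame-specific normalization factor κ
KAPPA_QUANTILE = 0.9
#: quantile level of the magnitude filter applied before variance/binarization
MAGNITUDE_QUANTILE = 0.2


def _vectors_of(field: VectorField | np.ndarray) -> np.ndarray:
    if isinstance(field, VectorField):
        return field.valid_vectors()
    v = np.asarray(field, float)
    if v.ndim != 2 or v.shape[1] != 2:
        raise ParameterError("expected an (N, 2) array of vectors")
    return v


def kappa(field: VectorField | np.ndarray) -> float:
    """Frame normalization factor: 0.9-quantile of valid-vector norms.

    Uses the linear-interpolation quantile convention (the numpy default),
    e.g. norms {1, …, 10} give κ = 9.1.
    """
    v = _vectors_of(field)
    if v.shape[0] < 1:
        raise ParameterError("kappa needs at least one valid vector")
    norms = np.hypot(v[:, 0], v[:, 1])
    return float(np.quantile(norms, KAPPA_QUANTILE))


def magnitude_filter_vectors(vectors: np.ndarray) -> np.ndarray:
    """Retain vectors whose norm strictly exceeds the 0.2-quantile of norms."""
    vectors = np.asarray(vectors, float)
    norms = np.hypot(vectors[:, 0], vectors[:, 1])
    if norms.size == 0:
        return vectors
    q = np.quantile(norms, MAGNITUDE_QUANTILE)
    return vectors[norms > q]


def component_variance_share(vectors: np.ndarray) -> float:
    """Varx / (Varx + Vary) of an already-filtered vector set.

    Sample variances (ddof = 1). Returns NaN (undefined) when the total
    variance is zero; raises when fewer than two vectors are supplied.
    """
    vectors = np.asarray(vectors, float)
    if vectors.shape[0] < 2:
        raise ParameterError("variance share needs >= 2 vectors")
    var_x = float(np.var(vectors[:, 0], ddof=1))
    var_y = float(np.var(vectors[:, 1], ddof=1))
    total = var_x + var_y
    if total == 0.0:
        return float("nan")
    return var_x / total


def variance_share(field: VectorField | np.ndarray) -> float:
    """Magnitude-filtered 1D variance share of a flow field.

    Vectors with norm above the 0.2-quantile are retained; the share is
    Varx/(Varx+Vary) of the retained components.
    """
    v = magnitude_filter_vectors(_vectors_of(field))
    return component_variance_share(v)


def binarize_directions(
    field: VectorField | np.ndarray, magnitude_filter: bool = True
) -> tuple[int, int]:
    """Count (n_left, n_right) directions of a field's vectors.

    With ``magnitude_filter`` the Q0.2 norm filter is applied first.
    vx = 0 vectors belong to neither class and are excluded.
    """
    v = _vectors_of(field)
    if v.shape[0] < 1:
        raise ParameterError("binarize_directions needs at least one valid vector")
    if magnitude_filter:
        v = magnitude_filter_vectors(v)
    n_left = int(np.sum(v[:, 0] < 0))
    n_right = int(np.sum(v[:, 0] > 0))
    if n_left + n_right == 0:
        raise ParameterError("all vectors excluded (zero or filtered out)")
    return n_left, n_right


def estimate_p(n_left: int, n_right: int) -> float:
    """Bernoulli MLE of the left-direction probability: n_left / total."""
    if n_left < 0 or n_right < 0:
        raise ParameterError("counts must be non-negative")
    total = n_left + n_right
    if total == 0:
        raise ParameterError("cannot estimate p from zero counts")
    return n_left / total


def binary_entropy(p: float) -> float:
    """Binary entropy H(p) in bits: −p·log2 p − (1−p)·log2(1−p).

    0·log2 0 is taken as 0, so H(0) = H(1) = 0 and H(0.5) = 1 exactly.
    """
    if not (0.0 <= p <= 1.0) or not np.isfinite(p):
        raise ParameterError(f"p must lie in [0, 1], got {p}")
    h = 0.0
    if p > 0.0:
        h -= p * np.log2(p)
    if p < 1.0:
        h -= (1.0 - p) * np.log2(1.0 - p)
    return float(h)


def _vote_masks(
    fields: list[VectorField], magnitude_filter: bool, persistence: bool
) -> list[np.ndarray]:
    """Grid-shaped boolean masks of the cells allowed to vote per field.

    A cell votes when it is valid, passes the per-field Q0.2 norm filter
    (if enabled) and has a nonzero x sign. With ``persistence``, the sign
    must additionally agree with the same grid cell's sign in the previous
    or next frame pair: migrating cells move persistently, while transient
    sign flips (crossing/merging cells, noise) do not.
    """
    signs = []
    for f in fields:
        norms = np.hypot(f.vx, f.vy)
        vn = norms[f.valid]
        ok = f.valid.copy()
        if magnitude_filter and vn.size:
            ok &= norms > np.quantile(vn, MAGNITUDE_QUANTILE)
        signs.append(np.where(ok, np.sign(f.vx), 0.0))
    masks = []
    n = len(fields)
    for i, s in enumerate(signs):
        vote = s != 0
        if persistence and n > 1:
            agree = np.zeros_like(vote)
            if i > 0:
                agree |= signs[i - 1] == s
            if i < n - 1:
                agree |= signs[i + 1] == s
            vote &= agree
        masks.append(vote)
    return masks


def summarize_directionality(
    fields: list[VectorField],
    magnitude_filter: bool = True,
    kappa_normalize: bool = True,
    weights: list[np.ndarray] | None = None,
    persistence: bool = False,
) -> DirectionSummary:
    """Pool a flow-field sequence into one per-sample direction summary.

    Left/right counts are pooled across frame pairs before p̂ and entropy.
    ``weights`` (optional, one grid-shaped array per field) weight each
    cell's vote — e.g. by the foreground fluorescence mass under the
    cell's window, so that a tight cluster of cells counts by its cell
    content rather than by the area it covers. ``persistence`` requires a
    cell's direction to repeat in an adjacent frame pair before it votes
    (see :func:`_vote_masks`). For the pooled variance share, each frame's
    vectors are divided by that frame's κ (when ``kappa_normalize``) and
    magnitude-filtered per frame, then pooled. Fields with no valid
    vectors are skipped (an error is raised only if *no* field
    contributes).
    """
    if len(fields) < 1:
        raise ParameterError("need at least one flow field")
    if weights is not None and len(weights) != len(fields):
        raise ParameterError("weights must align one-to-one with fields")
    grid_input = all(isinstance(f, VectorField) for f in fields)
    if (persistence or weights is not None) and not grid_input:
        raise ParameterError(
            "weights/persistence need grid-shaped VectorField inputs"
        )
    vote_masks = (
        _vote_masks(fields, magnitude_filter, persistence) if grid_input else None
    )
    kappas: list[float] = []
    n_left = n_right = 0.0
    pooled: list[np.ndarray] = []
    for i, f in enumerate(fields):
        v = f.valid_vectors() if isinstance(f, VectorField) else np.asarray(f, float)
        if v.shape[0] == 0:
            kappas.append(float("nan"))
            continue
        k = kappa(v)
        kappas.append(k)
        if vote_masks is not None:
            m = vote_masks[i]
            if weights is not None:
                w = np.asarray(weights[i], float)
                if w.shape != m.shape:
                    raise ParameterError(
                        f"field {i}: weights shape {w.shape} != grid {m.shape}"
                    )
            else:
                w = np.ones_like(f.vx)
            nl = float(w[m & (f.vx < 0)].sum())
            nr = float(w[m & (f.vx > 0)].sum())
        else:
            try:
                nl, nr = binarize_directions(v, magnitude_filter=magnitude_filter)
            except ParameterError:
                nl = nr = 0
        n_left += nl
        n_right += nr
        vn = v / k if (kappa_normalize and k > 0) else v
        pooled.append(magnitude_filter_vectors(vn))
    if n_left + n_right <= 0:
        raise ParameterError("no directed vectors in any field")
    p_hat = estimate_p(n_left, n_right)
    entropy = binary_entropy(p_hat)
    pooled_v = np.concatenate(pooled) if pooled else np.empty((0, 2))
    share = (
        component_variance_share(pooled_v) if pooled_v.shape[0] >= 2 else float("nan")
    )
    return DirectionSummary(
        kappa_per_frame=np.asarray(kappas),
        variance_share_x=share,
        n_left=n_left,
        n_right=n_right,
        p_hat=p_hat,
        entropy_bits=entropy,
    )
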